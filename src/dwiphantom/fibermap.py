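"""Per-voxel streamline segment-direction fields.

Every consecutive point pair of a streamline is one segment; a segment is
assigned to the voxel containing its midpoint and contributes its normalized
direction.  The white-matter attenuation of a voxel is the arithmetic mean of
the single-fiber WM attenuation over that voxel's segment directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

from .compartments import (
    PulseParams,
    TissueModelSet,
    attenuation_compartment,
    attenuation_tissue,
)
from .substrate import TissueFractionMap, Tractogram

logger = logging.getLogger(__name__)

__all__ = ["SegmentDirectionField", "assign_segments", "wm_attenuation_voxel",
           "wm_attenuation_volume"]


@dataclass
class SegmentDirectionField:
    """Bag of unit segment directions per voxel.

    ``directions[i]`` belongs to the voxel with flat index ``voxel_flat[i]``
    (C-order over ``grid_shape``); ``counts`` is the per-voxel tally and
    ``n_dropped`` the number of segments whose midpoint fell outside the grid.
    """

    grid_shape: Tuple[int, int, int]
    affine: np.ndarray
    directions: np.ndarray  # (S, 3), unit norm
    voxel_flat: np.ndarray  # (S,), int
    counts: np.ndarray  # grid_shape, int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if len(self.directions) != len(self.voxel_flat):
            raise ValueError("directions and voxel_flat length mismatch")
        if self.directions.size:
            norms = np.linalg.norm(self.directions, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise ValueError("segment directions must be unit-norm")
        if int(self.counts.sum()) != len(self.directions):
            raise ValueError("counts do not match the number of stored segments")

    @property
    def n_segments(self) -> int:
        return len(self.directions)

    def segment_directions(self, voxel: Tuple[int, int, int]) -> np.ndarray:
        flat = np.ravel_multi_index(voxel, self.grid_shape)
        return self.directions[self.voxel_flat == flat]

    def count_map_image(self) -> "nib.Nifti1Image":
        """Per-voxel segment-count map as NIfTI, for QC."""
        return nib.Nifti1Image(self.counts.astype(np.int32), self.affine)


def assign_segments(
    tractogram: Tractogram, grid: TissueFractionMap
) -> SegmentDirectionField:
    """Assign every streamline segment to the voxel containing its midpoint.

    Segments whose midpoint lies outside the grid are dropped and tallied.
    """
    shape = grid.grid_shape
    mids = []
    dirs = []
    for s in tractogram.streamlines:
        d = np.diff(s, axis=0)
        mids.append((s[:-1] + s[1:]) / 2.0)
        dirs.append(d / np.linalg.norm(d, axis=1, keepdims=True))
    if mids:
        mids_arr = np.vstack(mids)
        dirs_arr = np.vstack(dirs)
    else:
        mids_arr = np.empty((0, 3))
        dirs_arr = np.empty((0, 3))

    # voxel centers at integer indices: the containing cell is the nearest index
    cont = grid.world_to_voxel(mids_arr) if len(mids_arr) else np.empty((0, 3))
    idx = np.floor(cont + 0.5).astype(int) if len(cont) else np.empty((0, 3), int)
    inside = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1) if len(idx) \
        else np.zeros(0, dtype=bool)
    n_dropped = int(len(idx) - inside.sum())
    if n_dropped:
        logger.info("dropped %d segment(s) outside the grid", n_dropped)

    idx_in = idx[inside]
    flat = (
        np.ravel_multi_index(idx_in.T, shape) if len(idx_in) else np.empty(0, int)
    )
    counts = np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape)
    return SegmentDirectionField(
        grid_shape=shape,
        affine=grid.affine,
        directions=dirs_arr[inside],
        voxel_flat=flat,
        counts=counts,
        n_dropped=n_dropped,
    )


def wm_attenuation_voxel(
    field: SegmentDirectionField,
    voxel: Tuple[int, int, int],
    models: TissueModelSet,
    pulse: PulseParams,
    grad_dir: np.ndarray,
    fallback_powder: bool = False,
) -> float:
    """Mean single-fiber WM attenuation over a voxel's segment directions.

    With no segments in the voxel, either raises (default) or falls back to
    the orientation (powder) average of the WM model.
    """
    dirs = field.segment_directions(voxel)
    if len(dirs) == 0:
        if not fallback_powder:
            raise ValueError(f"no streamline segments in voxel {tuple(voxel)}")
        logger.info("voxel %s has no segments; using powder average", tuple(voxel))
        return attenuation_tissue("WM", models, pulse, grad_dir,
                                  powder_average=True)
    spec = models.spec("WM")
    vals = [attenuation_compartment(spec, pulse, grad_dir, d) for d in dirs]
    return float(np.mean(vals))


def _wm_log_components(
    models: TissueModelSet, pulse: PulseParams
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-compartment (weight, parallel log-slope, perpendicular log-atten).

    Both WM compartments factor as
    ``A = exp(cos2 * log_par + (1 - cos2) * log_perp)`` with ``cos2`` the
    squared cosine between fiber and gradient, which lets the volume
    evaluation reduce to one dot product per segment per direction.
    """
    from .compartments import b_value, cylinder_perp_log_attenuation

    spec = models.spec("WM")
    if spec.kind == "mixture":
        children, weights = spec.children, spec.weights
    else:
        children, weights = (spec,), (1.0,)
    b = b_value(pulse)
    ws, log_par, log_perp = [], [], []
    for child, w in zip(children, weights):
        ws.append(w)
        if child.kind == "zeppelin":
            log_par.append(-b * child.d_par)
            log_perp.append(-b * child.d_perp)
        elif child.kind == "cylinder":
            log_par.append(-b * child.d)
            log_perp.append(cylinder_perp_log_attenuation(child.d, child.radius,
                                                          pulse))
        elif child.kind == "isotropic":
            log_par.append(-b * child.md)
            log_perp.append(-b * child.md)
        else:
            raise ValueError(f"cannot vectorize WM compartment {child.kind!r}")
    return np.asarray(ws), np.asarray(log_par), np.asarray(log_perp)


def wm_attenuation_volume(
    field: SegmentDirectionField,
    models: TissueModelSet,
    pulse: PulseParams,
    grad_dir: np.ndarray,
    fallback_powder_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Vectorized per-voxel WM attenuation for one gradient direction.

    Voxels with zero segments get the powder-average value where
    ``fallback_powder_mask`` is set and NaN elsewhere.  Matches
    :func:`wm_attenuation_voxel` exactly on populated voxels.
    """
    g = np.asarray(grad_dir, dtype=float)
    g = g / np.linalg.norm(g)
    ws, log_par, log_perp = _wm_log_components(models, pulse)

    out = np.full(field.grid_shape, np.nan)
    flat_out = out.reshape(-1)
    if field.n_segments:
        cos2 = (field.directions @ g) ** 2  # (S,)
        att = (
            np.exp(cos2[:, None] * log_par[None, :]
                   + (1.0 - cos2)[:, None] * log_perp[None, :])
            @ ws
        )
        sums = np.bincount(field.voxel_flat, weights=att,
                           minlength=flat_out.size)
        populated = field.counts.reshape(-1) > 0
        flat_out[populated] = sums[populated] / field.counts.reshape(-1)[populated]

    if fallback_powder_mask is not None:
        need = fallback_powder_mask.reshape(-1) & ~(field.counts.reshape(-1) > 0)
        if np.any(need):
            pa = attenuation_tissue("WM", models, pulse, g, powder_average=True)
            flat_out[need] = pa
    return out
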