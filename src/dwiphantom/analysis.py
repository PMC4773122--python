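"""Validation-side estimators: DTI fitting, mixture recovery, connectomes.

These close the loop on simulated data: signals generated with a built-in
tissue preset and re-fit here must return the preset parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .compartments import B_PER_MM2_TO_SI
from .scanner import GradientScheme
from .substrate import Tractogram

__all__ = ["TensorFit", "ConnectivityMatrix", "fit_dti", "recover_fraction",
           "connectivity_matrix"]


@dataclass
class TensorFit:
    """Per-voxel diffusion tensors with rotation-invariant scalars (SI units)."""

    tensors: np.ndarray  # (..., 3, 3) symmetric
    md: np.ndarray  # (...,), m^2/s
    fa: np.ndarray  # (...,), in [0, 1]
    s0: np.ndarray  # (...,)
    valid: np.ndarray  # (...,) bool; False where the fit was impossible


def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    b = scheme.bvals * B_PER_MM2_TO_SI  # s/m^2
    g = scheme.bvecs
    return np.column_stack(
        [
            np.ones(len(scheme)),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2.0 * b * g[:, 0] * g[:, 1],
            -2.0 * b * g[:, 0] * g[:, 2],
            -2.0 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_dti(signals: np.ndarray, scheme: GradientScheme) -> TensorFit:
    """Ordinary-least-squares log-linear tensor fit.

    ``signals`` has the acquisition as its last axis.  Voxels with any
    non-positive signal are flagged invalid and excluded (their outputs are
    zero).  Requires >= 6 non-collinear DW directions plus >= 1 b = 0.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != len(scheme):
        raise ValueError("signal count must equal the scheme length")
    if np.sum(scheme.bvals > 0) < 6:
        raise ValueError("need at least 6 diffusion-weighted measurements")

    X = _design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("gradient scheme is rank-deficient (collinear directions)")

    lead_shape = signals.shape[:-1]
    flat = signals.reshape(-1, len(scheme))
    valid = np.all(flat > 0, axis=1)

    coeffs = np.zeros((flat.shape[0], 7))
    if np.any(valid):
        y = np.log(flat[valid])
        sol, *_ = np.linalg.lstsq(X, y.T, rcond=None)
        coeffs[valid] = sol.T

    dxx, dyy, dzz, dxy, dxz, dyz = (coeffs[:, i] for i in range(1, 7))
    tensors = np.zeros((flat.shape[0], 3, 3))
    tensors[:, 0, 0], tensors[:, 1, 1], tensors[:, 2, 2] = dxx, dyy, dzz
    tensors[:, 0, 1] = tensors[:, 1, 0] = dxy
    tensors[:, 0, 2] = tensors[:, 2, 0] = dxz
    tensors[:, 1, 2] = tensors[:, 2, 1] = dyz

    evals = np.linalg.eigvalsh(tensors)
    md = evals.mean(axis=1)
    num = np.sqrt(((evals - md[:, None]) ** 2).sum(axis=1))
    den = np.sqrt((evals**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
    fa = np.clip(np.nan_to_num(fa), 0.0, 1.0)

    s0 = np.exp(coeffs[:, 0])
    s0[~valid] = 0.0
    md[~valid] = 0.0
    fa[~valid] = 0.0
    tensors[~valid] = 0.0
    return TensorFit(
        tensors=tensors.reshape(lead_shape + (3, 3)),
        md=md.reshape(lead_shape),
        fa=fa.reshape(lead_shape),
        s0=s0.reshape(lead_shape),
        valid=valid.reshape(lead_shape),
    )


def recover_fraction(
    observed: np.ndarray, basis_a: np.ndarray, basis_b: np.ndarray
) -> float:
    """Least-squares weight w of ``observed = w * A + (1 - w) * B``.

    Clipped to [0, 1]; exact when the observation was generated by the
    mixture.  Identical bases are non-identifiable and raise.
    """
    a = np.asarray(basis_a, dtype=float).ravel()
    b = np.asarray(basis_b, dtype=float).ravel()
    y = np.asarray(observed, dtype=float).ravel()
    if y.shape != a.shape or a.shape != b.shape:
        raise ValueError("observed and basis signals must share one shape")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    d = a - b
    denom = float(d @ d)
    if denom <= 1e-30 * float(a @ a + b @ b + 1e-300):
        raise ValueError("basis signals are identical; weight is non-identifiable")
    w = float((y - b) @ d) / denom
    return min(1.0, max(0.0, w))


@dataclass
class ConnectivityMatrix:
    """Symmetric streamline-count matrix over integer parcel labels."""

    labels: np.ndarray  # (n_parcels,) parcel ids, sorted
    counts: np.ndarray  # (n_parcels, n_parcels) symmetric, zero diagonal
    n_skipped: int = 0  # streamlines without two valid, distinct parcels

    def __post_init__(self) -> None:
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if np.any(np.diag(self.counts) != 0):
            raise ValueError("diagonal must be zero (self-connections excluded)")

    def binarize(self, threshold: int = 1) -> np.ndarray:
        """Binary adjacency: 1 where counts >= threshold."""
        return (self.counts >= threshold).astype(np.int8)


def connectivity_matrix(
    tractogram: Tractogram,
    parcel_labels: np.ndarray,
    affine: np.ndarray,
    mode: str = "endpoint",
) -> ConnectivityMatrix:
    """Streamline-count connectivity over an integer label volume.

    ``endpoint`` mode (default): each streamline increments the pair given by
    the parcels at its two endpoints, once, if both are valid (> 0) and
    distinct.  ``passthrough`` mode increments every pair of distinct parcels
    the streamline visits.  Streamlines with an endpoint outside the grid are
    skipped and tallied.
    """
    if mode not in ("endpoint", "passthrough"):
        raise ValueError("mode must be 'endpoint' or 'passthrough'")
    labels_vol = np.asarray(parcel_labels)
    if labels_vol.ndim != 3:
        raise ValueError("parcel labels must be a 3D integer volume")
    inv = np.linalg.inv(np.asarray(affine, dtype=float))
    shape = np.asarray(labels_vol.shape)

    parcel_ids = np.unique(labels_vol)
    parcel_ids = parcel_ids[parcel_ids > 0]
    index = {int(p): i for i, p in enumerate(parcel_ids)}
    n = len(parcel_ids)
    counts = np.zeros((n, n), dtype=np.int64)
    n_skipped = 0

    def lookup(points: np.ndarray) -> Optional[np.ndarray]:
        vox = np.floor(points @ inv[:3, :3].T + inv[:3, 3] + 0.5).astype(int)
        if np.any(vox < 0) or np.any(vox >= shape):
            return None
        return labels_vol[vox[:, 0], vox[:, 1], vox[:, 2]]

    for s in tractogram.streamlines:
        pts = s if mode == "passthrough" else s[[0, -1]]
        lab = lookup(pts)
        if lab is None:
            n_skipped += 1
            continue
        visited = np.unique(lab[lab > 0])
        if mode == "endpoint":
            if len(lab) != 2 or lab[0] <= 0 or lab[1] <= 0 or lab[0] == lab[1]:
                n_skipped += 1
                continue
            pairs = [(int(lab[0]), int(lab[1]))]
        else:
            if len(visited) < 2:
                n_skipped += 1
                continue
            pairs = [
                (int(a), int(b))
                for ii, a in enumerate(visited)
                for b in visited[ii + 1 :]
            ]
        for a, b in pairs:
            ia, ib = index[a], index[b]
            counts[ia, ib] += 1
            counts[ib, ia] += 1

    return ConnectivityMatrix(labels=parcel_ids, counts=counts, n_skipped=n_skipped)
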