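"""Synthetic brain-like substrates and standard-format I/O.

Generates the two inputs the simulator needs — a 4-class tissue
volume-fraction map (WM, cortical GM, deep GM, CSF) and a white-matter
streamline tractogram — from a parametric recipe, so the full pipeline is
testable without any external data.  Real inputs in NIfTI / TCK / TRK are
read and written through nibabel.

Geometry convention: voxel indices are 0-based, a voxel's world position is
the center of its cell, and streamlines live in world millimeters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Mapping, Optional, Sequence, Tuple, Union

import nibabel as nib
import numpy as np

from .compartments import TISSUES

logger = logging.getLogger(__name__)

__all__ = [
    "TissueFractionMap",
    "Tractogram",
    "BundleSpec",
    "SubstrateRecipe",
    "generate_numerical_brain",
    "toy_parcellation",
    "read_fraction_map",
    "write_fraction_map",
    "read_tractogram",
    "write_tractogram",
]

_SUM_TOL = 1.0e-6

# tissue indices into the 4th axis of the fraction array
WM, CGM, DGM, CSF = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TissueFractionMap:
    """Per-voxel tissue volume fractions on a regular grid.

    ``fractions`` has shape ``grid_shape + (4,)`` ordered (WM, CGM, DGM, CSF);
    fractions sum to 1 inside ``brain_mask`` and to 0 outside.
    """

    fractions: np.ndarray
    affine: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        self.validate()

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.fractions.shape[:3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def validate(self) -> None:
        f = self.fractions
        if f.ndim != 4 or f.shape[3] != 4:
            raise ValueError(
                f"fractions must have shape (X, Y, Z, 4) for tissues {TISSUES}, "
                f"got {f.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.brain_mask.shape != f.shape[:3]:
            raise ValueError("brain_mask shape must match the grid")
        n_neg = int(np.sum(np.any(f < -_SUM_TOL, axis=-1)))
        if n_neg:
            raise ValueError(f"negative tissue fractions in {n_neg} voxel(s)")
        n_big = int(np.sum(np.any(f > 1.0 + _SUM_TOL, axis=-1)))
        if n_big:
            raise ValueError(f"tissue fractions > 1 in {n_big} voxel(s)")
        s = f.sum(axis=-1)
        bad_in = int(np.sum(np.abs(s[self.brain_mask] - 1.0) > _SUM_TOL))
        if bad_in:
            raise ValueError(
                f"fractions do not sum to 1 in {bad_in} in-mask voxel(s)"
            )
        bad_out = int(np.sum(np.abs(s[~self.brain_mask]) > _SUM_TOL))
        if bad_out:
            raise ValueError(
                f"nonzero fractions in {bad_out} voxel(s) outside the brain mask"
            )

    def tissue(self, name: str) -> np.ndarray:
        """Scalar fraction field for one tissue class."""
        return self.fractions[..., TISSUES.index(name)]

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world-mm points."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class Tractogram:
    """Streamlines as ordered 3D point lists in world millimeters."""

    streamlines: List[np.ndarray]
    nominal_step_mm: float = 0.7

    def __post_init__(self) -> None:
        if self.nominal_step_mm <= 0:
            raise ValueError("nominal_step_mm must be positive")
        self.streamlines = [
            np.asarray(s, dtype=float).reshape(-1, 3) for s in self.streamlines
        ]
        for s in self.streamlines:
            if len(s) < 2:
                raise ValueError("each streamline needs >= 2 points")
            if np.any(np.all(np.diff(s, axis=0) == 0.0, axis=1)):
                raise ValueError("consecutive streamline points must be distinct")

    def __len__(self) -> int:
        return len(self.streamlines)

    @property
    def n_segments(self) -> int:
        return sum(len(s) - 1 for s in self.streamlines)

    def mean_step_mm(self) -> float:
        total, n = 0.0, 0
        for s in self.streamlines:
            d = np.linalg.norm(np.diff(s, axis=0), axis=1)
            total += d.sum()
            n += len(d)
        return total / max(n, 1)


# ---------------------------------------------------------------------------
# Recipe
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BundleSpec:
    """One white-matter bundle archetype.

    kinds: ``straight`` (axis tube), ``crossing`` (two straight tubes meeting
    at ``angle_deg`` in the plane normal to ``plane_normal``), ``arc``
    (circular tube), ``kissing`` (two arcs tangent at ``center_mm``, curving
    apart).
    """

    kind: str
    radius_mm: float
    n_streamlines: int
    center_mm: Tuple[float, float, float]
    direction: Tuple[float, float, float] = (1.0, 0.0, 0.0)
    length_mm: float = 20.0
    angle_deg: float = 90.0
    arc_radius_mm: float = 12.0
    arc_span_deg: float = 120.0
    plane_normal: Tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.kind not in ("straight", "crossing", "arc", "kissing"):
            raise ValueError(f"unknown bundle kind {self.kind!r}")
        if self.radius_mm <= 0 or self.n_streamlines < 1:
            raise ValueError("bundle needs radius_mm > 0 and n_streamlines >= 1")
        if self.kind == "crossing" and not (0.0 < self.angle_deg <= 90.0):
            raise ValueError("crossing angle must lie in (0, 90] degrees")


@dataclass(frozen=True)
class SubstrateRecipe:
    """Parametric description of a synthetic numerical brain."""

    grid_shape: Tuple[int, int, int] = (40, 40, 40)
    voxel_size_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    rng_seed: int = 0
    bundles: Tuple[BundleSpec, ...] = ()
    brain_semiaxes_mm: Optional[Tuple[float, float, float]] = None
    csf_center_mm: Optional[Tuple[float, float, float]] = None
    csf_radii_mm: Tuple[float, float, float] = (4.0, 3.0, 3.0)
    gm_rim_mm: float = 2.0
    dgm_blobs: Tuple[Tuple[Tuple[float, float, float], float], ...] = ()
    nominal_step_mm: float = 0.7

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.voxel_size_mm)

    @property
    def center_mm(self) -> np.ndarray:
        # voxel centers span [0, (N-1)*vox]; grid center in world mm
        return (np.asarray(self.grid_shape) - 1) * np.asarray(self.voxel_size_mm) / 2.0

    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0], a[1, 1], a[2, 2] = self.voxel_size_mm
        return a

    @classmethod
    def default(
        cls, grid_shape: Tuple[int, int, int] = (40, 40, 40), rng_seed: int = 0
    ) -> "SubstrateRecipe":
        """Two bundles crossing at 90 deg plus an arc, CSF cavity, DGM blobs."""
        shape = np.asarray(grid_shape)
        vox = np.ones(3)
        c = (shape - 1) / 2.0  # world mm with unit voxels
        scale = float(shape.min()) / 40.0
        lo = c - np.array([0.0, 0.0, 0.25 * shape[2]])  # crossing plane, lower z
        return cls(
            grid_shape=tuple(int(s) for s in shape),
            voxel_size_mm=(1.0, 1.0, 1.0),
            rng_seed=rng_seed,
            bundles=(
                BundleSpec(
                    kind="crossing",
                    radius_mm=2.5 * scale,
                    n_streamlines=int(400 * scale**2),
                    center_mm=tuple(lo),
                    angle_deg=90.0,
                    length_mm=22.0 * scale,
                ),
                BundleSpec(
                    kind="arc",
                    radius_mm=2.0 * scale,
                    n_streamlines=int(250 * scale**2),
                    center_mm=tuple(c + np.array([0.0, -6.0, -2.0]) * scale),
                    arc_radius_mm=8.0 * scale,
                    arc_span_deg=150.0,
                    plane_normal=(0.0, 1.0, 0.0),
                ),
            ),
            brain_semiaxes_mm=tuple(0.45 * shape * vox),
            csf_center_mm=tuple(c + np.array([0.0, 0.0, 6.0]) * scale),
            csf_radii_mm=(4.0 * scale, 3.0 * scale, 3.0 * scale),
            gm_rim_mm=2.0 * scale,
            dgm_blobs=(
                (tuple(c + np.array([-7.0, 6.0, 4.0]) * scale), 2.5 * scale),
                (tuple(c + np.array([7.0, 6.0, 4.0]) * scale), 2.5 * scale),
            ),
        )


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero direction vector")
    return v / n


def _plane_basis(normal: Sequence[float]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = _unit(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, n)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(n, helper))
    v = np.cross(n, u)
    return u, v, n


def _centerlines(spec: BundleSpec, step: float) -> List[np.ndarray]:
    """Centerline polylines (one or two per bundle) sampled at ``step`` mm."""
    c = np.asarray(spec.center_mm, dtype=float)
    if spec.kind in ("straight", "crossing"):
        half = spec.length_mm / 2.0
        t = np.arange(-half, half + 0.5 * step, step)
        if spec.kind == "straight":
            return [c + np.outer(t, _unit(spec.direction))]
        u, v, _ = _plane_basis(spec.plane_normal)
        th = math.radians(spec.angle_deg)
        d1 = u
        d2 = math.cos(th) * u + math.sin(th) * v
        return [c + np.outer(t, d1), c + np.outer(t, d2)]
    if spec.kind == "arc":
        u, v, _ = _plane_basis(spec.plane_normal)
        R = spec.arc_radius_mm
        span = math.radians(spec.arc_span_deg)
        n_pts = max(int(round(R * span / step)) + 1, 2)
        ang = np.linspace(-span / 2.0, span / 2.0, n_pts)
        return [c + R * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))]
    # kissing: two arcs tangent at the center, curving in opposite senses
    u, v, _ = _plane_basis(spec.plane_normal)
    R = spec.arc_radius_mm
    span = math.radians(spec.arc_span_deg)
    n_pts = max(int(round(R * span / step)) + 1, 2)
    ang = np.linspace(-span / 2.0, span / 2.0, n_pts)
    out = []
    for sign in (+1.0, -1.0):
        # circle center offset so both arcs share the tangency point c with
        # tangent u; p(a) = center - sign*R*cos(a)*v + R*sin(a)*u
        center = c + sign * R * v
        pts = center - sign * R * np.outer(np.cos(ang), v) + R * np.outer(
            np.sin(ang), u
        )
        out.append(pts)
    return out


def _tube_streamlines(
    centerline: np.ndarray,
    radius: float,
    n_streamlines: int,
    rng: np.random.Generator,
    step: float,
) -> List[np.ndarray]:
    """Offset copies of the centerline filling a tube of the given radius."""
    # local frame per point: tangent + two normals (parallel-transport-lite:
    # frames from the mean tangent are fine for the gentle curves used here)
    tangents = np.gradient(centerline, axis=0)
    mean_t = _unit(tangents.sum(axis=0))
    u, v, _ = _plane_basis(mean_t)
    streams = []
    for _ in range(n_streamlines):
        while True:
            a, b = rng.uniform(-1.0, 1.0, size=2)
            if a * a + b * b <= 1.0:
                break
        offset = (a * u + b * v) * radius
        streams.append(centerline + offset)
    return streams


# ---------------------------------------------------------------------------
# Tissue classification / rasterization
# ---------------------------------------------------------------------------


def _classify_points(points: np.ndarray, recipe: SubstrateRecipe) -> np.ndarray:
    """Label world-mm points: -1 outside brain, else tissue index."""
    semi = (
        np.asarray(recipe.brain_semiaxes_mm)
        if recipe.brain_semiaxes_mm is not None
        else 0.45 * recipe.extent_mm
    )
    c = recipe.center_mm
    rel = (points - c) / semi
    rho2 = np.einsum("ij,ij->i", rel, rel)
    labels = np.full(len(points), -1, dtype=np.int8)
    inside = rho2 <= 1.0
    labels[inside] = WM

    # GM rim: between the shrunken inner ellipsoid and the brain surface
    inner = np.clip(semi - recipe.gm_rim_mm, 1e-3, None)
    rel_i = (points - c) / inner
    rim = inside & (np.einsum("ij,ij->i", rel_i, rel_i) > 1.0)
    labels[rim] = CGM

    for center, radius in recipe.dgm_blobs:
        d2 = np.einsum(
            "ij,ij->i", points - np.asarray(center), points - np.asarray(center)
        )
        labels[inside & (d2 <= radius**2)] = DGM

    if recipe.csf_center_mm is not None:
        rel_c = (points - np.asarray(recipe.csf_center_mm)) / np.asarray(
            recipe.csf_radii_mm
        )
        labels[inside & (np.einsum("ij,ij->i", rel_c, rel_c) <= 1.0)] = CSF
    return labels


def _rasterize_fractions(recipe: SubstrateRecipe) -> TissueFractionMap:
    """Partial-volume fractions by 3x3x3 sub-voxel occupancy counting."""
    shape = recipe.grid_shape
    vox = np.asarray(recipe.voxel_size_mm)
    affine = recipe.affine()
    sub = (np.arange(3) + 0.5) / 3.0 - 0.5  # sub-voxel offsets in voxel units
    offs = np.stack(np.meshgrid(sub, sub, sub, indexing="ij"), axis=-1).reshape(-1, 3)

    counts = np.zeros(shape + (4,), dtype=np.int16)
    n_in = np.zeros(shape, dtype=np.int16)
    yy, zz = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
    base_yz = np.column_stack(
        [np.zeros(yy.size), yy.ravel().astype(float), zz.ravel().astype(float)]
    )
    for x in range(shape[0]):  # slab-wise to bound memory
        base = base_yz.copy()
        base[:, 0] = x
        pts = (base[:, None, :] + offs[None, :, :]).reshape(-1, 3) * vox
        labels = _classify_points(pts, recipe).reshape(-1, 27)
        for j in range(4):
            counts[x].reshape(-1, 4)[:, j] = (labels == j).sum(axis=1)
        n_in[x] = counts[x].sum(axis=-1).reshape(shape[1], shape[2])

    mask = n_in >= 14  # majority of sub-samples inside the brain
    fractions = np.zeros(shape + (4,), dtype=float)
    denom = n_in[mask].astype(float)
    fractions[mask] = counts[mask] / denom[:, None]
    return TissueFractionMap(fractions=fractions, affine=affine, brain_mask=mask)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def generate_numerical_brain(
    recipe: SubstrateRecipe,
) -> Tuple[TissueFractionMap, Tractogram]:
    """Generate a synthetic tissue-fraction map and matching tractogram.

    Deterministic for a fixed ``recipe.rng_seed``.  Raises if the recipe has
    no bundles or if any bundle geometry leaves the grid bounds.
    """
    if not recipe.bundles:
        raise ValueError("recipe must define at least one bundle")
    rng = np.random.default_rng(recipe.rng_seed)
    step = recipe.nominal_step_mm

    streamlines: List[np.ndarray] = []
    for spec in recipe.bundles:
        for line in _centerlines(spec, step):
            streamlines.extend(
                _tube_streamlines(line, spec.radius_mm, spec.n_streamlines, rng, step)
            )

    lo = -np.asarray(recipe.voxel_size_mm) / 2.0
    hi = (np.asarray(recipe.grid_shape) - 0.5) * np.asarray(recipe.voxel_size_mm)
    all_pts = np.vstack(streamlines)
    if np.any(all_pts < lo) or np.any(all_pts >= hi):
        raise ValueError("bundle geometry exceeds the grid bounds")

    vf = _rasterize_fractions(recipe)
    return vf, Tractogram(streamlines=streamlines, nominal_step_mm=step)


def toy_parcellation(recipe: SubstrateRecipe, pad_mm: float = 2.0) -> np.ndarray:
    """Integer label volume with one parcel per bundle endpoint.

    Spheres of radius ``bundle radius + pad_mm`` centered on the two ends of
    every bundle centerline; labels start at 1, background is 0.  Intended as
    test scaffolding for connectivity-matrix construction.
    """
    shape = recipe.grid_shape
    vox = np.asarray(recipe.voxel_size_mm)
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    world = idx * vox
    labels = np.zeros(shape, dtype=np.int32)
    flat = labels.reshape(-1)
    next_label = 1
    for spec in recipe.bundles:
        for line in _centerlines(spec, recipe.nominal_step_mm):
            for end in (line[0], line[-1]):
                r = spec.radius_mm + pad_mm
                d2 = np.einsum("ij,ij->i", world - end, world - end)
                flat[d2 <= r * r] = next_label
                next_label += 1
    return labels


# ---------------------------------------------------------------------------
# I/O — NIfTI fraction maps
# ---------------------------------------------------------------------------


def write_fraction_map(vf: TissueFractionMap, path: Union[str, Path]) -> None:
    """Write as one 4D NIfTI with the 4 tissue components (WM, CGM, DGM, CSF)."""
    img = nib.Nifti1Image(vf.fractions.astype(np.float32), vf.affine)
    img.header.set_intent("estimate")
    nib.save(img, str(path))


def read_fraction_map(
    path: Union[str, Path, Mapping[str, Union[str, Path]]],
) -> TissueFractionMap:
    """Read a fraction map from one 4D NIfTI or a {tissue: path} mapping."""
    if isinstance(path, Mapping):
        missing = [t for t in TISSUES if t not in path]
        if missing:
            raise ValueError(f"missing tissue class file(s): {', '.join(missing)}")
        vols = []
        affine = None
        for t in TISSUES:
            img = nib.load(str(path[t]))
            data = np.asarray(img.dataobj, dtype=float)
            if data.ndim != 3:
                raise ValueError(f"per-tissue file for {t} must be 3D")
            if affine is None:
                affine = img.affine
            elif not np.allclose(img.affine, affine, atol=1e-6):
                raise ValueError(f"affine of {t} file disagrees with the others")
            vols.append(data)
        fractions = np.stack(vols, axis=-1)
    else:
        img = nib.load(str(path))
        fractions = np.asarray(img.dataobj, dtype=float)
        if fractions.ndim != 4 or fractions.shape[3] != 4:
            got = fractions.shape[3] if fractions.ndim == 4 else "n/a"
            raise ValueError(
                f"expected a 4D volume with 4 tissue components {TISSUES}, "
                f"got {got} component(s) in shape {fractions.shape}"
            )
        affine = img.affine

    n_neg = int(np.sum(np.any(fractions < -_SUM_TOL, axis=-1)))
    if n_neg:
        raise ValueError(
            f"fractions outside [0, 1] in {n_neg} voxel(s) (negative values)"
        )
    fractions = np.clip(fractions, 0.0, None)
    s = fractions.sum(axis=-1)
    mask = s > 0.5
    # renormalize in-mask sums within tolerance of 1 (stored precision)
    bad = mask & (np.abs(s - 1.0) > 1e-3)
    if np.any(bad):
        raise ValueError(
            f"in-mask fractions do not sum to 1 in {int(bad.sum())} voxel(s)"
        )
    out = fractions.copy()
    out[mask] /= s[mask][..., None]
    out[~mask] = 0.0
    return TissueFractionMap(fractions=out, affine=affine, brain_mask=mask)


# ---------------------------------------------------------------------------
# I/O — streamlines (TCK primary, TRK with explicit voxel-to-world handling)
# ---------------------------------------------------------------------------


def write_tractogram(
    tractogram: Tractogram,
    path: Union[str, Path],
    reference: Optional[TissueFractionMap] = None,
) -> None:
    """Write streamlines to TCK or TRK (by extension), world-mm coordinates.

    TRK needs grid geometry in its header; pass ``reference`` for TRK output.
    """
    path = Path(path)
    sl = nib.streamlines.Tractogram(
        tractogram.streamlines, affine_to_rasmm=np.eye(4)
    )
    if path.suffix.lower() == ".tck":
        hdr = {"step_size": str(tractogram.nominal_step_mm)}
        nib.streamlines.save(sl, str(path), header=hdr)
    elif path.suffix.lower() == ".trk":
        if reference is None:
            raise ValueError("TRK output requires a reference grid (voxel-to-world)")
        hdr = nib.streamlines.TrkFile.create_empty_header()
        hdr["voxel_sizes"] = reference.voxel_size_mm.astype(np.float32)
        hdr["dimensions"] = np.asarray(reference.grid_shape, dtype=np.int16)
        hdr["voxel_to_rasmm"] = reference.affine.astype(np.float32)
        hdr["voxel_order"] = "RAS"
        nib.streamlines.save(sl, str(path), header=hdr)
    else:
        raise ValueError(f"unsupported streamline format {path.suffix!r}")


def read_tractogram(
    path: Union[str, Path], nominal_step_mm: Optional[float] = None
) -> Tractogram:
    """Load a TCK/TRK file into world-mm streamlines.

    Single-point streamlines are dropped (with a logged count); an empty file
    yields an empty tractogram and a warning.  TRK files whose header lacks a
    usable voxel-to-world transform are rejected rather than guessed at.
    """
    path = Path(path)
    if path.suffix.lower() not in (".tck", ".trk"):
        raise ValueError(f"unsupported streamline format {path.suffix!r}")
    try:
        tf = nib.streamlines.load(str(path))
    except Exception as exc:  # malformed header, ambiguous space, ...
        raise ValueError(f"cannot read streamline file {path}: {exc}") from exc
    if path.suffix.lower() == ".trk":
        voxel_sizes = tf.header.get("voxel_sizes")
        if voxel_sizes is None or np.any(np.asarray(voxel_sizes) <= 0):
            raise ValueError(
                f"TRK header of {path} lacks valid voxel sizes; "
                "coordinate space is ambiguous"
            )
    streams = [np.asarray(s, dtype=float) for s in tf.tractogram.streamlines]
    kept = [s for s in streams if len(s) >= 2]
    n_dropped = len(streams) - len(kept)
    if n_dropped:
        logger.warning("dropped %d streamline(s) with < 2 points", n_dropped)
    if not kept:
        logger.warning("streamline file %s contains no usable streamlines", path)
    if nominal_step_mm is None:
        hdr_step = tf.header.get("step_size")
        try:
            nominal_step_mm = float(hdr_step)
        except (TypeError, ValueError):
            nominal_step_mm = 0.7
        if not math.isfinite(nominal_step_mm) or nominal_step_mm <= 0:
            nominal_step_mm = 0.7
    out = Tractogram.__new__(Tractogram)
    out.streamlines = kept
    out.nominal_step_mm = nominal_step_mm
    return out
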