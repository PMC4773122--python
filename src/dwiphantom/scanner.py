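"""Simulated diffusion-weighted spin-echo acquisition.

Assembles ideal volumes at the native high resolution —
``S_k(r) = S0(r) * sum_j v_j(r) A_{j,k}(r)`` — and degrades them the way a
scanner would: per-slice 2D k-space, complex Gaussian noise, central k-space
truncation (Gibbs ringing + partial volume), optional Fermi/Hamming
apodization, inverse FFT with magnitude reconstruction, and an
ideal-rectangular slice profile realized as a boxcar average over adjacent
native slices.

SNR convention: SNR = (mean noiseless b=0 signal over the WM-dominant mask at
target resolution) / (image-domain noise standard deviation); configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from . import fibermap
from .compartments import (
    B_PER_MM2_TO_SI,
    PulseParams,
    TissueModelSet,
    attenuation_isotropic,
    pulse_for_b,
)
from .relaxometry import SequenceTiming, TissueMRParams, s0_volume
from .substrate import TissueFractionMap, Tractogram

__all__ = [
    "GradientScheme",
    "Protocol",
    "SimulatedAcquisition",
    "generate_directions",
    "electrostatic_energy",
    "ideal_dw_volumes",
    "degrade",
    "add_kspace_noise",
    "simulate_acquisition",
    "fermi_filter",
    "hamming_filter",
]


# ---------------------------------------------------------------------------
# Gradient directions: antipodal electrostatic repulsion
# ---------------------------------------------------------------------------


def electrostatic_energy(points: np.ndarray) -> float:
    """Antipodal Coulomb energy sum_{i<j} 1/|x_i - x_j| + 1/|x_i + x_j|."""
    x = np.asarray(points, dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    summ = x[:, None, :] + x[None, :, :]
    dd = np.linalg.norm(diff, axis=-1)
    ds = np.linalg.norm(summ, axis=-1)
    iu = np.triu_indices(len(x), k=1)
    return float(np.sum(1.0 / dd[iu]) + np.sum(1.0 / ds[iu]))


def _energy_grad(flat: np.ndarray, n: int) -> Tuple[float, np.ndarray]:
    """Energy and gradient w.r.t. unconstrained coordinates (normalized inside)."""
    y = flat.reshape(n, 3)
    norms = np.linalg.norm(y, axis=1, keepdims=True)
    x = y / norms

    diff = x[:, None, :] - x[None, :, :]
    summ = x[:, None, :] + x[None, :, :]
    dd = np.linalg.norm(diff, axis=-1)
    ds = np.linalg.norm(summ, axis=-1)
    np.fill_diagonal(dd, np.inf)
    np.fill_diagonal(ds, np.inf)

    energy = 0.5 * float(np.sum(1.0 / dd) + np.sum(1.0 / ds))

    # dE/dx_i = -sum_j (x_i - x_j)/|..|^3 - sum_j (x_i + x_j)/|..|^3
    gd = -np.einsum("ijk,ij->ik", diff, dd**-3)
    gs = -np.einsum("ijk,ij->ik", summ, ds**-3)
    g_x = gd + gs
    # chain rule through normalization: (I - x x^T) / |y|
    g_y = (g_x - x * np.sum(g_x * x, axis=1, keepdims=True)) / norms
    return energy, g_y.reshape(-1)


def generate_directions(
    n: int,
    seed: int = 0,
    gtol: float = 1.0e-8,
    max_restarts: int = 8,
) -> np.ndarray:
    """Electrostatically optimized antipodal gradient directions.

    Minimizes the antipodal Coulomb energy from a seeded random start until
    the tangent-projected gradient infinity-norm falls below
    ``gtol * max(1, energy)`` (the energy grows like n^2, so an absolute
    threshold would be unattainable in double precision at large n);
    deterministic per seed.  Raises on non-convergence, reporting the final
    energy.
    """
    if n < 6:
        raise ValueError("need at least 6 directions")
    rng = np.random.default_rng(seed)
    last_energy = math.nan
    for _ in range(max_restarts):
        x = rng.standard_normal((n, 3))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        # L-BFGS stalls on its relative-f criterion near the optimum, so
        # re-warm-start it until the projected gradient actually meets gtol
        for _polish in range(12):
            res = minimize(
                _energy_grad,
                x.reshape(-1),
                args=(n,),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 20000, "ftol": 1e-18, "gtol": 1e-14},
            )
            x = res.x.reshape(n, 3)
            x /= np.linalg.norm(x, axis=1, keepdims=True)
            e, g = _energy_grad(x.reshape(-1), n)
            if np.max(np.abs(g)) < gtol * max(1.0, e):
                break
        last_energy = electrostatic_energy(x)
        if np.max(np.abs(g)) < gtol * max(1.0, last_energy):
            # canonical orientation: z >= 0 hemisphere, sorted for determinism
            flip = x[:, 2] < 0
            x[flip] *= -1.0
            order = np.lexsort((x[:, 2], x[:, 1], x[:, 0]))
            return x[order]
    raise RuntimeError(
        f"direction optimization did not converge (final energy {last_energy:.6f})"
    )


@dataclass(frozen=True)
class GradientScheme:
    """Acquisition list of (unit direction, b-value in s/mm^2) pairs."""

    bvals: np.ndarray  # (n,), s/mm^2
    bvecs: np.ndarray  # (n, 3), unit (zero vector allowed for b=0)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bvals", np.asarray(self.bvals, dtype=float))
        object.__setattr__(self, "bvecs", np.asarray(self.bvecs, dtype=float))
        if self.bvals.ndim != 1 or self.bvecs.shape != (len(self.bvals), 3):
            raise ValueError("bvals must be (n,) and bvecs (n, 3)")
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be >= 0")
        if not np.any(self.bvals == 0):
            raise ValueError("scheme needs at least one b = 0 entry")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("DW directions must be unit-norm")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    @property
    def shells(self) -> np.ndarray:
        return np.unique(self.bvals[self.bvals > 0])

    @classmethod
    def multishell(
        cls,
        n_directions: int,
        bvalues: Sequence[float],
        n_b0: int = 6,
        seed: int = 0,
    ) -> "GradientScheme":
        """b=0 block followed by the same optimized direction set per shell."""
        dirs = generate_directions(n_directions, seed=seed)
        bvals = [0.0] * n_b0
        bvecs = [np.zeros(3)] * n_b0
        for b in bvalues:
            bvals.extend([float(b)] * n_directions)
            bvecs.extend(dirs)
        return cls(bvals=np.asarray(bvals), bvecs=np.asarray(bvecs), seed=seed)


# ---------------------------------------------------------------------------
# Protocol / acquisition containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Protocol:
    """Everything needed to simulate one acquisition."""

    scheme: GradientScheme
    delta_s: float
    Delta_s: float
    timing: SequenceTiming
    native_voxel_mm: Tuple[float, float, float] = (0.7, 0.7, 0.7)
    downsample: Tuple[int, int, int] = (1, 1, 1)
    filter_name: str = "none"  # {none, fermi, hamming}
    filter_params: Dict[str, float] = field(default_factory=dict)
    snr: float = math.inf
    noise_seed: int = 0
    noise_mode: str = "slice2d"  # {slice2d, volume3d}

    def __post_init__(self) -> None:
        if any(int(f) != f or f < 1 for f in self.downsample):
            raise ValueError("downsample factors must be integers >= 1")
        if self.filter_name not in ("none", "fermi", "hamming"):
            raise ValueError(f"unknown filter {self.filter_name!r}")
        if not (self.snr > 0):
            raise ValueError("SNR must be positive (or inf)")
        if self.noise_mode not in ("slice2d", "volume3d"):
            raise ValueError("noise_mode must be 'slice2d' or 'volume3d'")
        if self.delta_s >= self.Delta_s:
            raise ValueError("delta must be < Delta")

    @property
    def target_voxel_mm(self) -> Tuple[float, float, float]:
        return tuple(
            v * f for v, f in zip(self.native_voxel_mm, self.downsample)
        )

    def pulse_for(self, b_s_per_mm2: float) -> PulseParams:
        return pulse_for_b(b_s_per_mm2, self.delta_s, self.Delta_s)


@dataclass
class SimulatedAcquisition:
    """4D magnitude image series plus its gradient table and provenance."""

    data: np.ndarray  # (X, Y, Z, n_volumes), non-negative
    affine: np.ndarray
    scheme: GradientScheme
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[3] != len(self.scheme):
            raise ValueError("volume count must equal the scheme length")
        if np.any(self.data < 0):
            raise ValueError("magnitude images must be non-negative")


# ---------------------------------------------------------------------------
# Ideal volumes
# ---------------------------------------------------------------------------


def ideal_dw_volumes(
    vf: TissueFractionMap,
    field_: fibermap.SegmentDirectionField,
    models: TissueModelSet,
    protocol: Protocol,
    mrparams: Optional[TissueMRParams] = None,
) -> np.ndarray:
    """Noise-free native-resolution 4D series S_k = S0 * sum_j v_j A_{j,k}.

    b = 0 volumes equal the anatomical S0 exactly; orientation-dependent
    tissues (WM, and the WM share of DGM) use the per-voxel segment-direction
    average, falling back to the powder average where fibers are absent but
    the tissue fraction is not.
    """
    if mrparams is None:
        mrparams = TissueMRParams.preset("3T")
    s0 = s0_volume(vf, mrparams, protocol.timing)
    shape = vf.grid_shape
    n_vol = len(protocol.scheme)
    out = np.empty(shape + (n_vol,), dtype=float)

    v_wm = vf.tissue("WM")
    v_cgm = vf.tissue("CGM")
    v_dgm = vf.tissue("DGM")
    v_csf = vf.tissue("CSF")
    md_cgm = models.CGM.md
    md_csf = models.CSF.md
    w_dgm = models.dgm_wm_weight
    wm_needed = (v_wm > 0) | (v_dgm > 0)

    pulses: Dict[float, PulseParams] = {
        float(b): protocol.pulse_for(float(b)) for b in protocol.scheme.shells
    }

    for k in range(n_vol):
        b_mm2 = float(protocol.scheme.bvals[k])
        if b_mm2 == 0.0:
            out[..., k] = s0
            continue
        b_si = b_mm2 * B_PER_MM2_TO_SI
        g = protocol.scheme.bvecs[k]
        pulse = pulses[b_mm2]
        a_wm = fibermap.wm_attenuation_volume(
            field_, models, pulse, g, fallback_powder_mask=wm_needed
        )
        a_wm = np.where(np.isnan(a_wm), 0.0, a_wm)
        a_cgm = float(attenuation_isotropic(md_cgm, b_si))
        a_csf = float(attenuation_isotropic(md_csf, b_si))
        a_dgm = w_dgm * a_wm + (1.0 - w_dgm) * a_cgm
        mix = (
            v_wm * a_wm + v_cgm * a_cgm + v_dgm * a_dgm + v_csf * a_csf
        )
        out[..., k] = s0 * mix
    return out


# ---------------------------------------------------------------------------
# k-space degradation
# ---------------------------------------------------------------------------


def fermi_filter(shape2d: Tuple[int, int], radius_frac: float = 0.9,
                 width_frac: float = 0.06) -> np.ndarray:
    """Radial Fermi low-pass window on a centered 2D k-space grid."""
    ky = np.fft.fftshift(np.fft.fftfreq(shape2d[0])) * 2.0  # in units of k_max
    kx = np.fft.fftshift(np.fft.fftfreq(shape2d[1])) * 2.0
    kr = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
    return 1.0 / (1.0 + np.exp((kr - radius_frac) / width_frac))


def hamming_filter(shape2d: Tuple[int, int]) -> np.ndarray:
    """Separable Hamming window 0.54 + 0.46 cos(pi k / k_max)."""
    wy = 0.54 + 0.46 * np.cos(np.pi * np.fft.fftshift(np.fft.fftfreq(shape2d[0])) * 2)
    wx = 0.54 + 0.46 * np.cos(np.pi * np.fft.fftshift(np.fft.fftfreq(shape2d[1])) * 2)
    return wy[:, None] * wx[None, :]


def _inplane_filter(protocol: Protocol, shape2d: Tuple[int, int]) -> Optional[np.ndarray]:
    if protocol.filter_name == "none":
        return None
    if protocol.filter_name == "fermi":
        return fermi_filter(shape2d, **protocol.filter_params)
    return hamming_filter(shape2d)


def add_kspace_noise(
    kspace: np.ndarray,
    snr: float,
    reference_signal: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Add i.i.d. complex Gaussian noise to an (unnormalized-FFT) 2D spectrum.

    The per-component standard deviation is chosen so that direct inverse-FFT
    reconstruction has image-domain noise SD ``reference_signal / snr``.
    """
    if snr <= 0:
        raise ValueError("SNR must be positive (or inf)")
    if not np.isfinite(snr):
        return kspace
    n_px = kspace.shape[-2] * kspace.shape[-1]
    sigma_k = (reference_signal / snr) * math.sqrt(n_px)
    noise = rng.standard_normal(kspace.shape) + 1j * rng.standard_normal(kspace.shape)
    return kspace + sigma_k * noise


def _noise_gain(protocol: Protocol, native_shape: Tuple[int, int, int]) -> float:
    """Final image-noise SD per unit k-space sigma (no-filter analytic form).

    Per-slice 2D reconstruction of an (Nx, Ny) plane cropped to (Mx, My) and
    rescaled to preserve DC has gain sqrt(F2)/(Nx*Ny) with F2 the sum of the
    squared filter values over the kept samples; the through-plane boxcar over
    ``fz`` slices divides by sqrt(fz).
    """
    nx, ny, _ = native_shape
    fx, fy, fz = protocol.downsample
    mx, my = nx // fx, ny // fy
    filt = _inplane_filter(protocol, (mx, my))
    f2 = float(np.sum(filt**2)) if filt is not None else float(mx * my)
    return math.sqrt(f2) / (nx * ny) / math.sqrt(fz)


def degrade(
    volume: np.ndarray,
    protocol: Protocol,
    rng: Optional[np.random.Generator] = None,
    reference_signal: Optional[float] = None,
) -> np.ndarray:
    """Degrade one native 3D volume through the simulated acquisition chain.

    Pipeline per axial slice: forward FFT -> k-space noise -> central crop to
    the target in-plane matrix -> apodization -> inverse FFT -> magnitude;
    then a boxcar average over ``fz`` adjacent native slices (ideal
    rectangular slice-selection profile).  With factor 1, no noise and no
    filter this is the identity up to floating-point round-trip.
    """
    fx, fy, fz = protocol.downsample
    nx, ny, nz = volume.shape
    if nx % fx or ny % fy or nz % fz:
        raise ValueError(
            f"native shape {volume.shape} not divisible by factors {protocol.downsample}"
        )
    mx, my = nx // fx, ny // fy
    noisy = np.isfinite(protocol.snr)

    # per-slice 2D spectra, centered
    k = np.fft.fftshift(np.fft.fft2(volume, axes=(0, 1)), axes=(0, 1))
    if noisy:
        if rng is None:
            rng = np.random.default_rng(protocol.noise_seed)
        if reference_signal is None:
            raise ValueError("finite SNR requires a reference signal level")
        # sigma_k such that the *final* image noise SD is reference/snr
        sigma_k = (reference_signal / protocol.snr) / _noise_gain(
            protocol, volume.shape
        )
        if protocol.noise_mode == "slice2d":
            k = k + sigma_k * (
                rng.standard_normal(k.shape) + 1j * rng.standard_normal(k.shape)
            )
        else:  # volume3d: noise lives in the 3D spectrum
            k3 = np.fft.fft(k, axis=2)
            k3 = k3 + sigma_k * math.sqrt(nz) * (
                rng.standard_normal(k.shape) + 1j * rng.standard_normal(k.shape)
            )
            k = np.fft.ifft(k3, axis=2)

    k = k[(nx - mx) // 2 : (nx - mx) // 2 + mx,
          (ny - my) // 2 : (ny - my) // 2 + my] * (mx / nx) * (my / ny)
    filt = _inplane_filter(protocol, (mx, my))
    if filt is not None:
        k = k * filt[:, :, None]
    cplx = np.fft.ifft2(np.fft.ifftshift(k, axes=(0, 1)), axes=(0, 1))
    # ideal-rect slice profile: the excited slab integrates the *complex*
    # magnetization over fz adjacent native slices; magnitude comes last
    if fz > 1:
        cplx = cplx.reshape(mx, my, nz // fz, fz).mean(axis=3)
    return np.abs(cplx)


# ---------------------------------------------------------------------------
# Full acquisition
# ---------------------------------------------------------------------------


def simulate_acquisition(
    vf: TissueFractionMap,
    tractogram: Tractogram,
    models: TissueModelSet,
    mrparams: TissueMRParams,
    protocol: Protocol,
) -> SimulatedAcquisition:
    """Run the full pipeline: segments -> S0 -> ideal volumes -> degradation.

    Each output volume receives independent noise; all randomness derives
    from ``protocol.noise_seed``.
    """
    field_ = fibermap.assign_segments(tractogram, vf)
    ideal = ideal_dw_volumes(vf, field_, models, protocol, mrparams)

    # SNR reference: mean noiseless b=0 signal over WM-dominant voxels at
    # target resolution
    ref = None
    if np.isfinite(protocol.snr):
        b0_idx = int(np.argmax(protocol.scheme.bvals == 0))
        quiet = replace(protocol, snr=math.inf)
        b0_target = degrade(ideal[..., b0_idx], quiet)
        wm_target = _downsample_mean(vf.tissue("WM"), protocol.downsample) > 0.5
        if not np.any(wm_target):
            wm_target = b0_target > 0
        ref = float(b0_target[wm_target].mean())

    seeds = np.random.SeedSequence(protocol.noise_seed).spawn(len(protocol.scheme))
    volumes = []
    for k in range(len(protocol.scheme)):
        rng = np.random.default_rng(seeds[k])
        volumes.append(degrade(ideal[..., k], protocol, rng=rng,
                               reference_signal=ref))
    data = np.stack(volumes, axis=-1)

    affine = vf.affine.copy()
    affine[:3, :3] = affine[:3, :3] @ np.diag(protocol.downsample)
    provenance = {
        "native_voxel_mm": list(protocol.native_voxel_mm),
        "target_voxel_mm": list(protocol.target_voxel_mm),
        "downsample": list(protocol.downsample),
        "filter": protocol.filter_name,
        "filter_params": dict(protocol.filter_params),
        "snr": protocol.snr if np.isfinite(protocol.snr) else "inf",
        "snr_reference": ref,
        "noise_seed": protocol.noise_seed,
        "noise_mode": protocol.noise_mode,
        "delta_s": protocol.delta_s,
        "Delta_s": protocol.Delta_s,
        "te_ms": protocol.timing.te_ms,
        "tr_ms": protocol.timing.tr_ms,
        "b0_T": protocol.timing.b0_T,
        "scheme_seed": protocol.scheme.seed,
        "n_volumes": len(protocol.scheme),
        "n_dropped_segments": field_.n_dropped,
    }
    return SimulatedAcquisition(
        data=data, affine=affine, scheme=protocol.scheme, provenance=provenance
    )


def _downsample_mean(volume: np.ndarray, factors: Tuple[int, int, int]) -> np.ndarray:
    fx, fy, fz = factors
    nx, ny, nz = volume.shape
    return (
        volume.reshape(nx // fx, fx, ny // fy, fy, nz // fz, fz)
        .mean(axis=(1, 3, 5))
    )
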