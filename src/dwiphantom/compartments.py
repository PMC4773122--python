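"""Analytic diffusion-attenuation models for the four tissue classes.

Each compartment returns a *normalized* attenuation ``A`` in ``(0, 1]`` for a
pulsed-gradient spin-echo experiment described by :class:`PulseParams`:

* ``isotropic`` — mono-exponential decay ``exp(-b * MD)`` (CSF, cortical GM);
* ``zeppelin`` — axially symmetric tensor with parallel/perpendicular
  diffusivities (extra-axonal hindered water);
* ``cylinder`` — free diffusion along the axis combined with
  Gaussian-phase-distribution (GPD) restricted diffusion perpendicular to it
  (intra-axonal water), parameterized by the cylinder radius;
* ``mixture`` — convex combination of child compartments.

White matter is a cylinder/zeppelin mixture, deep grey matter a WM/CGM
mixture; the built-in :func:`TissueModelSet.default` preset carries the
standard parameter values.

Units are SI throughout (m, s, T, rad/s/T).  User-facing b-values in s/mm^2
must be converted at the boundary (multiply by :data:`B_PER_MM2_TO_SI`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.special import jnp_zeros

__all__ = [
    "GAMMA_HYDROGEN",
    "B_PER_MM2_TO_SI",
    "PulseParams",
    "CompartmentSpec",
    "TissueModelSet",
    "TISSUES",
    "b_value",
    "gradient_for_b",
    "pulse_for_b",
    "attenuation_isotropic",
    "attenuation_zeppelin",
    "attenuation_cylinder",
    "cylinder_perp_log_attenuation",
    "attenuation_compartment",
    "attenuation_tissue",
    "powder_directions",
]

#: Hydrogen gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_HYDROGEN = 2.6752219e8

#: Multiply a b-value in s/mm^2 by this to get s/m^2.
B_PER_MM2_TO_SI = 1.0e6

TISSUES = ("WM", "CGM", "DGM", "CSF")

_UNIT_TOL = 1.0e-6


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {v.shape}")
    n = np.linalg.norm(v)
    if abs(n - 1.0) > _UNIT_TOL:
        raise ValueError(f"{name} must be unit-norm (|{name}| = {n:.8f})")
    return v


@dataclass(frozen=True)
class PulseParams:
    """Pulsed-gradient spin-echo timing and amplitude.

    Attributes
    ----------
    delta_s : float
        Gradient pulse duration (s).
    Delta_s : float
        Separation between the two pulse onsets (s).
    G_T_per_m : float
        Diffusion gradient amplitude (T/m).
    gamma_rad_per_s_per_T : float
        Gyromagnetic ratio; hydrogen by default.
    """

    delta_s: float
    Delta_s: float
    G_T_per_m: float
    gamma_rad_per_s_per_T: float = GAMMA_HYDROGEN

    def __post_init__(self) -> None:
        if self.delta_s <= 0 or self.Delta_s <= 0:
            raise ValueError("pulse durations must be positive")
        if self.delta_s >= self.Delta_s:
            raise ValueError(
                f"delta ({self.delta_s} s) must be < Delta ({self.Delta_s} s)"
            )
        if self.G_T_per_m < 0:
            raise ValueError("gradient amplitude must be >= 0")
        if self.gamma_rad_per_s_per_T <= 0:
            raise ValueError("gamma must be positive")

    @property
    def b_s_per_m2(self) -> float:
        """Stejskal–Tanner b-value, s/m^2."""
        return b_value(self)

    @property
    def b_s_per_mm2(self) -> float:
        return self.b_s_per_m2 / B_PER_MM2_TO_SI


def b_value(pulse: PulseParams) -> float:
    """Stejskal–Tanner b = gamma^2 G^2 delta^2 (Delta - delta/3), in s/m^2."""
    g, G, d, D = (
        pulse.gamma_rad_per_s_per_T,
        pulse.G_T_per_m,
        pulse.delta_s,
        pulse.Delta_s,
    )
    return g * g * G * G * d * d * (D - d / 3.0)


def gradient_for_b(
    b_s_per_m2: float,
    delta_s: float,
    Delta_s: float,
    gamma: float = GAMMA_HYDROGEN,
) -> float:
    """Invert the Stejskal–Tanner relation for the gradient amplitude G."""
    if delta_s >= Delta_s:
        raise ValueError("delta must be < Delta")
    if b_s_per_m2 < 0:
        raise ValueError("b must be >= 0")
    return math.sqrt(
        b_s_per_m2 / (gamma**2 * delta_s**2 * (Delta_s - delta_s / 3.0))
    )


def pulse_for_b(
    b_s_per_mm2: float,
    delta_s: float,
    Delta_s: float,
    gamma: float = GAMMA_HYDROGEN,
) -> PulseParams:
    """Build a :class:`PulseParams` whose amplitude realizes ``b`` (s/mm^2)."""
    G = gradient_for_b(b_s_per_mm2 * B_PER_MM2_TO_SI, delta_s, Delta_s, gamma)
    return PulseParams(delta_s, Delta_s, G, gamma)


# ---------------------------------------------------------------------------
# Compartment attenuations
# ---------------------------------------------------------------------------


def attenuation_isotropic(md_m2_per_s: float, b_s_per_m2) -> np.ndarray | float:
    """Isotropic Gaussian attenuation ``exp(-b * MD)``.

    Direction independent; valid for CSF and cortical GM.
    """
    if md_m2_per_s <= 0:
        raise ValueError("MD must be positive")
    b = np.asarray(b_s_per_m2, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    out = np.exp(-b * md_m2_per_s)
    return float(out) if out.ndim == 0 else out


def attenuation_zeppelin(
    d_par: float,
    d_perp: float,
    fiber_dir: np.ndarray,
    grad_dir: np.ndarray,
    b_s_per_m2: float,
) -> float:
    """Axially symmetric tensor attenuation.

    ``exp(-b * (d_perp + (d_par - d_perp) (g . n)^2))`` — antipodally
    symmetric in both the fiber axis ``n`` and the gradient direction ``g``.
    """
    if not (d_par >= d_perp > 0):
        raise ValueError("require d_par >= d_perp > 0")
    if b_s_per_m2 < 0:
        raise ValueError("b must be >= 0")
    n = _check_unit(fiber_dir, "fiber_dir")
    g = _check_unit(grad_dir, "grad_dir")
    c2 = float(np.dot(g, n)) ** 2
    return math.exp(-b_s_per_m2 * (d_perp + (d_par - d_perp) * c2))


# first 50 positive roots of J1'(x) = 0; module-level so they are computed once
_BESSEL_DERIV_ROOTS = jnp_zeros(1, 50)
_GPD_REL_TOL = 1.0e-10


def cylinder_perp_log_attenuation(
    d_m2_per_s: float, radius_m: float, pulse: PulseParams
) -> float:
    """GPD log-attenuation for diffusion restricted inside a cylinder,
    with the full gradient amplitude applied perpendicular to the axis.

    Uses the Neuman/Van Gelderen series over the roots ``a_m`` of
    ``J1'(a) = 0``::

        ln E = -2 g^2 G^2 sum_m [ 2 d lam^2 delta - 2
                                  + 2 e^{-d lam^2 delta} + 2 e^{-d lam^2 Delta}
                                  - e^{-d lam^2 (Delta-delta)}
                                  - e^{-d lam^2 (Delta+delta)} ]
                               / ( d^2 lam^6 (R^2 lam^2 - 1) )

    with ``lam = a_m / R``.  The series is truncated at 50 roots with a
    relative-term tolerance of 1e-10; failure to converge raises.
    """
    if d_m2_per_s <= 0:
        raise ValueError("intrinsic diffusivity must be positive")
    if radius_m <= 0:
        raise ValueError("cylinder radius must be positive")
    G = pulse.G_T_per_m
    if G == 0.0:
        return 0.0
    d = d_m2_per_s
    R = radius_m
    delta, Delta = pulse.delta_s, pulse.Delta_s
    gamma = pulse.gamma_rad_per_s_per_T

    lam = _BESSEL_DERIV_ROOTS / R
    dl2 = d * lam**2
    num = (
        2.0 * dl2 * delta
        - 2.0
        + 2.0 * np.exp(-dl2 * delta)
        + 2.0 * np.exp(-dl2 * Delta)
        - np.exp(-dl2 * (Delta - delta))
        - np.exp(-dl2 * (Delta + delta))
    )
    terms = num / (d**2 * lam**6 * (R**2 * lam**2 - 1.0))
    total = float(np.sum(terms))
    if total > 0 and abs(terms[-1]) > _GPD_REL_TOL * abs(total):
        raise RuntimeError(
            "GPD series not converged after 50 Bessel-derivative roots: "
            f"last relative term {abs(terms[-1]) / abs(total):.3e} > {_GPD_REL_TOL:.0e}"
        )
    return -2.0 * gamma**2 * G**2 * total


def attenuation_cylinder(
    d_m2_per_s: float,
    radius_m: float,
    fiber_dir: np.ndarray,
    grad_dir: np.ndarray,
    pulse: PulseParams,
) -> float:
    """Restricted-cylinder attenuation (GPD), separable parallel × perpendicular.

    Parallel to the axis the water diffuses freely: ``exp(-b cos^2(theta) d)``.
    Perpendicular the GPD log-attenuation scales with the squared
    perpendicular gradient component, i.e. with ``sin^2(theta)``.
    """
    n = _check_unit(fiber_dir, "fiber_dir")
    g = _check_unit(grad_dir, "grad_dir")
    c2 = float(np.dot(g, n)) ** 2
    s2 = max(0.0, 1.0 - c2)
    b = b_value(pulse)
    log_par = -b * c2 * d_m2_per_s
    log_perp = s2 * cylinder_perp_log_attenuation(d_m2_per_s, radius_m, pulse)
    return math.exp(log_par + log_perp)


# ---------------------------------------------------------------------------
# Compartment specs and tissue presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompartmentSpec:
    """One diffusion compartment, or a convex mixture of compartments."""

    kind: str  # {"isotropic", "zeppelin", "cylinder", "mixture"}
    md: Optional[float] = None  # isotropic MD, m^2/s
    d_par: Optional[float] = None  # zeppelin parallel diffusivity
    d_perp: Optional[float] = None  # zeppelin perpendicular diffusivity
    d: Optional[float] = None  # cylinder intrinsic diffusivity
    radius: Optional[float] = None  # cylinder radius, m
    children: Tuple["CompartmentSpec", ...] = ()
    weights: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        k = self.kind
        if k == "isotropic":
            if self.md is None or self.md <= 0:
                raise ValueError("isotropic compartment needs MD > 0")
        elif k == "zeppelin":
            if self.d_par is None or self.d_perp is None:
                raise ValueError("zeppelin needs d_par and d_perp")
            if not (self.d_par >= self.d_perp > 0):
                raise ValueError("require d_par >= d_perp > 0")
        elif k == "cylinder":
            if self.d is None or self.d <= 0:
                raise ValueError("cylinder needs intrinsic diffusivity d > 0")
            if self.radius is None or self.radius <= 0:
                raise ValueError("cylinder needs radius > 0")
        elif k == "mixture":
            if len(self.children) != len(self.weights) or not self.children:
                raise ValueError("mixture needs matching children and weights")
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0) or np.any(w > 1) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("mixture weights must lie in [0,1] and sum to 1")
        else:
            raise ValueError(f"unknown compartment kind {k!r}")

    @property
    def is_anisotropic(self) -> bool:
        if self.kind in ("zeppelin", "cylinder"):
            return True
        if self.kind == "mixture":
            return any(c.is_anisotropic for c in self.children)
        return False


def attenuation_compartment(
    spec: CompartmentSpec,
    pulse: PulseParams,
    grad_dir: np.ndarray,
    fiber_dir: Optional[np.ndarray] = None,
) -> float:
    """Evaluate one compartment's normalized attenuation."""
    if spec.kind == "isotropic":
        return float(attenuation_isotropic(spec.md, b_value(pulse)))
    if fiber_dir is None:
        raise ValueError(f"{spec.kind} compartment requires a fiber direction")
    if spec.kind == "zeppelin":
        return attenuation_zeppelin(
            spec.d_par, spec.d_perp, fiber_dir, grad_dir, b_value(pulse)
        )
    if spec.kind == "cylinder":
        return attenuation_cylinder(spec.d, spec.radius, fiber_dir, grad_dir, pulse)
    # mixture: linear in the weights, exact
    return float(
        sum(
            w * attenuation_compartment(c, pulse, grad_dir, fiber_dir)
            for c, w in zip(spec.children, spec.weights)
        )
    )


def _default_wm() -> CompartmentSpec:
    cylinder = CompartmentSpec(kind="cylinder", d=1.49e-9, radius=4.8e-6)
    zeppelin = CompartmentSpec(kind="zeppelin", d_par=1.49e-9, d_perp=0.72e-9)
    return CompartmentSpec(
        kind="mixture", children=(cylinder, zeppelin), weights=(0.59, 0.41)
    )


@dataclass(frozen=True)
class TissueModelSet:
    """One compartment spec per tissue class, with the built-in preset.

    Defaults: WM is a cylinder(59%)/zeppelin(41%) mixture sharing parallel
    diffusivity 1.49e-9 m^2/s (cylinder radius 4.8 um, zeppelin perpendicular
    0.72e-9); CGM and CSF are isotropic with MD 0.83e-9 and 3.19e-9; DGM is a
    20% WM / 80% CGM signal mixture.
    """

    WM: CompartmentSpec = field(default_factory=_default_wm)
    CGM: CompartmentSpec = field(
        default_factory=lambda: CompartmentSpec(kind="isotropic", md=0.83e-9)
    )
    CSF: CompartmentSpec = field(
        default_factory=lambda: CompartmentSpec(kind="isotropic", md=3.19e-9)
    )
    dgm_wm_weight: float = 0.20

    @classmethod
    def default(cls) -> "TissueModelSet":
        return cls()

    @property
    def DGM(self) -> CompartmentSpec:
        return CompartmentSpec(
            kind="mixture",
            children=(self.WM, self.CGM),
            weights=(self.dgm_wm_weight, 1.0 - self.dgm_wm_weight),
        )

    def spec(self, tissue: str) -> CompartmentSpec:
        if tissue not in TISSUES:
            raise KeyError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
        return getattr(self, tissue)


def powder_directions(n: int = 300) -> np.ndarray:
    """Fixed antipodal direction set for orientation averaging.

    Deterministic Fibonacci-hemisphere construction; returns an (n, 3) array
    of unit vectors covering one hemisphere (models are antipodal).
    """
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (1.0 + math.sqrt(5.0)) * i
    z = i / n  # upper hemisphere only
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


_POWDER_CACHE = powder_directions(300)


def attenuation_tissue(
    tissue: str,
    models: TissueModelSet,
    pulse: PulseParams,
    grad_dir: np.ndarray,
    fiber_dir: Optional[np.ndarray] = None,
    powder_average: bool = False,
) -> float:
    """Normalized attenuation of a tissue class.

    WM and DGM are orientation dependent and need ``fiber_dir``; pass
    ``powder_average=True`` to fall back to the orientation average over a
    fixed 300-direction antipodal set instead.
    """
    spec = models.spec(tissue)
    if not spec.is_anisotropic:
        return attenuation_compartment(spec, pulse, grad_dir)
    if fiber_dir is not None:
        return attenuation_compartment(spec, pulse, grad_dir, fiber_dir)
    if not powder_average:
        raise ValueError(
            f"tissue {tissue!r} requires fiber_dir (or powder_average=True)"
        )
    vals = [
        attenuation_compartment(spec, pulse, grad_dir, d) for d in _POWDER_CACHE
    ]
    return float(np.mean(vals))
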