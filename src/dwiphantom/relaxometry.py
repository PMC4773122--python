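"""Anatomical (non-diffusion-weighted) spin-echo signal from MR physics.

The equilibrium magnetization of tissue ``j`` is proportional to its proton
density and the static field::

    M_j ~ PD_j * (gamma * hbar)^2 * B0 / (4 * k_B * T_s)

and a multislice 2D spin-echo sequence weights it by relaxation::

    S0_j = M_j * exp(-TE / T2_j) * (1 - exp(-TR / T1_j))

Per-voxel anatomical signal is the volume-fraction-weighted sum of the four
tissue values.  The absolute scale is arbitrary; image-facing signals are
normalized so that a pure-CSF voxel at TE -> 0, TR -> inf reads 1 (only
ratios are physically meaningful).

Relaxation/PD presets ship for 1.5 T and 3 T scanners.  Deep GM is not a
separate column in the preset source and maps onto the GM constants
(overridable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .compartments import GAMMA_HYDROGEN, TISSUES
from .substrate import TissueFractionMap

__all__ = [
    "TissueRelaxation",
    "TissueMRParams",
    "SequenceTiming",
    "magnetization",
    "spin_echo_signal",
    "s0_volume",
    "HBAR",
    "K_BOLTZMANN",
]

HBAR = 1.054571817e-34  # J s
K_BOLTZMANN = 1.380649e-23  # J / K


@dataclass(frozen=True)
class TissueRelaxation:
    """PD (relative, CSF = 1), T1 and T2 in ms for one tissue."""

    pd: float
    t1_ms: float
    t2_ms: float

    def __post_init__(self) -> None:
        if not (self.t1_ms > self.t2_ms > 0):
            raise ValueError("require T1 > T2 > 0")
        if not (0 < self.pd <= 1):
            raise ValueError("PD must lie in (0, 1]")


# scanner-dependent tissue constants (spin-echo presets)
_PRESETS: Dict[str, Dict[str, TissueRelaxation]] = {
    "1.5T": {
        "WM": TissueRelaxation(pd=0.77, t1_ms=500.0, t2_ms=70.0),
        "GM": TissueRelaxation(pd=0.86, t1_ms=833.0, t2_ms=83.0),
        "CSF": TissueRelaxation(pd=1.00, t1_ms=2569.0, t2_ms=329.0),
    },
    "3T": {
        "WM": TissueRelaxation(pd=0.77, t1_ms=832.0, t2_ms=44.0),
        "GM": TissueRelaxation(pd=0.86, t1_ms=1331.0, t2_ms=51.0),
        "CSF": TissueRelaxation(pd=1.00, t1_ms=3700.0, t2_ms=500.0),
    },
}


@dataclass(frozen=True)
class TissueMRParams:
    """Relaxometry constants for the four tissue classes at one field strength."""

    field_strength: str
    WM: TissueRelaxation
    CGM: TissueRelaxation
    DGM: TissueRelaxation
    CSF: TissueRelaxation

    @classmethod
    def preset(cls, field_strength: str) -> "TissueMRParams":
        """Built-in constants for ``"1.5T"`` or ``"3T"``; DGM maps onto GM."""
        key = field_strength.upper().replace(" ", "")
        if key not in _PRESETS:
            raise KeyError(
                f"unknown field strength {field_strength!r}; choose from "
                f"{sorted(_PRESETS)}"
            )
        p = _PRESETS[key]
        return cls(field_strength=key, WM=p["WM"], CGM=p["GM"], DGM=p["GM"],
                   CSF=p["CSF"])

    def tissue(self, name: str) -> TissueRelaxation:
        if name == "GM":
            name = "CGM"
        if name not in TISSUES:
            raise KeyError(f"unknown tissue {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class SequenceTiming:
    """Spin-echo timing and static-field context."""

    te_ms: float
    tr_ms: float
    b0_T: float = 3.0
    ts_K: float = 310.0  # sample temperature, body heat by default

    def __post_init__(self) -> None:
        if not (0 < self.te_ms < self.tr_ms):
            raise ValueError("require 0 < TE < TR")
        if self.b0_T <= 0 or self.ts_K <= 0:
            raise ValueError("B0 and sample temperature must be positive")


def magnetization(pd: float, timing: SequenceTiming,
                  gamma: float = GAMMA_HYDROGEN) -> float:
    """Equilibrium magnetization, arbitrary units; linear in PD and B0."""
    if timing.b0_T <= 0 or timing.ts_K <= 0:
        raise ValueError("B0 and sample temperature must be positive")
    return pd * (gamma * HBAR) ** 2 * timing.b0_T / (4.0 * K_BOLTZMANN * timing.ts_K)


def spin_echo_signal(
    tissue: str,
    params: TissueMRParams,
    timing: SequenceTiming,
    normalized: bool = True,
) -> float:
    """Spin-echo S0 of one tissue.

    ``normalized=True`` (the default) replaces the physical magnetization by
    the relative proton density, so a pure-CSF voxel at TE -> 0, TR -> inf
    yields exactly 1.
    """
    t = params.tissue(tissue)
    m = t.pd if normalized else magnetization(t.pd, timing)
    return (
        m
        * np.exp(-timing.te_ms / t.t2_ms)
        * (1.0 - np.exp(-timing.tr_ms / t.t1_ms))
    )


def s0_volume(
    vf: TissueFractionMap, params: TissueMRParams, timing: SequenceTiming
) -> np.ndarray:
    """Volume-fraction-weighted anatomical signal, zero outside the brain mask."""
    s0 = np.array([spin_echo_signal(t, params, timing) for t in TISSUES])
    out = vf.fractions @ s0
    out[~vf.brain_mask] = 0.0
    return out
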