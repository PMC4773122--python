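"""Independent numerical oracles used by the test suite.

These deliberately avoid the code paths they validate:

* :func:`mc_cylinder_perp_attenuation` — Monte-Carlo random walk of spins in
  a reflecting disk, phases accumulated under the two gradient pulses;
* :func:`dirichlet_truncation` — direct trigonometric partial sum of a 1D
  profile restricted to a centered band of DFT frequencies;
* :func:`multistart_direction_energy` — brute-force random-restart minimum of
  the antipodal electrostatic energy.
"""

from __future__ import annotations

import math

import numpy as np


def _mc_path_integrals(
    n_walkers: int,
    n_steps: int,
    sigma: float,
    radius: float,
    s_delta: int,
    s_Delta: int,
    seed: int,
) -> np.ndarray:
    """Per-walker integral sum_s w_s (x_old + x) over the two pulse windows
    (w = +1 during the first pulse, -1 during the second), reflecting disk."""
    rng = np.random.default_rng(seed)
    # uniform start inside the disk (polar inversion sampling)
    r0 = radius * np.sqrt(rng.random(n_walkers))
    th0 = 2.0 * math.pi * rng.random(n_walkers)
    x = r0 * np.cos(th0)
    y = r0 * np.sin(th0)
    integral = np.zeros(n_walkers)
    x_old = np.empty_like(x)
    r2 = np.empty_like(x)
    radius2 = radius * radius
    for s in range(n_steps):
        np.copyto(x_old, x)
        steps = rng.standard_normal((2, n_walkers))
        x += sigma * steps[0]
        y += sigma * steps[1]
        np.multiply(x, x, out=r2)
        r2 += y * y
        out = r2 > radius2
        if out.any():  # radial specular reflection, few walkers per step
            rr = np.sqrt(r2[out])
            sc = (2.0 * radius - rr) / rr
            x[out] *= sc
            y[out] *= sc
        # trapezoid rule over the step; pulse edges fall on the grid
        if s < s_delta:
            integral += x_old
            integral += x
        elif s_Delta <= s < s_Delta + s_delta:
            integral -= x_old
            integral -= x
    return integral


def mc_cylinder_perp_attenuation_multi(
    d: float,
    radius: float,
    delta: float,
    Delta: float,
    G_values,
    gamma: float = 2.6752219e8,
    n_walkers: int = 100_000,
    seed: int = 1234,
    dt_max: float = 1.0e-5,
):
    """[(attenuation, standard error), ...] for gradient perpendicular to the
    axis, one entry per requested gradient amplitude.

    The accumulated spin phase is linear in G, so one set of walker paths
    serves every amplitude (results share paths but each carries its own
    standard error).
    """
    # keep the RMS step well below the radius, and make delta/Delta integer
    # multiples of dt so the pulse windows align with the step grid
    dt = min(dt_max, (radius / 20.0) ** 2 / (4.0 * d), delta / 100.0)
    s_delta = int(round(delta / dt))
    dt = delta / s_delta
    s_Delta = int(round(Delta / dt))
    n_steps = s_Delta + s_delta
    sigma = math.sqrt(2.0 * d * dt)
    integral = _mc_path_integrals(
        n_walkers, n_steps, sigma, radius, s_delta, s_Delta, seed
    )
    out = []
    for G in G_values:
        c = np.cos(integral * (0.5 * gamma * G * dt))
        out.append((float(c.mean()), float(c.std(ddof=1) / math.sqrt(n_walkers))))
    return out


def mc_cylinder_perp_attenuation(
    d: float,
    radius: float,
    delta: float,
    Delta: float,
    G: float,
    gamma: float = 2.6752219e8,
    n_walkers: int = 100_000,
    seed: int = 1234,
    dt_max: float = 1.0e-5,
):
    """(attenuation, standard error) for gradient perpendicular to the axis."""
    return mc_cylinder_perp_attenuation_multi(
        d, radius, delta, Delta, [G], gamma=gamma, n_walkers=n_walkers,
        seed=seed, dt_max=dt_max,
    )[0]


def dirichlet_truncation(profile: np.ndarray, keep: int) -> np.ndarray:
    """Band-limit a 1D profile to its ``keep`` centered DFT frequencies,
    resampled at ``keep`` points, by direct trigonometric summation.

    Matches an fftshift-crop-ifft pipeline but shares no code with it.
    """
    n = len(profile)
    coeffs = {}
    for m in range(-(keep // 2), keep - keep // 2):
        coeffs[m] = sum(
            profile[j] * np.exp(-2j * np.pi * m * j / n) for j in range(n)
        ) / n
    step = n // keep
    out = np.zeros(keep, dtype=complex)
    for i in range(keep):
        j = i * step  # coarse sample sits on the native grid
        for m, c in coeffs.items():
            out[i] += c * np.exp(2j * np.pi * m * j / n)
    return np.abs(out)


def dirichlet_truncation_fine(
    profile: np.ndarray, keep: int, oversample: int = 1
) -> np.ndarray:
    """Same band-limiting, evaluated on an ``oversample``-times finer grid
    (the trigonometric interpolant between native samples)."""
    n = len(profile)
    x = np.arange(n * oversample) / oversample
    out = np.zeros(len(x), dtype=complex)
    for m in range(-(keep // 2), keep - keep // 2):
        c = sum(profile[j] * np.exp(-2j * np.pi * m * j / n) for j in range(n)) / n
        out += c * np.exp(2j * np.pi * m * x / n)
    return np.abs(out)


def multistart_direction_energy(
    n: int, n_restarts: int = 100, seed: int = 0
) -> float:
    """Best antipodal electrostatic energy over random-restart local searches.

    Optimizes over spherical angles with derivative-free Powell search — an
    independent parameterization and optimizer from the implementation's
    normalized-Cartesian L-BFGS route.
    """
    from scipy.optimize import minimize

    rng = np.random.default_rng(seed)

    def energy_angles(angles: np.ndarray) -> float:
        th = angles[:n]
        ph = angles[n:]
        x = np.column_stack(
            [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
        )
        e = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                e += 1.0 / np.linalg.norm(x[i] - x[j])
                e += 1.0 / np.linalg.norm(x[i] + x[j])
        return e

    best = np.inf
    for _ in range(n_restarts):
        th0 = np.arccos(rng.uniform(-1, 1, size=n))
        ph0 = rng.uniform(0, 2 * np.pi, size=n)
        res = minimize(
            energy_angles,
            np.concatenate([th0, ph0]),
            method="Powell",
            options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 100000},
        )
        best = min(best, res.fun)
    return best
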