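"""Exponential kinetic fits for deconvoluted component timecourses.

Two forms are supported: a single-exponential decay
``I(t) = I0 * exp(-k t)`` for disappearing species and a rise to
plateau ``y(t) = b * (1 - exp(-k t))`` for appearing species.  Fits
are by nonlinear least squares with log-linear initialization; the
half-life of a first-order process is ``ln 2 / k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

#: fit tolerance for noise-free round trips
FIT_TOL = 1e-8


@dataclass
class KineticFit:
    """Result of a kinetic curve fit.

    ``amplitude`` is I(0) for the decay form and the plateau b for the
    rise form.  ``half_life`` is ``ln 2 / k`` (NaN when the fit did not
    converge to a positive rate).
    """

    model_form: str  # "decay" | "rise"
    amplitude: float
    rate: float
    r_squared: float
    half_life: float
    converged: bool
    message: str = ""

    @property
    def parameters(self) -> dict[str, float]:
        key = "I0" if self.model_form == "decay" else "b"
        return {key: self.amplitude, "k": self.rate}


def half_life(k: float) -> float:
    """First-order half-life ``ln 2 / k`` in the units of 1/k."""
    if k <= 0:
        raise ValueError(f"rate constant must be positive, got {k}")
    return math.log(2.0) / k


def _decay(t: np.ndarray, i0: float, k: float) -> np.ndarray:
    return i0 * np.exp(-k * t)


def _rise(t: np.ndarray, b: float, k: float) -> np.ndarray:
    return b * (1.0 - np.exp(-k * t))


def _r_squared(values: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((values - fitted) ** 2))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < FIT_TOL else 0.0
    return 1.0 - ss_res / ss_tot


def _validate(times, values) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ValueError("times and values must have equal length")
    if t.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t, y


def _init_rate(t: np.ndarray, z: np.ndarray) -> float:
    """Rate guess from a log-linear regression on positive residues z."""
    mask = z > 1e-12
    if mask.sum() < 2:
        return 0.1
    slope = np.polyfit(t[mask], np.log(z[mask]), 1)[0]
    return float(max(-slope, 1e-3))


def _flagged(form: str, amplitude: float, rate: float, r2: float, msg: str) -> KineticFit:
    hl = math.log(2.0) / rate if rate > 0 else math.nan
    return KineticFit(form, amplitude, rate, r2, hl, converged=False, message=msg)


def fit_exponential_decay(times, values) -> KineticFit:
    """Fit ``I(t) = I0 exp(-k t)`` by nonlinear least squares."""
    t, y = _validate(times, values)
    if np.ptp(y) < FIT_TOL:
        return _flagged("decay", float(y.mean()), 0.0, 1.0, "constant series: rate not identifiable")
    i0_guess = float(max(y[0], y.max(), 1e-6))
    k_guess = _init_rate(t, y / i0_guess)
    try:
        popt, _ = curve_fit(_decay, t, y, p0=[i0_guess, k_guess], maxfev=20000)
    except RuntimeError as e:
        return _flagged("decay", i0_guess, k_guess, 0.0, f"non-convergence: {e}")
    i0, k = float(popt[0]), float(popt[1])
    r2 = _r_squared(y, _decay(t, i0, k))
    if k <= 0:
        return _flagged("decay", i0, k, r2, "fitted rate is non-positive")
    return KineticFit("decay", i0, k, r2, half_life(k), converged=True)


def fit_exponential_rise(times, values) -> KineticFit:
    """Fit ``y(t) = b (1 - exp(-k t))`` by nonlinear least squares."""
    t, y = _validate(times, values)
    if np.all(np.abs(y) < FIT_TOL):
        return _flagged("rise", 0.0, 0.0, 1.0, "all-zero series: plateau at 0 boundary")
    if np.ptp(y) < FIT_TOL:
        return _flagged("rise", float(y.mean()), 0.0, 1.0, "constant series: rate not identifiable")
    b_guess = float(max(y[-1], y.max(), 1e-6))
    k_guess = _init_rate(t, 1.0 - np.clip(y / b_guess, None, 1.0 - 1e-12))
    try:
        popt, _ = curve_fit(_rise, t, y, p0=[b_guess, k_guess], maxfev=20000)
    except RuntimeError as e:
        return _flagged("rise", b_guess, k_guess, 0.0, f"non-convergence: {e}")
    b, k = float(popt[0]), float(popt[1])
    r2 = _r_squared(y, _rise(t, b, k))
    if k <= 0:
        return _flagged("rise", b, k, r2, "fitted rate is non-positive")
    return KineticFit("rise", b, k, r2, half_life(k), converged=True)
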