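"""Fitting of in vivo dye-clearance and infusion traces.

After a bolus dye injection the tissue fluorescence decays multi-exponentially
(fast elimination plus a slow lipid-reservoir tail). Traces are fitted with

    F(t) = a exp(-t/tau1) + b exp(-t/tau2) + c

by bounded nonlinear least squares with seeded multi-start, beginning at the
maximum-intensity sample when the injection rise was captured. An *effective*
time constant summarizes the bi-exponential decay as the time at which the
baseline-subtracted model falls to 1/e of its initial value; an
amplitude-weighted mean of the two constants is available as an alternative.

Infusion experiments (dye pumped at controlled rates) are summarized by
per-window ordinary least-squares slopes of the rising fluorescence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq, curve_fit

from .errors import DomainError, FitError

__all__ = [
    "ClearanceTrace",
    "ClearanceFit",
    "fit_double_exponential",
    "effective_time_constant",
    "fit_infusion_slope",
]

TAU_BOUNDS = (0.1, 1e4)  # minutes
#: amplitude below this fraction of the total marks the component unidentifiable
AMPLITUDE_ID_FRACTION = 1e-3


@dataclass(frozen=True)
class ClearanceTrace:
    """A time series of mean ROI fluorescence (times in minutes)."""

    times: np.ndarray
    intensities: np.ndarray
    baseline: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise DomainError("times and intensities must be 1-D, same length")
        if np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise DomainError("intensities must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class ClearanceFit:
    """Double-exponential fit, canonically ordered so tau1 <= tau2."""

    a: float
    tau1: float
    b: float
    tau2: float
    c: float
    residual: float  # sum of squared residuals
    tau2_identifiable: bool = True

    def __post_init__(self) -> None:
        if self.tau1 > self.tau2:
            raise DomainError("canonical ordering requires tau1 <= tau2")

    def model(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.a * np.exp(-t / self.tau1)
                + self.b * np.exp(-t / self.tau2) + self.c)


def _double_exp(t, a, tau1, b, tau2, c):
    return a * np.exp(-t / tau1) + b * np.exp(-t / tau2) + c


def _canonicalize(a, tau1, b, tau2, c, ssr) -> ClearanceFit:
    if tau1 > tau2:
        a, tau1, b, tau2 = b, tau2, a, tau1
    total = a + b
    identifiable = bool(total > 0 and b > AMPLITUDE_ID_FRACTION * total)
    return ClearanceFit(a=float(a), tau1=float(tau1), b=float(b),
                        tau2=float(tau2), c=float(c), residual=float(ssr),
                        tau2_identifiable=identifiable)


def fit_double_exponential(trace: ClearanceTrace, n_restarts: int = 16,
                           seed: int | None = None) -> ClearanceFit:
    """Fit F(t) = a exp(-t/tau1) + b exp(-t/tau2) + c to the post-peak decay.

    Fitting starts at the maximum-intensity sample so a captured injection
    rise is excluded; time is re-referenced to that sample. ``n_restarts``
    seeded initializations (log-uniform time constants, data-scaled
    amplitudes) are tried and the best-residual convergent fit is returned
    with time constants ordered ``tau1 <= tau2``. A vanishing slow amplitude
    is flagged via ``tau2_identifiable=False``.
    """
    peak = int(np.argmax(trace.intensities))
    t = trace.times[peak:] - trace.times[peak]
    y = trace.intensities[peak:]
    if t.size < 6:
        raise DomainError("need at least 6 samples after the peak")
    if np.ptp(y) == 0:
        raise FitError("degenerate (constant) trace")

    span = y[0] - y[-1]
    scale = max(abs(span), np.ptp(y))
    t_span = t[-1] - t[0]
    rng = np.random.default_rng(seed)
    lo = [0.0, TAU_BOUNDS[0], 0.0, TAU_BOUNDS[0], -np.inf]
    hi = [np.inf, TAU_BOUNDS[1], np.inf, TAU_BOUNDS[1], np.inf]

    best = None
    for k in range(n_restarts):
        if k == 0:
            tau1_0 = max(TAU_BOUNDS[0] * 2, 0.1 * t_span)
            tau2_0 = min(TAU_BOUNDS[1] / 2, t_span)
        else:
            tau1_0, tau2_0 = np.exp(rng.uniform(
                math.log(max(TAU_BOUNDS[0], t_span * 1e-3)),
                math.log(min(TAU_BOUNDS[1], t_span * 10.0)), size=2))
        p0 = [0.7 * scale, tau1_0, 0.3 * scale, tau2_0, float(y[-1])]
        try:
            popt, _ = curve_fit(_double_exp, t, y, p0=p0, bounds=(lo, hi),
                                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((y - _double_exp(t, *popt)) ** 2))
        if best is None or ssr < best[1]:
            best = (popt, ssr)
    if best is None:
        raise FitError("no restart of the double-exponential fit converged")
    popt, ssr = best
    return _canonicalize(*popt, ssr)


def effective_time_constant(fit: ClearanceFit, *,
                            weighted: bool = False) -> float:
    """Summarize the bi-exponential decay by one time constant (minutes).

    Default: the 1/e crossing of the baseline-subtracted model, i.e. the root
    of ``a exp(-t/tau1) + b exp(-t/tau2) = (a + b)/e``. With
    ``weighted=True`` the amplitude-weighted mean of tau1 and tau2 is
    returned instead. Either summary lies between min and max of the two
    time constants.
    """
    a, b = fit.a, fit.b
    if a + b <= 0:
        raise DomainError("fit has no decaying amplitude")
    if weighted:
        return (a * fit.tau1 + b * fit.tau2) / (a + b)
    if a == 0:
        return fit.tau2
    if b == 0 or not fit.tau2_identifiable and b < AMPLITUDE_ID_FRACTION * (a + b):
        return fit.tau1

    target = (a + b) / math.e

    def f(t: float) -> float:
        return a * math.exp(-t / fit.tau1) + b * math.exp(-t / fit.tau2) - target

    lo, hi = fit.tau1 * (1 - 1e-12), fit.tau2 * (1 + 1e-12)
    if f(lo) * f(hi) > 0:  # degenerate tau1 ~ tau2
        return fit.tau1
    return brentq(f, lo, hi, xtol=1e-10)


def fit_infusion_slope(trace: ClearanceTrace, pump_windows) -> list[dict]:
    """OLS slope and intercept of the fluorescence rise per pump window.

    ``pump_windows`` is an iterable of ``(t_start, t_end)`` pairs in the
    trace's time unit; each window must contain at least 3 samples. Returns a
    list of dicts with slope, intercept, their standard errors and n.
    """
    results = []
    for t0, t1 in pump_windows:
        if t1 <= t0:
            raise DomainError("pump window must have t_end > t_start")
        if t0 < trace.times[0] - 1e-12 or t1 > trace.times[-1] + 1e-12:
            raise DomainError("pump window outside the trace")
        mask = (trace.times >= t0) & (trace.times <= t1)
        if mask.sum() < 3:
            raise DomainError("pump window contains fewer than 3 samples")
        res = stats.linregress(trace.times[mask], trace.intensities[mask])
        results.append({
            "t_start": float(t0), "t_end": float(t1),
            "slope": float(res.slope), "intercept": float(res.intercept),
            "slope_stderr": float(res.stderr),
            "intercept_stderr": float(res.intercept_stderr),
            "n": int(mask.sum()),
        })
    return results
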