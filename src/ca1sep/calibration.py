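"""Calibrating the network to a target CA1 spiking probability.

In vivo, CA1 place cells fire at ~7 Hz at field peak, i.e. with probability
~0.14 per 20 ms gamma window.  Calibration asks: at what presynaptic
activity level does the model patch reach that output probability?  The
procedure sweeps activity levels, estimates the action-potential-initiation
(API) probability at each from Monte-Carlo input patterns, fits a Boltzmann
sigmoid

    f(x) = 1 / (1 + exp((x_half - x) / slope)),

and inverts the fit at the target probability.  The threshold surrogate has
one extra free parameter — its firing threshold theta — which is set first
by bisection (valid because the spiking fraction is non-increasing in
theta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .connectivity import ProjectionMap
from .patterns import random_pattern
from .response_models import ThresholdSurrogate, population_response

__all__ = [
    "ActivitySweep",
    "BoltzmannFit",
    "CalibrationResult",
    "FitError",
    "CalibrationError",
    "active_count_at",
    "sweep",
    "fit_boltzmann",
    "invert_for_target",
    "calibrate_threshold",
]


class FitError(RuntimeError):
    """Sigmoid fit impossible (degenerate sweep)."""


class CalibrationError(RuntimeError):
    """Target spiking probability unreachable for this model and activity."""


def active_count_at(p: float, n_pre: int) -> int:
    """Active presynaptic cells at proportion p: round(p * n_pre)."""
    return int(math.floor(p * n_pre + 0.5))


def boltzmann(x, x_half, slope):
    """Monotone sigmoid with unit amplitude; f(x_half) = 0.5."""
    return 1.0 / (1.0 + np.exp((x_half - x) / slope))


@dataclass(frozen=True)
class ActivitySweep:
    """API probability estimates over a grid of presynaptic activity levels."""

    levels: np.ndarray
    api_prob: np.ndarray
    n_patterns: int
    n_post: int
    pathway: str = ""

    def __post_init__(self):
        lv, ap = np.asarray(self.levels, float), np.asarray(self.api_prob, float)
        if lv.size == 0:
            raise ValueError("empty sweep")
        if lv.size != ap.size:
            raise ValueError("levels and api_prob differ in length")
        if np.any(np.diff(lv) <= 0):
            raise ValueError("levels must be strictly increasing")
        if np.any((ap < 0) | (ap > 1)):
            raise ValueError("api_prob outside [0, 1]")
        object.__setattr__(self, "levels", lv)
        object.__setattr__(self, "api_prob", ap)


@dataclass(frozen=True)
class BoltzmannFit:
    """Least-squares Boltzmann parameters; amplitude fixed at 1."""

    x_half: float
    slope: float
    residual_rms: float
    cov: np.ndarray

    def predict(self, x):
        return boltzmann(x, self.x_half, self.slope)


@dataclass(frozen=True)
class CalibrationResult:
    theta: float
    achieved: float
    n_patterns: int


def sweep(
    model: ThresholdSurrogate,
    pmap: ProjectionMap,
    levels,
    n_patterns: int,
    rng: np.random.Generator,
    pathway: str | None = None,
) -> ActivitySweep:
    """Estimate the API probability at each activity level.

    Per level, ``n_patterns`` random input patterns with round(level * n_pre)
    active cells are pushed through the network; api_prob is the mean output
    spiking fraction.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("empty level list")
    if np.any((levels <= 0) | (levels >= 1)):
        raise ValueError("levels must lie in (0, 1)")
    name = pathway or pmap.spec.name
    api = np.empty(levels.size)
    for i, lv in enumerate(levels):
        k = active_count_at(lv, pmap.spec.n_pre)
        frac = 0.0
        for _ in range(n_patterns):
            pat = random_pattern(pmap.spec.n_pre, k, rng)
            out = population_response(model, {name: pmap}, {name: pat})
            frac += out.k / pmap.n_post
        api[i] = frac / n_patterns
    return ActivitySweep(
        levels=levels, api_prob=api, n_patterns=n_patterns,
        n_post=pmap.n_post, pathway=name,
    )


def fit_boltzmann(sw: ActivitySweep) -> BoltzmannFit:
    """Fit the unit-amplitude Boltzmann sigmoid to a sweep.

    Weighted least squares: each point's weight follows the binomial counting
    noise of its probability estimate (variance y(1-y)/n_patterns, floored so
    saturated points keep a finite weight).  The covariance is reported on
    that absolute noise scale.
    """
    x, y = sw.levels, sw.api_prob
    if x.size < 3:
        raise FitError("need at least 3 levels to fit")
    if y.max() - y.min() < 1e-12 or y.max() < 0.01 or y.min() > 0.99:
        raise FitError(
            "degenerate sweep: no transition between 0 and 1 is visible"
        )
    x_half0 = float(x[np.argmin(np.abs(y - 0.5))])
    slope0 = max((x.max() - x.min()) / 10.0, 1e-6)
    # variance floor (y clipped to [0.02, 0.98]) keeps saturated points from
    # dominating: the sigmoid is only an approximation in the far tails
    sigma = np.sqrt(np.maximum(y * (1 - y), 0.02 * 0.98) / max(sw.n_patterns, 1))
    popt, pcov = curve_fit(
        boltzmann, x, y, p0=[x_half0, slope0],
        sigma=sigma, absolute_sigma=True,
        bounds=([x.min() - 5 * (x.max() - x.min()), 1e-12],
                [x.max() + 5 * (x.max() - x.min()), np.inf]),
        maxfev=20000,
    )
    resid = y - boltzmann(x, *popt)
    return BoltzmannFit(
        x_half=float(popt[0]),
        slope=float(popt[1]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        cov=pcov,
    )


def invert_for_target(fit: BoltzmannFit, p_target: float) -> float:
    """Activity level at which the fitted curve equals p_target.

    Closed form: x = x_half - slope * ln(1/p_target - 1); exact inverse of
    ``fit.predict``.
    """
    if not 0 < p_target < 1:
        raise ValueError(f"p_target={p_target} outside (0, 1)")
    return fit.x_half - fit.slope * math.log(1.0 / p_target - 1.0)


def calibrate_threshold(
    model: ThresholdSurrogate,
    pmap: ProjectionMap,
    activity: float,
    p_target: float,
    rng: np.random.Generator,
    n_patterns: int = 50,
    tol: float = 0.005,
    max_iter: int = 200,
) -> CalibrationResult:
    """Set the surrogate's theta so the patch spikes at p_target.

    Evaluates the mean spiking fraction on a fixed set of ``n_patterns``
    input patterns at the given activity level, as a function of theta, and
    bisects (the fraction is non-increasing in theta).  Stops when the
    fraction is within ``tol`` of p_target; if the fraction jumps over the
    target (atomic drive distribution, e.g. constant weights), the bisection
    collapses onto the jump and the nearer side is returned.  Raises
    :class:`CalibrationError` when p_target exceeds the largest reachable
    fraction.

    The model's ``theta`` attribute is updated in place to the returned value.
    """
    if not 0 < p_target < 1:
        raise ValueError(f"p_target={p_target} outside (0, 1)")
    name = pmap.spec.name
    k = active_count_at(activity, pmap.spec.n_pre)
    drives = np.empty((n_patterns, pmap.n_post))
    for i in range(n_patterns):
        pat = random_pattern(pmap.spec.n_pre, k, rng)
        drives[i] = model.drive({name: pmap}, {name: pat})

    def frac(theta: float) -> float:
        return float((drives >= theta).mean())

    # theta stays positive: a cell with no active synapses must never fire
    lo, hi = 1e-12, float(drives.max()) + 1.0
    f_lo = frac(lo)  # largest reachable fraction (cells with any positive drive)
    if f_lo < p_target - tol:
        raise CalibrationError(
            f"target {p_target} unreachable: max fraction {f_lo:.4f}"
        )
    best_theta, best_gap = lo, abs(f_lo - p_target)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = frac(mid)
        gap = abs(f_mid - p_target)
        if gap < best_gap:
            best_theta, best_gap = mid, gap
        if gap <= tol:
            model.theta = mid
            return CalibrationResult(theta=mid, achieved=f_mid, n_patterns=n_patterns)
        if f_mid > p_target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * max(1.0, abs(hi)):
            break
    # interval collapsed onto an atom of the drive distribution
    model.theta = best_theta
    return CalibrationResult(
        theta=best_theta, achieved=frac(best_theta), n_patterns=n_patterns
    )
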