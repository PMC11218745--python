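"""Intensity-discrimination task logic and psychometric threshold fitting.

Pairs of vibrotactile stimuli are presented: a 100%-intensity reference
followed by a second stimulus whose intensity descends a 5%-step grid.
The participant reports whether the two felt equal.  Per intensity, the
fraction of "equal" reports (the response ratio, 0 = always unequal,
1 = always equal) is fitted with a two-parameter logistic, and the
somatosensory sensitivity threshold is the intensity at which the
fitted curve crosses 0.5.

The trial scheduler works adaptively: after an initial randomized sweep
of the whole grid it concentrates trials on intensities whose current
response ratio is still ambiguous (strictly between 0.2 and 0.8),
falling back to the whole grid when nothing is ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)


class PsychometricFitError(RuntimeError):
    """No threshold can be computed from the responses."""


Trial = tuple[float, bool]


def response_ratios(trials: list[Trial]) -> dict[float, float]:
    """Per intensity, the fraction of trials reported as equal."""
    counts: dict[float, list[int]] = {}
    for intensity, equal in trials:
        eq, n = counts.setdefault(float(intensity), [0, 0])
        counts[float(intensity)] = [eq + bool(equal), n + 1]
    return {x: eq / n for x, (eq, n) in sorted(counts.items())}


def trial_counts(trials: list[Trial]) -> dict[float, int]:
    counts: dict[float, int] = {}
    for intensity, _ in trials:
        counts[float(intensity)] = counts.get(float(intensity), 0) + 1
    return dict(sorted(counts.items()))


@dataclass
class SchedulerState:
    """Seeded state of the adaptive intensity scheduler."""

    grid: tuple[float, ...]
    seed: int = 0
    max_trials: int = 53
    ambiguity_band: tuple[float, float] = (0.2, 0.8)

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError("intensity grid must be non-empty")
        self._rng = np.random.default_rng(self.seed)
        self._sweep = list(self._rng.permutation(np.asarray(self.grid, dtype=float)))


def next_intensity(trials: list[Trial], state: SchedulerState) -> float | None:
    """Choose the next second-stimulus intensity, or None when done.

    Initial phase: a seeded random sweep over the full grid.  Adaptive
    phase: sample uniformly among intensities whose current response
    ratio lies strictly inside the ambiguity band (untested intensities
    count as ambiguous); when none qualify, fall back to the full grid.
    """
    if len(trials) >= state.max_trials:
        return None
    if len(trials) < len(state._sweep):
        return float(state._sweep[len(trials)])
    ratios = response_ratios(trials)
    lo, hi = state.ambiguity_band
    ambiguous = [x for x in state.grid
                 if x not in ratios or lo < ratios[x] < hi]
    pool = ambiguous if ambiguous else list(state.grid)
    return float(pool[state._rng.integers(len(pool))])


@dataclass
class PsychometricFit:
    """Fitted logistic: ratio = 1 / (1 + exp(−(x − midpoint)/slope))."""

    midpoint_pct: float
    slope: float
    converged: bool
    n_trials_used: int
    boundary: bool = False

    @property
    def threshold_pct(self) -> float:
        return self.midpoint_pct


def _logistic(x, midpoint, slope):
    from scipy.special import expit

    return expit((x - midpoint) / slope)


def fit_sigmoid(ratios: dict[float, float],
                weights: dict[float, int] | None = None,
                likelihood: bool = False) -> PsychometricFit:
    """Fit the response-ratio curve with a 2-parameter logistic.

    By default a weighted least-squares fit of the per-intensity ratios
    (weights = trial counts); with ``likelihood=True`` a binomial
    maximum-likelihood fit of the same logistic.  The asymptotes are
    fixed at 0 and 1 — the response scale is defined that way — so no
    lapse parameters are fitted.  One-sided data (all ratios on the same
    side of 0.5) or optimizer failure yield ``converged=False``.
    """
    xs = np.array(sorted(ratios))
    ys = np.array([ratios[x] for x in xs])
    n_used = int(sum((weights or {}).values())) if weights else len(xs)
    if len(xs) < 3:
        return PsychometricFit(np.nan, np.nan, False, n_used)
    if ys.min() > 0.5 or ys.max() < 0.5 or np.ptp(ys) < 1e-12:
        return PsychometricFit(np.nan, np.nan, False, n_used)
    w = np.array([(weights or {}).get(x, 1) for x in xs], dtype=float)

    # start near the empirical 0.5 crossing
    crossing = xs[np.argmin(np.abs(ys - 0.5))]
    span = (xs.max() - xs.min()) or 1.0
    p0 = (float(crossing), span / 10.0)
    try:
        if likelihood:
            def nll(params):
                p = np.clip(_logistic(xs, *params), 1e-9, 1 - 1e-9)
                return -np.sum(w * (ys * np.log(p) + (1 - ys) * np.log(1 - p)))
            from scipy.optimize import minimize
            res = minimize(nll, p0, method="Nelder-Mead")
            if not res.success:
                raise RuntimeError(res.message)
            midpoint, slope = res.x
        else:
            import warnings

            from scipy.optimize import OptimizeWarning

            with warnings.catch_warnings():
                # near-step data make the parameter covariance singular;
                # only the point estimate is used here
                warnings.simplefilter("ignore", OptimizeWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                # slope is bounded below: steeper than ~1/20 of a grid
                # step is indistinguishable from a step function, and an
                # unbounded fit diverges on step-like data
                (midpoint, slope), _ = curve_fit(
                    _logistic, xs, ys, p0=p0, sigma=1.0 / np.sqrt(w),
                    absolute_sigma=False, method="trf", max_nfev=10000,
                    bounds=([xs.min() - 2 * span, 0.25],
                            [xs.max() + 2 * span, 10 * span]))
    except (RuntimeError, ValueError) as exc:
        logger.info("sigmoid fit failed: %s", exc)
        return PsychometricFit(np.nan, np.nan, False, n_used)
    if slope <= 0:
        return PsychometricFit(float(midpoint), float(slope), False, n_used)
    boundary = not (xs.min() <= midpoint <= xs.max())
    return PsychometricFit(float(midpoint), float(slope), True, n_used,
                           boundary=boundary)


def estimate_threshold(trials: list[Trial], likelihood: bool = False
                       ) -> PsychometricFit:
    """Response ratios → sigmoid fit → 50%-point threshold.

    Raises :class:`PsychometricFitError` when no converged fit is
    possible (mirroring the exclusion of participants whose responses
    stay too inconsistent for a threshold).
    """
    ratios = response_ratios(trials)
    fit = fit_sigmoid(ratios, trial_counts(trials), likelihood=likelihood)
    fit.n_trials_used = len(trials)
    if not fit.converged:
        raise PsychometricFitError(
            f"no threshold from {len(trials)} trials: responses one-sided "
            "or fit did not converge")
    return fit


def run_discrimination_session(observer, scheduler: SchedulerState,
                               rng: np.random.Generator | None = None
                               ) -> list[Trial]:
    """Drive the adaptive scheduler against a simulated observer.

    ``observer`` is a :class:`gridtap.simulate.PsychoSimConfig`; the
    scheduler picks intensities, the observer answers, until the trial
    budget is exhausted.
    """
    from .simulate import equal_probability

    if rng is None:
        rng = np.random.default_rng(observer.seed)
    trials: list[Trial] = []
    while (x := next_intensity(trials, scheduler)) is not None:
        equal = bool(rng.random() < equal_probability(x, observer))
        trials.append((x, equal))
    return trials
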