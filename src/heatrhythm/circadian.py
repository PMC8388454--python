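"""Circadian (cosinor-style) harmonic models of hourly behavior budgets.

Two model forms are supported:

* ``single`` — baseline plus one sine wave with the period fixed at 24 h::

      y(h) = mu + a * sin(2*pi/24 * h + b)

  used for behaviors with one daily peak (rest, activity, heavy breathing).

* ``double`` — baseline plus a sine and a cosine wave whose periods are
  both estimated freely::

      y(h) = mu + a * sin(2*pi/T1 * h + b) + c * cos(2*pi/T2 * h + d)

  used for behaviors with several daily peaks (eating, rumination), which
  are driven by management events (milking, feed delivery) as much as by
  the light cycle.

Phases ``b`` and ``d`` are additive radian offsets.  Fitting is nonlinear
least squares (`scipy.optimize.least_squares`) started from a deterministic
brute-force grid search; the core estimator is the scikit-learn-compatible
:class:`CircadianRegressor`, with :func:`fit_model` as a thin functional
wrapper.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CircadianModel",
    "GridConfig",
    "CircadianFit",
    "PatternSummary",
    "PatternComparison",
    "CircadianRegressor",
    "evaluate_model",
    "model_mean",
    "grid_initialize",
    "fit_model",
    "adjusted_r2",
    "summarize_pattern",
    "compare_patterns",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class CircadianModel:
    """Parameter set of a single- or double-harmonic circadian model.

    ``form`` is ``"single"`` or ``"double"``.  For the single form ``c``,
    ``d`` and ``period2`` must be ``None`` and ``period1`` is conventionally
    24 h.  Phases are additive: a printed equation written as
    ``cos(2*pi/T' * Hour - d)`` corresponds to ``d_stored = -d_printed``.
    """

    form: str
    mu: float
    a: float
    b: float
    period1: float = 24.0
    c: Optional[float] = None
    d: Optional[float] = None
    period2: Optional[float] = None
    behavior: Optional[str] = None

    def __post_init__(self) -> None:
        if self.form not in ("single", "double"):
            raise ValueError(f"unknown model form {self.form!r}")
        if self.period1 <= 0:
            raise ValueError("period1 must be positive")
        if self.form == "single":
            if self.c is not None or self.d is not None or self.period2 is not None:
                raise ValueError("single form takes no second-harmonic parameters")
        else:
            if self.c is None or self.d is None or self.period2 is None:
                raise ValueError("double form requires c, d and period2")
            if self.period2 <= 0:
                raise ValueError("period2 must be positive")

    def evaluate(self, hour):
        """Model value (minutes/hour) at ``hour``; vectorized over arrays."""
        h = np.asarray(hour, dtype=float)
        y = self.mu + self.a * np.sin(_TWO_PI / self.period1 * h + self.b)
        if self.form == "double":
            y = y + self.c * np.cos(_TWO_PI / self.period2 * h + self.d)
        return float(y) if np.isscalar(hour) else y

    def normalized(self) -> "CircadianModel":
        """Equivalent model with non-negative amplitudes and phases in (-pi, pi].

        Uses the identities ``-a*sin(x+b) = a*sin(x+b+pi)`` and
        ``-c*cos(x+d) = c*cos(x+d+pi)``; pointwise values are unchanged.
        """
        a, b = self.a, self.b
        if a < 0:
            a, b = -a, b + math.pi
        b = _wrap_phase(b)
        if self.form == "single":
            return replace(self, a=a, b=b)
        c, d = self.c, self.d
        if c < 0:
            c, d = -c, d + math.pi
        return replace(self, a=a, b=b, c=c, d=_wrap_phase(d))

    @property
    def n_parameters(self) -> int:
        return 3 if self.form == "single" else 7


def _wrap_phase(phi: float) -> float:
    """Map a radian phase into (-pi, pi]."""
    wrapped = math.remainder(phi, _TWO_PI)
    if wrapped <= -math.pi:
        wrapped += _TWO_PI
    return wrapped


def evaluate_model(model: CircadianModel, hour):
    """Evaluate ``model`` at ``hour`` (any real number; periodicity is innate)."""
    return model.evaluate(hour)


def model_mean(model: CircadianModel, n_grid: int = 1440) -> float:
    """Time average of the model over one 24-h day on a uniform grid.

    For the single form (period exactly 24 h) the harmonic averages to zero
    over the grid and the result equals ``mu`` to floating-point precision.
    """
    if n_grid < 1440:
        raise ValueError("n_grid must be at least 1440")
    hours = np.arange(n_grid) * (24.0 / n_grid)
    return float(np.mean(model.evaluate(hours)))


def adjusted_r2(rss: float, tss: float, n: int, p: int) -> tuple[float, float]:
    """Coefficient of determination and its parameter-count-adjusted version.

    r2 = 1 - RSS/TSS;  r2_adj = 1 - ((n-1)/(n-p)) * (1 - r2).
    """
    if tss <= 0:
        raise ValueError("tss must be positive")
    if p < 1 or n <= p:
        raise ValueError("requires n > p >= 1")
    r2 = 1.0 - rss / tss
    r2_adj = 1.0 - (n - 1) / (n - p) * (1.0 - r2)
    return r2, r2_adj


# --------------------------------------------------------------------------
# Grid-search initialization


@dataclass(frozen=True)
class GridConfig:
    """Candidate grid for brute-force initialization of the nonlinear fit.

    ``phases`` are radian offsets tried for every wave; ``amplitude_fractions``
    multiply the data half-range ``(max - min)/2``; ``periods`` (hours) is used
    only by the double form, where all pairs with ``period2 <= period1`` are
    enumerated.  The defaults cover periods from 4 h to 26 h in 0.5-h steps.
    """

    phases: tuple = tuple(i * math.pi / 8 for i in range(16))
    amplitude_fractions: tuple = (0.25, 0.5, 0.75, 1.0)
    periods: tuple = tuple(np.arange(4.0, 26.0 + 1e-9, 0.5))


_DOUBLE_PHASES = (0.0, math.pi / 2, math.pi, 3 * math.pi / 2)


def default_grid(form: str) -> GridConfig:
    if form == "single":
        return GridConfig()
    return GridConfig(phases=_DOUBLE_PHASES, amplitude_fractions=(0.5,))


def _hour_statistics(hours, values):
    """Sufficient statistics for RSS over repeated hour values.

    RSS(theta) = sum_h n_h * (ybar_h - f(h))**2 + sum_i (y_i - ybar_{h(i)})**2,
    so candidate RSS can be scored on the unique hours only.
    """
    hours = np.asarray(hours, dtype=float)
    values = np.asarray(values, dtype=float)
    uniq, inverse, counts = np.unique(hours, return_inverse=True, return_counts=True)
    sums = np.bincount(inverse, weights=values)
    means = sums / counts
    resid_const = float(np.sum((values - means[inverse]) ** 2))
    return uniq, counts.astype(float), means, resid_const


def grid_initialize(hours, values, form: str, grid: Optional[GridConfig] = None) -> CircadianModel:
    """Deterministic brute-force search for nonlinear-fit start values.

    The baseline ``mu`` is pinned at the sample mean and amplitudes are seeded
    from the data half-range; the candidate minimizing RSS is returned.  Ties
    are broken toward the smallest period, then the smallest phase.
    """
    hours = np.asarray(hours, dtype=float)
    values = np.asarray(values, dtype=float)
    if hours.shape != values.shape or hours.ndim != 1:
        raise ValueError("hours and values must be 1-d arrays of equal length")
    if grid is None:
        grid = default_grid(form)
    if len(grid.phases) == 0 or len(grid.amplitude_fractions) == 0:
        raise ValueError("empty grid")
    if form == "double" and len(grid.periods) == 0:
        raise ValueError("empty grid")

    mu = float(np.mean(values))
    half_range = (float(np.max(values)) - float(np.min(values))) / 2.0
    uniq, counts, means, _ = _hour_statistics(hours, values)
    resid0 = means - mu  # candidate residual target on unique hours

    if form == "single":
        # candidates ordered (phase, amplitude) so argmin tie-breaks correctly
        phases = np.array(sorted(grid.phases), dtype=float)
        amps = np.array(sorted(a * half_range for a in grid.amplitude_fractions))
        basis = np.sin(_TWO_PI / 24.0 * uniq[None, :] + phases[:, None])  # (P, H)
        pred = amps[None, :, None] * basis[:, None, :]  # (P, A, H)
        rss = np.einsum("h,pah->pa", counts, (resid0[None, None, :] - pred) ** 2)
        i, j = np.unravel_index(np.argmin(rss), rss.shape)
        return CircadianModel("single", mu=mu, a=float(amps[j]), b=float(phases[i]))

    periods = np.array(sorted(grid.periods), dtype=float)
    phases = np.array(sorted(grid.phases), dtype=float)
    amp = grid.amplitude_fractions[0] * half_range
    best = None
    # enumerate period pairs with period2 <= period1 to remove the sin/cos
    # relabelling symmetry; candidate order (T1, T2, b, d) fixes tie-breaking
    sin_waves = {
        (ti, bi): amp * np.sin(_TWO_PI / periods[ti] * uniq + phases[bi])
        for ti in range(len(periods))
        for bi in range(len(phases))
    }
    cos_waves = {
        (ti, di): amp * np.cos(_TWO_PI / periods[ti] * uniq + phases[di])
        for ti in range(len(periods))
        for di in range(len(phases))
    }
    for i1 in range(len(periods)):
        for i2 in range(i1 + 1):
            for bi in range(len(phases)):
                s = sin_waves[(i1, bi)]
                for di in range(len(phases)):
                    r = resid0 - s - cos_waves[(i2, di)]
                    rss = float(np.dot(counts, r * r))
                    if best is None or rss < best[0]:
                        best = (rss, i1, i2, bi, di)
    _, i1, i2, bi, di = best
    return CircadianModel(
        "double",
        mu=mu,
        a=float(amp),
        b=float(phases[bi]),
        period1=float(periods[i1]),
        c=float(amp),
        d=float(phases[di]),
        period2=float(periods[i2]),
    )


# --------------------------------------------------------------------------
# Nonlinear least-squares fit


@dataclass
class CircadianFit:
    """Result of a nonlinear least-squares circadian fit."""

    model: CircadianModel
    model_normalized: CircadianModel
    rss: float
    tss: float
    r2: float
    r2_adj: float
    n: int
    p: int
    converged: bool
    grid_candidates_evaluated: int
    param_names: tuple = ()
    param_cov: Optional[np.ndarray] = field(default=None, repr=False)

    def predict(self, hours):
        return self.model.evaluate(hours)

    def predict_se(self, hours):
        """Pointwise standard error of the fitted curve.

        Delta-method band from the linearized parameter covariance at the
        optimum; NaN when the covariance is unavailable.
        """
        h = np.atleast_1d(np.asarray(hours, dtype=float))
        if self.param_cov is None:
            return np.full(h.shape, np.nan)
        g = _model_gradient(self.model, h)  # (n_points, p)
        var = np.einsum("ij,jk,ik->i", g, self.param_cov, g)
        return np.sqrt(np.clip(var, 0.0, None))


def _pack(model: CircadianModel):
    if model.form == "single":
        return np.array([model.mu, model.a, model.b])
    return np.array([model.mu, model.a, model.b, model.period1, model.c, model.d, model.period2])


def _unpack(form: str, theta, behavior=None) -> CircadianModel:
    if form == "single":
        return CircadianModel("single", *map(float, theta), behavior=behavior)
    mu, a, b, t1, c, d, t2 = map(float, theta)
    return CircadianModel("double", mu, a, b, t1, c, d, t2, behavior=behavior)


def _model_gradient(model: CircadianModel, hours: np.ndarray) -> np.ndarray:
    """Analytic gradient of the model value w.r.t. its free parameters."""
    h = hours
    w1 = _TWO_PI / model.period1
    arg1 = w1 * h + model.b
    cols = [np.ones_like(h), np.sin(arg1), model.a * np.cos(arg1)]
    if model.form == "double":
        cols.append(model.a * np.cos(arg1) * (-_TWO_PI * h / model.period1**2))
        w2 = _TWO_PI / model.period2
        arg2 = w2 * h + model.d
        cols.append(np.cos(arg2))
        cols.append(-model.c * np.sin(arg2))
        cols.append(-model.c * np.sin(arg2) * (-_TWO_PI * h / model.period2**2))
        # column order: mu, a, b, period1, c, d, period2
    return np.column_stack(cols)


_PERIOD_BOUNDS = (2.0, 48.0)


class CircadianRegressor(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares cosinor regressor for hourly behavior data.

    Parameters
    ----------
    form : {"single", "double"}
        Single harmonic with the period fixed at 24 h, or sine-plus-cosine
        with both periods estimated freely.
    grid : GridConfig, optional
        Candidate grid for the brute-force start; defaults per form.
    max_iter : int
        Iteration cap for the least-squares refinement.

    Attributes
    ----------
    model_ : CircadianModel
        Fitted parameters (raw signs/phases as returned by the optimizer).
    fit_result_ : CircadianFit
        Full fit record including RSS/TSS, (adjusted) R², convergence flag
        and the linearized parameter covariance.
    """

    def __init__(self, form: str = "single", grid: Optional[GridConfig] = None,
                 max_iter: int = 500):
        self.form = form
        self.grid = grid
        self.max_iter = max_iter

    def fit(self, X, y):
        hours = np.asarray(X, dtype=float)
        if hours.ndim == 2:
            if hours.shape[1] != 1:
                raise ValueError("X must be a 1-d array of hours or an (n, 1) column")
            hours = hours[:, 0]
        values = np.asarray(y, dtype=float)
        if hours.shape != values.shape:
            raise ValueError("X and y lengths differ")
        if not np.all(np.isfinite(values)) or not np.all(np.isfinite(hours)):
            raise ValueError("inputs must be finite")
        grid = self.grid if self.grid is not None else default_grid(self.form)
        start = grid_initialize(hours, values, self.form, grid)
        p = start.n_parameters
        n = hours.size
        if n <= p:
            raise ValueError(f"need more than {p} observations, got {n}")

        n_candidates = len(grid.phases) * len(grid.amplitude_fractions)
        if self.form == "double":
            k = len(grid.periods)
            n_candidates = k * (k + 1) // 2 * len(grid.phases) ** 2

        def residuals(theta):
            return _unpack(self.form, theta).evaluate(hours) - values

        theta0 = _pack(start)
        if self.form == "single":
            bounds = (-np.inf, np.inf)
        else:
            lo = np.full(7, -np.inf)
            hi = np.full(7, np.inf)
            lo[[3, 6]] = _PERIOD_BOUNDS[0]
            hi[[3, 6]] = _PERIOD_BOUNDS[1]
            bounds = (lo, hi)
        res = least_squares(
            residuals, theta0, bounds=bounds, method="trf",
            ftol=1e-10, xtol=1e-8, gtol=1e-10, max_nfev=self.max_iter * (p + 1),
        )
        rss_start = float(np.sum(residuals(theta0) ** 2))
        rss = float(np.sum(res.fun**2))
        converged = res.status > 0
        if rss > rss_start:  # refinement must never lose to its start
            model = start
            rss = rss_start
            converged = False
        else:
            model = _unpack(self.form, res.x, behavior=getattr(self, "behavior_label", None))
        if not converged:
            warnings.warn("circadian fit did not converge", RuntimeWarning)

        tss = float(np.sum((values - values.mean()) ** 2))
        r2, r2a = adjusted_r2(rss, tss, n, p)
        cov = None
        if n > p and rss > 0:
            g = _model_gradient(model, hours)
            jtj = g.T @ g
            cov = rss / (n - p) * np.linalg.pinv(jtj)
        names = ("mu", "a", "b") if self.form == "single" else (
            "mu", "a", "b", "period1", "c", "d", "period2")
        self.model_ = model
        self.fit_result_ = CircadianFit(
            model=model,
            model_normalized=model.normalized(),
            rss=rss, tss=tss, r2=r2, r2_adj=r2a, n=n, p=p,
            converged=converged,
            grid_candidates_evaluated=n_candidates,
            param_names=names, param_cov=cov,
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        hours = np.asarray(X, dtype=float)
        if hours.ndim == 2:
            hours = hours[:, 0]
        return self.model_.evaluate(hours)


def fit_model(hours, values, form: str, grid: Optional[GridConfig] = None,
              behavior: Optional[str] = None) -> CircadianFit:
    """Fit a circadian model to (hour, minutes) observations.

    Thin wrapper over :class:`CircadianRegressor`; see that class for the
    estimation details.
    """
    reg = CircadianRegressor(form=form, grid=grid)
    if behavior is not None:
        reg.behavior_label = behavior
    reg.fit(np.asarray(hours, dtype=float), np.asarray(values, dtype=float))
    fit = reg.fit_result_
    if behavior is not None and fit.model.behavior is None:
        fit.model = replace(fit.model, behavior=behavior)
        fit.model_normalized = fit.model.normalized()
    return fit


# --------------------------------------------------------------------------
# Pattern summaries


@dataclass
class PatternSummary:
    peak_hours: list
    peak_values: list
    trough_hours: list
    trough_values: list
    daily_range: float


@dataclass
class PatternComparison:
    behavior: Optional[str]
    mean_difference: float          # model_mean(NS) - model_mean(HS)
    peak_shift_hours: float         # principal peak, NS - HS, wrapped to (-12, 12]
    range_difference: float         # daily_range(NS) - daily_range(HS)
    hourly_difference_curve: np.ndarray  # NS - HS at hours 0..23


def _local_extrema(y: np.ndarray, circular: bool, minutes_per_step: float,
                   merge_minutes: float = 10.0, prominence_fraction: float = 0.1):
    """Indices of prominent local maxima and minima on a sampled curve.

    Extrema must rise (or fall) by at least ``prominence_fraction`` of the
    curve's daily range — low-amplitude ripple (e.g. a sub-hourly harmonic
    riding on a dominant wave) is not a differentiated peak.  Extrema closer
    than ``merge_minutes`` are merged and ``circular`` wraps detection across
    the day boundary (appropriate for strictly 24-h-periodic models).
    """
    from scipy.signal import find_peaks

    n = y.size
    span = float(np.max(y) - np.min(y))
    if span == 0.0:
        return [], []
    prominence = prominence_fraction * span
    distance = max(1, int(round(merge_minutes / minutes_per_step)))

    def detect(signal):
        if circular:
            tiled = np.concatenate([signal, signal, signal])
            idx, _ = find_peaks(tiled, prominence=prominence, distance=distance)
            return sorted({int(i - n) for i in idx if n <= i < 2 * n})
        idx, _ = find_peaks(signal, prominence=prominence, distance=distance)
        return [int(i) for i in idx]

    return detect(y), detect(-y)


def summarize_pattern(fit_or_model, resolution_minutes: float = 1.0,
                      prominence_fraction: float = 0.1) -> PatternSummary:
    """Locate the differentiated daily peaks and troughs of a circadian curve.

    The curve is sampled on a ``resolution_minutes`` grid over [0, 24);
    extrema within 10 min of each other are merged and extrema with a
    prominence below ``prominence_fraction`` of the daily range are ignored.
    """
    model = fit_or_model.model if isinstance(fit_or_model, CircadianFit) else fit_or_model
    step = resolution_minutes / 60.0
    hours = np.arange(0.0, 24.0, step)
    y = model.evaluate(hours)
    circular = model.form == "single" and abs(model.period1 - 24.0) < 1e-9
    max_idx, min_idx = _local_extrema(y, circular, resolution_minutes,
                                      prominence_fraction=prominence_fraction)
    return PatternSummary(
        peak_hours=[float(hours[i]) for i in max_idx],
        peak_values=[float(y[i]) for i in max_idx],
        trough_hours=[float(hours[i]) for i in min_idx],
        trough_values=[float(y[i]) for i in min_idx],
        daily_range=float(np.max(y) - np.min(y)),
    )


def compare_patterns(fit_ns: CircadianFit, fit_hs: CircadianFit) -> PatternComparison:
    """Contrast the no-stress and heat-stress fits of one behavior."""
    b_ns, b_hs = fit_ns.model.behavior, fit_hs.model.behavior
    if b_ns is not None and b_hs is not None and b_ns != b_hs:
        raise ValueError(f"fits are for different behaviors: {b_ns!r} vs {b_hs!r}")
    s_ns = summarize_pattern(fit_ns)
    s_hs = summarize_pattern(fit_hs)

    def principal_peak(s: PatternSummary) -> float:
        if not s.peak_hours:
            return math.nan
        i = int(np.argmax(s.peak_values))
        return s.peak_hours[i]

    shift = principal_peak(s_ns) - principal_peak(s_hs)
    if math.isfinite(shift):
        shift = math.remainder(shift, 24.0)
        if shift <= -12.0:
            shift += 24.0
    hours = np.arange(24.0)
    return PatternComparison(
        behavior=b_ns or b_hs,
        mean_difference=model_mean(fit_ns.model) - model_mean(fit_hs.model),
        peak_shift_hours=shift,
        range_difference=s_ns.daily_range - s_hs.daily_range,
        hourly_difference_curve=fit_ns.model.evaluate(hours) - fit_hs.model.evaluate(hours),
    )
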