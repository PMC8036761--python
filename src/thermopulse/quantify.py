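"""Biological quantification on top of the slope read-out.

Two estimators:

* a linear calibration of endpoint percent change against cell
  concentration, with inverse prediction (concentration from a measured
  endpoint) and a delta-method uncertainty, and
* a four-parameter logistic fit to a proliferation percent-change
  series, yielding the exponential-phase rate and hence the doubling
  time ``60 ln2 / rate`` in minutes, plus a heuristic phase
  segmentation (lag / exponential / stationary).

Both treat percent change as proportional to areal biomass, which holds
while the interface layer stays thin compared with the probing depth at
the regression-window end (the solver's small-layer linearity regime).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .analysis import SlopeSeries, plateau_time
from .errors import FitError

__all__ = [
    "CalibrationFit",
    "GrowthFit",
    "PhaseSegmentation",
    "fit_calibration",
    "predict_concentration",
    "fit_growth",
    "phase_segmentation",
]


@dataclass(frozen=True)
class CalibrationFit:
    """OLS line of endpoint percent change versus concentration."""

    slope: float  # % per mg mL^-1
    intercept: float  # %
    residual_sd: float  # %
    inverse_prediction_sd: float  # mg mL^-1; residual_sd / |slope|
    n_points: int
    slope_stderr: float = float("nan")
    intercept_stderr: float = float("nan")


def fit_calibration(concentrations, endpoints) -> CalibrationFit:
    """Least-squares endpoint-vs-concentration line (linear abscissa).

    Requires at least two distinct concentrations.  The inverse
    prediction sd is the residual sd divided by |slope| (delta method).
    """
    x = np.asarray(list(concentrations), dtype=float)
    y = np.asarray(list(endpoints), dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise FitError("calibration needs >= 2 (concentration, endpoint) pairs")
    if np.unique(x).size < 2:
        raise FitError("calibration needs >= 2 distinct concentrations")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    dof = max(1, x.size - 2)
    residual_sd = float(np.sqrt((resid @ resid) / dof))
    if res.slope == 0:
        raise FitError("calibration slope is zero; concentration not identifiable")
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_sd=residual_sd,
        inverse_prediction_sd=residual_sd / abs(res.slope),
        n_points=int(x.size),
        slope_stderr=float(res.stderr),
        intercept_stderr=float(res.intercept_stderr),
    )


def predict_concentration(fit: CalibrationFit, endpoint_pct: float) -> tuple[float, float]:
    """Invert the calibration line: ``(y - b) / m`` with its sd."""
    if fit.slope == 0:
        raise FitError("zero calibration slope; concentration not identifiable")
    return (endpoint_pct - fit.intercept) / fit.slope, fit.inverse_prediction_sd


@dataclass(frozen=True)
class GrowthFit:
    """Logistic growth fit to a percent-change curve.

    The default model is a lagged logistic: the percent change stays at
    ``baseline`` through a lag of fitted length, then rises along a
    logistic of exponential-limit rate ``rate`` to
    ``baseline + amplitude``.  Equivalently, with
    ``fold = (amplitude + initial_step) / initial_step`` the population
    expands ``fold``-fold from its inoculum.  ``doubling_time_min =
    60 ln2 / rate``; ``t_mid`` is the half-amplitude crossing and
    ``lag_estimate`` the fitted end of the lag (for the plain logistic
    model, the 5%-of-amplitude rise time).
    """

    baseline: float  # %
    amplitude: float  # %
    t_mid: float  # h
    rate: float  # h^-1
    doubling_time_min: float
    lag_estimate: float  # h
    residual_sd: float
    converged: bool
    model: str = "lagged_logistic"


def _logistic(t, baseline, amplitude, t_mid, rate):
    return baseline + amplitude / (1.0 + np.exp(-rate * (t - t_mid)))


def _lagged_logistic(t, baseline, step, fold, lag, rate):
    """Flat until ``lag``, then logistic expansion ``step`` -> ``step*fold``.

    ``step`` is the percent-change footprint of the inoculum itself;
    the observable rise above baseline is ``step * (N/N0 - 1)`` with
    ``N/N0`` a logistic from 1 to ``fold``.
    """
    dt = np.maximum(0.0, np.asarray(t, dtype=float) - lag)
    n_rel = fold / (1.0 + (fold - 1.0) * np.exp(-rate * dt))
    return baseline + step * (n_rel - 1.0)


def _init_guesses(t, y):
    n_early = max(3, t.size // 5)
    base0 = float(np.median(y[:n_early]))
    amp0 = float(y.max() - y.min())
    half = base0 + 0.5 * amp0
    above = np.nonzero(y >= half)[0]
    t_mid0 = float(t[above[0]]) if above.size else float(t[t.size // 2])
    i = int(np.clip(np.searchsorted(t, t_mid0), 1, t.size - 2))
    dy = (y[i + 1] - y[i - 1]) / (t[i + 1] - t[i - 1])
    rate0 = float(np.clip(4.0 * dy / amp0, 1e-2, 1e2)) if amp0 > 0 else 0.5
    return base0, amp0, t_mid0, rate0


def fit_growth(series: SlopeSeries | tuple, model: str = "lagged_logistic") -> GrowthFit:
    """Fit a logistic growth form to a percent-change series.

    Accepts a :class:`SlopeSeries` or a ``(t_h, pct_change)`` pair.
    ``model`` is ``"lagged_logistic"`` (default: an explicit flat lag
    joined continuously to a logistic — matches the lag/log/stationary
    phase structure and leaves the rate unbiased by the lag) or
    ``"logistic"`` (plain 4-parameter logistic).  The lagged model is
    fitted from several starting fold-expansions and the best
    least-squares solution kept.  A flat or unfittable series returns
    ``converged=False`` (rate nan) rather than raising.
    """
    if isinstance(series, SlopeSeries):
        t = series.t_h
        y = series.pct_change
    else:
        t, y = (np.asarray(a, dtype=float) for a in series)
    if t.size < 5:
        raise FitError("growth fit needs at least 5 datapoints")
    if model not in ("lagged_logistic", "logistic"):
        raise FitError(f"unknown growth model {model!r}")

    failed = GrowthFit(
        baseline=float("nan"),
        amplitude=float("nan"),
        t_mid=float("nan"),
        rate=float("nan"),
        doubling_time_min=float("nan"),
        lag_estimate=float("nan"),
        residual_sd=float("nan"),
        converged=False,
        model=model,
    )
    rng_y = float(y.max() - y.min())
    if rng_y <= 0 or not np.isfinite(rng_y):
        return failed
    base0, amp0, t_mid0, rate0 = _init_guesses(t, y)
    span = float(t[-1] - t[0])

    if model == "logistic":
        try:
            popt, _ = optimize.curve_fit(
                _logistic,
                t,
                y,
                p0=[base0, amp0, t_mid0, rate0],
                bounds=(
                    [-np.inf, 1e-12, t[0] - span, 1e-4],
                    [np.inf, np.inf, t[-1] + span, 1e4],
                ),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            return failed
        baseline, amplitude, t_mid, rate = (float(p) for p in popt)
        resid = y - _logistic(t, *popt)
        lag_est = t_mid - math.log(19.0) / rate
    else:
        lo = [-np.inf, 1e-12, 1.0 + 1e-9, float(t[0]), 1e-4]
        hi = [np.inf, np.inf, 1e9, float(t[-1]), 1e4]
        best = None
        # the cost surface has local minima along the fold/lag/rate ridge,
        # so seed the solver from a grid of fold-expansions and rates
        for fold0 in (3.0, 5.0, 10.0, 20.0, 50.0, 100.0, 300.0):
            for r0 in (0.5 * rate0, rate0, 2.0 * rate0):
                lag0 = float(
                    np.clip(t_mid0 - math.log(fold0 - 1.0) / r0, t[0], t[-1])
                )
                p0 = [base0, amp0 / (fold0 - 1.0), fold0, lag0, r0]
                try:
                    res = optimize.least_squares(
                        lambda p: _lagged_logistic(t, *p) - y,
                        p0,
                        bounds=(lo, hi),
                        max_nfev=20000,
                    )
                except (RuntimeError, ValueError):
                    continue
                if res.success and (best is None or res.cost < best.cost):
                    best = res
        if best is None:
            return failed
        c0, step, fold, lag, rate = (float(p) for p in best.x)
        baseline = c0
        amplitude = step * (fold - 1.0)
        t_mid = lag + math.log(max(fold - 1.0, 1e-12)) / rate
        lag_est = lag
        resid = y - _lagged_logistic(t, *best.x)

    residual_sd = float(np.sqrt(np.mean(resid**2)))
    # Reject degenerate "fits" where the rise is not actually resolved.
    if amplitude < 5.0 * max(residual_sd, 1e-12) or rate <= 1e-4:
        return failed
    return GrowthFit(
        baseline=baseline,
        amplitude=amplitude,
        t_mid=t_mid,
        rate=rate,
        doubling_time_min=60.0 * math.log(2.0) / rate,
        lag_estimate=lag_est,
        residual_sd=residual_sd,
        converged=True,
        model=model,
    )


def fit_growth_multichannel(series_list, model: str = "lagged_logistic") -> GrowthFit:
    """Joint growth fit over replicate sensor channels.

    Multi-channel rigs measure several sensors of one culture condition
    sequentially.  Each channel's percent-change series is re-centred on
    its own lag-phase median (removing the first-pulse normalisation
    offset, which differs per channel), the channels are pooled, and a
    single growth model is fitted — statistically steadier than
    averaging per-channel fits.
    """
    ts, ys = [], []
    for series in series_list:
        t = series.t_h if isinstance(series, SlopeSeries) else np.asarray(series[0], float)
        y = series.pct_change if isinstance(series, SlopeSeries) else np.asarray(series[1], float)
        n_early = max(3, t.size // 5)
        ys.append(y - np.median(y[:n_early]))
        ts.append(t)
    t = np.concatenate(ts)
    y = np.concatenate(ys)
    order = np.argsort(t, kind="stable")
    return fit_growth((t[order], y[order]), model=model)


@dataclass(frozen=True)
class PhaseSegmentation:
    """Lag / exponential / stationary boundaries of a growth series.

    Missing phases are ``None`` with the corresponding flag False.
    """

    lag_end: float | None  # h
    exp_window: tuple[float, float] | None  # h
    stationary_start: float | None  # h
    has_growth: bool
    has_stationary: bool


def phase_segmentation(
    series: SlopeSeries,
    baseline_points: int = 10,
    plateau_tolerance_pct: float | None = None,
) -> PhaseSegmentation:
    """Heuristic growth-phase boundaries from a percent-change series.

    The lag ends when the percent change first exceeds the early
    baseline by 3 baseline standard deviations (with a small floor for
    noiseless input); the stationary phase starts at the plateau time;
    the exponential window spans the two.
    """
    k = min(baseline_points, max(3, len(series) // 10))
    base = series.pct_change[:k]
    base_mean = float(base.mean())
    base_sd = max(float(base.std(ddof=1)) if base.size > 1 else 0.0, 1e-6)
    threshold = base_mean + 3.0 * base_sd
    above = series.pct_change > threshold
    # require a sustained exceedance so single noise spikes don't end the lag
    run = 3 if len(series) >= 3 else 1
    lag_end = None
    for i in range(len(series) - run + 1):
        if above[i : i + run].all():
            lag_end = float(series.t_h[i])
            break
    has_growth = lag_end is not None

    stationary_start = None
    if has_growth:
        tol = plateau_tolerance_pct
        if tol is None:
            amplitude = float(series.pct_change.max() - base_mean)
            tol = max(0.05 * amplitude, 3.0 * base_sd)
        stationary_start = plateau_time(series, tol)
        if stationary_start is not None and stationary_start <= lag_end:
            stationary_start = None
    has_stationary = stationary_start is not None

    exp_window = None
    if has_growth:
        exp_end = stationary_start if has_stationary else float(series.t_h[-1])
        if exp_end > lag_end:
            exp_window = (lag_end, exp_end)
    return PhaseSegmentation(
        lag_end=lag_end,
        exp_window=exp_window,
        stationary_start=stationary_start,
        has_growth=has_growth,
        has_stationary=has_stationary,
    )
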