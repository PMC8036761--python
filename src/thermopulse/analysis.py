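"""Slope read-out pipeline.

Each heat pulse yields a voltage transient; plotted against the square
root of time its early part is close to linear, and the slope of an
ordinary least-squares fit inside a fixed sqrt(t) window is the read-out
statistic.  Slopes are normalised as percent change relative to the
first pulse, which cancels sensor-to-sensor differences in cold
resistance.  The default window is [0.16, 0.56] sqrt(s), i.e. the
25.6–313.6 ms portion of the pulse — late enough for the pulse to probe
past the substrate foil, early enough to stay sensitive to a thin
interface layer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .electrics import PulseRecord, SensorSpec, temperature_from_resistance
from .errors import ConfigurationError, WindowError
from .thermal import TransientCurve

__all__ = [
    "RegressionWindow",
    "SlopeSeries",
    "voltage_to_temperature",
    "sqrt_time_regression",
    "slope_series",
    "endpoint_statistic",
    "plateau_time",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionWindow:
    """Closed interval in sqrt(t) over which the slope is regressed."""

    start_sqrt: float = 0.16  # sqrt(s)
    end_sqrt: float = 0.56  # sqrt(s)

    def __post_init__(self) -> None:
        if not 0.0 < self.start_sqrt < self.end_sqrt:
            raise ConfigurationError(
                f"window requires 0 < start < end (got {self.start_sqrt}, {self.end_sqrt})"
            )

    @classmethod
    def from_times(cls, t_start: float, t_end: float) -> "RegressionWindow":
        """Window from plain times in seconds (e.g. 25.6 ms, 313.6 ms)."""
        return cls(start_sqrt=math.sqrt(t_start), end_sqrt=math.sqrt(t_end))


@dataclass
class SlopeSeries:
    """Per-pulse regression results and normalised percent change.

    ``pct_change[i] = 100 (slope_i - slope_0) / slope_0`` with the first
    (or configured baseline) pulse as reference; entry 0 is exactly 0
    under the default first-pulse baseline.  ``unit`` records whether
    slopes are V s^-1/2 or K s^-1/2.
    """

    pulse_index: np.ndarray
    t_h: np.ndarray  # pulse onset, hours since experiment start
    slope: np.ndarray
    intercept: np.ndarray
    r2: np.ndarray
    pct_change: np.ndarray
    unit: str = "K s^-1/2"

    def __len__(self) -> int:
        return len(self.pulse_index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pulse_index": self.pulse_index.astype(int),
                "t_h": self.t_h,
                "slope": self.slope,
                "intercept": self.intercept,
                "r2": self.r2,
                "pct_change": self.pct_change,
            }
        )


def voltage_to_temperature(record: PulseRecord, spec: SensorSpec) -> TransientCurve:
    """Convert a 4-wire voltage transient to a temperature-rise transient.

    ``R(t) = V(t)/I`` then the resistance–temperature relation inverted;
    an affine map of the voltage, hence the exact inverse of the
    noiseless forward synthesis.
    """
    if record.current <= 0:
        raise ConfigurationError(
            f"pulse {record.pulse_index}: current must be positive (got {record.current})"
        )
    resistance = record.voltage / record.current
    temp = temperature_from_resistance(spec, resistance)
    return TransientCurve(t=record.t_rel, dT=np.asarray(temp) - spec.t_ref)


def sqrt_time_regression(
    t: np.ndarray,
    signal: np.ndarray,
    window: RegressionWindow | None = None,
) -> tuple[float, float, float]:
    """OLS of the signal against sqrt(t) inside the closed window.

    Returns ``(slope, intercept, r2)`` with the slope per sqrt-second.
    A perfectly flat in-window signal fits exactly, so its r2 is
    reported as 1.
    """
    if window is None:
        window = RegressionWindow()
    t = np.asarray(t, dtype=float)
    signal = np.asarray(signal, dtype=float)
    sqrt_t = np.sqrt(t)
    mask = (sqrt_t >= window.start_sqrt) & (sqrt_t <= window.end_sqrt)
    n_in = int(mask.sum())
    if n_in < 3:
        raise WindowError(
            f"only {n_in} samples inside the sqrt(t) window "
            f"[{window.start_sqrt}, {window.end_sqrt}]; need >= 3"
        )
    x = sqrt_t[mask]
    y = signal[mask]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    # a numerically flat signal is a perfect (zero-slope) fit, not r2 = 0/0
    scale = n_in * (float(np.abs(y).max()) + 1e-300) ** 2
    if ss_res <= 1e-24 * scale:
        r2 = 1.0
    elif ss_tot <= 0.0:
        r2 = 0.0
    else:
        r2 = max(0.0, 1.0 - ss_res / ss_tot)
    return float(slope), float(intercept), float(r2)


def slope_series(
    records,
    spec: SensorSpec,
    window: RegressionWindow | None = None,
    domain: str = "temperature",
    baseline: str | tuple[str, int] = "first",
) -> SlopeSeries:
    """Regress every pulse and normalise against the baseline slope.

    ``domain`` selects whether the regression runs on the raw voltage or
    on the converted temperature transient; the two give identical
    percent-change series because voltage is an affine function of
    temperature at fixed current.  ``baseline`` is ``"first"`` (the
    field convention) or ``("mean", k)`` to average the first k
    slopes.  Pulses with non-finite samples are dropped with a warning.
    """
    if domain not in ("temperature", "voltage"):
        raise ConfigurationError(f"unknown regression domain {domain!r}")
    if window is None:
        window = RegressionWindow()
    rows = []
    for record in records:
        if not np.all(np.isfinite(record.voltage)):
            logger.warning(
                "dropping pulse %d: non-finite voltage samples", record.pulse_index
            )
            continue
        if domain == "temperature":
            curve = voltage_to_temperature(record, spec)
            t, y = curve.t, curve.dT
        else:
            t, y = record.t_rel, record.voltage
        slope, intercept, r2 = sqrt_time_regression(t, y, window)
        rows.append((record.pulse_index, record.onset / 3600.0, slope, intercept, r2))
    if not rows:
        raise ConfigurationError("no usable pulses in the record sequence")
    arr = np.array(rows, dtype=float)
    slopes = arr[:, 2]
    if baseline == "first":
        ref = slopes[0]
    elif isinstance(baseline, tuple) and baseline[0] == "mean":
        k = int(baseline[1])
        if k < 1:
            raise ConfigurationError("mean baseline needs k >= 1")
        ref = float(slopes[: min(k, len(slopes))].mean())
    else:
        raise ConfigurationError(f"unknown baseline {baseline!r}")
    if ref == 0.0:
        raise ConfigurationError("baseline slope is zero; cannot normalise")
    pct = 100.0 * (slopes - ref) / ref
    return SlopeSeries(
        pulse_index=arr[:, 0].astype(int),
        t_h=arr[:, 1],
        slope=slopes,
        intercept=arr[:, 3],
        r2=arr[:, 4],
        pct_change=pct,
        unit="K s^-1/2" if domain == "temperature" else "V s^-1/2",
    )


def endpoint_statistic(
    series: SlopeSeries, t_from: float = 2.0, t_to: float = 12.0
) -> tuple[float, float]:
    """Mean and sd of percent change over the closed time window [h].

    The default 2–12 h window summarises the settled state of a
    sedimentation run.  The sd uses the n-1 normalisation (0 for a
    single point).
    """
    mask = (series.t_h >= t_from) & (series.t_h <= t_to)
    if not mask.any():
        raise WindowError(
            f"no slope datapoints inside the endpoint window [{t_from}, {t_to}] h"
        )
    vals = series.pct_change[mask]
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


def plateau_time(
    series: SlopeSeries,
    tolerance_pct: float,
    reference: float | None = None,
) -> float | None:
    """First time after which the series stays within tolerance of its plateau.

    ``reference`` defaults to the mean over the final quarter of the
    series.  Returns the onset time (hours) of the first pulse from
    which every later percent change deviates by at most
    ``tolerance_pct``, or ``None`` if the series never settles.
    """
    if tolerance_pct <= 0:
        raise ConfigurationError("tolerance_pct must be positive")
    pct = series.pct_change
    if reference is None:
        tail = max(1, len(pct) // 4)
        reference = float(pct[-tail:].mean())
    within = np.abs(pct - reference) <= tolerance_pct
    # index of first sample from which all subsequent samples are within
    idx = None
    for i in range(len(within) - 1, -1, -1):
        if within[i]:
            idx = i
        else:
            break
    if idx is None:
        return None
    return float(series.t_h[idx])
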