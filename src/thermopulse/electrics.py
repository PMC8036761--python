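"""Electrical model of the resistive heater/thermometer.

The meander doubles as heater and resistance thermometer:
``R = R_ref [1 + alpha (T - T_ref)]``.  A source-measure unit sources a
fixed current and reads back the 4-wire voltage, so a measured voltage
transient maps affinely to the heater temperature transient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .thermal import LayerStack, TransientCurve

__all__ = [
    "SensorSpec",
    "PulseProtocol",
    "PulseRecord",
    "resistance_from_temperature",
    "temperature_from_resistance",
    "drive_current_for_power",
    "synthesize_pulse",
    "DEFAULT_NOISE_SD",
]

#: Default additive white voltage noise, volts (0.2 mV).
DEFAULT_NOISE_SD = 2e-4


@dataclass(frozen=True)
class SensorSpec:
    """Electrical/thermal description of one foil sensor.

    ``r_ref`` is the cold resistance at ``t_ref`` (room temperature);
    manufactured sensors fall in the 7–10 ohm range.  ``alpha`` is the
    temperature coefficient of resistance of the copper track.
    """

    r_ref: float = 8.0  # ohm at t_ref
    t_ref: float = 293.15  # K
    alpha: float = 3.818e-3  # K^-1
    heater_area: float = 81e-6  # m^2
    stack: LayerStack | None = None

    def __post_init__(self) -> None:
        if self.r_ref <= 0:
            raise ConfigurationError(f"r_ref must be positive (got {self.r_ref})")
        if self.alpha <= 0:
            raise ConfigurationError(f"alpha must be positive (got {self.alpha})")
        if self.heater_area <= 0:
            raise ConfigurationError("heater_area must be positive")


@dataclass(frozen=True)
class PulseProtocol:
    """Heat-pulse timing.

    Defaults follow the sedimentation protocol (0.5 W, 1 s pulse, 60 s
    cooling, 500 Hz sampling); proliferation runs stretch the cooling
    interval to 300 s.  Pulse k starts at ``k * (pulse + cooling)``
    seconds and pulses are emitted while ``onset + pulse_duration``
    stays within ``total_duration``.
    """

    power: float = 0.5  # W
    pulse_duration: float = 1.0  # s
    cooling_time: float = 60.0  # s
    sample_rate: float = 500.0  # Hz
    total_duration: float | None = None  # s
    n_pulses: int | None = None

    def __post_init__(self) -> None:
        for name in ("power", "pulse_duration", "cooling_time", "sample_rate"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if (self.total_duration is None) == (self.n_pulses is None):
            raise ConfigurationError(
                "specify exactly one of total_duration or n_pulses"
            )
        if self.n_pulses is not None and self.n_pulses < 1:
            raise ConfigurationError("n_pulses must be >= 1")
        if self.total_duration is not None and self.total_duration < self.pulse_duration:
            raise ConfigurationError("total_duration shorter than one pulse")

    @property
    def period(self) -> float:
        """Seconds between consecutive pulse onsets."""
        return self.pulse_duration + self.cooling_time

    def onsets(self) -> np.ndarray:
        """Pulse onset times in seconds since experiment start."""
        if self.n_pulses is not None:
            count = self.n_pulses
        else:
            count = int(
                math.floor((self.total_duration - self.pulse_duration) / self.period)
            ) + 1
        return np.arange(count) * self.period


@dataclass
class PulseRecord:
    """One pulse's sampled 4-wire voltage transient."""

    pulse_index: int
    onset: float  # s since experiment start
    current: float  # A
    t_rel: np.ndarray  # s since pulse onset
    voltage: np.ndarray  # V

    def __post_init__(self) -> None:
        self.t_rel = np.asarray(self.t_rel, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.pulse_index < 0:
            raise ConfigurationError("pulse_index must be >= 0")
        if self.t_rel.shape != self.voltage.shape:
            raise ConfigurationError("t_rel and voltage must have equal length")


def resistance_from_temperature(spec: SensorSpec, temperature: float):
    """Track resistance at the given absolute temperature (K)."""
    temperature = np.asarray(temperature, dtype=float)
    r = spec.r_ref * (1.0 + spec.alpha * (temperature - spec.t_ref))
    return r if r.ndim else float(r)


def temperature_from_resistance(spec: SensorSpec, resistance: float):
    """Absolute temperature (K) from track resistance — exact inverse."""
    resistance = np.asarray(resistance, dtype=float)
    if np.any(resistance <= 0):
        raise ConfigurationError("resistance must be positive")
    t = spec.t_ref + (resistance / spec.r_ref - 1.0) / spec.alpha
    return t if t.ndim else float(t)


def drive_current_for_power(r_init: float, power: float) -> float:
    """Current delivering ``power`` into the cold resistance: ``sqrt(P/R)``.

    Computing the current from each sensor's own initial resistance is
    what makes the deposited pulse power uniform across sensors.
    """
    if r_init <= 0:
        raise ConfigurationError(f"r_init must be positive (got {r_init})")
    if power < 0:
        raise ConfigurationError(f"power must be >= 0 (got {power})")
    return math.sqrt(power / r_init)


def synthesize_pulse(
    spec: SensorSpec,
    curve: TransientCurve,
    current: float,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng: np.random.Generator | int | None = None,
    pulse_index: int = 0,
    onset: float = 0.0,
) -> PulseRecord:
    """Render a thermal transient into a noisy 4-wire voltage record.

    The noiseless mean is exactly ``I * R(T_ref + dT(t))``; additive
    white Gaussian noise of standard deviation ``noise_sd`` (volts) is
    superimposed.  Deterministic for a given generator state.
    """
    if noise_sd < 0:
        raise ConfigurationError(f"noise_sd must be >= 0 (got {noise_sd})")
    r = resistance_from_temperature(spec, spec.t_ref + curve.dT)
    volts = current * np.asarray(r, dtype=float)
    if noise_sd > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        volts = volts + rng.normal(0.0, noise_sd, size=volts.shape)
    return PulseRecord(
        pulse_index=pulse_index,
        onset=onset,
        current=current,
        t_rel=curve.t.copy(),
        voltage=volts,
    )
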