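"""Synthetic culture generator.

Emulates the two study conditions of the pulsed-thermal assay:

* **Sedimentation** — a fixed inoculum of dried yeast in water settles
  onto the sensor at its Stokes velocity; no growth.  Used for
  calibration of the slope response against cell concentration.
* **Proliferation** — *S. cerevisiae* growing in YP medium: a lag phase
  of fixed duration followed by logistic growth whose carrying capacity
  is set by the supplied glucose.

Ground-truth biology is expressed as *areal biovolume* (m^3 of cells per
m^2 of sensor) at the interface and mapped to a thermally insulating
cell layer through a packing fraction and an effective-medium mixing
rule; full raw datasets are then rendered through the thermal solver and
the electrical forward model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .electrics import (
    DEFAULT_NOISE_SD,
    PulseProtocol,
    PulseRecord,
    SensorSpec,
    drive_current_for_power,
    synthesize_pulse,
)
from .errors import ConfigurationError
from .thermal import (
    POLYIMIDE,
    WATER,
    GridSettings,
    LayerStack,
    MaterialLayer,
    simulate_step_response,
)

__all__ = [
    "CultureScenario",
    "BiomassTrajectory",
    "DILUTION_SERIES_MG_ML",
    "CALIBRATION_SLOPE",
    "CALIBRATION_INTERCEPT",
    "sedimentation_scenario",
    "proliferation_scenario",
    "stokes_velocity",
    "sedimentation_trajectory",
    "growth_trajectory",
    "maxwell_eucken",
    "layer_from_biomass",
    "default_stack",
    "default_sensor",
    "generate_experiment",
    "calibration_endpoints",
]

#: Two-fold dilution series of dried yeast plus the pure-water control, mg/mL.
DILUTION_SERIES_MG_ML = (8.0, 4.0, 2.0, 1.0, 0.5, 0.25, 0.125, 0.0)

#: Endpoint response line of the physical sensor: percent change in
#: slope versus concentration in mg/mL.
CALIBRATION_SLOPE = 0.7806  # % per mg mL^-1
CALIBRATION_INTERCEPT = -0.2194  # %


@dataclass(frozen=True)
class CultureScenario:
    """Ground-truth biological trajectory and its physical mapping.

    Sedimentation mode uses ``concentration_mg_ml`` and
    ``column_height``; proliferation mode uses ``od_start``,
    ``glucose_g_l`` and the growth parameters.  The remaining fields
    describe the cells and how biomass converts to an interface layer.
    Cell thermal properties are configuration defaults inside
    literature-plausible ranges, not measured claims.
    """

    mode: str  # "sedimentation" | "proliferation"
    concentration_mg_ml: float | None = None
    od_start: float | None = None
    glucose_g_l: float | None = None
    column_height: float = 5.3e-3  # m; 1.5 mL in a 19 mm tube
    cell_radius: float = 2.5e-6  # m
    excess_density: float = 100.0  # kg m^-3 above the medium
    viscosity: float = 1e-3  # Pa s
    cell_k: float = 0.45  # W m^-1 K^-1
    cell_rho: float = 1100.0  # kg m^-3
    cell_cp: float = 3500.0  # J kg^-1 K^-1
    lag_h: float = 5.0
    doubling_time_min: float = 90.0
    yield_od_per_g_l: float = 0.4  # OD600 gained per g/L glucose consumed
    od_to_areal_biovolume: float = 1e-5  # m^3 m^-2 per OD600 unit
    packing_fraction: float = 0.64

    def __post_init__(self) -> None:
        if self.mode not in ("sedimentation", "proliferation"):
            raise ConfigurationError(f"unknown scenario mode {self.mode!r}")
        if self.mode == "sedimentation":
            if self.concentration_mg_ml is None or self.concentration_mg_ml < 0:
                raise ConfigurationError(
                    "sedimentation scenario needs concentration_mg_ml >= 0"
                )
            if self.column_height <= 0:
                raise ConfigurationError("column_height must be positive")
        else:
            if self.od_start is None or self.od_start <= 0:
                raise ConfigurationError("proliferation scenario needs od_start > 0")
            if self.glucose_g_l is None or self.glucose_g_l < 0:
                raise ConfigurationError("proliferation scenario needs glucose_g_l >= 0")
            if self.doubling_time_min <= 0:
                raise ConfigurationError("doubling_time_min must be positive")
            if self.lag_h < 0:
                raise ConfigurationError("lag_h must be >= 0")
        for name in (
            "cell_radius",
            "viscosity",
            "cell_k",
            "cell_rho",
            "cell_cp",
            "yield_od_per_g_l",
            "od_to_areal_biovolume",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 < self.packing_fraction <= 1.0:
            raise ConfigurationError("packing_fraction must lie in (0, 1]")


def sedimentation_scenario(concentration_mg_ml: float, **kwargs) -> CultureScenario:
    """Dilution-series scenario at one concentration."""
    return CultureScenario(
        mode="sedimentation", concentration_mg_ml=concentration_mg_ml, **kwargs
    )


def proliferation_scenario(
    od_start: float, glucose_g_l: float, **kwargs
) -> CultureScenario:
    """Growth scenario at one starting density and glucose supply."""
    return CultureScenario(
        mode="proliferation", od_start=od_start, glucose_g_l=glucose_g_l, **kwargs
    )


@dataclass
class BiomassTrajectory:
    """Areal biovolume at the sensor interface over time."""

    t_h: np.ndarray  # hours
    areal_biovolume: np.ndarray  # m^3 m^-2

    def __post_init__(self) -> None:
        self.t_h = np.asarray(self.t_h, dtype=float)
        self.areal_biovolume = np.asarray(self.areal_biovolume, dtype=float)
        if np.any(self.areal_biovolume < 0):
            raise ConfigurationError("areal biovolume must be non-negative")


def stokes_velocity(radius: float, excess_density: float, viscosity: float) -> float:
    """Terminal settling velocity ``(2/9) drho g r^2 / mu`` of a sphere."""
    g = 9.81
    return (2.0 / 9.0) * excess_density * g * radius**2 / viscosity


def sedimentation_trajectory(
    scenario: CultureScenario, t_grid_h: np.ndarray
) -> BiomassTrajectory:
    """Deposited biovolume of a uniformly suspended, Stokes-settling inoculum.

    A suspension of initial concentration c (kg m^-3, numerically equal
    to mg/mL) and column height H deposits the fraction
    ``min(1, v_s t / H)`` of its content; the plateau areal biovolume is
    ``c H / rho_cell`` by mass balance.
    """
    if scenario.mode != "sedimentation":
        raise ConfigurationError("scenario is not a sedimentation scenario")
    t_s = np.asarray(t_grid_h, dtype=float) * 3600.0
    v_s = stokes_velocity(
        scenario.cell_radius, scenario.excess_density, scenario.viscosity
    )
    frac = np.minimum(1.0, v_s * t_s / scenario.column_height)
    total = (
        scenario.concentration_mg_ml * scenario.column_height / scenario.cell_rho
    )
    return BiomassTrajectory(t_h=np.asarray(t_grid_h), areal_biovolume=total * frac)


def growth_trajectory(
    scenario: CultureScenario, t_grid_h: np.ndarray
) -> BiomassTrajectory:
    """Lag + logistic growth mapped to interface biovolume.

    Population (OD600-equivalent) stays at ``od_start`` through the lag,
    then follows a logistic with exponential-limit rate
    ``ln 2 / doubling_time`` and carrying capacity
    ``K = od_start + yield * glucose`` (plateau increment proportional
    to the supplied glucose).  Biomass converts to areal biovolume via
    the single ``od_to_areal_biovolume`` constant.
    """
    if scenario.mode != "proliferation":
        raise ConfigurationError("scenario is not a proliferation scenario")
    t_h = np.asarray(t_grid_h, dtype=float)
    n0 = scenario.od_start
    cap = n0 + scenario.yield_od_per_g_l * scenario.glucose_g_l
    rate = math.log(2.0) / (scenario.doubling_time_min / 60.0)  # h^-1
    dt = np.maximum(0.0, t_h - scenario.lag_h)
    if cap <= n0:
        n = np.full_like(t_h, n0)
    else:
        n = cap / (1.0 + ((cap - n0) / n0) * np.exp(-rate * dt))
    return BiomassTrajectory(
        t_h=t_h, areal_biovolume=scenario.od_to_areal_biovolume * n
    )


def maxwell_eucken(k_medium: float, k_cell: float, phi: float) -> float:
    """Maxwell–Eucken effective conductivity, medium continuous phase.

    ``phi`` is the cell (dispersed-phase) volume fraction.  Reduces to
    the medium conductivity at phi=0 and the cell conductivity at
    phi=1, and always lies between the series and parallel bounds.
    """
    if not 0.0 <= phi <= 1.0:
        raise ConfigurationError("phi must lie in [0, 1]")
    num = 2.0 * k_medium + k_cell - 2.0 * phi * (k_medium - k_cell)
    den = 2.0 * k_medium + k_cell + phi * (k_medium - k_cell)
    return k_medium * num / den


def layer_from_biomass(
    areal_biovolume: float,
    packing_fraction: float,
    cell: MaterialLayer,
    medium: MaterialLayer,
) -> MaterialLayer | None:
    """Effective interface layer for a given settled biovolume.

    The layer thickness is ``areal_biovolume / packing_fraction`` (cells
    plus interstitial medium); conductivity follows the Maxwell–Eucken
    rule with the medium continuous, density and heat capacity are
    volume/mass weighted.  Returns ``None`` for zero biovolume (the
    stack is unchanged).
    """
    if not 0.0 < packing_fraction <= 1.0:
        raise ConfigurationError("packing_fraction must lie in (0, 1]")
    if areal_biovolume < 0:
        raise ConfigurationError("areal_biovolume must be >= 0")
    if areal_biovolume == 0.0:
        return None
    phi = packing_fraction
    k_eff = maxwell_eucken(medium.k, cell.k, phi)
    rho_eff = phi * cell.rho + (1.0 - phi) * medium.rho
    rhocp_eff = phi * cell.rho * cell.cp + (1.0 - phi) * medium.rho * medium.cp
    return MaterialLayer(
        name="cell layer",
        k=k_eff,
        rho=rho_eff,
        cp=rhocp_eff / rho_eff,
        thickness=areal_biovolume / packing_fraction,
    )


def default_stack(
    substrate: MaterialLayer = POLYIMIDE, medium: MaterialLayer = WATER
) -> LayerStack:
    """Default device stack: heater | substrate foil | medium, adiabatic back.

    The copper meander sits on the underside of the foil over an air
    cut-out, so the pulse probes upward through the substrate into the
    culture; the backside is treated as adiabatic.
    """
    return LayerStack(above=(substrate, medium))


def default_sensor(r_ref: float = 8.0) -> SensorSpec:
    """A representative sensor on the default stack."""
    return SensorSpec(r_ref=r_ref, stack=default_stack())


def _cell_material(scenario: CultureScenario) -> MaterialLayer:
    return MaterialLayer(
        "cell",
        k=scenario.cell_k,
        rho=scenario.cell_rho,
        cp=scenario.cell_cp,
        thickness=1.0,  # placeholder; only properties are used
    )


def trajectory_for(scenario: CultureScenario, t_grid_h: np.ndarray) -> BiomassTrajectory:
    """Dispatch to the mode-appropriate trajectory."""
    if scenario.mode == "sedimentation":
        return sedimentation_trajectory(scenario, t_grid_h)
    return growth_trajectory(scenario, t_grid_h)


def generate_experiment(
    scenario: CultureScenario,
    spec: SensorSpec,
    protocol: PulseProtocol,
    seed: int | None = 0,
    *,
    noise_sd: float = DEFAULT_NOISE_SD,
    grid: GridSettings | None = None,
    solver_cache: dict | None = None,
) -> list[PulseRecord]:
    """Render a full raw pulse dataset for one scenario.

    For each pulse onset the biological trajectory sets the interface
    layer, the thermal solver produces the heater transient, and the
    electrical model converts it to a noisy 4-wire voltage record.
    Deterministic for a given ``seed``.  ``solver_cache`` (a dict) may
    be shared across calls to reuse thermal solves for identical layer
    thicknesses — replicate sensors and plateaued trajectories then cost
    almost nothing.
    """
    if spec.stack is None:
        raise ConfigurationError("sensor spec carries no layer stack")
    if protocol.cooling_time + protocol.pulse_duration <= protocol.pulse_duration:
        raise ConfigurationError("protocol period must exceed the pulse duration")
    onsets = protocol.onsets()
    traj = trajectory_for(scenario, onsets / 3600.0)
    cell = _cell_material(scenario)
    medium = spec.stack.above[-1]
    base_above = spec.stack.above[:-1]
    current = drive_current_for_power(spec.r_ref, protocol.power)
    rng = np.random.default_rng(
        seed if seed is None else [int(seed) % (2**31), 17]
    )
    cache = {} if solver_cache is None else solver_cache
    records: list[PulseRecord] = []
    for idx, onset in enumerate(onsets):
        layer = layer_from_biomass(
            float(traj.areal_biovolume[idx]), scenario.packing_fraction, cell, medium
        )
        key = 0 if layer is None else round(layer.thickness * 1e12)
        curve = cache.get(key)
        if curve is None:
            above = base_above + (() if layer is None else (layer,)) + (medium,)
            curve = simulate_step_response(
                spec.stack.with_above(above),
                protocol.power,
                protocol.pulse_duration,
                protocol.sample_rate,
                grid=grid,
            )
            cache[key] = curve
        records.append(
            synthesize_pulse(
                spec,
                curve,
                current,
                noise_sd=noise_sd,
                rng=rng,
                pulse_index=idx,
                onset=float(onset),
            )
        )
    return records


def multichannel_experiment(
    scenario: CultureScenario,
    protocol: PulseProtocol,
    seed: int = 0,
    r_refs=(7.0, 8.0, 9.0, 10.0),
    *,
    noise_sd: float = DEFAULT_NOISE_SD,
    grid: GridSettings | None = None,
    solver_cache: dict | None = None,
) -> list[tuple[SensorSpec, list[PulseRecord]]]:
    """One culture condition measured on several sensors sequentially.

    Mirrors a multiplexed source-measure setup: each channel gets its
    own sensor (cold resistances ``r_refs``, spanning the manufactured
    range) observing the same biological trajectory with independent
    read noise.  Returns ``(sensor, records)`` per channel.  The
    percent-change normalisation makes the channels directly
    comparable despite their different cold resistances.
    """
    cache = {} if solver_cache is None else solver_cache
    stack = default_stack()
    out = []
    for ch, r_ref in enumerate(r_refs):
        sensor = SensorSpec(r_ref=float(r_ref), stack=stack)
        records = generate_experiment(
            scenario,
            sensor,
            protocol,
            seed=(int(seed) * 101 + ch) % (2**31),
            noise_sd=noise_sd,
            grid=grid,
            solver_cache=cache,
        )
        out.append((sensor, records))
    return out


def calibration_endpoints(
    concentrations_mg_ml,
    n_replicates: int = 4,
    noise_sd_pct: float = 0.25,
    seed: int | None = 0,
    slope: float = CALIBRATION_SLOPE,
    intercept: float = CALIBRATION_INTERCEPT,
) -> tuple[np.ndarray, np.ndarray]:
    """Endpoint percent-change draws from the sensor's linear response.

    Bypasses the physics: endpoint percent change is drawn directly from
    the ground-truth line ``y = slope * c + intercept`` plus Gaussian
    noise, replicate-by-replicate.  Used to exercise calibration
    recovery independently of assumed cell thermal properties.

    Returns (concentration, endpoint_pct) arrays of length
    ``len(concentrations) * n_replicates``.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    if noise_sd_pct < 0:
        raise ConfigurationError("noise_sd_pct must be >= 0")
    conc = np.repeat(np.asarray(list(concentrations_mg_ml), dtype=float), n_replicates)
    rng = np.random.default_rng(
        seed if seed is None else [int(seed) % (2**31), 23]
    )
    pct = slope * conc + intercept + rng.normal(0.0, noise_sd_pct, size=conc.shape)
    return conc, pct
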