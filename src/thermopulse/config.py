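"""Experiment configuration file.

A single YAML document describes one simulated experiment: sensor
electrics, layer materials, pulse protocol, biological scenario, and
analysis settings.  Keys carry their unit as a suffix (``power_w``,
``thickness_m``) to prevent unit drift; unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .analysis import RegressionWindow
from .culture import CultureScenario
from .electrics import DEFAULT_NOISE_SD, PulseProtocol, SensorSpec
from .errors import ConfigurationError
from .thermal import LayerStack, MaterialLayer

__all__ = ["ExperimentConfig", "load_config", "config_from_dict", "EXAMPLE_CONFIG"]


@dataclass
class ExperimentConfig:
    """Fully resolved experiment description."""

    sensor: SensorSpec
    protocol: PulseProtocol
    scenario: CultureScenario
    window: RegressionWindow
    domain: str = "temperature"
    baseline: str | tuple[str, int] = "first"
    endpoint_from_h: float = 2.0
    endpoint_to_h: float = 12.0
    noise_sd_v: float = DEFAULT_NOISE_SD
    seed: int = 0


def _require_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _material(section: dict, where: str, **extra) -> MaterialLayer:
    _require_keys(
        section,
        {"name", "k_w_per_mk", "rho_kg_per_m3", "cp_j_per_kgk", "thickness_m"},
        where,
    )
    try:
        return MaterialLayer(
            name=section.get("name", where),
            k=float(section["k_w_per_mk"]),
            rho=float(section["rho_kg_per_m3"]),
            cp=float(section["cp_j_per_kgk"]),
            **extra,
        )
    except KeyError as exc:
        raise ConfigurationError(f"{where}: missing key {exc}") from exc


def config_from_dict(doc: dict) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a parsed YAML mapping."""
    if not isinstance(doc, dict):
        raise ConfigurationError("config root must be a mapping")
    _require_keys(
        doc,
        {
            "seed",
            "sensor",
            "substrate",
            "medium",
            "cell",
            "packing_fraction",
            "protocol",
            "scenario",
            "analysis",
            "noise_sd_v",
        },
        "config",
    )

    sensor_sec = dict(doc.get("sensor", {}))
    _require_keys(
        sensor_sec,
        {
            "r_ref_ohm",
            "t_ref_k",
            "alpha_per_k",
            "heater_area_m2",
            "heater_areal_heat_capacity_j_per_m2k",
        },
        "sensor",
    )

    sub_sec = dict(doc.get("substrate", {}))
    backing = sub_sec.pop("backing", "adiabatic")
    thickness = float(sub_sec.pop("thickness_m", 40e-6))
    substrate = _material(
        {**sub_sec, "name": sub_sec.get("name", "substrate")},
        "substrate",
        thickness=thickness,
    )
    med_sec = dict(doc.get("medium", {"k_w_per_mk": 0.60, "rho_kg_per_m3": 998.0, "cp_j_per_kgk": 4182.0}))
    medium = _material(
        {**med_sec, "name": med_sec.get("name", "medium")}, "medium", semi_infinite=True
    )
    if backing == "adiabatic":
        below: tuple[MaterialLayer, ...] = ()
    elif backing == "semi-infinite-air":
        below = (
            MaterialLayer("air", k=0.026, rho=1.2, cp=1005.0, semi_infinite=True),
        )
    else:
        raise ConfigurationError(f"unknown substrate backing {backing!r}")

    area = float(sensor_sec.get("heater_area_m2", 81e-6))
    stack = LayerStack(
        above=(substrate, medium),
        below=below,
        heater_areal_heat_capacity=float(
            sensor_sec.get("heater_areal_heat_capacity_j_per_m2k", 51.7)
        ),
        heater_area=area,
    )
    sensor = SensorSpec(
        r_ref=float(sensor_sec.get("r_ref_ohm", 8.0)),
        t_ref=float(sensor_sec.get("t_ref_k", 293.15)),
        alpha=float(sensor_sec.get("alpha_per_k", 3.818e-3)),
        heater_area=area,
        stack=stack,
    )

    proto_sec = dict(doc.get("protocol", {}))
    _require_keys(
        proto_sec,
        {
            "power_w",
            "pulse_duration_s",
            "cooling_time_s",
            "sample_rate_hz",
            "total_duration_s",
            "n_pulses",
        },
        "protocol",
    )
    protocol = PulseProtocol(
        power=float(proto_sec.get("power_w", 0.5)),
        pulse_duration=float(proto_sec.get("pulse_duration_s", 1.0)),
        cooling_time=float(proto_sec.get("cooling_time_s", 60.0)),
        sample_rate=float(proto_sec.get("sample_rate_hz", 500.0)),
        total_duration=(
            float(proto_sec["total_duration_s"])
            if "total_duration_s" in proto_sec
            else None
        ),
        n_pulses=(
            int(proto_sec["n_pulses"]) if "n_pulses" in proto_sec else None
        ),
    )

    cell_sec = dict(doc.get("cell", {}))
    _require_keys(
        cell_sec,
        {
            "k_w_per_mk",
            "rho_kg_per_m3",
            "cp_j_per_kgk",
            "radius_m",
            "excess_density_kg_per_m3",
        },
        "cell",
    )
    scen_sec = dict(doc.get("scenario", {}))
    _require_keys(
        scen_sec,
        {
            "mode",
            "concentration_mg_per_ml",
            "od_start",
            "glucose_g_per_l",
            "column_height_m",
            "viscosity_pa_s",
            "lag_h",
            "doubling_time_min",
            "yield_od_per_g_per_l",
            "od_to_areal_biovolume_m",
        },
        "scenario",
    )
    if "mode" not in scen_sec:
        raise ConfigurationError("scenario: missing key 'mode'")
    kwargs = dict(
        mode=scen_sec["mode"],
        cell_k=float(cell_sec.get("k_w_per_mk", 0.45)),
        cell_rho=float(cell_sec.get("rho_kg_per_m3", 1100.0)),
        cell_cp=float(cell_sec.get("cp_j_per_kgk", 3500.0)),
        cell_radius=float(cell_sec.get("radius_m", 2.5e-6)),
        excess_density=float(cell_sec.get("excess_density_kg_per_m3", 100.0)),
        packing_fraction=float(doc.get("packing_fraction", 0.64)),
    )
    optional = {
        "concentration_mg_per_ml": ("concentration_mg_ml", float),
        "od_start": ("od_start", float),
        "glucose_g_per_l": ("glucose_g_l", float),
        "column_height_m": ("column_height", float),
        "viscosity_pa_s": ("viscosity", float),
        "lag_h": ("lag_h", float),
        "doubling_time_min": ("doubling_time_min", float),
        "yield_od_per_g_per_l": ("yield_od_per_g_l", float),
        "od_to_areal_biovolume_m": ("od_to_areal_biovolume", float),
    }
    for key, (attr, conv) in optional.items():
        if key in scen_sec:
            kwargs[attr] = conv(scen_sec[key])
    scenario = CultureScenario(**kwargs)

    ana_sec = dict(doc.get("analysis", {}))
    _require_keys(
        ana_sec,
        {"window_sqrt_s", "domain", "baseline", "endpoint_from_h", "endpoint_to_h"},
        "analysis",
    )
    win = ana_sec.get("window_sqrt_s", [0.16, 0.56])
    if not (isinstance(win, (list, tuple)) and len(win) == 2):
        raise ConfigurationError("analysis.window_sqrt_s must be [start, end]")
    baseline = ana_sec.get("baseline", "first")
    if isinstance(baseline, str) and baseline.startswith("mean:"):
        baseline = ("mean", int(baseline.split(":", 1)[1]))

    return ExperimentConfig(
        sensor=sensor,
        protocol=protocol,
        scenario=scenario,
        window=RegressionWindow(float(win[0]), float(win[1])),
        domain=str(ana_sec.get("domain", "temperature")),
        baseline=baseline,
        endpoint_from_h=float(ana_sec.get("endpoint_from_h", 2.0)),
        endpoint_to_h=float(ana_sec.get("endpoint_to_h", 12.0)),
        noise_sd_v=float(doc.get("noise_sd_v", DEFAULT_NOISE_SD)),
        seed=int(doc.get("seed", 0)),
    )


def load_config(path) -> ExperimentConfig:
    """Load and validate an experiment config YAML file."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: invalid YAML: {exc}") from exc
    return config_from_dict(doc)


#: A complete, runnable sedimentation demo config (30 min run).
EXAMPLE_CONFIG = """\
seed: 1
sensor:
  r_ref_ohm: 8.0
  t_ref_k: 293.15
  alpha_per_k: 3.818e-3
  heater_area_m2: 8.1e-5
  heater_areal_heat_capacity_j_per_m2k: 51.7
substrate:
  k_w_per_mk: 0.12
  rho_kg_per_m3: 1420.0
  cp_j_per_kgk: 1090.0
  thickness_m: 4.0e-5
  backing: adiabatic
medium:
  k_w_per_mk: 0.60
  rho_kg_per_m3: 998.0
  cp_j_per_kgk: 4182.0
cell:
  k_w_per_mk: 0.45
  rho_kg_per_m3: 1100.0
  cp_j_per_kgk: 3500.0
  radius_m: 2.5e-6
  excess_density_kg_per_m3: 100.0
packing_fraction: 0.64
protocol:
  power_w: 0.5
  pulse_duration_s: 1.0
  cooling_time_s: 60.0
  sample_rate_hz: 500.0
  total_duration_s: 1830.0
scenario:
  mode: sedimentation
  concentration_mg_per_ml: 8.0
  column_height_m: 5.3e-3
analysis:
  window_sqrt_s: [0.16, 0.56]
  domain: temperature
  baseline: first
  endpoint_from_h: 0.25
  endpoint_to_h: 0.5
noise_sd_v: 2.0e-4
"""
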