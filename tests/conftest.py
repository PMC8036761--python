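"""Shared fixtures.

All synthetic data is generated at test time.  A session-wide solver
cache lets independent tests reuse thermal solves for identical layer
stacks, which keeps the end-to-end simulation tests fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from thermopulse import (
    DILUTION_SERIES_MG_ML,
    PulseProtocol,
    default_sensor,
    generate_experiment,
    multichannel_experiment,
    proliferation_scenario,
    sedimentation_scenario,
    slope_series,
)


@pytest.fixture(scope="session")
def solver_cache() -> dict:
    return {}


@pytest.fixture(scope="session")
def sensor():
    return default_sensor()


@pytest.fixture(scope="session")
def dilution_series_noiseless(sensor, solver_cache):
    """Noise-free slope series for the full dilution series (1.8 h runs)."""
    protocol = PulseProtocol(total_duration=1.8 * 3600.0)
    out = {}
    for conc in DILUTION_SERIES_MG_ML:
        records = generate_experiment(
            sedimentation_scenario(conc),
            sensor,
            protocol,
            seed=1,
            noise_sd=0.0,
            solver_cache=solver_cache,
        )
        out[conc] = slope_series(records, sensor)
    return out


@pytest.fixture(scope="session")
def glucose_series_noiseless(sensor, solver_cache):
    """Noise-free 16 h proliferation runs across the glucose series."""
    protocol = PulseProtocol(cooling_time=300.0, total_duration=16 * 3600.0)
    out = {}
    for glucose in (0.16, 2.50, 10.00):
        records = generate_experiment(
            proliferation_scenario(0.2, glucose),
            sensor,
            protocol,
            seed=1,
            noise_sd=0.0,
            solver_cache=solver_cache,
        )
        out[glucose] = slope_series(records, sensor)
    return out


@pytest.fixture(scope="session")
def od_series_noiseless(sensor, solver_cache):
    """Noise-free 24 h proliferation runs across starting densities."""
    protocol = PulseProtocol(cooling_time=300.0, total_duration=24 * 3600.0)
    out = {}
    for od in (0.1, 0.2, 0.4, 0.8):
        records = generate_experiment(
            proliferation_scenario(od, 10.0),
            sensor,
            protocol,
            seed=1,
            noise_sd=0.0,
            solver_cache=solver_cache,
        )
        out[od] = slope_series(records, sensor)
    return out


@pytest.fixture(scope="session")
def proliferation_channels(solver_cache):
    """One noisy 18 h four-channel proliferation experiment (Td = 90 min)."""
    protocol = PulseProtocol(cooling_time=300.0, total_duration=18 * 3600.0)
    scenario = proliferation_scenario(od_start=0.2, glucose_g_l=10.0)
    return multichannel_experiment(
        scenario, protocol, seed=3, solver_cache=solver_cache
    )
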