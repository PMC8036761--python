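"""Synthetic culture generator: trajectories, mixing rule, datasets."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermopulse import (
    WATER,
    ConfigurationError,
    MaterialLayer,
    PulseProtocol,
    calibration_endpoints,
    default_sensor,
    generate_experiment,
    growth_trajectory,
    layer_from_biomass,
    maxwell_eucken,
    proliferation_scenario,
    sedimentation_scenario,
    sedimentation_trajectory,
    stokes_velocity,
)
from thermopulse.thermal import FAST_GRID


class TestSedimentation:
    def test_stokes_velocity_for_yeast_sized_particle(self):
        v = stokes_velocity(2.5e-6, 100.0, 1e-3)
        assert v == pytest.approx(1.36e-6, rel=0.01)

    def test_zero_concentration_stays_clean(self):
        scen = sedimentation_scenario(0.0)
        traj = sedimentation_trajectory(scen, np.linspace(0, 12, 50))
        np.testing.assert_array_equal(traj.areal_biovolume, 0.0)

    def test_mass_balance_at_plateau_and_proportionality(self):
        t = np.linspace(0, 24, 100)
        for conc in (0.5, 8.0):
            scen = sedimentation_scenario(conc)
            traj = sedimentation_trajectory(scen, t)
            expected = conc * scen.column_height / scen.cell_rho
            assert traj.areal_biovolume[-1] == pytest.approx(expected, rel=1e-12)
        assert np.all(np.diff(traj.areal_biovolume) >= 0)

    def test_plateau_reached_near_column_transit_time(self):
        scen = sedimentation_scenario(1.0)
        v = stokes_velocity(scen.cell_radius, scen.excess_density, scen.viscosity)
        t_settle_h = scen.column_height / v / 3600.0
        assert 0.5 < t_settle_h < 2.0  # within the first couple of hours
        t = np.array([t_settle_h * 0.999, t_settle_h * 1.001, t_settle_h * 2])
        traj = sedimentation_trajectory(scen, t)
        assert traj.areal_biovolume[1] == pytest.approx(traj.areal_biovolume[2])
        assert traj.areal_biovolume[0] < traj.areal_biovolume[1]

    def test_zero_column_height_rejected(self):
        with pytest.raises(ConfigurationError):
            sedimentation_scenario(1.0, column_height=0.0)


class TestGrowth:
    def test_population_doubles_after_lag_in_low_density_limit(self):
        # enormous carrying capacity -> pure exponential after the lag
        scen = proliferation_scenario(0.2, 1e6, lag_h=5.0, doubling_time_min=90.0)
        t = np.array([0.0, 5.0, 6.5])
        traj = growth_trajectory(scen, t)
        n = traj.areal_biovolume / scen.od_to_areal_biovolume
        assert n[0] == pytest.approx(0.2)
        assert n[1] == pytest.approx(0.2, rel=1e-6)
        assert n[2] == pytest.approx(0.4, rel=1e-3)

    def test_plateau_increment_scales_with_glucose(self):
        t = np.array([200.0])  # far into stationary phase
        incr = {}
        for g in (10.0, 0.16):
            scen = proliferation_scenario(0.2, g)
            n_inf = growth_trajectory(scen, t).areal_biovolume[0]
            n_0 = growth_trajectory(scen, np.array([0.0])).areal_biovolume[0]
            incr[g] = n_inf - n_0
        assert incr[10.0] / incr[0.16] == pytest.approx(62.5, rel=1e-3)

    def test_halving_inoculum_delays_threshold_by_one_doubling(self):
        t = np.linspace(0, 30, 30001)
        thresh = 0.8  # OD units, well below saturation
        times = {}
        for od in (0.4, 0.2):
            scen = proliferation_scenario(od, 1e6, doubling_time_min=90.0)
            n = growth_trajectory(scen, t).areal_biovolume / scen.od_to_areal_biovolume
            times[od] = t[np.nonzero(n >= thresh)[0][0]]
        assert times[0.2] - times[0.4] == pytest.approx(1.5, abs=0.01)

    def test_monotone_and_bounded_by_carrying_capacity(self):
        scen = proliferation_scenario(0.2, 10.0)
        t = np.linspace(0, 48, 500)
        n = growth_trajectory(scen, t).areal_biovolume / scen.od_to_areal_biovolume
        assert np.all(np.diff(n) >= 0)
        cap = scen.od_start + scen.yield_od_per_g_l * scen.glucose_g_l
        assert n[-1] <= cap + 1e-9
        assert n[-1] == pytest.approx(cap, rel=1e-3)

    def test_invalid_growth_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            proliferation_scenario(0.2, 10.0, doubling_time_min=0.0)
        with pytest.raises(ConfigurationError):
            proliferation_scenario(0.0, 10.0)


class TestCellLayer:
    cell = MaterialLayer("cell", k=0.40, rho=1100.0, cp=3500.0, thickness=1.0)

    def test_zero_biovolume_means_no_layer(self):
        assert layer_from_biomass(0.0, 0.64, self.cell, WATER) is None

    def test_full_packing_recovers_cell_conductivity(self):
        layer = layer_from_biomass(1e-5, 1.0, self.cell, WATER)
        assert layer.k == pytest.approx(self.cell.k, rel=1e-12)
        assert layer.thickness == pytest.approx(1e-5)

    def test_thickness_scales_inverse_packing(self):
        layer = layer_from_biomass(1e-5, 0.5, self.cell, WATER)
        assert layer.thickness == pytest.approx(2e-5)

    @settings(derandomize=True, max_examples=50)
    @given(phi=st.floats(0.01, 0.99), k_cell=st.floats(0.1, 0.59))
    def test_mixing_rule_between_series_and_parallel_bounds(self, phi, k_cell):
        k_m = 0.60
        k_eff = maxwell_eucken(k_m, k_cell, phi)
        series = 1.0 / (phi / k_cell + (1 - phi) / k_m)
        parallel = phi * k_cell + (1 - phi) * k_m
        assert series - 1e-12 <= k_eff <= parallel + 1e-12
        assert min(k_cell, k_m) < k_eff < max(k_cell, k_m)


class TestGenerateExperiment:
    def test_pulse_count_and_onset_convention(self, solver_cache):
        sensor = default_sensor()
        proto = PulseProtocol(total_duration=610.0)
        recs = generate_experiment(
            sedimentation_scenario(0.0),
            sensor,
            proto,
            seed=1,
            grid=FAST_GRID,
            solver_cache=solver_cache,
        )
        assert len(recs) == 10
        assert [r.onset for r in recs] == [61.0 * k for k in range(10)]
        assert recs[0].current == pytest.approx(0.25)

    def test_same_seed_reproduces_identical_dataset(self, solver_cache):
        sensor = default_sensor()
        proto = PulseProtocol(total_duration=130.0)
        kw = dict(seed=5, grid=FAST_GRID, solver_cache=solver_cache)
        a = generate_experiment(sedimentation_scenario(1.0), sensor, proto, **kw)
        b = generate_experiment(sedimentation_scenario(1.0), sensor, proto, **kw)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.voltage, rb.voltage)

    def test_requires_stack(self):
        from thermopulse import SensorSpec

        with pytest.raises(ConfigurationError):
            generate_experiment(
                sedimentation_scenario(1.0),
                SensorSpec(),
                PulseProtocol(total_duration=130.0),
            )


class TestCalibrationEndpoints:
    def test_noiseless_draws_lie_on_the_response_line(self):
        conc, pct = calibration_endpoints([1.0, 4.0], n_replicates=2, noise_sd_pct=0.0)
        np.testing.assert_allclose(pct, 0.7806 * conc - 0.2194, rtol=1e-12)

    def test_replication_and_determinism(self):
        c1, p1 = calibration_endpoints([1.0, 2.0], n_replicates=4, seed=9)
        c2, p2 = calibration_endpoints([1.0, 2.0], n_replicates=4, seed=9)
        assert c1.shape == (8,)
        np.testing.assert_array_equal(p1, p2)
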