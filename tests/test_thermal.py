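"""Thermal core: effusivity, probing depth, closed form, FD solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermopulse import (
    FAST_GRID,
    POLYIMIDE,
    WATER,
    ConfigurationError,
    GridSettings,
    InvalidMaterialError,
    LayerStack,
    MaterialLayer,
    TransientCurve,
    analytic_semiinfinite,
    default_stack,
    effusivity,
    layer_from_biomass,
    probing_depth,
    simulate_step_response,
    sqrt_time_regression,
)


def material(k=0.6, rho=998.0, cp=4182.0, **kw):
    return MaterialLayer("m", k=k, rho=rho, cp=cp, **kw)


class TestEffusivity:
    @pytest.mark.parametrize(
        "k,rho,cp,expected",
        [
            (0.60, 998.0, 4182.0, 1582.5),  # water
            (0.12, 1420.0, 1090.0, 431.0),  # polyimide foil
        ],
    )
    def test_known_materials(self, k, rho, cp, expected):
        e = effusivity(material(k, rho, cp, thickness=1e-3))
        assert e == pytest.approx(expected, rel=1e-3)

    def test_vanishing_conductivity_limit(self):
        e = effusivity(material(k=1e-15, thickness=1e-3))
        assert e == pytest.approx(0.0, abs=1e-3)

    @pytest.mark.parametrize("bad", [dict(k=-1.0), dict(rho=0.0), dict(cp=-5.0)])
    def test_nonphysical_properties_rejected(self, bad):
        with pytest.raises(InvalidMaterialError):
            material(thickness=1e-3, **bad)


class TestProbingDepth:
    def test_inverts_to_expected_time_for_substrate(self):
        # depth 2*sqrt(a t) = 40 um in polyimide -> t = (d/2)^2 / a ~ 5.2 ms
        a = POLYIMIDE.diffusivity
        t = (40e-6 / 2.0) ** 2 / a
        assert t == pytest.approx(5.2e-3, rel=0.01)
        assert probing_depth(a, t) == pytest.approx(40e-6, rel=1e-12)

    def test_zero_time_and_sqrt_scaling(self):
        assert probing_depth(1e-7, 0.0) == 0.0
        assert probing_depth(1e-7, 4.0) == pytest.approx(2.0 * probing_depth(1e-7, 1.0))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            probing_depth(1e-7, -1.0)


class TestAnalyticSemiInfinite:
    def test_sqrt_slope_for_water_at_device_flux(self):
        # 0.5 W over 81 mm^2 entirely into water
        q = 0.5 / 81e-6
        e = effusivity(material(thickness=1e-3))
        t = np.linspace(1e-3, 1.0, 500)
        dT = analytic_semiinfinite(e, q, t)
        slope = 2.0 * q / (e * math.sqrt(math.pi))
        assert slope == pytest.approx(4.40, rel=2e-3)
        np.testing.assert_allclose(dT, slope * np.sqrt(t), rtol=1e-12)

    def test_zero_time_and_effusivity_scaling(self):
        assert analytic_semiinfinite(1582.5, 6173.0, 0.0) == 0.0
        assert analytic_semiinfinite(2 * 1582.5, 6173.0, 0.25) == pytest.approx(
            analytic_semiinfinite(1582.5, 6173.0, 0.25) / 2.0
        )


def window_slope(curve: TransientCurve) -> float:
    return sqrt_time_regression(curve.t, curve.dT)[0]


class TestSolver:
    def test_matches_closed_form_for_homogeneous_half_spaces(self):
        """Water on both sides, weightless heater: the FD solution must track
        the constant-flux half-space solution within 2% over the analysis
        range (the flux splits evenly between the two half-spaces)."""
        stack = LayerStack(
            above=(WATER,), below=(WATER,), heater_areal_heat_capacity=0.0
        )
        curve = simulate_step_response(stack, 0.5, 1.0, 500.0)
        q_half = 0.5 / stack.heater_area / 2.0
        expected = analytic_semiinfinite(WATER.effusivity, q_half, curve.t)
        mask = curve.t >= 0.0256
        rel = np.abs(curve.dT[mask] - expected[mask]) / expected[mask]
        assert rel.max() < 0.02
        slope = window_slope(curve)
        assert slope == pytest.approx(
            2.0 * q_half / (WATER.effusivity * math.sqrt(math.pi)), rel=0.02
        )

    def test_zero_power_stays_at_ambient(self):
        curve = simulate_step_response(default_stack(), 0.0, 0.1, 500.0)
        np.testing.assert_array_equal(curve.dT, 0.0)

    def test_positive_power_gives_positive_monotone_early_rise(self):
        curve = simulate_step_response(default_stack(), 0.5, 1.0, 500.0, grid=FAST_GRID)
        assert np.all(curve.dT > 0)
        assert np.all(np.diff(curve.dT) > 0)

    def test_thin_insulating_film_steepens_window_slope(self):
        """An insulating 20 um film on the heater raises the early-window
        slope — the heat-blocking effect the sensor exploits."""
        film = material(k=0.4, rho=1100.0, cp=3500.0, thickness=20e-6)
        bare = LayerStack(above=(WATER,), below=(WATER,))
        coated = LayerStack(above=(film, WATER), below=(WATER,))
        s_bare = window_slope(simulate_step_response(bare, 0.5, 1.0, 500.0))
        s_coated = window_slope(simulate_step_response(coated, 0.5, 1.0, 500.0))
        assert s_coated > s_bare

    def test_response_linear_in_power(self):
        """Conduction is linear: doubling the power doubles the response."""
        stack = default_stack()
        curve = simulate_step_response(stack, 0.5, 0.2, 500.0, grid=FAST_GRID)
        curve2 = simulate_step_response(stack, 1.0, 0.2, 500.0, grid=FAST_GRID)
        np.testing.assert_allclose(curve2.dT, 2 * curve.dT, rtol=1e-10)

    def test_slope_monotone_in_layer_thickness_and_conductivity(self):
        cellprops = material(k=0.45, rho=1100.0, cp=3500.0, thickness=1.0)
        slopes_th = []
        for th in (0.0, 10e-6, 30e-6):
            layer = layer_from_biomass(th * 0.64, 0.64, cellprops, WATER)
            above = (POLYIMIDE, WATER) if layer is None else (POLYIMIDE, layer, WATER)
            stack = default_stack().with_above(above)
            slopes_th.append(
                window_slope(simulate_step_response(stack, 0.5, 1.0, 500.0, grid=FAST_GRID))
            )
        assert slopes_th[0] < slopes_th[1] < slopes_th[2]

        slopes_k = []
        for k in (0.30, 0.45, 0.60):
            layer = material(k=k, rho=1100.0, cp=3500.0, thickness=20e-6)
            stack = default_stack().with_above((POLYIMIDE, layer, WATER))
            slopes_k.append(
                window_slope(simulate_step_response(stack, 0.5, 1.0, 500.0, grid=FAST_GRID))
            )
        assert slopes_k[0] > slopes_k[1] > slopes_k[2]

    def test_small_layer_slope_is_affine_in_thickness(self):
        """Window slope vs thickness deviates < 5% from the secant up to
        ~60 um — the linear regime that makes slope a biomass proxy."""
        cellprops = material(k=0.45, rho=1100.0, cp=3500.0, thickness=1.0)

        def slope_at(th):
            layer = layer_from_biomass(th * 0.64, 0.64, cellprops, WATER)
            above = (POLYIMIDE, WATER) if layer is None else (POLYIMIDE, layer, WATER)
            return window_slope(
                simulate_step_response(
                    default_stack().with_above(above), 0.5, 1.0, 500.0
                )
            )

        s0 = slope_at(0.0)
        s_end = slope_at(60e-6)
        for th in (15e-6, 30e-6, 45e-6):
            s = slope_at(th)
            secant = s0 + (s_end - s0) * th / 60e-6
            assert abs((s - s0) - (secant - s0)) / (secant - s0) < 0.05

    def test_grid_convergence_of_window_slope(self):
        stack = default_stack()
        coarse = simulate_step_response(stack, 0.5, 1.0, 500.0)
        fine = simulate_step_response(
            stack,
            0.5,
            1.0,
            500.0,
            grid=GridSettings(film_dx=0.5e-6, min_film_cells=16, substeps=8),
        )
        s_c, s_f = window_slope(coarse), window_slope(fine)
        assert abs(s_c - s_f) / s_f < 0.005

    def test_invalid_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_step_response(default_stack(), 0.5, -1.0, 500.0)
        with pytest.raises(ConfigurationError):
            simulate_step_response(default_stack(), -0.5, 1.0, 500.0)
        with pytest.raises(ConfigurationError):
            GridSettings(substeps=0)
        with pytest.raises(ConfigurationError):
            GridSettings(stretch_ratio=0.9)


class TestStackValidation:
    def test_top_side_must_terminate_semi_infinite(self):
        with pytest.raises(ConfigurationError):
            LayerStack(above=(material(thickness=1e-5),))

    def test_semi_infinite_only_terminal(self):
        with pytest.raises(ConfigurationError):
            LayerStack(above=(WATER, WATER))

    def test_transient_curve_requires_increasing_positive_time(self):
        with pytest.raises(ConfigurationError):
            TransientCurve(t=np.array([0.0, 0.1]), dT=np.zeros(2))


@settings(derandomize=True, max_examples=50)
@given(
    k=st.floats(0.01, 10.0),
    rho=st.floats(1.0, 5000.0),
    cp=st.floats(10.0, 10000.0),
)
def test_effusivity_diffusivity_consistency(k, rho, cp):
    """e^2 = k * rho * cp and a = k / (rho cp) imply e = k / sqrt(a)."""
    layer = MaterialLayer("x", k=k, rho=rho, cp=cp, thickness=1e-3)
    assert effusivity(layer) == pytest.approx(k / math.sqrt(layer.diffusivity), rel=1e-9)
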