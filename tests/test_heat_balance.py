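"""Unit and property tests for the individual heat budget."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from heatstrain.heat_balance import (
    ClothingParameters,
    HeatBalanceConfig,
    WeatherConditions,
    clothing_surface_temperature,
    convection_coefficient,
    dry_heat_exchange,
    evaporative_heat_loss,
    heat_storage,
    hourly_temperature_gain,
    is_at_risk,
    respiratory_heat_loss,
    saturation_vapor_pressure,
    solar_gain,
    storage_for_gain,
)
from heatstrain.physiology import build_body_profile

CLO = ClothingParameters()
CFG = HeatBalanceConfig()


def _weather(t=30.0, rh=0.3, solar=0.0, wind=2.5):
    return WeatherConditions(t, rh, solar, wind)


class TestPsychrometrics:
    @pytest.mark.parametrize(
        "temp, expected",
        [(0.0, 0.6108), (36.0, 5.941), (20.0, 2.3384)],  # vs published tables
    )
    def test_tetens_values(self, temp, expected):
        assert saturation_vapor_pressure(temp) == pytest.approx(expected, rel=1e-3)

    def test_strictly_increasing(self):
        temps = [-20 + i for i in range(81)]
        vals = [saturation_vapor_pressure(t) for t in temps]
        assert all(b > a > 0 for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("temp", [-20.1, 60.1])
    def test_out_of_range_rejected(self, temp):
        with pytest.raises(ValueError):
            saturation_vapor_pressure(temp)


class TestConvection:
    @pytest.mark.parametrize(
        "wind, expected",
        [(2.5, 8.3 * 2.5**0.6), (0.3, 8.3 * 0.3**0.6), (1.0, 8.3)],
    )
    def test_power_law(self, wind, expected):
        assert convection_coefficient(wind) == pytest.approx(expected)

    def test_floor_applies_in_near_still_air(self):
        # 8.3·v^0.6 dips below 3.1 around v = 0.2 m/s
        assert convection_coefficient(0.05) == CFG.convection_coefficient_floor

    def test_non_decreasing_in_wind(self):
        winds = [0.05 * (i + 1) for i in range(100)]
        vals = [convection_coefficient(v) for v in winds]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_non_positive_wind_rejected(self):
        with pytest.raises(ValueError):
            convection_coefficient(0.0)


class TestClothingSurfaceTemperature:
    def test_no_gradient_no_sun(self):
        assert clothing_surface_temperature(_weather(t=36.0)) == pytest.approx(36.0)

    def test_melbourne_shade_value(self):
        t_cl = clothing_surface_temperature(_weather(t=43.2, rh=0.16, wind=2.5))
        assert t_cl == pytest.approx(40.12, abs=0.01)

    def test_zero_insulation_returns_skin_temperature(self):
        clo = ClothingParameters(insulation=0.0)
        for t, solar in [(10.0, 0.0), (45.0, 800.0)]:
            assert clothing_surface_temperature(_weather(t=t, solar=solar), clo) == 36.0

    def test_agrees_with_numeric_root_finder(self):
        """Closed-form solve vs brentq on the surface balance residual."""
        f_p = CFG.projected_area_fraction
        for t_a in range(10, 51, 5):
            for wind in (0.3, 2.5):
                for solar in (0.0, 600.0):
                    w = _weather(t=float(t_a), solar=solar, wind=wind)
                    h_c = convection_coefficient(wind)

                    def residual(t_cl):
                        return (CLO.skin_temperature - t_cl) / CLO.insulation - (
                            h_c * (t_cl - t_a)
                            - (1 - CLO.clothing_albedo) * f_p * solar
                        )

                    numeric = brentq(residual, -50.0, 150.0, xtol=1e-10)
                    assert clothing_surface_temperature(w) == pytest.approx(
                        numeric, abs=1e-6
                    )


class TestSolarGain:
    def test_zero_indoors(self):
        assert solar_gain(_weather(solar=0.0), 1.81) == 0.0

    def test_table_value_with_default_albedos(self):
        # 600·0.25·1.81·[0.4·1.08·0.7 + 0.6·0.7] with both albedos 0.3
        expected = 600 * 0.25 * 1.81 * (0.4 * 1.08 * 0.7 + 0.6 * 0.7)
        assert solar_gain(_weather(solar=600.0), 1.81) == pytest.approx(expected)

    def test_linear_in_flux(self):
        one = solar_gain(_weather(solar=300.0), 1.81)
        two = solar_gain(_weather(solar=600.0), 1.81)
        assert two == pytest.approx(2 * one)


class TestDryExchange:
    def test_zero_at_skin_temperature_no_sun(self):
        assert dry_heat_exchange(_weather(t=36.0), 1.81) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_decreasing_in_air_temperature(self):
        cool = dry_heat_exchange(_weather(t=25.0), 1.81)
        warm = dry_heat_exchange(_weather(t=35.0), 1.81)
        assert cool > warm

    def test_net_gain_above_skin_temperature(self):
        assert dry_heat_exchange(_weather(t=43.2, rh=0.16), 1.81) < 0.0

    def test_sign_flip_at_skin_temperature_without_sun(self):
        assert dry_heat_exchange(_weather(t=35.5), 1.81) > 0.0
        assert dry_heat_exchange(_weather(t=36.5), 1.81) < 0.0


class TestEvaporativeLoss:
    def test_saturated_air_at_skin_temperature_blocks_evaporation(self):
        loss, capacity = evaporative_heat_loss(
            _weather(t=36.0, rh=1.0), 1.81, 9.41
        )
        assert capacity == 0.0 and loss == 0.0

    def test_sweat_limited_value(self):
        loss, _ = evaporative_heat_loss(_weather(t=43.2, rh=0.16), 1.81, 9.41)
        assert loss == pytest.approx(9.41 * 1.81 * 2426 * 0.85 / 60, rel=1e-9)

    def test_loss_non_increasing_in_humidity(self):
        losses = [
            evaporative_heat_loss(_weather(t=38.0, rh=rh, wind=0.3), 1.81, 9.41)[0]
            for rh in [0.1 * i for i in range(11)]
        ]
        assert all(b <= a for a, b in zip(losses, losses[1:]))

    def test_loss_never_exceeds_capacity(self):
        for rh in (0.2, 0.6, 0.9):
            loss, capacity = evaporative_heat_loss(
                _weather(t=34.0, rh=rh, wind=0.3), 1.6, 11.0
            )
            assert 0.0 <= loss <= capacity


def _profile(mass=70.0, height=170.0, sex="male", age=30.0, exertion="moderate"):
    return build_body_profile(age, sex, mass, height, exertion)


class TestHeatStorage:
    def test_budget_closure_random_inputs(self):
        """|M + R − C − E − S| < 1e-9 W over 10,000 random valid inputs."""
        import numpy as np

        rng = np.random.default_rng(42)
        n = 10_000
        temps = rng.uniform(-20, 60, n)
        rhs = rng.uniform(0, 1, n)
        solars = rng.uniform(0, 1100, n)
        winds = rng.uniform(0.05, 12, n)
        masses = rng.uniform(10, 150, n)
        heights = rng.uniform(60, 210, n)
        exertions = rng.choice(["rest", "minimal", "moderate", "heavy"], n)
        ages = rng.uniform(0, 100, n)
        sexes = rng.choice(["male", "female"], n)
        for i in range(n):
            w = WeatherConditions(temps[i], rhs[i], solars[i], winds[i])
            body = build_body_profile(
                ages[i], sexes[i], masses[i], heights[i], exertions[i]
            )
            fx = heat_storage(w, body)
            residual = (
                fx.metabolic + fx.solar_gain - fx.dry_exchange - fx.evaporative_loss
                - fx.storage
            )
            assert abs(residual) < 1e-9
            assert 0.0 <= fx.evaporative_loss <= fx.evaporative_capacity + 1e-12

    def test_storage_strictly_increasing_in_air_temperature(self):
        body = _profile()
        prev = None
        for t in range(10, 51, 2):
            s = heat_storage(_weather(t=float(t), rh=0.4, solar=300.0), body).storage
            if prev is not None:
                assert s > prev
            prev = s

    def test_monotonicity_grid(self):
        """Storage non-decreasing in T_a, humidity and solar over a grid."""
        import numpy as np

        body = _profile()
        temps = np.linspace(10, 48, 20)
        rhs = np.linspace(0, 1, 10)
        solars = np.linspace(0, 900, 5)
        grid = np.empty((20, 10, 5))
        for i, t in enumerate(temps):
            for j, rh in enumerate(rhs):
                for k, sol in enumerate(solars):
                    grid[i, j, k] = heat_storage(
                        WeatherConditions(t, rh, sol, 2.5), body
                    ).storage
        assert (np.diff(grid, axis=0) >= -1e-12).all()
        assert (np.diff(grid, axis=1) >= -1e-12).all()
        assert (np.diff(grid, axis=2) >= -1e-12).all()

    def test_storage_monotone_in_metabolic_rate_and_sweat(self):
        w = _weather(t=38.0, rh=0.3)
        by_exertion = [
            heat_storage(w, _profile(exertion=e)).storage
            for e in ("rest", "minimal", "moderate", "heavy")
        ]
        assert all(b > a for a, b in zip(by_exertion, by_exertion[1:]))
        # sweat-limited regime: more sweat, less storage
        lo = build_body_profile(30, "male", 70, 170, "moderate", sweat_rate_override=4.0)
        hi = build_body_profile(30, "male", 70, 170, "moderate", sweat_rate_override=8.0)
        assert heat_storage(w, hi).storage < heat_storage(w, lo).storage

    def test_limit_no_gradients(self):
        """At T_a = T_sk with no sun, storage reduces to M − E."""
        w = _weather(t=36.0, rh=0.5)
        body = _profile()
        fx = heat_storage(w, body)
        assert fx.dry_exchange == pytest.approx(0.0, abs=1e-12)
        assert fx.solar_gain == 0.0
        assert fx.storage == pytest.approx(
            body.metabolic_rate - fx.evaporative_loss, abs=1e-9
        )

    def test_female_stores_at_least_as_much_as_male(self):
        """Same body and weather, both sweat-limited: the male sweat
        advantage only raises evaporative loss."""
        w = _weather(t=40.0, rh=0.2)
        for age in (20.0, 45.0, 70.0):
            male = build_body_profile(age, "male", 70, 170, "moderate")
            female = build_body_profile(age, "female", 70, 170, "moderate")
            assert heat_storage(w, female).storage >= heat_storage(w, male).storage

    def test_respiratory_flag_reduces_net_metabolic(self):
        w = _weather(t=20.0, rh=0.5)
        body = _profile()
        off = heat_storage(w, body)
        on = heat_storage(w, body, config=HeatBalanceConfig(include_respiratory_loss=True))
        assert on.respiratory_loss > 0.0
        assert on.storage == pytest.approx(off.storage - on.respiratory_loss)
        assert on.respiratory_loss == pytest.approx(
            respiratory_heat_loss(body.metabolic_rate, w)
        )


class TestTemperatureGain:
    def test_zero_storage_zero_gain(self):
        assert hourly_temperature_gain(0.0, 70.0) == 0.0

    def test_threshold_storage_value(self):
        # 2 °C/h at 70 kg needs 2·3.5·70000/3600 ≈ 136.1 W
        assert hourly_temperature_gain(136.11111111111111, 70.0) == pytest.approx(2.0)

    def test_inverse_proportional_to_mass(self):
        assert hourly_temperature_gain(200.0, 140.0) == pytest.approx(
            hourly_temperature_gain(200.0, 70.0) / 2
        )

    @pytest.mark.parametrize("mass", [10.0, 35.0, 62.5, 70.0, 88.0, 120.0, 150.0])
    def test_threshold_inversion_round_trip(self, mass):
        gain = hourly_temperature_gain(storage_for_gain(2.0, mass), mass)
        assert gain == pytest.approx(2.0, abs=1e-12)

    def test_non_positive_mass_rejected(self):
        with pytest.raises(ValueError):
            hourly_temperature_gain(100.0, 0.0)


class TestRisk:
    def test_threshold_inclusive(self):
        assert is_at_risk(2.0)
        assert not is_at_risk(1.999)

    def test_configurable_threshold(self):
        assert is_at_risk(1.7, HeatBalanceConfig(risk_threshold=1.5))


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(air_temperature=70.0),
            dict(relative_humidity=1.2),
            dict(relative_humidity=-0.1),
            dict(solar_radiation=-5.0),
            dict(wind_speed=0.0),
        ],
    )
    def test_weather_invariants(self, kwargs):
        base = dict(
            air_temperature=30.0, relative_humidity=0.5, solar_radiation=0.0,
            wind_speed=1.0,
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            WeatherConditions(**base)

    def test_clothing_fraction_invariants(self):
        with pytest.raises(ValueError):
            ClothingParameters(clothed_proportion=1.5)
        with pytest.raises(ValueError):
            ClothingParameters(insulation=-0.01)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    t=st.floats(-20, 60),
    rh=st.floats(0, 1),
    solar=st.floats(0, 1100),
    wind=st.floats(0.05, 12),
    mass=st.floats(10, 150),
    height=st.floats(60, 210),
)
def test_budget_closure_property(t, rh, solar, wind, mass, height):
    """Flux components always sum to storage, for any valid input."""
    w = WeatherConditions(t, rh, solar, wind)
    body = build_body_profile(30.0, "female", mass, height, "moderate")
    fx = heat_storage(w, body)
    assert math.isclose(
        fx.storage,
        fx.metabolic + fx.solar_gain - fx.dry_exchange - fx.evaporative_loss,
        abs_tol=1e-9,
    )
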