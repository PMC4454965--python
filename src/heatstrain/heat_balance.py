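"""Steady-state heat budget for a single individual.

The model balances metabolic heat production, absorbed solar radiation,
dry (convective/conductive) exchange and evaporative cooling for a person
with fixed skin temperature sweating at their maximal rate.  The net
storage flux, divided by the body's heat capacity, gives the hourly
core-temperature change used as the heat-strain risk measure.

Sign conventions: ``solar_gain`` and ``metabolic`` are gains (W into the
body); ``dry_exchange`` and ``evaporative_loss`` are losses (positive =
heat leaving the body), so dry exchange goes negative when air is hotter
than skin and the body gains heat through its surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "WeatherConditions",
    "ClothingParameters",
    "HeatBalanceConfig",
    "FluxBreakdown",
    "saturation_vapor_pressure",
    "convection_coefficient",
    "clothing_surface_temperature",
    "solar_gain",
    "dry_heat_exchange",
    "evaporative_heat_loss",
    "respiratory_heat_loss",
    "heat_storage",
    "hourly_temperature_gain",
    "storage_for_gain",
    "is_at_risk",
]

_T_MIN, _T_MAX = -20.0, 60.0


@dataclass(frozen=True)
class WeatherConditions:
    """One station-time weather observation as seen by an individual.

    Parameters
    ----------
    air_temperature : float
        Air (dry-bulb) temperature in °C.
    relative_humidity : float
        Relative humidity as a fraction in [0, 1].
    solar_radiation : float
        Global horizontal shortwave flux in W·m⁻² (0 indoors).
    wind_speed : float
        Effective air speed over the body in m·s⁻¹ (must be > 0; still
        air is represented by the body-movement value 0.3 m·s⁻¹).
    """

    air_temperature: float
    relative_humidity: float
    solar_radiation: float
    wind_speed: float

    def __post_init__(self) -> None:
        if not _T_MIN <= self.air_temperature <= _T_MAX:
            raise ValueError(
                f"air_temperature {self.air_temperature} °C outside "
                f"[{_T_MIN}, {_T_MAX}]"
            )
        if not 0.0 <= self.relative_humidity <= 1.0:
            raise ValueError(
                f"relative_humidity {self.relative_humidity} not a fraction in [0, 1]"
            )
        if self.solar_radiation < 0.0:
            raise ValueError(f"solar_radiation {self.solar_radiation} < 0")
        if self.wind_speed <= 0.0:
            raise ValueError(f"wind_speed {self.wind_speed} must be > 0")


@dataclass(frozen=True)
class ClothingParameters:
    """Single-layer clothing and skin surface constants.

    Defaults are the conventional fixed values for a lightly clothed
    person: 0.6 clo of dry insulation (0.6 × 0.155 = 0.093 m²·K·W⁻¹),
    40 % of the body covered with a 1.08 area ratio, albedo 0.3 for both
    skin and fabric, 85 % of sweat evaporating effectively, and skin held
    at 36 °C (no explicit skin-temperature equilibrium is solved).
    """

    clothing_albedo: float = 0.3
    clothed_proportion: float = 0.4
    clothing_area_ratio: float = 1.08
    evaporation_efficiency: float = 0.85
    insulation: float = 0.093
    skin_albedo: float = 0.3
    skin_temperature: float = 36.0

    def __post_init__(self) -> None:
        for name in ("clothing_albedo", "clothed_proportion",
                     "evaporation_efficiency", "skin_albedo"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} {v} not a fraction in [0, 1]")
        if self.insulation < 0.0:
            raise ValueError(f"insulation {self.insulation} < 0")


@dataclass(frozen=True)
class HeatBalanceConfig:
    """Physical constants and transfer-coefficient choices.

    ``body_heat_capacity`` (3.5 J·g⁻¹·K⁻¹) converts net storage into an
    hourly core-temperature change, and ``risk_threshold`` (2.0 °C·h⁻¹)
    classifies an individual as at risk of heat strain.  The remaining
    fields select the engineering correlations: latent heat of sweat
    evaporated at skin temperature, the Lewis-relation coefficient tying
    the evaporative capacity to the convective coefficient, the fraction
    of total surface area projected toward the sun, and the
    natural-convection floor under the forced-convection power law.
    """

    body_heat_capacity: float = 3.5
    latent_heat_vaporization: float = 2426.0
    lewis_ratio: float = 16.5
    projected_area_fraction: float = 0.25
    convection_coefficient_floor: float = 3.1
    include_respiratory_loss: bool = False
    risk_threshold: float = 2.0


@dataclass(frozen=True)
class FluxBreakdown:
    """Component heat flows (W) and the resulting temperature-gain rate.

    ``metabolic`` is the net internal production delivered to the body
    surface budget (gross metabolic rate minus respiratory loss when that
    term is enabled), so the closure
    ``storage = metabolic + solar_gain - dry_exchange - evaporative_loss``
    always holds.  ``evaporative_capacity`` is the environmental ceiling
    on evaporation; ``evaporative_loss`` never exceeds it.
    """

    metabolic: float
    solar_gain: float
    dry_exchange: float
    evaporative_loss: float
    evaporative_capacity: float
    storage: float
    hourly_temp_gain: float
    respiratory_loss: float = field(default=0.0)


def saturation_vapor_pressure(temperature: float) -> float:
    """Saturation water-vapor pressure in kPa (Tetens formula).

    ``p = 0.6108 · exp(17.27·T / (T + 237.3))`` for T in °C; valid over
    the model's temperature range [-20, 60] °C.
    """
    if not _T_MIN <= temperature <= _T_MAX:
        raise ValueError(f"temperature {temperature} °C outside [{_T_MIN}, {_T_MAX}]")
    return 0.6108 * math.exp(17.27 * temperature / (temperature + 237.3))


def convection_coefficient(
    wind_speed: float, config: HeatBalanceConfig = HeatBalanceConfig()
) -> float:
    """Convective heat-transfer coefficient h_c in W·m⁻²·K⁻¹.

    Forced-convection power law ``8.3 · v^0.6`` with a floor at the
    natural-convection value so h_c never vanishes in near-still air.
    """
    if wind_speed <= 0.0:
        raise ValueError(f"wind_speed {wind_speed} must be > 0")
    return max(8.3 * wind_speed**0.6, config.convection_coefficient_floor)


def clothing_surface_temperature(
    weather: WeatherConditions,
    clothing: ClothingParameters = ClothingParameters(),
    config: HeatBalanceConfig = HeatBalanceConfig(),
) -> float:
    """Steady-state outer clothing surface temperature T_cl in °C.

    Solves the linear surface balance: conduction through the layer
    equals convection to air minus absorbed solar flux,

        (T_sk - T_cl) / I_cl = h_c·(T_cl - T_a) - (1 - α_cl)·f_p·R_sol.

    With zero insulation the layer vanishes and T_cl equals skin
    temperature.
    """
    if clothing.insulation == 0.0:
        return clothing.skin_temperature
    h_c = convection_coefficient(weather.wind_speed, config)
    absorbed = (
        (1.0 - clothing.clothing_albedo)
        * config.projected_area_fraction
        * weather.solar_radiation
    )
    inv_i = 1.0 / clothing.insulation
    return (
        clothing.skin_temperature * inv_i
        + h_c * weather.air_temperature
        + absorbed
    ) / (h_c + inv_i)


def solar_gain(
    weather: WeatherConditions,
    surface_area: float,
    clothing: ClothingParameters = ClothingParameters(),
    config: HeatBalanceConfig = HeatBalanceConfig(),
) -> float:
    """Shortwave radiation absorbed by the body, in W.

    The projected-area fraction converts global horizontal flux to the
    flux intercepted by the body; clothed and bare segments absorb with
    their own albedos, the clothed segment magnified by the clothing
    area ratio.
    """
    if surface_area <= 0.0:
        raise ValueError(f"surface_area {surface_area} must be > 0")
    p = clothing.clothed_proportion
    absorptance = (
        p * clothing.clothing_area_ratio * (1.0 - clothing.clothing_albedo)
        + (1.0 - p) * (1.0 - clothing.skin_albedo)
    )
    return weather.solar_radiation * config.projected_area_fraction * surface_area * absorptance


def _clothed_conduction_flux(
    weather: WeatherConditions,
    clothing: ClothingParameters,
    config: HeatBalanceConfig,
) -> float:
    """Conductive flux density (W·m⁻²) through the clothed segment.

    Algebraically equal to (T_sk - T_cl)/I_cl with T_cl from
    :func:`clothing_surface_temperature`, written in a form that is
    finite in the zero-insulation limit.
    """
    h_c = convection_coefficient(weather.wind_speed, config)
    absorbed = (
        (1.0 - clothing.clothing_albedo)
        * config.projected_area_fraction
        * weather.solar_radiation
    )
    gradient = clothing.skin_temperature - weather.air_temperature
    return (h_c * gradient - absorbed) / (1.0 + h_c * clothing.insulation)


def dry_heat_exchange(
    weather: WeatherConditions,
    surface_area: float,
    clothing: ClothingParameters = ClothingParameters(),
    config: HeatBalanceConfig = HeatBalanceConfig(),
) -> float:
    """Net dry (sensible) heat loss from the body, in W.

    Bare-skin convection plus conduction through the clothed layer to
    its solar-heated surface.  Positive = loss; the sign flips once air
    temperature exceeds skin temperature (sooner in strong sun, because
    the clothing surface runs hot).
    """
    if surface_area <= 0.0:
        raise ValueError(f"surface_area {surface_area} must be > 0")
    h_c = convection_coefficient(weather.wind_speed, config)
    p = clothing.clothed_proportion
    bare = (
        h_c
        * surface_area
        * (1.0 - p)
        * (clothing.skin_temperature - weather.air_temperature)
    )
    clothed = surface_area * p * _clothed_conduction_flux(weather, clothing, config)
    return bare + clothed


def evaporative_heat_loss(
    weather: WeatherConditions,
    surface_area: float,
    max_sweat_rate: float,
    clothing: ClothingParameters = ClothingParameters(),
    config: HeatBalanceConfig = HeatBalanceConfig(),
) -> tuple[float, float]:
    """Evaporative cooling, returned as ``(loss, capacity)`` in W.

    The sweat-limited loss converts the maximal sweat rate
    (g·min⁻¹·m⁻²) to latent heat at the configured evaporation
    efficiency.  The environmental capacity follows the Lewis relation,
    proportional to h_c and the skin-to-air vapor-pressure gradient, and
    is floored at zero (supersaturated air cannot heat the body through
    this term).  The realized loss is the smaller of the two.
    """
    if max_sweat_rate < 0.0:
        raise ValueError(f"max_sweat_rate {max_sweat_rate} must be >= 0")
    if surface_area <= 0.0:
        raise ValueError(f"surface_area {surface_area} must be > 0")
    sweat_limited = (
        max_sweat_rate
        * surface_area
        * config.latent_heat_vaporization
        * clothing.evaporation_efficiency
        / 60.0
    )
    h_c = convection_coefficient(weather.wind_speed, config)
    gradient = saturation_vapor_pressure(
        clothing.skin_temperature
    ) - weather.relative_humidity * saturation_vapor_pressure(weather.air_temperature)
    capacity = max(config.lewis_ratio * h_c * surface_area * gradient, 0.0)
    return min(sweat_limited, capacity), capacity


def respiratory_heat_loss(
    metabolic_rate: float,
    weather: WeatherConditions,
    config: HeatBalanceConfig = HeatBalanceConfig(),
) -> float:
    """Respiratory (latent + dry) heat loss in W, standard empirical form.

    ``0.0014·M·(34 - T_a) + 0.0173·M·(5.87 - φ·p_sat(T_a))``.  May go
    negative in very hot humid air (breathing then warms the body).
    """
    p_air = weather.relative_humidity * saturation_vapor_pressure(weather.air_temperature)
    return 0.0014 * metabolic_rate * (34.0 - weather.air_temperature) + 0.0173 * metabolic_rate * (
        5.87 - p_air
    )


def heat_storage(
    weather: WeatherConditions,
    body: "BodyProfile",
    clothing: ClothingParameters = ClothingParameters(),
    config: HeatBalanceConfig = HeatBalanceConfig(),
) -> FluxBreakdown:
    """Full steady-state budget for one individual: S = M + R − C − E."""
    resp = 0.0
    if config.include_respiratory_loss:
        resp = respiratory_heat_loss(body.metabolic_rate, weather, config)
    metabolic = body.metabolic_rate - resp
    solar = solar_gain(weather, body.surface_area, clothing, config)
    dry = dry_heat_exchange(weather, body.surface_area, clothing, config)
    evap, capacity = evaporative_heat_loss(
        weather, body.surface_area, body.max_sweat_rate, clothing, config
    )
    storage = metabolic + solar - dry - evap
    return FluxBreakdown(
        metabolic=metabolic,
        solar_gain=solar,
        dry_exchange=dry,
        evaporative_loss=evap,
        evaporative_capacity=capacity,
        storage=storage,
        hourly_temp_gain=hourly_temperature_gain(storage, body.mass, config),
        respiratory_loss=resp,
    )


def hourly_temperature_gain(
    storage: float, mass: float, config: HeatBalanceConfig = HeatBalanceConfig()
) -> float:
    """Core-temperature change rate in °C·h⁻¹ implied by a storage flux.

    ΔT/hour = S·3600 / (c_b · mass·1000) with c_b in J·g⁻¹·K⁻¹.
    """
    if mass <= 0.0:
        raise ValueError(f"mass {mass} must be > 0")
    return storage * 3600.0 / (config.body_heat_capacity * mass * 1000.0)


def storage_for_gain(
    gain: float, mass: float, config: HeatBalanceConfig = HeatBalanceConfig()
) -> float:
    """Inverse of :func:`hourly_temperature_gain`: storage (W) giving a rate."""
    if mass <= 0.0:
        raise ValueError(f"mass {mass} must be > 0")
    return gain * config.body_heat_capacity * mass * 1000.0 / 3600.0


def is_at_risk(
    hourly_gain: float, config: HeatBalanceConfig = HeatBalanceConfig()
) -> bool:
    """True when the hourly gain meets or exceeds the risk threshold.

    The comparison is inclusive: a gain of exactly the threshold
    (default 2.0 °C·h⁻¹) counts as at risk.
    """
    return hourly_gain >= config.risk_threshold
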