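"""Individual physiology: surface area, maximal sweat rate, metabolic rate.

These are the person-level inputs to the heat budget.  Surface area
follows the classic height-mass power law; the maximal sweat rate is a
linear function of sex, acclimatization and age fitted to hyperthermia
studies; metabolic rate is anchored at four exertion levels for a 70 kg
reference body and scaled allometrically with mass.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EXERTION_LEVELS",
    "BodyProfile",
    "SweatModelCoefficients",
    "MetabolicModel",
    "body_surface_area",
    "max_sweat_rate",
    "metabolic_rate",
    "build_body_profile",
]

EXERTION_LEVELS = ("rest", "minimal", "moderate", "heavy")


@dataclass(frozen=True)
class SweatModelCoefficients:
    """Linear model of maximal sweat rate (g·min⁻¹·m⁻²).

    rate = intercept + male_effect·[male] + acclimatization_effect·[accl]
           + age_slope·age,
    with the male indicator forced to 0 below ``child_age_cutoff``
    (pre-pubescent boys sweat like girls) and the result clamped below
    at ``floor`` so very old unacclimatized strata keep a small positive
    rate.
    """

    intercept: float = 7.39
    male_effect: float = 2.61
    acclimatization_effect: float = 1.16
    age_slope: float = -0.07
    child_age_cutoff: float = 14.0
    floor: float = 0.5


@dataclass(frozen=True)
class MetabolicModel:
    """Exertion-level metabolic anchors (W at the reference mass) and
    the allometric mass exponent.

    The default anchors are 125 / 225 / 600 / 1280 W for rest, minimal,
    moderate and heavy exertion at 70 kg; other masses scale as
    (mass / 70)^0.75.  Set ``mass_exponent`` to 1.0 for linear scaling.
    """

    reference_mass: float = 70.0
    rest: float = 125.0
    minimal: float = 225.0
    moderate: float = 600.0
    heavy: float = 1280.0
    mass_exponent: float = 0.75

    def __post_init__(self) -> None:
        if not self.rest < self.minimal < self.moderate < self.heavy:
            raise ValueError("metabolic anchors must increase with exertion level")

    def anchor(self, exertion: str) -> float:
        if exertion not in EXERTION_LEVELS:
            raise ValueError(
                f"unknown exertion level {exertion!r}; expected one of {EXERTION_LEVELS}"
            )
        return getattr(self, exertion)


@dataclass(frozen=True)
class BodyProfile:
    """One physiological agent, ready for the heat budget."""

    mass: float
    height: float
    surface_area: float
    max_sweat_rate: float
    metabolic_rate: float
    sex: str
    age: float
    acclimatized: bool = True


def body_surface_area(mass: float, height: float) -> float:
    """Body surface area in m² from mass (kg) and height (cm).

    A = 0.007184 · mass^0.425 · height^0.725.
    """
    if mass <= 0.0 or height <= 0.0:
        raise ValueError(f"mass {mass} and height {height} must both be > 0")
    return 0.007184 * mass**0.425 * height**0.725


def max_sweat_rate(
    age: float,
    sex: str,
    acclimatized: bool = True,
    coefficients: SweatModelCoefficients = SweatModelCoefficients(),
) -> float:
    """Maximal sweat rate in g·min⁻¹·m⁻² for an age/sex/acclimatization
    combination (see :class:`SweatModelCoefficients`)."""
    if age < 0.0:
        raise ValueError(f"age {age} must be >= 0")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    male = 1.0 if (sex == "male" and age >= coefficients.child_age_cutoff) else 0.0
    rate = (
        coefficients.intercept
        + coefficients.male_effect * male
        + coefficients.acclimatization_effect * (1.0 if acclimatized else 0.0)
        + coefficients.age_slope * age
    )
    return max(rate, coefficients.floor)


def metabolic_rate(
    exertion: str, mass: float, model: MetabolicModel = MetabolicModel()
) -> float:
    """Metabolic heat production in W for an exertion level and body mass."""
    if mass <= 0.0:
        raise ValueError(f"mass {mass} must be > 0")
    return model.anchor(exertion) * (mass / model.reference_mass) ** model.mass_exponent


def build_body_profile(
    age: float,
    sex: str,
    mass: float,
    height: float,
    exertion: str,
    acclimatized: bool = True,
    sweat_coefficients: SweatModelCoefficients = SweatModelCoefficients(),
    metabolic_model: MetabolicModel = MetabolicModel(),
    sweat_rate_override: float | None = None,
) -> BodyProfile:
    """Assemble an internally consistent :class:`BodyProfile`.

    ``sweat_rate_override`` replaces the modelled sweat rate — used by
    the population layer, where sweat rates are discretized into bins.
    """
    rate = (
        sweat_rate_override
        if sweat_rate_override is not None
        else max_sweat_rate(age, sex, acclimatized, sweat_coefficients)
    )
    return BodyProfile(
        mass=mass,
        height=height,
        surface_area=body_surface_area(mass, height),
        max_sweat_rate=rate,
        metabolic_rate=metabolic_rate(exertion, mass, metabolic_model),
        sex=sex,
        age=age,
        acclimatized=acclimatized,
    )
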