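"""Scaling the individual heat budget to a population.

The population is represented by weighted *person-types*: cells of an
(age group × sex) stratum sharing a discretized body size (10 cm height
× 20 kg mass blocks), a discretized maximal sweat rate (2 g·min⁻¹·m⁻²
blocks) and an exposure/exertion assignment derived from occupation
data.  Each person-type is evaluated once against the day's weather and
its weight contributes wholesale to the stratum's at-risk proportion —
far cheaper than simulating every individual, and exact whenever
individuals sit on their bin representatives.

Exposure categories: ``not_exposed`` people can fully modify their
environment and are never at risk; ``indoors`` people see still air and
no sun; ``outdoors`` people see a light breeze and the recorded solar
flux.  For reporting, rest and minimal exertion are merged, giving the
seven cells of :data:`RISK_CELLS`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .heat_balance import (
    ClothingParameters,
    HeatBalanceConfig,
    heat_storage,
    is_at_risk,
)
from .physiology import (
    EXERTION_LEVELS,
    MetabolicModel,
    SweatModelCoefficients,
    build_body_profile,
    max_sweat_rate,
)
from .weather_io import WeatherRecord, to_exposure_weather

__all__ = [
    "EXPOSURE_CATEGORIES",
    "RISK_CELLS",
    "HEIGHT_BIN_CM",
    "MASS_BIN_KG",
    "SWEAT_BIN",
    "ExposureAssignment",
    "PersonType",
    "RiskBreakdown",
    "representative_age",
    "bin_representative",
    "discretize_body_distribution",
    "default_exposure_mapping",
    "assign_exposure_exertion",
    "build_person_types",
    "population_risk",
    "risk_time_series",
    "breakdowns_to_frame",
]

EXPOSURE_CATEGORIES = ("not_exposed", "indoors", "outdoors")

#: Reporting cells: exposure × merged exertion, plus the never-at-risk
#: remainder.
RISK_CELLS = (
    "not_exposed",
    "indoors_rest_minimal",
    "indoors_moderate",
    "indoors_heavy",
    "outdoors_rest_minimal",
    "outdoors_moderate",
    "outdoors_heavy",
)

HEIGHT_BIN_CM = 10.0
MASS_BIN_KG = 20.0
SWEAT_BIN = 2.0

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class ExposureAssignment:
    """One exposure × exertion cell with its within-stratum weight."""

    exposure: str
    exertion: str
    weight: float

    def __post_init__(self) -> None:
        if self.exposure not in EXPOSURE_CATEGORIES:
            raise ValueError(f"unknown exposure {self.exposure!r}")
        if self.exertion not in EXERTION_LEVELS:
            raise ValueError(f"unknown exertion {self.exertion!r}")
        if self.weight < 0.0:
            raise ValueError(f"weight {self.weight} < 0")

    @property
    def cell(self) -> str:
        """Reporting cell this assignment falls into."""
        if self.exposure == "not_exposed":
            return "not_exposed"
        level = "rest_minimal" if self.exertion in ("rest", "minimal") else self.exertion
        return f"{self.exposure}_{level}"


@dataclass(frozen=True)
class PersonType:
    """A weighted population cell: demographics × body bin × exposure."""

    age_group: str
    sex: str
    height_bin: float
    mass_bin: float
    sweat_bin: float
    exposure: ExposureAssignment
    weight: float


@dataclass(frozen=True)
class RiskBreakdown:
    """Proportion of one age-sex stratum at risk, total and per cell."""

    age_group: str
    sex: str
    total_at_risk: float
    by_cell: dict[str, float] = field(default_factory=dict)


def representative_age(age_group: str, open_ended_offset: float = 5.0) -> float:
    """Representative (midpoint) age of a band label like ``'35-44'``.

    Open-ended labels like ``'75+'`` use lower edge + ``open_ended_offset``
    (default 5 years, giving 80 for 75+).
    """
    label = age_group.strip()
    if label.endswith("+"):
        return float(label[:-1]) + open_ended_offset
    lo, hi = label.split("-")
    return (float(lo) + float(hi)) / 2.0


def bin_representative(value: float, width: float) -> float:
    """Midpoint of the ``width``-wide block (anchored at 0) containing
    ``value``."""
    return width * math.floor(value / width) + width / 2.0


def _check_stratum_sums(df: pd.DataFrame, what: str) -> None:
    if (df["proportion"] < 0).any():
        raise ValueError(f"{what} table contains negative proportions")
    sums = df.groupby(["age_group", "sex"], sort=False)["proportion"].sum()
    bad = sums[(sums - 1.0).abs() > _SUM_TOL]
    if not bad.empty:
        detail = ", ".join(f"{k}: {v:.6f}" for k, v in bad.items())
        raise ValueError(f"{what} proportions must sum to 1 per stratum ({detail})")


def discretize_body_distribution(population_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a height×mass proportion table onto 10 cm × 20 kg blocks.

    Input columns: ``age_group, sex, height_cm, mass_kg, proportion``
    with proportions summing to 1 within each age-sex stratum.  Output
    columns: ``age_group, sex, height_bin, mass_bin, weight`` with bin
    representatives at block midpoints and weights summed within blocks
    (total weight per stratum conserved).
    """
    required = {"age_group", "sex", "height_cm", "mass_kg", "proportion"}
    missing = required - set(population_table.columns)
    if missing:
        raise ValueError(f"population table missing column(s): {sorted(missing)}")
    _check_stratum_sums(population_table, "population")
    df = population_table.copy()
    df["height_bin"] = df["height_cm"].map(lambda h: bin_representative(h, HEIGHT_BIN_CM))
    df["mass_bin"] = df["mass_kg"].map(lambda m: bin_representative(m, MASS_BIN_KG))
    out = (
        df.groupby(["age_group", "sex", "height_bin", "mass_bin"], sort=False)[
            "proportion"
        ]
        .sum()
        .reset_index()
        .rename(columns={"proportion": "weight"})
    )
    return out


def default_exposure_mapping() -> dict[str, dict[str, str]]:
    """Shipped occupation → (exposure, exertion) mapping.

    Loaded from the packaged ``data/occupation_mapping.yaml``; edit a
    copy and pass it through ``assign_exposure_exertion`` to change the
    classification.
    """
    import importlib.resources

    import yaml

    text = (
        importlib.resources.files("heatstrain")
        .joinpath("data/occupation_mapping.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def assign_exposure_exertion(
    occupation_table: pd.DataFrame,
    mapping: dict[str, dict[str, str]] | None = None,
) -> pd.DataFrame:
    """Turn occupation shares into an exposure × exertion distribution.

    Input columns: ``age_group, sex, occupation, proportion`` summing to
    1 per stratum.  Output columns: ``age_group, sex, exposure,
    exertion, weight`` (again summing to 1 per stratum).  An occupation
    absent from ``mapping`` is a configuration error.
    """
    if mapping is None:
        mapping = default_exposure_mapping()
    required = {"age_group", "sex", "occupation", "proportion"}
    missing = required - set(occupation_table.columns)
    if missing:
        raise ValueError(f"occupation table missing column(s): {sorted(missing)}")
    _check_stratum_sums(occupation_table, "occupation")
    unmapped = sorted(set(occupation_table["occupation"]) - set(mapping))
    if unmapped:
        raise KeyError(f"occupation(s) missing from exposure mapping: {unmapped}")
    df = occupation_table.copy()
    df["exposure"] = df["occupation"].map(lambda o: mapping[o]["exposure"])
    df["exertion"] = df["occupation"].map(lambda o: mapping[o]["exertion"])
    out = (
        df.groupby(["age_group", "sex", "exposure", "exertion"], sort=False)[
            "proportion"
        ]
        .sum()
        .reset_index()
        .rename(columns={"proportion": "weight"})
    )
    for row in out.itertuples():  # validates category names
        ExposureAssignment(row.exposure, row.exertion, row.weight)
    return out


def build_person_types(
    binned_population: pd.DataFrame,
    exposure_distribution: pd.DataFrame,
    sweat_coefficients: SweatModelCoefficients = SweatModelCoefficients(),
    stratum_shares: dict[tuple[str, str], float] | None = None,
    acclimatized: bool = True,
) -> list[PersonType]:
    """Cross body bins with exposure cells into weighted person-types.

    Each person-type's weight is ``stratum share × body-bin weight ×
    exposure-cell weight``; total weight per stratum therefore equals
    the stratum's population share (uniform across strata when
    ``stratum_shares`` is omitted).  The stratum's sweat rate is the
    model value at the band's representative age, discretized into
    2 g·min⁻¹·m⁻² blocks.
    """
    strata = sorted(
        set(map(tuple, binned_population[["age_group", "sex"]].drop_duplicates().values))
    )
    if stratum_shares is None:
        stratum_shares = {s: 1.0 / len(strata) for s in strata}
    exp_groups = {
        key: grp
        for key, grp in exposure_distribution.groupby(["age_group", "sex"], sort=False)
    }
    types: list[PersonType] = []
    for age_group, sex in strata:
        key = (age_group, sex)
        if key not in exp_groups:
            raise ValueError(f"no exposure distribution for stratum {key}")
        share = stratum_shares[key]
        sweat = max_sweat_rate(
            representative_age(age_group), sex, acclimatized, sweat_coefficients
        )
        sweat_bin = bin_representative(sweat, SWEAT_BIN)
        bodies = binned_population[
            (binned_population["age_group"] == age_group)
            & (binned_population["sex"] == sex)
        ]
        for body in bodies.itertuples():
            for exp in exp_groups[key].itertuples():
                assignment = ExposureAssignment(exp.exposure, exp.exertion, exp.weight)
                types.append(
                    PersonType(
                        age_group=age_group,
                        sex=sex,
                        height_bin=body.height_bin,
                        mass_bin=body.mass_bin,
                        sweat_bin=sweat_bin,
                        exposure=assignment,
                        weight=share * body.weight * exp.weight,
                    )
                )
    return types


def population_risk(
    person_types: list[PersonType],
    record: WeatherRecord,
    clothing: ClothingParameters = ClothingParameters(),
    metabolic_model: MetabolicModel = MetabolicModel(),
    config: HeatBalanceConfig = HeatBalanceConfig(),
    solar_scale: float = 1.0,
) -> list[RiskBreakdown]:
    """Evaluate every person-type against one day's weather.

    Returns one :class:`RiskBreakdown` per age-sex stratum: the fraction
    of the stratum at risk (hourly gain ≥ threshold), in total and per
    exposure × exertion cell.  Not-exposed weight never contributes.
    """
    totals: dict[tuple[str, str], float] = {}
    at_risk: dict[tuple[str, str], dict[str, float]] = {}
    memo: dict[tuple, bool] = {}
    for pt in person_types:
        key = (pt.age_group, pt.sex)
        totals[key] = totals.get(key, 0.0) + pt.weight
        cells = at_risk.setdefault(key, {c: 0.0 for c in RISK_CELLS})
        if pt.exposure.exposure == "not_exposed":
            continue
        mkey = (
            pt.mass_bin,
            pt.height_bin,
            pt.sweat_bin,
            pt.exposure.exposure,
            pt.exposure.exertion,
        )
        if mkey not in memo:
            weather = to_exposure_weather(record, pt.exposure.exposure, solar_scale)
            profile = build_body_profile(
                age=representative_age(pt.age_group),
                sex=pt.sex,
                mass=pt.mass_bin,
                height=pt.height_bin,
                exertion=pt.exposure.exertion,
                metabolic_model=metabolic_model,
                sweat_rate_override=pt.sweat_bin,
            )
            fluxes = heat_storage(weather, profile, clothing, config)
            memo[mkey] = is_at_risk(fluxes.hourly_temp_gain, config)
        if memo[mkey]:
            cells[pt.exposure.cell] += pt.weight
    breakdowns: list[RiskBreakdown] = []
    for key in sorted(totals):
        total_w = totals[key]
        cells = {c: w / total_w for c, w in at_risk[key].items()}
        breakdowns.append(
            RiskBreakdown(
                age_group=key[0],
                sex=key[1],
                total_at_risk=sum(cells.values()),
                by_cell=cells,
            )
        )
    return breakdowns


def risk_time_series(
    person_types: list[PersonType],
    weather_series: list[WeatherRecord],
    clothing: ClothingParameters = ClothingParameters(),
    metabolic_model: MetabolicModel = MetabolicModel(),
    config: HeatBalanceConfig = HeatBalanceConfig(),
    solar_scale: float = 1.0,
) -> pd.DataFrame:
    """Daily risk breakdowns over a weather series, as a tidy frame.

    One row per date × age group × sex × cell (plus a ``total`` row per
    stratum), with the day's driving weather echoed for plotting.
    """
    if not weather_series:
        raise ValueError("weather series is empty")
    frames = []
    for record in weather_series:
        breakdowns = population_risk(
            person_types, record, clothing, metabolic_model, config, solar_scale
        )
        frames.append(breakdowns_to_frame(breakdowns, record))
    return pd.concat(frames, ignore_index=True)


def breakdowns_to_frame(
    breakdowns: list[RiskBreakdown], record: WeatherRecord
) -> pd.DataFrame:
    """Flatten breakdowns for one day into tidy rows."""
    rows = []
    for b in breakdowns:
        entries = list(b.by_cell.items()) + [("total", b.total_at_risk)]
        for cell, proportion in entries:
            rows.append(
                {
                    "date": record.date,
                    "station": record.station,
                    "air_temperature_c": record.air_temperature_c,
                    "relative_humidity_pct": record.relative_humidity_pct,
                    "solar_radiation_wm2": record.solar_radiation_wm2,
                    "age_group": b.age_group,
                    "sex": b.sex,
                    "cell": cell,
                    "proportion": proportion,
                }
            )
    return pd.DataFrame(rows)
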