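"""Seeded generators for population, occupation and weather tables.

Real national height-mass tabulations and occupation breakdowns are
custom statistical products that cannot be redistributed, so this module
produces synthetic stand-ins with the statistical structure the
simulation assumes: heights Gaussian within each age-sex stratum, mass
derived from a log-normal BMI times height squared (with a configurable
height–BMI correlation), and occupation shares calibrated so that —
under the shipped exposure mapping — four times as many males as
females do moderate-or-heavy work outdoors.  The anthropometric
defaults approximate Australian distributions; they are configuration,
not demographic claims.  All outputs are fully determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from datetime import timedelta

import numpy as np
import pandas as pd

from .population import default_exposure_mapping

__all__ = [
    "AGE_GROUPS",
    "GeneratorConfig",
    "generate_population_table",
    "generate_occupation_table",
    "generate_weather_series",
    "outdoor_exertion_ratio",
]

#: Age bands (label, population share). Shares sum to 1.
AGE_GROUPS: tuple[tuple[str, float], ...] = (
    ("0-4", 0.065),
    ("5-14", 0.125),
    ("15-24", 0.130),
    ("25-34", 0.145),
    ("35-44", 0.140),
    ("45-54", 0.130),
    ("55-64", 0.115),
    ("65-74", 0.085),
    ("75+", 0.065),
)

# (height mean cm, height SD cm, BMI median kg·m⁻², log-BMI SD)
_DEFAULT_ANTHROPOMETRY: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("0-4", "male"): (95.0, 8.0, 16.0, 0.10),
    ("0-4", "female"): (94.0, 8.0, 16.0, 0.10),
    ("5-14", "male"): (140.0, 12.0, 18.0, 0.15),
    ("5-14", "female"): (139.0, 12.0, 18.0, 0.15),
    ("15-24", "male"): (177.0, 7.0, 24.0, 0.18),
    ("15-24", "female"): (163.0, 6.5, 23.0, 0.18),
    ("25-34", "male"): (178.0, 7.0, 26.0, 0.18),
    ("25-34", "female"): (164.0, 6.5, 25.0, 0.18),
    ("35-44", "male"): (177.0, 7.0, 27.0, 0.18),
    ("35-44", "female"): (163.0, 6.5, 26.0, 0.18),
    ("45-54", "male"): (176.0, 7.0, 27.5, 0.18),
    ("45-54", "female"): (162.0, 6.5, 26.5, 0.18),
    ("55-64", "male"): (175.0, 7.0, 27.5, 0.18),
    ("55-64", "female"): (161.0, 6.5, 27.0, 0.18),
    ("65-74", "male"): (173.0, 7.0, 27.0, 0.18),
    ("65-74", "female"): (159.0, 6.5, 27.0, 0.18),
    ("75+", "male"): (170.0, 7.0, 26.0, 0.16),
    ("75+", "female"): (157.0, 6.5, 26.0, 0.16),
}

# Occupation shares per stratum (sum to 1 each).  Calibrated so the
# population-weighted male:female weight ratio in outdoor
# moderate-or-heavy cells is 4 under the shipped exposure mapping.
_CHILD_0_4 = {"child_indoor": 0.90, "not_in_labour_force": 0.10}
_CHILD_5_14 = {
    "child_indoor": 0.80,
    "outdoor_play": 0.04,
    "home_duties": 0.06,
    "not_in_labour_force": 0.10,
}
_WORKING_MALE = {
    "construction": 0.10,
    "agriculture": 0.0525,
    "outdoor_trades": 0.08,
    "transport": 0.05,
    "office": 0.19,
    "sales_clerical": 0.12,
    "education_health": 0.08,
    "manufacturing": 0.10,
    "hospitality": 0.05,
    "home_duties": 0.0275,
    "not_in_labour_force": 0.10,
    "student": 0.05,
}
_WORKING_FEMALE = {
    "construction": 0.01,
    "agriculture": 0.02,
    "outdoor_trades": 0.02,
    "transport": 0.02,
    "office": 0.26,
    "sales_clerical": 0.16,
    "education_health": 0.17,
    "manufacturing": 0.05,
    "hospitality": 0.07,
    "home_duties": 0.07,
    "not_in_labour_force": 0.10,
    "student": 0.05,
}
_OLDER_MALE = {
    "retired_home": 0.50,
    "light_activity_indoor": 0.20,
    "gardening_outdoor": 0.05,
    "office": 0.05,
    "not_in_labour_force": 0.20,
}
_OLDER_FEMALE = {
    "retired_home": 0.52,
    "light_activity_indoor": 0.20,
    "gardening_outdoor": 0.02,
    "office": 0.06,
    "not_in_labour_force": 0.20,
}
_ELDERLY = {
    "retired_home": 0.48,
    "light_activity_indoor": 0.15,
    "housework_moderate": 0.10,
    "gardening_outdoor": 0.02,
    "not_in_labour_force": 0.25,
}


def _default_occupation_shares() -> dict[tuple[str, str], dict[str, float]]:
    shares: dict[tuple[str, str], dict[str, float]] = {}
    for label, _ in AGE_GROUPS:
        for sex in ("male", "female"):
            if label == "0-4":
                table = _CHILD_0_4
            elif label == "5-14":
                table = _CHILD_5_14
            elif label in ("15-24", "25-34", "35-44", "45-54", "55-64"):
                table = _WORKING_MALE if sex == "male" else _WORKING_FEMALE
            elif label == "65-74":
                table = _OLDER_MALE if sex == "male" else _OLDER_FEMALE
            else:
                table = _ELDERLY
            shares[(label, sex)] = dict(table)
    return shares


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic generators; the seed fixes everything.

    ``n_per_stratum`` is the number of individuals sampled to tabulate
    each age-sex height-mass distribution.  Weather fields drive a
    summer sinusoid-plus-AR-noise series with heat-spike days that are
    guaranteed to carry the series maximum temperature.
    """

    seed: int = 0
    n_per_stratum: int = 400
    sex_split: float = 0.5
    height_bmi_correlation: float = 0.2
    age_group_shares: tuple[tuple[str, float], ...] = AGE_GROUPS
    anthropometry: dict[tuple[str, str], tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_ANTHROPOMETRY)
    )
    occupation_shares: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=_default_occupation_shares
    )
    outdoor_ratio_target: float = 4.0
    outdoor_ratio_tolerance: float = 0.05
    # weather series
    station: str = "synthetic"
    start_date: str = "2014-01-01"
    n_days: int = 59
    base_temperature: float = 27.0
    seasonal_amplitude: float = 2.0
    temperature_noise_sd: float = 3.0
    spike_days: tuple[int, ...] = (15, 43)
    spike_boost: float = 4.0

    def __post_init__(self) -> None:
        total = sum(s for _, s in self.age_group_shares)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"age group shares sum to {total}, expected 1")
        if not 0.0 < self.sex_split < 1.0:
            raise ValueError("sex_split must be a fraction in (0, 1)")
        for key, (_, h_sd, _, b_sd) in self.anthropometry.items():
            if h_sd <= 0 or b_sd <= 0:
                raise ValueError(f"non-positive SD in anthropometry for {key}")

    def stratum_shares(self) -> dict[tuple[str, str], float]:
        """Population share of each (age group, sex) stratum."""
        out = {}
        for label, share in self.age_group_shares:
            out[(label, "male")] = share * self.sex_split
            out[(label, "female")] = share * (1.0 - self.sex_split)
        return out


def generate_population_table(config: GeneratorConfig) -> pd.DataFrame:
    """Sample a height-mass proportion table per age-sex stratum.

    Heights are Gaussian; mass is BMI × height² with log-normal BMI,
    the two coupled through a Gaussian copula at the configured
    correlation.  Values are rounded to whole cm/kg and tabulated, so
    proportions sum to 1 within each stratum.
    """
    rng = np.random.default_rng(config.seed)
    rho = config.height_bmi_correlation
    if not -1.0 < rho < 1.0:
        raise ValueError(f"height_bmi_correlation {rho} outside (-1, 1)")
    rows = []
    for label, _ in config.age_group_shares:
        for sex in ("male", "female"):
            h_mean, h_sd, bmi_median, bmi_log_sd = config.anthropometry[(label, sex)]
            z_h = rng.standard_normal(config.n_per_stratum)
            z_b = rho * z_h + np.sqrt(1.0 - rho**2) * rng.standard_normal(
                config.n_per_stratum
            )
            heights = np.maximum(np.round(h_mean + h_sd * z_h), 40.0)
            bmi = bmi_median * np.exp(bmi_log_sd * z_b)
            masses = np.maximum(np.round(bmi * (heights / 100.0) ** 2), 3.0)
            counts = (
                pd.DataFrame({"height_cm": heights, "mass_kg": masses})
                .value_counts()
                .sort_index()
            )
            for (h, m), c in counts.items():
                rows.append(
                    {
                        "age_group": label,
                        "sex": sex,
                        "height_cm": h,
                        "mass_kg": m,
                        "proportion": c / config.n_per_stratum,
                    }
                )
    return pd.DataFrame(rows)


def outdoor_exertion_ratio(
    config: GeneratorConfig, mapping: dict[str, dict[str, str]] | None = None
) -> float:
    """Population-weighted male:female weight ratio in outdoor
    moderate-or-heavy exposure cells implied by the occupation shares."""
    if mapping is None:
        mapping = default_exposure_mapping()
    weight = {"male": 0.0, "female": 0.0}
    for label, age_share in config.age_group_shares:
        for sex in ("male", "female"):
            sex_share = config.sex_split if sex == "male" else 1.0 - config.sex_split
            for occ, share in config.occupation_shares[(label, sex)].items():
                entry = mapping[occ]
                if entry["exposure"] == "outdoors" and entry["exertion"] in (
                    "moderate",
                    "heavy",
                ):
                    weight[sex] += age_share * sex_share * share
    if weight["female"] == 0.0:
        raise ValueError("no female outdoor moderate/heavy weight; ratio undefined")
    return weight["male"] / weight["female"]


def generate_occupation_table(
    config: GeneratorConfig, mapping: dict[str, dict[str, str]] | None = None
) -> pd.DataFrame:
    """Emit the occupation share table, checking its calibration.

    The table is deterministic (shares are configuration, not draws).
    Raises if shares do not sum to 1 in some stratum or if the implied
    outdoor moderate/heavy male:female ratio misses the configured
    target by more than the configured relative tolerance.
    """
    for key, table in config.occupation_shares.items():
        total = sum(table.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occupation shares for {key} sum to {total}")
        if any(v < 0 for v in table.values()):
            raise ValueError(f"negative occupation share in {key}")
    ratio = outdoor_exertion_ratio(config, mapping)
    target = config.outdoor_ratio_target
    if abs(ratio - target) > config.outdoor_ratio_tolerance * target:
        raise ValueError(
            f"occupation shares imply outdoor moderate/heavy male:female "
            f"ratio {ratio:.3f}, outside {config.outdoor_ratio_tolerance:.0%} "
            f"of target {target}"
        )
    rows = []
    for label, _ in config.age_group_shares:
        for sex in ("male", "female"):
            for occ, share in sorted(config.occupation_shares[(label, sex)].items()):
                rows.append(
                    {
                        "age_group": label,
                        "sex": sex,
                        "occupation": occ,
                        "proportion": share,
                    }
                )
    return pd.DataFrame(rows)


def generate_weather_series(config: GeneratorConfig) -> pd.DataFrame:
    """Seeded synthetic summer 3 p.m. weather series.

    Temperature is a gentle seasonal sinusoid plus AR(1) noise;
    humidity is anticorrelated with temperature; solar radiation is a
    clear-sky level minus cloudiness tied to humidity.  Days listed in
    ``spike_days`` (0-based indices) are overwritten with heat-wave
    values strictly above the rest of the series, the first spike being
    the overall maximum.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_days
    t = np.arange(n)
    noise = np.empty(n)
    noise[0] = rng.standard_normal()
    for i in range(1, n):  # AR(1), lag correlation 0.6
        noise[i] = 0.6 * noise[i - 1] + 0.8 * rng.standard_normal()
    temp = (
        config.base_temperature
        + config.seasonal_amplitude * np.cos(2.0 * np.pi * t / n)
        + config.temperature_noise_sd * noise
    )
    temp = np.clip(temp, 10.0, 46.0)
    spikes = [d for d in config.spike_days if 0 <= d < n]
    if spikes:
        peak = float(temp.max())
        for rank, day in enumerate(spikes):
            temp[day] = min(peak + config.spike_boost - 0.5 * rank, 47.5)
    humidity = np.clip(
        90.0 - 1.8 * (temp - 15.0) + 8.0 * rng.standard_normal(n), 5.0, 95.0
    )
    solar = np.clip(
        950.0 - 6.0 * humidity + 60.0 * rng.standard_normal(n), 50.0, 1000.0
    )
    start = _date.fromisoformat(config.start_date)
    rows = [
        {
            "date": (start + timedelta(days=int(i))).isoformat(),
            "station": config.station,
            "air_temperature_c": round(float(temp[i]), 1),
            "relative_humidity_pct": round(float(humidity[i]), 0),
            "solar_radiation_wm2": round(float(solar[i]), 0),
        }
        for i in range(n)
    ]
    return pd.DataFrame(rows)
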