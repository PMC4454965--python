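"""Weather input handling.

Reads 3 p.m. station observations (temperature, relative humidity, solar
radiation) from CSV, validates them, and converts a station record into
the conditions an individual actually experiences given their exposure
category: outdoors adds a 2.5 m·s⁻¹ light breeze and the recorded solar
flux, indoors a 0.3 m·s⁻¹ body-movement air speed and no solar load.

Humidity is a percentage in files (station convention) and a fraction
everywhere inside the model; the conversion happens only here.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path

from .heat_balance import WeatherConditions

__all__ = [
    "OUTDOOR_WIND_SPEED",
    "INDOOR_WIND_SPEED",
    "WeatherRecord",
    "WeatherValidationError",
    "read_weather_csv",
    "write_weather_csv",
    "builtin_city_fixtures",
    "sydney_new_year_record",
    "to_exposure_weather",
]

logger = logging.getLogger(__name__)

#: Effective wind speeds by exposure category (m·s⁻¹).
OUTDOOR_WIND_SPEED = 2.5
INDOOR_WIND_SPEED = 0.3

WEATHER_COLUMNS = (
    "date",
    "station",
    "air_temperature_c",
    "relative_humidity_pct",
    "solar_radiation_wm2",
)


@dataclass(frozen=True)
class WeatherRecord:
    """One station-date observation (humidity in %, as published)."""

    date: str
    station: str
    air_temperature_c: float
    relative_humidity_pct: float
    solar_radiation_wm2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_humidity_pct <= 100.0:
            raise ValueError(
                f"relative_humidity_pct {self.relative_humidity_pct} outside [0, 100]"
            )
        if self.solar_radiation_wm2 < 0.0:
            raise ValueError(f"solar_radiation_wm2 {self.solar_radiation_wm2} < 0")


class WeatherValidationError(ValueError):
    """Raised when a weather CSV contains malformed rows.

    ``problems`` lists human-readable messages, each naming the 1-based
    file line of the offending row.
    """

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


def read_weather_csv(path: str | Path) -> list[WeatherRecord]:
    """Read and validate a weather CSV, returning records in date order."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            logger.warning("weather file %s is empty", path)
            return []
        missing = [c for c in WEATHER_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise WeatherValidationError(
                [f"missing required column(s): {', '.join(missing)}"]
            )
        records: list[WeatherRecord] = []
        problems: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    WeatherRecord(
                        date=row["date"],
                        station=row["station"],
                        air_temperature_c=float(row["air_temperature_c"]),
                        relative_humidity_pct=float(row["relative_humidity_pct"]),
                        solar_radiation_wm2=float(row["solar_radiation_wm2"]),
                    )
                )
            except (TypeError, ValueError) as exc:
                problems.append(f"line {lineno}: {exc}")
    if problems:
        raise WeatherValidationError(problems)
    if not records:
        logger.warning("weather file %s contains a header but no rows", path)
    records.sort(key=lambda r: r.date)
    return records


def write_weather_csv(records: list[WeatherRecord], path: str | Path) -> None:
    """Write records in the schema :func:`read_weather_csv` expects."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(WEATHER_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.date,
                    r.station,
                    repr(r.air_temperature_c),
                    repr(r.relative_humidity_pct),
                    repr(r.solar_radiation_wm2),
                ]
            )


def builtin_city_fixtures() -> dict[str, WeatherRecord]:
    """The four January-2014 extreme city-days used as worked examples.

    The most extreme 3 p.m. conditions recorded that month in four
    Australian capitals spanning a latitude (and humidity) gradient.
    """
    return {
        "hobart": WeatherRecord("2014-01-28", "hobart", 36.5, 15.0, 595.0),
        "melbourne": WeatherRecord("2014-01-16", "melbourne", 43.2, 16.0, 600.0),
        "sydney": WeatherRecord("2014-01-29", "sydney", 29.0, 45.0, 713.0),
        "brisbane": WeatherRecord("2014-01-04", "brisbane", 35.5, 47.0, 706.0),
    }


def sydney_new_year_record(solar_radiation_wm2: float = 0.0) -> WeatherRecord:
    """Sydney, 1 January 2014, 3 p.m.: 24.9 °C, 62 % humidity.

    The published conditions for this day do not include a solar flux,
    so it must be supplied by the caller (default 0: indoor-equivalent).
    """
    return WeatherRecord("2014-01-01", "sydney", 24.9, 62.0, solar_radiation_wm2)


def to_exposure_weather(
    record: WeatherRecord, exposure: str, solar_scale: float = 1.0
) -> WeatherConditions:
    """Convert a station record into per-exposure model conditions.

    ``solar_scale`` rescales the recorded solar flux (for sensitivity to
    how a daily radiation estimate maps to the 3 p.m. instantaneous
    flux); it defaults to 1.
    """
    if exposure == "outdoors":
        wind, solar = OUTDOOR_WIND_SPEED, record.solar_radiation_wm2 * solar_scale
    elif exposure == "indoors":
        wind, solar = INDOOR_WIND_SPEED, 0.0
    else:
        raise ValueError(
            f"exposure must be 'indoors' or 'outdoors', got {exposure!r} "
            "(not-exposed person-types are never evaluated against weather)"
        )
    return WeatherConditions(
        air_temperature=record.air_temperature_c,
        relative_humidity=record.relative_humidity_pct / 100.0,
        solar_radiation=solar,
        wind_speed=wind,
    )
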