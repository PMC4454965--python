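"""Risk report and figure output."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = ["write_risk_report", "stacked_bar_figure", "time_series_figure"]

REPORT_COLUMNS = ("age_group", "sex", "cell", "date", "proportion")


def write_risk_report(
    risk_frame: pd.DataFrame,
    out_dir: str | Path,
    seed: int | None = None,
    run_config: dict | None = None,
) -> tuple[Path, Path]:
    """Write the tidy risk CSV and a JSON summary with run metadata.

    The CSV has one row per age group × sex × cell × date (proportions
    written with full precision so a re-read reproduces them exactly).
    The JSON records the seed, a hash of the effective configuration,
    the package version, and per-date peak risk strata.
    """
    if risk_frame.empty:
        raise ValueError("risk frame is empty; nothing to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "risk.csv"
    tidy = risk_frame[list(REPORT_COLUMNS)].copy()
    tidy.to_csv(csv_path, index=False, float_format="%.17g")

    totals = risk_frame[risk_frame["cell"] == "total"]
    peak = (
        totals.loc[totals.groupby("date")["proportion"].idxmax()]
        .set_index("date")[["age_group", "sex", "proportion"]]
        .to_dict("index")
    )
    config_str = json.dumps(run_config or {}, sort_keys=True, default=str)
    summary = {
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(config_str.encode()).hexdigest()[:16],
        "run_config": run_config or {},
        "n_dates": int(totals["date"].nunique()),
        "n_strata": int(totals.groupby(["age_group", "sex"]).ngroups),
        "peak_stratum_by_date": peak,
    }
    json_path = out_dir / "summary.json"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))
    return csv_path, json_path


def _cells(frame: pd.DataFrame) -> list[str]:
    order = [
        "outdoors_heavy",
        "outdoors_moderate",
        "outdoors_rest_minimal",
        "indoors_heavy",
        "indoors_moderate",
        "indoors_rest_minimal",
    ]
    return [c for c in order if c in set(frame["cell"])]


def stacked_bar_figure(risk_frame: pd.DataFrame, path: str | Path) -> Path:
    """Stacked bar chart of at-risk proportion by age-sex stratum,
    divided into exposure × exertion cells, one panel per station-date."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    days = risk_frame[["station", "date"]].drop_duplicates().values.tolist()
    cells = _cells(risk_frame)
    cmap = plt.get_cmap("viridis")
    colors = {c: cmap(i / max(len(cells) - 1, 1)) for i, c in enumerate(cells)}
    fig, axes = plt.subplots(
        len(days), 1, figsize=(10, 3.0 * len(days)), squeeze=False, sharex=True
    )
    for ax, (station, day) in zip(axes[:, 0], days):
        sub = risk_frame[(risk_frame["station"] == station) & (risk_frame["date"] == day)]
        strata = (
            sub[["age_group", "sex"]]
            .drop_duplicates()
            .sort_values(["sex", "age_group"])
            .values.tolist()
        )
        labels = [f"{a}\n{s[0].upper()}" for a, s in strata]
        bottom = [0.0] * len(strata)
        for cell in cells:
            heights = []
            for a, s in strata:
                row = sub[
                    (sub["age_group"] == a) & (sub["sex"] == s) & (sub["cell"] == cell)
                ]
                heights.append(float(row["proportion"].iloc[0]) if len(row) else 0.0)
            ax.bar(labels, heights, bottom=bottom, color=colors[cell], label=cell)
            bottom = [b + h for b, h in zip(bottom, heights)]
        ax.set_title(f"{station} {day}")
        ax.set_ylabel("proportion at risk")
    axes[0, 0].legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def time_series_figure(
    risk_frame: pd.DataFrame, path: str | Path, age_group: str = "75+"
) -> Path:
    """Daily at-risk proportion for one age band, by sex and cell, with
    the driving air temperature on a secondary axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = risk_frame[risk_frame["age_group"] == age_group]
    cells = _cells(sub[sub["proportion"] > 0]) or _cells(sub)
    fig, axes = plt.subplots(2, 1, figsize=(11, 7), sharex=True)
    for ax, sex in zip(axes, ("female", "male")):
        s = sub[sub["sex"] == sex]
        dates = sorted(s["date"].unique())
        bottom = [0.0] * len(dates)
        cmap = plt.get_cmap("viridis")
        for i, cell in enumerate(cells):
            heights = [
                float(
                    s[(s["date"] == d) & (s["cell"] == cell)]["proportion"].iloc[0]
                )
                if len(s[(s["date"] == d) & (s["cell"] == cell)])
                else 0.0
                for d in dates
            ]
            ax.bar(
                range(len(dates)),
                heights,
                bottom=bottom,
                color=cmap(i / max(len(cells) - 1, 1)),
                label=cell,
            )
            bottom = [b + h for b, h in zip(bottom, heights)]
        twin = ax.twinx()
        temps = [
            float(s[s["date"] == d]["air_temperature_c"].iloc[0]) for d in dates
        ]
        twin.plot(range(len(dates)), temps, color="black", lw=1)
        twin.set_ylabel("air temperature (°C)")
        ax.set_title(f"{age_group} {sex}")
        ax.set_ylabel("proportion at risk")
        step = max(len(dates) // 10, 1)
        ax.set_xticks(range(0, len(dates), step))
        ax.set_xticklabels([dates[i] for i in range(0, len(dates), step)], rotation=45)
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
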