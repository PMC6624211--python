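"""Reading, validating and filtering sighting-record tables.

A usable sighting is a live animal reported by a member of the public
with valid coordinates inside the study window.  Cleaning applies, in
order: coordinate/date validation at read time, removal of non-live
records (hospital presentations, dead or euthanised animals), and
removal of same-day same-location repeat reports.  Every exclusion is
counted in a :class:`CleaningReport` that must reconcile to the input
row count.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import StudyWindow
from .synthetic import RECORD_COLUMNS

__all__ = [
    "CleaningReport",
    "read_sightings",
    "filter_live",
    "deduplicate",
    "clean_pipeline",
    "summarize_attributes",
    "reporter_stats",
]

MANDATORY_COLUMNS = ["id", "date", "x", "y", "status"]

#: coordinate rounding used to decide "same location"; 1e-3 km = 1 m
DEFAULT_COORD_PRECISION_KM = 1e-3


@dataclass
class CleaningReport:
    n_input: int = 0
    n_excluded_coords: int = 0
    n_excluded_status: int = 0
    n_excluded_duplicate: int = 0

    @property
    def n_retained(self) -> int:
        return (
            self.n_input
            - self.n_excluded_coords
            - self.n_excluded_status
            - self.n_excluded_duplicate
        )

    def to_json(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["n_retained"] = self.n_retained
        Path(path).write_text(json.dumps(doc, indent=2))


def read_sightings(
    path_or_frame: str | Path | pd.DataFrame,
    window: StudyWindow,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Parse a sighting CSV and flag invalid rows without dropping them.

    Adds two boolean columns: ``coord_valid`` (numeric coordinates
    inside the window) and ``date_valid`` (parseable calendar date).
    Missing mandatory columns raise, naming the first absent column.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame, dtype={"id": str, "reporter_id": str})
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"mandatory column {col!r} missing from sighting table")
    df["x"] = pd.to_numeric(df["x"], errors="coerce")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    parsed = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    df["date"] = parsed.dt.date
    df["date_valid"] = parsed.notna()
    finite = df["x"].notna() & df["y"].notna()
    inside = np.zeros(len(df), dtype=bool)
    if finite.any():
        inside[finite.to_numpy()] = window.contains(
            df.loc[finite, "x"].to_numpy(), df.loc[finite, "y"].to_numpy()
        )
    df["coord_valid"] = finite.to_numpy() & inside
    report = CleaningReport(n_input=len(df))
    return df, report


def drop_invalid(
    records: pd.DataFrame, report: CleaningReport | None = None
) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop rows flagged invalid at read time, counting them."""
    if report is None:
        report = CleaningReport(n_input=len(records))
    bad = ~(records["coord_valid"] & records["date_valid"])
    report.n_excluded_coords += int(bad.sum())
    return records.loc[~bad].copy(), report


def filter_live(
    records: pd.DataFrame, report: CleaningReport | None = None
) -> tuple[pd.DataFrame, CleaningReport]:
    """Keep live sightings only; injured/dead/euthanised records are
    clinical events, not observation effort, and are excluded."""
    if report is None:
        report = CleaningReport(n_input=len(records))
    keep = records["status"] == "alive_sighting"
    report.n_excluded_status += int((~keep).sum())
    return records.loc[keep].copy(), report


def deduplicate(
    records: pd.DataFrame,
    report: CleaningReport | None = None,
    precision_km: float = DEFAULT_COORD_PRECISION_KM,
    multi_animal_column: str = "multi_animal",
) -> tuple[pd.DataFrame, CleaningReport]:
    """Collapse same-day same-location repeat reports to one record.

    Rows sharing (x, y, date) after rounding coordinates to
    ``precision_km`` are taken to be repeat reports of the same animal;
    the row with the lexicographically smallest id is retained.  Rows
    flagged truthy in ``multi_animal_column`` (when present) are exempt
    — they encode deliberate multi-animal sightings at one location.
    """
    if report is None:
        report = CleaningReport(n_input=len(records))
    if records.empty:
        return records.copy(), report
    df = records.copy()
    kx = np.round(df["x"].to_numpy() / precision_km).astype(np.int64)
    ky = np.round(df["y"].to_numpy() / precision_km).astype(np.int64)
    key = pd.DataFrame({"_kx": kx, "_ky": ky, "_kd": df["date"].astype(str).to_numpy()})
    exempt = (
        df[multi_animal_column].fillna(False).astype(bool).to_numpy()
        if multi_animal_column in df.columns
        else np.zeros(len(df), dtype=bool)
    )
    order = np.lexsort((df["id"].astype(str).to_numpy(),))
    rank = np.empty(len(df), dtype=int)
    rank[order] = np.arange(len(df))
    first_rank = key.assign(_r=rank).groupby(["_kx", "_ky", "_kd"])['_r'].transform("min")
    keep = exempt | (rank == first_rank.to_numpy())
    report.n_excluded_duplicate += int((~keep).sum())
    return df.loc[keep].copy(), report


def clean_pipeline(
    path_or_frame: str | Path | pd.DataFrame,
    window: StudyWindow,
    precision_km: float = DEFAULT_COORD_PRECISION_KM,
) -> tuple[pd.DataFrame, CleaningReport]:
    """read -> drop invalid -> live only -> deduplicate, one report."""
    df, report = read_sightings(path_or_frame, window)
    df, report = drop_invalid(df, report)
    df, report = filter_live(df, report)
    df, report = deduplicate(df, report, precision_km=precision_km)
    return df, report


def summarize_attributes(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions by sex, age class and physical location.

    Proportions for age class and physical location are shares of all
    records (unknown is a reported category).  The male/female split is
    additionally reported over sexed records only, mirroring the
    "out of the sexed animals" convention.
    """
    rows = []
    n = len(records)
    for attr in ("sex", "age_class", "physical_location"):
        if attr not in records.columns:
            continue
        counts = records[attr].value_counts()
        for level, count in counts.items():
            rows.append(
                {
                    "attribute": attr,
                    "level": level,
                    "count": int(count),
                    "proportion": count / n if n else np.nan,
                }
            )
        if attr == "sex":
            n_sexed = int(counts.get("male", 0) + counts.get("female", 0))
            for level in ("male", "female"):
                rows.append(
                    {
                        "attribute": "sex_of_sexed",
                        "level": level,
                        "count": int(counts.get(level, 0)),
                        "proportion": counts.get(level, 0) / n_sexed if n_sexed else np.nan,
                    }
                )
    return pd.DataFrame(rows, columns=["attribute", "level", "count", "proportion"])


def reporter_stats(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-year reporter participation.

    Rows without a reporter id are excluded from the statistic and
    counted.  Returns a per-year table (distinct reporters, sightings,
    mean sightings per reporter) and overall means across years.
    """
    has_rep = records["reporter_id"].notna() & (records["reporter_id"].astype(str) != "")
    df = records.loc[has_rep]
    n_missing = int((~has_rep).sum())
    if df.empty:
        return (
            pd.DataFrame(columns=["year", "n_reporters", "n_sightings", "sightings_per_reporter"]),
            {"n_missing_reporter": n_missing, "mean_reporters_per_year": np.nan,
             "mean_sightings_per_reporter": np.nan},
        )
    years = pd.to_datetime(df["date"].astype(str)).dt.year
    per_year = (
        df.assign(year=years)
        .groupby("year")
        .agg(n_reporters=("reporter_id", "nunique"), n_sightings=("id", "size"))
        .reset_index()
    )
    per_year["sightings_per_reporter"] = per_year["n_sightings"] / per_year["n_reporters"]
    overall = {
        "n_missing_reporter": n_missing,
        "mean_reporters_per_year": float(per_year["n_reporters"].mean()),
        "mean_sightings_per_reporter": float(per_year["sightings_per_reporter"].mean()),
        "range_reporters_per_year": (
            int(per_year["n_reporters"].min()),
            int(per_year["n_reporters"].max()),
        ),
    }
    return per_year, overall
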