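"""Measurement tables, plausibility filtering and the monthly age grid.

The in-memory container for anthropometry is a long-format
:class:`pandas.DataFrame` with one row per measurement and columns

    cohort_id, child_id, sex, age_days, length_cm[, laz]

``sex`` is "male"/"female", ``age_days`` a non-negative integer and
``length_cm`` a positive float. All operations in this module take and
return such frames.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig, DEFAULT_CONFIG

__all__ = [
    "AgeBin",
    "three_month_bins",
    "read_measurements",
    "average_duplicate_ages",
    "filter_plausible",
    "month_grid",
]

REQUIRED_COLUMNS = ("cohort_id", "child_id", "sex", "age_days", "length_cm")
_SEX_ALIASES = {
    "male": "male", "m": "male", "1": "male",
    "female": "female", "f": "female", "2": "female",
}


class MissingColumnError(ValueError):
    """A required column is absent from an input table."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"missing required column(s): {', '.join(self.columns)}")


@dataclass(frozen=True)
class AgeBin:
    """Half-open age interval [lower, upper) in months."""

    lower_months: float
    upper_months: float

    def __post_init__(self):
        if not (self.upper_months > self.lower_months >= 0):
            raise ValueError("AgeBin requires upper > lower >= 0")

    def bounds_days(self, month_days: float) -> tuple[float, float]:
        return self.lower_months * month_days, self.upper_months * month_days

    def contains_days(self, age_days, month_days: float):
        lo, hi = self.bounds_days(month_days)
        a = np.asarray(age_days, float)
        return (a >= lo) & (a < hi)

    @property
    def label(self) -> str:
        return f"{self.lower_months:g}-{self.upper_months:g}"


def three_month_bins(max_months: int = 24) -> list[AgeBin]:
    """The standard 3-month incidence bins [0,3), [3,6), ... up to ``max_months``."""
    return [AgeBin(lo, lo + 3) for lo in range(0, max_months, 3)]


def read_measurements(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a long-format anthropometry CSV.

    Returns ``(measurements, parse_errors)``. Rows whose sex, age or length
    cannot be parsed are moved to ``parse_errors`` with a ``reason`` column;
    no plausibility filtering happens here.

    Raises
    ------
    MissingColumnError
        If a required column is absent.
    ValueError
        If the file has no data rows.
    """
    raw = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise MissingColumnError(missing)
    if raw.empty:
        raise ValueError(f"no data rows in {path}")

    df = raw.copy()
    reasons = pd.Series("", index=df.index)

    sex = df["sex"].astype(str).str.strip().str.lower().map(_SEX_ALIASES)
    reasons[sex.isna()] += "unparseable sex;"
    age = pd.to_numeric(df["age_days"], errors="coerce")
    bad_age = age.isna() | (age < 0) | (age != age.round())
    reasons[bad_age] += "unparseable age_days;"
    length = pd.to_numeric(df["length_cm"], errors="coerce")
    reasons[length.isna() | (length <= 0)] += "unparseable length_cm;"

    laz = pd.to_numeric(df["laz"], errors="coerce") if "laz" in df.columns else np.nan

    ok = reasons == ""
    out = pd.DataFrame(
        {
            "cohort_id": df.loc[ok, "cohort_id"],
            "child_id": df.loc[ok, "child_id"],
            "sex": sex[ok],
            "age_days": age[ok].astype(int),
            "length_cm": length[ok].astype(float),
            "laz": laz[ok] if isinstance(laz, pd.Series) else np.nan,
        }
    ).reset_index(drop=True)
    errors = raw.loc[~ok].assign(reason=reasons[~ok].str.rstrip(";")).reset_index(drop=True)
    return out, errors


def average_duplicate_ages(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated records of a child at one age to their mean.

    When a child has several anthropometry records at the same ``age_days``,
    length (and LAZ, if present) are replaced by the arithmetic mean so that
    each (child, age) appears once.
    """
    keys = ["cohort_id", "child_id", "age_days"]
    if not df.duplicated(keys).any():
        return df.copy()
    agg: dict[str, str] = {"sex": "first", "length_cm": "mean"}
    if "laz" in df.columns:
        agg["laz"] = "mean"
    extra = [c for c in df.columns if c not in keys and c not in agg]
    agg.update({c: "first" for c in extra})
    out = df.groupby(keys, as_index=False, sort=True).agg(agg)
    return out[list(df.columns)]


def filter_plausible(
    df: pd.DataFrame, bound: float | None = None, config: AnalysisConfig = DEFAULT_CONFIG
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition measurements into biologically plausible and extreme LAZ.

    Measurements with LAZ strictly beyond ±``bound`` (default 6) are dropped,
    following growth-standard cleaning practice; the boundary value itself is
    kept. Dropped rows are returned with a ``reason`` column for reporting.
    """
    if "laz" not in df.columns or df["laz"].isna().any():
        raise ValueError("filter_plausible requires a fully computed 'laz' column")
    b = config.laz_bound if bound is None else bound
    keep = df["laz"].abs() <= b
    kept = df.loc[keep].reset_index(drop=True)
    dropped = df.loc[~keep].copy()
    dropped["reason"] = np.where(dropped["laz"] > b, f"laz > {b:g}", f"laz < -{b:g}")
    return kept, dropped.reset_index(drop=True)


def month_grid(df: pd.DataFrame, config: AnalysisConfig = DEFAULT_CONFIG,
               max_month: int = 24) -> pd.DataFrame:
    """Assign each child's measurements to a monthly age grid.

    Month 0 ("birth") takes the earliest measurement at age <=
    ``config.birth_window_days``. Each month ``m`` in 1..``max_month`` takes
    the measurement nearest to ``m * month_days`` within
    ±``config.grid_window_days``, the earlier measurement winning ties.
    Months with no qualifying measurement are simply absent (sparse grid).

    Returns a frame with columns cohort_id, child_id, sex, month, age_days,
    length_cm, laz — one row per (child, observed month). Duplicate ages must
    already be averaged. Deterministic and independent of input row order.
    """
    if config.grid_window_days > config.month_days / 2:
        raise ValueError(
            "grid_window_days must not exceed half a month: windows would overlap "
            "and a measurement could populate two months"
        )
    data = df.sort_values(["cohort_id", "child_id", "age_days"], kind="mergesort")
    if data.duplicated(["cohort_id", "child_id", "age_days"]).any():
        raise ValueError("duplicate (child, age_days) rows: run average_duplicate_ages first")

    ages = data["age_days"].to_numpy(float)
    # with the window below half a month, a measurement can only populate its
    # nearest month on the 30.4167-day grid
    month = np.rint(ages / config.month_days).astype(int)
    dist = np.abs(ages - month * config.month_days)
    eligible = (dist <= config.grid_window_days) & (month >= 1) & (month <= max_month)

    cand = data.loc[eligible, ["cohort_id", "child_id", "sex", "age_days", "length_cm", "laz"]]
    cand = cand.assign(month=month[eligible], _dist=dist[eligible])
    # ties (two measurements equidistant from the month age): earlier age wins,
    # via the stable sort on (_dist, age_days)
    cand = (
        cand.sort_values(["cohort_id", "child_id", "month", "_dist", "age_days"], kind="mergesort")
        .drop_duplicates(["cohort_id", "child_id", "month"], keep="first")
        .drop(columns="_dist")
    )

    birth = data.loc[ages <= config.birth_window_days]
    birth = birth.drop_duplicates(["cohort_id", "child_id"], keep="first")  # earliest, data sorted
    birth = birth[["cohort_id", "child_id", "sex", "age_days", "length_cm", "laz"]].assign(month=0)

    out = pd.concat([birth, cand], ignore_index=True)
    out = out.sort_values(["cohort_id", "child_id", "month"], kind="mergesort").reset_index(drop=True)
    return out[["cohort_id", "child_id", "sex", "month", "age_days", "length_cm", "laz"]]
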