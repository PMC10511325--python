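"""Within-child linear growth velocity and comparison with velocity standards.

Velocity over a 3-month interval is the change in length (cm) between the
two endpoint measurements divided by the elapsed time in months — using the
*actual* ages of the endpoint measurements, not the nominal interval bounds,
so schedule jitter does not bias the rate. Endpoints are taken from the
monthly grid, i.e. within a two-week window of each nominal month age. The
same machinery computes LAZ change per month.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .anthro import AgeBin
from .config import AnalysisConfig, DEFAULT_CONFIG

__all__ = [
    "child_velocity",
    "cohort_velocity",
    "VelocityReference",
    "percentile_band",
    "three_month_intervals",
]

_METRIC_COL = {"cm_per_month": "length_cm", "laz_per_month": "laz"}


def three_month_intervals(max_months: int = 24) -> list[AgeBin]:
    return [AgeBin(lo, lo + 3) for lo in range(0, max_months, 3)]


def child_velocity(
    grid: pd.DataFrame,
    interval: AgeBin,
    metric: str = "cm_per_month",
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Per-child velocity over one interval; children missing either
    endpoint measurement are skipped.

    Returns cohort_id, child_id, sex, velocity.
    """
    col = _METRIC_COL[metric]
    lo_m, hi_m = int(interval.lower_months), int(interval.upper_months)
    ends = grid.loc[grid["month"].isin([lo_m, hi_m])]
    wide = ends.pivot_table(
        index=["cohort_id", "child_id", "sex"],
        columns="month",
        values=[col, "age_days"],
    )
    if (col, lo_m) not in wide.columns or (col, hi_m) not in wide.columns:
        return pd.DataFrame(columns=["cohort_id", "child_id", "sex", "velocity"])
    ok = wide[(col, lo_m)].notna() & wide[(col, hi_m)].notna()
    wide = wide.loc[ok]
    d_months = (wide[("age_days", hi_m)] - wide[("age_days", lo_m)]) / config.month_days
    vel = (wide[(col, hi_m)] - wide[(col, lo_m)]) / d_months
    out = vel.rename("velocity").reset_index()
    return out


def cohort_velocity(
    grid: pd.DataFrame,
    intervals: Sequence[AgeBin] | None = None,
    metric: str = "cm_per_month",
    by_sex: bool = True,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Mean velocity per cohort (and sex) for each interval.

    The cohort estimate is the unweighted mean of child velocities; its
    sampling variance is the sample variance divided by n. Cells with no
    eligible children are absent from the output.
    """
    intervals = list(intervals) if intervals is not None else three_month_intervals()
    keys = ["cohort_id", "sex"] if by_sex else ["cohort_id"]
    rows = []
    for iv in intervals:
        per_child = child_velocity(grid, iv, metric=metric, config=config)
        if per_child.empty:
            continue
        for key, sub in per_child.groupby(keys, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            n = len(sub)
            v = sub["velocity"].to_numpy(float)
            rows.append(
                (*key, iv.label, iv.lower_months, iv.upper_months, metric,
                 float(v.mean()), float(v.var(ddof=1) / n) if n > 1 else np.nan, n)
            )
    return pd.DataFrame(
        rows,
        columns=[*keys, "age_interval", "lower_months", "upper_months", "metric",
                 "value", "variance", "n_children"],
    )


@dataclass
class VelocityReference:
    """Percentile table of linear growth velocity (cm/month) by sex and
    3-month age interval, e.g. the WHO growth-velocity standards.

    CSV schema: sex, interval (like "0-3"), percentile (p1/p15/p25/p50/p75),
    cm_per_month. Percentile values must increase within (sex, interval).
    """

    table: pd.DataFrame

    _ORDER = ("p1", "p15", "p25", "p50", "p75")

    def __post_init__(self):
        need = {"sex", "interval", "percentile", "cm_per_month"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"velocity reference missing columns: {sorted(missing)}")
        for (sex, iv), sub in self.table.groupby(["sex", "interval"]):
            vals = sub.set_index("percentile")["cm_per_month"]
            ordered = [vals[p] for p in self._ORDER if p in vals.index]
            if not np.all(np.diff(ordered) > 0):
                raise ValueError(f"percentile values not increasing for {sex} {iv}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "VelocityReference":
        return cls(pd.read_csv(path))

    @classmethod
    def synthetic(cls) -> "VelocityReference":
        """Packaged synthetic percentile table used by tests and examples."""
        p = resources.files("growthfalter.data").joinpath("velocity_reference_synthetic.csv")
        with p.open() as fh:
            return cls(pd.read_csv(fh))

    def percentiles(self, sex: str, interval: str) -> pd.Series:
        sub = self.table[(self.table["sex"] == sex) & (self.table["interval"] == interval)]
        if sub.empty:
            raise KeyError(f"no velocity reference rows for sex={sex!r} interval={interval!r}")
        vals = sub.set_index("percentile")["cm_per_month"]
        return vals.reindex([p for p in self._ORDER if p in vals.index])


def percentile_band(value: float, sex: str, interval: str, ref: VelocityReference) -> str:
    """Locate a velocity against reference percentiles.

    Bands are left-closed: a value exactly at a tabulated percentile falls in
    the band starting there. Returns e.g. "below p1", "between p25 and p50",
    or "at or above p75".
    """
    pct = ref.percentiles(sex, interval)
    names, cuts = list(pct.index), pct.to_numpy(float)
    if value < cuts[0]:
        return f"below {names[0]}"
    for i in range(len(cuts) - 1):
        if cuts[i] <= value < cuts[i + 1]:
            return f"between {names[i]} and {names[i + 1]}"
    return f"at or above {names[-1]}"
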