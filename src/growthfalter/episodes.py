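"""Incident stunting episodes and month-by-month stunting-status dynamics.

Stunting is LAZ < -2 (severe: LAZ < -3; any cutoff may be passed). A child
contributes an incident episode

* at birth, when the birth measurement is already below the cutoff
  (children are considered at risk from birth);
* at every observed crossing from at-or-above to below the cutoff;
* at study entry, when the first measurement is post-birth and already
  below the cutoff — onset is then imputed at the age halfway between
  birth and that first measurement.

Status classification at each observed month of the monthly grid uses six
mutually exclusive categories that encode both the current state and the
child's history:

=================  ==========================================================
never_stunted      LAZ >= -2 at the current and every previous age
newly_stunted      LAZ < -2 now, never below -2 before
still_stunted      LAZ < -2 at the previous and current age
stunting_reversal  LAZ < -2 at the previous age, >= -2 now
stunting_relapse   previously stunted, LAZ >= -2 at the previous age,
                   < -2 now
no_longer_stunted  previously reversed, LAZ >= -2 now (and at previous age)
=================  ==========================================================

"Previous age" is the most recent *observed* prior month, so sparse grids
are handled without imputation.
"""
from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .anthro import AgeBin, three_month_bins
from .config import AnalysisConfig, DEFAULT_CONFIG

__all__ = [
    "STATUS_CATEGORIES",
    "detect_incident_episodes",
    "first_onsets",
    "incidence_proportion",
    "classify_status",
    "status_proportions",
    "ever_and_current_stunting",
    "stratify_by_birth_laz",
    "post_reversal_laz",
]

STATUS_CATEGORIES = (
    "never_stunted",
    "newly_stunted",
    "still_stunted",
    "stunting_reversal",
    "stunting_relapse",
    "no_longer_stunted",
)

_CURRENTLY_STUNTED = ("newly_stunted", "still_stunted", "stunting_relapse")
_REVERSED_NOT_STUNTED = ("stunting_reversal", "no_longer_stunted")


def detect_incident_episodes(
    df: pd.DataFrame,
    cutoff: float = -2.0,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Find every incident episode (onset) for each child.

    Parameters
    ----------
    df:
        Measurement-level frame (cohort_id, child_id, age_days, laz), one row
        per (child, age); duplicate ages already averaged.
    cutoff:
        z-score threshold; -2 for stunting, -3 for severe stunting.

    Returns
    -------
    DataFrame with columns cohort_id, child_id, onset_age_days, onset_kind
    (at_birth / observed_crossing / imputed_at_entry), one row per episode in
    chronological order. Children with no episode contribute no rows.
    """
    if df.empty:
        return pd.DataFrame(columns=["cohort_id", "child_id", "onset_age_days", "onset_kind"])
    d = df.sort_values(["cohort_id", "child_id", "age_days"], kind="mergesort")
    grp = d.groupby(["cohort_id", "child_id"], sort=False)
    laz = d["laz"].to_numpy(float)
    age = d["age_days"].to_numpy(float)
    stunted = laz < cutoff
    is_first = ~d.duplicated(["cohort_id", "child_id"]).to_numpy()
    prev_stunted = np.roll(stunted, 1)

    onset = np.full(len(d), np.nan)
    kind = np.full(len(d), "", dtype=object)

    born_stunted = is_first & stunted & (age <= config.birth_window_days)
    onset[born_stunted] = 0.0
    kind[born_stunted] = "at_birth"

    entry_stunted = is_first & stunted & (age > config.birth_window_days)
    onset[entry_stunted] = age[entry_stunted] / 2.0
    kind[entry_stunted] = "imputed_at_entry"

    crossing = ~is_first & stunted & ~prev_stunted
    onset[crossing] = age[crossing]
    kind[crossing] = "observed_crossing"

    hit = kind != ""
    out = d.loc[hit, ["cohort_id", "child_id"]].copy()
    out["onset_age_days"] = onset[hit]
    out["onset_kind"] = kind[hit]
    return out.reset_index(drop=True)


def first_onsets(episodes: pd.DataFrame) -> pd.DataFrame:
    """First (incident) onset per child: cohort_id, child_id, onset_age_days, onset_kind."""
    if episodes.empty:
        return episodes.copy()
    return (
        episodes.sort_values(["cohort_id", "child_id", "onset_age_days"], kind="mergesort")
        .drop_duplicates(["cohort_id", "child_id"], keep="first")
        .reset_index(drop=True)
    )


def incidence_proportion(
    df: pd.DataFrame,
    bins: Sequence[AgeBin] | None = None,
    cutoff: float = -2.0,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Per-cohort incidence proportion of first stunting onset by age bin.

    For each half-open age bin, the denominator is the number of children at
    risk: never stunted before the bin starts and under observation in the
    bin (a measurement inside the bin, or an imputed onset falling in it).
    The numerator counts children whose first onset falls inside the bin.
    The sampling variance is binomial, p(1-p)/n.

    Returns one row per (cohort, bin): cohort_id, age_bin, lower_months,
    upper_months, n_at_risk, n_incident, proportion, variance. Bins with
    nobody at risk carry NaN proportion and are flagged ``degenerate``.
    """
    bins = list(bins) if bins is not None else three_month_bins()
    eps = first_onsets(detect_incident_episodes(df, cutoff=cutoff, config=config))
    children = df[["cohort_id", "child_id"]].drop_duplicates()
    merged = children.merge(eps, on=["cohort_id", "child_id"], how="left")
    onset = merged["onset_age_days"].to_numpy(float)
    age = df["age_days"].to_numpy(float)

    rows = []
    for b in bins:
        lo, hi = b.bounds_days(config.month_days)
        in_bin = df.loc[(age >= lo) & (age < hi), ["cohort_id", "child_id"]].drop_duplicates()
        observed = pd.MultiIndex.from_frame(merged[["cohort_id", "child_id"]]).isin(
            pd.MultiIndex.from_frame(in_bin))
        onset_in_bin = ~np.isnan(onset) & (onset >= lo) & (onset < hi)
        at_risk = (np.isnan(onset) | (onset >= lo)) & (observed | onset_in_bin)
        tab = merged.assign(_risk=at_risk, _inc=onset_in_bin & at_risk).groupby(
            "cohort_id", sort=True)[["_risk", "_inc"]].sum()
        for cohort, (n_risk, n_inc) in tab.iterrows():
            n_risk, n_inc = int(n_risk), int(n_inc)
            if n_risk:
                p = n_inc / n_risk
                rows.append((cohort, b.label, b.lower_months, b.upper_months,
                             n_risk, n_inc, p, p * (1 - p) / n_risk, False))
            else:
                rows.append((cohort, b.label, b.lower_months, b.upper_months,
                             0, 0, np.nan, np.nan, True))
    out = pd.DataFrame(
        rows,
        columns=["cohort_id", "age_bin", "lower_months", "upper_months",
                 "n_at_risk", "n_incident", "proportion", "variance", "degenerate"],
    )
    return out.sort_values(["cohort_id", "lower_months"], kind="mergesort").reset_index(drop=True)


def classify_status(
    grid: pd.DataFrame,
    months: Iterable[int] = range(0, 16),
    cutoff: float = -2.0,
) -> pd.DataFrame:
    """Classify each child's stunting status at every observed grid month.

    ``grid`` is a monthly-grid frame (from :func:`growthfalter.anthro.month_grid`);
    the analysis is intended for cohorts measured at least monthly. Returns
    cohort_id, child_id, month, laz, status.
    """
    months = set(months)
    d = grid.loc[grid["month"].isin(months)].sort_values(
        ["cohort_id", "child_id", "month"], kind="mergesort"
    )
    if d.empty:
        return pd.DataFrame(columns=["cohort_id", "child_id", "month", "laz", "status"])
    key = d["cohort_id"].astype(str) + "\x00" + d["child_id"].astype(str)
    stunted = (d["laz"] < cutoff).to_numpy()
    is_first = (~key.duplicated()).to_numpy()
    prev_stunted = np.roll(stunted, 1)
    prev_stunted[is_first] = False
    # any stunted month strictly before the current one, within each child
    ever_before = np.roll(pd.Series(stunted).groupby(key.to_numpy()).cummax().to_numpy(), 1)
    ever_before[is_first] = False

    status = np.empty(len(d), dtype=object)
    status[stunted & prev_stunted] = "still_stunted"
    status[stunted & ~prev_stunted & ever_before] = "stunting_relapse"
    status[stunted & ~prev_stunted & ~ever_before] = "newly_stunted"
    status[~stunted & prev_stunted] = "stunting_reversal"
    status[~stunted & ~prev_stunted & ever_before] = "no_longer_stunted"
    status[~stunted & ~prev_stunted & ~ever_before] = "never_stunted"

    out = d[["cohort_id", "child_id", "month", "laz"]].copy()
    out["status"] = status
    return out.reset_index(drop=True)


def status_proportions(status_df: pd.DataFrame, by: Sequence[str] = ()) -> pd.DataFrame:
    """Proportion of children in each of the six categories per month.

    Simple aggregation over all children observed at each month (not pooled
    across cohorts), so the six proportions sum to one. Extra grouping
    columns (e.g. region) may be passed via ``by``.
    """
    keys = [*by, "month"]
    counts = (
        status_df.groupby([*keys, "status"], sort=True).size().unstack("status", fill_value=0)
    )
    for c in STATUS_CATEGORIES:
        if c not in counts.columns:
            counts[c] = 0
    counts = counts[list(STATUS_CATEGORIES)]
    props = counts.div(counts.sum(axis=1), axis=0)
    props["n_children"] = counts.sum(axis=1)
    return props.reset_index()


def ever_and_current_stunting(status_df: pd.DataFrame) -> pd.DataFrame:
    """Per-month proportions currently stunted, ever stunted, and reversed-
    and-not-currently-stunted.

    The six categories encode history, so at any month: *ever stunted* is
    everyone not ``never_stunted``; *currently stunted* is newly/still/
    relapse; *reversed and not stunted* is reversal/no_longer (= ever -
    current).
    """
    s = status_df
    def _agg(sub: pd.DataFrame) -> pd.Series:
        n = len(sub)
        cur = sub["status"].isin(_CURRENTLY_STUNTED).sum() / n
        ever = (sub["status"] != "never_stunted").sum() / n
        rev = sub["status"].isin(_REVERSED_NOT_STUNTED).sum() / n
        return pd.Series({"current": cur, "ever": ever, "reversed_not_stunted": rev,
                          "n_children": n})
    out = s.groupby("month", sort=True).apply(_agg, include_groups=False).reset_index()
    out["n_children"] = out["n_children"].astype(int)
    return out


def stratify_by_birth_laz(df: pd.DataFrame, max_age_days: float = 30.0) -> pd.DataFrame:
    """Assign each child a birth-LAZ stratum from the first measurement
    before 30 days of age: below -2, -2 to 0, or at least 0.

    Children without a measurement before ``max_age_days`` are excluded.
    Returns cohort_id, child_id, birth_laz, birth_stratum.
    """
    early = df.loc[df["age_days"] < max_age_days]
    first = (
        early.sort_values(["cohort_id", "child_id", "age_days"], kind="mergesort")
        .drop_duplicates(["cohort_id", "child_id"], keep="first")
    )
    laz = first["laz"].to_numpy(float)
    stratum = np.where(laz < -2, "<-2", np.where(laz < 0, "-2 to 0", ">=0"))
    out = first[["cohort_id", "child_id"]].copy()
    out["birth_laz"] = laz
    out["birth_stratum"] = stratum
    return out.reset_index(drop=True)


def post_reversal_laz(
    grid: pd.DataFrame,
    reversal_ages: Sequence[int] = (3, 6, 9, 12),
    followup_ages: Sequence[int] = (6, 9, 12, 15),
    cutoff: float = -2.0,
) -> pd.DataFrame:
    """Within-child LAZ change after stunting reversal.

    For children whose status at month ``r`` (in ``reversal_ages``) is
    ``stunting_reversal``, compute LAZ(f) - LAZ(r) at each later follow-up
    month ``f`` and summarise per cohort: mean difference, sampling variance
    of the mean, and n. Cells with no eligible children are absent.
    """
    status = classify_status(grid, months=range(0, max(followup_ages) + 1), cutoff=cutoff)
    laz_wide = status.pivot_table(
        index=["cohort_id", "child_id"], columns="month", values="laz"
    )
    stat_wide = status.pivot(
        index=["cohort_id", "child_id"], columns="month", values="status"
    )
    rows = []
    for r in reversal_ages:
        if r not in stat_wide.columns:
            continue
        reversers = stat_wide[r] == "stunting_reversal"
        for f in followup_ages:
            if f <= r or f not in laz_wide.columns:
                continue
            diff = (laz_wide.loc[reversers, f] - laz_wide.loc[reversers, r]).dropna()
            for cohort, vals in diff.groupby(level="cohort_id"):
                n = len(vals)
                mean = float(vals.mean())
                var = float(vals.var(ddof=1) / n) if n > 1 else np.nan
                rows.append((cohort, r, f, n, mean, var))
    return pd.DataFrame(
        rows,
        columns=["cohort_id", "reversal_month", "followup_month", "n", "mean_diff", "variance"],
    )
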