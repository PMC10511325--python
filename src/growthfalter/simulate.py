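"""Seeded multi-cohort longitudinal anthropometry generator with ground truth.

The generator emulates the statistical structure of a pooled multi-country
infant growth study: 21 cohorts measured monthly and 11 measured quarterly,
region-shifted birth-LAZ distributions (South Asia lowest), a population
mean LAZ that declines by about 0.5 z from birth to 15 months, within-child
AR(1) autocorrelation, cohort- and child-level random effects, measurement
error, and non-informative missingness. Every child's latent (noise-free)
monthly LAZ path is retained as ground truth, together with the implied
first stunting onset and six-category status sequence, so pipeline
estimates can be checked against generator truth.

The latent model on the monthly grid m = 0..24 is

    LAZ*_cjm = mu_region(m) + b_cohort(c) + b_child(j) + a_jm
    mu_region(m) = birth_mean_region + drift * min(m, 15) / 15
    a_jm AR(1): stationary SD ``ar1_sd``, lag-1 correlation ``ar1_rho``

and observations are LAZ*_cjm + N(0, measurement_error_sd) at scheduled
visits, converted to length (cm) through the packaged LMS reference.

A second, deliberately minimal generator (`simulate_constant_hazard`)
produces cohorts in which stunting onset is an absorbing event with a known
constant monthly hazard, so 3-month-bin incidence has the closed form
1 - (1-h)^3 for calibration checks.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import MONTH_DAYS
from .lms import LMSReference, load_synthetic_reference

__all__ = ["GeneratorConfig", "Truth", "simulate", "truth_summaries",
           "simulate_constant_hazard"]

#: region -> mean birth LAZ; South Asia lowest, consistent with the
#: qualitative regional ordering of multi-country growth studies. Together
#: with a birth SD of 1.0 these give ~13% stunting at birth overall.
DEFAULT_REGION_MEANS: Mapping[str, float] = {
    "South Asia": -1.10,
    "Africa": -0.75,
    "Latin America": -0.55,
}
_REGION_CYCLE = ("South Asia", "Africa", "South Asia", "Latin America")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study design and distributional parameters of the generator.

    Defaults describe the emulated study: 21 monthly + 11 quarterly cohorts,
    a 0.5 z decline in mean LAZ from birth to month 15, birth LAZ SD of 1 z
    (child effect 0.8 + AR component 0.6 in quadrature), measurement error
    0.3 z, 10% missed visits.
    """

    monthly_cohorts: int = 21
    quarterly_cohorts: int = 11
    children_per_cohort: int = 150
    region_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_MEANS))
    drift_to_15m: float = -0.5       # z change in mean LAZ, birth -> month 15
    ar1_rho: float = 0.9             # lag-1 autocorrelation of monthly residual
    ar1_sd: float = 0.6              # stationary SD of the AR(1) component (z)
    child_effect_sd: float = 0.8     # between-child SD (z)
    cohort_effect_sd: float = 0.25   # between-cohort SD (z)
    measurement_error_sd: float = 0.3  # independent error per measurement (z)
    missingness_rate: float = 0.10   # per-visit Bernoulli miss probability
    post_reversal_drift: float = 0.0  # extra z/month applied after a reversal
    age_jitter_days: float = 3.0     # uniform jitter of visit ages
    max_month: int = 24
    seed: int = 0

    def __post_init__(self):
        bad = (
            min(self.ar1_sd, self.child_effect_sd, self.cohort_effect_sd,
                self.measurement_error_sd) < 0
            or not (0 <= self.ar1_rho < 1)
            or not (0 <= self.missingness_rate <= 1)
            or self.monthly_cohorts < 0 or self.quarterly_cohorts < 0
            or self.monthly_cohorts + self.quarterly_cohorts < 1
            or self.children_per_cohort < 1 or self.max_month < 1
            or self.age_jitter_days < 0
        )
        if bad:
            raise ValueError("invalid generator configuration")


@dataclass(frozen=True)
class Truth:
    """Ground truth of one simulated study."""

    cohorts: pd.DataFrame   # cohort_id, region, schedule, cohort_effect
    children: pd.DataFrame  # cohort_id, child_id, sex, region, child_effect
    latent: pd.DataFrame    # cohort_id, child_id, month, laz_latent, status, stunted
    onsets: pd.DataFrame    # cohort_id, child_id, first_onset_month (NaN if never)


def _nominal_age_days(month: np.ndarray) -> np.ndarray:
    # ceil keeps month m inside the 3-month bin that contains m months
    return np.ceil(month * MONTH_DAYS).astype(int)


def _status_from_path(stunted_path: np.ndarray) -> list[str]:
    """Six-category status sequence for one fully observed monthly path."""
    out = []
    ever = False
    for m, s in enumerate(stunted_path):
        prev = stunted_path[m - 1] if m > 0 else False
        if s and prev:
            out.append("still_stunted")
        elif s and ever:
            out.append("stunting_relapse")
        elif s:
            out.append("newly_stunted")
        elif prev:
            out.append("stunting_reversal")
        elif ever:
            out.append("no_longer_stunted")
        else:
            out.append("never_stunted")
        ever = ever or s
    return out


def simulate(
    config: GeneratorConfig = GeneratorConfig(),
    seed: int | None = None,
    lms: LMSReference | None = None,
) -> tuple[pd.DataFrame, Truth]:
    """Draw one study: (measurement table, ground truth).

    The measurement table is long-format (cohort_id, child_id, sex,
    age_days, length_cm, laz) as the pipeline expects. Fully reproducible:
    the same config and seed give identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    ref = lms if lms is not None else load_synthetic_reference()

    n_coh = cfg.monthly_cohorts + cfg.quarterly_cohorts
    n_child = cfg.children_per_cohort
    n_total = n_coh * n_child
    months = np.arange(cfg.max_month + 1)
    n_m = months.size

    regions = [_REGION_CYCLE[i % len(_REGION_CYCLE)] for i in range(n_coh)]
    regions = [r if r in cfg.region_means else list(cfg.region_means)[0] for r in regions]
    schedule = ["monthly"] * cfg.monthly_cohorts + ["quarterly"] * cfg.quarterly_cohorts
    cohort_ids = [f"C{i + 1:02d}" for i in range(n_coh)]
    b_cohort = rng.normal(0.0, cfg.cohort_effect_sd, n_coh)

    # per-child structure, cohort-major ordering
    coh_idx = np.repeat(np.arange(n_coh), n_child)
    child_ids = np.array([f"{cohort_ids[c]}-{j + 1:04d}"
                          for c in range(n_coh) for j in range(n_child)])
    sex = np.where(rng.random(n_total) < 0.5, "male", "female")
    b_child = rng.normal(0.0, cfg.child_effect_sd, n_total)

    # latent AR(1) residual on the monthly grid
    a = np.empty((n_total, n_m))
    a[:, 0] = rng.normal(0.0, cfg.ar1_sd, n_total)
    innov_sd = cfg.ar1_sd * math.sqrt(1.0 - cfg.ar1_rho**2)
    for m in range(1, n_m):
        a[:, m] = cfg.ar1_rho * a[:, m - 1] + rng.normal(0.0, innov_sd, n_total)

    region_mean = np.array([cfg.region_means[regions[c]] for c in coh_idx])
    mu = region_mean[:, None] + cfg.drift_to_15m * np.minimum(months, 15)[None, :] / 15.0
    latent = mu + b_cohort[coh_idx][:, None] + b_child[:, None] + a

    stunted = latent < -2.0
    if cfg.post_reversal_drift != 0.0:
        # after the first latent reversal, add a linear drift to the path
        for i in range(n_total):
            below = np.nonzero(stunted[i])[0]
            if below.size == 0:
                continue
            after = np.nonzero(~stunted[i] & (months > below[0]))[0]
            if after.size:
                r = after[0]
                latent[i, r + 1:] += cfg.post_reversal_drift * (months[r + 1:] - months[r])
        stunted = latent < -2.0

    # truth: onset and status from the latent path
    first_onset = np.where(stunted.any(axis=1), stunted.argmax(axis=1), np.nan)
    statuses = [_status_from_path(stunted[i]) for i in range(n_total)]

    # observation schedule and measurement process
    visit_step = np.where(np.array(schedule)[coh_idx] == "monthly", 1, 3)
    obs_mask = (months[None, :] % visit_step[:, None]) == 0
    obs_mask &= rng.random((n_total, n_m)) >= cfg.missingness_rate

    rows_i, rows_m = np.nonzero(obs_mask)
    month_obs = months[rows_m]
    nominal = _nominal_age_days(month_obs)
    if cfg.age_jitter_days > 0:
        jitter = rng.integers(-int(cfg.age_jitter_days), int(cfg.age_jitter_days) + 1,
                              rows_i.size)
        jitter[month_obs == 0] = 0  # birth visits stay in the first week
        age_days = np.maximum(nominal + jitter, 0)
    else:
        age_days = nominal
    laz_obs = latent[rows_i, rows_m] + rng.normal(0.0, cfg.measurement_error_sd, rows_i.size)

    length = np.empty(rows_i.size)
    for s in ("male", "female"):
        m = sex[rows_i] == s
        if m.any():
            length[m] = np.asarray(ref.length(laz_obs[m], age_days[m], s))

    measurements = pd.DataFrame({
        "cohort_id": np.array(cohort_ids)[coh_idx[rows_i]],
        "child_id": child_ids[rows_i],
        "sex": sex[rows_i],
        "age_days": age_days,
        "length_cm": np.round(length, 4),
        "laz": laz_obs,
    })

    truth = Truth(
        cohorts=pd.DataFrame({
            "cohort_id": cohort_ids, "region": regions, "schedule": schedule,
            "cohort_effect": b_cohort,
        }),
        children=pd.DataFrame({
            "cohort_id": np.array(cohort_ids)[coh_idx], "child_id": child_ids,
            "sex": sex, "region": np.array(regions)[coh_idx], "child_effect": b_child,
        }),
        latent=pd.DataFrame({
            "cohort_id": np.repeat(np.array(cohort_ids)[coh_idx], n_m),
            "child_id": np.repeat(child_ids, n_m),
            "month": np.tile(months, n_total),
            "laz_latent": latent.ravel(),
            "stunted": stunted.ravel(),
            "status": np.concatenate(statuses),
        }),
        onsets=pd.DataFrame({
            "cohort_id": np.array(cohort_ids)[coh_idx], "child_id": child_ids,
            "first_onset_month": first_onset,
        }),
    )
    return measurements, truth


def truth_summaries(truth: Truth, bin_months: int = 3) -> dict[str, pd.DataFrame]:
    """Generator-implied true incidence, status and prevalence tables.

    Derived directly from the latent paths: true per-bin incidence
    proportions (among children not yet stunted at the bin start), true
    six-category status proportions per month, and true ever/current
    stunting per month. These are the targets for recovery tests.
    """
    latent = truth.latent
    onset = truth.onsets["first_onset_month"].to_numpy(float)
    max_month = int(latent["month"].max())

    rows = []
    for lo in range(0, max_month, bin_months):
        hi = lo + bin_months
        at_risk = np.isnan(onset) | (onset >= lo)
        incident = (~np.isnan(onset)) & (onset >= lo) & (onset < hi)
        n_risk = int(at_risk.sum())
        rows.append((f"{lo}-{hi}", lo, hi, n_risk, int(incident.sum()),
                     incident.sum() / n_risk if n_risk else np.nan))
    incidence = pd.DataFrame(
        rows, columns=["age_bin", "lower_months", "upper_months",
                       "n_at_risk", "n_incident", "proportion"])

    counts = latent.groupby(["month", "status"]).size().unstack(fill_value=0)
    status_props = counts.div(counts.sum(axis=1), axis=0).reset_index()

    cur = latent["status"].isin(("newly_stunted", "still_stunted", "stunting_relapse"))
    ever = latent["status"] != "never_stunted"
    prev = latent.assign(current=cur, ever=ever).groupby("month")[["current", "ever"]].mean()

    return {"incidence": incidence, "status_proportions": status_props,
            "prevalence": prev.reset_index()}


def simulate_constant_hazard(
    hazard: float,
    n_cohorts: int = 5,
    children_per_cohort: int = 1000,
    max_month: int = 24,
    seed: int = 0,
    lms: LMSReference | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohorts where stunting onset is absorbing with constant monthly hazard.

    Every child is observed monthly at the nominal grid ages with no noise:
    LAZ is -1 before onset and -2.5 from the onset month on. Onset may occur
    at any month including birth, so the true incidence proportion in any
    3-month bin is 1 - (1 - hazard)^3. Returns (measurements, onset truth).
    """
    if not (0 <= hazard < 1):
        raise ValueError("hazard must be in [0, 1)")
    rng = np.random.default_rng(seed)
    ref = lms if lms is not None else load_synthetic_reference()
    n_total = n_cohorts * children_per_cohort
    months = np.arange(max_month + 1)

    onset_draws = rng.random((n_total, months.size)) < hazard
    has = onset_draws.any(axis=1)
    onset = np.where(has, onset_draws.argmax(axis=1), np.nan)

    stunted = months[None, :] >= np.where(np.isnan(onset), np.inf, onset)[:, None]
    laz = np.where(stunted, -2.5, -1.0)

    coh = np.repeat([f"H{i + 1:02d}" for i in range(n_cohorts)], children_per_cohort)
    child = np.array([f"{c}-{j:04d}" for c, j in zip(coh, np.tile(
        np.arange(children_per_cohort), n_cohorts))])
    sex = np.where(np.arange(n_total) % 2 == 0, "male", "female")

    rows_i = np.repeat(np.arange(n_total), months.size)
    rows_m = np.tile(months, n_total)
    age_days = _nominal_age_days(rows_m)
    laz_flat = laz[rows_i, rows_m]
    length = np.empty(rows_i.size)
    for s in ("male", "female"):
        m = sex[rows_i] == s
        length[m] = np.asarray(ref.length(laz_flat[m], age_days[m], s))

    measurements = pd.DataFrame({
        "cohort_id": coh[rows_i], "child_id": child[rows_i], "sex": sex[rows_i],
        "age_days": age_days, "length_cm": np.round(length, 4), "laz": laz_flat,
    })
    onset_truth = pd.DataFrame({
        "cohort_id": coh, "child_id": child, "first_onset_month": onset,
    })
    return measurements, onset_truth
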