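"""Incident-episode detection and the six-category status state machine."""
import itertools

import numpy as np
import pandas as pd
import pytest

import growthfalter as gf
from growthfalter import MONTH_DAYS

from conftest import make_child, make_grid


# ------------------------------------------------------------------ oracle

def oracle_status(seq):
    """Brute-force classification of a stunted/not-stunted month sequence,
    each category written as a literal predicate on the history; asserts the
    six categories are mutually exclusive and exhaustive at every month."""
    out = []
    for m, cur in enumerate(seq):
        prior = seq[:m]
        prev = prior[-1] if prior else False
        ever = any(prior)
        hits = {
            "never_stunted": not cur and not ever,
            "newly_stunted": cur and not ever,
            "still_stunted": cur and prev,
            "stunting_relapse": cur and ever and not prev,
            "stunting_reversal": not cur and prev,
            "no_longer_stunted": not cur and ever and not prev,
        }
        assert sum(hits.values()) == 1
        out.append(next(k for k, v in hits.items() if v))
    return out


def oracle_onset_months(seq):
    """Months at which an incident episode starts (birth or re-crossing)."""
    return [m for m, s in enumerate(seq) if s and (m == 0 or not seq[m - 1])]


def all_binary_sequences(max_len=6):
    for n in range(1, max_len + 1):
        yield from itertools.product([False, True], repeat=n)


# --------------------------------------------------------- episode detection

class TestDetectEpisodes:
    def test_born_stunted_is_incident_at_birth(self):
        df = make_child({0: -2.5})
        eps = gf.detect_incident_episodes(df)
        assert len(eps) == 1
        assert eps.loc[0, "onset_kind"] == "at_birth"
        assert eps.loc[0, "onset_age_days"] == 0

    def test_two_crossings_give_two_episodes(self):
        ages = {int(np.ceil(m * MONTH_DAYS)): z
                for m, z in zip([1, 2, 3, 4], [-1.5, -2.3, -1.8, -2.1])}
        eps = gf.detect_incident_episodes(make_child(ages))
        # onset at the below-cutoff measurement of months 2 and 4
        assert len(eps) == 2
        assert eps["onset_kind"].tolist() == ["observed_crossing"] * 2
        assert eps["onset_age_days"].tolist() == [
            np.ceil(2 * MONTH_DAYS), np.ceil(4 * MONTH_DAYS)]

    def test_late_entry_onset_imputed_at_midpoint(self):
        eps = gf.detect_incident_episodes(make_child({60: -2.4}))
        assert eps.loc[0, "onset_kind"] == "imputed_at_entry"
        assert eps.loc[0, "onset_age_days"] == pytest.approx(30.0)

    def test_empty_input_empty_output(self):
        eps = gf.detect_incident_episodes(make_child({}).iloc[0:0])
        assert eps.empty

    def test_onset_count_matches_oracle_on_all_sequences(self):
        for seq in all_binary_sequences():
            laz = {int(np.ceil(m * MONTH_DAYS)): (-2.5 if s else -1.5)
                   for m, s in enumerate(seq)}
            eps = gf.detect_incident_episodes(make_child(laz))
            assert len(eps) == len(oracle_onset_months(seq)), seq


# ----------------------------------------------------------- classification

class TestClassifyStatus:
    def test_never_stunted_throughout(self):
        grid = make_grid({m: -1.0 for m in range(6)})
        st = gf.classify_status(grid)
        assert (st["status"] == "never_stunted").all()

    def test_never_newly_reversal_relapse_sequence(self):
        grid = make_grid(dict(enumerate([-1.5, -2.3, -1.8, -2.2])))
        st = gf.classify_status(grid)
        assert st["status"].tolist() == [
            "never_stunted", "newly_stunted", "stunting_reversal", "stunting_relapse"]

    def test_boundary_minus_two_is_not_stunted(self):
        st = gf.classify_status(make_grid({0: -2.0, 1: -2.0}))
        assert (st["status"] == "never_stunted").all()

    def test_matches_enumeration_oracle_exactly(self):
        """State machine equals the brute-force reference on every
        stunted/not-stunted sequence of length <= 6 (126 cases)."""
        frames, expected = [], []
        for i, seq in enumerate(all_binary_sequences()):
            laz = {m: (-2.5 if s else -1.5) for m, s in enumerate(seq)}
            frames.append(make_grid(laz, child=f"c{i}"))
            expected.extend(oracle_status(seq))
        st = gf.classify_status(pd.concat(frames, ignore_index=True))
        st = st.sort_values(["child_id", "month"], key=lambda s: (
            s.str.removeprefix("c").astype(int) if s.name == "child_id" else s))
        # rebuild in enumeration order
        order = {f"c{i}": i for i in range(126)}
        st = st.assign(_o=st["child_id"].map(order)).sort_values(["_o", "month"])
        assert st["status"].tolist() == expected

    def test_gap_uses_most_recent_observed_month(self):
        # stunted at month 2, month 3 unobserved, back above at month 4
        st = gf.classify_status(make_grid({0: -1.0, 2: -2.5, 4: -1.0}))
        assert st["status"].tolist() == [
            "never_stunted", "newly_stunted", "stunting_reversal"]


# ------------------------------------------------------------- proportions

class TestStatusProportions:
    def test_single_child_never_stunted(self):
        st = gf.classify_status(make_grid({m: -1.0 for m in range(4)}))
        props = gf.status_proportions(st)
        assert (props["never_stunted"] == 1.0).all()

    def test_two_children_half_half(self):
        a = make_grid({0: -2.5, 1: -2.5}, child="a")
        b = make_grid({0: -1.0, 1: -1.0}, child="b")
        props = gf.status_proportions(gf.classify_status(pd.concat([a, b])))
        assert props.loc[props["month"] == 1, "still_stunted"].item() == 0.5
        assert props.loc[props["month"] == 1, "never_stunted"].item() == 0.5

    def test_proportions_sum_to_one_on_simulation(self, monthly_grid):
        props = gf.status_proportions(gf.classify_status(monthly_grid))
        total = props[list(gf.STATUS_CATEGORIES)].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-12)


class TestEverAndCurrent:
    def test_all_never_gives_zero_ever(self):
        st = gf.classify_status(make_grid({m: -1.0 for m in range(4)}))
        ec = gf.ever_and_current_stunting(st)
        assert (ec["ever"] == 0).all() and (ec["current"] == 0).all()

    def test_single_episode_child(self):
        st = gf.classify_status(make_grid({0: -1, 1: -1, 2: -1, 3: -2.5, 4: -1, 5: -1}))
        ec = gf.ever_and_current_stunting(st).set_index("month")
        assert ec.loc[2, "ever"] == 0 and ec.loc[3, "ever"] == 1
        assert ec.loc[3, "current"] == 1 and ec.loc[4, "current"] == 0
        assert ec.loc[5, "reversed_not_stunted"] == 1

    def test_ever_monotone_on_simulation(self, monthly_grid):
        ec = gf.ever_and_current_stunting(gf.classify_status(monthly_grid))
        assert (np.diff(ec["ever"]) >= 0).all()

    def test_newly_implies_no_prior_stunting_and_relapse_implies_reversal(self, monthly_grid):
        st = gf.classify_status(monthly_grid)
        for (_, _), sub in st.groupby(["cohort_id", "child_id"], sort=False):
            seq = (sub.sort_values("month")["laz"] < -2).tolist()
            stats = sub.sort_values("month")["status"].tolist()
            for i, s in enumerate(stats):
                if s == "newly_stunted":
                    assert not any(seq[:i])
                if s == "stunting_relapse":
                    assert any(seq[:i]) and not seq[i - 1]


# --------------------------------------------------------------- incidence

class TestIncidence:
    def test_simple_ratio(self):
        frames = []
        for i in range(10):
            laz = {0: -1.0, 120: (-2.5 if i < 2 else -1.0)}  # onset in [3,6) for 2
            frames.append(make_child(laz, child=f"c{i}"))
        inc = gf.incidence_proportion(pd.concat(frames), bins=[gf.AgeBin(3, 6)])
        row = inc.iloc[0]
        assert row["n_at_risk"] == 10 and row["n_incident"] == 2
        assert row["proportion"] == pytest.approx(0.2)
        assert row["variance"] == pytest.approx(0.2 * 0.8 / 10)

    def test_all_stunted_at_birth_empties_later_bins(self):
        frames = [make_child({0: -2.5, 120: -2.6}, child=f"c{i}") for i in range(5)]
        inc = gf.incidence_proportion(pd.concat(frames))
        later = inc[inc["lower_months"] > 0]
        assert (later["n_at_risk"] == 0).all() and later["degenerate"].all()
        first = inc[inc["lower_months"] == 0].iloc[0]
        assert first["proportion"] == 1.0

    def test_first_incidents_sum_to_ever_stunted(self, default_sim):
        measurements, _ = default_sim
        # bins must span every onset age (month-24 visits land just past
        # 24 nominal months), hence the extra closing bin
        bins = gf.three_month_bins(27)
        inc = gf.incidence_proportion(measurements, bins=bins)
        eps = gf.first_onsets(gf.detect_incident_episodes(measurements))
        assert inc["n_incident"].sum() == len(eps)

    def test_constant_hazard_recovery_small(self):
        m, _ = gf.simulate_constant_hazard(0.08, n_cohorts=2, children_per_cohort=400, seed=5)
        inc = gf.incidence_proportion(m)
        agg = inc.groupby("lower_months").agg(x=("n_incident", "sum"), n=("n_at_risk", "sum"))
        p_true = 1 - (1 - 0.08) ** 3
        for _, row in agg.iterrows():
            se = np.sqrt(p_true * (1 - p_true) / row["n"])
            assert abs(row["x"] / row["n"] - p_true) < 3 * se


# ------------------------------------------------- birth strata & reversal

class TestBirthStrata:
    @pytest.mark.parametrize("laz,expected", [
        (-2.0, "-2 to 0"), (-2.1, "<-2"), (0.0, ">=0"), (-0.5, "-2 to 0")])
    def test_boundaries(self, laz, expected):
        out = gf.stratify_by_birth_laz(make_child({5: laz}))
        assert out.loc[0, "birth_stratum"] == expected

    def test_child_without_early_measurement_excluded(self):
        out = gf.stratify_by_birth_laz(make_child({45: -1.0}))
        assert out.empty


class TestPostReversalLaz:
    def test_no_change_gives_zero_difference(self):
        grid = make_grid({2: -2.5, 3: -1.5, 6: -1.5})
        out = gf.post_reversal_laz(grid)
        row = out[(out["reversal_month"] == 3) & (out["followup_month"] == 6)].iloc[0]
        assert row["mean_diff"] == pytest.approx(0.0)

    def test_mean_of_two_reversers(self):
        a = make_grid({2: -2.5, 3: -1.5, 6: -2.0}, child="a")   # diff -0.5
        b = make_grid({2: -2.2, 3: -1.1, 6: -2.0}, child="b")   # diff -0.9
        out = gf.post_reversal_laz(pd.concat([a, b]))
        row = out[(out["reversal_month"] == 3) & (out["followup_month"] == 6)].iloc[0]
        assert row["n"] == 2 and row["mean_diff"] == pytest.approx(-0.7)

    def test_imposed_drift_recovered(self):
        def pooled_cell(drift):
            cfg = gf.GeneratorConfig(monthly_cohorts=4, quarterly_cohorts=0,
                                     children_per_cohort=400, post_reversal_drift=drift,
                                     measurement_error_sd=0.0, missingness_rate=0.0,
                                     age_jitter_days=0.0, seed=9)
            measurements, _ = gf.simulate(cfg)
            out = gf.post_reversal_laz(gf.month_grid(measurements))
            cell = out[(out["reversal_month"] == 3) & (out["followup_month"] == 6)]
            return gf.pool_mean_difference(cell["mean_diff"], cell["variance"])

        base, shifted = pooled_cell(0.0), pooled_cell(-0.1)
        # drift of -0.1 z/month over 3 months shifts the mean difference by -0.3
        se = np.hypot(base.se_mu, shifted.se_mu)
        assert abs((shifted.mu - base.mu) - (-0.3)) < 3 * se
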