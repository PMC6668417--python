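"""The variance-gated decision tree and its component tests.

Oracles: k = 2 reductions to the two-sample t tests (exact identities),
pingouin as an independent implementation of Welch ANOVA and Games–Howell,
and published studentized-range critical values.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lipoglo.stats import (
    anova_tukey,
    bonferroni_alpha,
    call_changes,
    decision_tree,
    games_howell,
    groups_from_frame,
    levene,
    robust_two_way,
    welch_anova,
)


@pytest.fixture()
def het_groups(rng):
    return [rng.normal(0, 1, 12), rng.normal(0.5, 3, 9), rng.normal(-0.2, 0.5, 15)]


class TestLevene:
    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0])
        res = levene([g, g.copy(), g.copy()])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_detects_ninefold_variance_difference(self):
        rng = np.random.default_rng(21)
        res = levene([rng.normal(0, 1, 50), rng.normal(0, 3, 50)])
        assert res.p_value < 0.05

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n = 1"):
            levene([np.array([1.0]), np.array([1.0, 2.0])])

    def test_uses_mean_centering(self, rng):
        groups = [rng.exponential(1, 20), rng.exponential(2, 20)]
        ours = levene(groups)
        stat, _ = sps.levene(*groups, center="mean")
        assert ours.statistic == pytest.approx(stat)


class TestAnovaTukey:
    def test_k2_tukey_equals_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 14)
        res = anova_tukey([a, b])
        t = sps.ttest_ind(a, b, equal_var=True)
        assert res.pairwise["p_value"].iloc[0] == pytest.approx(t.pvalue, abs=1e-6)

    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = anova_tukey([g, g.copy()])
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.pairwise["p_value"].iloc[0] == pytest.approx(1.0)

    def test_pairwise_table_symmetric_in_group_order(self, het_groups):
        res = anova_tukey(het_groups, labels=["a", "b", "c"])
        rev = anova_tukey(het_groups[::-1], labels=["c", "b", "a"])
        p1 = {frozenset((r.group1, r.group2)): r.p_value for r in res.pairwise.itertuples()}
        p2 = {frozenset((r.group1, r.group2)): r.p_value for r in rev.pairwise.itertuples()}
        for key in p1:
            assert p1[key] == pytest.approx(p2[key], abs=1e-10)

    def test_studentized_range_matches_published_critical_value(self):
        # q(0.05; k=3, df=10) = 3.88 in standard tables
        assert sps.studentized_range.isf(0.05, 3, 10) == pytest.approx(3.88, abs=0.01)


class TestWelchAnova:
    def test_k2_equals_welch_t(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 4, 20)
        res = welch_anova([a, b])
        t = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(t.statistic**2, abs=1e-9)
        assert res.p_value == pytest.approx(t.pvalue, abs=1e-9)

    def test_k2_equal_variance_balanced_equals_classical_f(self, rng):
        # with k=2, balanced n and exactly equal sample variances the
        # heteroscedastic correction vanishes identically
        a = rng.normal(0, 1, 15)
        b = (a - a.mean()) * 1.0 + 0.5  # same sample variance, shifted
        res = welch_anova([a, b])
        f, _ = sps.f_oneway(a, b)
        assert res.statistic == pytest.approx(f, abs=1e-6)

    def test_large_n_limit_approaches_classical_f(self, rng):
        groups = [rng.normal(m, 1, 2000) for m in (0.0, 0.05, 0.1)]
        res = welch_anova(groups)
        f, _ = sps.f_oneway(*groups)
        assert res.statistic == pytest.approx(f, rel=5e-3)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            welch_anova([np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0])])

    def test_matches_pingouin(self, het_groups):
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame(
            {
                "value": np.concatenate(het_groups),
                "group": np.repeat(["a", "b", "c"], [len(g) for g in het_groups]),
            }
        )
        ours = welch_anova(het_groups)
        ref = pg.welch_anova(data=df, dv="value", between="group")
        assert ours.statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        pcol = "p_unc" if "p_unc" in ref.columns else "p-unc"
        assert ours.p_value == pytest.approx(float(ref[pcol].iloc[0]), rel=1e-6)
        assert ours.df[1] == pytest.approx(float(ref["ddof2"].iloc[0]), rel=1e-9)


class TestGamesHowell:
    def test_k2_close_to_welch_t(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 3, 12)
        res = games_howell([a, b])
        t = sps.ttest_ind(a, b, equal_var=False)
        assert res.pairwise["p_value"].iloc[0] == pytest.approx(t.pvalue, abs=2e-2)

    def test_identical_groups_p_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = games_howell([g, g.copy(), g.copy()])
        assert (res.pairwise["p_value"] == 1.0).all()

    def test_shifted_group_detected(self, rng):
        base = [rng.normal(0, 1, 20) for _ in range(2)]
        shifted = rng.normal(10, 1, 20)  # 10 SD away
        res = games_howell(base + [shifted], labels=["a", "b", "out"])
        pw = res.pairwise.set_index(["group1", "group2"])["p_value"]
        assert pw[("a", "out")] < 1e-4
        assert pw[("b", "out")] < 1e-4
        assert pw[("a", "b")] > 0.5

    def test_matches_pingouin(self, het_groups):
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame(
            {
                "value": np.concatenate(het_groups),
                "group": np.repeat(["a", "b", "c"], [len(g) for g in het_groups]),
            }
        )
        ours = games_howell(het_groups, labels=["a", "b", "c"]).pairwise
        ref = pg.pairwise_gameshowell(data=df, dv="value", between="group")
        ours_idx = ours.set_index(["group1", "group2"])["p_value"]
        for _, row in ref.iterrows():
            key = (row["A"], row["B"]) if (row["A"], row["B"]) in ours_idx else (row["B"], row["A"])
            assert ours_idx[key] == pytest.approx(float(row["pval"]), abs=1e-6)


class TestRobustTwoWay:
    def _layout(self, rng, effect=0.0, n=10):
        f1 = np.repeat(["a", "b"], 2 * n)
        f2 = np.tile(np.repeat(["x", "y"], n), 2)
        vals = rng.normal(0, 1, 4 * n)
        vals[f1 == "b"] += effect
        return vals, f1, f2

    def test_seed_reproducibility(self, rng):
        vals, f1, f2 = self._layout(rng)
        r1 = robust_two_way(vals, f1, f2, seed=9)
        r2 = robust_two_way(vals, f1, f2, seed=9)
        assert (r1.p_factor1, r1.p_factor2, r1.p_interaction) == (
            r2.p_factor1, r2.p_factor2, r2.p_interaction
        )

    def test_three_sd_main_effect_detected(self):
        hits = 0
        reps = 100
        for rep in range(reps):
            rng = np.random.default_rng(7000 + rep)
            vals, f1, f2 = self._layout(rng, effect=3.0)
            res = robust_two_way(vals, f1, f2, seed=rep)
            hits += res.p_factor1 < 0.01
        assert hits >= 95

    def test_empty_cell_rejected(self, rng):
        vals, f1, f2 = self._layout(rng)
        keep = ~((f1 == "b") & (f2 == "y"))
        with pytest.raises(ValueError, match="empty cell"):
            robust_two_way(vals[keep], f1[keep], f2[keep])

    def test_small_cell_rejected(self, rng):
        vals = rng.normal(0, 1, 12)
        f1 = np.repeat(["a", "b"], 6)
        f2 = np.tile(np.repeat(["x", "y"], 3), 2)
        with pytest.raises(ValueError, match="n = 3 < 4"):
            robust_two_way(vals, f1, f2)

    def test_three_by_two_layout_supported(self, rng):
        f1 = np.repeat(["a", "b", "c"], 12)
        f2 = np.tile(np.repeat(["x", "y"], 6), 3)
        vals = rng.normal(0, 1, 36)
        res = robust_two_way(vals, f1, f2, seed=0)
        for p in (res.p_factor1, res.p_factor2, res.p_interaction):
            assert 0.0 <= p <= 1.0


class TestBonferroni:
    def test_four_subclass_family(self):
        thr = bonferroni_alpha(4)
        assert thr.alpha == pytest.approx(0.0125)

    def test_three_region_family_reported_threshold(self):
        thr = bonferroni_alpha(3)
        assert thr.alpha == pytest.approx(0.05 / 3)
        assert thr.reported == 0.017

    def test_single_comparison(self):
        assert bonferroni_alpha(1).alpha == 0.05

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0)


class TestCallChanges:
    def _table(self, means, label="VLDL", n=6, sd=1.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for tp, mu in means.items():
            for v in rng.normal(mu, sd, n):
                rows.append({"label": label, "timepoint": tp, "value": v})
        return pd.DataFrame(rows)

    def test_identical_series_all_none(self):
        tab = self._table({1: 10.0, 2: 10.0}, seed=1)
        calls = call_changes(tab, tab.copy())
        assert (calls["call"] == "none").all()

    def test_inflated_vldl_called_up(self):
        control = self._table({1: 10.0, 2: 10.0}, seed=2)
        treated = self._table({1: 10.0, 2: 25.0}, seed=3)
        calls = call_changes(treated, control).set_index("timepoint")
        assert calls.loc[2, "call"] == "up"
        assert calls.loc[1, "call"] == "none"

    def test_depleted_class_called_down(self):
        control = self._table({1: 30.0}, seed=4)
        treated = self._table({1: 10.0}, seed=5)
        calls = call_changes(treated, control)
        assert calls["call"].iloc[0] == "down"

    def test_positive_difference_without_significance_is_none(self):
        control = self._table({1: 10.0}, n=4, sd=8.0, seed=6)
        treated = self._table({1: 11.0}, n=4, sd=8.0, seed=7)
        calls = call_changes(treated, control)
        assert calls["mean_diff"].iloc[0] != 0.0
        if calls["p_value"].iloc[0] >= 0.05:
            assert calls["call"].iloc[0] == "none"

    def test_unmatched_labels_rejected(self):
        a = self._table({1: 10.0}, label="VLDL")
        b = self._table({1: 10.0}, label="LDL")
        with pytest.raises(ValueError, match="unmatched labels"):
            call_changes(a, b)


class TestDecisionTree:
    def test_homoscedastic_data_takes_anova_branch(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, 20) for m in (0, 0, 1)]
        res = decision_tree(groups)
        assert res.branch == "anova_tukey"

    def test_heteroscedastic_data_takes_welch_branch(self, rng):
        groups = [rng.normal(0, 1, 40), rng.normal(0, 6, 40), rng.normal(0, 1, 40)]
        res = decision_tree(groups)
        assert res.branch == "welch_games_howell"

    def test_groups_from_frame_round_trip(self, rng):
        df = pd.DataFrame(
            {"value": rng.normal(0, 1, 30), "group": np.repeat(["a", "b", "c"], 10)}
        )
        groups, labels = groups_from_frame(df)
        assert labels == ["a", "b", "c"]
        assert sum(g.size for g in groups) == 30


def test_all_p_values_within_unit_interval(rng):
    groups = [rng.normal(0, s, 12) for s in (1, 2, 3)]
    for res in (levene(groups), anova_tukey(groups), welch_anova(groups), games_howell(groups)):
        assert 0.0 <= res.p_value <= 1.0
        if res.pairwise is not None:
            assert res.pairwise["p_value"].between(0, 1).all()
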