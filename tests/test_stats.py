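"""Group-comparison battery: ANOVA variants, Holm-Šidák, t-tests."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvrflow.stats import (
    brown_forsythe,
    holm_sidak,
    mixed_anova,
    one_way_anova,
    t_tests,
    two_way_anova,
)


def _group_table(rng, n_per_cell=8, effects=None):
    effects = effects or {}
    rows = []
    i = 0
    for grp in ("young", "older"):
        for sex in ("M", "F"):
            shift = effects.get((grp, sex), 0.0)
            for _ in range(n_per_cell):
                rows.append(
                    {"subject": f"s{i}", "group": grp, "sex": sex,
                     "value": rng.normal(shift, 1.0)}
                )
                i += 1
    return pd.DataFrame(rows)


class TestOneWay:
    def test_textbook_sums_of_squares(self):
        res = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(13.5)
        assert res.df == (1, 4)

    def test_identical_groups_f_zero(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0)

    def test_f_equals_squared_t_for_two_groups(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        f = one_way_anova([a, b])
        t = t_tests(a, b, paired=False)
        assert f.statistic == pytest.approx(t.statistic**2, rel=1e-12)
        assert f.p == pytest.approx(t.p, rel=1e-12)

    def test_matches_scipy(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(9)
        groups = [rng.normal(m, 1, 10) for m in (0.0, 0.3, 0.8)]
        res = one_way_anova(groups)
        ref = f_oneway(*groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])


class TestTwoWay:
    def test_pure_additive_effects_no_interaction(self):
        rows = []
        for i, grp in enumerate(("young", "older")):
            for j, sex in enumerate(("M", "F")):
                for k in range(6):
                    rows.append(
                        {"group": grp, "sex": sex,
                         "value": 2.0 * i + 3.0 * j + 0.1 * k}
                    )
        res = two_way_anova(pd.DataFrame(rows))
        inter = next(r for r in res if r.comparison == "group:sex")
        assert inter.statistic == pytest.approx(0.0, abs=1e-12)

    def test_interaction_detected_for_cell_specific_shift(self):
        rng = np.random.default_rng(5)
        table = _group_table(rng, n_per_cell=12,
                             effects={("young", "M"): 1.5})
        res = two_way_anova(table)
        inter = next(r for r in res if r.comparison == "group:sex")
        assert inter.p < 0.05

    def test_empty_cell_raises(self):
        rng = np.random.default_rng(0)
        table = _group_table(rng)
        table = table[~((table.group == "older") & (table.sex == "F"))]
        with pytest.raises(ValueError, match="non-empty"):
            two_way_anova(table)

    def test_matches_pingouin_on_balanced_design(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        table = _group_table(rng, n_per_cell=10,
                             effects={("young", "M"): 0.8, ("older", "F"): 0.3})
        mine = {r.comparison: r for r in two_way_anova(table)}
        ref = pg.anova(data=table, dv="value", between=["group", "sex"])
        for name, key in [("group", "group"), ("sex", "sex"),
                          ("group * sex", "group:sex")]:
            row = ref[ref.Source == name].iloc[0]
            assert mine[key].statistic == pytest.approx(row.F, rel=1e-6)
            assert mine[key].p == pytest.approx(row["p_unc"], rel=1e-6)


def _mixed_table(rng, n_young=10, n_older=10, group_shift=0.0,
                 cond_shift=0.0, inter_shift=0.0, subj_sd=1.0):
    rows = []
    i = 0
    for grp, n in (("young", n_young), ("older", n_older)):
        for _ in range(n):
            base = rng.normal(0, subj_sd) + (group_shift if grp == "young" else 0)
            for c, cond in enumerate(("normo", "co2_4", "co2_6")):
                val = base + cond_shift * c + rng.normal(0, 1)
                if grp == "older":
                    val += inter_shift * c
                rows.append({"subject": f"s{i}", "group": grp,
                             "condition": cond, "value": val})
            i += 1
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_group_effect_without_condition_effect(self):
        rng = np.random.default_rng(2)
        table = _mixed_table(rng, group_shift=5.0, cond_shift=0.0)
        res = {r.comparison: r for r in mixed_anova(table)}
        assert res["group"].p < 1e-6
        assert res["condition"].p > 0.01

    def test_missing_condition_names_subject(self):
        rng = np.random.default_rng(2)
        table = _mixed_table(rng)
        table = table[~((table.subject == "s3")
                        & (table.condition == "co2_6"))]
        with pytest.raises(ValueError, match="s3"):
            mixed_anova(table)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        table = _mixed_table(rng, group_shift=0.8, cond_shift=0.5,
                             inter_shift=-0.4)
        mine = {r.comparison: r for r in mixed_anova(table)}
        ref = pg.mixed_anova(data=table, dv="value", within="condition",
                             subject="subject", between="group")
        pairs = [("group", "group"), ("condition", "condition"),
                 ("Interaction", "group:condition")]
        for src, key in pairs:
            row = ref[ref.Source == src].iloc[0]
            assert mine[key].statistic == pytest.approx(row.F, rel=1e-6)
            assert mine[key].p == pytest.approx(row["p_unc"], rel=1e-6)


class TestHolmSidak:
    def test_worked_example(self):
        out = holm_sidak([0.01, 0.04, 0.30], alpha=0.05)
        assert out.p_adjusted.iloc[0] == pytest.approx(1 - 0.99**3, rel=1e-9)
        assert out.p_adjusted.iloc[1] == pytest.approx(1 - 0.96**2, rel=1e-9)
        assert out.p_adjusted.iloc[2] == pytest.approx(0.30, rel=1e-9)
        assert list(out.reject) == [True, False, False]

    def test_all_zero_all_rejected(self):
        out = holm_sidak([0.0, 0.0, 0.0])
        assert out.reject.all()

    def test_single_p_reduces_to_plain_comparison(self):
        out = holm_sidak([0.03])
        assert out.p_adjusted.iloc[0] == pytest.approx(0.03)
        assert bool(out.reject.iloc[0])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.uniform(0, 0.2, 8)
        mine = holm_sidak(p, alpha=0.05)
        reject, adj, *_ = multipletests(p, alpha=0.05, method="holm-sidak")
        assert np.allclose(mine.p_adjusted, adj, rtol=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_adjusted_p_valid_and_monotone(self, pvals):
        out = holm_sidak(pvals)
        assert ((out.p_adjusted >= 0) & (out.p_adjusted <= 1)).all()
        ranked = out.sort_values("p", kind="stable")
        assert np.all(np.diff(ranked.p_adjusted) >= -1e-12)


class TestTTests:
    def test_paired_hand_calculation(self):
        res = t_tests([1.0, 2.0, 3.0], [0.0, 0.0, 0.0], paired=True)
        assert res.statistic == pytest.approx(3.464, abs=1e-3)
        assert res.df == (2.0,)

    def test_paired_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero-variance"):
            t_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)

    def test_unpaired_identical_samples_t_zero(self):
        res = t_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=False)
        assert res.statistic == pytest.approx(0.0)

    def test_welch_differs_under_unequal_variance(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 5, 30)
        pooled = t_tests(a, b)
        welch = t_tests(a, b, welch=True)
        assert pooled.df != welch.df


class TestBrownForsythe:
    def test_tenfold_spread_detected(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0, 10, 20)
        assert brown_forsythe([a, b]).p < 0.05

    def test_equal_spread_not_flagged(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 30)
        b = rng.normal(5, 1, 30)
        assert brown_forsythe([a, b]).p > 0.05

    def test_two_groups_reduce_to_t_on_deviations(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0, 2, 18)
        bf = brown_forsythe([a, b])
        dev_a = np.abs(a - np.median(a))
        dev_b = np.abs(b - np.median(b))
        t = t_tests(dev_a, dev_b)
        assert bf.statistic == pytest.approx(t.statistic**2, rel=1e-9)
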