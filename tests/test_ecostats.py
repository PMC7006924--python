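"""Flume preference, Fv/Fm and the factorial statistics."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coralquant.ecostats import (
    FlumePeriod,
    FlumeTrial,
    arcsine_sqrt,
    cue_time_proportion,
    fvfm,
    ks_two_sample,
    mann_whitney_bonferroni,
    scheirer_ray_hare,
    tukey_hsd,
    two_way_anova,
)
from coralquant.synthdata import gen_flume, gen_phenotypes


class TestFvFm:
    @pytest.mark.parametrize("f0,fm,expected", [(0, 1000, 1.0), (1000, 1000, 0.0),
                                                (300, 1000, 0.7)])
    def test_values(self, f0, fm, expected):
        assert fvfm(f0, fm) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fvfm(10, 0)
        with pytest.raises(ValueError):
            fvfm(20, 10)


class TestCueTimeProportion:
    def test_always_in_cue_is_100(self):
        (trial,) = gen_flume(1, p_cue=1.0, seed=0)
        assert cue_time_proportion(trial) == 100.0

    def test_side_sticker_scores_50(self):
        periods = (
            FlumePeriod("left", tuple(["left"] * 24)),
            FlumePeriod("right", tuple(["left"] * 24)),
        )
        trial = FlumeTrial("l1", "cue", periods)
        assert cue_time_proportion(trial) == 50.0

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(33)
        obs1 = tuple(rng.choice(["left", "right"], size=24))
        obs2 = tuple(rng.choice(["left", "right"], size=24))
        trial = FlumeTrial(
            "l1", "cue", (FlumePeriod("left", obs1), FlumePeriod("right", obs2))
        )
        expected = (obs1.count("left") + obs2.count("right")) / 48 * 100
        assert cue_time_proportion(trial) == pytest.approx(expected)

    def test_indifferent_walker_averages_50(self):
        trials = gen_flume(200, p_cue=0.5, seed=4)
        props = [cue_time_proportion(t) for t in trials]
        se = 100 * math.sqrt(0.25 / (48 * 200))
        assert np.mean(props) == pytest.approx(50.0, abs=4 * se)

    def test_cue_side_must_swap(self):
        with pytest.raises(ValueError, match="swap"):
            FlumeTrial(
                "l", "cue",
                (FlumePeriod("left", ("left",) * 24), FlumePeriod("left", ("left",) * 24)),
            )


class TestKS:
    def test_identical_and_separated(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = ks_two_sample(x, x)
        assert res.statistic == 0 and res.pvalue == pytest.approx(1.0)
        res = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert res.statistic == 1.0

    def test_small_sample_matches_permutation_enumeration(self):
        rng = np.random.default_rng(55)
        x = rng.normal(size=4)
        y = rng.normal(loc=1.0, size=4)
        res = ks_two_sample(x, y)
        # enumerate all C(8,4) label assignments of the pooled values
        pooled = np.concatenate([x, y])
        d_obs = res.statistic

        def ks_d(a, b):
            grid = np.sort(pooled)
            fa = np.searchsorted(np.sort(a), grid, side="right") / len(a)
            fb = np.searchsorted(np.sort(b), grid, side="right") / len(b)
            return np.max(np.abs(fa - fb))

        count = total = 0
        for idx in combinations(range(8), 4):
            a = pooled[list(idx)]
            b = pooled[[i for i in range(8) if i not in idx]]
            total += 1
            if ks_d(a, b) >= d_obs - 1e-12:
                count += 1
        assert res.pvalue_exact == pytest.approx(count / total, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


@pytest.fixture
def balanced_frame():
    rng = np.random.default_rng(2)
    rows = []
    for trt in ["control", "MeOH", "PbTx", "Kbrevis"]:
        for t in [24, 48]:
            for _ in range(5):
                rows.append({"treatment": trt, "time_h": t,
                             "response": float(rng.normal())})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_constant_response_gives_zero_f(self, balanced_frame):
        table = two_way_anova(balanced_frame.assign(response=3.0))
        effects = table.drop(index="residual")
        assert (effects.F == 0).all() and (effects.p == 1).all()

    def test_matches_statsmodels_type1(self, balanced_frame):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        mine = two_way_anova(balanced_frame)
        fit = smf.ols("response ~ C(treatment) * C(time_h)", balanced_frame).fit()
        ref = anova_lm(fit, typ=1)
        for my_row, ref_row in zip(
            ["treatment", "time_h", "treatment:time_h"],
            ["C(treatment)", "C(time_h)", "C(treatment):C(time_h)"],
        ):
            assert mine.loc[my_row, "F"] == pytest.approx(ref.loc[ref_row, "F"])
            assert mine.loc[my_row, "p"] == pytest.approx(ref.loc[ref_row, "PR(>F)"])

    def test_single_factor_collapse_equals_one_way(self, balanced_frame):
        df = balanced_frame.assign(time_h=24)
        table = two_way_anova(df)
        groups = [g.response.to_numpy() for _, g in df.groupby("treatment")]
        f, p = stats.f_oneway(*groups)
        assert table.loc["treatment", "F"] == pytest.approx(f)
        assert table.loc["treatment", "p"] == pytest.approx(p)

    def test_empty_cell_named(self, balanced_frame):
        df = balanced_frame[
            ~((balanced_frame.treatment == "PbTx") & (balanced_frame.time_h == 48))
        ]
        with pytest.raises(ValueError, match="PbTx"):
            two_way_anova(df)

    def test_strong_effect_detected_downstream_of_generator(self):
        obs = gen_phenotypes(
            {("control", 24): 0.6, ("control", 48): 0.6,
             ("Kbrevis", 24): 0.3, ("Kbrevis", 48): 0.3},
            sd=0.02, n=5, seed=9,
        )
        table = two_way_anova(obs)
        assert table.loc["treatment", "p"] < 0.001


class TestTukey:
    def test_identical_groups_not_separated(self):
        df = pd.DataFrame(
            {"treatment": np.repeat(["a", "b", "c"], 5),
             "response": np.tile([0.0, 1.0, 2.0, 3.0, 4.0], 3)}
        )
        table = tukey_hsd(df, factor="treatment")
        assert (table["p_adj"].astype(float) > 0.9).all()

    def test_two_groups_ordering_matches_t_test(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {
                "treatment": ["a"] * 8 + ["b"] * 8,
                "response": np.concatenate(
                    [rng.normal(size=8), rng.normal(0.8, size=8)]
                ),
            }
        )
        table = tukey_hsd(df, factor="treatment")
        t_p = stats.ttest_ind(
            df.response[df.treatment == "a"], df.response[df.treatment == "b"]
        ).pvalue
        # with 2 groups the studentized range test is t-test equivalent
        assert float(table["p_adj"].iloc[0]) == pytest.approx(t_p, abs=1e-3)

    def test_large_separation_significant(self):
        df = pd.DataFrame(
            {"treatment": ["a"] * 6 + ["b"] * 6,
             "response": [0.0] * 6 + [10.0] * 6}
        )
        df["response"] += np.random.default_rng(0).normal(0, 0.1, 12)
        table = tukey_hsd(df, factor="treatment")
        assert (table["p_adj"].astype(float) < 0.001).all()


class TestScheirerRayHare:
    def test_permuted_labels_give_small_h(self, balanced_frame):
        # factor levels carry identically distributed data: H has a null
        # chi-square distribution, so p should not be extreme
        table = scheirer_ray_hare(balanced_frame)
        assert table.loc["treatment", "H"] >= 0

    def test_single_level_factor_collapses_to_kruskal_wallis(self, balanced_frame):
        df = balanced_frame.assign(time_h=24)
        table = scheirer_ray_hare(df)
        groups = [g.response.to_numpy() for _, g in df.groupby("treatment")]
        h, p = stats.kruskal(*groups)
        assert table.loc["treatment", "H"] == pytest.approx(h, abs=1e-9)
        assert table.loc["treatment", "p"] == pytest.approx(p, rel=1e-9)

    def test_kruskal_equivalence_with_ties(self, balanced_frame):
        df = balanced_frame.assign(
            time_h=24, response=balanced_frame.response.round(0)
        )
        table = scheirer_ray_hare(df)
        groups = [g.response.to_numpy() for _, g in df.groupby("treatment")]
        h, _ = stats.kruskal(*groups)
        assert table.loc["treatment", "H"] == pytest.approx(h, abs=1e-9)


class TestMannWhitneyBonferroni:
    def test_identical_groups_adjusted_to_one(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [1.5, 2.5, 3.5], "c": [1.2, 2.2, 3.2]}
        table = mann_whitney_bonferroni(groups)
        assert (table.p_adj <= 1).all()
        assert (table.p_adj >= table.p_raw).all()

    def test_single_comparison_unadjusted(self):
        rng = np.random.default_rng(6)
        groups = {"a": rng.normal(size=10), "b": rng.normal(size=10)}
        table = mann_whitney_bonferroni(groups, comparisons=[("a", "b")])
        assert table.p_adj.iloc[0] == pytest.approx(table.p_raw.iloc[0])

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=4)
        y = rng.normal(size=5)
        table = mann_whitney_bonferroni({"x": x, "y": y}, comparisons=[("x", "y")])
        # enumerate the exact U null distribution over label assignments
        pooled = np.concatenate([x, y])
        u_obs = table.U.iloc[0]
        n, m = len(x), len(y)
        us = []
        for idx in combinations(range(n + m), n):
            a = pooled[list(idx)]
            b = pooled[[i for i in range(n + m) if i not in idx]]
            us.append(sum((ai > bi) + 0.5 * (ai == bi) for ai in a for bi in b))
        us = np.array(us)
        p_tail = np.mean(us >= u_obs), np.mean(us <= u_obs)
        p_exact = min(1.0, 2 * min(p_tail))
        assert table.p_raw.iloc[0] == pytest.approx(p_exact, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_bonferroni({"a": [], "b": [1.0]}, [("a", "b")])


class TestArcsineSqrt:
    @pytest.mark.parametrize("p,expected", [(0, 0.0), (1, math.pi / 2),
                                            (0.25, math.pi / 6)])
    def test_closed_form(self, p, expected):
        assert arcsine_sqrt(p) == pytest.approx(expected)

    def test_monotone(self):
        grid = np.linspace(0, 1, 50)
        vals = [arcsine_sqrt(p) for p in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_domain(self):
        with pytest.raises(ValueError):
            arcsine_sqrt(1.5)
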