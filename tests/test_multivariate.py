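import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from apicomp.multivariate import (CompositionalManova, adjust_pvalues,
                                  mancova_pillai, manova_pillai,
                                  pairwise_posthoc, pearson_clr_carbonyl,
                                  wilcoxon_by_taxon, wilcoxon_rank_sum)

hyp = settings(derandomize=True, max_examples=40, deadline=None)


def enumerate_rank_sum_p(x, y):
    """Independent oracle: exact two-sided Mann-Whitney p by enumerating
    every assignment of the pooled ranks into the two groups."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    N = n1 * len(y)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u_min = min(u_obs, N - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if u <= u_min + 1e-9 or u >= N - u_min - 1e-9:
            count += 1
    return count / total


class TestPillaiManova:
    def test_single_response_equals_one_way_anova(self, rng):
        y = rng.normal(size=24)
        g = np.repeat(["a", "b"], 12)
        res = CompositionalManova(y[:, None], pd.DataFrame({"g": g}),
                                  factors=("g",), interaction=False).fit()
        f, p = stats.f_oneway(y[:12], y[12:])
        term = res.terms["g"]
        assert term.f_value == pytest.approx(f, abs=1e-8)
        assert term.p_value == pytest.approx(p, abs=1e-8)
        # Pillai V equals eta-squared = SSB/(SSB+SSE) for one response
        grand = y.mean()
        ssb = sum(len(grp) * (grp.mean() - grand) ** 2 for grp in (y[:12], y[12:]))
        sst = ((y - grand) ** 2).sum()
        assert term.statistic == pytest.approx(ssb / sst, abs=1e-8)

    def test_matches_statsmodels_type_iii_unbalanced(self, rng):
        from statsmodels.multivariate.manova import MANOVA
        n = 50
        Y = rng.normal(size=(n, 4))
        data = pd.DataFrame({
            "age_class": rng.choice(["young", "old"], n),
            "source": rng.choice(["CA", "AZ"], n),
        })
        mine = manova_pillai(Y, data)
        df = data.copy()
        for i in range(4):
            df[f"y{i}"] = Y[:, i]
        ref = MANOVA.from_formula(
            "y0 + y1 + y2 + y3 ~ C(age_class, Sum) * C(source, Sum)", df
        ).mv_test()
        pairs = [("age_class", "C(age_class, Sum)"),
                 ("source", "C(source, Sum)"),
                 ("age_class:source", "C(age_class, Sum):C(source, Sum)")]
        for mine_term, ref_term in pairs:
            ref_row = ref.results[ref_term]["stat"].loc["Pillai's trace"]
            assert mine.terms[mine_term].statistic \
                == pytest.approx(ref_row["Value"], abs=1e-8)
            assert mine.terms[mine_term].p_value \
                == pytest.approx(ref_row["Pr > F"], abs=1e-8)

    def test_identical_group_means_give_zero_trace(self):
        block = np.array([[0.0, 1], [1, 0], [2, 2], [3, 1], [1, 3], [0, 0]])
        Y = np.vstack([block, block])  # both groups identical
        data = pd.DataFrame({"g": np.repeat(["a", "b"], 6)})
        res = CompositionalManova(Y, data, factors=("g",),
                                  interaction=False).fit()
        assert res.terms["g"].statistic == pytest.approx(0.0, abs=1e-12)
        assert res.terms["g"].p_value == pytest.approx(1.0, abs=1e-9)

    def test_invariance_to_linear_recombination(self, rng):
        Y = rng.normal(size=(40, 3))
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)  # invertible
        data = pd.DataFrame({"g": rng.choice(["a", "b"], 40)})
        v1 = CompositionalManova(Y, data, ("g",), False).fit().terms["g"]
        v2 = CompositionalManova(Y @ A, data, ("g",), False).fit().terms["g"]
        assert v1.statistic == pytest.approx(v2.statistic, abs=1e-8)

    def test_singular_error_advises_panel_reduction(self, rng):
        Y = rng.normal(size=(30, 3))
        Y = np.column_stack([Y, Y[:, 0]])  # collinear responses
        data = pd.DataFrame({"g": np.repeat(["a", "b"], 15)})
        with pytest.raises(np.linalg.LinAlgError, match="panel"):
            CompositionalManova(Y, data, ("g",), False).fit()


class TestMancova:
    def test_covariate_equal_to_response_drives_p_to_zero(self, rng):
        n = 40
        Y = rng.normal(size=(n, 3))
        data = pd.DataFrame({"source": rng.choice(["CA", "AZ"], n),
                             "log_carbonyl": Y[:, 0]})
        res = mancova_pillai(Y, data)
        assert res.terms["log_carbonyl"].p_value < 1e-12

    def test_constant_covariate_reduces_to_manova(self, rng, caplog):
        n = 30
        Y = rng.normal(size=(n, 2))
        data = pd.DataFrame({"source": np.repeat(["CA", "AZ"], 15),
                             "log_carbonyl": np.ones(n)})
        with caplog.at_level("WARNING"):
            res = mancova_pillai(Y, data)
        plain = manova_pillai(Y, data, factors=("source",), interaction=False)
        assert res.terms["source"].p_value \
            == pytest.approx(plain.terms["source"].p_value, abs=1e-12)
        assert "constant covariate" in caplog.text

    def test_independent_covariate_leaves_factor_test_similar(self, rng):
        # paired simulation: with an unrelated covariate the factor p-values
        # track the plain MANOVA p-values closely on average
        diffs = []
        for _ in range(60):
            n = 40
            Y = rng.normal(size=(n, 3))
            data = pd.DataFrame({"source": rng.choice(["CA", "AZ"], n),
                                 "log_carbonyl": rng.normal(size=n)})
            p_cov = mancova_pillai(Y, data).terms["source"].p_value
            p_plain = manova_pillai(Y, data, ("source",), False) \
                .terms["source"].p_value
            diffs.append(p_cov - p_plain)
        assert abs(np.mean(diffs)) < 0.05


class TestWilcoxon:
    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 5), (4, 4), (6, 3), (8, 8)])
    def test_exact_matches_enumeration(self, n1, n2, rng):
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(enumerate_rank_sum_p(x, y), abs=1e-12)

    def test_spec_case_p_one_third(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_normal_approximation_close_to_exact_at_n8(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(0.5, 1, size=8)
        p_exact = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact").pvalue
        p_asym = stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic").pvalue
        assert abs(p_exact - p_asym) < 0.01

    def test_by_taxon_frame_and_corrections(self, rng):
        vals = pd.DataFrame(rng.normal(size=(20, 4)),
                            columns=list("abcd"))
        vals.loc[:9, "a"] += 3.0
        groups = np.array(["old"] * 10 + ["young"] * 10)
        res = wilcoxon_by_taxon(vals, groups)
        f = res.frame
        assert (f["p_bonferroni"] >= f["p_raw"] - 1e-15).all()
        assert (f["p_bh"] >= f["p_raw"] - 1e-15).all()
        assert (f["p_by"] >= f["p_bh"] - 1e-15).all()
        assert res.significant(0.01, "p_bonferroni") == ["a"]
        assert f["p_raw"].idxmin() == "a"


class TestAdjustPvalues:
    def test_bonferroni_hand_case(self):
        assert adjust_pvalues([0.01] + [0.5] * 4, "bonferroni")[0] \
            == pytest.approx(0.05)

    def test_bh_step_up_hand_case(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones_stay_ones(self):
        for m in ("bonferroni", "bh", "by"):
            assert adjust_pvalues([1.0, 1.0], m) == pytest.approx([1.0, 1.0])

    @hyp
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20),
           st.sampled_from(["bonferroni", "bh", "by"]))
    def test_matches_statsmodels(self, p, method):
        from statsmodels.stats.multitest import multipletests
        sm_name = {"bonferroni": "bonferroni", "bh": "fdr_bh",
                   "by": "fdr_by"}[method]
        ref = multipletests(p, method=sm_name)[1]
        assert np.allclose(adjust_pvalues(p, method), ref, atol=1e-12)


class TestPosthoc:
    def test_two_identical_groups_not_significant(self):
        Y = pd.DataFrame({"y": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        res = pairwise_posthoc(Y, ["a"] * 3 + ["b"] * 3)
        assert res["p_adj"].iloc[0] >= 0.999

    def test_shifted_group_detected_others_not(self, rng):
        groups = np.repeat(list("abcd"), 15)
        y = rng.normal(size=60)
        y[groups == "d"] += 5.0
        res = pairwise_posthoc(pd.DataFrame({"y": y}), groups)
        has_d = res.apply(lambda r: "d" in (r.group_a, r.group_b), axis=1)
        assert (res.loc[has_d, "p_adj"] < 0.01).all()
        assert (res.loc[~has_d, "p_adj"] > 0.05).all()

    def test_two_groups_close_to_t_test(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(1.0, 1, size=12)
        res = pairwise_posthoc(pd.DataFrame({"v": np.concatenate([x, y])}),
                               ["a"] * 12 + ["b"] * 12)
        t_p = stats.ttest_ind(x, y).pvalue
        # with k = 2 the studentized range test coincides with the t-test
        assert res["p_adj"].iloc[0] == pytest.approx(t_p, abs=1e-6)

    def test_singleton_group_excluded(self, rng, caplog):
        y = rng.normal(size=7)
        with caplog.at_level("WARNING"):
            res = pairwise_posthoc(pd.DataFrame({"y": y}),
                                   ["a"] * 3 + ["b"] * 3 + ["c"])
        assert set(res.group_a) | set(res.group_b) == {"a", "b"}


class TestPearson:
    def test_perfect_correlations(self):
        Z = pd.DataFrame({"up": [1.0, 2, 3, 4], "down": [4.0, 3, 2, 1]})
        res = pearson_clr_carbonyl(Z, [2.0, 4, 6, 8])
        assert res.loc["up", "r"] == pytest.approx(1.0)
        assert res.loc["down", "r"] == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        res = pearson_clr_carbonyl(pd.DataFrame({"t": [1.0, 2, 3]}),
                                   [1.0, 2, 4])
        assert res.loc["t", "r"] == pytest.approx(9 / np.sqrt(84), abs=1e-4)

    def test_zero_variance_gives_nan(self, caplog):
        Z = pd.DataFrame({"flat": [1.0, 1, 1]})
        with caplog.at_level("WARNING"):
            res = pearson_clr_carbonyl(Z, [1.0, 2, 3])
        assert np.isnan(res.loc["flat", "r"])
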