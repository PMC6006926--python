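import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apicomp.ordination import (Anosim, DistLM, anosim, distance, distlm,
                                pca_clr)


class TestDistance:
    def test_identical_rows_zero(self):
        X = np.array([[1.0, 2, 3], [1.0, 2, 3]])
        for metric in ("bray_curtis", "euclidean"):
            assert distance(X, metric).values[0, 1] == pytest.approx(0.0)

    def test_bray_curtis_disjoint_is_one(self):
        assert distance(np.array([[1.0, 0], [0, 1.0]]),
                        "bray_curtis").values[0, 1] == pytest.approx(1.0)

    def test_euclidean_three_four_five(self):
        assert distance(np.array([[0.0, 0], [3.0, 4]]),
                        "euclidean").values[0, 1] == pytest.approx(5.0)

    def test_all_zero_sample_rejected_for_bray_curtis(self):
        with pytest.raises(ValueError, match="all-zero"):
            distance(np.array([[1.0, 1], [0.0, 0]]), "bray_curtis")


class TestClrPca:
    def test_rank_one_data_explained_by_pc1(self):
        u = np.array([1.0, -2, 0.5, 3, -1])
        v = np.array([2.0, -1, 1])
        res = pca_clr(np.outer(u, v))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_loadings_orthogonal_and_reconstruction(self, rng):
        X = rng.normal(size=(30, 5))
        res = pca_clr(X)
        V = res.loadings.to_numpy()
        sd = np.sqrt(np.sum(V ** 2, axis=0))
        E = V / sd  # unscale back to eigenvectors
        assert np.allclose(E.T @ E, np.eye(5), atol=1e-8)
        Xc = X - X.mean(0)
        assert np.allclose(res.scores.to_numpy() @ E.T, Xc, atol=1e-8)

    def test_explained_fractions_contract(self, rng):
        res = pca_clr(rng.normal(size=(20, 6)))
        ev = res.explained_variance_ratio
        assert (np.diff(ev) <= 1e-12).all()
        assert ev.sum() == pytest.approx(1.0, abs=1e-9)
        assert ((ev >= 0) & (ev <= 1)).all()

    def test_carbonyl_vector_is_score_correlation(self, rng):
        X = rng.normal(size=(25, 4))
        carb = rng.normal(size=25)
        res = pca_clr(X, carbonyl=carb)
        r_ref = stats.pearsonr(carb, res.scores["PC1"]).statistic
        assert res.carbonyl_vector[0] == pytest.approx(r_ref, abs=1e-10)


def enumerate_anosim_p(dm, grouping):
    """Oracle: exact p over all distinct label assignments (combinations)."""
    grouping = np.asarray(grouping)
    n = len(grouping)
    labels, counts = np.unique(grouping, return_counts=True)
    ranks = stats.rankdata(dm.condensed())
    iu = np.triu_indices(n, k=1)
    M = n * (n - 1) // 2

    def r_stat(g):
        within = g[iu[0]] == g[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (M / 2)

    r_obs = r_stat(grouping)
    count = total = 0
    for idx in itertools.combinations(range(n), counts[0]):
        g = np.full(n, labels[1], dtype=object)
        g[list(idx)] = labels[0]
        total += 1
        if r_stat(g) >= r_obs - 1e-12:
            count += 1
    return count / total


class TestAnosim:
    def test_fully_separated_clusters_r_one(self):
        X = np.vstack([np.zeros((3, 2)), 10 + np.eye(3, 2)])
        X[:3] += 0.01 * np.arange(3)[:, None]
        dm = distance(X, "euclidean")
        res = Anosim(dm, ["a"] * 3 + ["b"] * 3).fit(n_perm=199, seed=0)
        assert res.R == pytest.approx(1.0)

    @pytest.mark.parametrize("sizes", [(2, 2), (3, 2), (3, 3)])
    def test_exhaustive_p_matches_enumeration(self, sizes, rng):
        n = sum(sizes)
        dm = distance(rng.normal(size=(n, 3)), "euclidean")
        g = ["a"] * sizes[0] + ["b"] * sizes[1]
        res = Anosim(dm, g).fit(exhaustive=True)
        assert res.p_value == pytest.approx(enumerate_anosim_p(dm, g), abs=1e-12)

    def test_r_in_range_and_monotone_invariance(self, rng):
        X = rng.normal(size=(12, 4))
        dm = distance(X, "euclidean")
        g = rng.choice(["a", "b"], 12).tolist() if False else \
            (["a"] * 6 + ["b"] * 6)
        r1 = Anosim(dm, g).fit(99, seed=1).R
        # squaring distances is a monotone transform: ranks unchanged
        from apicomp.ordination import DistanceMatrix
        dm2 = DistanceMatrix(dm.values ** 2, "euclidean")
        r2 = Anosim(dm2, g).fit(99, seed=1).R
        assert -1 <= r1 <= 1
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_null_p_values_roughly_uniform(self, rng):
        # iid data, random labels: permutation p should be uniform on its grid
        pvals = []
        for _ in range(300):
            X = rng.normal(size=(12, 3))
            dm = distance(X, "euclidean")
            pvals.append(Anosim(dm, ["a"] * 6 + ["b"] * 6)
                         .fit(99, seed=int(rng.integers(2**31))).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_degenerate_groupings_rejected(self, rng):
        dm = distance(rng.normal(size=(4, 2)), "euclidean")
        with pytest.raises(ValueError):
            Anosim(dm, ["a", "a", "a", "b"])


class TestDistLM:
    def test_univariate_euclidean_equals_regression_f(self, rng):
        y = rng.normal(size=20)
        x = 0.5 * y + rng.normal(size=20)
        dm = distance(y[:, None], "euclidean")
        res = DistLM(dm, x).fit(n_perm=99, seed=0)
        r = stats.linregress(x, y)
        f_ref = r.rvalue ** 2 / (1 - r.rvalue ** 2) * (20 - 2)
        assert res.pseudo_f == pytest.approx(f_ref, abs=1e-8)
        assert res.r_squared == pytest.approx(r.rvalue ** 2, abs=1e-8)

    def test_multivariate_euclidean_equals_rda_trace(self, rng):
        Y = rng.normal(size=(18, 4))
        x = rng.normal(size=18)
        dm = distance(Y, "euclidean")
        res = DistLM(dm, x).fit(n_perm=99, seed=0)
        # redundancy-analysis oracle computed directly from Y
        Yc = Y - Y.mean(0)
        X = np.column_stack([np.ones(18), x])
        H = X @ np.linalg.pinv(X.T @ X) @ X.T
        fit = H @ Yc
        f_ref = (np.sum(fit ** 2) / 1) / (np.sum((Yc - fit) ** 2) / (18 - 2))
        assert res.pseudo_f == pytest.approx(f_ref, abs=1e-8)

    def test_r2_bounds_and_exact_two_level_fit(self):
        # distances are an exact function of the predictor's two levels
        y = np.array([0.0, 0.0, 0.0, 5.0, 5.0, 5.0])
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        dm = distance(y[:, None], "euclidean")
        res = DistLM(dm, x).fit(n_perm=19, seed=0)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_null_p_values_roughly_uniform(self, rng):
        pvals = []
        for _ in range(300):
            Y = rng.normal(size=(12, 3))
            dm = distance(Y, "euclidean")
            pvals.append(DistLM(dm, rng.normal(size=12))
                         .fit(99, seed=int(rng.integers(2**31))).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_predictor_rejected(self, rng):
        dm = distance(rng.normal(size=(6, 2)), "euclidean")
        with pytest.raises(ValueError, match="constant"):
            DistLM(dm, np.ones(6))

    def test_skbio_permanova_cross_check(self, rng):
        # two-level predictor: DistLM pseudo-F coincides with PERMANOVA's
        from skbio.stats.distance import permanova, DistanceMatrix as SkDM
        X = rng.normal(size=(16, 3)) ** 2
        g = np.repeat([0.0, 1.0], 8)
        dm = distance(X, "bray_curtis")
        mine = DistLM(dm, g).fit(n_perm=99, seed=0)
        ref = permanova(SkDM(dm.values), grouping=list(np.repeat(["a", "b"], 8)),
                        permutations=99)
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-8)
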