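"""Distance matrices, CLR-PCA biplots, ANOSIM and distance-based linear models.

:class:`Anosim` and :class:`DistLM` follow the estimator/results pattern:
construct from a distance matrix plus grouping/predictor, call ``fit`` with a
permutation budget and seed, read the statistic and permutation p-value off
the results object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

METRICS = ("bray_curtis", "euclidean")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a metric label."""

    values: np.ndarray
    metric: str
    ids: list | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def distance(X, metric: str = "bray_curtis", ids=None) -> DistanceMatrix:
    """Pairwise distances between sample rows (bray_curtis or euclidean)."""
    if isinstance(X, pd.DataFrame):
        ids = X.index.tolist() if ids is None else ids
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if metric == "bray_curtis":
        if (X < 0).any():
            raise ValueError("Bray-Curtis requires non-negative abundances")
        if (X.sum(axis=1) == 0).any():
            raise ValueError("Bray-Curtis undefined for an all-zero sample")
        d = squareform(pdist(X, metric="braycurtis"))
    elif metric == "euclidean":
        d = squareform(pdist(X, metric="euclidean"))
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    return DistanceMatrix(d, metric, ids)


# ---------------------------------------------------------------------------
# CLR principal components (covariance biplot)


class PcaResults:
    """Scores, loadings and explained-variance fractions of a CLR-PCA."""

    def __init__(self, scores: pd.DataFrame, loadings: pd.DataFrame,
                 explained: np.ndarray, carbonyl_vector: np.ndarray | None):
        self.scores = scores
        self.loadings = loadings
        self.explained_variance_ratio = explained
        #: correlation of the supplementary carbonyl covariate with each PC
        self.carbonyl_vector = carbonyl_vector

    def summary(self) -> str:
        parts = [
            "CLR principal component analysis (covariance biplot)",
            "explained variance: "
            + ", ".join(f"PC{i+1} {v:.1%}" for i, v in
                        enumerate(self.explained_variance_ratio[:4])),
        ]
        if self.carbonyl_vector is not None:
            parts.append(
                "carbonyl vector (corr with PC1, PC2): "
                f"({self.carbonyl_vector[0]:.3f}, {self.carbonyl_vector[1]:.3f})"
            )
        return "\n".join(parts)


class ClrPca:
    """PCA of a CLR matrix with covariance-biplot scaling.

    Loadings are eigenvectors scaled by the square root of their eigenvalue,
    so vector lengths are proportional to the standard deviation of each
    taxon's log-ratio to the rest of the panel.  An optional carbonyl vector
    is rendered as a supplementary variable via its correlation with the
    sample scores.
    """

    def __init__(self, Z, carbonyl=None):
        self.Z = pd.DataFrame(Z)
        self.carbonyl = None if carbonyl is None else np.asarray(carbonyl, float)
        if self.carbonyl is not None and self.carbonyl.size != len(self.Z):
            raise ValueError("carbonyl vector length mismatch")

    def fit(self) -> PcaResults:
        X = self.Z.to_numpy(dtype=float)
        Xc = X - X.mean(axis=0, keepdims=True)
        n = Xc.shape[0]
        cov = Xc.T @ Xc / (n - 1)
        eigval, eigvec = np.linalg.eigh(cov)
        order = np.argsort(eigval)[::-1]
        eigval = np.clip(eigval[order], 0.0, None)
        eigvec = eigvec[:, order]
        total = eigval.sum()
        explained = eigval / total if total > 0 else eigval
        scores = Xc @ eigvec
        loadings = eigvec * np.sqrt(eigval)[None, :]
        k = eigval.size
        pcs = [f"PC{i+1}" for i in range(k)]
        scores_df = pd.DataFrame(scores, index=self.Z.index, columns=pcs)
        load_df = pd.DataFrame(loadings, index=self.Z.columns, columns=pcs)
        carb = None
        if self.carbonyl is not None:
            carb = np.zeros(k)
            yc = self.carbonyl - self.carbonyl.mean()
            ys = np.sqrt((yc ** 2).sum())
            for i in range(k):
                sc = scores[:, i] - scores[:, i].mean()
                denom = ys * np.sqrt((sc ** 2).sum())
                carb[i] = float(yc @ sc / denom) if denom > 0 else 0.0
        return PcaResults(scores_df, load_df, explained, carb)


def pca_clr(Z, carbonyl=None) -> PcaResults:
    return ClrPca(Z, carbonyl).fit()


# ---------------------------------------------------------------------------
# ANOSIM


class AnosimResults:
    def __init__(self, R: float, p_value: float, n_perm: int, nobs: int):
        self.R = R
        self.p_value = p_value
        self.n_perm = n_perm
        self.nobs = nobs

    def summary(self) -> str:
        return (f"ANOSIM: R = {self.R:.4f}, p = {self.p_value:.4g} "
                f"({self.n_perm} permutations, n = {self.nobs})")


class Anosim:
    """Analysis of similarities on ranked distances.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2; the permutation p-value counts label shuffles whose R is
    at least the observed one (the observed labelling is included in both
    numerator and denominator).
    """

    def __init__(self, dm: DistanceMatrix, grouping):
        self.dm = dm
        self.grouping = np.asarray(grouping)
        if self.grouping.size != dm.n:
            raise ValueError("grouping length mismatch")
        _, counts = np.unique(self.grouping, return_counts=True)
        if len(counts) < 2 or (counts < 2).any():
            raise ValueError("need >= 2 groups, each with >= 2 members")

    @staticmethod
    def _r_stat(ranks: np.ndarray, within: np.ndarray, M: int) -> float:
        rw = ranks[within].mean()
        rb = ranks[~within].mean()
        return float((rb - rw) / (M / 2.0))

    def fit(self, n_perm: int = 9999, seed: int | None = None,
            exhaustive: bool = False) -> AnosimResults:
        """Monte-Carlo permutation test, or exhaustive enumeration of every
        label permutation when ``exhaustive`` (feasible for small n)."""
        cond = self.dm.condensed()
        ranks = rankdata(cond)
        n = self.dm.n
        M = n * (n - 1) // 2
        iu = np.triu_indices(n, k=1)

        def within_mask(g):
            return (g[iu[0]] == g[iu[1]])

        r_obs = self._r_stat(ranks, within_mask(self.grouping), M)
        if exhaustive:
            from itertools import permutations
            count = total = 0
            for perm in permutations(range(n)):
                g = self.grouping[list(perm)]
                total += 1
                if self._r_stat(ranks, within_mask(g), M) >= r_obs - 1e-12:
                    count += 1
            return AnosimResults(r_obs, count / total, total, n)
        if n_perm < 99:
            logger.warning("n_perm = %d is low; p-value resolution is coarse",
                           n_perm)
        rng = np.random.default_rng(seed)
        count = 1
        for _ in range(n_perm):
            g = rng.permutation(self.grouping)
            if self._r_stat(ranks, within_mask(g), M) >= r_obs:
                count += 1
        p = count / (n_perm + 1)
        return AnosimResults(r_obs, p, n_perm, n)


def anosim(dm: DistanceMatrix, grouping, n_perm: int = 9999,
           seed: int | None = None) -> AnosimResults:
    return Anosim(dm, grouping).fit(n_perm, seed)


# ---------------------------------------------------------------------------
# DistLM


class DistLMResults:
    def __init__(self, pseudo_f: float, p_value: float, r_squared: float,
                 n_perm: int, nobs: int, scheme: str):
        self.pseudo_f = pseudo_f
        self.p_value = p_value
        self.r_squared = r_squared
        self.n_perm = n_perm
        self.nobs = nobs
        self.scheme = scheme

    def summary(self) -> str:
        return (f"DistLM: pseudo-F = {self.pseudo_f:.4f}, "
                f"p = {self.p_value:.4g}, R^2 = {self.r_squared:.4f} "
                f"({self.n_perm} {self.scheme} permutations, n = {self.nobs})")


class DistLM:
    """Distance-based linear model of a community on a predictor.

    The squared distances are Gower-centered, G = -1/2 J D^2 J, and the
    predictor's hat matrix H partitions tr(G):

        pseudo-F = [tr(HGH)/m] / [tr((I-H)G(I-H)) / (n-m-1)]

    with m predictors; R^2 = tr(HGH)/tr(G).  Significance comes from
    permuting either the raw predictor rows (``scheme="raw"``, default) or
    the residuals under the reduced (intercept-only) model, which for a
    single predictor block is the same exchangeable set.
    """

    def __init__(self, dm: DistanceMatrix, predictor):
        self.dm = dm
        X = np.asarray(predictor, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != dm.n:
            raise ValueError("predictor length mismatch")
        if not np.all(np.isfinite(X)):
            raise ValueError("predictor must be finite")
        if any(np.ptp(X[:, j]) == 0 for j in range(X.shape[1])):
            raise ValueError("constant predictor carries no information")
        if dm.n < 4:
            raise ValueError("need n >= 4")
        self.X = X
        n = dm.n
        J = np.eye(n) - np.ones((n, n)) / n
        self.G = -0.5 * J @ (dm.values ** 2) @ J

    @staticmethod
    def _hat(X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        Xd = np.column_stack([np.ones(n), X])
        return Xd @ np.linalg.pinv(Xd.T @ Xd) @ Xd.T

    def _stats(self, X: np.ndarray) -> tuple[float, float]:
        n = self.dm.n
        m = X.shape[1]
        H = self._hat(X)
        HGH = H @ self.G @ H
        num = np.trace(HGH) / m
        R = np.eye(n) - H
        den = np.trace(R @ self.G @ R) / (n - m - 1)
        F = num / den if den > 0 else np.inf
        r2 = np.trace(HGH) / np.trace(self.G) if np.trace(self.G) > 0 else np.nan
        return float(F), float(r2)

    def fit(self, n_perm: int = 9999, seed: int | None = None,
            scheme: str = "raw") -> DistLMResults:
        if scheme not in ("raw", "residual"):
            raise ValueError("scheme must be 'raw' or 'residual'")
        rng = np.random.default_rng(seed)
        f_obs, r2 = self._stats(self.X)
        if scheme == "residual":
            # residuals of X under the intercept-only reduced model
            Xp_base = self.X - self.X.mean(axis=0, keepdims=True)
        else:
            Xp_base = self.X
        count = 1
        for _ in range(n_perm):
            perm = rng.permutation(self.dm.n)
            f_perm, _ = self._stats(Xp_base[perm])
            if f_perm >= f_obs:
                count += 1
        p = count / (n_perm + 1)
        return DistLMResults(f_obs, p, r2, n_perm, self.dm.n, scheme)


def distlm(dm: DistanceMatrix, predictor, n_perm: int = 9999,
           seed: int | None = None, scheme: str = "raw") -> DistLMResults:
    return DistLM(dm, predictor).fit(n_perm, seed, scheme)
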