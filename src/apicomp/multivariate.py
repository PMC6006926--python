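"""Parametric and rank-based tests on CLR matrices.

The central estimator is :class:`CompositionalManova`, a Pillai-trace
MANOVA/MANCOVA for the unbalanced two-way (age x source) design: responses
are CLR scores of the abundant-OTU panel, hypothesis and error
cross-product matrices come from Type III contrasts so term tests are
order-invariant, and Pillai's trace V = sum lambda/(1+lambda) over the
eigenvalues of E^-1 H is converted to an approximate F (exact when s = 1).

Rank-based comparisons (Wilcoxon rank sum per taxon with Bonferroni /
Benjamini-Hochberg / Benjamini-Yekutieli corrections), Tukey-type post hoc
contrasts and per-taxon Pearson correlations against log carbonyl round out
the module.  "FDR", listed in addition to Benjamini-Hochberg, is
implemented as the Benjamini-Yekutieli step-up, the standard stricter
FDR control under dependence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Pillai-trace MANOVA / MANCOVA


@dataclass
class PillaiTest:
    """One model term's Pillai trace with its F approximation."""

    statistic: float       # Pillai's V
    f_value: float
    df1: float
    df2: float
    p_value: float


class ManovaResults:
    """Fitted MANOVA/MANCOVA: per-term Pillai tests plus model metadata."""

    def __init__(self, terms: dict[str, PillaiTest], nobs: int,
                 n_responses: int, response_names, model_desc: str):
        self.terms = terms
        self.nobs = nobs
        self.n_responses = n_responses
        self.response_names = list(response_names)
        self.model_desc = model_desc

    def __getitem__(self, term: str) -> PillaiTest:
        return self.terms[term]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pillai_V": {t: r.statistic for t, r in self.terms.items()},
                "F": {t: r.f_value for t, r in self.terms.items()},
                "df1": {t: r.df1 for t, r in self.terms.items()},
                "df2": {t: r.df2 for t, r in self.terms.items()},
                "p": {t: r.p_value for t, r in self.terms.items()},
            }
        )

    def summary(self) -> str:
        lines = [
            f"Pillai-trace multivariate linear model ({self.model_desc})",
            f"n = {self.nobs} samples, {self.n_responses} responses "
            f"({', '.join(self.response_names)})",
            "",
            self.to_frame().to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def _effect_code(values, name: str) -> tuple[np.ndarray, list]:
    """Sum-to-zero (+1/-1) coding for a two-level factor."""
    levels = sorted(pd.unique(values))
    if len(levels) != 2:
        raise ValueError(f"factor {name!r} must have exactly 2 levels, "
                         f"got {levels}")
    return np.where(np.asarray(values) == levels[0], 1.0, -1.0), levels


def _pillai_from_HE(H: np.ndarray, E: np.ndarray, q: int, n_obs: int,
                    rank_x: int) -> PillaiTest:
    p = H.shape[0]
    try:
        lam = np.linalg.eigvals(np.linalg.solve(E, H))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "error cross-product matrix is singular; reduce the response "
            "panel (collinear CLR columns?)"
        ) from err
    lam = np.real(lam)
    lam = np.clip(lam, 0.0, None)
    V = float(np.sum(lam / (1.0 + lam)))
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    n_ = (n_obs - rank_x - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n_ + s + 1)
    if V >= s:  # perfect separation; F is infinite
        return PillaiTest(V, np.inf, df1, df2, 0.0)
    F = (2 * n_ + s + 1) / (2 * m + s + 1) * (V / s) / (1 - V / s)
    p_val = float(stats.f.sf(F, df1, df2)) if df2 > 0 else np.nan
    return PillaiTest(V, float(F), df1, df2, p_val)


class CompositionalManova:
    """Two-way Pillai-trace MANOVA (optionally with covariates -> MANCOVA).

    Parameters
    ----------
    endog : DataFrame or ndarray, n x p
        Response matrix (CLR scores of the taxon panel).
    data : DataFrame
        Per-sample design information holding the factor columns (and any
        covariate columns), aligned row-wise with ``endog``.
    factors : sequence of str
        One or two two-level factor column names (e.g. age_class, source).
    interaction : bool
        Include the factor interaction (only meaningful with two factors).
    covariates : sequence of str
        Numeric columns entered as regression terms; their presence makes
        the model a MANCOVA with factor terms tested on covariate-adjusted
        cross-products.  A constant covariate is dropped with a warning
        (the model then reduces to the plain MANOVA).
    """

    def __init__(self, endog, data: pd.DataFrame, factors=("age_class", "source"),
                 interaction: bool = True, covariates=()):
        self.endog = pd.DataFrame(endog)
        if len(self.endog) != len(data):
            raise ValueError("endog and data have different lengths")
        self.data = data.reset_index(drop=True)
        self.endog.index = self.data.index
        self.factors = tuple(factors)
        self.interaction = interaction and len(self.factors) == 2
        covs = []
        for c in covariates:
            col = np.asarray(self.data[c], dtype=float)
            if not np.all(np.isfinite(col)):
                raise ValueError(f"covariate {c!r} has non-finite values")
            if np.ptp(col) == 0:
                logger.warning("constant covariate %r dropped; model reduces "
                               "to a MANOVA", c)
            else:
                covs.append(c)
        self.covariates = tuple(covs)

    def _design(self) -> tuple[np.ndarray, dict[str, list[int]]]:
        n = len(self.data)
        cols = [np.ones(n)]
        term_cols: dict[str, list[int]] = {}
        codes = {}
        for f in self.factors:
            x, _ = _effect_code(self.data[f], f)
            codes[f] = x
            term_cols[f] = [len(cols)]
            cols.append(x)
        if self.interaction:
            a, b = self.factors
            term_cols[f"{a}:{b}"] = [len(cols)]
            cols.append(codes[a] * codes[b])
        for c in self.covariates:
            term_cols[c] = [len(cols)]
            cols.append(np.asarray(self.data[c], dtype=float))
        return np.column_stack(cols), term_cols

    def fit(self) -> ManovaResults:
        Y = self.endog.to_numpy(dtype=float)
        n, p = Y.shape
        X, term_cols = self._design()
        rank_x = np.linalg.matrix_rank(X)
        if n <= rank_x + p - 1:
            raise ValueError(
                f"n = {n} too small for {p} responses and model rank {rank_x}"
            )
        XtX = X.T @ X
        XtX_inv = np.linalg.pinv(XtX)
        B = XtX_inv @ X.T @ Y
        resid = Y - X @ B
        E = resid.T @ resid

        terms = {}
        for term, idx in term_cols.items():
            L = np.zeros((len(idx), X.shape[1]))
            for r, j in enumerate(idx):
                L[r, j] = 1.0
            LB = L @ B
            M = L @ XtX_inv @ L.T
            H = LB.T @ np.linalg.solve(M, LB)
            terms[term] = _pillai_from_HE(H, E, q=len(idx), n_obs=n,
                                          rank_x=rank_x)
        desc = " + ".join(list(self.factors)
                          + ([":".join(self.factors)] if self.interaction else [])
                          + list(self.covariates))
        kind = "MANCOVA" if self.covariates else "MANOVA"
        return ManovaResults(terms, n, p, self.endog.columns,
                             f"{kind}: {desc}")


def manova_pillai(Y, data: pd.DataFrame, factors=("age_class", "source"),
                  interaction: bool = True) -> ManovaResults:
    """Two-way Pillai MANOVA of a CLR panel on age and source."""
    return CompositionalManova(Y, data, factors, interaction).fit()


def mancova_pillai(Y, data: pd.DataFrame, factor: str = "source",
                   covariate: str = "log_carbonyl",
                   interaction: bool = False) -> ManovaResults:
    """Pillai MANCOVA: one factor with a numeric covariate (log carbonyl)."""
    return CompositionalManova(Y, data, factors=(factor,), interaction=interaction,
                               covariates=(covariate,)).fit()


# ---------------------------------------------------------------------------
# rank-based tests and corrections


def adjust_pvalues(p, method: str) -> np.ndarray:
    """Multiple-testing adjustment: bonferroni, bh (FDR) or by (FDR under
    dependence).  Step-up methods enforce monotonicity and cap at 1."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method in ("bh", "by"):
        order = np.argsort(p, kind="stable")
        ranked = p[order]
        scale = m / np.arange(1, m + 1)
        if method == "by":
            scale = scale * np.sum(1.0 / np.arange(1, m + 1))
        adj = ranked * scale
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        out = np.empty(m)
        out[order] = adj
        return out
    raise ValueError(f"unknown adjustment method {method!r}")


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null enumeration when both samples have n <= 8 and there are no
    ties; tie-corrected normal approximation otherwise.  Returns
    (rank-sum statistic W of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # all observations identical: no evidence either way
        w = x.size * (pooled.size + 1) / 2.0
        return w, 1.0
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank sum
    return w, float(res.pvalue)


class RankTestResults:
    """Per-taxon Wilcoxon old-vs-young comparison with corrections."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    def significant(self, alpha: float = 0.05, column: str = "p_bh") -> list[str]:
        return self.frame.index[self.frame[column] <= alpha].tolist()

    def summary(self) -> str:
        return ("Wilcoxon rank-sum by taxon (old vs young)\n"
                + self.frame.to_string(float_format=lambda v: f"{v:.4g}"))


def wilcoxon_by_taxon(values: pd.DataFrame, groups,
                      old_label="old", young_label="young") -> RankTestResults:
    """Wilcoxon rank-sum per taxon comparing two age classes.

    ``values`` is samples x taxa (normalized cell abundances by default);
    ``groups`` a per-sample label vector.  Bonferroni, Benjamini-Hochberg
    and Benjamini-Yekutieli adjusted p-values accompany the raw ones.
    """
    groups = np.asarray(groups)
    old = values.loc[groups == old_label]
    young = values.loc[groups == young_label]
    stats_w, pvals = [], []
    for taxon in values.columns:
        w, p = wilcoxon_rank_sum(old[taxon].to_numpy(), young[taxon].to_numpy())
        stats_w.append(w)
        pvals.append(p)
    pvals = np.asarray(pvals)
    frame = pd.DataFrame({
        "W": stats_w,
        "p_raw": pvals,
        "p_bonferroni": adjust_pvalues(pvals, "bonferroni"),
        "p_bh": adjust_pvalues(pvals, "bh"),
        "p_by": adjust_pvalues(pvals, "by"),
    }, index=values.columns)
    return RankTestResults(frame)


def pairwise_posthoc(Y: pd.DataFrame, grouping) -> pd.DataFrame:
    """Tukey HSD pairwise contrasts per response across >= 2 cohorts.

    Groups of size 1 are excluded with a warning.  Returns a tidy frame
    (response, group_a, group_b, mean_diff, p_adj).
    """
    grouping = np.asarray(grouping)
    labels = [g for g in pd.unique(grouping)]
    sizes = {g: int((grouping == g).sum()) for g in labels}
    kept = [g for g in labels if sizes[g] >= 2]
    for g in labels:
        if sizes[g] < 2:
            logger.warning("group %r has a single member; excluded from "
                           "post hoc contrasts", g)
    if len(kept) < 2:
        raise ValueError("need at least two groups of size >= 2")
    rows = []
    for col in Y.columns:
        samples = [Y.loc[grouping == g, col].to_numpy() for g in kept]
        res = stats.tukey_hsd(*samples)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                rows.append({
                    "response": col,
                    "group_a": kept[i],
                    "group_b": kept[j],
                    "mean_diff": float(np.mean(samples[i]) - np.mean(samples[j])),
                    "p_adj": float(res.pvalue[i, j]),
                })
    return pd.DataFrame(rows)


def pearson_clr_carbonyl(Z: pd.DataFrame, log_carbonyl) -> pd.DataFrame:
    """Independent Pearson correlations of per-taxon CLR scores with log
    carbonyl.  Zero-variance inputs yield NaN with a warning."""
    y = np.asarray(log_carbonyl, dtype=float)
    if y.size != len(Z):
        raise ValueError("carbonyl vector length mismatch")
    if y.size < 3:
        raise ValueError("need n >= 3 for a correlation test")
    rows = {}
    y_const = np.ptp(y) == 0
    for taxon in Z.columns:
        x = Z[taxon].to_numpy(dtype=float)
        if np.ptp(x) == 0 or y_const:
            logger.warning("zero-variance input for %r; correlation undefined",
                           taxon)
            rows[taxon] = {"r": np.nan, "p": np.nan}
            continue
        r, p = stats.pearsonr(x, y)
        rows[taxon] = {"r": float(r), "p": float(p)}
    return pd.DataFrame(rows).T
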