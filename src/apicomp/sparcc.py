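"""From-scratch SparCC: basis correlations from compositional count data.

Read counts only carry relative information, so ordinary correlations of
proportions are confounded by the closure.  SparCC estimates correlations of
the unobserved basis (absolute) abundances from the log-ratio variance
matrix

    t_ij = var(log(x_i / x_j)) = w_i + w_j - 2 rho_ij sqrt(w_i w_j)

by assuming the average correlation is small: dropping the rho terms when
summing t_ij over j gives a linear system for the basis variances w, from
which rho follows pair by pair.  Strongly correlated pairs violate the
sparsity assumption, so the estimator iteratively excludes the most
correlated pair above a threshold and re-solves.

A bootstrap of column-wise count shuffles provides two-sided pseudo
p-values, and a reliability flag trips when the count panel exceeds 70%
zeros, the regime in which SparCC output is considered unreliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Zero-fraction above which SparCC estimates are flagged unreliable.
SPARSITY_LIMIT = 0.70

_EPS_VARIANCE = 1e-10


def sparsity_fraction(counts) -> float:
    """Fraction of zero entries in a samples x taxa count panel."""
    arr = np.asarray(counts)
    return float((arr == 0).mean())


def _fractions(counts: np.ndarray) -> np.ndarray:
    """Component fractions under the Dirichlet posterior with an add-one
    prior: the posterior mean (counts + 1) / (total + D)."""
    counts = np.asarray(counts, dtype=float)
    a = counts + 1.0
    return a / a.sum(axis=1, keepdims=True)


def log_ratio_variances(fractions: np.ndarray) -> np.ndarray:
    """t_ij = var(log(x_i / x_j)) over samples; symmetric, zero diagonal."""
    logf = np.log(fractions)
    d = fractions.shape[1]
    t = np.empty((d, d))
    var = logf.var(axis=0, ddof=1)
    cov = np.cov(logf.T, ddof=1)
    for i in range(d):
        t[i] = var[i] + var - 2.0 * cov[i]
    np.fill_diagonal(t, 0.0)
    return np.clip(t, 0.0, None)


def basis_solution(t: np.ndarray,
                   excluded: set[tuple[int, int]] | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Solve for basis variances and correlations given t (and exclusions).

    With no exclusions this is the closed-form basic SparCC estimate:
    M w = t_row where M = (D-2) I + 11'.
    """
    d = t.shape[0]
    if d < 4:
        raise ValueError("need at least 4 taxa to solve the basis system")
    M = np.ones((d, d)) + np.eye(d) * (d - 2.0)
    t_eff = t.copy()
    if excluded:
        for i, j in excluded:
            M[i, i] -= 1.0
            M[j, j] -= 1.0
            M[i, j] -= 1.0
            M[j, i] -= 1.0
            t_eff[i, j] = 0.0
            t_eff[j, i] = 0.0
    w = np.linalg.solve(M, t_eff.sum(axis=1))
    n_clip = int((w <= 0).sum())
    if n_clip:
        logger.warning("%d negative basis variance estimate(s) clipped", n_clip)
    w = np.maximum(w, _EPS_VARIANCE)
    sw = np.sqrt(w)
    rho = (w[:, None] + w[None, :] - t) / (2.0 * np.outer(sw, sw))
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho, w


@dataclass
class SparccResults:
    """Basis correlation estimates with bootstrap pseudo p-values."""

    rho: pd.DataFrame
    omega: pd.Series
    t: pd.DataFrame
    pseudo_p: pd.DataFrame | None
    sparsity_fraction: float
    reliability_flag: bool
    n_excluded_pairs: int = 0

    def edges(self, p_max: float = 0.05, rho_min: float = 0.0) -> pd.DataFrame:
        """Tidy edge list (taxon_a, taxon_b, rho, p) filtered by thresholds."""
        taxa = self.rho.index.tolist()
        rows = []
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                r = self.rho.iloc[i, j]
                p = self.pseudo_p.iloc[i, j] if self.pseudo_p is not None else np.nan
                if abs(r) >= rho_min and (np.isnan(p) or p <= p_max):
                    rows.append({"taxon_a": taxa[i], "taxon_b": taxa[j],
                                 "rho": r, "p": p})
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p"])

    def summary(self) -> str:
        off = self.rho.to_numpy()[np.triu_indices(len(self.rho), 1)]
        lines = [
            f"SparCC basis correlations over {len(self.rho)} taxa",
            f"off-diagonal rho: min {off.min():.3f}, max {off.max():.3f}",
            f"panel sparsity: {self.sparsity_fraction:.1%}"
            + ("  [UNRELIABLE: >70% zeros]" if self.reliability_flag else ""),
        ]
        return "\n".join(lines)


class SparCC:
    """SparCC estimator over a samples x taxa count panel."""

    def __init__(self, counts, n_inner_iter: int = 20,
                 exclusion_threshold: float = 0.1):
        if isinstance(counts, pd.DataFrame):
            self.taxa = counts.columns.tolist()
            counts = counts.to_numpy()
        else:
            counts = np.asarray(counts)
            self.taxa = [f"t{i}" for i in range(counts.shape[1])]
        if counts.ndim != 2 or counts.shape[1] < 4:
            raise ValueError("need a 2-D panel with >= 4 taxa")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.n_inner_iter = n_inner_iter
        self.exclusion_threshold = exclusion_threshold

    def _estimate(self, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
        f = _fractions(counts)
        t = log_ratio_variances(f)
        d = t.shape[0]
        excluded: set[tuple[int, int]] = set()
        rho, w = basis_solution(t)
        for _ in range(self.n_inner_iter):
            masked = np.abs(rho).copy()
            np.fill_diagonal(masked, 0.0)
            for i, j in excluded:
                masked[i, j] = masked[j, i] = 0.0
            i, j = np.unravel_index(np.argmax(masked), masked.shape)
            if masked[i, j] <= self.exclusion_threshold:
                break
            excluded.add((min(i, j), max(i, j)))
            # stop before the system degenerates: every taxon must keep
            # at least 3 partners
            partners = np.full(d, d - 1)
            for a, b in excluded:
                partners[a] -= 1
                partners[b] -= 1
            if (partners < 3).any():
                logger.warning("exclusion would leave a taxon with < 3 "
                               "partners; stopping with partial refinement")
                excluded.discard((min(i, j), max(i, j)))
                break
            rho, w = basis_solution(t, excluded)
        return rho, w, t, len(excluded)

    def fit(self, n_boot: int = 100, seed: int | None = None) -> SparccResults:
        """Estimate basis correlations; bootstrap pseudo-p with ``n_boot``
        column-wise shuffles (``n_boot=0`` skips the bootstrap)."""
        rho, w, t, n_excl = self._estimate(self.counts)
        pseudo_p = None
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            exceed = np.ones_like(rho)  # observed counts once
            n, d = self.counts.shape
            for _ in range(n_boot):
                shuffled = np.empty_like(self.counts)
                for j in range(d):
                    shuffled[:, j] = self.counts[rng.permutation(n), j]
                rho_b, _, _, _ = self._estimate(shuffled)
                exceed += (np.abs(rho_b) >= np.abs(rho)).astype(float)
            pvals = exceed / (1.0 + n_boot)
            np.fill_diagonal(pvals, np.nan)
            pseudo_p = pd.DataFrame(pvals, index=self.taxa, columns=self.taxa)
        frac = sparsity_fraction(self.counts)
        return SparccResults(
            rho=pd.DataFrame(rho, index=self.taxa, columns=self.taxa),
            omega=pd.Series(w, index=self.taxa),
            t=pd.DataFrame(t, index=self.taxa, columns=self.taxa),
            pseudo_p=pseudo_p,
            sparsity_fraction=frac,
            reliability_flag=frac > SPARSITY_LIMIT,
            n_excluded_pairs=n_excl,
        )


def sparcc(counts, n_inner_iter: int = 20, exclusion_threshold: float = 0.1,
           n_boot: int = 100, seed: int | None = None) -> SparccResults:
    """One-call SparCC with the reference defaults."""
    return SparCC(counts, n_inner_iter, exclusion_threshold).fit(n_boot, seed)
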