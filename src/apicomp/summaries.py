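"""Community summaries: prevalence/specificity calls, whole-gut projection,
alpha diversity and rarefaction."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import OtuTable

logger = logging.getLogger(__name__)

PREVALENCE_DEFINITIONS = ("rel_abund_ge_0.5pct", "reads_ge_2")

#: Prevalence cut-off for the caste-specificity rule.
SPECIFICITY_PREVALENCE = 0.5
#: Relative-abundance detection threshold (0.5%) behind that rule.
SPECIFICITY_ABUNDANCE = 0.005


def prevalence(counts: pd.DataFrame,
               definition: str = "rel_abund_ge_0.5pct") -> pd.Series:
    """Per-taxon fraction of samples in which the taxon is "present".

    Presence is either relative abundance >= 0.5% of the sample's reads or
    at least two reads in the library; exact ties count as present.
    """
    if counts.empty:
        raise ValueError("empty count table")
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("samples with zero reads; drop them first")
    if definition == "rel_abund_ge_0.5pct":
        hits = counts.div(totals, axis=0) >= SPECIFICITY_ABUNDANCE
    elif definition == "reads_ge_2":
        hits = counts >= 2
    else:
        raise ValueError(
            f"unknown prevalence definition {definition!r}; "
            f"choose from {PREVALENCE_DEFINITIONS}")
    return hits.mean(axis=0)


@dataclass
class SpecificityCall:
    """Caste-specificity of one taxon from worker and queen prevalences."""

    taxon: str
    worker_prevalence: float
    queen_prevalence: float
    call: str


def classify_specificity(worker_prev: float, queen_prev: float,
                         threshold: float = SPECIFICITY_PREVALENCE,
                         taxon: str = "") -> SpecificityCall:
    """Four-way caste call from the 50%-prevalence rule.

    worker_specific iff worker >= threshold > queen; queen_specific is the
    mirror image; shared iff both reach the threshold; rare otherwise.
    """
    for name, v in (("worker", worker_prev), ("queen", queen_prev)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} prevalence must be in [0, 1], got {v}")
    w = worker_prev >= threshold
    q = queen_prev >= threshold
    call = {(True, True): "shared", (True, False): "worker_specific",
            (False, True): "queen_specific", (False, False): "rare"}[(w, q)]
    return SpecificityCall(taxon, worker_prev, queen_prev, call)


def specificity_table(worker_counts: pd.DataFrame, queen_counts: pd.DataFrame,
                      threshold: float = SPECIFICITY_PREVALENCE) -> pd.DataFrame:
    """Specificity calls for the taxa shared between two caste tables."""
    taxa = [t for t in worker_counts.columns if t in queen_counts.columns]
    wp = prevalence(worker_counts[taxa])
    qp = prevalence(queen_counts[taxa])
    rows = [classify_specificity(wp[t], qp[t], threshold, t) for t in taxa]
    return pd.DataFrame(
        {"worker_prevalence": [r.worker_prevalence for r in rows],
         "queen_prevalence": [r.queen_prevalence for r in rows],
         "call": [r.call for r in rows]},
        index=pd.Index(taxa, name="taxon"))


def whole_gut_projection(cells_by_niche: dict[str, pd.Series]) -> pd.Series:
    """Expected whole-gut relative abundance for one queen.

    Sums tissue-specific bacterial cell counts across the queen's niches and
    renormalises, emulating what sequencing the entire gut at once would
    return.  Missing niches are skipped with a warning.
    """
    available = {n: s for n, s in cells_by_niche.items() if s is not None}
    if not available:
        raise ValueError("queen has no niche profiles")
    if len(available) < len(cells_by_niche):
        missing = sorted(set(cells_by_niche) - set(available))
        logger.warning("missing niche(s) %s; projecting over the rest", missing)
    frame = pd.DataFrame(available)
    total = frame.to_numpy().sum()
    if not total > 0:
        raise ValueError("queen has zero total cells")
    return frame.sum(axis=1) / total


def whole_gut_table(cells: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Whole-gut projection for every queen in a normalized cell table.

    ``cells`` is sample-indexed (one row per queen x niche); ``metadata``
    supplies ``queen_id`` and ``niche`` per sample.
    """
    out = {}
    for queen, sample_ids in metadata.groupby("queen_id").groups.items():
        ids = [s for s in sample_ids if s in cells.index]
        profiles = {metadata.loc[s, "niche"]: cells.loc[s] for s in ids}
        out[queen] = whole_gut_projection(profiles)
    return pd.DataFrame(out).T.rename_axis("queen_id")


# ---------------------------------------------------------------------------
# alpha diversity


def alpha_diversity(counts_row) -> dict[str, float]:
    """Observed richness, Shannon entropy (nats) and inverse Simpson."""
    x = np.asarray(counts_row, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if not total > 0:
        raise ValueError("empty sample")
    p = x[x > 0] / total
    return {
        "observed_otus": int((x > 0).sum()),
        "shannon": float(-(p * np.log(p)).sum()),
        "inv_simpson": float(1.0 / (p ** 2).sum()),
    }


def alpha_diversity_table(table: OtuTable) -> pd.DataFrame:
    rows = {s: alpha_diversity(table.counts.loc[s]) for s in table.sample_ids}
    return pd.DataFrame(rows).T.rename_axis("sample_id")


def rarefaction_curve(counts_row, depths, mode: str = "exact",
                      seed: int | None = None,
                      n_draws: int = 1000) -> pd.Series:
    """Expected OTU richness at each subsampling depth.

    ``exact`` uses the hypergeometric expectation
    E[S_d] = sum_i (1 - C(N - N_i, d) / C(N, d)); ``monte_carlo`` averages
    observed richness over ``n_draws`` random subsamples without
    replacement.  Depths beyond the library size give NaN in exact mode.
    """
    x = np.asarray(counts_row, dtype=np.int64)
    N = int(x.sum())
    if N <= 0:
        raise ValueError("empty sample")
    depths = np.asarray(depths, dtype=np.int64)
    out = np.empty(depths.size, dtype=float)
    if mode == "exact":
        logC_N = gammaln(N + 1)
        for k, d in enumerate(depths):
            if d > N:
                out[k] = np.nan
                continue
            # log [C(N - N_i, d) / C(N, d)] for each taxon, -inf when N-N_i < d
            terms = np.zeros(x.size)
            for i, ni in enumerate(x):
                if ni == 0:
                    terms[i] = 0.0  # absent taxa contribute nothing
                    continue
                if N - ni < d:
                    terms[i] = 1.0
                else:
                    lr = (gammaln(N - ni + 1) - gammaln(d + 1) - gammaln(N - ni - d + 1)
                          - (logC_N - gammaln(d + 1) - gammaln(N - d + 1)))
                    terms[i] = 1.0 - np.exp(lr)
            out[k] = terms[x > 0].sum()
    elif mode == "monte_carlo":
        rng = np.random.default_rng(seed)
        pool = np.repeat(np.arange(x.size), x)
        for k, d in enumerate(depths):
            if d > N:
                out[k] = np.nan
                continue
            richness = np.empty(n_draws)
            for b in range(n_draws):
                sub = rng.choice(pool, size=int(d), replace=False)
                richness[b] = np.unique(sub).size
            out[k] = richness.mean()
    else:
        raise ValueError("mode must be 'exact' or 'monte_carlo'")
    return pd.Series(out, index=depths, name="expected_richness")
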