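"""Config-driven orchestration: simulate -> normalize -> analyze -> report.

A :class:`RunConfig` either points at input files (counts, metadata, qPCR,
copy numbers, carbonyl) or carries a simulation block; :func:`run_pipeline`
executes the full analysis and writes a deterministic TSV report bundle plus
a run log recording every analysis decision (normalization convention,
pseudocount, metric, permutation counts, seeds), so reruns with the same
config and seed are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as io_mod
from .carbonyl import carbonyl_table, log_carbonyl
from .multivariate import (manova_pillai, mancova_pillai, pearson_clr_carbonyl,
                           wilcoxon_by_taxon)
from .normalize import (clr_from_cells, normalize_study, percent_change_with_age,
                        select_panel, copy_corrected_proportions)
from .ordination import anosim, distance, distlm, pca_clr
from .simulate import StudyConfig, generate_study
from .sparcc import SparCC
from .summaries import alpha_diversity_table, prevalence, whole_gut_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Everything a full pipeline run needs.

    Either ``simulate`` (a :class:`StudyConfig`) or the five input paths
    must be given.  ``seed`` is mandatory whenever any stochastic stage runs
    (simulation or permutation tests).
    """

    simulate: StudyConfig | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    qpcr_path: str | None = None
    copy_numbers_path: str | None = None
    carbonyl_path: str | None = None
    panel_core: int = 9
    panel_anosim: int = 37
    panel_sparcc: int = 200
    n_perm: int = 9999
    sparcc_boot: int = 100
    seed: int | None = None
    correction: str = "bh"
    metric: str = "bray_curtis"
    convention: str = "divide"
    pseudocount_reads: float = 0.5
    out_dir: str = "results"

    def __post_init__(self) -> None:
        stochastic = self.simulate is not None or self.n_perm > 0 \
            or self.sparcc_boot > 0
        if stochastic and self.seed is None:
            raise ValueError("seed is required when stochastic stages run")
        if self.simulate is None and not (
                self.counts_path and self.metadata_path and self.qpcr_path):
            raise ValueError("provide either a simulation block or input paths")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as err:
                raise PipelineError(f"stage {name!r} failed: {err}") from err
        return wrapper
    return deco


def _stage_seed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2 ** 31))


@_stage("load")
def _load_inputs(cfg: RunConfig) -> dict:
    if cfg.simulate is not None:
        return generate_study(cfg.simulate)
    table = io_mod.read_otu_table(cfg.counts_path)
    meta = io_mod.read_metadata(cfg.metadata_path)
    table = table.with_metadata(meta)
    qpcr = io_mod.read_qpcr(cfg.qpcr_path)
    copies = (io_mod.read_copy_numbers(cfg.copy_numbers_path)
              if cfg.copy_numbers_path else io_mod.CopyNumberMap())
    carbonyl = None
    if cfg.carbonyl_path:
        carbonyl = carbonyl_table(io_mod.read_carbonyl(cfg.carbonyl_path))
    return {"otu_table": table, "metadata": table.metadata, "qpcr": qpcr,
            "copy_numbers": copies, "carbonyl": carbonyl}


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run the whole analysis; returns {table name: written path}."""
    study = _load_inputs(cfg)
    table = study["otu_table"]
    table, excluded = table.drop_empty_samples()
    meta = table.metadata
    qpcr = study["qpcr"]
    copies = study["copy_numbers"]
    carbonyl = study["carbonyl"]

    n_otus = len(table.otu_ids)
    panel_core = min(cfg.panel_core, n_otus)
    panel_anosim = min(cfg.panel_anosim, n_otus)
    panel_sparcc = min(cfg.panel_sparcc, n_otus)
    for name, want, got in (("core", cfg.panel_core, panel_core),
                            ("anosim", cfg.panel_anosim, panel_anosim),
                            ("sparcc", cfg.panel_sparcc, panel_sparcc)):
        if got < want:
            logger.warning("panel %s clipped from %d to %d available OTUs",
                           name, want, got)

    tables: dict[str, pd.DataFrame] = {}
    log_lines = [
        "apicomp pipeline run",
        f"seed: {cfg.seed}",
        f"samples retained: {len(table.sample_ids)} "
        f"(excluded zero-read: {excluded})",
        f"normalization convention: {cfg.convention}; "
        f"proportions over all reads; pooled-OTU copy number "
        f"{copies.default_mean}",
        f"CLR pseudocount: {cfg.pseudocount_reads} read equivalent "
        "(multiplicative replacement)",
        f"panels: core {panel_core}, anosim/distlm {panel_anosim}, "
        f"sparcc {panel_sparcc}",
        f"distance metric: {cfg.metric} on copy-corrected relative abundance",
        f"permutations: {cfg.n_perm}; sparcc bootstraps: {cfg.sparcc_boot}",
        f"multiple-testing correction reported as q: {cfg.correction}",
    ]

    # --- normalization ---------------------------------------------------
    cells = _run_normalize(table, qpcr, copies, panel_core, cfg)
    clr = clr_from_cells(cells, table, cfg.pseudocount_reads)
    named_panel = [t for t in cells.panel if t != "other"]

    # --- carbonyl covariate ----------------------------------------------
    log_carb_by_queen = None
    if carbonyl is not None:
        log_carb_by_queen = pd.Series(
            log_carbonyl(carbonyl["carbonyl_nmol_per_mg"].to_numpy()),
            index=carbonyl.index)
        tables["carbonyl"] = carbonyl[
            ["A345", "path_cm", "volume_ul", "protein_mg",
             "carbonyl_nmol_per_mg"]]

    # --- per-niche statistics --------------------------------------------
    niche_stats, mancova_rows, ord_rows, score_frames = [], [], [], []
    for niche in io_mod.NICHES:
        ids = meta.index[meta["niche"] == niche]
        ids = [s for s in ids if s in cells.cells.index]
        if len(ids) < 8:
            logger.warning("niche %r has %d samples; skipped", niche, len(ids))
            continue
        sub_meta = meta.loc[ids]
        sub_cells = cells.cells.loc[ids]
        sub_clr = clr.z.loc[ids]
        niche_stats.append(_niche_table(
            niche, sub_cells, sub_clr, sub_meta, named_panel, cfg))
        if log_carb_by_queen is not None:
            mancova_rows.append(_niche_mancova(
                niche, sub_clr, sub_meta, named_panel, log_carb_by_queen))
            scores = _niche_ordination(
                niche, table, sub_meta, copies, panel_anosim, cfg,
                log_carb_by_queen, sub_clr, named_panel, ord_rows)
            score_frames.append(scores)
    tables["niche_stats"] = pd.concat(niche_stats, ignore_index=True)
    if mancova_rows:
        tables["mancova_pearson"] = pd.concat(mancova_rows, ignore_index=True)
    if ord_rows:
        tables["anosim_distlm"] = pd.DataFrame(ord_rows)
    if score_frames:
        tables["pca_scores"] = pd.concat(score_frames)

    # --- SparCC per niche -------------------------------------------------
    tables["sparcc_edges"] = _run_sparcc(table, meta, panel_sparcc, cfg)

    # --- whole-gut projection + specificity + alpha diversity -------------
    whole = whole_gut_table(cells.cells, meta)
    tables["whole_gut"] = whole
    tables["specificity"] = _age_specificity(whole, meta)
    tables["alpha_diversity"] = alpha_diversity_table(table)

    written = io_mod.write_results(tables, cfg.out_dir)
    log_path = Path(cfg.out_dir) / "run_log.txt"
    log_path.write_text("\n".join(log_lines) + "\n")
    out = {p.stem: p for p in written}
    out["run_log"] = log_path
    return out


@_stage("normalize")
def _run_normalize(table, qpcr, copies, panel_core, cfg):
    return normalize_study(table, qpcr, copies, panel=panel_core,
                           convention=cfg.convention,
                           pseudocount_reads=cfg.pseudocount_reads)


@_stage("niche_stats")
def _niche_table(niche, sub_cells, sub_clr, sub_meta, named_panel, cfg):
    """Table-1-style per-niche frame: abundance class, percent change,
    Wilcoxon q, MANOVA age F/p."""
    age = sub_meta["age_class"].to_numpy()
    wt = wilcoxon_by_taxon(sub_cells[named_panel], age).frame
    man = manova_pillai(sub_clr[named_panel], sub_meta).terms["age_class"]
    rel = sub_cells.div(sub_cells.sum(axis=1), axis=0)
    rows = []
    for taxon in named_panel:
        mean_old = sub_cells.loc[age == "old", taxon].mean()
        mean_young = sub_cells.loc[age == "young", taxon].mean()
        rows.append({
            "niche": niche,
            "taxon": taxon,
            "abundance_class": "H" if rel[taxon].mean() >= 0.01 else "L",
            "percent_change": percent_change_with_age(mean_old, mean_young),
            "wilcoxon_q": wt.loc[taxon, f"p_{cfg.correction}"],
            "manova_age_F": man.f_value,
            "manova_age_p": man.p_value,
        })
    return pd.DataFrame(rows)


@_stage("mancova_pearson")
def _niche_mancova(niche, sub_clr, sub_meta, named_panel, log_carb_by_queen):
    data = sub_meta.copy()
    data["log_carbonyl"] = log_carb_by_queen.loc[data["queen_id"]].to_numpy()
    res = mancova_pillai(sub_clr[named_panel], data, factor="source",
                         covariate="log_carbonyl")
    pear = pearson_clr_carbonyl(sub_clr[named_panel],
                                data["log_carbonyl"].to_numpy())
    cov = res.terms["log_carbonyl"]
    fac = res.terms["source"]
    rows = []
    for taxon in named_panel:
        rows.append({
            "niche": niche, "taxon": taxon,
            "pearson_r": pear.loc[taxon, "r"],
            "pearson_p": pear.loc[taxon, "p"],
            "mancova_source_V": fac.statistic, "mancova_source_p": fac.p_value,
            "mancova_carbonyl_V": cov.statistic,
            "mancova_carbonyl_p": cov.p_value,
        })
    return pd.DataFrame(rows)


@_stage("ordination")
def _niche_ordination(niche, table, sub_meta, copies, panel_anosim, cfg,
                      log_carb_by_queen, sub_clr, named_panel, ord_rows):
    """ANOSIM + DistLM on the top-37 panel; CLR-PCA scores for the biplot."""
    ids = sub_meta.index
    top = select_panel(table, panel_anosim)
    counts = table.counts.loc[ids, top].to_numpy(dtype=float)
    keep = counts.sum(axis=1) > 0
    counts, kept_ids = counts[keep], ids[keep]
    props = counts / counts.sum(axis=1, keepdims=True)
    q = copy_corrected_proportions(props, copies.vector(top))
    dm = distance(q, cfg.metric, ids=list(kept_ids))
    km = sub_meta.loc[kept_ids]
    carb = log_carb_by_queen.loc[km["queen_id"]].to_numpy()
    niche_idx = list(io_mod.NICHES).index(niche)
    for fi, factor in enumerate(("age_class", "source")):
        res = anosim(dm, km[factor].to_numpy(), cfg.n_perm,
                     _stage_seed(cfg.seed, 100 + 10 * niche_idx + fi))
        ord_rows.append({"niche": niche, "test": "anosim", "factor": factor,
                         "statistic": res.R, "p": res.p_value,
                         "R2": np.nan, "n_perm": cfg.n_perm})
    dres = distlm(dm, carb, cfg.n_perm,
                  _stage_seed(cfg.seed, 200 + niche_idx))
    ord_rows.append({"niche": niche, "test": "distlm", "factor": "log_carbonyl",
                     "statistic": dres.pseudo_f, "p": dres.p_value,
                     "R2": dres.r_squared, "n_perm": cfg.n_perm})
    pca = pca_clr(sub_clr[named_panel], carbonyl=log_carb_by_queen.loc[
        sub_meta["queen_id"]].to_numpy())
    scores = pca.scores[["PC1", "PC2"]].copy()
    scores.insert(0, "niche", niche)
    scores["pc1_var"] = pca.explained_variance_ratio[0]
    scores["pc2_var"] = pca.explained_variance_ratio[1]
    return scores


@_stage("sparcc")
def _run_sparcc(table, meta, panel_sparcc, cfg):
    top = select_panel(table, panel_sparcc)
    frames = []
    for k, niche in enumerate(io_mod.NICHES):
        ids = meta.index[meta["niche"] == niche]
        if len(ids) < 8:
            continue
        panel_counts = table.counts.loc[ids, top]
        res = SparCC(panel_counts).fit(
            n_boot=cfg.sparcc_boot, seed=_stage_seed(cfg.seed, 500 + k))
        edges = res.edges(p_max=0.05, rho_min=0.2)
        edges.insert(0, "niche", niche)
        edges["unreliable"] = res.reliability_flag
        frames.append(edges)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["niche", "taxon_a", "taxon_b", "rho", "p", "unreliable"])


@_stage("specificity")
def _age_specificity(whole: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Prevalence/specificity of whole-gut profiles between the two age
    classes (the within-study analogue of the longevity-phenotype rule)."""
    from .summaries import classify_specificity
    age_by_queen = meta.drop_duplicates("queen_id").set_index("queen_id")[
        "age_class"]
    old = whole.loc[age_by_queen.loc[whole.index] == "old"]
    young = whole.loc[age_by_queen.loc[whole.index] == "young"]
    po = prevalence(old)
    py = prevalence(young)
    rows = []
    for taxon in whole.columns:
        call = classify_specificity(po[taxon], py[taxon], taxon=taxon)
        rows.append({"taxon": taxon, "old_prevalence": po[taxon],
                     "young_prevalence": py[taxon],
                     "call": call.call.replace("worker", "old")
                                      .replace("queen", "young")})
    return pd.DataFrame(rows).set_index("taxon")
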