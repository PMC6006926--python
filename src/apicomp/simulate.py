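"""Synthetic study generator emulating the 63-queen x 4-niche sampling design.

The generator produces complete studies — OTU read counts, per-sample qPCR
community sizes, sample metadata and per-queen fat-body carbonyl assays —
with the statistical structure the downstream analysis assumes:

* counts per sample are Dirichlet-multinomial around an effect-shifted niche
  base composition (overdispersed, compositional, dominated by a handful of
  conspicuous phylotypes);
* qPCR totals are lognormal around the niche community-size means
  (mouth 1.4 M, midgut 14.2 M, ileum 17.9 M, rectum 121.2 M gene copies);
* low-abundance "other" OTUs form a sparse power-law tail of rare taxa;
* carbonyl (biological age) is an age-class mean plus a source shift plus
  optional per-taxon CLR-linked terms plus Gaussian noise, truncated at zero.

Every injected effect is recorded in a ``truth`` dictionary so recovery tests
can check estimates against what was simulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import NICHES, AGE_CLASSES, OtuTable, QpcrTable, CopyNumberMap

logger = logging.getLogger(__name__)

#: Short ids of the nine conspicuous OTUs, ranked by overall read totals.
TAXA = (
    "firm5", "apium", "kunkeei", "firm4", "alpha21",
    "asteroides", "alvi", "apicola", "delftia",
)

OTHER = "other"

SOURCES = ("CA", "AZ")

# Niche base compositions over the nine named OTUs plus the pooled rare
# fraction.  Mouth and midgut are dominated (>95%) by P. apium and
# L. kunkeei; the hindgut (ileum, rectum) is Lactobacillus firm5-dominated
# with B. asteroides and firm4 increasing toward the rectum.
_BASE_COMPOSITION = {
    "mouth": {
        "apium": 0.70, "kunkeei": 0.195, "alpha21": 0.04, "firm5": 0.02,
        "delftia": 0.01, "firm4": 0.005, "asteroides": 0.005, "alvi": 0.005,
        "apicola": 0.003, OTHER: 0.017,
    },
    "midgut": {
        "apium": 0.55, "kunkeei": 0.30, "alpha21": 0.05, "firm5": 0.04,
        "firm4": 0.01, "asteroides": 0.012, "delftia": 0.008, "alvi": 0.005,
        "apicola": 0.002, OTHER: 0.023,
    },
    "ileum": {
        "firm5": 0.55, "apium": 0.15, "asteroides": 0.10, "firm4": 0.08,
        "alpha21": 0.06, "kunkeei": 0.02, "alvi": 0.015, "apicola": 0.005,
        "delftia": 0.005, OTHER: 0.015,
    },
    "rectum": {
        "firm5": 0.55, "firm4": 0.15, "asteroides": 0.12, "alpha21": 0.08,
        "apium": 0.04, "kunkeei": 0.02, "alvi": 0.012, "apicola": 0.005,
        "delftia": 0.003, OTHER: 0.02,
    },
}

# Directions follow the reported age succession: Acetobacteraceae
# (P. apium, Alpha 2.1) and Delftia decline with age while fermentative
# Lactobacillus/Bifidobacterium gain ground in the hindgut; mouth apium and
# midgut kunkeei accrue with age.
_AGE_LOG2_EFFECTS = {
    ("mouth", "apium"): 1.0,
    ("mouth", "delftia"): -2.0,
    ("midgut", "kunkeei"): 1.0,
    ("midgut", "alpha21"): -1.0,
    ("midgut", "delftia"): -2.0,
    ("ileum", "asteroides"): 1.0,
    ("ileum", "apium"): -1.0,
    ("ileum", "delftia"): -2.0,
    ("rectum", "asteroides"): 1.0,
    ("rectum", "apium"): -1.5,
    ("rectum", "alpha21"): -1.0,
}

_SOURCE_LOG2_EFFECTS = {
    ("mouth", "kunkeei"): 0.5,
    ("rectum", "firm4"): 0.5,
}


@dataclass
class CarbonylConfig:
    """Carbonyl (biological age) generating model, in nmol/mg protein."""

    young_mean: float = 4.0
    old_mean: float = 8.0
    source_shift: float = 1.0   # added for source CA (biologically older)
    sd: float = 1.5
    taxon_link: dict[str, float] = field(
        default_factory=lambda: {"asteroides": 0.8, "delftia": -0.8}
    )


@dataclass
class StudyConfig:
    """Complete parameterisation of a synthetic queen-microbiota study.

    Defaults mirror the real design: 16/16 young/old CA queens and 15/16
    young/old AZ queens (63 total), four niches per queen, niche community
    sizes and sequencing depths at the reported means.
    """

    n_queens_per_cell: dict = field(default_factory=lambda: {
        ("young", "CA"): 16, ("old", "CA"): 16,
        ("young", "AZ"): 15, ("old", "AZ"): 16,
    })
    niches: tuple = NICHES
    base_composition: dict = field(
        default_factory=lambda: {n: dict(c) for n, c in _BASE_COMPOSITION.items()}
    )
    age_log2_effects: dict = field(default_factory=lambda: dict(_AGE_LOG2_EFFECTS))
    source_log2_effects: dict = field(default_factory=lambda: dict(_SOURCE_LOG2_EFFECTS))
    #: Dirichlet concentration per niche; 80 gives the modest within-cohort
    #: spread implied by the study's detectability of ~2-fold shifts at
    #: half the design's group size.
    overdispersion: dict = field(default_factory=lambda: {n: 80.0 for n in NICHES})
    #: Expected reads per library (lognormal geometric mean), per niche.
    depth_mean: dict = field(default_factory=lambda: {
        "mouth": 21_000.0, "midgut": 25_000.0, "ileum": 30_000.0, "rectum": 38_000.0,
    })
    depth_log_sd: float = 0.2
    #: Expected total 16S gene copies per extraction (geometric mean).
    qpcr_mean: dict = field(default_factory=lambda: {
        "mouth": 1.4e6, "midgut": 14.2e6, "ileum": 17.9e6, "rectum": 121.2e6,
    })
    qpcr_log_sd: float = 0.25
    #: Number of rare OTUs the pooled "other" mass is split across.
    n_rare_otus: int = 51
    #: Power-law decay exponent for the rare tail weights; 0.5 keeps every
    #: rare OTU well below the ninth-ranked named OTU dataset-wide.
    rare_tail_exponent: float = 0.5
    carbonyl: CarbonylConfig = field(default_factory=CarbonylConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for niche, comp in self.base_composition.items():
            s = sum(comp.values())
            if abs(s - 1.0) > 1e-6:
                raise ValueError(f"composition for {niche!r} sums to {s}, not 1")
            if any(v < 0 for v in comp.values()):
                raise ValueError(f"negative proportion in {niche!r} composition")
        for niche, c in self.overdispersion.items():
            if not c > 0:
                raise ValueError(f"overdispersion for {niche!r} must be > 0")
        for niche, d in self.depth_mean.items():
            if not d >= 100:
                raise ValueError(f"depth_mean for {niche!r} must be >= 100")
        if not (self.depth_log_sd >= 0 and self.qpcr_log_sd >= 0):
            raise ValueError("log-sds must be >= 0")
        if not self.carbonyl.sd > 0:
            raise ValueError("carbonyl sd must be > 0")
        for niche, m in self.qpcr_mean.items():
            if not m > 0:
                raise ValueError(f"qpcr_mean for {niche!r} must be > 0")

    def null(self) -> "StudyConfig":
        """Copy of this config with every injected effect removed."""
        import copy
        cfg = copy.deepcopy(self)
        cfg.age_log2_effects = {}
        cfg.source_log2_effects = {}
        cfg.carbonyl.old_mean = cfg.carbonyl.young_mean
        cfg.carbonyl.source_shift = 0.0
        cfg.carbonyl.taxon_link = {}
        return cfg

    @property
    def otu_ids(self) -> list[str]:
        rare = [f"rare{i:03d}" for i in range(1, self.n_rare_otus + 1)]
        return list(TAXA) + rare

    def full_composition(self, niche: str, age_class: str = "young",
                         source: str = "AZ") -> np.ndarray:
        """Effect-shifted composition over all OTUs (named + rare tail).

        Age effects apply multiplicatively (2**log2) to the old class,
        source effects to the CA source, followed by renormalisation.
        The "other" mass is split across the rare tail with power-law
        weights, so rare taxa are individually tiny and, combined with the
        Dirichlet overdispersion, sparse across samples.
        """
        comp = self.base_composition[niche]
        named = np.array([comp.get(t, 0.0) for t in TAXA], dtype=float)
        if age_class == "old":
            for (n, t), eff in self.age_log2_effects.items():
                if n == niche and t in TAXA:
                    named[TAXA.index(t)] *= 2.0 ** eff
        if source == "CA":
            for (n, t), eff in self.source_log2_effects.items():
                if n == niche and t in TAXA:
                    named[TAXA.index(t)] *= 2.0 ** eff
        other_mass = comp.get(OTHER, 0.0)
        ranks = np.arange(1, self.n_rare_otus + 1, dtype=float)
        w = ranks ** -self.rare_tail_exponent
        rare = other_mass * w / w.sum() if self.n_rare_otus else np.array([])
        full = np.concatenate([named, rare])
        total = full.sum()
        if total <= 0:
            raise ValueError("composition has zero total mass after effects")
        return full / total


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_counts(config: StudyConfig, niche: str, age_class: str,
                    source: str, n_samples: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Dirichlet-multinomial counts (n_samples x OTUs) for one design cell."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    p = config.full_composition(niche, age_class, source)
    conc = config.overdispersion[niche]
    alpha = np.maximum(conc * p, 1e-12)
    depth_gm = config.depth_mean[niche]
    out = np.zeros((n_samples, p.size), dtype=np.int64)
    for i in range(n_samples):
        depth = int(round(depth_gm * np.exp(rng.normal(0.0, config.depth_log_sd))))
        if depth <= 0:
            raise ValueError("drawn sequencing depth must be positive")
        q = rng.dirichlet(alpha)
        s = q.sum()
        if not s > 0:
            raise ValueError("Dirichlet draw with zero mass")
        out[i] = rng.multinomial(depth, q / s)
    return out


def generate_qpcr(config: StudyConfig, niche: str, n_samples: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Lognormal qPCR totals with geometric mean at the niche mean."""
    mean = config.qpcr_mean[niche]
    return mean * np.exp(rng.normal(0.0, config.qpcr_log_sd, size=n_samples))


def generate_carbonyl(config: StudyConfig, queens: pd.DataFrame,
                      rng: np.random.Generator,
                      clr_scores: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-queen carbonyl assay records.

    ``queens`` has one row per queen with columns ``age_class`` and
    ``source``.  If ``clr_scores`` (queens x taxa CLR values) is given, the
    configured ``taxon_link`` slopes act through it.  Values are drawn as
    age-class mean + source shift + linked terms + Gaussian noise, truncated
    at zero; the absorbance that would have produced each value under the
    assay constants (1 cm path, 100 ul resuspension, 0.5 mg protein,
    epsilon = 22 mM^-1 cm^-1) is back-computed so the records round-trip
    through the assay arithmetic.
    """
    cb = config.carbonyl
    means = np.where(queens["age_class"] == "old", cb.old_mean, cb.young_mean)
    shift = np.where(queens["source"] == "CA", cb.source_shift, 0.0)
    linked = np.zeros(len(queens))
    if clr_scores is not None:
        for taxon, slope in cb.taxon_link.items():
            if taxon in clr_scores.columns:
                z = clr_scores.loc[queens.index, taxon].to_numpy()
                linked += slope * (z - z.mean())  # centered: adds covariance,
                # not a population-mean shift
    values = means + shift + linked + rng.normal(0.0, cb.sd, size=len(queens))
    n_trunc = int((values < 0).sum())
    if n_trunc:
        logger.warning("%d carbonyl draw(s) truncated at 0", n_trunc)
    values = np.maximum(values, 0.0)
    # invert carbonyl_per_mg: value = (A345 / (22*path)) * volume / protein
    path_cm, volume_ul, protein_mg = 1.0, 100.0, 0.5
    a345 = values * protein_mg * 22.0 * path_cm / volume_ul
    out = pd.DataFrame({
        "A345": a345,
        "path_cm": path_cm,
        "volume_ul": volume_ul,
        "protein_mg": protein_mg,
        "carbonyl_nmol_per_mg": values,
        "age_class": queens["age_class"].to_numpy(),
        "source": queens["source"].to_numpy(),
    }, index=queens.index)
    out.attrs["n_truncated"] = n_trunc
    return out


def generate_study(config: StudyConfig) -> dict:
    """Generate a full study: one sample per queen x niche.

    Returns a dict with keys ``otu_table`` (counts + metadata),
    ``qpcr`` (:class:`QpcrTable`), ``metadata``, ``carbonyl`` (per-queen
    frame), ``copy_numbers`` and ``truth`` (all injected effects).
    """
    rng = _rng(config.seed)

    # queen roster, deterministic order over design cells
    rows = []
    qi = 0
    for age_class in AGE_CLASSES:
        for source in SOURCES:
            n = config.n_queens_per_cell.get((age_class, source), 0)
            for _ in range(n):
                qi += 1
                rows.append({
                    "queen_id": f"Q{qi:03d}",
                    "age_class": age_class,
                    "source": source,
                    "age_months": 5.0 if age_class == "young" else 17.0,
                })
    queens = pd.DataFrame(rows).set_index("queen_id")

    otu_ids = config.otu_ids
    count_blocks, meta_rows, qpcr_vals, qpcr_ids = [], [], [], []
    for niche in config.niches:
        for age_class in AGE_CLASSES:
            for source in SOURCES:
                mask = (queens["age_class"] == age_class) & (queens["source"] == source)
                ids = queens.index[mask]
                if len(ids) == 0:
                    continue
                counts = generate_counts(config, niche, age_class, source, len(ids), rng)
                totals = generate_qpcr(config, niche, len(ids), rng)
                for k, qid in enumerate(ids):
                    sid = f"{qid}_{niche}"
                    meta_rows.append({
                        "sample_id": sid, "queen_id": qid, "niche": niche,
                        "age_class": age_class, "source": source,
                        "age_months": queens.loc[qid, "age_months"],
                    })
                    qpcr_ids.append(sid)
                    qpcr_vals.append(totals[k])
                count_blocks.append(counts)
    counts = pd.DataFrame(
        np.vstack(count_blocks),
        index=[r["sample_id"] for r in meta_rows],
        columns=otu_ids,
    )
    counts.index.name = "sample_id"
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    table = OtuTable(counts, metadata)
    qpcr = QpcrTable(pd.Series(qpcr_vals, index=pd.Index(qpcr_ids, name="sample_id"),
                               name="total_copies"))

    # carbonyl linkage acts through the queen's rectum CLR (the dominant
    # niche), computed from the same counts the analyst will see
    clr_scores = None
    if config.carbonyl.taxon_link:
        from .normalize import clr_transform
        rect = metadata.index[metadata["niche"] == "rectum"]
        if len(rect):
            sub = counts.loc[rect, list(TAXA)].to_numpy(dtype=float)
            z = clr_transform(sub, pseudocount=0.5)
            clr_scores = pd.DataFrame(
                z, index=metadata.loc[rect, "queen_id"], columns=list(TAXA))
    carbonyl = generate_carbonyl(config, queens, rng, clr_scores)

    truth = {
        "age_log2_effects": {f"{n}:{t}": e for (n, t), e in
                             config.age_log2_effects.items() if e != 0},
        "source_log2_effects": {f"{n}:{t}": e for (n, t), e in
                                config.source_log2_effects.items() if e != 0},
        "carbonyl": {
            "age_difference": config.carbonyl.old_mean - config.carbonyl.young_mean,
            "source_shift": config.carbonyl.source_shift,
            "taxon_link": dict(config.carbonyl.taxon_link),
        },
        "qpcr_mean": dict(config.qpcr_mean),
        "seed": config.seed,
    }
    return {
        "otu_table": table,
        "qpcr": qpcr,
        "metadata": metadata,
        "carbonyl": carbonyl,
        "copy_numbers": CopyNumberMap(),
        "truth": truth,
    }


def config_from_dict(d: dict) -> StudyConfig:
    """Build a StudyConfig from a (YAML-loaded) plain dict.

    Tuple-keyed maps are written in YAML as ``"age,source": n`` and
    ``"niche:taxon": effect`` strings.
    """
    d = dict(d)
    if "n_queens_per_cell" in d:
        d["n_queens_per_cell"] = {
            tuple(k.split(",")): int(v) for k, v in d["n_queens_per_cell"].items()
        }
    for key in ("age_log2_effects", "source_log2_effects"):
        if key in d:
            d[key] = {tuple(k.split(":")): float(v) for k, v in d[key].items()}
    if "niches" in d:
        d["niches"] = tuple(d["niches"])
    if "carbonyl" in d and isinstance(d["carbonyl"], dict):
        d["carbonyl"] = CarbonylConfig(**d["carbonyl"])
    return StudyConfig(**d)
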