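"""Readers, writers and validated containers for the tabular pipeline inputs.

Every downstream module consumes the containers defined here (:class:`OtuTable`,
:class:`CopyNumberMap`, :class:`QpcrTable`) rather than re-parsing files, so all
cross-file consistency checks live in one place.

Two OTU-table dialects are supported and auto-detected by header:

* mothur ``shared``-style TSV: ``label<TAB>Group<TAB>numOtus<TAB>Otu001 ...``
  with one row per sample (the ``Group`` column holds the sample id);
* plain CSV with a leading sample-id column and one column per OTU.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four alimentary-tract compartments sampled per queen.
NICHES = ("mouth", "midgut", "ileum", "rectum")

#: Chronological age classes (first-year vs second-year queens).
AGE_CLASSES = ("young", "old")

#: 16S rRNA gene copies per genome for the nine conspicuous gut phylotypes.
#: Core genomes carry four copies; L. kunkeei five, B. asteroides two,
#: P. apium one, and Acetobacteraceae Alpha 2.1 is assigned one after its
#: closest relative (P. apium).
DEFAULT_COPY_NUMBERS = {
    "firm5": 4.0,
    "firm4": 4.0,
    "apium": 1.0,
    "kunkeei": 5.0,
    "alpha21": 1.0,
    "asteroides": 2.0,
    "alvi": 4.0,
    "apicola": 4.0,
    "delftia": 4.0,
}

#: Mean copy number applied to the pooled low-abundance ("other") fraction.
DEFAULT_POOLED_COPY_NUMBER = 4.2

REQUIRED_METADATA_COLUMNS = ("queen_id", "niche", "age_class", "source", "age_months")


class FormatError(ValueError):
    """A file failed to parse in its declared dialect."""


@dataclass
class OtuTable:
    """Integer read counts (samples x OTUs) with per-sample metadata attached.

    Parameters
    ----------
    counts
        Non-negative integer matrix indexed by sample id, one column per OTU.
    metadata
        Per-sample records indexed by sample id with columns
        ``queen_id, niche, age_class, source, age_months``.  May be ``None``
        for a bare count table (e.g. straight after parsing, before the
        metadata join).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample id(s): {dupes}")
        if self.counts.columns.has_duplicates:
            dupes = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate OTU id(s): {dupes}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("counts must be numeric")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"OTU {self.counts.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(arr != np.round(arr))[0]
            raise FormatError(
                f"non-integer count at sample {self.counts.index[i]!r}, "
                f"OTU {self.counts.columns[j]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        if self.metadata is not None:
            self.metadata = validate_metadata(self.metadata)
            missing = self.counts.index.difference(self.metadata.index)
            if len(missing):
                raise FormatError(f"samples missing metadata: {missing.tolist()}")
            self.metadata = self.metadata.loc[self.counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def otu_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    def totals(self) -> pd.Series:
        """Reads per sample."""
        return self.counts.sum(axis=1)

    def proportions(self) -> pd.DataFrame:
        """Relative read abundance per sample; rows sum to one."""
        tot = self.totals()
        if (tot == 0).any():
            bad = tot.index[tot == 0].tolist()
            raise ValueError(f"zero-read sample(s), drop first: {bad}")
        return self.counts.div(tot, axis=0)

    def drop_empty_samples(self) -> tuple["OtuTable", list[str]]:
        """Return a table without all-zero samples plus the dropped ids.

        Mirrors the study's exclusion of sequencing libraries that returned
        no usable reads; each exclusion is logged.
        """
        tot = self.counts.sum(axis=1)
        dropped = tot.index[tot == 0].tolist()
        if not dropped:
            return self, []
        for sid in dropped:
            logger.warning("excluding zero-read sample %r", sid)
        keep = tot > 0
        meta = self.metadata.loc[keep] if self.metadata is not None else None
        return OtuTable(self.counts.loc[keep], meta), dropped

    def rank_otus(self) -> list[str]:
        """OTU ids ordered by total raw reads (descending), ties by id."""
        tot = self.counts.sum(axis=0)
        order = sorted(tot.index, key=lambda o: (-tot[o], o))
        return order

    def with_metadata(self, metadata: pd.DataFrame) -> "OtuTable":
        return OtuTable(self.counts, metadata)


@dataclass
class CopyNumberMap:
    """Taxon -> 16S rRNA gene copies per genome, with a pooled-OTU mean."""

    copies: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COPY_NUMBERS))
    default_mean: float = DEFAULT_POOLED_COPY_NUMBER

    def __post_init__(self) -> None:
        for taxon, c in self.copies.items():
            if not c > 0:
                raise ValueError(f"copy number for {taxon!r} must be > 0, got {c}")
        if not self.default_mean > 0:
            raise ValueError("default_mean must be > 0")

    def get(self, taxon: str) -> float:
        """Copies for *taxon*; unknown taxa fall back to the pooled mean."""
        try:
            return self.copies[taxon]
        except KeyError:
            logger.warning(
                "taxon %r absent from copy-number map; using mean %.3g",
                taxon, self.default_mean,
            )
            return self.default_mean

    def vector(self, taxa) -> np.ndarray:
        return np.array([self.get(t) for t in taxa], dtype=float)


@dataclass
class QpcrTable:
    """Total 16S rRNA gene copies per DNA extraction, keyed by sample id."""

    totals: pd.Series

    def __post_init__(self) -> None:
        if self.totals.index.has_duplicates:
            dupes = self.totals.index[self.totals.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate qPCR sample row(s): {dupes}")
        if (self.totals <= 0).any():
            bad = self.totals.index[self.totals <= 0].tolist()
            raise ValueError(f"non-positive qPCR total(s) for sample(s): {bad}")
        self.totals = self.totals.astype(float)

    def check_against(self, table: OtuTable) -> list[str]:
        """Report qPCR samples missing from the OTU table (and vice versa)."""
        extra = self.totals.index.difference(table.counts.index).tolist()
        missing = table.counts.index.difference(self.totals.index).tolist()
        for sid in extra:
            logger.warning("qPCR total for unknown sample %r", sid)
        return missing

    def get(self, sample_id: str) -> float:
        return float(self.totals[sample_id])


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-sample metadata frame (niche/age vocabularies, ages)."""
    missing_cols = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise FormatError(f"metadata missing required column(s): {missing_cols}")
    bad_niche = set(meta["niche"]) - set(NICHES)
    if bad_niche:
        raise FormatError(
            f"unknown niche value(s) {sorted(bad_niche)}; allowed: {list(NICHES)}"
        )
    bad_age = set(meta["age_class"]) - set(AGE_CLASSES)
    if bad_age:
        raise FormatError(
            f"unknown age_class value(s) {sorted(bad_age)}; allowed: {list(AGE_CLASSES)}"
        )
    months = pd.to_numeric(meta["age_months"], errors="coerce")
    if months.isna().any() or (months <= 0).any():
        bad = meta.index[months.isna() | (months <= 0)].tolist()
        raise FormatError(f"age_months must be positive for sample(s): {bad}")
    out = meta.copy()
    out["age_months"] = months.astype(float)
    return out


# ---------------------------------------------------------------------------
# readers


def _detect_format(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    first_fields = header.replace(",", "\t").split("\t")
    if len(first_fields) >= 3 and first_fields[0].strip() == "label" \
            and first_fields[1].strip() == "Group":
        return "shared"
    return "csv"


def read_otu_table(path, format: str = "auto") -> OtuTable:
    """Read an OTU count table in the mothur shared dialect or plain CSV.

    Samples with zero total reads are *kept* here (flagged on access through
    :meth:`OtuTable.drop_empty_samples`) so that exclusions are explicit.
    """
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    if format == "shared":
        df = pd.read_csv(path, sep="\t")
        expected = ["label", "Group", "numOtus"]
        if list(df.columns[:3]) != expected:
            raise FormatError(
                f"shared file must start with columns {expected}, got {list(df.columns[:3])}"
            )
        n_declared = df["numOtus"].unique()
        counts = df.drop(columns=["label", "numOtus"]).set_index("Group")
        counts.index.name = "sample_id"
        if len(n_declared) != 1 or int(n_declared[0]) != counts.shape[1]:
            raise FormatError(
                f"numOtus declares {sorted(int(x) for x in n_declared)} OTUs "
                f"but {counts.shape[1]} count columns are present"
            )
    elif format == "csv":
        counts = pd.read_csv(path, index_col=0)
        counts.index.name = "sample_id"
    else:
        raise ValueError(f"unknown format {format!r}")
    counts.index = counts.index.astype(str)
    table = OtuTable(counts)
    n_empty = int((table.counts.sum(axis=1) == 0).sum())
    if n_empty:
        warnings.warn(
            f"{n_empty} sample(s) have zero reads and are flagged for exclusion",
            stacklevel=2,
        )
    return table


def read_metadata(path) -> pd.DataFrame:
    """Read and validate the per-sample metadata CSV (indexed by sample_id)."""
    meta = pd.read_csv(path, index_col=0)
    meta.index = meta.index.astype(str)
    meta.index.name = "sample_id"
    if meta.index.has_duplicates:
        raise FormatError("duplicate sample id in metadata")
    return validate_metadata(meta)


def read_qpcr(path) -> QpcrTable:
    """Read per-sample qPCR totals (CSV: sample_id,total_copies)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("qPCR CSV needs columns sample_id,total_copies")
    ser = pd.Series(
        pd.to_numeric(df.iloc[:, 1]).to_numpy(),
        index=df.iloc[:, 0].astype(str),
        name="total_copies",
    )
    return QpcrTable(ser)


def read_copy_numbers(path, default_mean: float = DEFAULT_POOLED_COPY_NUMBER) -> CopyNumberMap:
    """Read the taxon -> copy-number CSV (taxon,copies)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("copy-number CSV needs columns taxon,copies")
    taxa = df.iloc[:, 0].astype(str)
    if taxa.duplicated().any():
        raise FormatError("duplicate taxon in copy-number CSV")
    copies = dict(zip(taxa, pd.to_numeric(df.iloc[:, 1])))
    return CopyNumberMap(copies, default_mean)


def read_carbonyl(path) -> pd.DataFrame:
    """Read the carbonyl assay CSV (queen_id,A345,path_cm,volume_ul,protein_mg)."""
    df = pd.read_csv(path)
    required = {"queen_id", "A345", "volume_ul", "protein_mg"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"carbonyl CSV missing column(s): {sorted(missing)}")
    if "path_cm" not in df.columns:
        df["path_cm"] = 1.0
    return df.set_index("queen_id")


# ---------------------------------------------------------------------------
# writers


def write_otu_table(table: OtuTable, path, format: str = "csv") -> None:
    path = Path(path)
    if format == "csv":
        table.counts.to_csv(path)
    elif format == "shared":
        df = table.counts.reset_index(names="Group")
        df.insert(0, "label", "0.03")
        df.insert(2, "numOtus", table.counts.shape[1])
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write each result frame as a deterministic TSV under *out_dir*.

    Floats are rendered with a fixed ``%.10g`` format so reruns with the same
    seed and configuration are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        dest = out_dir / f"{name}.tsv"
        df.to_csv(dest, sep="\t", float_format="%.10g")
        written.append(dest)
    return written
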