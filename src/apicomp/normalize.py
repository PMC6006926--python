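"""Absolute-abundance normalization and the centered log-ratio transform.

Amplicon reads count 16S gene copies, not cells: a genome with four rRNA
operons contributes four times the reads of a single-operon genome at equal
cell number.  Scaling the proportional abundance ``p_i`` of each taxon by
the qPCR community size ``T`` (total gene copies per extraction) and
dividing by its per-genome copy number ``c_i`` estimates cell abundance:

    cells_i = T * p_i / c_i

so the copy-weighted total is conserved: sum_i cells_i * c_i = T * sum_i p_i.
OTUs outside the conspicuous panel are pooled ("other") and corrected by the
mean copy number 4.2.

The literal reading of "multiplied by copy number" (cells_i = T * p_i * c_i)
double-counts multi-operon genomes; it is exposed via
``convention="multiply"`` for sensitivity checks only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OtuTable, QpcrTable, CopyNumberMap

logger = logging.getLogger(__name__)

DEFAULT_PANEL_SIZE = 9


def cells_from_reads(p, copy_numbers, total: float, convention: str = "divide"):
    """Estimated cells per taxon from proportions, copy numbers and qPCR total.

    Parameters
    ----------
    p : array-like
        Proportional read abundances (>= 0, sum <= 1; the panel may exclude
        the pooled remainder).
    copy_numbers : array-like
        Per-genome 16S copy numbers, > 0, aligned with ``p``.
    total : float
        qPCR community size T (total 16S gene copies per extraction).
    convention : {"divide", "multiply"}
        "divide" (default) treats reads as gene-copy mass and divides by the
        per-genome copy number, yielding cells; "multiply" is the literal
        variant kept for sensitivity analysis.
    """
    p = np.asarray(p, dtype=float)
    c = np.asarray(copy_numbers, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be >= 0")
    if p.sum() > 1 + 1e-9:
        raise ValueError(f"proportions sum to {p.sum()}, > 1")
    if (c <= 0).any():
        raise ValueError("copy numbers must be > 0")
    if not total > 0:
        raise ValueError("qPCR total must be > 0")
    if convention == "divide":
        return total * p / c
    if convention == "multiply":
        return total * p * c
    raise ValueError(f"unknown convention {convention!r}")


def pool_low_abundance(p_rare_sum: float, default_mean: float, total: float) -> float:
    """Pooled "other" cell count: T * (sum of rare proportions) / mean copies."""
    if p_rare_sum < 0:
        raise ValueError("rare proportion mass must be >= 0")
    return total * p_rare_sum / default_mean


def copy_corrected_proportions(p, copy_numbers):
    """Relative abundance corrected by copy number: (p/c) renormalised to 1."""
    p = np.asarray(p, dtype=float)
    c = np.asarray(copy_numbers, dtype=float)
    q = p / c
    s = q.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("all-zero composition cannot be renormalised")
    return q / s


def percent_change_with_age(mean_old: float, mean_young: float) -> float:
    """Average percent change in cell number with age.

    ``100 * (old - young) / young``; bounded below by -100 because cell
    number loss cannot exceed 100%.  Undefined (NaN) when the young mean
    is zero.
    """
    if mean_young == 0:
        return float("nan")
    if mean_young < 0 or mean_old < 0:
        raise ValueError("cell means must be >= 0")
    return 100.0 * (mean_old - mean_young) / mean_young


def multiplicative_replacement(x, delta) -> np.ndarray:
    """Replace zeros by ``delta`` while shrinking nonzeros to preserve totals.

    Operates row-wise on a matrix of non-negative values; ``delta`` may be a
    scalar or a per-entry array on the same scale as ``x``.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    delta = np.broadcast_to(np.asarray(delta, dtype=float), x.shape)
    out = x.copy()
    zero = x == 0
    if not zero.any():
        return out
    totals = x.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("all-zero row has no compositional information")
    replaced_mass = np.where(zero, delta, 0.0).sum(axis=1, keepdims=True)
    shrink = 1.0 - replaced_mass / totals
    if np.any(shrink <= 0):
        raise ValueError("pseudocount mass exceeds row total")
    out = np.where(zero, delta, x * shrink)
    return out


def clr_transform(x, pseudocount: float | np.ndarray = 0.0) -> np.ndarray:
    """Centered log-ratio transform, row-wise.

    ``z_ij = ln x_ij - mean_k ln x_ik``.  Rows sum to zero and the transform
    is invariant to per-row positive scaling.  Zeros are handled by
    multiplicative replacement with ``pseudocount`` before taking logs; with
    ``pseudocount=0`` any zero raises.  A 1-D input returns a 1-D result.
    """
    x_in = np.asarray(x, dtype=float)
    one_d = x_in.ndim == 1
    x = np.atleast_2d(x_in)
    if (x < 0).any():
        raise ValueError("CLR input must be non-negative")
    if np.any(x.sum(axis=1) <= 0):
        raise ValueError("all-zero row has no composition")
    if (x == 0).any():
        if np.all(np.asarray(pseudocount) <= 0):
            raise ValueError("zeros present; supply a positive pseudocount")
        x = multiplicative_replacement(x, pseudocount)
    logs = np.log(x)
    z = logs - logs.mean(axis=1, keepdims=True)
    return z[0] if one_d else z


@dataclass
class CellAbundanceTable:
    """Per-sample estimated bacterial cell counts over a fixed taxon panel.

    ``cells`` holds the named panel plus (by default) a pooled ``other``
    column; ``provenance`` records the copy numbers, qPCR totals and
    conventions used so the normalization is auditable.
    """

    cells: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def panel(self) -> list[str]:
        return self.cells.columns.tolist()

    def relative(self) -> pd.DataFrame:
        tot = self.cells.sum(axis=1)
        return self.cells.div(tot, axis=0)


@dataclass
class ClrMatrix:
    """CLR scores per sample over a taxon panel, with the pseudocount policy."""

    z: pd.DataFrame
    pseudocount_policy: dict = field(default_factory=dict)

    def panel(self, taxa) -> pd.DataFrame:
        return self.z[list(taxa)]


def select_panel(table: OtuTable, n: int = DEFAULT_PANEL_SIZE) -> list[str]:
    """Top-*n* OTUs by total raw reads across retained libraries (ties by id)."""
    if n > len(table.otu_ids):
        raise ValueError(f"panel size {n} exceeds {len(table.otu_ids)} OTUs")
    return table.rank_otus()[:n]


def normalize_study(
    table: OtuTable,
    qpcr: QpcrTable,
    copy_numbers: CopyNumberMap | None = None,
    panel: list[str] | int = DEFAULT_PANEL_SIZE,
    include_other: bool = True,
    renormalize: str = "all",
    convention: str = "divide",
    pseudocount_reads: float = 0.5,
) -> CellAbundanceTable:
    """qPCR- and copy-number-normalise an OTU table to cell abundances.

    Parameters
    ----------
    panel
        Either an explicit list of taxon ids or a panel size *n* (the top-n
        OTUs by raw reads).
    include_other
        Pool the remaining OTUs into an ``other`` column corrected by the
        mean copy number.
    renormalize : {"all", "panel"}
        "all" (default): proportions are taken over all reads, so the panel
        plus ``other`` partitions the community and the copy-weighted total
        equals the qPCR total exactly.  "panel": proportions are renormalised
        over the panel alone before scaling (the pooled column is then
        computed from the untouched rare mass).
    """
    if copy_numbers is None:
        copy_numbers = CopyNumberMap()
    table, _ = table.drop_empty_samples()
    if isinstance(panel, int):
        panel = select_panel(table, panel)
    missing = qpcr.check_against(table)
    if missing:
        raise ValueError(f"samples missing qPCR totals: {missing}")

    props = table.proportions()
    p_panel = props[panel].to_numpy()
    p_rare = 1.0 - p_panel.sum(axis=1)
    p_rare = np.clip(p_rare, 0.0, None)
    c = copy_numbers.vector(panel)
    totals = qpcr.totals.loc[table.counts.index].to_numpy()

    if renormalize == "panel":
        panel_sums = p_panel.sum(axis=1, keepdims=True)
        if np.any(panel_sums <= 0):
            raise ValueError("a sample has no reads in the selected panel")
        p_used = p_panel / panel_sums
    elif renormalize == "all":
        p_used = p_panel
    else:
        raise ValueError(f"unknown renormalize mode {renormalize!r}")

    cells = np.empty_like(p_used)
    for i in range(p_used.shape[0]):
        cells[i] = cells_from_reads(p_used[i], c, totals[i], convention)
    frame = pd.DataFrame(cells, index=table.counts.index, columns=panel)
    if include_other:
        other = np.array([
            pool_low_abundance(p_rare[i], copy_numbers.default_mean, totals[i])
            for i in range(len(p_rare))
        ])
        frame["other"] = other
    prov = {
        "panel": list(panel),
        "copy_numbers": {t: copy_numbers.get(t) for t in panel},
        "default_mean": copy_numbers.default_mean,
        "convention": convention,
        "renormalize": renormalize,
        "include_other": include_other,
        "qpcr_totals": dict(zip(table.counts.index, totals)),
        "pseudocount_reads": pseudocount_reads,
    }
    return CellAbundanceTable(frame, prov)


def clr_from_cells(
    cell_table: CellAbundanceTable,
    table: OtuTable | None = None,
    pseudocount_reads: float = 0.5,
) -> ClrMatrix:
    """CLR-transform a cell-abundance table.

    Zero cells are replaced multiplicatively by the cell-unit equivalent of
    ``pseudocount_reads`` reads (default half a read): for taxon *i* in a
    sample with read total N and qPCR total T the replacement is
    ``pseudocount_reads / N * T / c_i``.  When the read totals are not
    available a common floor of half the smallest positive cell value is
    used instead.
    """
    X = cell_table.cells.to_numpy(dtype=float)
    if (X == 0).any():
        prov = cell_table.provenance
        if table is not None and prov.get("qpcr_totals"):
            N = table.counts.sum(axis=1).loc[cell_table.cells.index].to_numpy()
            T = np.array([prov["qpcr_totals"][s] for s in cell_table.cells.index])
            c = np.array([
                prov["copy_numbers"].get(t, prov.get("default_mean", 4.2))
                for t in cell_table.cells.columns
            ])
            delta = pseudocount_reads / N[:, None] * T[:, None] / c[None, :]
        else:
            floor = X[X > 0].min() / 2.0
            delta = np.full_like(X, floor)
        z = clr_transform(X, pseudocount=delta)
        policy = {"mode": "multiplicative", "pseudocount_reads": pseudocount_reads}
    else:
        z = clr_transform(X)
        policy = {"mode": "none"}
    return ClrMatrix(pd.DataFrame(z, index=cell_table.cells.index,
                                  columns=cell_table.cells.columns), policy)
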