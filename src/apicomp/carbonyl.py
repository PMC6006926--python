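"""Protein-carbonyl assay arithmetic: the biological-age proxy.

Oxidized-protein carbonyl groups accumulate in honey bee fat body tissue in a
clock-like fashion and are read out spectrophotometrically after DNPH
derivatization.  Beer-Lambert with the millimolar extinction coefficient of
aliphatic hydrozones (22 mM^-1 cm^-1) converts absorbance at 345 nm to a
concentration; multiplying by the resuspension volume (1 mM = 1 nmol/ul) and
dividing by the protein mass gives nmol carbonyl per mg protein.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Millimolar extinction coefficient of aliphatic hydrozones at 345 nm.
EXTINCTION_MM = 22.0


def carbonyl_per_mg(a345, path_cm=1.0, volume_ul=100.0, protein_mg=0.5):
    """nmol carbonyl groups per mg protein from the assay readings.

    concentration [mM] = A345 / (epsilon * path); nmol = mM * volume_ul
    (1 mM is 1 nmol/ul); result = nmol / protein_mg.  Linear in A345 and
    volume, inverse in path length and protein mass.
    """
    a345 = np.asarray(a345, dtype=float)
    path_cm = np.asarray(path_cm, dtype=float)
    volume_ul = np.asarray(volume_ul, dtype=float)
    protein_mg = np.asarray(protein_mg, dtype=float)
    if (a345 < 0).any():
        raise ValueError("absorbance must be >= 0")
    if (path_cm <= 0).any() or (volume_ul <= 0).any():
        raise ValueError("path length and volume must be > 0")
    if (protein_mg <= 0).any():
        raise ValueError("protein mass must be > 0")
    conc_mm = a345 / (EXTINCTION_MM * path_cm)
    nmol = conc_mm * volume_ul
    result = nmol / protein_mg
    return float(result) if result.ndim == 0 else result


def log_carbonyl(values, base: float | None = None) -> np.ndarray:
    """Log-transform carbonyl values (natural log by default).

    Zeros are offset to half the smallest positive value before the log, with
    a warning; an all-zero vector raises.
    """
    v = np.asarray(values, dtype=float).copy()
    if (v < 0).any():
        raise ValueError("carbonyl values must be >= 0")
    if (v == 0).any():
        pos = v[v > 0]
        if pos.size == 0:
            raise ValueError("all carbonyl values are zero; nothing to log")
        offset = pos.min() / 2.0
        logger.warning("%d zero carbonyl value(s) offset to %.4g before log",
                       int((v == 0).sum()), offset)
        v[v == 0] = offset
    out = np.log(v)
    if base is not None:
        out = out / np.log(base)
    return out


def carbonyl_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Add the derived nmol/mg column to an assay frame (queen-indexed)."""
    out = frame.copy()
    out["carbonyl_nmol_per_mg"] = carbonyl_per_mg(
        out["A345"].to_numpy(),
        out.get("path_cm", pd.Series(1.0, index=out.index)).to_numpy(),
        out["volume_ul"].to_numpy(),
        out["protein_mg"].to_numpy(),
    )
    return out
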