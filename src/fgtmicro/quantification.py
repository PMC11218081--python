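"""Absolute bacterial load from 16S qPCR, background calling, cytokine correction.

The standard curve is an ordinary least-squares fit of Ct on log10(copies per
reaction) over a ten-fold dilution series. Amplification efficiency is the
usual 10^(-1/slope) - 1. Total copies per sample scale the per-reaction
quantity by extract_volume / load_volume (50 uL / 5 uL = x10 by default).
Copy loads are not normalised to per-species 16S gene copy number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# 16S rRNA gene copies per E. coli genome: converts genome equivalents of the
# quantification standard to 16S copies when the input is in genomes.
ECOLI_16S_COPIES_PER_GENOME = 7


@dataclass
class StandardCurve:
    """Fitted qPCR standard curve: Ct = intercept + slope * log10(copies)."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self):
        if self.slope >= 0:
            raise ValueError(f"standard-curve slope must be negative, got {self.slope}")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared must be in [0,1], got {self.r_squared}")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency, 10^(-1/slope) - 1 (1.0 = perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def genomes_to_copies(genome_equivalents, copies_per_genome: int = ECOLI_16S_COPIES_PER_GENOME):
    """Convert genome equivalents of the standard organism to 16S copies."""
    return np.asarray(genome_equivalents, dtype=float) * copies_per_genome


def fit_standard_curve(copies, ct) -> StandardCurve:
    """Fit the standard curve by OLS of Ct on log10(copies per reaction).

    ``copies`` and ``ct`` are parallel arrays over the dilution series
    (replicates allowed). Requires >= 3 distinct copy levels. Warns when the
    fit quality (r^2 < 0.98) or efficiency (outside [0.9, 1.1]) suggests a
    problematic assay.
    """
    copies = np.asarray(copies, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if copies.shape != ct.shape:
        raise ValueError("copies and ct must be parallel arrays")
    if (copies <= 0).any():
        raise ValueError("standard copies must be strictly positive")
    levels = np.unique(copies)
    if len(levels) < 3:
        raise ValueError(f"need >= 3 distinct copy levels, got {len(levels)}")
    x = np.log10(copies)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log10(copies)")
    fit = stats.linregress(x, ct)
    curve = StandardCurve(slope=fit.slope, intercept=fit.intercept, r_squared=fit.rvalue**2)
    if curve.r_squared < 0.98:
        logger.warning("standard curve r^2 = %.4f < 0.98", curve.r_squared)
    if not 0.9 <= curve.efficiency <= 1.1:
        logger.warning("amplification efficiency %.3f outside [0.9, 1.1]", curve.efficiency)
    return curve


def fit_standard_curve_from_table(standards: pd.DataFrame) -> StandardCurve:
    """Fit from a standards DataFrame with columns ``copies`` and ``ct``."""
    return fit_standard_curve(standards["copies"].to_numpy(), standards["ct"].to_numpy())


def ct_to_total_copies(
    ct,
    curve: StandardCurve,
    load_volume_ul: float = 5.0,
    extract_volume_ul: float = 50.0,
) -> pd.DataFrame:
    """Convert Ct values to copies per reaction and total copies per extract.

    copies_per_reaction = 10^((ct - intercept) / slope); total copies scale
    by extract_volume / load_volume. Non-finite Ct (no amplification) gives
    zero copies and ``no_amplification=True``. ``ct`` may be a Series
    (indexed by sample id) or an array.
    """
    if load_volume_ul <= 0 or extract_volume_ul <= 0:
        raise ValueError("volumes must be positive")
    index = ct.index if isinstance(ct, pd.Series) else None
    ct_arr = np.asarray(ct, dtype=float)
    finite = np.isfinite(ct_arr)
    copies = np.zeros_like(ct_arr)
    copies[finite] = 10.0 ** ((ct_arr[finite] - curve.intercept) / curve.slope)
    total = copies * (extract_volume_ul / load_volume_ul)
    out = pd.DataFrame(
        {
            "ct": ct_arr,
            "copies_per_reaction": copies,
            "total_copies": total,
            "no_amplification": ~finite,
        }
    )
    if index is not None:
        out.index = index
        out.index.name = "sample_id"
    return out


def call_signature_above_background(
    loads: pd.DataFrame,
    meta: pd.DataFrame,
    cutoff: float = 700.0,
) -> pd.DataFrame:
    """Fraction of samples per (site, group) with total copies above background.

    A sample is above background iff total_copies > cutoff (strictly). The
    returned frame carries numerator, denominator and fraction per stratum.
    ``loads`` must be indexed by sample_id with a ``total_copies`` column.
    """
    merged = meta.merge(
        loads["total_copies"].rename_axis("sample_id").reset_index(), on="sample_id", how="inner"
    )
    non_control = merged[merged["group"] != "control"]
    if non_control.empty:
        raise ValueError("no non-control samples with load measurements")
    merged["above_background"] = merged["total_copies"] > cutoff
    rows = []
    for (site, group), sub in merged.groupby(["site", "group"], sort=True):
        rows.append(
            {
                "site": site,
                "group": group,
                "n_above": int(sub["above_background"].sum()),
                "n_total": int(len(sub)),
                "fraction_above": sub["above_background"].mean(),
            }
        )
    return pd.DataFrame(rows)


def normalize_cytokines(plate: pd.DataFrame, reference_well: str) -> pd.DataFrame:
    """Protein-normalise cytokine concentrations across wells.

    Correction factor per well = protein_well / protein_reference; the
    corrected analyte concentration is factor x raw pg/mL. Requires columns
    well, analyte, concentration_pg_ml, protein_ug_ml.
    """
    bad = plate.loc[plate["protein_ug_ml"] <= 0, "well"].tolist()
    if bad:
        raise ValueError(f"non-positive total protein in well(s): {bad}")
    ref = plate.loc[plate["well"] == reference_well, "protein_ug_ml"]
    if ref.empty:
        raise ValueError(f"reference well {reference_well!r} not found")
    ref_protein = float(ref.iloc[0])
    out = plate.copy()
    out["correction_factor"] = out["protein_ug_ml"] / ref_protein
    out["corrected_pg_ml"] = out["correction_factor"] * out["concentration_pg_ml"]
    return out
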