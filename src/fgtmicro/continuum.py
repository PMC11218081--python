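"""Intra-patient compositional sharedness along the genital tract.

A taxon "counts" at a site when its relative abundance is at least 0.5%
(inclusive, configurable). For each patient with matched samples the module
computes the prevalent-taxon set per site, the Sorensen-Dice coefficient
DSC = 2c / (S1 + S2) for every site pair, Venn region counts over the
patient's sites, and a full-continuum flag (the most abundant lower-GT
taxon is detectable at every upper-GT site). Paired composition similarity
within an organ is the squared Pearson correlation of the two fraction
vectors (Spearman available as an option).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import CountTable, LOWER_GT_SITES, UPPER_GT_SITES

logger = logging.getLogger(__name__)


@dataclass
class RelAbundanceTable:
    """Taxa x samples fractions; every non-empty column sums to 1."""

    taxon_ids: list
    sample_ids: list
    fractions: np.ndarray

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError("fractions shape inconsistent with id lists")
        if (self.fractions < 0).any() or (self.fractions > 1 + 1e-12).any():
            raise ValueError("fractions must lie in [0,1]")
        sums = self.fractions.sum(axis=0)
        bad = ~(np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-12))
        if bad.any():
            j = int(np.argmax(bad))
            raise ValueError(
                f"column {self.sample_ids[j]!r} sums to {sums[j]}; expected 0 or 1"
            )

    def sample(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None
        return self.fractions[:, j]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fractions, index=self.taxon_ids, columns=self.sample_ids)


def relative_abundance(counts: CountTable) -> RelAbundanceTable:
    """Per-sample normalisation of a count table; empty samples give a zero column."""
    totals = counts.sample_sums().astype(float)
    empty = totals == 0
    if empty.any():
        logger.warning(
            "samples with zero reads get zero columns: %s",
            [s for s, e in zip(counts.sample_ids, empty) if e],
        )
    safe = np.where(empty, 1.0, totals)
    fractions = counts.counts / safe
    return RelAbundanceTable(list(counts.taxon_ids), list(counts.sample_ids), fractions)


def prevalent_taxa(relabund: RelAbundanceTable, sample_id: str, min_frac: float = 0.005) -> set:
    """Taxa at or above the relative-abundance floor in one sample.

    ``min_frac = 0`` degenerates to "all taxa with nonzero abundance".
    """
    fractions = relabund.sample(sample_id)
    if min_frac <= 0:
        mask = fractions > 0
    else:
        mask = fractions >= min_frac
    return {t for t, m in zip(relabund.taxon_ids, mask) if m}


def sorensen(set1, set2) -> float:
    """Sorensen-Dice coefficient 2c/(S1+S2) between two taxon sets.

    Defined as 0 (with a warning) when both sets are empty, keeping
    downstream medians stable.
    """
    set1, set2 = set(set1), set(set2)
    denom = len(set1) + len(set2)
    if denom == 0:
        logger.warning("Sorensen of two empty sets defined as 0")
        return 0.0
    return 2.0 * len(set1 & set2) / denom


def venn_regions(site_sets: dict) -> dict:
    """Exclusive Venn region counts over named sets.

    Keys are frozensets of site names; values count taxa present in exactly
    those sites. Counts sum to the size of the union.
    """
    sites = list(site_sets)
    union = set().union(*site_sets.values()) if site_sets else set()
    regions: dict = {}
    for taxon in union:
        member = frozenset(s for s in sites if taxon in site_sets[s])
        regions[member] = regions.get(member, 0) + 1
    return regions


@dataclass
class ContinuumResult:
    """Per-patient continuum summary over the requested sites."""

    patient_id: str
    site_sets: dict  # site -> prevalent taxon set
    pairwise: pd.DataFrame  # site_a, site_b, s1, s2, shared, dsc
    venn: dict  # frozenset(site names) -> exclusive taxon count
    shared_all_sites: set = field(default_factory=set)
    full_continuum: bool | None = None


def continuum_profile(
    relabund: RelAbundanceTable,
    meta: pd.DataFrame,
    patient_id: str,
    sites,
    min_frac: float = 0.005,
) -> ContinuumResult | None:
    """Continuum summary for one patient over an ordered site list.

    Returns None (with a warning) when the patient has samples at fewer than
    two of the requested sites. The full-continuum flag is True when, for
    every lower-GT site present, the patient's single most abundant taxon at
    that site is prevalent (>= min_frac) at all requested upper-GT sites
    present; it is None when the site list has no lower/upper pair.
    """
    psub = meta[(meta["patient_id"] == patient_id) & (meta["site"].isin(list(sites)))]
    available = {}
    for _, row in psub.iterrows():
        if row["sample_id"] in relabund.sample_ids:
            available[row["site"]] = row["sample_id"]
    matched = [s for s in sites if s in available]
    if len(matched) < 2:
        logger.warning(
            "patient %s has %d matched site(s) among %s; skipped",
            patient_id, len(matched), list(sites),
        )
        return None

    site_sets = {s: prevalent_taxa(relabund, available[s], min_frac) for s in matched}
    rows = []
    for sa, sb in combinations(matched, 2):
        s1, s2 = site_sets[sa], site_sets[sb]
        rows.append(
            {
                "site_a": sa,
                "site_b": sb,
                "s1": len(s1),
                "s2": len(s2),
                "shared": len(s1 & s2),
                "dsc": sorensen(s1, s2),
            }
        )
    pairwise = pd.DataFrame(rows)
    venn = venn_regions(site_sets)
    shared_all = set.intersection(*site_sets.values()) if site_sets else set()

    lower = [s for s in matched if s in LOWER_GT_SITES]
    upper = [s for s in matched if s in UPPER_GT_SITES]
    full = None
    if lower and upper:
        full = True
        for s in lower:
            fr = relabund.sample(available[s])
            if fr.max() <= 0:
                full = False
                continue
            top = relabund.taxon_ids[int(np.argmax(fr))]
            if not all(top in site_sets[u] for u in upper):
                full = False
    return ContinuumResult(patient_id, site_sets, pairwise, venn, shared_all, full)


def paired_composition_r2(
    relabund: RelAbundanceTable,
    sample_a: str,
    sample_b: str,
    method: str = "pearson",
) -> float | None:
    """Squared correlation of two samples' fraction vectors.

    Computed over the union of taxa nonzero in either sample. Returns None
    (reported as missing) when that union has fewer than 3 taxa or a vector
    is constant.
    """
    xa, xb = relabund.sample(sample_a), relabund.sample(sample_b)
    mask = (xa > 0) | (xb > 0)
    if mask.sum() < 3:
        return None
    xa, xb = xa[mask], xb[mask]
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return None
    if method == "pearson":
        r = stats.pearsonr(xa, xb).statistic
    elif method == "spearman":
        r = stats.spearmanr(xa, xb).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r**2)
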