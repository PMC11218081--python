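"""Prevalence-based contaminant identification against negative controls.

For every taxon a 2x2 presence/absence (count >= 1) by sample-class
(true sample vs pooled negative control) table is tested for
over-representation in controls: Fisher's exact one-sided test when any
expected cell is below 5 (the classical small-count rule), otherwise a
Pearson chi-square halved to one side. Taxa with p below the prevalence
threshold (default 0.5) are flagged; a taxon absent from every control is
never flagged. All four control types (air, knife, extraction, sequencing)
are pooled for the test; a per-control-type presence breakdown is reported
for audit but does not drive flagging.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import CountTable

logger = logging.getLogger(__name__)


def score_contaminants(
    counts: CountTable,
    meta: pd.DataFrame,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score every taxon for contamination by the prevalence test.

    Returns a DataFrame indexed by taxon_id with columns: n_present_samples,
    n_samples, n_present_controls, n_controls, p_value, test (``fisher`` or
    ``chi2``), is_contaminant, plus per-control-type presence counts. Taxa
    with zero reads everywhere are excluded (warning logged).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0,1)")
    meta_idx = meta.set_index("sample_id")
    missing = [s for s in counts.sample_ids if s not in meta_idx.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    groups = meta_idx.loc[counts.sample_ids, "group"].to_numpy()
    is_control = groups == "control"
    n_controls = int(is_control.sum())
    n_true = int((~is_control).sum())
    if n_controls == 0:
        raise ValueError("prevalence test requires at least one negative control")
    if n_true == 0:
        raise ValueError("prevalence test requires at least one non-control sample")

    present = counts.counts >= 1  # presence floor: a single read counts
    pres_ctrl = present[:, is_control].sum(axis=1)
    pres_true = present[:, ~is_control].sum(axis=1)

    ctypes = meta_idx.loc[counts.sample_ids, "control_type"].to_numpy()
    by_type = {
        f"n_present_{ct}": present[:, ctypes == ct].sum(axis=1)
        for ct in sorted(set(ctypes) - {"none"})
    }

    rows = []
    for i, taxon in enumerate(counts.taxon_ids):
        a, b = int(pres_ctrl[i]), n_controls - int(pres_ctrl[i])
        c, d = int(pres_true[i]), n_true - int(pres_true[i])
        if a + c == 0:
            logger.warning("taxon %s absent everywhere; excluded from contaminant report", taxon)
            continue
        p, test = _one_sided_prevalence_p(a, b, c, d)
        flagged = bool(p < threshold) and a > 0  # never flag a taxon absent from controls
        row = {
            "taxon_id": taxon,
            "n_present_samples": c,
            "n_samples": n_true,
            "n_present_controls": a,
            "n_controls": n_controls,
            "p_value": p,
            "test": test,
            "is_contaminant": flagged,
        }
        for col, arr in by_type.items():
            row[col] = int(arr[i])
        rows.append(row)
    return pd.DataFrame(rows).set_index("taxon_id")


def _one_sided_prevalence_p(a: int, b: int, c: int, d: int):
    """One-sided p for over-representation in controls.

    Table rows: controls (present a, absent b), true samples (present c,
    absent d). Fisher exact when any expected cell < 5, else Pearson
    chi-square halved to the control-enriched side.
    """
    table = np.array([[a, b], [c, d]])
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected < 5).any():
        return stats.fisher_exact(table, alternative="greater")[1], "fisher"
    p_two = stats.chi2_contingency(table, correction=False)[1]
    ctrl_rate = a / (a + b)
    true_rate = c / (c + d)
    p = p_two / 2.0 if ctrl_rate > true_rate else 1.0 - p_two / 2.0
    return p, "chi2"


def remove_contaminants(counts: CountTable, report: pd.DataFrame) -> CountTable:
    """Drop flagged taxa rows; samples and remaining counts are untouched."""
    unknown = sorted(set(report.index) - set(counts.taxon_ids))
    if unknown:
        raise ValueError(f"contaminant report references unknown taxa: {unknown}")
    flagged = set(report.index[report["is_contaminant"]])
    keep = [t for t in counts.taxon_ids if t not in flagged]
    if not keep:
        logger.warning("all %d taxa flagged as contaminants; empty table returned", counts.n_taxa)
    return counts.select_taxa(keep)


def filter_low_information(
    counts: CountTable,
    min_count: int = 5,
    min_prevalence_frac: float = 0.10,
    iqr_drop_frac: float = 0.05,
):
    """Apply the low-information OTU filters.

    Keep taxa with >= ``min_count`` reads in at least
    ceil(min_prevalence_frac * n_samples) samples; then remove the
    ``iqr_drop_frac`` fraction of survivors with the smallest inter-quartile
    range of counts across samples (a low-variance filter; ties broken by
    taxon id, lowest id dropped first).

    Returns ``(filtered CountTable, removal dict)`` where the dict lists the
    taxa removed by each rule.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if counts.n_taxa == 0 or counts.n_samples == 0:
        raise ValueError("count table must be non-empty")
    needed = math.ceil(min_prevalence_frac * counts.n_samples)
    prev_ok = (counts.counts >= min_count).sum(axis=1) >= needed
    removed_prevalence = [t for t, ok in zip(counts.taxon_ids, prev_ok) if not ok]
    survivors = [t for t, ok in zip(counts.taxon_ids, prev_ok) if ok]
    sub = counts.select_taxa(survivors) if survivors else counts.select_taxa([])

    n_drop = int(len(survivors) * iqr_drop_frac)
    removed_iqr: list = []
    if n_drop > 0:
        iqr = stats.iqr(sub.counts, axis=1)
        order = sorted(range(len(survivors)), key=lambda i: (iqr[i], survivors[i]))
        removed_iqr = [survivors[i] for i in order[:n_drop]]
        keep = [t for t in survivors if t not in set(removed_iqr)]
        sub = sub.select_taxa(keep)
    return sub, {"prevalence": removed_prevalence, "iqr": removed_iqr}
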