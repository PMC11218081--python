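"""Rarefaction, Ward clustering, rule-based community typing, frequency tests.

Samples are rarefied per anatomical site to the lowest common read count
(after dropping samples below a floor), clustered by Ward linkage on
Euclidean distances between genus-level fraction vectors, and assigned a
rule-based community label by dominant-genus thresholds:

1. Lactobacillus >= 75%                      -> lactobacillus_dominant
2. Gardnerella >= 50%, Lactobacillus second  -> gardnerella_lactobacillus
3. Streptococcus >= 36% (vaginal sites only) -> streptococcus_dominant
4. otherwise                                 -> high_diversity_other

Cluster/category frequencies between clinical groups are compared with a
Pearson chi-squared test (no continuity correction) and 2x2 associations
with Fisher's exact test reporting the sample cross-product odds ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .io_tables import CountTable, VAGINAL_SITES
from .continuum import RelAbundanceTable

logger = logging.getLogger(__name__)

CLUSTER_LABELS = (
    "lactobacillus_dominant",
    "gardnerella_lactobacillus",
    "streptococcus_dominant",
    "high_diversity_other",
)


def rarefy(counts: CountTable, depth="min", seed: int = 0, min_depth: int = 500):
    """Randomly sub-sample every sample to a common depth, without replacement.

    ``depth='min'`` uses the lowest read count among samples at or above
    ``min_depth``; shallower samples are dropped with a warning (mirroring
    the exclusion of low-read samples). Column sums of the result equal the
    depth exactly; drawing uses the multivariate hypergeometric distribution
    (sampling reads without replacement).
    """
    totals = counts.sample_sums()
    if depth == "min":
        eligible = totals[totals >= min_depth]
        if eligible.size == 0:
            raise ValueError(f"no sample reaches the minimum depth {min_depth}")
        depth = int(eligible.min())
    else:
        depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    keep = totals >= depth
    dropped = [s for s, k in zip(counts.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy drops %d sample(s) below depth %d: %s", len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    kept_ids = [s for s, k in zip(counts.sample_ids, keep) if k]
    cols = []
    for j, k in enumerate(keep):
        if not k:
            continue
        col = counts.counts[:, j]
        if col.sum() == depth:
            cols.append(col.copy())
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
    mat = np.column_stack(cols) if cols else np.zeros((counts.n_taxa, 0), int)
    return CountTable(list(counts.taxon_ids), kept_ids, mat)


def hca_clusters(relabund: RelAbundanceTable, k: int):
    """Ward/Euclidean hierarchical clustering of samples, cut into k groups.

    Returns ``(linkage matrix, labels)`` where labels is a pandas Series of
    1..k flat cluster ids indexed by sample id.
    """
    n = len(relabund.sample_ids)
    if n < 2:
        raise ValueError("clustering needs >= 2 samples")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    Z = linkage(relabund.fractions.T, method="ward", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return Z, pd.Series(labels, index=relabund.sample_ids, name="cluster")


@dataclass
class ClusterAssignment:
    """Community-type label for one sample with the rule that fired."""

    sample_id: str
    site: str
    label: str
    rule_trace: str


def assign_cluster_label(
    fractions: pd.Series,
    site: str,
    sample_id: str = "",
    lacto_cut: float = 0.75,
    gard_cut: float = 0.50,
    strep_cut: float = 0.36,
) -> ClusterAssignment:
    """Assign the rule-based community label from genus-level fractions.

    ``fractions`` is a Series indexed by genus, summing to 1. Rules fire in
    precedence order; the Streptococcus rule applies to vaginal sites only.
    The Gardnerella/Lactobacillus rule requires Gardnerella above its cut
    with Lactobacillus the next-most-abundant genus.
    """
    total = float(fractions.sum())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"genus fractions must sum to 1, got {total}")
    get = lambda g: float(fractions.get(g, 0.0))
    lacto, gard, strep = get("Lactobacillus"), get("Gardnerella"), get("Streptococcus")
    if lacto >= lacto_cut:
        label, trace = "lactobacillus_dominant", f"Lactobacillus {lacto:.3f} >= {lacto_cut}"
    elif gard >= gard_cut and _second_genus(fractions) == "Lactobacillus":
        label = "gardnerella_lactobacillus"
        trace = f"Gardnerella {gard:.3f} >= {gard_cut} with Lactobacillus second"
    elif site in VAGINAL_SITES and strep >= strep_cut:
        label = "streptococcus_dominant"
        trace = f"Streptococcus {strep:.3f} >= {strep_cut} (vaginal site)"
    else:
        label, trace = "high_diversity_other", "no dominance threshold fired"
    return ClusterAssignment(sample_id=sample_id, site=site, label=label, rule_trace=trace)


def _second_genus(fractions: pd.Series):
    if len(fractions) < 2:
        return None
    order = fractions.sort_values(ascending=False, kind="stable")
    return order.index[1]


def assign_cluster_labels(
    genus_relabund: RelAbundanceTable,
    meta: pd.DataFrame,
    **cuts,
) -> pd.DataFrame:
    """Vectorised labelling of every sample in a genus-level abundance table."""
    site_of = meta.set_index("sample_id")["site"]
    rows = []
    frame = genus_relabund.to_frame()
    for sid in genus_relabund.sample_ids:
        fr = frame[sid]
        if fr.sum() == 0:
            logger.warning("sample %s is empty; labelled high_diversity_other", sid)
            rows.append((sid, site_of.get(sid, "control"), "high_diversity_other", "empty sample"))
            continue
        a = assign_cluster_label(fr / fr.sum(), site_of.get(sid, "control"), sample_id=sid, **cuts)
        rows.append((a.sample_id, a.site, a.label, a.rule_trace))
    return pd.DataFrame(rows, columns=["sample_id", "site", "label", "rule_trace"])


def chi_squared_test(table) -> tuple:
    """Pearson chi-squared test of independence, no continuity correction.

    ``table`` is an r x c array of non-negative integer counts (rows =
    groups, columns = categories). Zero-sum columns are dropped with a
    warning before testing. Returns (statistic, df, p_value); a table left
    with a single column is degenerate and returns (0.0, 0, 1.0).
    """
    arr = np.asarray(table)
    if (arr < 0).any():
        raise ValueError("contingency table cells must be non-negative")
    if (arr.sum(axis=1) == 0).any():
        raise ValueError("every row (group) must have a positive total")
    zero_cols = arr.sum(axis=0) == 0
    if zero_cols.any():
        logger.warning("dropping %d all-zero column(s) before chi-squared test", zero_cols.sum())
        arr = arr[:, ~zero_cols]
    if arr.shape[1] < 2:
        return 0.0, 0, 1.0
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fisher_or(table) -> dict:
    """Fisher's exact test on a 2x2 table with the sample cross-product OR.

    OR = (a*d)/(b*c); when b*c = 0 the OR is reported as inf (or 0 when the
    numerator is also 0) with a note. The two-sided exact p sums all tables
    with the observed margins whose probability does not exceed the observed
    table's.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_or requires a 2x2 table")
    if (arr < 0).any():
        raise ValueError("contingency table cells must be non-negative")
    (a, b), (c, d) = arr
    note = ""
    if b * c == 0:
        odds = 0.0 if a * d == 0 else np.inf
        note = "cross-product denominator zero; OR degenerate"
    else:
        odds = (a * d) / (b * c)
    p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
    return {"odds_ratio": float(odds), "p_value": p, "note": note}


def type_frequency_comparison(
    assignments: pd.DataFrame,
    meta: pd.DataFrame,
    site,
) -> tuple:
    """Group x community-label contingency table and its chi-squared test.

    ``site`` may be a single site or an iterable of sites (e.g. both vaginal
    sampling points). Labels absent from every group are dropped. Returns
    (contingency DataFrame, (statistic, df, p_value)).
    """
    sites = [site] if isinstance(site, str) else list(site)
    merged = assignments.merge(
        meta[["sample_id", "group"]], on="sample_id", how="left"
    )
    sub = merged[(merged["site"].isin(sites)) & (merged["group"] != "control")]
    groups = sorted(sub["group"].unique())
    if len(groups) < 2:
        raise ValueError(f"need >= 2 clinical groups at site(s) {sites}, found {groups}")
    tab = pd.crosstab(sub["group"], sub["label"])
    tab = tab.loc[:, tab.sum(axis=0) > 0]
    stat, df, p = chi_squared_test(tab.to_numpy())
    return tab, (stat, df, p)
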