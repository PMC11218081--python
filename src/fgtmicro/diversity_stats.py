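"""Alpha/beta diversity and group comparison statistics.

Shannon entropy is computed in nats (natural log; a base option exists).
Bray-Curtis dissimilarity between relative-abundance profiles is
1 - sum(min(p_i, p_j)) and is returned as a scikit-bio DistanceMatrix.
Group comparisons use Mann-Whitney (two groups) or Kruskal-Wallis (more),
with Dunn's z-based post-hoc pairwise comparisons and Bonferroni-style
multiplicity adjustment. PERMANOVA computes the pseudo-F from among/within
sums of squared distances with an explicitly seeded label-permutation null,
p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)


def shannon(fractions, base: float | None = None) -> float:
    """Shannon diversity -sum(p log p) of one sample's relative abundances.

    ``fractions`` must sum to 1 (or be all zero for an empty sample, giving
    0). Natural log by default; pass ``base`` for another logarithm base.
    """
    p = np.asarray(fractions, dtype=float)
    if (p < 0).any():
        raise ValueError("fractions must be non-negative")
    total = p.sum()
    if total == 0:
        return 0.0
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"fractions must sum to 1, got {total}")
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def alpha_diversity_table(relabund, meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-sample Shannon index, optionally joined with site/group metadata."""
    rows = [
        {"sample_id": sid, "shannon": shannon(relabund.fractions[:, j])}
        for j, sid in enumerate(relabund.sample_ids)
    ]
    out = pd.DataFrame(rows)
    if meta is not None:
        out = out.merge(meta[["sample_id", "site", "group"]], on="sample_id", how="left")
    return out


def bray_curtis(relabund) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix between all samples.

    Empty (all-zero) samples get distance 1 to everything else (warning).
    """
    X = relabund.fractions.T  # samples x taxa
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples for a distance matrix")
    sums = X.sum(axis=1)
    empty = sums == 0
    if empty.any():
        logger.warning(
            "empty samples at distance 1 to all others: %s",
            [s for s, e in zip(relabund.sample_ids, empty) if e],
        )
    d = squareform(pdist(X, metric=lambda u, v: 1.0 - np.minimum(u, v).sum()))
    if empty.any():
        d[empty, :] = 1.0
        d[:, empty] = 1.0
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(relabund.sample_ids))


def rank_group_test(values, groups) -> float:
    """Two-sided Mann-Whitney (2 groups) or Kruskal-Wallis (>2) p-value."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [values[groups == g] for g in labels]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    if len(labels) == 2:
        if np.ptp(values) == 0:
            return 1.0  # total ties carry no ordering information
        return float(stats.mannwhitneyu(arrays[0], arrays[1],
                                        alternative="two-sided", method="auto").pvalue)
    if np.ptp(values) == 0:
        return 1.0
    return float(stats.kruskal(*arrays).pvalue)


def dunn_adjust(p_values) -> np.ndarray:
    """Multiplicity adjustment for Dunn's pairwise comparisons.

    Bonferroni over the m comparisons performed: adjusted p = min(1, m * p).
    A single comparison is returned unchanged.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one comparison")
    return np.minimum(1.0, p * p.size)


def dunn_posthoc(values, groups) -> pd.DataFrame:
    """Dunn's z-based pairwise comparisons after a Kruskal-Wallis test.

    Uses pooled mid-ranks with tie correction; returns a DataFrame with one
    row per group pair: z, raw two-sided p, and the adjusted p from
    ``dunn_adjust``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    size = {g: int((groups == g).sum()) for g in labels}
    rows = []
    for ga, gb in combinations(labels, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / size[ga] + 1.0 / size[gb]))
        z = (mean_rank[ga] - mean_rank[gb]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": ga, "group_b": gb, "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = dunn_adjust(out["p_raw"].to_numpy())
    return out


def _permanova_f(d2: np.ndarray, groups: np.ndarray, labels, n: int) -> float:
    """Pseudo-F from a squared-distance matrix and a grouping."""
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in labels:
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_among = ss_total - ss_within
    a = len(labels)
    if ss_within == 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(dist: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0) -> tuple:
    """One-way PERMANOVA on a distance matrix.

    Returns (pseudo-F, p) with p = (1 + #{permuted F >= observed F}) /
    (1 + n_perm). Groups of size one are allowed (their within-group sum of
    squares is zero) with a warning.
    """
    groups = np.asarray(groups)
    d2 = np.asarray(dist.data, dtype=float) ** 2
    n = d2.shape[0]
    if len(groups) != n:
        raise ValueError("grouping length must match the distance matrix")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    sizes = [(groups == g).sum() for g in labels]
    if any(s == 1 for s in sizes):
        logger.warning("PERMANOVA grouping contains singleton group(s)")
    f_obs = _permanova_f(d2, groups, labels, n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        if _permanova_f(d2, perm, labels, n) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)
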