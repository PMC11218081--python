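"""LEfSe-style discriminative-taxon detection between two clinical classes.

Per feature (taxon at a chosen rank, as relative abundance scaled to the
1e6 convention): (1) a Kruskal-Wallis screen across the two classes at
``kw_alpha``; (2) an optional subclass consistency check - pairwise Wilcoxon
between subclasses across classes must agree in sign; (3) an effect size
from repeated bootstrap rounds of a one-dimensional linear discriminant on
the surviving feature, reported as log10 of the absolute class-mean
discriminant difference. A feature is a discriminative signature iff it
passes the screen and consistency check and its log score exceeds the
cutoff (default 2).
"""

from __future__ import annotations

import logging
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import CountTable, RANKS

logger = logging.getLogger(__name__)

ABUNDANCE_SCALE = 1e6


def taxonomy_rollup(counts: CountTable, taxonomy: pd.DataFrame, level: str) -> CountTable:
    """Sum counts within each label of a taxonomic rank.

    Taxa missing from the taxonomy, or classified 'unclassified' at the
    requested rank, pool into ``unclassified_<rank>``. Column (sample) sums
    are conserved. Label order follows first appearance in the input table.
    """
    if level not in RANKS:
        raise ValueError(f"unknown rank {level!r}; expected one of {RANKS}")
    fallback = f"unclassified_{level}"
    if level in taxonomy.columns:
        mapping = taxonomy[level].to_dict()
    else:
        mapping = {}
    labels = []
    for t in counts.taxon_ids:
        lab = mapping.get(t, "unclassified")
        labels.append(fallback if lab in ("", "unclassified") else lab)
    order = list(pd.unique(pd.Series(labels)))
    pos = {lab: i for i, lab in enumerate(order)}
    mat = np.zeros((len(order), counts.n_samples), dtype=np.int64)
    for row, lab in zip(counts.counts, labels):
        mat[pos[lab]] += row
    return CountTable(order, list(counts.sample_ids), mat)


def _subclass_consistent(x: np.ndarray, classes: np.ndarray, subclasses: np.ndarray,
                         class_labels) -> bool:
    """Pairwise Wilcoxon/MW between subclasses across the two classes must
    agree in direction (no significant pair may contradict the class-level
    sign)."""
    ca, cb = class_labels
    subs_a = pd.unique(subclasses[classes == ca])
    subs_b = pd.unique(subclasses[classes == cb])
    overall = np.sign(x[classes == ca].mean() - x[classes == cb].mean())
    for sa, sb in product(subs_a, subs_b):
        xa = x[(classes == ca) & (subclasses == sa)]
        xb = x[(classes == cb) & (subclasses == sb)]
        if len(xa) == 0 or len(xb) == 0:
            continue
        diff = np.sign(xa.mean() - xb.mean())
        if diff != 0 and overall != 0 and diff != overall:
            return False
    return True


def lefse(
    relabund,
    classes,
    subclasses=None,
    kw_alpha: float = 0.05,
    lda_cutoff: float = 2.0,
    n_boot: int = 30,
    boot_frac: float = 2.0 / 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-class LEfSe-style differential abundance.

    ``relabund`` is a RelAbundanceTable (or anything with ``taxon_ids``,
    ``sample_ids`` and a taxa x samples ``fractions`` array); ``classes`` is
    a per-sample label array with exactly two distinct values. Returns one
    row per retained feature: kw_p, passed_subclass, lda_log_score,
    enriched_class, significant.
    """
    X = np.asarray(relabund.fractions, dtype=float) * ABUNDANCE_SCALE
    classes = np.asarray(classes)
    if len(classes) != X.shape[1]:
        raise ValueError("class labels must match the sample count")
    class_labels = list(pd.unique(classes))
    if len(class_labels) != 2:
        raise ValueError(f"exactly 2 classes required, got {class_labels}")
    if subclasses is not None:
        subclasses = np.asarray(subclasses)

    ca, cb = class_labels
    ia, ib = np.flatnonzero(classes == ca), np.flatnonzero(classes == cb)
    rng = np.random.default_rng(seed)
    # Pre-draw stratified bootstrap index sets shared across features.
    na = max(1, int(round(boot_frac * len(ia))))
    nb = max(1, int(round(boot_frac * len(ib))))
    boots = [
        (rng.choice(ia, size=na, replace=False), rng.choice(ib, size=nb, replace=False))
        for _ in range(n_boot)
    ]

    rows = []
    for i, taxon in enumerate(relabund.taxon_ids):
        x = X[i]
        if not x.any():
            logger.info("feature %s is all-zero; dropped", taxon)
            continue
        if np.ptp(x) == 0:
            kw_p = 1.0
        else:
            kw_p = float(stats.kruskal(x[ia], x[ib]).pvalue)
        passed_kw = kw_p < kw_alpha
        passed_sub = True
        if passed_kw and subclasses is not None:
            passed_sub = _subclass_consistent(x, classes, subclasses, class_labels)
        # Bootstrap LDA effect size: mean class difference of the (one-
        # dimensional) discriminant over subsampled rounds.
        diffs = [x[sa].mean() - x[sb].mean() for sa, sb in boots]
        effect = abs(float(np.mean(diffs)))
        score = float(np.log10(max(effect, 1e-10)))
        mean_a, mean_b = x[ia].mean(), x[ib].mean()
        if mean_a != mean_b:
            enriched = ca if mean_a > mean_b else cb
        else:  # tie on means: break by higher median
            enriched = ca if np.median(x[ia]) >= np.median(x[ib]) else cb
        rows.append(
            {
                "feature": taxon,
                "kw_p": kw_p,
                "passed_subclass": bool(passed_sub),
                "lda_log_score": score,
                "enriched_class": enriched,
                "significant": bool(passed_kw and passed_sub and score > lda_cutoff),
            }
        )
    return pd.DataFrame(rows).set_index("feature")
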