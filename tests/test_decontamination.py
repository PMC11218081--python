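from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import fgtmicro as fg


def _meta(n_true, n_ctrl):
    rows = []
    for i in range(n_true):
        rows.append((f"s{i}", f"p{i}", "higher_vagina", "benign", "none", "swab"))
    for i in range(n_ctrl):
        rows.append((f"c{i}", "none", "control", "control", "air", "swab"))
    return pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "site", "group", "control_type", "material"]
    )


def _presence_table(present_true, n_true, present_ctrl, n_ctrl, taxon="tax"):
    """Counts with a given presence pattern plus a ubiquitous anchor taxon."""
    row = [1] * present_true + [0] * (n_true - present_true)
    row += [1] * present_ctrl + [0] * (n_ctrl - present_ctrl)
    anchor = [1] * (n_true + n_ctrl)
    ids = [f"s{i}" for i in range(n_true)] + [f"c{i}" for i in range(n_ctrl)]
    return fg.CountTable([taxon, "anchor"], ids, np.array([row, anchor]))


def fisher_one_sided_oracle(a, b, c, d):
    """P(X >= a) for X ~ Hypergeom(N, a+c, a+b): over-representation in controls."""
    n_total = a + b + c + d
    return float(hypergeom.sf(a - 1, n_total, a + c, a + b))


def test_taxon_absent_from_controls_never_flagged():
    counts = _presence_table(30, 40, 0, 8)
    report = fg.score_contaminants(counts, _meta(40, 8))
    assert not report.loc["tax", "is_contaminant"]


def test_fisher_branch_matches_hypergeometric_enumeration():
    # 5/5 controls vs 1/10 samples: exact one-sided p, flagged at 0.5
    counts = _presence_table(1, 10, 5, 5)
    report = fg.score_contaminants(counts, _meta(10, 5))
    expected = fisher_one_sided_oracle(5, 0, 1, 9)
    assert report.loc["tax", "test"] == "fisher"
    assert report.loc["tax", "p_value"] == pytest.approx(expected, rel=1e-12)
    assert report.loc["tax", "is_contaminant"]


def test_prevalence_p_matches_oracle_on_small_margins():
    """Fisher-branch p equals exhaustive hypergeometric tail for margins <= 12."""
    for a, b, c, d in product(range(0, 5), repeat=4):
        if a + c == 0 or a + b == 0 or c + d == 0:
            continue
        counts = _presence_table(c, c + d, a, a + b)
        report = fg.score_contaminants(counts, _meta(c + d, a + b))
        row = report.loc["tax"]
        if row["test"] == "fisher":
            assert row["p_value"] == pytest.approx(
                fisher_one_sided_oracle(a, b, c, d), rel=1e-9
            ), (a, b, c, d)


def test_scoring_invariant_to_per_sample_scaling(decontam_dataset):
    table, meta, _ = decontam_dataset
    scaled = fg.CountTable(
        list(table.taxon_ids), list(table.sample_ids), table.counts * 7
    )
    r1 = fg.score_contaminants(table, meta)
    r2 = fg.score_contaminants(scaled, meta)
    pd.testing.assert_frame_equal(r1, r2)


def test_recovers_spiked_contaminants(decontam_dataset):
    """Prevalence test recovers the generator's kitome flags (recall/precision)."""
    table, meta, truth = decontam_dataset
    assert (meta["group"] == "control").sum() == 8
    assert (meta["group"] != "control").sum() == 40
    report = fg.score_contaminants(table, meta, threshold=0.5)
    flagged = set(report.index[report["is_contaminant"]])
    true_contam = set(truth.contaminant_taxa()) & set(report.index)
    assert len(true_contam) == 20
    tp = len(flagged & true_contam)
    assert tp / len(true_contam) >= 0.9  # recall
    assert tp / max(len(flagged), 1) >= 0.8  # precision


def test_remove_contaminants_arithmetic_and_identity(decontam_dataset):
    table, meta, _ = decontam_dataset
    report = fg.score_contaminants(table, meta)
    cleaned = fg.remove_contaminants(table, report)
    flagged = report.index[report["is_contaminant"]]
    kept = [t for t in table.taxon_ids if t not in set(flagged)]
    assert cleaned.taxon_ids == kept
    assert cleaned.sample_ids == table.sample_ids
    removed = table.select_taxa(list(flagged)).counts.sum(axis=0)
    assert np.array_equal(table.sample_sums() - removed, cleaned.sample_sums())
    # zero flags -> identity
    none = report.copy()
    none["is_contaminant"] = False
    same = fg.remove_contaminants(table, none)
    assert np.array_equal(same.counts, table.counts)
    # unknown taxa -> error
    bogus = report.rename(index={report.index[0]: "not_a_taxon"})
    with pytest.raises(ValueError, match="unknown"):
        fg.remove_contaminants(table, bogus)


def test_rescoring_after_removal_flags_nothing(decontam_dataset):
    table, meta, _ = decontam_dataset
    report = fg.score_contaminants(table, meta)
    cleaned = fg.remove_contaminants(table, report)
    rescore = fg.score_contaminants(cleaned, meta)
    assert not rescore["is_contaminant"].any()


def test_low_information_filter_rules():
    n = 20
    taxa, rows = [], []
    # boundary: >=5 counts in exactly 2/20 = 10% of samples -> retained
    taxa.append("keep_boundary")
    rows.append([5, 5] + [0] * (n - 2))
    # never reaches 5 anywhere -> removed by prevalence rule
    taxa.append("drop_low")
    rows.append([4] * n)
    for i in range(8):  # filler taxa with increasing IQR
        taxa.append(f"t{i:02d}")
        rows.append(list(range(10 + i, 10 + i + n)))
    table = fg.CountTable(taxa, [f"s{i}" for i in range(n)], np.array(rows))
    filtered, removed = fg.filter_low_information(table, 5, 0.10, iqr_drop_frac=0.0)
    assert "keep_boundary" in filtered.taxon_ids
    assert removed["prevalence"] == ["drop_low"]
    with pytest.raises(ValueError):
        fg.filter_low_information(table, min_count=0)


def test_iqr_filter_removes_exact_fraction():
    """With 100 survivors and a 5% drop fraction, exactly the 5 lowest-IQR go."""
    rng = np.random.default_rng(0)
    n = 40
    taxa = [f"t{i:03d}" for i in range(100)]
    spread = np.arange(1, 101)  # taxon i has counts spanning ~spread[i]
    rows = [10 + rng.integers(0, s + 1, size=n) + 5 for s in spread]
    table = fg.CountTable(taxa, [f"s{i}" for i in range(n)], np.array(rows))
    from scipy.stats import iqr

    filtered, removed = fg.filter_low_information(table, 5, 0.10, iqr_drop_frac=0.05)
    assert len(removed["iqr"]) == 5
    kept_iqr = iqr(filtered.counts, axis=1).min()
    dropped = table.select_taxa(removed["iqr"])
    assert iqr(dropped.counts, axis=1).max() <= kept_iqr + 1e-12
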