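import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import fgtmicro as fg
from fgtmicro.continuum import RelAbundanceTable


# --- rarefaction -----------------------------------------------------------

def test_rarefy_conserves_depth_and_caps_counts(default_dataset):
    table, _, _ = default_dataset
    rare = fg.rarefy(table, depth=1000, seed=3)
    assert (rare.sample_sums() == 1000).all()
    original = table.select_samples(rare.sample_ids)
    assert (rare.counts <= original.counts).all()


def test_rarefy_identity_at_full_depth(small_counts):
    sub = small_counts.select_samples(["s3"])  # total = 20
    rare = fg.rarefy(sub, depth=20, seed=0, min_depth=1)
    assert np.array_equal(rare.counts, sub.counts)


def test_rarefy_min_drops_shallow_samples(small_counts):
    # totals are 4, 10, 20 -> with floor 10 the depth is 10 and s1 is dropped
    rare = fg.rarefy(small_counts, depth="min", seed=1, min_depth=10)
    assert rare.sample_ids == ["s2", "s3"]
    assert (rare.sample_sums() == 10).all()
    with pytest.raises(ValueError):
        fg.rarefy(small_counts, depth=0)


def test_rarefied_fraction_matches_hypergeometric_expectation():
    """A taxon holding 50% of reads keeps a mean fraction of 0.50 after rarefying."""
    table = fg.CountTable(["a", "b"], ["s"], np.array([[10000], [10000]]))
    fracs = [
        fg.rarefy(table, depth=10000, seed=s).counts[0, 0] / 10000 for s in range(500)
    ]
    sd = np.sqrt(hypergeom(20000, 10000, 10000).var()) / 10000
    assert abs(np.mean(fracs) - 0.5) <= 3 * sd / np.sqrt(500)


# --- hierarchical clustering ----------------------------------------------

def _ra(matrix, taxa=None, samples=None):
    taxa = taxa or [f"t{i}" for i in range(matrix.shape[0])]
    samples = samples or [f"s{j}" for j in range(matrix.shape[1])]
    return RelAbundanceTable(taxa, samples, matrix)


def test_identical_samples_co_cluster():
    X = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    _, labels = fg.hca_clusters(_ra(X), k=2)
    assert labels["s0"] == labels["s1"] != labels["s2"]


def test_duplicated_samples_merge_first():
    rng = np.random.default_rng(1)
    X = rng.dirichlet(np.ones(5), size=6).T
    dup = np.column_stack([X, X])
    ra = _ra(dup, samples=[f"s{j}" for j in range(12)])
    for k in (2, 4, 6):
        _, labels = fg.hca_clusters(ra, k=k)
        for j in range(6):
            assert labels[f"s{j}"] == labels[f"s{j + 6}"]
    with pytest.raises(ValueError):
        fg.hca_clusters(ra, k=13)


def test_recovers_three_dirichlet_modes():
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(3)
    modes = [np.array([20, 1, 1, 1, 1]), np.array([1, 20, 1, 1, 1]), np.array([1, 1, 20, 1, 1])]
    truth = [i % 3 for i in range(60)]
    X = np.vstack([rng.dirichlet(modes[t]) for t in truth]).T
    _, labels = fg.hca_clusters(_ra(X), k=3)
    assert adjusted_rand_score(truth, labels.to_numpy()) >= 0.9


# --- rule-based community labels -------------------------------------------

@pytest.mark.parametrize(
    "fractions, site, expected",
    [
        ({"Lactobacillus": 0.80, "Gardnerella": 0.20}, "higher_vagina", "lactobacillus_dominant"),
        ({"Gardnerella": 0.55, "Lactobacillus": 0.35, "Prevotella": 0.10}, "cervix",
         "gardnerella_lactobacillus"),
        ({"Streptococcus": 0.40, "Lactobacillus": 0.30, "Prevotella": 0.30}, "lower_vagina",
         "streptococcus_dominant"),
        # the Streptococcus rule is vagina-only
        ({"Streptococcus": 0.40, "Lactobacillus": 0.30, "Prevotella": 0.30}, "cervix",
         "high_diversity_other"),
        # Gardnerella high but Lactobacillus not second -> falls through
        ({"Gardnerella": 0.55, "Prevotella": 0.30, "Lactobacillus": 0.15}, "cervix",
         "high_diversity_other"),
        ({f"g{i}": 0.05 for i in range(20)}, "higher_vagina", "high_diversity_other"),
    ],
)
def test_assign_cluster_label_precedence(fractions, site, expected):
    a = fg.assign_cluster_label(pd.Series(fractions), site)
    assert a.label == expected
    assert a.rule_trace


def test_assign_cluster_label_requires_normalised_input():
    with pytest.raises(ValueError, match="sum to 1"):
        fg.assign_cluster_label(pd.Series({"Lactobacillus": 0.5}), "cervix")


def test_boundary_thresholds_inclusive():
    a = fg.assign_cluster_label(
        pd.Series({"Lactobacillus": 0.75, "Gardnerella": 0.25}), "cervix"
    )
    assert a.label == "lactobacillus_dominant"
    b = fg.assign_cluster_label(
        pd.Series({"Streptococcus": 0.36, "Lactobacillus": 0.34, "Gardnerella": 0.30}),
        "lower_vagina",
    )
    assert b.label == "streptococcus_dominant"


# --- frequency statistics ---------------------------------------------------

def test_chi_squared_matches_formula_oracle():
    rng = np.random.default_rng(8)
    for _ in range(30):
        tab = rng.integers(1, 40, size=(rng.integers(2, 4), rng.integers(2, 5)))
        stat, df, p = fg.chi_squared_test(tab)
        expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
        oracle = ((tab - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(oracle, abs=1e-10)
        assert df == (tab.shape[0] - 1) * (tab.shape[1] - 1)


def test_chi_squared_identical_rows_is_null():
    stat, df, p = fg.chi_squared_test([[5, 10, 5], [5, 10, 5]])
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi_squared_drops_zero_columns():
    stat, df, p = fg.chi_squared_test([[5, 0, 10], [5, 0, 10]])
    assert df == 1
    assert p == pytest.approx(1.0)
    # degenerate to a single informative column
    stat, df, p = fg.chi_squared_test([[5, 0], [7, 0]])
    assert (stat, df, p) == (0.0, 0, 1.0)


def test_fisher_or_symmetric_table():
    res = fg.fisher_or([[1, 1], [1, 1]])
    assert res["odds_ratio"] == 1.0
    assert res["p_value"] == 1.0


def test_fisher_or_degenerate_cells_noted():
    res = fg.fisher_or([[5, 0], [3, 2]])
    assert np.isinf(res["odds_ratio"])
    assert res["note"]
    with pytest.raises(ValueError):
        fg.fisher_or([[1, 2, 3], [4, 5, 6]])


def test_fisher_exact_p_matches_enumeration_oracle():
    """Two-sided exact p equals brute-force hypergeometric enumeration."""
    from scipy.stats import hypergeom

    rng = np.random.default_rng(2)
    for _ in range(40):
        a, b, c, d = rng.integers(0, 13, size=4)
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            continue
        n, r1, c1 = a + b + c + d, a + b, a + c
        dist = hypergeom(n, r1, c1)
        support = range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
        p_obs = dist.pmf(a)
        oracle = sum(dist.pmf(k) for k in support if dist.pmf(k) <= p_obs * (1 + 1e-12))
        res = fg.fisher_or([[a, b], [c, d]])
        assert res["p_value"] == pytest.approx(oracle, rel=1e-9), (a, b, c, d)


def _assignments(labels, sites="higher_vagina"):
    n = len(labels)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "site": sites,
            "label": labels,
            "rule_trace": "",
        }
    )


def _meta(groups):
    n = len(groups)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "patient_id": [f"p{i}" for i in range(n)],
            "site": "higher_vagina",
            "group": groups,
            "control_type": "none",
            "material": "swab",
        }
    )


def test_type_frequency_comparison_builds_table_and_tests():
    labels = ["lactobacillus_dominant"] * 6 + ["high_diversity_other"] * 4
    groups = ["benign"] * 5 + ["cancer"] * 5
    tab, (stat, df, p) = fg.type_frequency_comparison(
        _assignments(labels), _meta(groups), "higher_vagina"
    )
    assert tab.to_numpy().sum() == 10
    assert df == 1
    with pytest.raises(ValueError, match="2 clinical groups"):
        fg.type_frequency_comparison(_assignments(labels), _meta(["benign"] * 10), "higher_vagina")


def test_type_frequency_all_same_label_is_degenerate():
    labels = ["high_diversity_other"] * 10
    groups = ["benign"] * 5 + ["cancer"] * 5
    _, (stat, df, p) = fg.type_frequency_comparison(
        _assignments(labels), _meta(groups), "higher_vagina"
    )
    assert p == 1.0
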