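import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fgtmicro as fg
from fgtmicro.continuum import RelAbundanceTable, venn_regions
from fgtmicro.synthetic_data import SimulationParams


def _ra(frame):
    return RelAbundanceTable(list(frame.index), list(frame.columns), frame.to_numpy())


def test_relative_abundance_normalises_and_handles_empty(small_counts):
    ra = fg.relative_abundance(small_counts)
    assert np.allclose(ra.fractions[:, 0], [0.75, 0.25, 0, 0])
    scaled = fg.CountTable(small_counts.taxon_ids, small_counts.sample_ids, small_counts.counts * 7)
    assert np.allclose(fg.relative_abundance(scaled).fractions, ra.fractions)
    empty = fg.CountTable(["a"], ["s1"], np.array([[0]]))
    assert fg.relative_abundance(empty).fractions.sum() == 0.0


def test_prevalent_taxa_threshold_inclusive():
    frame = pd.DataFrame(
        {"s": [0.005, 0.0049, 0.99, 0.0001]}, index=["A", "B", "C", "D"]
    )
    ra = _ra(frame)
    assert fg.prevalent_taxa(ra, "s", 0.005) == {"A", "C"}
    assert fg.prevalent_taxa(ra, "s", 0.0) == {"A", "B", "C", "D"}  # all nonzero
    with pytest.raises(KeyError):
        fg.prevalent_taxa(ra, "nope")


def test_sorensen_printed_formula_cases():
    assert fg.sorensen({"A", "B"}, {"A", "B"}) == 1.0
    assert fg.sorensen({"A"}, {"B"}) == 0.0
    assert fg.sorensen({"A", "B", "C"}, {"B", "C", "D"}) == pytest.approx(2 * 2 / 6)
    assert fg.sorensen(set(), set()) == 0.0


@settings(derandomize=True, max_examples=200)
@given(
    s1=st.sets(st.integers(0, 30), max_size=15),
    s2=st.sets(st.integers(0, 30), max_size=15),
)
def test_sorensen_properties(s1, s2):
    d = fg.sorensen(s1, s2)
    assert d == fg.sorensen(s2, s1)
    assert 0.0 <= d <= 1.0
    if s1 or s2:
        assert (d == 1.0) == (s1 == s2)
        # Jaccard identity: DSC = 2J / (1 + J)
        j = len(s1 & s2) / len(s1 | s2)
        assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)


def _meta_for(patient, sites):
    return pd.DataFrame(
        {
            "sample_id": [f"{patient}_{s}" for s in sites],
            "patient_id": patient,
            "site": sites,
            "group": "benign",
            "control_type": "none",
            "material": "swab",
        }
    )


def test_continuum_profile_identical_sites_fully_shared():
    sites = ["higher_vagina", "endometrium_higher"]
    frame = pd.DataFrame(
        {f"p1_{s}": [0.6, 0.3, 0.1] for s in sites}, index=["A", "B", "C"]
    )
    res = fg.continuum_profile(_ra(frame), _meta_for("p1", sites), "p1", sites)
    assert (res.pairwise["dsc"] == 1.0).all()
    assert res.venn == {frozenset(sites): 3}
    assert res.full_continuum is True


def test_continuum_profile_hand_enumerated_set_algebra():
    # sets {A,B}, {B,C}, {C} at three sites
    sites = ["higher_vagina", "cervix", "endometrium_higher"]
    cols = {
        "p1_higher_vagina": [0.5, 0.5, 0.0],
        "p1_cervix": [0.0, 0.5, 0.5],
        "p1_endometrium_higher": [0.0, 0.0, 1.0],
    }
    frame = pd.DataFrame(cols, index=["A", "B", "C"])
    res = fg.continuum_profile(_ra(frame), _meta_for("p1", sites), "p1", sites)
    pw = res.pairwise.set_index(["site_a", "site_b"])["dsc"]
    assert pw[("higher_vagina", "cervix")] == pytest.approx(0.5)
    assert pw[("cervix", "endometrium_higher")] == pytest.approx(2 / 3)
    assert pw[("higher_vagina", "endometrium_higher")] == 0.0
    assert res.venn == {
        frozenset({"higher_vagina"}): 1,
        frozenset({"higher_vagina", "cervix"}): 1,
        frozenset({"cervix", "endometrium_higher"}): 1,
    }
    # Venn region counts sum to the union size
    assert sum(res.venn.values()) == 3
    # top vaginal taxon A (tie broken to A) absent upstream -> no full continuum
    assert res.full_continuum is False


def test_continuum_profile_skips_unmatched_patient():
    sites = ["higher_vagina", "endometrium_higher"]
    frame = pd.DataFrame({"p1_higher_vagina": [1.0]}, index=["A"])
    res = fg.continuum_profile(
        _ra(frame), _meta_for("p1", ["higher_vagina"]), "p1", sites
    )
    assert res is None


def test_venn_regions_sum_to_union_on_random_sets():
    rng = np.random.default_rng(0)
    for _ in range(50):
        sets = {
            f"site{k}": set(rng.choice(20, size=rng.integers(0, 10), replace=False))
            for k in range(4)
        }
        regions = venn_regions(sets)
        assert sum(regions.values()) == len(set().union(*sets.values()))


def test_dsc_monotone_in_continuum_weight():
    """Stronger ascension (larger w) gives larger vagina<->endometrium overlap."""
    medians = {}
    for w in (0.1, 0.9):
        params = SimulationParams(continuum_w=w)
        table, meta, truth = fg.simulate_dataset(
            50, 1, params=params, seed=11,
            sites=("higher_vagina", "endometrium_higher"), controls_per_type=0,
        )
        ra = fg.relative_abundance(table)
        dscs = []
        for pid in truth.lower_gt_composition:
            if not pid.startswith("B"):
                continue
            res = fg.continuum_profile(
                ra, meta, pid, ["higher_vagina", "endometrium_higher"]
            )
            dscs.append(res.pairwise["dsc"].iloc[0])
        medians[w] = np.median(dscs)
    assert medians[0.9] > medians[0.1]


def test_paired_r2_against_direct_pearson():
    frame = pd.DataFrame(
        {"a": [0.5, 0.3, 0.2], "b": [0.2, 0.3, 0.5]}, index=["A", "B", "C"]
    )
    ra = _ra(frame)
    x, y = np.array([0.5, 0.3, 0.2]), np.array([0.2, 0.3, 0.5])
    r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert fg.paired_composition_r2(ra, "a", "b") == pytest.approx(r_oracle**2, rel=1e-12)
    # self-pairing and exact proportionality are perfect
    assert fg.paired_composition_r2(ra, "a", "a") == pytest.approx(1.0)
    # fewer than 3 taxa in the union -> missing
    tiny = _ra(pd.DataFrame({"a": [0.5, 0.5, 0.0], "b": [0.4, 0.6, 0.0]}, index=list("ABC")))
    assert fg.paired_composition_r2(tiny, "a", "b") is None
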