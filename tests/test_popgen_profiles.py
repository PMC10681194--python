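"""Frequency profiles, G-test calibration pieces, p-distances and NJ trees."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faw_haplotyper.coib_typing import CoibCall
from faw_haplotyper.popgen_profiles import (
    DistanceMatrix,
    PopulationProfile,
    build_profile,
    compare_profiles,
    g_statistic,
    holm_adjust,
    nj_tree,
    pairwise_comparisons,
    pdistance_matrix,
    reference_joint_alignment,
    snp_strain_composition,
)
from faw_haplotyper.sequence_core import SpecimenRecord


def _meta(n, population="P1"):
    return [SpecimenRecord(f"{population}_{i}", population, 2021, "corn", "T") for i in range(n)]


def _coib(specimen_id, category, variant=None):
    return CoibCall(specimen_id, category, None, variant)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def test_profile_frequencies():
    calls = (
        [_coib(f"P1_{i}", "CSh1") for i in range(2)]
        + [_coib(f"P1_{i+2}", "CSh2") for i in range(6)]
        + [_coib(f"P1_{i+8}", "CSh4") for i in range(2)]
    )
    (profile,) = build_profile(calls, _meta(10), "COIB-category")
    assert profile.counts == {"CSh1": 2, "CSh2": 6, "CSh4": 2}
    assert profile.frequencies == {"CSh1": 0.2, "CSh2": 0.6, "CSh4": 0.2}
    assert abs(sum(profile.frequencies.values()) - 1.0) < 1e-12


def test_profile_excludes_untyped():
    calls = [_coib(f"P1_{i}", "CSh2") for i in range(7)] + [
        _coib(f"P1_{i+7}", "ambiguous") for i in range(3)
    ]
    (profile,) = build_profile(calls, _meta(10), "COIB-category")
    assert profile.total == 7
    assert profile.n_excluded == 3


def test_empty_call_list_gives_empty_profile():
    assert build_profile([], _meta(3), "COIB-category") == []
    (profile,) = build_profile(
        [_coib("P1_0", "no_call")], _meta(1), "COIB-category"
    )
    assert profile.total == 0
    assert profile.frequencies == {}


def test_unknown_specimen_rejected():
    with pytest.raises(ValueError, match="missing from metadata"):
        build_profile([_coib("ghost", "CSh2")], _meta(2), "COIB-category")


def test_grouping_by_population_and_year():
    meta = [
        SpecimenRecord("a", "TX", 2004, "corn", "T"),
        SpecimenRecord("b", "TX", 2007, "corn", "T"),
        SpecimenRecord("c", "TX", 2007, "corn", "T"),
    ]
    calls = [_coib("a", "CSh2"), _coib("b", "CSh2"), _coib("c", "CSh4")]
    profiles = build_profile(calls, meta, "COIB-category", keys=("population", "year"))
    assert [p.population for p in profiles] == ["TX/2004", "TX/2007"]
    assert profiles[1].counts == {"CSh2": 1, "CSh4": 1}


def test_snp_strain_composition():
    profile = snp_strain_composition(
        {"s1": "C/C", "s2": "C/C", "s3": "C/R", "s4": "R/R"}
    )
    assert profile.frequencies == {"C-strain": 0.5, "heterozygote": 0.25, "R-strain": 0.25}
    all_c = snp_strain_composition({f"s{i}": "C/C" for i in range(5)})
    assert all_c.frequencies == {"C-strain": 1.0}
    assert snp_strain_composition({}).total == 0
    with pytest.raises(ValueError, match="unknown SNP C"):
        snp_strain_composition({"s1": "C/T"})


# ---------------------------------------------------------------------------
# G-test
# ---------------------------------------------------------------------------


def test_g_statistic_known_value():
    # rows (10,0) vs (0,10): G = 2 * (10 ln 2 + 10 ln 2) = 40 ln 2
    assert g_statistic([[10, 0], [0, 10]]) == pytest.approx(40 * math.log(2))


def test_g_zero_iff_proportional_rows():
    assert g_statistic([[5, 10, 5], [10, 20, 10]]) == pytest.approx(0.0, abs=1e-12)
    assert g_statistic([[5, 10], [10, 5]]) > 0


@given(
    st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)), min_size=2, max_size=6)
)
@settings(derandomize=True, max_examples=30)
def test_g_invariant_under_category_reordering(cols):
    table = np.array(cols).T
    if table.sum() == 0:
        return
    rng = np.random.default_rng(0)
    perm = rng.permutation(table.shape[1])
    assert g_statistic(table) == pytest.approx(g_statistic(table[:, perm]))


def _profile(pop, counts):
    return PopulationProfile(pop, "COIB-category", counts)


def test_identical_profiles_not_significant():
    p1 = _profile("A", {"CSh1": 10, "CSh2": 30})
    p2 = _profile("B", {"CSh1": 10, "CSh2": 30})
    comp = compare_profiles(p1, p2, replicates=500, seed=0)
    assert comp.statistic == pytest.approx(0.0, abs=1e-12)
    assert comp.p_permutation > 0.99


def test_disjoint_profiles_strongly_significant():
    comp = compare_profiles(
        _profile("A", {"x": 10}), _profile("B", {"y": 10}), replicates=2000, seed=1
    )
    assert comp.statistic == pytest.approx(40 * math.log(2))
    assert comp.p_permutation < 0.01


def test_single_category_not_computable():
    comp = compare_profiles(
        _profile("A", {"x": 10}), _profile("B", {"x": 5}), replicates=100, seed=0
    )
    assert not comp.computable


def test_marker_mismatch_rejected():
    p1 = _profile("A", {"x": 1})
    p2 = PopulationProfile("B", "Tpi-strain", {"x": 1})
    with pytest.raises(ValueError, match="different markers"):
        compare_profiles(p1, p2)


def test_permutation_seed_reproducible():
    p1 = _profile("A", {"x": 12, "y": 18})
    p2 = _profile("B", {"x": 20, "y": 10})
    a = compare_profiles(p1, p2, replicates=1000, seed=7)
    b = compare_profiles(p1, p2, replicates=1000, seed=7)
    assert a.p_permutation == b.p_permutation


def test_holm_adjustment_known_example():
    # sorted p: .005*4=.02, .01*3=.03, .03*2=.06, .04*1=.04 lifted to .06
    adj = holm_adjust([0.01, 0.04, 0.03, 0.005])
    assert adj == pytest.approx([0.03, 0.06, 0.06, 0.02])


def test_plot_profiles_writes_figure(tmp_path):
    pytest.importorskip("matplotlib")
    from faw_haplotyper.popgen_profiles import plot_profiles

    profiles = [
        _profile("TX", {"CSh1": 2, "CSh2": 7, "CSh4": 1}),
        _profile("FL", {"CSh1": 1, "CSh2": 2, "CSh4": 7}),
    ]
    out = tmp_path / "profiles.png"
    plot_profiles(profiles, out)
    assert out.stat().st_size > 0


def test_pairwise_comparisons_count():
    profiles = [
        _profile("A", {"x": 5, "y": 5}),
        _profile("B", {"x": 6, "y": 4}),
        _profile("C", {"x": 1, "y": 9}),
    ]
    comps = pairwise_comparisons(profiles, replicates=200, seed=0)
    assert len(comps) == 3


# ---------------------------------------------------------------------------
# p-distances
# ---------------------------------------------------------------------------


def test_pdistance_basic_cases():
    d = pdistance_matrix({"a": "AAAA", "b": "AAAT", "c": "AAAA"})
    assert d["a", "b"] == pytest.approx(0.25)
    assert d["a", "c"] == 0.0
    assert np.allclose(d.matrix, d.matrix.T)
    assert np.all(np.diag(d.matrix) == 0)


def test_pdistance_pairwise_deletion():
    # gap column dropped: 0 mismatches over 3 compared columns
    d = pdistance_matrix({"a": "AA-A", "b": "AATA"})
    assert d["a", "b"] == 0.0
    # ambiguity also triggers pairwise deletion
    d = pdistance_matrix({"a": "AAYA", "b": "AATA"})
    assert d["a", "b"] == 0.0


def test_pdistance_no_comparable_columns_is_error():
    with pytest.raises(ValueError, match="no comparable columns"):
        pdistance_matrix({"a": "A--A", "b": "-TT-"})


def test_pdistance_requires_joint_alignment():
    with pytest.raises(ValueError, match="equal lengths"):
        pdistance_matrix({"a": "AAAA", "b": "AAA"})


def test_reference_joint_alignment_handles_indels():
    anchor = "ACGTACGTACGTACGTACGT"
    seqs = {
        "ref": anchor,
        "ins": anchor[:10] + "TTT" + anchor[10:],
        "del": anchor[:5] + anchor[8:],
    }
    joint = reference_joint_alignment(seqs, anchor)
    lengths = {len(s) for s in joint.values()}
    assert len(lengths) == 1
    for label, seq in seqs.items():
        assert joint[label].replace("-", "") == seq


# ---------------------------------------------------------------------------
# Neighbor-Joining
# ---------------------------------------------------------------------------


def test_nj_three_taxa_closed_form():
    d = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
    tree = nj_tree(d)
    lengths = {child.label: length for child, length in tree.root.children}
    assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})


def test_nj_needs_three_taxa():
    d = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float))
    with pytest.raises(ValueError, match="at least 3"):
        nj_tree(d)


from conftest import random_additive_matrix as _random_additive_matrix


def test_nj_recovers_additive_trees():
    rng = np.random.default_rng(5)
    for _ in range(10):
        n = int(rng.integers(4, 9))
        d = _random_additive_matrix(rng, n)
        tree = nj_tree(d)
        recovered = tree.tip_distances()
        order = [recovered.labels.index(l) for l in d.labels]
        back = recovered.matrix[np.ix_(order, order)]
        assert np.max(np.abs(back - d.matrix)) < 1e-9


def test_nj_matches_independent_implementation():
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(11)
    d = _random_additive_matrix(rng, 7)
    ours = nj_tree(d).tip_distances()
    sk_tree = skbio_nj(SkbioDM(d.matrix, ids=d.labels))
    for i, a in enumerate(d.labels):
        for j, b in enumerate(d.labels):
            if i < j:
                sk_d = sk_tree.find(a).distance(sk_tree.find(b))
                assert ours[a, b] == pytest.approx(sk_d, abs=1e-9)


def test_nj_ties_are_deterministic():
    d = DistanceMatrix(list("ABCDE"), np.ones((5, 5)) - np.eye(5))
    t1 = nj_tree(d).to_newick()
    t2 = nj_tree(d).to_newick()
    assert t1 == t2


def test_nj_newick_format():
    d = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
    nwk = nj_tree(d).to_newick()
    assert nwk == "(A:1.000000,B:1.000000,C:3.000000);"


def test_nj_negative_branch_clamping():
    # strongly non-additive matrix can produce a negative branch estimate
    m = np.array(
        [[0.0, 0.1, 0.6, 0.65], [0.1, 0.0, 0.65, 0.6], [0.6, 0.65, 0.0, 0.1], [0.65, 0.6, 0.1, 0.0]]
    )
    d = DistanceMatrix(list("ABCD"), m)
    clamped = nj_tree(d, clamp_negative=True)

    def lengths(node):
        for child, length in node.children:
            yield length
            yield from lengths(child)

    assert all(l >= 0 for l in lengths(clamped.root))
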