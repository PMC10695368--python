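"""HLA similarity and heterozygosity metrics against independent oracles."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import depth_tcr as d
from depth_tcr.metrics import AssociationProfile

REFS = [f"t{i}" for i in range(10)]

set_strategy = st.sets(st.integers(min_value=0, max_value=15), max_size=10)


def make_profile(score_map):
    return AssociationProfile(REFS, {a: np.asarray(v, dtype=float)
                                     for a, v in score_map.items()})


@pytest.fixture()
def random_profile():
    rng = np.random.default_rng(5)
    alleles = [f"{g}*{i:02d}" for g in "ABC" for i in (1, 2, 3)]
    return AssociationProfile(REFS, {a: rng.random(len(REFS))
                                     for a in alleles})


# ------------------------------------------------------------------- TCR sets

def test_allele_tcr_set_boundary_is_strict():
    profile = make_profile({"A*01": [0.4, 0.5, 0.6] + [0.0] * 7})
    assert d.allele_tcr_set(profile, "A*01") == {"t2"}
    empty = make_profile({"A*01": [0.0] * 10})
    assert d.allele_tcr_set(empty, "A*01") == frozenset()
    full = make_profile({"A*01": [1.0] * 10})
    assert d.allele_tcr_set(full, "A*01") == set(REFS)


def test_individual_union_breadth():
    # six disjoint sets of sizes 1..6 over a large reference
    refs = [f"t{i}" for i in range(25)]
    scores, start = {}, 0
    for k, size in enumerate([1, 2, 3, 4, 5, 6]):
        vec = np.zeros(25)
        vec[start:start + size] = 1.0
        scores[f"A*{k:02d}"] = vec
        start += size
    profile = AssociationProfile(refs, scores)
    union, breadth = d.individual_tcr_union(list(scores), profile)
    assert breadth == 21
    same = make_profile({"A*01": [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]})
    union, breadth = d.individual_tcr_union(["A*01"] * 6, same)
    assert union == {"t0", "t1"} and breadth == 2


def test_breadth_monotone_in_cutoff(random_profile):
    alleles = list(random_profile.scores)[:6]
    breadths = [d.individual_tcr_union(alleles, random_profile, cutoff)[1]
                for cutoff in (0.1, 0.3, 0.5, 0.7, 0.9)]
    assert all(a >= b for a, b in zip(breadths, breadths[1:]))


# -------------------------------------------------------------------- jaccard

def test_jaccard_examples():
    assert d.jaccard_distance({"t1", "t2", "t3"}, {"t2", "t3", "t4"}) == 0.5
    assert d.jaccard_distance({"a"}, {"a"}) == 0.0
    assert d.jaccard_distance({"a"}, {"b"}) == 1.0
    with pytest.warns(UserWarning):
        assert d.jaccard_distance(set(), set()) == 0.0


@settings(max_examples=300, deadline=None, derandomize=True)
@given(set_strategy, set_strategy, set_strategy)
def test_jaccard_is_a_metric(a, b, c):
    def dist(x, y):
        if not (x | y):
            return 0.0
        return d.jaccard_distance(x, y)

    assert dist(a, b) == dist(b, a)
    assert (dist(a, b) == 0) == (a == b)
    assert dist(a, c) <= dist(a, b) + dist(b, c) + 1e-12


# ------------------------------------------------------------------- spearman

def test_spearman_distance_examples():
    profile = make_profile({
        "A*01": np.linspace(0.1, 0.9, 10),
        "A*02": np.linspace(0.1, 0.9, 10),
        "A*03": np.linspace(0.9, 0.1, 10),
    })
    assert d.allele_distance_cor(profile, "A*01", "A*02") == pytest.approx(0.0)
    assert d.allele_distance_cor(profile, "A*01", "A*03") == pytest.approx(2.0)


def test_spearman_distance_hand_computed_ranks():
    refs = ["t0", "t1", "t2"]
    profile = AssociationProfile(refs, {
        "A*01": np.array([0.1, 0.2, 0.9]),
        "A*02": np.array([0.2, 0.1, 0.8]),
    })
    # ranks (1,2,3) vs (2,1,3): rho = 1 - 6*2/(3*8) = 0.5, distance 0.5
    assert d.allele_distance_cor(profile, "A*01", "A*02") == pytest.approx(0.5)


def test_spearman_constant_vector_warns_and_returns_neutral():
    profile = make_profile({"A*01": [0.5] * 10, "A*02": np.linspace(0, 1, 10)})
    with pytest.warns(UserWarning):
        assert d.allele_distance_cor(profile, "A*01", "A*02") == 1.0


# ----------------------------------------------------------- optimal transport

def test_ot_examples():
    assert d.optimal_transport_cost(np.zeros((6, 6))) == 0.0
    assert d.optimal_transport_cost(np.full((6, 6), 3.7)) == pytest.approx(3.7)
    assert d.optimal_transport_cost(np.array([[1.0, 2.0], [3.0, 0.0]])) == 0.5


def test_ot_rejects_invalid():
    with pytest.raises(ValueError):
        d.optimal_transport_cost(np.array([[1.0, -0.1], [0.2, 0.3]]))
    with pytest.raises(ValueError):
        d.optimal_transport_cost(np.ones((2, 3)))


def test_ot_matches_permutation_brute_force():
    rng = np.random.default_rng(11)
    for _ in range(25):
        cost = rng.random((6, 6))
        brute = min(sum(cost[i, p[i]] for i in range(6)) / 6
                    for p in itertools.permutations(range(6)))
        assert d.optimal_transport_cost(cost) == pytest.approx(brute, abs=1e-12)


# ------------------------------------------------- between-individual distances

def test_cost_matrix_shape_and_entries(random_profile):
    alleles = list(random_profile.scores)
    g1, g2 = alleles[:6], alleles[3:9]
    mat = d.between_individual_cost_matrix(
        g1, g2, lambda a, b: d.allele_distance_cor(random_profile, a, b))
    assert mat.shape == (6, 6)
    assert mat[0, 0] == pytest.approx(
        d.allele_distance_cor(random_profile, g1[0], g2[0]))
    # matched alleles give zero entries
    assert mat[3, 0] == pytest.approx(0.0)


def test_dist_breadth_fig_style_example():
    # |A|=5, |B|=4, |A and B|=3 -> (2+1)/6 = 0.5
    refs = [f"t{i}" for i in range(6)]
    profile = AssociationProfile(refs, {
        "A*01": np.array([1, 1, 1, 1, 1, 0], dtype=float),
        "B*01": np.array([0, 0, 1, 1, 1, 1], dtype=float),
    })
    assert d.dist_breadth(["A*01"] * 6, ["B*01"] * 6, profile) == 0.5


def test_dist_cor_zero_for_identical_genotypes(random_profile):
    g = list(random_profile.scores)[:6]
    assert d.dist_cor(g, g, random_profile) == pytest.approx(0.0)


def test_dist_cor_symmetry(random_profile):
    alleles = list(random_profile.scores)
    g1, g2 = alleles[:6], alleles[3:9]
    assert d.dist_cor(g1, g2, random_profile) == pytest.approx(
        d.dist_cor(g2, g1, random_profile))


def test_distance_matrix_invariants(random_profile):
    alleles = list(random_profile.scores)
    geno = pd.DataFrame({
        "individual_id": ["i1", "i2", "i3"],
        **{f"allele_{k + 1}": [alleles[(k + j) % 9] for j in range(3)]
           for k in range(6)},
    })
    for method in ("breadth", "cor"):
        mat = d.distance_matrix(geno, random_profile, method=method)
        arr = mat.to_numpy()
        np.testing.assert_allclose(arr, arr.T)
        np.testing.assert_allclose(np.diag(arr), 0.0)
        assert (arr >= 0).all()


# -------------------------------------------------------------- heterozygosity

def test_heterozygosity_fully_homozygous_individual(random_profile):
    a = list(random_profile.scores)[0]
    scores = d.heterozygosity_metrics("i1", [a] * 6, random_profile)
    assert scores.homozygous == 1
    assert scores.mean_depth_cor == 0.0
    assert scores.mean_depth_set == 0.0


def test_heterozygous_flag_zero_when_all_genes_heterozygous(random_profile):
    alleles = list(random_profile.scores)
    g = [alleles[0], alleles[1], alleles[3], alleles[4], alleles[6], alleles[7]]
    scores = d.heterozygosity_metrics("i1", g, random_profile)
    assert scores.homozygous == 0


def test_mean_of_per_gene_distances():
    """A genotype with known per-gene distances averages them."""
    refs = [f"t{i}" for i in range(5)]

    profile = AssociationProfile(refs, {
        "A*01": np.array([1, 1, 1, 1, 1], dtype=float),
        "A*02": np.array([1, 1, 1, 1, 0], dtype=float),  # jaccard 1/5
        "B*01": np.array([1, 1, 1, 0, 0], dtype=float),
        "B*02": np.array([1, 0, 0, 1, 0], dtype=float),  # jaccard 3/4
        "C*01": np.array([1, 0, 0, 0, 0], dtype=float),
        "C*02": np.array([1, 0, 0, 0, 0], dtype=float),  # jaccard 0
    })
    g = ["A*01", "A*02", "B*01", "B*02", "C*01", "C*02"]
    scores = d.heterozygosity_metrics("i1", g, profile)
    assert scores.mean_depth_set == pytest.approx((1 / 5 + 3 / 4 + 0) / 3)
    assert scores.depth_breadth == 5


def test_heterozygosity_table_and_mean_aa(small_world):
    universe, cohort, _ = small_world
    rng = np.random.default_rng(3)
    alleles = list(universe.pseudo_table["allele"])
    profile = AssociationProfile(REFS, {a: rng.random(10) for a in alleles})
    table = d.heterozygosity_table(cohort.genotypes.head(10), profile,
                                   universe.pseudo_table)
    assert len(table) == 10
    assert (table["mean_aa"] >= 0).all() and (table["mean_aa"] <= 1).all()
    assert set(table["homozygous"]) <= {0, 1}


# ------------------------------------------------------------------- mean AA

def test_mean_aa_identity_and_symmetry():
    assert d.mean_aa_allele_distance("ACDEF", "ACDEF") == 0.0
    x = d.mean_aa_allele_distance("ACDEF", "ACDEW")
    y = d.mean_aa_allele_distance("ACDEW", "ACDEF")
    assert x == pytest.approx(y)
    assert x > 0


def test_mean_aa_single_substitution_scaling():
    base = "A" * 34
    sub = "W" + "A" * 33
    per_residue = d.mean_aa_allele_distance("A", "W")
    assert d.mean_aa_allele_distance(base, sub) == pytest.approx(
        per_residue / 34)
    with pytest.raises(ValueError):
        d.mean_aa_allele_distance("ACD", "AC")


def test_association_profile_validation():
    with pytest.raises(ValueError):
        AssociationProfile(REFS, {"A*01": np.ones(3)})
    with pytest.raises(ValueError):
        AssociationProfile(REFS, {"A*01": np.full(10, 1.5)})
    profile = make_profile({"A*01": [0.2] * 10})
    with pytest.raises(KeyError):
        profile.score_vector("B*01")
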