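"""Co-occurrence testing, FDR, negative sampling and splits."""

import math
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import depth_tcr as d
from depth_tcr.discovery import ContingencyCounts, _largest_remainder
from depth_tcr.simulate import simulate


def hypergeom_tail_exact(n11, n10, n01, n00):
    """Independent oracle: exact upper-tail hypergeometric probability."""
    N, K, n = n11 + n10 + n01 + n00, n11 + n10, n11 + n01
    total = Fraction(0)
    for k in range(n11, min(K, n) + 1):
        total += Fraction(math.comb(K, k) * math.comb(N - K, n - k),
                          math.comb(N, n))
    return float(total)


# ---------------------------------------------------------------- contingency

def test_contingency_tiny_exhaustive_case():
    occ = d.OccurrenceMatrix(["i1", "i2", "i3", "i4"], ["t1"],
                             np.array([[1], [1], [0], [0]], dtype=bool))
    geno = pd.DataFrame({
        "individual_id": ["i1", "i2", "i3", "i4"],
        "allele_1": ["A*01", "A*01", "A*02", "A*02"],
        "allele_2": ["A*01"] * 4,
        "allele_3": ["B*01"] * 4, "allele_4": ["B*01"] * 4,
        "allele_5": ["C*01"] * 4, "allele_6": ["C*01"] * 4,
    })
    c = d.build_contingency(occ, geno, "t1", "A*02")
    assert (c.n11, c.n10, c.n01, c.n00) == (0, 2, 2, 0)
    c = d.build_contingency(occ, geno, "t1", "A*01")
    assert (c.n11, c.n10, c.n01, c.n00) == (2, 0, 2, 0)


def test_contingency_matches_brute_force_loop(small_world):
    universe, cohort, truth = small_world
    occ = d.OccurrenceMatrix.from_cohort(cohort)
    rng = np.random.default_rng(0)
    allele_cols = cohort.genotypes.filter(like="allele_")
    for _ in range(15):
        tcr = occ.tcrs[rng.integers(len(occ.tcrs))]
        allele = allele_cols.iloc[rng.integers(len(allele_cols)),
                                  rng.integers(6)]
        c = d.build_contingency(occ, cohort.genotypes, tcr, allele)
        n11 = n10 = n01 = n00 = 0
        for i, ind in enumerate(occ.individuals):
            has_t = occ.presence[i, occ.tcrs.index(tcr)]
            has_a = allele in set(allele_cols.iloc[i])
            n11 += has_t and has_a
            n10 += has_t and not has_a
            n01 += not has_t and has_a
            n00 += not (has_t or has_a)
        assert (c.n11, c.n10, c.n01, c.n00) == (n11, n10, n01, n00)


def test_contingency_unknown_ids_raise(small_world):
    _, cohort, _ = small_world
    occ = d.OccurrenceMatrix.from_cohort(cohort)
    with pytest.raises(KeyError):
        d.build_contingency(occ, cohort.genotypes, "no_such_tcr", "A*01")
    with pytest.raises(KeyError):
        d.build_contingency(occ, cohort.genotypes, occ.tcrs[0], "Z*99")


# -------------------------------------------------------------------- fisher

def test_fisher_enumerated_example():
    # N=10, 3 TCR carriers, 4 allele carriers, full overlap:
    # p = C(4,3) C(6,0) / C(10,3) = 1/30
    p = d.fisher_one_sided(ContingencyCounts(3, 0, 1, 6))
    assert p == pytest.approx(1 / 30, abs=1e-12)


def test_fisher_boundary_cases():
    # n11 at the lower bound of the support
    assert d.fisher_one_sided(ContingencyCounts(0, 3, 4, 3)) == 1.0
    # every individual carries the allele: no discrimination possible
    assert d.fisher_one_sided(ContingencyCounts(3, 0, 7, 0)) == 1.0


def test_fisher_matches_exact_oracle_on_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n11, n10, n01, n00 = rng.integers(0, 8, size=4)
        c = ContingencyCounts(int(n11), int(n10), int(n01), int(n00))
        if c.total == 0:
            continue
        assert d.fisher_one_sided(c) == pytest.approx(
            hypergeom_tail_exact(c.n11, c.n10, c.n01, c.n00), abs=1e-12)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ContingencyCounts(-1, 2, 3, 4)


# ------------------------------------------------------------------------ BH

def bh_oracle(p):
    """Independent step-up implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def test_bh_enumerated_example():
    q = d.bh_fdr([0.01, 0.02, 0.04, 0.9])
    assert int((q < 0.05).sum()) == 2


def test_bh_degenerate_vectors():
    np.testing.assert_allclose(d.bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
    np.testing.assert_allclose(d.bh_fdr([0.123]), [0.123])


def test_bh_rejects_invalid_p():
    with pytest.raises(ValueError):
        d.bh_fdr([0.1, 1.2])
    with pytest.raises(ValueError):
        d.bh_fdr([-0.1])


def test_bh_matches_step_up_oracle():
    rng = np.random.default_rng(7)
    for _ in range(50):
        p = rng.random(rng.integers(1, 60))
        np.testing.assert_allclose(d.bh_fdr(p), bh_oracle(p), atol=1e-12)


# ----------------------------------------------------------------- discovery

def test_public_filter_threshold():
    presence = np.array([[1, 1, 0], [0, 1, 0], [0, 1, 1]], dtype=bool)
    occ = d.OccurrenceMatrix(["a", "b", "c"], ["t1", "t2", "t3"], presence)
    filtered = occ.public_filter()
    assert filtered.tcrs == ["t2"]  # only TCR in >= 2 individuals


def test_perfect_signal_recovers_every_planted_pair():
    cfg = d.SimulationConfig(n_individuals=50, n_public_tcrs=150,
                             n_planted_pairs=15, p_carrier=1.0,
                             p_background=0.0, seed=23)
    _, cohort, truth = simulate(cfg)
    occ = d.OccurrenceMatrix.from_cohort(cohort).public_filter()
    tested = d.select_positive_pairs(occ, cohort.genotypes)
    found = set(tested.loc[tested["label"] == 1, ["tcr_id", "allele"]]
                .itertuples(index=False, name=None))
    public = set(occ.tcrs)
    expected = {(t, a) for t, a in truth.planted_pairs if t in public}
    assert expected <= found


def test_negative_sampling_counts_per_allele(small_labeled):
    counts = small_labeled.groupby(["allele", "label"]).size().unstack(fill_value=0)
    for allele, row in counts.iterrows():
        assert row.get(0, 0) == 5 * row.get(1, 0), allele


def test_negative_sampling_is_deterministic(small_world):
    _, cohort, _ = small_world
    occ = d.OccurrenceMatrix.from_cohort(cohort).public_filter()
    tested = d.select_positive_pairs(occ, cohort.genotypes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = d.sample_negative_pairs(tested, seed=5)
        b = d.sample_negative_pairs(tested, seed=5)
    pd.testing.assert_frame_equal(a, b)


def test_negative_popfreq_matching_quality():
    """Two-sample KS statistic between positive- and negative-TCR population
    frequencies stays moderate for alleles with enough positives."""
    from scipy.stats import ks_2samp
    cfg = d.SimulationConfig(n_individuals=400, n_public_tcrs=3000,
                             n_planted_pairs=200, seed=31)
    _, cohort, _ = simulate(cfg)
    occ = d.OccurrenceMatrix.from_cohort(cohort).public_filter()
    tested = d.select_positive_pairs(occ, cohort.genotypes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labeled = d.sample_negative_pairs(tested, seed=1)
    stats = []
    for _, g in labeled.groupby("allele"):
        pos = g.loc[g["label"] == 1, "tcr_popfreq"]
        neg = g.loc[g["label"] == 0, "tcr_popfreq"]
        if len(pos) >= 8:
            stats.append(ks_2samp(pos, neg).statistic)
    assert stats and np.mean(stats) < 0.2


def test_split_partition_and_exact_ratio(small_labeled):
    table = small_labeled
    assert set(table["split"]) <= {"train", "valid", "test"}
    assert table["split"].notna().all()
    by = table.groupby(["split", "label"]).size().unstack(fill_value=0)
    for split in ("train", "valid", "test"):
        assert by.loc[split, 0] == 5 * by.loc[split, 1]
    n_pos = int((table["label"] == 1).sum())
    train_pos = by.loc["train", 1]
    assert train_pos == round(0.6 * n_pos) or abs(train_pos - 0.6 * n_pos) <= 1


def test_split_100_positives_gives_60_train():
    labeled = pd.DataFrame({
        "tcr_id": [f"t{i}" for i in range(600)],
        "allele": ["A*01"] * 600,
        "label": [1] * 100 + [0] * 500,
    })
    out = d.split_pairs(labeled, seed=0)
    by = out.groupby(["split", "label"]).size().unstack()
    assert by.loc["train", 1] == 60 and by.loc["train", 0] == 300
    assert by.loc["valid", 1] == 20 and by.loc["valid", 0] == 100
    assert by.loc["test", 1] == 20 and by.loc["test", 0] == 100


def test_split_degenerate_fraction_and_errors(small_labeled):
    out = d.split_pairs(small_labeled, fractions=(1.0, 0.0, 0.0), seed=1)
    assert (out["split"] == "train").all()
    with pytest.raises(ValueError):
        d.split_pairs(small_labeled, fractions=(0.5, 0.2, 0.2))


def test_largest_remainder_allocation_is_exact():
    counts = _largest_remainder(7, (0.6, 0.2, 0.2))
    assert counts.sum() == 7 and counts[0] in (4, 5)


def test_leave_one_hla_out_contract(small_labeled):
    allele = small_labeled.loc[small_labeled["label"] == 1, "allele"].iloc[0]
    out = d.make_leave_one_hla_out_split(small_labeled, allele, seed=2)
    test = out[out["split"] == "test"]
    trainvalid = out[out["split"] != "test"]
    assert set(test["allele"]) == {allele}
    assert allele not in set(trainvalid["allele"])
    assert not (set(test["tcr_id"]) & set(trainvalid["tcr_id"]))
    # every pair of the held-out allele ends up in test
    assert len(test) == int((small_labeled["allele"] == allele).sum())


def test_leave_one_hla_out_unknown_allele(small_labeled):
    with pytest.raises(KeyError):
        d.make_leave_one_hla_out_split(small_labeled, "Z*99")
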