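"""HLA similarity and heterozygosity metrics from TCR-HLA association scores.

Given a reference list of TCRs (chosen per application, e.g. TCRs with a
cancer-reactive signature) and a predicted association score for every
(allele, reference TCR) pair, each allele maps to (a) the set of reference
TCRs scored above the classification cutoff and (b) its full score vector.
From these the module derives:

* between-individual distances over the 6 class-I alleles of each
  individual (homozygous alleles counted twice):
  ``dist_breadth`` — Jaccard distance between the two individual-level
  TCR-set unions; ``dist_cor`` — the 6x6 matrix of (1 - Spearman) allele
  distances reduced to a scalar by optimal transport with uniform
  marginals;
* individual-level heterozygosity metrics: ``depth_breadth`` (size of the
  TCR-set union), ``mean_depth_cor`` / ``mean_depth_set`` (mean over the
  A/B/C genes of the between-allele distance of the gene's two alleles,
  with the correlation resp. Jaccard distance), the binary ``homozygous``
  indicator, and ``mean_aa`` (the same gene average with a purely
  sequence-based allele distance over pseudo sequences).

The exported square distance matrix and per-individual score table are
plain CSVs, directly consumable by kernel-regression or survival tooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import spearmanr

from depth_tcr.features import blosum62_matrix

__all__ = [
    "AssociationProfile", "allele_tcr_set", "individual_tcr_union",
    "jaccard_distance", "allele_distance_cor", "allele_distance_set",
    "between_individual_cost_matrix", "optimal_transport_cost",
    "dist_breadth", "dist_cor", "distance_matrix",
    "HeterozygosityScores", "heterozygosity_metrics", "heterozygosity_table",
    "mean_aa_allele_distance",
]

SCORE_CUTOFF = 0.5
N_CLASS_I_ALLELES = 6


@dataclass
class AssociationProfile:
    """Association scores of every allele against a reference TCR list."""

    reference_tcrs: list[str]
    scores: dict[str, np.ndarray]  # allele -> vector over reference_tcrs

    def __post_init__(self) -> None:
        n = len(self.reference_tcrs)
        for allele, vec in self.scores.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (n,):
                raise ValueError(
                    f"score vector for {allele} has length {vec.shape}, "
                    f"expected ({n},)")
            if ((vec < 0) | (vec > 1)).any():
                raise ValueError(f"scores for {allele} outside [0, 1]")
            self.scores[allele] = vec

    @classmethod
    def from_scores(cls, table: pd.DataFrame) -> "AssociationProfile":
        """Build from a long table with columns tcr_id, allele, score."""
        wide = table.pivot_table(index="tcr_id", columns="allele",
                                 values="score")
        if wide.isna().any().any():
            raise ValueError("score table is not complete over TCR x allele")
        refs = list(wide.index)
        return cls(refs, {a: wide[a].to_numpy(dtype=float)
                          for a in wide.columns})

    def score_vector(self, allele: str) -> np.ndarray:
        if allele not in self.scores:
            raise KeyError(f"allele {allele!r} not in the association profile")
        return self.scores[allele]


def allele_tcr_set(profile: AssociationProfile, allele: str,
                   cutoff: float = SCORE_CUTOFF) -> frozenset[str]:
    """Reference TCRs scored strictly above the cutoff for one allele."""
    vec = profile.score_vector(allele)
    return frozenset(t for t, s in zip(profile.reference_tcrs, vec)
                     if s > cutoff)


def individual_tcr_union(alleles, profile: AssociationProfile,
                         cutoff: float = SCORE_CUTOFF
                         ) -> tuple[frozenset[str], int]:
    """Union of the allele TCR sets and its size (the breadth)."""
    union: frozenset[str] = frozenset()
    for a in alleles:
        union = union | allele_tcr_set(profile, a, cutoff)
    return union, len(union)


def jaccard_distance(a, b) -> float:
    """|A xor B| / |A or B|; 0 when both sets are empty (with a warning)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        warnings.warn("Jaccard distance of two empty sets; defining it as 0",
                      stacklevel=2)
        return 0.0
    return len(a ^ b) / len(union)


def allele_distance_cor(profile: AssociationProfile, allele_a: str,
                        allele_b: str) -> float:
    """1 - Spearman correlation of the two alleles' score vectors, in [0, 2].

    A constant score vector leaves the correlation undefined; the distance
    falls back to the neutral value 1 with a warning rather than aborting
    cohort-scale matrix computations.
    """
    va = profile.score_vector(allele_a)
    vb = profile.score_vector(allele_b)
    if len(va) < 2:
        raise ValueError("Spearman distance needs at least 2 reference TCRs")
    if np.all(va == va[0]) or np.all(vb == vb[0]):
        warnings.warn(
            f"constant score vector for {allele_a!r} or {allele_b!r}: "
            "Spearman correlation undefined, using distance 1", stacklevel=2)
        return 1.0
    rho = spearmanr(va, vb).statistic
    return float(1.0 - rho)


def allele_distance_set(profile: AssociationProfile, allele_a: str,
                        allele_b: str, cutoff: float = SCORE_CUTOFF) -> float:
    """Jaccard distance between the two alleles' TCR sets."""
    return jaccard_distance(allele_tcr_set(profile, allele_a, cutoff),
                            allele_tcr_set(profile, allele_b, cutoff))


def _six_alleles(genotype) -> list[str]:
    alleles = list(genotype)
    if len(alleles) != N_CLASS_I_ALLELES:
        raise ValueError(
            f"expected {N_CLASS_I_ALLELES} class-I alleles, got {len(alleles)}")
    return alleles


def between_individual_cost_matrix(g1, g2, allele_dist) -> np.ndarray:
    """6x6 matrix of allele distances between two genotypes.

    ``allele_dist(a, b)`` supplies the between-allele distance; homozygous
    alleles are treated as separate entities (rows/columns repeat).
    """
    a1, a2 = _six_alleles(g1), _six_alleles(g2)
    cache: dict[tuple[str, str], float] = {}
    out = np.empty((N_CLASS_I_ALLELES, N_CLASS_I_ALLELES))
    for i, x in enumerate(a1):
        for j, y in enumerate(a2):
            key = (x, y)
            if key not in cache:
                cache[key] = float(allele_dist(x, y))
            out[i, j] = cache[key]
    return out


def optimal_transport_cost(cost: np.ndarray) -> float:
    """Earth-mover cost between two uniform allele sets.

    With equal uniform marginals (mass 1/k per allele on both sides) an
    optimal transport plan is a permutation, so the cost reduces to the
    assignment-problem minimum divided by k.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.shape[0] != cost.shape[1]:
        raise ValueError("cost must be a square matrix")
    if not np.isfinite(cost).all() or (cost < 0).any():
        raise ValueError("cost entries must be finite and nonnegative")
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum() / cost.shape[0])


def dist_breadth(g1, g2, profile: AssociationProfile,
                 cutoff: float = SCORE_CUTOFF) -> float:
    """Jaccard distance between the two individuals' TCR-set unions."""
    u1, _ = individual_tcr_union(g1, profile, cutoff)
    u2, _ = individual_tcr_union(g2, profile, cutoff)
    return jaccard_distance(u1, u2)


def dist_cor(g1, g2, profile: AssociationProfile) -> float:
    """Optimal-transport reduction of the 6x6 (1 - Spearman) matrix."""
    cost = between_individual_cost_matrix(
        g1, g2, lambda a, b: allele_distance_cor(profile, a, b))
    return optimal_transport_cost(cost)


def _genotype_rows(genotypes: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    allele_cols = [c for c in genotypes.columns if c.startswith("allele_")]
    if len(allele_cols) != N_CLASS_I_ALLELES:
        raise ValueError("genotype table must have 6 allele_* columns")
    return list(genotypes["individual_id"]), genotypes[allele_cols].to_numpy()


def distance_matrix(genotypes: pd.DataFrame, profile: AssociationProfile,
                    method: str = "breadth",
                    cutoff: float = SCORE_CUTOFF) -> pd.DataFrame:
    """Symmetric between-individual distance matrix for a cohort.

    ``method`` selects ``"breadth"`` (Jaccard over union TCR sets) or
    ``"cor"`` (optimal transport over 1 - Spearman allele distances).
    """
    ids, rows = _genotype_rows(genotypes)
    n = len(ids)
    out = np.zeros((n, n))
    if method == "breadth":
        unions = [individual_tcr_union(rows[i], profile, cutoff)[0]
                  for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = jaccard_distance(unions[i], unions[j])
    elif method == "cor":
        dcache = {}

        def adist(a, b):
            key = (a, b) if a <= b else (b, a)
            if key not in dcache:
                dcache[key] = allele_distance_cor(profile, *key)
            return dcache[key]

        for i in range(n):
            for j in range(i + 1, n):
                cost = between_individual_cost_matrix(rows[i], rows[j], adist)
                out[i, j] = out[j, i] = optimal_transport_cost(cost)
    else:
        raise ValueError(f"unknown method {method!r}; use 'breadth' or 'cor'")
    return pd.DataFrame(out, index=ids, columns=ids)


def mean_aa_allele_distance(pseudo_a: str, pseudo_b: str) -> float:
    """Purely sequence-based distance between two pseudo sequences.

    Mean over aligned positions of a per-residue substitution distance
    d(x, y) in [0, 1] with d(x, x) = 0, derived from BLOSUM62 as
    ``(s(x,x) + s(y,y) - 2 s(x,y)) / (s(x,x) + s(y,y) - 2 min(S))``.
    """
    if len(pseudo_a) != len(pseudo_b):
        raise ValueError("pseudo sequences must have equal length")
    blosum = blosum62_matrix()
    s_min = blosum.to_numpy().min()
    total = 0.0
    for x, y in zip(pseudo_a, pseudo_b):
        sxx, syy, sxy = blosum.at[x, x], blosum.at[y, y], blosum.at[x, y]
        total += (sxx + syy - 2.0 * sxy) / (sxx + syy - 2.0 * s_min)
    return total / len(pseudo_a)


@dataclass(frozen=True)
class HeterozygosityScores:
    """Per-individual HLA-I diversity metrics."""

    individual_id: str
    homozygous: int
    depth_breadth: int
    mean_depth_cor: float
    mean_depth_set: float
    mean_aa: float


def heterozygosity_metrics(individual_id: str, genotype,
                           profile: AssociationProfile,
                           pseudo_table: pd.DataFrame | None = None,
                           cutoff: float = SCORE_CUTOFF
                           ) -> HeterozygosityScores:
    """Heterozygosity metrics for one individual.

    ``genotype`` lists the 6 class-I alleles grouped two per gene
    (A, A, B, B, C, C).  ``mean_aa`` requires the pseudo-sequence table and
    is NaN when it is not supplied.
    """
    alleles = _six_alleles(genotype)
    gene_pairs = [(alleles[0], alleles[1]), (alleles[2], alleles[3]),
                  (alleles[4], alleles[5])]
    homozygous = int(any(a == b for a, b in gene_pairs))

    _, breadth = individual_tcr_union(alleles, profile, cutoff)
    mean_cor = float(np.mean([
        0.0 if a == b else allele_distance_cor(profile, a, b)
        for a, b in gene_pairs]))
    mean_set = float(np.mean([
        0.0 if a == b else allele_distance_set(profile, a, b, cutoff)
        for a, b in gene_pairs]))

    if pseudo_table is not None:
        pseudo_of = dict(zip(pseudo_table["allele"], pseudo_table["pseudo_seq"]))
        mean_aa = float(np.mean([
            mean_aa_allele_distance(pseudo_of[a], pseudo_of[b])
            for a, b in gene_pairs]))
    else:
        mean_aa = float("nan")
    return HeterozygosityScores(individual_id, homozygous, breadth,
                                mean_cor, mean_set, mean_aa)


def heterozygosity_table(genotypes: pd.DataFrame, profile: AssociationProfile,
                         pseudo_table: pd.DataFrame | None = None,
                         cutoff: float = SCORE_CUTOFF) -> pd.DataFrame:
    """Heterozygosity metrics for every individual of a genotype table."""
    ids, rows = _genotype_rows(genotypes)
    records = [heterozygosity_metrics(i, r, profile, pseudo_table, cutoff)
               for i, r in zip(ids, rows)]
    return pd.DataFrame([vars(r) for r in records])
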