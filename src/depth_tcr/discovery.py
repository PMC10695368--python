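"""Co-occurrence discovery of TCR-HLA pairs and training-set construction.

A TCR is "public" if observed in at least two cohort individuals.  For
every public TCR x HLA allele pair, a one-sided Fisher's exact test on the
2x2 carrier table asks whether the TCR is enriched among allele carriers;
Benjamini-Hochberg control at FDR < 0.05 over all tested pairs selects the
positive pairs.  Negatives are then drawn from the non-positive pairs under
two bias controls: per allele, exactly five negatives per positive (so the
HLA frequency spectrum of the negatives is proportional to that of the
positives), with negative TCRs bin-matched to the population-frequency
distribution of that allele's positive TCRs (Fisher's test preferentially
selects prevalent TCRs, and an unmatched sample would let a model score
prevalence instead of sequence).  Labeled pairs are finally split
60/20/20 into train/validation/test, each split keeping the 1:5
positive:negative ratio exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OccurrenceMatrix",
    "ContingencyCounts",
    "carrier_matrix",
    "build_contingency",
    "fisher_one_sided",
    "bh_fdr",
    "test_all_pairs",
    "select_positive_pairs",
    "sample_negative_pairs",
    "split_pairs",
    "make_leave_one_hla_out_split",
    "attach_tcr_sequences",
]

PUBLIC_TCR_MIN_INDIVIDUALS = 2
NEGATIVE_RATIO = 5
SPLIT_FRACTIONS = (0.6, 0.2, 0.2)


@dataclass
class OccurrenceMatrix:
    """Boolean individuals x TCRs presence matrix."""

    individuals: list[str]
    tcrs: list[str]
    presence: np.ndarray  # bool (n_individuals, n_tcrs)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.individuals), len(self.tcrs)):
            raise ValueError("presence shape does not match id lists")

    @classmethod
    def from_cohort(cls, cohort) -> "OccurrenceMatrix":
        occ = cohort.occurrence
        return cls(list(occ.index), list(occ.columns), occ.to_numpy())

    @classmethod
    def from_repertoire(cls, repertoire: pd.DataFrame,
                        catalog: pd.DataFrame) -> "OccurrenceMatrix":
        """Build from long-format repertoire rows using a TCR catalog to map
        (cdr3_aa, v_gene) back to TCR ids."""
        key_to_id = {(c, v): t for t, c, v in
                     catalog[["tcr_id", "cdr3_aa", "v_gene"]].itertuples(index=False)}
        individuals = sorted(repertoire["individual_id"].unique())
        ind_idx = {x: i for i, x in enumerate(individuals)}
        tcrs = list(catalog["tcr_id"])
        tcr_idx = {t: j for j, t in enumerate(tcrs)}
        presence = np.zeros((len(individuals), len(tcrs)), dtype=bool)
        for ind, cdr3, v in repertoire[["individual_id", "cdr3_aa",
                                        "v_gene"]].itertuples(index=False):
            tid = key_to_id.get((cdr3, v))
            if tid is not None:
                presence[ind_idx[ind], tcr_idx[tid]] = True
        return cls(individuals, tcrs, presence)

    def public_filter(self, min_individuals: int = PUBLIC_TCR_MIN_INDIVIDUALS
                      ) -> "OccurrenceMatrix":
        """Keep TCRs observed in at least ``min_individuals`` individuals."""
        keep = self.presence.sum(axis=0) >= min_individuals
        return OccurrenceMatrix(self.individuals,
                                [t for t, k in zip(self.tcrs, keep) if k],
                                self.presence[:, keep])

    def popfreq(self) -> np.ndarray:
        """Fraction of cohort individuals carrying each TCR."""
        return self.presence.mean(axis=0)


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 carrier table for one TCR-HLA pair."""

    n11: int  # TCR present and allele carried
    n10: int  # TCR present, allele absent
    n01: int  # allele carried, TCR absent
    n00: int  # neither

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def carrier_matrix(genotypes: pd.DataFrame,
                   alleles: list[str] | None = None
                   ) -> tuple[np.ndarray, list[str], list[str]]:
    """Individuals x alleles carrier indicator (an individual carries an
    allele if it appears at least once in the genotype)."""
    allele_cols = genotypes.filter(like="allele_")
    arr = allele_cols.to_numpy()
    if alleles is None:
        alleles = sorted(pd.unique(arr.ravel()))
    carriers = np.stack([(arr == a).any(axis=1) for a in alleles], axis=1)
    return carriers, list(genotypes["individual_id"]), list(alleles)


def build_contingency(occurrence: OccurrenceMatrix, genotypes: pd.DataFrame,
                      tcr_id: str, allele: str) -> ContingencyCounts:
    """Count the 2x2 carrier table for one pair."""
    if tcr_id not in occurrence.tcrs:
        raise KeyError(f"unknown TCR {tcr_id!r}")
    carriers, individuals, _ = carrier_matrix(genotypes, [allele])
    if not carriers.any() and allele not in set(
            genotypes.filter(like="allele_").to_numpy().ravel()):
        raise KeyError(f"allele {allele!r} not present in the cohort genotypes")
    if individuals != occurrence.individuals:
        order = pd.Index(individuals).get_indexer(occurrence.individuals)
        if (order < 0).any():
            raise ValueError("genotype and occurrence individuals differ")
        carriers = carriers[order]
    has_tcr = occurrence.presence[:, occurrence.tcrs.index(tcr_id)]
    has_hla = carriers[:, 0]
    n11 = int(np.sum(has_tcr & has_hla))
    n10 = int(np.sum(has_tcr & ~has_hla))
    n01 = int(np.sum(~has_tcr & has_hla))
    n00 = int(np.sum(~has_tcr & ~has_hla))
    return ContingencyCounts(n11, n10, n01, n00)


def _hypergeom_sf(n11, total, tcr_carriers, hla_carriers):
    # P(X >= n11) for X ~ Hypergeom(N, K, n); sf(k) = P(X > k)
    return hypergeom.sf(np.asarray(n11) - 1, total, tcr_carriers, hla_carriers)


def fisher_one_sided(c: ContingencyCounts) -> float:
    """One-sided Fisher's exact test toward co-occurrence enrichment.

    Under the null the overlap ``n11`` follows a hypergeometric law with
    population ``N`` (cohort size), ``K`` TCR carriers and ``n`` allele
    carriers; the p-value is ``P(X >= n11)``.
    """
    p = float(_hypergeom_sf(c.n11, c.total, c.n11 + c.n10, c.n11 + c.n01))
    return min(p, 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_all_pairs(occurrence: OccurrenceMatrix,
                   genotypes: pd.DataFrame) -> pd.DataFrame:
    """Fisher-test every public TCR against every allele in the cohort.

    Returns one row per pair: tcr_id, allele, n11, p_value, fdr_q,
    tcr_popfreq.  The q-values are corrected jointly over all tested pairs.
    """
    if not occurrence.individuals:
        raise ValueError("empty cohort")
    carriers, individuals, alleles = carrier_matrix(genotypes)
    if individuals != occurrence.individuals:
        order = pd.Index(individuals).get_indexer(occurrence.individuals)
        if (order < 0).any():
            raise ValueError("genotype and occurrence individuals differ")
        carriers = carriers[order]

    presence = occurrence.presence
    total = presence.shape[0]
    n11 = presence.T.astype(np.int64) @ carriers.astype(np.int64)  # tcr x allele
    tcr_carriers = presence.sum(axis=0)[:, None]
    hla_carriers = carriers.sum(axis=0)[None, :]
    p = _hypergeom_sf(n11, total, tcr_carriers, hla_carriers)
    p = np.minimum(p, 1.0)

    t_idx, a_idx = np.meshgrid(np.arange(len(occurrence.tcrs)),
                               np.arange(len(alleles)), indexing="ij")
    table = pd.DataFrame({
        "tcr_id": np.asarray(occurrence.tcrs)[t_idx.ravel()],
        "allele": np.asarray(alleles)[a_idx.ravel()],
        "n11": n11.ravel(),
        "p_value": p.ravel(),
    })
    table["fdr_q"] = bh_fdr(table["p_value"].to_numpy())
    popfreq = occurrence.popfreq()
    table["tcr_popfreq"] = popfreq[t_idx.ravel()]
    return table


def select_positive_pairs(occurrence: OccurrenceMatrix, genotypes: pd.DataFrame,
                          fdr_level: float = 0.05) -> pd.DataFrame:
    """Label pairs with ``fdr_q < fdr_level`` as positive.

    Returns the full tested table with a ``label`` column (1 positive,
    0 otherwise); downstream steps subset/augment it.
    """
    table = test_all_pairs(occurrence, genotypes)
    table["label"] = (table["fdr_q"] < fdr_level).astype(int)
    return table


def sample_negative_pairs(tested: pd.DataFrame, ratio: int = NEGATIVE_RATIO,
                          seed: int = 0, n_bins: int = 10) -> pd.DataFrame:
    """Sample bias-matched negatives from the non-positive pairs.

    Per allele with ``k`` positives, draw exactly ``ratio * k`` negative
    pairs for that same allele (keeping the HLA frequency spectrum of the
    negatives proportional to the positives).  Candidates are binned by TCR
    population frequency on the deciles of the allele's positive TCRs and
    drawn without replacement bin by bin; an exhausted bin borrows from the
    nearest nonempty bin (a warning records each fallback).

    Returns the labeled table: all positives plus the sampled negatives.
    """
    rng = np.random.default_rng(seed)
    if "label" not in tested.columns:
        raise ValueError("run select_positive_pairs first (no label column)")
    positives = tested[tested["label"] == 1]
    out = [positives]
    for allele, pos in positives.groupby("allele", sort=True):
        needed = ratio * len(pos)
        cand = tested[(tested["allele"] == allele) & (tested["label"] == 0)]
        if len(cand) < needed:
            raise ValueError(
                f"allele {allele}: only {len(cand)} candidate negatives for "
                f"{needed} required; cohort too small or ratio too high")
        edges = np.quantile(pos["tcr_popfreq"].to_numpy(),
                            np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
        if len(edges) < 2:  # all positive popfreqs identical: single bin
            edges = np.array([edges[0], edges[0]])
        # assign positives and candidates to the same bins
        pos_bins = np.clip(np.searchsorted(edges, pos["tcr_popfreq"], "right") - 1,
                           0, len(edges) - 2)
        cand_bins = np.clip(np.searchsorted(edges, cand["tcr_popfreq"], "right") - 1,
                            0, len(edges) - 2)
        quota = np.bincount(pos_bins, minlength=len(edges) - 1) * ratio
        remaining = [list(cand.index[cand_bins == b])
                     for b in range(len(edges) - 1)]
        for b in range(len(remaining)):
            rng.shuffle(remaining[b])
        chosen: list[int] = []
        for b, q in enumerate(quota):
            take = remaining[b][:q]
            remaining[b] = remaining[b][q:]
            short = q - len(take)
            if short:
                # borrow from the nearest nonempty bin
                order = sorted(range(len(remaining)),
                               key=lambda j: (abs(j - b), j))
                for j in order:
                    if short == 0:
                        break
                    grab = remaining[j][:short]
                    remaining[j] = remaining[j][short:]
                    take += grab
                    short -= len(grab)
                if short:
                    raise ValueError(
                        f"allele {allele}: exhausted all popfreq bins with "
                        f"{short} negatives still required")
                warnings.warn(
                    f"allele {allele}: popfreq bin {b} exhausted; borrowed "
                    f"from neighbouring bins", stacklevel=2)
            chosen += take
        out.append(tested.loc[chosen])
    labeled = pd.concat(out, ignore_index=True)
    return labeled.sort_values(["allele", "label", "tcr_id"],
                               ascending=[True, False, True],
                               ignore_index=True)


def _largest_remainder(n: int, fractions) -> np.ndarray:
    """Split ``n`` items into integer counts proportional to ``fractions``."""
    fractions = np.asarray(fractions, dtype=float)
    raw = n * fractions
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def split_pairs(labeled: pd.DataFrame, fractions=SPLIT_FRACTIONS,
                seed: int = 0) -> pd.DataFrame:
    """Assign train/valid/test splits preserving the 1:5 ratio exactly.

    Positives are allocated by largest-remainder rounding of the fractions;
    each split then receives exactly ``ratio`` negatives per positive,
    where ``ratio`` is the overall negative:positive count ratio (so the
    class balance is identical in every split).
    """
    fractions = tuple(fractions)
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    labeled = labeled.copy()
    pos_idx = labeled.index[labeled["label"] == 1].to_numpy()
    neg_idx = labeled.index[labeled["label"] == 0].to_numpy()
    if len(pos_idx) and len(neg_idx) % len(pos_idx) == 0:
        ratio = len(neg_idx) // len(pos_idx)
        pos_counts = _largest_remainder(len(pos_idx), fractions)
        neg_counts = pos_counts * ratio
    else:
        pos_counts = _largest_remainder(len(pos_idx), fractions)
        neg_counts = _largest_remainder(len(neg_idx), fractions)
    rng.shuffle(pos_idx)
    rng.shuffle(neg_idx)
    names = ("train", "valid", "test")
    split = pd.Series(index=labeled.index, dtype=object)
    for idx, counts in ((pos_idx, pos_counts), (neg_idx, neg_counts)):
        start = 0
        for name, c in zip(names, counts):
            split.loc[idx[start:start + c]] = name
            start += c
    labeled["split"] = split
    return labeled


def make_leave_one_hla_out_split(labeled: pd.DataFrame, held_out_allele: str,
                                 seed: int = 0,
                                 valid_fraction: float = 0.25) -> pd.DataFrame:
    """Hold one allele (and all its TCRs) out as the test set.

    The test split is every labeled pair of ``held_out_allele``.  Pairs of
    other alleles whose TCR appears in the test set are dropped entirely,
    so the train/valid TCR universe is disjoint from the test TCRs; the
    remainder is split train/valid per label (default 75/25, i.e. the same
    3:1 proportion as a 60/20 train/valid split).
    """
    alleles = set(labeled["allele"])
    if held_out_allele not in alleles:
        raise KeyError(f"allele {held_out_allele!r} has no labeled pairs")
    rng = np.random.default_rng(seed)
    test = labeled[labeled["allele"] == held_out_allele].copy()
    test_tcrs = set(test["tcr_id"])
    rest = labeled[(labeled["allele"] != held_out_allele)
                   & ~labeled["tcr_id"].isin(test_tcrs)].copy()
    parts = [test.assign(split="test")]
    for _, group in rest.groupby("label", sort=True):
        idx = group.index.to_numpy()
        rng.shuffle(idx)
        n_valid = int(round(valid_fraction * len(idx)))
        split = pd.Series("train", index=group.index, dtype=object)
        split.loc[idx[:n_valid]] = "valid"
        parts.append(group.assign(split=split))
    return pd.concat(parts, ignore_index=True)


def attach_tcr_sequences(table: pd.DataFrame,
                         catalog: pd.DataFrame) -> pd.DataFrame:
    """Join cdr3_aa and v_gene onto a pair table by tcr_id."""
    merged = table.merge(catalog[["tcr_id", "cdr3_aa", "v_gene"]],
                         on="tcr_id", how="left", validate="many_to_one")
    if merged["cdr3_aa"].isna().any():
        missing = merged.loc[merged["cdr3_aa"].isna(), "tcr_id"].unique()
        raise KeyError(f"TCR ids missing from catalog: {missing[:5].tolist()}")
    return merged
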