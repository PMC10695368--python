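"""Synthetic cohorts with planted HLA-restricted TCRs.

Real discovery cohorts pair each individual's HLA genotype with the set of
TCR beta-chain clonotypes observed in their repertoire.  An HLA-restricted
("planted") TCR is seen more often in carriers of its restricting allele
than in non-carriers, which is exactly the co-occurrence signal the
discovery stage screens for.  The generator emulates that structure:

* a sequence universe — random HLA pseudo sequences, germline CDR1/CDR2/CDR2.5
  strings per V gene, and a catalog of TCRs (CDR3 + V gene);
* a cohort — genotypes drawn i.i.d. from per-gene allele frequencies
  (two alleles per gene; homozygotes arise naturally), and a boolean
  individuals x TCRs occurrence table where planted TCRs occur with
  probability ``p_carrier`` in carriers of their allele and
  ``p_background`` elsewhere;
* an association mechanism at the sequence level — each planted TCR's CDR3
  carries a short motif copied from its restricting allele's pseudo
  sequence, so that TCR-HLA compatibility is a function of the sequences
  themselves and a trained model can generalise to unseen TCRs and alleles.
  Setting ``motif_len=0`` removes the sequence signal and leaves pure
  co-occurrence structure (useful for null experiments).

Occurrence is presence/absence only: clone sizes play no role in the
discovery statistics being emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from depth_tcr.features import AMINO_ACIDS

GENES = ("A", "B", "C")

__all__ = [
    "GENES",
    "SimulationConfig",
    "Universe",
    "Cohort",
    "GroundTruth",
    "generate_sequence_universe",
    "generate_cohort",
    "simulate",
    "write_cohort",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the standard recovery condition used throughout the
    test suite: 300 individuals, 20 class-I alleles (7/7/6 across the A/B/C
    genes, uniform frequencies), 2,000 public TCRs, 100 planted pairs,
    carrier occurrence probability 0.5 against a 0.05 background.
    """

    n_individuals: int = 300
    n_alleles_per_gene: dict[str, int] = field(
        default_factory=lambda: {"A": 7, "B": 7, "C": 6}
    )
    #: per-gene allele frequency vectors; None means uniform per gene
    allele_freqs: dict[str, tuple[float, ...]] | None = None
    n_public_tcrs: int = 2000
    n_planted_pairs: int = 100
    #: mean occurrence probability for non-carriers; per-TCR rates are
    #: heavy-tailed (see frac_high_publicity) with this mean
    p_background: float = 0.05
    p_carrier: float = 0.5
    #: fraction of TCRs that are "highly public" (prevalent in many
    #: repertoires regardless of HLA); their non-carrier occurrence rate is
    #: p_background times a factor drawn uniformly from
    #: high_publicity_factors, the rest share a common low rate chosen so
    #: the overall mean stays p_background
    frac_high_publicity: float = 0.25
    high_publicity_factors: tuple[float, float] = (1.4, 5.0)
    cdr3_length_range: tuple[int, int] = (10, 18)
    pseudo_len: int = 34
    #: residues of the restricting allele's pseudo sequence copied into the
    #: CDR3 of a planted TCR; 0 disables the sequence-level signal
    motif_len: int = 6
    #: number of allele clusters ("supertypes") sharing the first
    #: ``motif_len`` pseudo-sequence residues; 0 gives every allele its own
    #: private motif
    n_supertypes: int = 4
    cdr1_len: int = 6
    cdr2_len: int = 6
    cdr2_5_len: int = 4
    n_v_genes: int = 30
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if set(self.n_alleles_per_gene) != set(GENES):
            raise ValueError(f"n_alleles_per_gene must have keys {GENES}")
        if any(n < 1 for n in self.n_alleles_per_gene.values()):
            raise ValueError("each gene needs at least one allele")
        if not self.p_carrier > self.p_background:
            raise ValueError(
                "p_carrier must exceed p_background "
                f"({self.p_carrier} <= {self.p_background})"
            )
        if not (0.0 <= self.p_background <= 1.0 and 0.0 <= self.p_carrier <= 1.0):
            raise ValueError("occurrence probabilities must lie in [0, 1]")
        lo, hi = self.cdr3_length_range
        if not (6 <= lo <= hi <= 27):
            raise ValueError("cdr3_length_range must satisfy 6 <= min <= max <= 27")
        if self.motif_len < 0 or (self.motif_len and lo < self.motif_len + 2):
            raise ValueError(
                "motif_len must be >= 0 and fit inside the shortest CDR3 "
                "between its conserved first and last residues"
            )
        if self.motif_len > self.pseudo_len:
            raise ValueError("motif_len cannot exceed pseudo_len")
        if self.n_supertypes < 0:
            raise ValueError("n_supertypes must be nonnegative")
        lo_pub, hi_pub = self.high_publicity_factors
        if not 0.0 <= self.frac_high_publicity < 1.0:
            raise ValueError("frac_high_publicity must lie in [0, 1)")
        if not 0.0 <= lo_pub <= hi_pub:
            raise ValueError("high_publicity_factors must be nonnegative "
                             "and ordered")
        if hi_pub * self.p_background > 1.0:
            raise ValueError("largest high-publicity occurrence rate "
                             "exceeds 1")
        if self._low_publicity_rate() < 0.0:
            raise ValueError(
                "high-publicity tail too heavy: the implied low-publicity "
                "rate is negative")
        if self.allele_freqs is not None:
            for gene in GENES:
                freqs = np.asarray(self.allele_freqs[gene], dtype=float)
                if len(freqs) != self.n_alleles_per_gene[gene]:
                    raise ValueError(f"allele_freqs[{gene}] has wrong length")
                if (freqs < 0).any() or not np.isclose(freqs.sum(), 1.0):
                    raise ValueError(
                        f"allele_freqs[{gene}] must be nonnegative and sum to 1"
                    )
        if self.n_public_tcrs < 1 or self.n_v_genes < 1:
            raise ValueError("n_public_tcrs and n_v_genes must be positive")
        if self.n_planted_pairs > self.n_public_tcrs:
            raise ValueError(
                "n_planted_pairs cannot exceed the number of TCRs "
                "(each TCR is restricted by at most one allele)"
            )

    def _low_publicity_rate(self) -> float:
        """Occurrence rate of ordinary TCRs so the mean is p_background."""
        f = self.frac_high_publicity
        if f == 0.0:
            return self.p_background
        mean_hi = self.p_background * sum(self.high_publicity_factors) / 2.0
        return (self.p_background - f * mean_hi) / (1.0 - f)

    def gene_freqs(self, gene: str) -> np.ndarray:
        if self.allele_freqs is not None:
            return np.asarray(self.allele_freqs[gene], dtype=float)
        n = self.n_alleles_per_gene[gene]
        return np.full(n, 1.0 / n)

    def allele_names(self) -> list[str]:
        return [
            f"{gene}*{i + 1:02d}"
            for gene in GENES
            for i in range(self.n_alleles_per_gene[gene])
        ]


@dataclass
class Universe:
    """Sequence universe: pseudo sequences, V-gene CDRs, TCR catalog."""

    pseudo_table: pd.DataFrame  # columns: allele, pseudo_seq
    vcdr_table: pd.DataFrame    # columns: v_gene, cdr1, cdr2, cdr2_5
    tcr_catalog: pd.DataFrame   # columns: tcr_id, cdr3_aa, v_gene


@dataclass
class Cohort:
    """Genotypes plus the individuals x TCRs occurrence table."""

    genotypes: pd.DataFrame   # individual_id, allele_1..allele_6 (A,A,B,B,C,C)
    occurrence: pd.DataFrame  # bool, index individual_id, columns tcr_id
    tcr_catalog: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.genotypes.filter(like="allele_").shape[1]
        if counts != 2 * len(GENES):
            raise ValueError("genotypes must carry exactly 2 alleles per gene")
        if self.occurrence.dtypes.ne(bool).any():
            raise ValueError("occurrence entries must be boolean")


@dataclass(frozen=True)
class GroundTruth:
    """The planted (tcr_id, allele) pairs."""

    planted_pairs: frozenset[tuple[str, str]]

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.planted_pairs)
        return pd.DataFrame(rows, columns=["tcr_id", "allele"])


def _random_strings(rng: np.random.Generator, n: int, length: int) -> list[str]:
    letters = np.array(list(AMINO_ACIDS))
    idx = rng.integers(0, len(letters), size=(n, length))
    return ["".join(row) for row in letters[idx]]


def generate_sequence_universe(config: SimulationConfig) -> Universe:
    """Draw pseudo sequences, V-gene CDR strings and a TCR catalog.

    Deterministic given ``config.seed``.  CDR3s follow the conserved
    C...F convention with interior residues uniform over the 20-letter
    alphabet and lengths uniform over ``cdr3_length_range``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])

    alleles = config.allele_names()
    pseudo_seqs = _random_strings(rng, len(alleles), config.pseudo_len)
    if config.motif_len and config.n_supertypes:
        # alleles of a supertype share their first motif_len contact
        # residues, the segment a planted TCR's CDR3 complements
        supertype_motifs = _random_strings(rng, config.n_supertypes,
                                           config.motif_len)
        assignment = rng.integers(0, config.n_supertypes, size=len(alleles))
        pseudo_seqs = [supertype_motifs[s] + seq[config.motif_len:]
                       for s, seq in zip(assignment, pseudo_seqs)]
    pseudo_table = pd.DataFrame({
        "allele": alleles,
        "pseudo_seq": pseudo_seqs,
    })

    v_genes = [f"TRBV{i + 1:02d}" for i in range(config.n_v_genes)]
    vcdr_table = pd.DataFrame({
        "v_gene": v_genes,
        "cdr1": _random_strings(rng, len(v_genes), config.cdr1_len),
        "cdr2": _random_strings(rng, len(v_genes), config.cdr2_len),
        "cdr2_5": _random_strings(rng, len(v_genes), config.cdr2_5_len),
    })

    lo, hi = config.cdr3_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_public_tcrs)
    interiors = _random_strings(rng, config.n_public_tcrs, hi - 2)
    cdr3s = ["C" + interiors[i][: lengths[i] - 2] + "F"
             for i in range(config.n_public_tcrs)]
    tcr_catalog = pd.DataFrame({
        "tcr_id": [f"T{i + 1:05d}" for i in range(config.n_public_tcrs)],
        "cdr3_aa": cdr3s,
        "v_gene": [v_genes[j] for j in rng.integers(0, len(v_genes),
                                                    size=config.n_public_tcrs)],
    })
    return Universe(pseudo_table, vcdr_table, tcr_catalog)


def generate_cohort(
    config: SimulationConfig, universe: Universe
) -> tuple[Cohort, GroundTruth]:
    """Draw genotypes and occurrence, planting HLA-restricted TCRs.

    Each planted TCR is restricted by exactly one allele (planting samples
    TCRs without replacement and assigns each a uniformly chosen allele).
    When ``motif_len > 0`` the planted TCR's CDR3 positions
    ``1..motif_len`` are overwritten with the first ``motif_len`` residues
    of the restricting allele's pseudo sequence, giving downstream models a
    sequence-level association rule that generalises beyond the planted
    pairs themselves.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])

    n = config.n_individuals
    individual_ids = [f"ind_{i + 1:04d}" for i in range(n)]

    genotype_cols: dict[str, list[str]] = {"individual_id": individual_ids}
    for gene in GENES:
        freqs = config.gene_freqs(gene)
        names = [f"{gene}*{i + 1:02d}" for i in range(len(freqs))]
        draws = rng.choice(len(freqs), size=(n, 2), p=freqs)
        for copy in (0, 1):
            col = f"allele_{2 * GENES.index(gene) + copy + 1}"
            genotype_cols[col] = [names[j] for j in draws[:, copy]]
    genotypes = pd.DataFrame(genotype_cols)

    alleles = config.allele_names()
    catalog = universe.tcr_catalog.copy()
    tcr_ids = catalog["tcr_id"].tolist()

    planted_tcr_idx = rng.choice(len(tcr_ids), size=config.n_planted_pairs,
                                 replace=False)
    planted_alleles = rng.integers(0, len(alleles), size=config.n_planted_pairs)
    planted = [(tcr_ids[t], alleles[a])
               for t, a in zip(planted_tcr_idx, planted_alleles)]

    if config.motif_len:
        pseudo_of = dict(zip(universe.pseudo_table["allele"],
                             universe.pseudo_table["pseudo_seq"]))
        cdr3 = catalog["cdr3_aa"].to_numpy(dtype=object)
        for t_idx, a_idx in zip(planted_tcr_idx, planted_alleles):
            motif = pseudo_of[alleles[a_idx]][: config.motif_len]
            s = cdr3[t_idx]
            cdr3[t_idx] = s[0] + motif + s[1 + config.motif_len:]
        catalog["cdr3_aa"] = cdr3

    # heavy-tailed per-TCR publicity: most TCRs occur at a low background
    # rate, a minority are highly public irrespective of HLA carriage
    rates = np.full(len(tcr_ids), config._low_publicity_rate())
    n_high = round(config.frac_high_publicity * len(tcr_ids))
    if n_high:
        high_idx = rng.choice(len(tcr_ids), size=n_high, replace=False)
        lo_pub, hi_pub = config.high_publicity_factors
        rates[high_idx] = config.p_background * rng.uniform(lo_pub, hi_pub,
                                                            size=n_high)
    presence = rng.random((n, len(tcr_ids))) < rates[None, :]
    allele_arr = genotypes.filter(like="allele_").to_numpy()
    for t_idx, a_idx in zip(planted_tcr_idx, planted_alleles):
        carriers = (allele_arr == alleles[a_idx]).any(axis=1)
        presence[carriers, t_idx] = rng.random(int(carriers.sum())) < config.p_carrier

    occurrence = pd.DataFrame(presence, index=pd.Index(individual_ids,
                                                       name="individual_id"),
                              columns=tcr_ids)
    cohort = Cohort(genotypes, occurrence, catalog)
    return cohort, GroundTruth(frozenset(planted))


def simulate(config: SimulationConfig) -> tuple[Universe, Cohort, GroundTruth]:
    """Convenience wrapper: universe + cohort in one call."""
    universe = generate_sequence_universe(config)
    cohort, truth = generate_cohort(config, universe)
    # the cohort's catalog carries the planted motifs; keep universe in sync
    universe = replace(universe, tcr_catalog=cohort.tcr_catalog)
    return universe, cohort, truth


def write_cohort(outdir: str | Path, universe: Universe, cohort: Cohort,
                 truth: GroundTruth | None = None) -> None:
    """Write the cohort as plain TSV/CSV files.

    Layout: ``repertoire.tsv`` (individual_id, cdr3_aa, v_gene; one row per
    observed TCR per individual), ``genotypes.tsv``, ``pseudo.tsv``,
    ``vcdr.tsv`` and optionally ``ground_truth.csv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    occ = cohort.occurrence
    ind_idx, tcr_idx = np.nonzero(occ.to_numpy())
    catalog = cohort.tcr_catalog.set_index("tcr_id")
    tcr_ids = occ.columns.to_numpy()[tcr_idx]
    repertoire = pd.DataFrame({
        "individual_id": occ.index.to_numpy()[ind_idx],
        "cdr3_aa": catalog.loc[tcr_ids, "cdr3_aa"].to_numpy(),
        "v_gene": catalog.loc[tcr_ids, "v_gene"].to_numpy(),
    })
    repertoire.to_csv(outdir / "repertoire.tsv", sep="\t", index=False)
    cohort.genotypes.to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
    universe.pseudo_table.to_csv(outdir / "pseudo.tsv", sep="\t", index=False)
    universe.vcdr_table.to_csv(outdir / "vcdr.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_frame().to_csv(outdir / "ground_truth.csv", index=False)
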