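# depth-tcr

Sequence-based prediction of TCR–HLA association, and HLA similarity /
heterozygosity metrics derived from the predictions.

Which T-cell receptors (TCRs) a person's repertoire contains depends on
which HLA alleles they carry.  This package implements the full pipeline
that exploits that dependence, for immunogenomics researchers working with
cohort repertoire + HLA genotype data:

1. **Pair discovery** — screen every public TCR (seen in ≥ 2 individuals)
   against every HLA allele with a one-sided Fisher's exact test on the
   2×2 carrier table; call pairs with Benjamini–Hochberg FDR < 0.05
   *positive*.  Sample 5 bias-matched *negative* pairs per positive (HLA
   frequencies proportional to the positives; negative TCRs matched on
   population frequency per allele) and split 60/20/20 keeping the 1:5
   ratio exact in every split.
2. **Classification** — a two-branch neural network scores a (TCR, HLA)
   pair in (0, 1): the HLA branch is a dense layer over the flattened,
   encoded HLA *pseudo sequence* (the contact positions); the TCR branch
   runs a CNN over the CDR3 (padded to 27 by anchoring both ends, `'.'`
   in the middle) and concatenates it with the CDR3 length and the
   CDR1/CDR2/CDR2.5/CDR3 encodings.  Training uses Adam on binary
   cross-entropy with early stopping on validation AUC; predictions come
   from an ensemble (mean score over members trained from different
   seeds).
3. **HLA metrics** — from a table of association scores between alleles
   and a reference TCR list:
   * between-individual distances over the 6 class-I alleles:
     `dist_breadth` = Jaccard distance |A△B|/|A∪B| of the two individuals'
     union TCR sets, and `dist_cor` = optimal-transport reduction (uniform
     1/6 marginals) of the 6×6 matrix of (1 − Spearman ρ) allele
     distances;
   * per-individual heterozygosity: `depth_breadth` (union TCR-set size),
     `mean_depth_cor` / `mean_depth_set` / `mean_aa` (mean over the A/B/C
     genes of the between-allele distance of the gene's two alleles), and
     the binary `homozygous` flag.

A synthetic-cohort generator with planted HLA-restricted TCRs (elevated
occurrence in carriers, supertype-complementary CDR3 motifs) makes the
whole pipeline runnable and testable with no external data; real
repertoire/genotype/pseudo-sequence tables drop into the same TSV
interfaces.  See `docs/methods.md` for the model details and the
generator's assumptions.

## Worked example

Simulate the standard cohort (300 individuals, 20 class-I alleles, 2,000
public TCRs, 100 planted pairs), discover and label pairs, train a
3-member ensemble, and evaluate on the held-out test split:

```python
import depth_tcr as d
from depth_tcr import experiments as ex

out = ex.train_eval_experiment(d.SimulationConfig(seed=0),
                               n_members=3, base_seed=0)
print(out["ensemble"].summary())
print(out["report"].summary())
```

```
Ensemble of 3 classifiers (mean score)
member validation AUCs: 0.829, 0.844, 0.840
mean validation AUC:    0.8378
n_pos=20  n_neg=100  AUC=0.8615  sensitivity=0.3000  specificity=0.9000  (cutoff 0.5)
```

The ensemble separates held-out positive from negative pairs with AUC
0.86.  Sensitivity at the default 0.5 cutoff is low at this small training
size (the model is conservative under the 1:5 class ratio) while
specificity is high — the ranking, summarised by the AUC, is the robust
quantity.  Continuing, score a reference TCR list against every allele and
derive HLA metrics for the first three individuals:

```python
universe = out["universe"]
catalog = universe.tcr_catalog.head(40)
pairs = catalog.assign(key=1).merge(
    universe.pseudo_table.assign(key=1)[["allele", "key"]],
    on="key").drop(columns="key")
data = d.encode_pairs(pairs, universe.pseudo_table, universe.vcdr_table)
profile = d.AssociationProfile.from_scores(out["ensemble"].predict_table(data))
genotypes = out["cohort"].genotypes.head(3)
print(d.distance_matrix(genotypes, profile, method="cor").round(3))
print(d.heterozygosity_table(genotypes, profile, universe.pseudo_table).round(3))
```

```
          ind_0001  ind_0002  ind_0003
ind_0001     0.000     0.006     0.006
ind_0002     0.006     0.000     0.009
ind_0003     0.006     0.009     0.000

individual_id  homozygous  depth_breadth  mean_depth_cor  mean_depth_set  mean_aa
     ind_0001           0              1           0.011           1.000    0.643
     ind_0002           0              1           0.022           0.333    0.624
     ind_0003           1              2           0.001           0.000    0.226
```

`ind_0003` is homozygous at one gene and accordingly shows near-zero
score-based allele distances and the lowest sequence-based diversity
(`mean_aa`).  Both tables are plain DataFrames/CSVs ready for downstream
kernel-regression or survival tooling.

The same pipeline is available from the shell:

```bash
depth-tcr simulate --out cohort/ --seed 0
depth-tcr discover --repertoire cohort/repertoire.tsv \
    --genotypes cohort/genotypes.tsv --seed 0 --out pairs.csv
depth-tcr train --pairs pairs.csv --pseudo cohort/pseudo.tsv \
    --vcdr cohort/vcdr.tsv --ensemble 3 --seed 0 --out model/
depth-tcr predict --model model/ --pairs pairs.csv \
    --pseudo cohort/pseudo.tsv --vcdr cohort/vcdr.tsv --out scores.csv
depth-tcr metrics hetero --scores scores.csv \
    --genotypes cohort/genotypes.tsv --pseudo cohort/pseudo.tsv --out het.csv
```

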