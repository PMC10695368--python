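"""End-to-end experiment recipes on synthetic cohorts.

Each function composes the pipeline — simulate, discover, encode, train,
evaluate — into one reproducible experiment with a structured result dict.
They are the building blocks of the package's self-validation: planted-pair
recovery of the discovery stage, held-out classification accuracy of the
ensemble, and generalization to an allele excluded from training.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from depth_tcr import discovery, features, model as model_mod
from depth_tcr.simulate import SimulationConfig, simulate

__all__ = [
    "discovery_experiment",
    "null_discovery_experiment",
    "labeled_pairs_from_cohort",
    "encode_splits",
    "train_eval_experiment",
    "leave_one_out_experiment",
]


def discovery_experiment(config: SimulationConfig) -> dict:
    """Simulate a cohort and measure planted-pair recovery at FDR 0.05.

    Returns recovery (fraction of planted pairs rediscovered), precision
    (fraction of discoveries that are planted), and the tested table.
    """
    universe, cohort, truth = simulate(config)
    occ = discovery.OccurrenceMatrix.from_cohort(cohort).public_filter()
    tested = discovery.select_positive_pairs(occ, cohort.genotypes)
    found = set(tested.loc[tested["label"] == 1, ["tcr_id", "allele"]]
                .itertuples(index=False, name=None))
    planted = truth.planted_pairs
    hits = len(found & planted)
    return {
        "universe": universe, "cohort": cohort, "truth": truth,
        "tested": tested,
        "n_discovered": len(found),
        "recovery": hits / len(planted) if planted else float("nan"),
        "precision": hits / len(found) if found else float("nan"),
    }


def null_discovery_experiment(config: SimulationConfig) -> dict:
    """Discovery on a cohort with no planted pairs: every hit is false.

    Under the global null the false-discovery proportion is 1 whenever
    anything is discovered and 0 otherwise; its average over seeds is what
    Benjamini-Hochberg controls at the nominal level.
    """
    null_config = replace(config, n_planted_pairs=0)
    universe, cohort, _ = simulate(null_config)
    occ = discovery.OccurrenceMatrix.from_cohort(cohort).public_filter()
    tested = discovery.select_positive_pairs(occ, cohort.genotypes)
    n_disc = int((tested["label"] == 1).sum())
    return {
        "n_discovered": n_disc,
        "n_tested": len(tested),
        "false_discovery_proportion": 1.0 if n_disc else 0.0,
    }


def labeled_pairs_from_cohort(config: SimulationConfig,
                              sampling_seed: int | None = None,
                              loo_allele: str | None = None) -> dict:
    """Discovery plus negative sampling plus splitting, with sequences.

    With ``loo_allele`` the split is leave-one-HLA-out; ``"auto"`` picks
    the allele with the most positive pairs (mirroring the practice of
    holding out a frequent allele so the test set is informative).
    """
    seed = config.seed if sampling_seed is None else sampling_seed
    out = discovery_experiment(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        labeled = discovery.sample_negative_pairs(out["tested"], seed=seed)
    if loo_allele is None:
        labeled = discovery.split_pairs(labeled, seed=seed)
    else:
        if loo_allele == "auto":
            loo_allele = (labeled[labeled["label"] == 1]
                          .groupby("allele").size().idxmax())
        labeled = discovery.make_leave_one_hla_out_split(labeled, loo_allele,
                                                         seed=seed)
    out["labeled"] = discovery.attach_tcr_sequences(
        labeled, out["cohort"].tcr_catalog)
    out["loo_allele"] = loo_allele
    return out


def encode_splits(labeled: pd.DataFrame, universe, scheme: str = "one_hot"
                  ) -> dict[str, features.EncodedDataset]:
    """Encode the train/valid/test subsets of a labeled pair table."""
    return {
        split: features.encode_pairs(
            labeled[labeled["split"] == split].reset_index(drop=True),
            universe.pseudo_table, universe.vcdr_table, scheme)
        for split in ("train", "valid", "test")
    }


def train_eval_experiment(config: SimulationConfig,
                          model_config: model_mod.ModelConfig | None = None,
                          n_members: int = 3, base_seed: int = 0,
                          permute_labels: bool = False) -> dict:
    """Train an ensemble on discovered pairs; evaluate on the test split.

    ``permute_labels`` shuffles the training and validation labels (a
    negative control: the sequence signal is destroyed while the class
    balance is kept, so held-out AUC should fall to chance).
    """
    out = labeled_pairs_from_cohort(config)
    data = encode_splits(out["labeled"], out["universe"])
    if permute_labels:
        rng = np.random.default_rng([base_seed, 99])
        for split in ("train", "valid"):
            data[split].labels = rng.permutation(data[split].labels)
    ensemble = model_mod.train_ensemble(data["train"], data["valid"],
                                        model_config, n_members=n_members,
                                        base_seed=base_seed)
    report = model_mod.evaluate(ensemble.predict(data["test"]),
                                data["test"].labels)
    out.update({"data": data, "ensemble": ensemble, "report": report})
    return out


def leave_one_out_experiment(config: SimulationConfig,
                             model_config: model_mod.ModelConfig | None = None,
                             held_out_allele: str = "auto",
                             base_seed: int = 0) -> dict:
    """Hold one allele (and its TCRs) out entirely; train and evaluate.

    Measures generalization to an allele never seen during training, the
    hardest setting for a sequence-based association model.
    """
    out = labeled_pairs_from_cohort(config, loo_allele=held_out_allele)
    data = encode_splits(out["labeled"], out["universe"])
    model = model_mod.TCRHLAModel(data["train"], data["valid"],
                                  model_config or model_mod.ModelConfig())
    result = model.fit(seed=base_seed)
    report = model_mod.evaluate(result.predict(data["test"]),
                                data["test"].labels)
    out.update({"data": data, "result": result, "report": report})
    return out
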