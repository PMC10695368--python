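"""The TCR-HLA association classifier: model, results, ensembles, evaluation.

The public surface follows the statsmodels convention: a
:class:`TCRHLAModel` is constructed from encoded training/validation data
plus a :class:`ModelConfig`; :meth:`TCRHLAModel.fit` runs mini-batch Adam
on binary cross-entropy, monitors the validation AUC once per epoch, and
returns a :class:`TCRHLAResults` holding the parameters of the epoch with
the best validation AUC (early stopping with patience).  An
:class:`EnsembleResults` averages the scores of several results objects
trained from different seeds; the published configuration uses 20 members,
where score averaging stabilises the prediction against seed-to-seed
training noise.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from depth_tcr import _net
from depth_tcr.features import EncodedDataset

__all__ = [
    "ModelConfig", "TCRHLAModel", "TCRHLAResults", "EnsembleResults",
    "train_ensemble", "evaluate", "EvalReport", "cross_validate_hyperparams",
    "DEFAULT_ENSEMBLE_SIZE",
]

DEFAULT_ENSEMBLE_SIZE = 20


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the two-branch classifier.

    ``head_units`` fixes both the number of head dense layers (one or two)
    and their widths; ``dropout_p`` applies after the last head layer.
    ``pool_size=None`` means global max-pooling over the convolution
    output, i.e. pure motif detection with no positional information.
    """

    scheme: str = "one_hot"
    conv_filters: int = 32
    conv_kernel: int = 3
    pool_size: int | None = None
    hla_dense_units: int = 32
    tcr_dense_units: int = 32
    head_units: tuple[int, ...] = (32,)
    dropout_p: float = 0.2
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.head_units) not in (1, 2):
            raise ValueError("head_units must contain one or two layer widths")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.pool_size is not None and self.pool_size < 1:
            raise ValueError("pool_size must be positive (or None for global)")
        if self.conv_kernel < 1 or self.conv_filters < 1:
            raise ValueError("conv_filters and conv_kernel must be positive")


def _as_batch(data: EncodedDataset, idx=None) -> dict:
    if idx is None:
        return {"hla": data.hla, "cdr3": data.cdr3, "cdr_flat": data.cdr_flat,
                "cdr3_len_onehot": data.cdr3_len_onehot}
    return {"hla": data.hla[idx], "cdr3": data.cdr3[idx],
            "cdr_flat": data.cdr_flat[idx],
            "cdr3_len_onehot": data.cdr3_len_onehot[idx]}


class TCRHLAModel:
    """Two-branch neural classifier of TCR-HLA association.

    Parameters
    ----------
    train_data, valid_data : EncodedDataset
        Labeled encoded pairs.  The validation set drives early stopping
        and must contain both classes.
    config : ModelConfig, optional
    """

    def __init__(self, train_data: EncodedDataset,
                 valid_data: EncodedDataset | None = None,
                 config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        if train_data.scheme != self.config.scheme:
            raise ValueError(
                f"dataset encoded with scheme {train_data.scheme!r} but "
                f"config expects {self.config.scheme!r}")
        if self.config.conv_kernel > train_data.cdr3.shape[1]:
            raise ValueError("conv_kernel wider than the padded CDR3")
        if set(np.unique(train_data.labels)) - {0, 1}:
            raise ValueError("training labels must be 0/1")
        self.train_data = train_data
        self.valid_data = valid_data
        if valid_data is not None and len(np.unique(valid_data.labels)) < 2:
            raise ValueError("validation set must contain both classes "
                             "(AUC is undefined otherwise)")

    def _init_params(self, rng: np.random.Generator) -> dict:
        d = self.train_data
        c = self.config
        return _net.init_params(
            rng,
            hla_flat_dim=d.hla.shape[1] * d.hla.shape[2],
            cdr3_channels=d.cdr3.shape[2],
            flat_dim=d.cdr_flat.shape[1],
            len_dim=d.cdr3_len_onehot.shape[1],
            conv_filters=c.conv_filters,
            conv_kernel=c.conv_kernel,
            cdr3_positions=d.cdr3.shape[1],
            pool_size=c.pool_size,
            hla_dense_units=c.hla_dense_units,
            tcr_dense_units=c.tcr_dense_units,
            head_units=tuple(c.head_units),
        )

    def fit(self, seed: int | None = None, verbose: bool = False
            ) -> "TCRHLAResults":
        """Train with Adam + early stopping on validation AUC.

        Returns the results object holding the parameter snapshot from the
        epoch with the highest validation AUC.  Deterministic given the
        seed (``config.seed`` unless overridden here).
        """
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        if self.valid_data is None:
            raise ValueError("fit() requires a validation set for early stopping")
        rng = np.random.default_rng([cfg.seed, 2024])
        params = self._init_params(rng)
        state = _net.AdamState(params)
        n = len(self.train_data)
        y = self.train_data.labels.astype(np.float64)
        valid_batch = _as_batch(self.valid_data)
        y_valid = self.valid_data.labels

        best_auc, best_epoch, best_params = -np.inf, -1, None
        log_rows = []
        since_improvement = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                batch = _as_batch(self.train_data, idx)
                loss, grads = _net.loss_and_grads(
                    params, batch, y[idx], pool_size=cfg.pool_size,
                    dropout_p=cfg.dropout_p, rng=rng)
                _net.adam_step(params, grads, state, lr=cfg.learning_rate,
                               weight_decay=cfg.weight_decay)
                epoch_loss += loss * len(idx)
            epoch_loss /= n
            valid_scores = _net.forward(params, valid_batch,
                                        pool_size=cfg.pool_size)
            valid_auc = float(roc_auc_score(y_valid, valid_scores))
            log_rows.append({"epoch": epoch, "train_loss": epoch_loss,
                             "valid_auc": valid_auc})
            if verbose:
                print(f"epoch {epoch:3d}  loss {epoch_loss:.4f}  "
                      f"valid AUC {valid_auc:.4f}")
            if valid_auc > best_auc:
                best_auc, best_epoch = valid_auc, epoch
                best_params = copy.deepcopy(params)
                since_improvement = 0
            else:
                since_improvement += 1
                if since_improvement >= cfg.patience:
                    break
        return TCRHLAResults(model=self, config=cfg, params=best_params,
                             log=pd.DataFrame(log_rows), best_epoch=best_epoch)


@dataclass
class TCRHLAResults:
    """Fitted classifier: best-epoch parameters, training log, prediction."""

    model: TCRHLAModel | None
    config: ModelConfig
    params: dict[str, np.ndarray]
    log: pd.DataFrame
    best_epoch: int

    @property
    def best_valid_auc(self) -> float:
        return float(self.log.loc[self.log["epoch"] == self.best_epoch,
                                  "valid_auc"].iloc[0])

    def predict(self, data: EncodedDataset) -> np.ndarray:
        """Association scores in (0, 1) for encoded pairs."""
        return _net.forward(self.params, _as_batch(data),
                            pool_size=self.config.pool_size)

    def predict_table(self, data: EncodedDataset) -> pd.DataFrame:
        out = data.pairs.copy()
        out["score"] = self.predict(data)
        return out

    def summary(self) -> str:
        c = self.config
        n_params = sum(int(np.prod(v.shape)) for v in self.params.values())
        lines = [
            "TCR-HLA association classifier — fit results",
            "=" * 46,
            f"encoding scheme        {c.scheme}",
            f"conv filters/kernel    {c.conv_filters}/{c.conv_kernel}",
            f"dense units (HLA/TCR)  {c.hla_dense_units}/{c.tcr_dense_units}",
            f"head layers            {tuple(c.head_units)}  dropout {c.dropout_p}",
            f"parameters             {n_params}",
            f"epochs run             {len(self.log)}",
            f"best epoch             {self.best_epoch}",
            f"best validation AUC    {self.best_valid_auc:.4f}",
        ]
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savez(outdir / "params.npz", **self.params)
        cfg = asdict(self.config)
        cfg["head_units"] = list(cfg["head_units"])
        (outdir / "config.json").write_text(json.dumps(
            {"config": cfg, "best_epoch": self.best_epoch}, indent=2))
        self.log.to_csv(outdir / "training_log.csv", index=False)

    @classmethod
    def load(cls, outdir: str | Path) -> "TCRHLAResults":
        outdir = Path(outdir)
        blob = json.loads((outdir / "config.json").read_text())
        cfg = blob["config"]
        cfg["head_units"] = tuple(cfg["head_units"])
        params = dict(np.load(outdir / "params.npz"))
        return cls(model=None, config=ModelConfig(**cfg), params=params,
                   log=pd.read_csv(outdir / "training_log.csv"),
                   best_epoch=blob["best_epoch"])


@dataclass
class EnsembleResults:
    """Mean-score ensemble of fitted classifiers.

    The prediction is the arithmetic mean of the members' scores, so the
    output is invariant to member order and still lies in (0, 1).
    """

    members: list[TCRHLAResults] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("an ensemble needs at least one member")
        schemes = {m.config.scheme for m in self.members}
        if len(schemes) > 1:
            raise ValueError(f"members use mixed encoding schemes {schemes}")

    def predict(self, data: EncodedDataset) -> np.ndarray:
        return np.mean([m.predict(data) for m in self.members], axis=0)

    def predict_table(self, data: EncodedDataset) -> pd.DataFrame:
        out = data.pairs.copy()
        out["score"] = self.predict(data)
        return out

    def summary(self) -> str:
        aucs = [m.best_valid_auc for m in self.members]
        return "\n".join([
            f"Ensemble of {len(self.members)} classifiers (mean score)",
            f"member validation AUCs: "
            + ", ".join(f"{a:.3f}" for a in aucs),
            f"mean validation AUC:    {np.mean(aucs):.4f}",
        ])

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "ensemble.json").write_text(
            json.dumps({"n_members": len(self.members)}))
        for i, m in enumerate(self.members):
            m.save(outdir / f"member_{i:02d}")

    @classmethod
    def load(cls, outdir: str | Path) -> "EnsembleResults":
        outdir = Path(outdir)
        n = json.loads((outdir / "ensemble.json").read_text())["n_members"]
        return cls([TCRHLAResults.load(outdir / f"member_{i:02d}")
                    for i in range(n)])


def train_ensemble(train_data: EncodedDataset, valid_data: EncodedDataset,
                   config: ModelConfig | None = None,
                   n_members: int = DEFAULT_ENSEMBLE_SIZE,
                   base_seed: int = 0, verbose: bool = False
                   ) -> EnsembleResults:
    """Train ``n_members`` models from seeds derived from ``base_seed``."""
    config = config or ModelConfig()
    model = TCRHLAModel(train_data, valid_data, config)
    members = []
    for i in range(n_members):
        seed = int(np.random.SeedSequence([base_seed, i]).generate_state(1)[0]
                   % (2 ** 31))
        members.append(model.fit(seed=seed, verbose=verbose))
    return EnsembleResults(members)


@dataclass(frozen=True)
class EvalReport:
    """AUC plus sensitivity/specificity at the classification cutoff."""

    auc: float
    sensitivity: float
    specificity: float
    cutoff: float
    n_pos: int
    n_neg: int

    def summary(self) -> str:
        return (f"n_pos={self.n_pos}  n_neg={self.n_neg}  "
                f"AUC={self.auc:.4f}  sensitivity={self.sensitivity:.4f}  "
                f"specificity={self.specificity:.4f}  (cutoff {self.cutoff})")


def evaluate(scores, labels, cutoff: float = 0.5) -> EvalReport:
    """Score a set of predictions.

    AUC uses the rank statistic with midranks for ties; a pair is called
    associated when its score is strictly greater than ``cutoff``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("evaluation requires both classes")
    pred_pos = scores > cutoff
    is_pos = labels == 1
    tp = int(np.sum(pred_pos & is_pos))
    tn = int(np.sum(~pred_pos & ~is_pos))
    return EvalReport(
        auc=float(roc_auc_score(labels, scores)),
        sensitivity=tp / int(is_pos.sum()),
        specificity=tn / int((~is_pos).sum()),
        cutoff=cutoff,
        n_pos=int(is_pos.sum()),
        n_neg=int((~is_pos).sum()),
    )


def cross_validate_hyperparams(grid: list[ModelConfig], data: EncodedDataset,
                               k: int = 3, seed: int = 0,
                               verbose: bool = False
                               ) -> tuple[ModelConfig, pd.DataFrame]:
    """Pick the config with the best mean validation AUC over k folds.

    Each fold's held-out part serves as the validation set (it both drives
    early stopping and supplies the fold AUC).  Ties break toward the
    first config in the grid.
    """
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    if k < 2:
        raise ValueError("cross-validation needs k >= 2 folds")
    folds = list(StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
                 .split(np.zeros(len(data)), data.labels))
    rows = []
    for ci, cfg in enumerate(grid):
        aucs = []
        for fi, (tr, va) in enumerate(folds):
            model = TCRHLAModel(data.subset(tr), data.subset(va), cfg)
            res = model.fit(seed=int(np.random.SeedSequence(
                [seed, ci, fi]).generate_state(1)[0] % (2 ** 31)))
            aucs.append(res.best_valid_auc)
        rows.append({"config_index": ci, "mean_valid_auc": float(np.mean(aucs))})
        if verbose:
            print(f"config {ci}: mean valid AUC {rows[-1]['mean_valid_auc']:.4f}")
    table = pd.DataFrame(rows)
    best = int(table["mean_valid_auc"].idxmax())  # first max wins
    return grid[best], table
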