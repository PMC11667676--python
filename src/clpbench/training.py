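"""Model training: imbalance-aware losses, early stopping, grid search,
and the hyperparameter-subsampling analysis.

Classification uses binary cross-entropy with inverse-class-frequency loss
re-weighting (majority class normalized to weight 1, so a 10:1 imbalance
gives the minority class weight 10); regression uses mean squared error.
Early stopping monitors validation loss with a patience of 5 epochs and an
improvement tolerance of 1e-5, restoring the best epoch's weights.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import classification_suite, regression_suite
from .models import ModelConfig, SequenceModel, XGBoostModel, build_model
from .nn import Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig", "TrainingResult", "class_weights", "loss_value",
    "weighted_bce_with_logits", "mse_loss", "early_stopping",
    "train_sequence_model", "train_xgboost", "grid_search",
    "subsample_analysis",
]


@dataclass(frozen=True)
class TrainingConfig:
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 5            # epochs (trees for the XGBoost baseline)
    tolerance: float = 1e-5      # minimum meaningful drop in validation loss
    reweight_loss: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class TrainingResult:
    best_epoch: int
    stop_epoch: int
    train_loss_trace: list[float]
    val_loss_trace: list[float]
    final_val_loss: float
    config: ModelConfig | None = None

    def __post_init__(self):
        if self.val_loss_trace and not np.isclose(
                self.final_val_loss, min(self.val_loss_trace)):
            raise ValueError("final_val_loss must equal the trace minimum")


def class_weights(labels) -> dict[int, float]:
    """Inverse-frequency class weights, majority class normalized to 1.

    350 actives vs 3500 inactives gives weights {1: 10, 0: 1}.
    """
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("class_weights needs at least one example of each "
                         f"class; got only class {classes.tolist()}")
    majority = counts.max()
    return {int(c): float(majority / n) for c, n in zip(classes, counts)}


# --- losses ---------------------------------------------------------------

def _softplus(z: Tensor) -> Tensor:
    # max(z,0) + log1p(exp(-|z|)), numerically stable
    absz = z.relu() * 2.0 - z
    return z.relu() + ((absz * -1.0).exp() + 1.0).log()


def weighted_bce_with_logits(logits: Tensor, targets: np.ndarray,
                             weights: np.ndarray | None = None) -> Tensor:
    """Per-molecule weighted binary cross-entropy (mean over the batch)."""
    if not np.all(np.isfinite(logits.data)):
        raise FloatingPointError("non-finite predictions in loss")
    y = np.asarray(targets, dtype=np.float64)
    per = _softplus(logits) - logits * Tensor(y)
    if weights is not None:
        per = per * Tensor(np.asarray(weights, dtype=np.float64))
    return per.mean()


def mse_loss(predictions: Tensor, targets: np.ndarray) -> Tensor:
    if not np.all(np.isfinite(predictions.data)):
        raise FloatingPointError("non-finite predictions in loss")
    diff = predictions - Tensor(np.asarray(targets, dtype=np.float64))
    return (diff * diff).mean()


def loss_value(predictions: np.ndarray, targets: np.ndarray, task: str,
               weights: np.ndarray | None = None) -> float:
    """Scalar loss on plain arrays (probabilities for classification)."""
    predictions = np.asarray(predictions, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if predictions.shape != targets.shape:
        raise ValueError("length mismatch")
    if not np.all(np.isfinite(predictions)):
        raise FloatingPointError("non-finite predictions")
    if task == "classification":
        p = np.clip(predictions, 1e-12, 1 - 1e-12)
        per = -(targets * np.log(p) + (1 - targets) * np.log(1 - p))
        if weights is not None:
            per = per * weights
        return float(per.mean())
    return float(((predictions - targets) ** 2).mean())


# --- early stopping -------------------------------------------------------

def early_stopping(trace, patience: int = 5,
                   tolerance: float = 1e-5) -> tuple[int, int]:
    """Apply patience semantics to a validation-loss trace.

    An epoch improves iff it lowers the best-so-far loss by strictly more
    than `tolerance`; after `patience` consecutive non-improving epochs
    training halts.  Returns (stop_epoch, best_epoch) as 1-based epochs;
    stop_epoch is len(trace) if the trace ends before the patience is
    exhausted.
    """
    best = np.inf
    best_epoch = 0
    bad = 0
    for epoch, value in enumerate(trace, start=1):
        if best - value > tolerance:
            best = value
            best_epoch = epoch
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                return epoch, best_epoch
    return len(trace), best_epoch


# --- training loops -------------------------------------------------------

def train_sequence_model(model: SequenceModel, X_train: np.ndarray,
                         y_train: np.ndarray, X_val: np.ndarray,
                         y_val: np.ndarray,
                         config: TrainingConfig) -> TrainingResult:
    """Minibatch Adam training with early stopping on validation loss."""
    task = model.config.task
    rng = np.random.default_rng(config.seed)
    y_train = np.asarray(y_train, dtype=np.float64)
    y_val = np.asarray(y_val, dtype=np.float64)
    weights_by_class = None
    w_train = w_val = None
    if task == "classification" and config.reweight_loss:
        weights_by_class = class_weights(y_train)
        w_train = np.vectorize(weights_by_class.get)(y_train.astype(int))
        w_val = np.array([weights_by_class.get(int(y), 1.0) for y in y_val])
    optimizer = model.make_optimizer()

    train_trace: list[float] = []
    val_trace: list[float] = []
    best_state = model.state()
    best = np.inf
    best_epoch = 0
    bad = 0
    stop_epoch = 0
    for epoch in range(1, config.max_epochs + 1):
        stop_epoch = epoch
        order = rng.permutation(len(X_train))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            out = model.forward(X_train[idx], rng=rng, training=True)
            if task == "classification":
                batch_w = w_train[idx] if w_train is not None else None
                batch_loss = weighted_bce_with_logits(out, y_train[idx],
                                                      batch_w)
            else:
                batch_loss = mse_loss(out, y_train[idx])
            optimizer.zero_grad()
            batch_loss.backward()
            model.mask_pad_gradient()
            optimizer.step()
            epoch_losses.append(float(batch_loss.data))
        train_trace.append(float(np.mean(epoch_losses)))
        preds = model.predict(X_val)
        val_loss = loss_value(preds, y_val, task, w_val)
        val_trace.append(val_loss)
        if best - val_loss > config.tolerance:
            best = val_loss
            best_epoch = epoch
            best_state = model.state()
            bad = 0
        else:
            bad += 1
            if bad >= config.patience:
                break
    model.load_state(best_state)
    return TrainingResult(best_epoch=best_epoch, stop_epoch=stop_epoch,
                          train_loss_trace=train_trace,
                          val_loss_trace=val_trace,
                          final_val_loss=float(min(val_trace)),
                          config=model.config)


def train_xgboost(config: ModelConfig, train_smiles, y_train, val_smiles,
                  y_val, training: TrainingConfig) -> tuple[XGBoostModel, float]:
    """Fit the fingerprint baseline with tree-count early stopping."""
    model = XGBoostModel(config)
    sample_weight = None
    w_val = None
    if config.task == "classification" and training.reweight_loss:
        weights = class_weights(y_train)
        sample_weight = np.vectorize(weights.get)(
            np.asarray(y_train, dtype=int))
        w_val = np.array([weights.get(int(y), 1.0) for y in y_val])
    model.fit(train_smiles, y_train, val_smiles, y_val,
              sample_weight=sample_weight, patience=training.patience)
    val_loss = loss_value(model.predict(val_smiles), y_val, config.task,
                          w_val)
    return model, val_loss


# --- grid search ----------------------------------------------------------

def _evaluate(task: str, y_true, y_pred) -> dict[str, float]:
    report = (classification_suite(y_true, y_pred) if task == "classification"
              else regression_suite(y_true, y_pred))
    return report.to_dict()


def grid_search(configs: list[ModelConfig], data, folds,
                training: TrainingConfig,
                test_indices: np.ndarray | None = None) -> pd.DataFrame:
    """Train every configuration on every Monte Carlo fold.

    `data` is an object exposing `X` (padded index matrix), `y`,
    `smiles` (list) and `vocab`; `folds` is a list of (train_idx, val_idx)
    index arrays; `test_indices` adds held-out test metrics per run.
    A failed run (non-finite loss) is recorded with ``failed=True`` and
    excluded from selection rather than aborting the search.
    """
    if not configs:
        raise ValueError("empty configuration grid")
    rows = []
    for ci, cfg in enumerate(configs):
        for fi, (tr, va) in enumerate(folds):
            row = {"config_id": ci, "label": cfg.short_label(),
                   "architecture": cfg.architecture,
                   "encoding": cfg.encoding.strategy if
                   cfg.architecture != "XGBoost" else "fingerprint",
                   "fold": fi, "failed": False}
            row.update(_config_columns(cfg))
            try:
                if cfg.architecture == "XGBoost":
                    smiles = data.smiles
                    model, val_loss = train_xgboost(
                        cfg, [smiles[i] for i in tr], data.y[tr],
                        [smiles[i] for i in va], data.y[va], training)
                    val_pred = model.predict([smiles[i] for i in va])
                    test_pred = (model.predict([smiles[i] for i in test_indices])
                                 if test_indices is not None else None)
                else:
                    model = build_model(cfg, data.vocab)
                    result = train_sequence_model(
                        model, data.X[tr], data.y[tr], data.X[va], data.y[va],
                        training)
                    val_loss = result.final_val_loss
                    row["best_epoch"] = result.best_epoch
                    val_pred = model.predict(data.X[va])
                    test_pred = (model.predict(data.X[test_indices])
                                 if test_indices is not None else None)
                row["val_loss"] = val_loss
                for key, value in _evaluate(cfg.task, data.y[va],
                                            val_pred).items():
                    row[f"val_{key}"] = value
                if test_pred is not None:
                    for key, value in _evaluate(cfg.task,
                                                data.y[test_indices],
                                                test_pred).items():
                        row[f"test_{key}"] = value
            except FloatingPointError as exc:
                warnings.warn(f"run {cfg.short_label()} fold {fi} failed: "
                              f"{exc}")
                row["failed"] = True
                row["val_loss"] = np.nan
            rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    if len(ok):
        best = (ok.groupby("config_id")["val_loss"].mean().idxmin())
        table.attrs["best_config_id"] = int(best)
    return table


def _config_columns(cfg: ModelConfig) -> dict:
    cols = {"n_layers": cfg.n_layers, "learning_rate": cfg.learning_rate}
    if cfg.architecture == "CNN":
        cols.update(cnn_n_filters=cfg.cnn_n_filters,
                    cnn_kernel_length=cfg.cnn_kernel_length,
                    embedding_dim=cfg.encoding.dim)
    elif cfg.architecture == "RNN":
        cols.update(rnn_hidden_dim=cfg.rnn_hidden_dim,
                    embedding_dim=cfg.encoding.dim)
    elif cfg.architecture == "Transformer":
        cols.update(transformer_n_heads=cfg.transformer_n_heads,
                    transformer_mlp_dim=cfg.transformer_mlp_dim,
                    embedding_dim=cfg.encoding.dim)
    else:
        cols.update(xgb_max_depth=cfg.xgb_max_depth, xgb_eta=cfg.xgb_eta,
                    xgb_col_fraction=cfg.xgb_col_fraction,
                    xgb_sample_fraction=cfg.xgb_sample_fraction)
    return cols


# --- hyperparameter-budget analysis ---------------------------------------

def subsample_analysis(table: pd.DataFrame, sample_sizes, n_repeats: int,
                       seed: int, metric: str, k_top: int = 10,
                       rank_by: str = "val_loss") -> pd.DataFrame:
    """Performance attainable with a random hyperparameter budget.

    For each budget k, draw k configurations uniformly without
    replacement, rank them by mean validation loss, and record the mean
    test metric of the top `k_top` (all of them when k < k_top).  Returns
    mean and standard deviation over repeats per budget.
    """
    ok = table[~table["failed"]]
    per_config = ok.groupby("config_id").agg(
        rank_value=(rank_by, "mean"), metric=(metric, "mean"))
    n = len(per_config)
    rng = np.random.default_rng(seed)
    rows = []
    for k in sample_sizes:
        if k > n:
            raise ValueError(f"budget {k} exceeds table size {n}")
        values = []
        for _ in range(n_repeats):
            pick = per_config.iloc[rng.choice(n, size=k, replace=False)]
            top = pick.nsmallest(min(k_top, k), "rank_value")
            values.append(top["metric"].mean())
        rows.append({"budget": k, "mean": float(np.mean(values)),
                     "sd": float(np.std(values, ddof=0)),
                     "n_repeats": n_repeats})
    return pd.DataFrame(rows)
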