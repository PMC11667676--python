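"""Performance metrics and statistical model comparison.

Classification is summarized by balanced accuracy,
``BA = (TP/nP + TN/nN) / 2``, the mean of sensitivity and specificity —
0.5 for any degenerate one-class predictor regardless of imbalance.
Regression is summarized by the concordance index: the fraction of
molecule pairs with distinct true potency whose predicted ordering matches
the true ordering (prediction ties credit 1/2).  Model comparison follows
a paired design across datasets: a Friedman omnibus test, then all
pairwise two-sided Wilcoxon signed-rank tests with Holm–Bonferroni
step-down correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MetricReport", "balanced_accuracy", "concordance_index",
    "classification_suite", "regression_suite", "compare_models",
    "ComparisonReport", "holm_bonferroni", "top_k_hyperparameter_frequency",
]


@dataclass(frozen=True)
class MetricReport:
    """Per-model metric values for one evaluation set."""

    task: str
    balanced_accuracy: float | None = None
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    concordance_index: float | None = None
    rmse: float | None = None
    r2: float | None = None
    tp: int | None = None
    tn: int | None = None
    n_pos: int | None = None
    n_neg: int | None = None
    precision_defined: bool = True

    def __post_init__(self):
        for name in ("balanced_accuracy", "accuracy", "precision", "recall",
                     "f1", "concordance_index"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0 + 1e-12:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.tp is not None and self.tp > self.n_pos:
            raise ValueError("TP exceeds nP")
        if self.tn is not None and self.tn > self.n_neg:
            raise ValueError("TN exceeds nN")

    def to_dict(self) -> dict[str, float]:
        keys = (("balanced_accuracy", "accuracy", "precision", "recall", "f1")
                if self.task == "classification"
                else ("concordance_index", "rmse", "r2"))
        return {k: float(getattr(self, k)) for k in keys}


def balanced_accuracy(tp: int, tn: int, n_pos: int, n_neg: int) -> float:
    """Mean of sensitivity TP/nP and specificity TN/nN."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both classes must be represented "
                         f"(nP={n_pos}, nN={n_neg})")
    if not (0 <= tp <= n_pos and 0 <= tn <= n_neg):
        raise ValueError("counts inconsistent")
    return 0.5 * (tp / n_pos + tn / n_neg)


def concordance_index(y_true, y_pred) -> float:
    """Fraction of correctly ordered pairs among pairs with distinct truth.

    Prediction ties earn 1/2; pairs tied in the true values are excluded.
    Invariant under strictly monotone transforms of the predictions.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("inputs must be matched 1-D vectors")
    if len(y_true) < 2:
        raise ValueError("need at least two observations")
    dt = y_true[:, None] - y_true[None, :]
    dp = y_pred[:, None] - y_pred[None, :]
    iu = np.triu_indices(len(y_true), k=1)
    dt, dp = dt[iu], dp[iu]
    comparable = dt != 0
    if not comparable.any():
        raise ValueError("all true values are tied; no comparable pairs")
    dt, dp = dt[comparable], dp[comparable]
    credit = np.where(dp == 0, 0.5, (np.sign(dp) == np.sign(dt)).astype(float))
    return float(credit.mean())


def classification_suite(labels, probabilities,
                         threshold: float = 0.5) -> MetricReport:
    """Standard classification metrics at a fixed decision threshold."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape or len(y) == 0:
        raise ValueError("inputs must be matched nonempty vectors")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    precision_defined = (tp + fp) > 0
    if not precision_defined:
        logger.warning("no positive predictions; precision reported as 0")
    precision = tp / (tp + fp) if precision_defined else 0.0
    recall = tp / n_pos if n_pos else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return MetricReport(
        task="classification",
        balanced_accuracy=balanced_accuracy(tp, tn, n_pos, n_neg),
        accuracy=(tp + tn) / len(y),
        precision=precision, recall=recall, f1=f1,
        tp=tp, tn=tn, n_pos=n_pos, n_neg=n_neg,
        precision_defined=precision_defined)


def regression_suite(y_true, y_pred) -> MetricReport:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or len(y_true) == 0:
        raise ValueError("inputs must be matched nonempty vectors")
    resid = y_true - y_pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return MetricReport(task="regression",
                        concordance_index=concordance_index(y_true, y_pred),
                        rmse=rmse, r2=r2)


# --- statistical comparison ----------------------------------------------

def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, >= raw)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


@dataclass
class ComparisonReport:
    friedman_statistic: float
    friedman_p: float
    pairwise: pd.DataFrame      # model_a, model_b, statistic, p_raw, p_holm
    alpha: float = 0.05

    def significant_pairs(self) -> pd.DataFrame:
        return self.pairwise[self.pairwise["p_holm"] < self.alpha]


def compare_models(metric_matrix: pd.DataFrame, alpha: float = 0.05,
                   alternative: str = "two-sided") -> ComparisonReport:
    """Paired comparison of models across datasets.

    `metric_matrix`: rows = datasets, columns = models, cells = the pooled
    metric (balanced accuracy or concordance index).  Runs the Friedman
    omnibus test, then all pairwise Wilcoxon signed-rank tests with Holm
    correction.  The Wilcoxon test uses the exact null distribution for
    n <= 12 without ties and drops zero differences.
    """
    if metric_matrix.isna().any().any():
        gaps = [(str(r), str(c)) for r, c in
                zip(*np.where(metric_matrix.isna()))]
        raise ValueError(f"unpaired design; missing cells at {gaps}")
    if metric_matrix.shape[1] < 2 or metric_matrix.shape[0] < 3:
        raise ValueError("need >= 2 models and >= 3 datasets")
    columns = [metric_matrix[c].to_numpy(dtype=float)
               for c in metric_matrix.columns]
    if all(np.allclose(col, columns[0]) for col in columns[1:]):
        stat, p = 0.0, 1.0          # identical models: nothing to rank
    else:
        stat, p = stats.friedmanchisquare(*columns)
        if not np.isfinite(stat):   # zero rank variance
            stat, p = 0.0, 1.0
    rows = []
    for a, b in itertools.combinations(metric_matrix.columns, 2):
        diff = metric_matrix[a].to_numpy() - metric_matrix[b].to_numpy()
        nonzero = diff[diff != 0]
        if len(nonzero) == 0:
            rows.append({"model_a": a, "model_b": b, "statistic": 0.0,
                         "p_raw": 1.0})
            continue
        method = ("exact" if len(nonzero) <= 12
                  and len(np.unique(np.abs(nonzero))) == len(nonzero)
                  else "approx")
        res = stats.wilcoxon(nonzero, alternative=alternative,
                             method=method, correction=(method == "approx"))
        rows.append({"model_a": a, "model_b": b,
                     "statistic": float(res.statistic),
                     "p_raw": float(res.pvalue)})
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = holm_bonferroni(pairwise["p_raw"].to_numpy())
    return ComparisonReport(float(stat), float(p), pairwise, alpha)


def top_k_hyperparameter_frequency(table: pd.DataFrame, keys,
                                   k: int = 10,
                                   rank_by: str = "val_loss",
                                   ascending: bool = True,
                                   dataset_column: str | None = None
                                   ) -> pd.DataFrame:
    """Value frequencies of each hyperparameter among the top-k configs.

    Configurations are ranked by the mean of `rank_by` per configuration
    (ascending for losses — the default — or descending for metrics such
    as test balanced accuracy); the top k are inspected.  Returns one row
    per (dataset, key, value) with its frequency, and marks the modal
    value.
    """
    for key in keys:
        if key not in table.columns:
            raise KeyError(f"unknown hyperparameter key {key!r}")
    groups = ([(None, table)] if dataset_column is None
              else list(table.groupby(dataset_column)))
    rows = []
    for dataset, sub in groups:
        ok = sub[~sub["failed"]] if "failed" in sub.columns else sub
        per_config = ok.groupby("config_id").agg(
            rank_value=(rank_by, "mean"),
            **{key: (key, "first") for key in keys})
        if len(per_config) < k:
            raise ValueError(f"table has {len(per_config)} configurations; "
                             f"top-{k} requested")
        top = (per_config.nsmallest(k, "rank_value") if ascending
               else per_config.nlargest(k, "rank_value"))
        for key in keys:
            counts = top[key].value_counts()
            modal = counts.idxmax()
            for value, count in counts.items():
                rows.append({"dataset": dataset, "hyperparameter": key,
                             "value": value, "frequency": count / k,
                             "is_modal": value == modal})
    return pd.DataFrame(rows)
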