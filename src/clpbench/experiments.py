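"""Config-driven orchestration of the full benchmark.

A benchmark run walks the factorial design — datasets x architectures x
string notations x token encodings — and, per cell, grid-searches
hyperparameters with Monte Carlo validation, selects the best
configuration by mean validation loss, and reports test metrics.  All
seeds derive from one master seed; a manifest records everything needed
for an exact rerun.

Classification splits use a scaled version of the study design: training
molecules are drawn at random per class, while validation and test
molecules must be dissimilar (edit distance > 10, Tanimoto < 0.60) to the
partitions before them; the scaled fractions (35% of each class for
training, 8% each for validation and test) leave the slack the
dissimilarity filter needs.  Regression uses the grouped 70/15/15 split.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemlang
from .chemlang import build_vocabulary, filter_by_length, pad, tokenize
from .evaluation import compare_models
from .models import (HyperparameterGrid, ModelConfig, reduced_grid,
                     table2_grid)
from .splits import (DataSplit, SplitCriteria, classification_split,
                     grouped_regression_split, monte_carlo_folds)
from .synthetic_data import SyntheticConfig, generate, records_to_frame
from .training import TrainingConfig, grid_search

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "TaskData", "prepare_task_data",
           "split_dataset", "run_benchmark"]

NOTATIONS = ("SMILES", "SELFIES")
ENCODINGS = ("one_hot", "random", "learnable")


@dataclass
class TaskData:
    """A notation-specific view of one dataset, ready for training."""

    smiles: list[str]
    y: np.ndarray
    X: np.ndarray
    vocab: chemlang.Vocabulary
    notation: str


@dataclass
class ExperimentConfig:
    datasets: list[SyntheticConfig] = field(default_factory=lambda: [
        SyntheticConfig(task="classification", n_molecules=1100, seed=0)])
    data_files: list[str] = field(default_factory=list)
    notations: tuple[str, ...] = ("SMILES",)
    encodings: tuple[str, ...] = ("learnable",)
    architectures: tuple[str, ...] = ("CNN", "RNN", "Transformer", "XGBoost")
    grid_scale: str = "reduced"            # "full" | "reduced"
    n_folds: int = 2
    max_epochs: int = 30
    reweight_loss: bool = True
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self):
        if not (self.datasets or self.data_files):
            raise ValueError("no data source configured")
        for n in self.notations:
            if n not in NOTATIONS:
                raise ValueError(f"unknown notation {n!r}")
        for e in self.encodings:
            if e not in ENCODINGS:
                raise ValueError(f"unknown encoding {e!r}")
        if self.grid_scale not in ("full", "reduced"):
            raise ValueError("grid_scale must be 'full' or 'reduced'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        datasets = [SyntheticConfig(**d) for d in raw.pop("datasets", [])]
        for key in ("notations", "encodings", "architectures"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(datasets=datasets, **raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    def grid(self) -> HyperparameterGrid:
        return table2_grid() if self.grid_scale == "full" else reduced_grid()


def prepare_task_data(records, notation: str,
                      max_tokens: int = chemlang.MAX_TOKENS_DEFAULT
                      ) -> tuple[TaskData, list]:
    """Length-filter, tokenize, build the vocabulary, and pad.

    Returns the TaskData and the retained records (in order).
    """
    retained = filter_by_length(records, max_tokens)
    sequences = [tokenize(r.smiles, notation) for r in retained]
    vocab = build_vocabulary(sequences)
    X = pad(sequences, vocab)
    y = np.array([float(r.value) for r in retained])
    return TaskData([r.smiles for r in retained], y, X, vocab, notation), \
        retained


def split_dataset(records, task: str, seed: int,
                  criteria: SplitCriteria | None = None) -> DataSplit:
    """Task-appropriate split of a record list."""
    if task == "classification":
        labels = np.array([int(r.value) for r in records])
        n_act, n_inact = int(labels.sum()), int((labels == 0).sum())
        sizes = ((round(0.35 * n_act), round(0.35 * n_inact)),
                 (round(0.08 * n_act), round(0.08 * n_inact)),
                 (round(0.08 * n_act), round(0.08 * n_inact)))
        return classification_split(records, sizes=sizes,
                                    criteria=criteria, seed=seed)
    return grouped_regression_split(records, seed=seed, criteria=criteria)


def run_benchmark(config: ExperimentConfig) -> Path:
    """Execute the factorial benchmark; returns the output directory."""
    t_start = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master_seed = np.random.SeedSequence(config.seed)
    seeds = master_seed.generate_state(4 + len(config.datasets))

    all_rows: list[pd.DataFrame] = []
    best_by_cell: list[dict] = []
    failures: list[dict] = []
    for di, ds_cfg in enumerate(config.datasets):
        ds_name = f"{ds_cfg.task}-{di}"
        ds_seed = int(seeds[4 + di] % 2**31)
        records = generate(dataclasses.replace(ds_cfg, seed=ds_seed))
        records_to_frame(records).to_csv(out_dir / f"data-{ds_name}.csv",
                                         index=False)
        task = ds_cfg.task
        # one split per dataset, shared across cells
        data_smiles, _ = prepare_task_data(records, "SMILES")
        retained = filter_by_length(records)
        split = split_dataset(retained, task, seed=ds_seed)
        split.to_json(out_dir / f"split-{ds_name}.json")
        folds = monte_carlo_folds(split.train, k=config.n_folds,
                                  val_fraction=0.2, seed=ds_seed)
        training = TrainingConfig(max_epochs=config.max_epochs,
                                  reweight_loss=config.reweight_loss,
                                  seed=ds_seed)
        grid = config.grid()
        for arch in config.architectures:
            cells = ([("none", "fingerprint")] if arch == "XGBoost" else
                     [(n, e) for n in config.notations
                      for e in config.encodings])
            for notation, enc in cells:
                cell_name = f"{ds_name}/{arch}/{notation}/{enc}"
                try:
                    if arch == "XGBoost":
                        data = data_smiles
                        configs = grid.configs(arch, task, seed=ds_seed)
                    else:
                        data, _ = prepare_task_data(records, notation)
                        configs = grid.configs(arch, task,
                                               encoding_strategy=enc,
                                               seed=ds_seed)
                    table = grid_search(configs, data, folds, training,
                                        test_indices=split.test)
                    table.insert(0, "dataset", ds_name)
                    table.insert(1, "notation", notation)
                    all_rows.append(table)
                    ok = table[~table["failed"]]
                    if not len(ok):
                        raise RuntimeError("all runs failed in this cell")
                    best_id = table.attrs["best_config_id"]
                    best_rows = ok[ok["config_id"] == best_id]
                    metric = ("test_balanced_accuracy"
                              if task == "classification"
                              else "test_concordance_index")
                    best_by_cell.append({
                        "dataset": ds_name, "architecture": arch,
                        "notation": notation, "encoding": enc,
                        "best_label": best_rows["label"].iloc[0],
                        "mean_val_loss": float(best_rows["val_loss"].mean()),
                        metric: float(best_rows[metric].mean()),
                    })
                    logger.info("cell %s done (best %s)", cell_name,
                                best_rows["label"].iloc[0])
                except Exception as exc:   # isolate per-cell failures
                    logger.exception("cell %s failed", cell_name)
                    failures.append({"cell": cell_name, "error": str(exc)})

    master = pd.concat(all_rows, ignore_index=True) if all_rows else \
        pd.DataFrame()
    master.to_csv(out_dir / "master.csv", index=False)
    best_df = pd.DataFrame(best_by_cell)
    best_df.to_csv(out_dir / "best_by_cell.csv", index=False)

    comparison = None
    if len(config.datasets) >= 3 and len(config.architectures) >= 2:
        for task in {d.task for d in config.datasets}:
            metric = ("test_balanced_accuracy" if task == "classification"
                      else "test_concordance_index")
            sub = best_df[best_df["dataset"].str.startswith(task)]
            if sub.empty or metric not in sub.columns:
                continue
            matrix = sub.pivot_table(index="dataset", columns="architecture",
                                     values=metric)
            if matrix.shape[0] >= 3 and matrix.notna().all().all():
                report = compare_models(matrix)
                comparison = {
                    "task": task,
                    "friedman_statistic": report.friedman_statistic,
                    "friedman_p": report.friedman_p,
                    "pairwise": report.pairwise.to_dict(orient="records"),
                }
                (out_dir / f"comparison-{task}.json").write_text(
                    json.dumps(comparison, indent=2))

    config_text = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(config_text.encode()).hexdigest(),
        "seed": config.seed,
        "n_cells": len(best_by_cell),
        "failures": failures,
        "elapsed_seconds": round(time.time() - t_start, 1),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    logger.info("benchmark complete: %d cells, %d failures, %.1fs",
                len(best_by_cell), len(failures),
                manifest["elapsed_seconds"])
    return out_dir
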