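"""Data partitioning: dissimilarity-filtered classification splits, grouped
regression splits, Monte Carlo validation folds, and the underlying
string/fingerprint distances.

Classification test (and validation) molecules must be *distant* from the
reference partitions under two strict criteria: canonical-SMILES
Levenshtein edit distance greater than 10 to every reference molecule, and
Tanimoto similarity on extended-connectivity (Morgan radius-2, 1024-bit)
fingerprints below 0.60 against every reference molecule.  Regression
splits keep whole analog groups (single-linkage clusters at Tanimoto >=
0.6) inside one partition and allocate groups greedily, largest first, to
70/15/15 fractions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

__all__ = [
    "SplitCriteria", "DataSplit", "InfeasibleSplitError",
    "levenshtein", "tanimoto", "morgan_fingerprints", "tanimoto_matrix",
    "select_dissimilar", "classification_split", "grouped_regression_split",
    "monte_carlo_folds",
]


class InfeasibleSplitError(RuntimeError):
    """Requested partition sizes cannot be met under the criteria."""


@dataclass(frozen=True)
class SplitCriteria:
    """Strict dissimilarity thresholds and fingerprint parameters."""

    min_edit_distance: int = 10      # strict: selected iff distance > this
    max_tanimoto: float = 0.60       # strict: selected iff similarity < this
    fingerprint_radius: int = 2
    fingerprint_bits: int = 1024

    def __post_init__(self):
        if self.min_edit_distance < 0:
            raise ValueError("min_edit_distance must be >= 0")
        if not 0.0 < self.max_tanimoto <= 1.0:
            raise ValueError("max_tanimoto must lie in (0, 1]")


@dataclass
class DataSplit:
    """Disjoint index partitions plus a recomputable dissimilarity audit."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    audit: dict = field(default_factory=dict)
    criteria: SplitCriteria | None = None
    seed: int | None = None

    def __post_init__(self):
        sets = [set(map(int, self.train)), set(map(int, self.validation)),
                set(map(int, self.test))]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("partitions are not disjoint")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "train": [int(i) for i in self.train],
            "validation": [int(i) for i in self.validation],
            "test": [int(i) for i in self.test],
            "audit": {k: (list(map(float, v)) if hasattr(v, "__len__") else v)
                      for k, v in self.audit.items()},
            "criteria": (None if self.criteria is None
                         else vars(self.criteria).copy()),
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "DataSplit":
        payload = json.loads(text)
        crit = payload.get("criteria")
        return cls(np.asarray(payload["train"], dtype=int),
                   np.asarray(payload["validation"], dtype=int),
                   np.asarray(payload["test"], dtype=int),
                   audit=payload.get("audit", {}),
                   criteria=SplitCriteria(**crit) if crit else None,
                   seed=payload.get("seed"))


# --- distances ------------------------------------------------------------

def levenshtein(a: str, b: str) -> int:
    """Insert/delete/substitute edit distance between two strings."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Intersection-over-union of two equal-length binary fingerprints."""
    fp_a = np.asarray(fp_a, dtype=bool)
    fp_b = np.asarray(fp_b, dtype=bool)
    if fp_a.shape != fp_b.shape:
        raise ValueError("fingerprints must have equal bit length")
    union = np.logical_or(fp_a, fp_b).sum()
    if union == 0:
        logger.warning("tanimoto of two empty fingerprints defined as 0")
        return 0.0
    return float(np.logical_and(fp_a, fp_b).sum() / union)


def morgan_fingerprints(smiles: list[str],
                        criteria: SplitCriteria | None = None) -> np.ndarray:
    """Extended-connectivity fingerprints as a (n, bits) boolean matrix."""
    criteria = criteria or SplitCriteria()
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=criteria.fingerprint_radius, fpSize=criteria.fingerprint_bits)
    out = np.zeros((len(smiles), criteria.fingerprint_bits), dtype=bool)
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES at index {i}: {smi!r}")
        out[i, list(gen.GetFingerprint(mol).GetOnBits())] = True
    return out


def tanimoto_matrix(fps_a: np.ndarray, fps_b: np.ndarray) -> np.ndarray:
    """All-pairs Tanimoto similarity between two fingerprint matrices."""
    a = np.asarray(fps_a, dtype=np.float64)
    b = np.asarray(fps_b, dtype=np.float64)
    inter = a @ b.T
    union = a.sum(1)[:, None] + b.sum(1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-12), 0.0)
    return sim


# --- dissimilar selection -------------------------------------------------

def _eligibility(pool_smiles: list[str], pool_fps: np.ndarray,
                 ref_smiles: list[str], ref_fps: np.ndarray,
                 criteria: SplitCriteria) -> np.ndarray:
    """Boolean mask over the pool: distant from *every* reference molecule."""
    sims = tanimoto_matrix(pool_fps, ref_fps)
    mask = sims.max(axis=1) < criteria.max_tanimoto
    # edit distance only where the cheap fingerprint screen passed,
    # short-circuiting on the first near neighbour
    for i in np.flatnonzero(mask):
        for ref in ref_smiles:
            if levenshtein(pool_smiles[i], ref) <= criteria.min_edit_distance:
                mask[i] = False
                break
    return mask


def _audit_versus(smiles: list[str], fps: np.ndarray,
                  ref_smiles: list[str], ref_fps: np.ndarray):
    """Exact nearest-reference edit distance and max Tanimoto per molecule."""
    max_tani = tanimoto_matrix(fps, ref_fps).max(axis=1)
    min_edit = np.array([min(levenshtein(s, r) for r in ref_smiles)
                         for s in smiles])
    return min_edit, max_tani


def select_dissimilar(pool, reference, criteria: SplitCriteria,
                      n_active: int, n_inactive: int,
                      seed: int) -> list[int]:
    """Pick class-stratified pool indices distant from all reference records.

    `pool` and `reference` are sequences of records with `.smiles` and
    binary `.value`.  Returns positions into `pool`.
    """
    rng = np.random.default_rng(seed)
    pool_smiles = [r.smiles for r in pool]
    ref_smiles = [r.smiles for r in reference]
    pool_fps = morgan_fingerprints(pool_smiles, criteria)
    ref_fps = morgan_fingerprints(ref_smiles, criteria)
    eligible = _eligibility(pool_smiles, pool_fps, ref_smiles, ref_fps,
                            criteria)
    labels = np.array([int(r.value) for r in pool])
    chosen: list[int] = []
    for label, want in ((1, n_active), (0, n_inactive)):
        cand = np.flatnonzero(eligible & (labels == label))
        if len(cand) < want:
            raise InfeasibleSplitError(
                f"need {want} eligible molecules of class {label} but only "
                f"{len(cand)} of {int((labels == label).sum())} satisfy "
                f"edit distance > {criteria.min_edit_distance} and "
                f"Tanimoto < {criteria.max_tanimoto}")
        chosen.extend(int(i) for i in rng.choice(cand, size=want,
                                                 replace=False))
    return chosen


def classification_split(records, sizes=((350, 3500), (75, 750), (75, 750)),
                         criteria: SplitCriteria | None = None,
                         seed: int = 0) -> DataSplit:
    """Random train; validation distant from train; test distant from both.

    `sizes` gives (actives, inactives) per partition in train/val/test
    order.  The audit stores, for every validation and test molecule, the
    exact nearest-train edit distance and maximum train Tanimoto.
    """
    criteria = criteria or SplitCriteria()
    rng = np.random.default_rng(seed)
    labels = np.array([int(r.value) for r in records])
    (tr_a, tr_i), (va_a, va_i), (te_a, te_i) = sizes

    train_idx: list[int] = []
    for label, want in ((1, tr_a), (0, tr_i)):
        cand = np.flatnonzero(labels == label)
        if len(cand) < want:
            raise InfeasibleSplitError(
                f"dataset has only {len(cand)} molecules of class {label}; "
                f"{want} requested for training")
        train_idx.extend(int(i) for i in rng.choice(cand, size=want,
                                                    replace=False))
    train_set = set(train_idx)
    rest = [i for i in range(len(records)) if i not in train_set]

    pool = [records[i] for i in rest]
    val_pos = select_dissimilar(pool, [records[i] for i in train_idx],
                                criteria, va_a, va_i,
                                seed=int(rng.integers(2**31)))
    val_idx = [rest[p] for p in val_pos]
    val_set = set(val_idx)
    rest2 = [i for i in rest if i not in val_set]
    reference = [records[i] for i in train_idx + val_idx]
    test_pos = select_dissimilar([records[i] for i in rest2], reference,
                                 criteria, te_a, te_i,
                                 seed=int(rng.integers(2**31)))
    test_idx = [rest2[p] for p in test_pos]

    train_smiles = [records[i].smiles for i in train_idx]
    train_fps = morgan_fingerprints(train_smiles, criteria)
    audit = {}
    for name, idx in (("validation", val_idx), ("test", test_idx)):
        smi = [records[i].smiles for i in idx]
        fps = morgan_fingerprints(smi, criteria)
        min_edit, max_tani = _audit_versus(smi, fps, train_smiles, train_fps)
        audit[f"{name}_min_train_edit_distance"] = min_edit
        audit[f"{name}_max_train_tanimoto"] = max_tani
    logger.info("classification split: train=%d val=%d test=%d",
                len(train_idx), len(val_idx), len(test_idx))
    return DataSplit(np.asarray(train_idx), np.asarray(val_idx),
                     np.asarray(test_idx), audit=audit, criteria=criteria,
                     seed=seed)


# --- grouped regression split ---------------------------------------------

def analog_groups(smiles: list[str], criteria: SplitCriteria | None = None,
                  threshold: float = 0.6) -> np.ndarray:
    """Single-linkage clusters at Tanimoto >= threshold (group labels)."""
    criteria = criteria or SplitCriteria()
    fps = morgan_fingerprints(smiles, criteria)
    sims = tanimoto_matrix(fps, fps)
    adj = csr_matrix(sims >= threshold)
    _, labels = connected_components(adj, directed=False)
    return labels


def grouped_regression_split(records, fractions=(0.70, 0.15, 0.15),
                             seed: int = 0,
                             criteria: SplitCriteria | None = None,
                             threshold: float = 0.6) -> DataSplit:
    """Allocate whole analog groups to train/val/test, largest first.

    Each group goes to the partition with the largest remaining deficit
    relative to its target fraction, so fractions are met to within one
    group's size.
    """
    if len(records) < 20:
        raise ValueError("grouped split needs at least 20 molecules")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    criteria = criteria or SplitCriteria()
    smiles = [r.smiles for r in records]
    labels = analog_groups(smiles, criteria, threshold)
    n = len(records)
    groups: dict[int, list[int]] = {}
    for i, g in enumerate(labels):
        groups.setdefault(int(g), []).append(i)
    group_list = list(groups.values())
    if max(len(g) for g in group_list) > 0.70 * n:
        raise InfeasibleSplitError(
            f"one analog group covers {max(len(g) for g in group_list)} of "
            f"{n} molecules; lower the clustering threshold "
            f"(currently {threshold})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(group_list))
    group_list = sorted((group_list[i] for i in order), key=len, reverse=True)
    names = ("train", "validation", "test")
    parts: dict[str, list[int]] = {k: [] for k in names}
    for grp in group_list:
        deficits = {k: fractions[j] * n - len(parts[k])
                    for j, k in enumerate(names)}
        parts[max(deficits, key=deficits.get)].extend(grp)

    train_fps = morgan_fingerprints([smiles[i] for i in parts["train"]],
                                    criteria)
    test_fps = morgan_fingerprints([smiles[i] for i in parts["test"]],
                                   criteria)
    audit = {
        "n_groups": len(group_list),
        "largest_group": max(len(g) for g in group_list),
        "test_max_train_tanimoto":
            tanimoto_matrix(test_fps, train_fps).max(axis=1),
    }
    logger.info("grouped regression split: %d groups; train=%d val=%d test=%d",
                len(group_list), *(len(parts[k]) for k in names))
    return DataSplit(*(np.asarray(sorted(parts[k])) for k in names),
                     audit=audit, criteria=criteria, seed=seed)


# --- Monte Carlo validation folds -----------------------------------------

def monte_carlo_folds(train_pool, k: int = 5, val_fraction: float = 0.2,
                      seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """k independent random train/validation resamples of the pool.

    Unlike disjoint k-fold cross-validation, validation sets may overlap
    across folds.  Per-fold seeds derive from the master seed.
    """
    pool = np.asarray(train_pool)
    if len(pool) < 10:
        raise ValueError("pool too small for Monte Carlo validation")
    n_val = round(val_fraction * len(pool))
    if not 0 < n_val < len(pool):
        raise ValueError(f"val_fraction={val_fraction} leaves a degenerate "
                         f"validation set ({n_val} of {len(pool)})")
    folds = []
    for child in np.random.SeedSequence(seed).spawn(k):
        rng = np.random.default_rng(child)
        perm = rng.permutation(len(pool))
        folds.append((pool[perm[n_val:]], pool[perm[:n_val]]))
    return folds
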