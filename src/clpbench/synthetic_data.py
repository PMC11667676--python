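"""Synthetic structure–activity data with recoverable planted signal.

Two dataset families are generated, mirroring the two task designs the
benchmark targets:

* **Classification** ("hit discovery"): structurally diverse molecules
  assembled from a fragment grammar (scaffold + random substituents,
  optionally a second ring system).  A molecule is active iff it carries at
  least one *pharmacophore* fragment; actives are constructed by explicit
  pharmacophore placement and verified by substructure matching, so a
  brute-force match oracle reproduces every label exactly.  Class balance
  is exact: ``round(n_molecules * active_fraction)`` actives.

* **Regression** ("lead optimization"): analog series.  Each series has a
  parent molecule (a larger scaffold plus fixed core substituents, and a
  series-level pharmacophore complement); analogs add one small variable
  group.  The pKi value is linear in the pharmacophore indicator vector
  plus Gaussian noise, so ordinary least squares recovers the planted
  effect sizes.

All randomness flows from a single integer seed through per-stage
``numpy`` generator streams; identical configs give byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

from .chemlang import canonicalize

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentGrammar", "SyntheticConfig", "MoleculeRecord",
    "GrammarError", "GenerationError",
    "default_classification_grammar", "default_regression_grammar",
    "assemble_molecule", "generate_classification_set",
    "generate_regression_set", "generate", "records_to_frame",
    "write_csv", "write_smi",
]


class GrammarError(ValueError):
    """A grammar fragment is not a valid molecular string."""


class GenerationError(RuntimeError):
    """The requested dataset cannot be realized under the grammar."""


# --- grammar --------------------------------------------------------------

_CLS_SCAFFOLDS = (
    "c1ccccc1", "c1ccncc1", "c1cncnc1", "c1ccsc1", "c1ccoc1",
    "c1cc[nH]c1", "c1cnc[nH]1", "c1ccc2ccccc2c1", "c1ccc2ncccc2c1",
    "c1ccc2[nH]ccc2c1", "C1CCNCC1", "C1CCCCC1",
)

_CLS_SUBSTITUENTS = (
    "C", "CC", "CCC", "CCCC", "C(C)C", "C(C)(C)C", "O", "OC", "OCC", "OCCC",
    "OC(C)C", "N", "NC", "NCC", "N(C)C", "Cl", "Br", "F", "C(=O)C",
    "C(=O)OC", "C(=O)O", "C(=O)OCC", "C(=O)NC", "CO", "CCO", "CCN", "CN",
    "C=C", "SC", "N1CCCC1", "N1CCCCC1", "N1CCOCC1", "C1CC1", "c1ccccc1",
    "Cc1ccccc1", "Oc1ccccc1", "CCc1ccccc1", "c1ccncc1", "C1CCCC1",
    "OCC(C)C",
)

# Effect-carrying fragments.  They exercise multi-character and bracket
# tokens (Cl/Br appear in substituents; [N+]/[O-] here) and never occur as
# substructures of the plain substituents above, so substructure matching
# is an exact label oracle.
_PHARMACOPHORES = ("C(F)(F)F", "S(N)(=O)=O", "[N+](=O)[O-]", "C#N")

_REG_SCAFFOLDS = (
    "c1ccc2ccccc2c1", "c1ccc2ncccc2c1", "c1ccc2[nH]ccc2c1",
    "C1Cc2ccccc2C1", "c1ccc(-c2ccccc2)cc1",
)

_REG_CORES = (
    "CC", "OC", "N(C)C", "C(=O)NC", "N1CCOCC1", "Cc1ccccc1", "OCC", "C(C)C",
)

_REG_VARIABLE = ("C", "Cl", "F", "O", "N", "OC", "CC", "Br")


@dataclass(frozen=True)
class FragmentGrammar:
    """Chemically valid building blocks with implicit attachment points.

    Substituents attach through their first atom to any scaffold carbon
    bearing at least one hydrogen; attachments that fail valence
    sanitization are resampled.
    """

    scaffolds: tuple[str, ...] = _CLS_SCAFFOLDS
    substituents: tuple[str, ...] = _CLS_SUBSTITUENTS
    pharmacophores: tuple[str, ...] = _PHARMACOPHORES
    core_substituents: tuple[str, ...] = _REG_CORES
    variable_substituents: tuple[str, ...] = _REG_VARIABLE
    extra_ring_prob: float = 0.35
    max_substituents: int = 4

    def __post_init__(self):
        for name, frags in [("scaffold", self.scaffolds),
                            ("substituent", self.substituents),
                            ("pharmacophore", self.pharmacophores),
                            ("core_substituent", self.core_substituents),
                            ("variable_substituent", self.variable_substituents)]:
            for frag in frags:
                if Chem.MolFromSmiles(frag) is None:
                    raise GrammarError(
                        f"invalid {name} fragment: {frag!r} does not parse")

    def pharmacophore_queries(self) -> list[Chem.Mol]:
        # SMARTS parsing: a SMILES-parsed query can silently fail to match
        # charged groups (e.g. the nitro N+) because of valence bookkeeping
        return [Chem.MolFromSmarts(p) for p in self.pharmacophores]


def default_classification_grammar() -> FragmentGrammar:
    return FragmentGrammar()


def default_regression_grammar() -> FragmentGrammar:
    return FragmentGrammar(scaffolds=_REG_SCAFFOLDS)


# --- config and record ----------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    Defaults reflect the emulated study conditions: classification sets of
    5500 molecules with 10% actives; regression sets organized as analog
    series of ~5 molecules with pKi noise of 0.3 log units.
    """

    task: str                               # "classification" | "regression"
    n_molecules: int = 5500
    active_fraction: float = 0.10
    n_scaffolds: int | None = None          # defaults to full grammar
    pharmacophore_fragments: tuple[str, ...] = _PHARMACOPHORES
    effect_sizes: tuple[float, ...] = (1.5, 1.0, -0.8, 0.5)
    intercept: float = 6.0                  # baseline pKi
    noise_sd: float = 0.3
    label_noise: float = 0.0
    series_size: int = 5                    # regression analogs per series
    pharmacophore_prob: float = 0.25        # per-fragment series inclusion
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.label_noise <= 0.5:
            raise ValueError("label_noise must lie in [0, 0.5]")
        if self.task == "regression" and len(self.effect_sizes) == 0:
            raise ValueError("regression requires non-empty effect_sizes "
                             "(no signal to recover)")
        if self.task == "regression" and \
                len(self.effect_sizes) != len(self.pharmacophore_fragments):
            raise ValueError("effect_sizes must align with "
                             "pharmacophore_fragments")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass(frozen=True)
class MoleculeRecord:
    """One synthetic molecule: canonical SMILES, task value, provenance."""

    smiles: str
    value: float | int | None
    scaffold_id: int
    planted_features: tuple[int, ...]

    def __post_init__(self):
        if canonicalize(self.smiles) != self.smiles:
            raise ValueError(f"smiles not canonical: {self.smiles!r}")


# --- assembly -------------------------------------------------------------

def _attach(mol: Chem.Mol, frag_smiles: str,
            rng: np.random.Generator) -> Chem.Mol | None:
    """Bond a fragment's first atom to a random C-H carbon; None on failure."""
    frag = Chem.MolFromSmiles(frag_smiles)
    if frag is None:
        raise GrammarError(f"invalid fragment: {frag_smiles!r} does not parse")
    candidates = [a.GetIdx() for a in mol.GetAtoms()
                  if a.GetSymbol() == "C" and a.GetTotalNumHs() > 0]
    if not candidates:
        return None
    site = int(rng.choice(candidates))
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
        return out
    except Exception:
        return None


def assemble_molecule(rng: np.random.Generator, grammar: FragmentGrammar,
                      scaffold_id: int,
                      pharmacophores: tuple[int, ...] = ()) -> MoleculeRecord:
    """Assemble one molecule on the given scaffold (value unset).

    Substituent count, sites, and the optional second ring system are drawn
    only from `rng`.  `pharmacophores` indexes grammar fragments to place.
    """
    if not 0 <= scaffold_id < len(grammar.scaffolds):
        raise GrammarError(f"scaffold_id {scaffold_id} outside grammar "
                           f"({len(grammar.scaffolds)} scaffolds)")
    for _ in range(50):
        mol = Chem.MolFromSmiles(grammar.scaffolds[scaffold_id])
        if grammar.extra_ring_prob > 0 and rng.random() < grammar.extra_ring_prob:
            ring = grammar.scaffolds[int(rng.integers(len(grammar.scaffolds)))]
            attached = _attach(mol, ring, rng)
            if attached is not None:
                mol = attached
        if grammar.substituents:
            for _ in range(int(rng.integers(1, grammar.max_substituents + 1))):
                sub = grammar.substituents[
                    int(rng.integers(len(grammar.substituents)))]
                attached = _attach(mol, sub, rng)
                if attached is not None:
                    mol = attached
        ok = True
        for pi in pharmacophores:
            attached = _attach(mol, grammar.pharmacophores[pi], rng)
            if attached is None:
                ok = False
                break
            mol = attached
        if ok:
            smiles = Chem.MolToSmiles(mol)
            return MoleculeRecord(smiles, None, scaffold_id,
                                  _match_features(smiles, grammar))
    raise GenerationError(
        f"could not place fragments on scaffold {scaffold_id}")


def _match_features(smiles: str, grammar: FragmentGrammar) -> tuple[int, ...]:
    mol = Chem.MolFromSmiles(smiles)
    return tuple(int(mol.HasSubstructMatch(q))
                 for q in grammar.pharmacophore_queries())


# --- dataset generation ---------------------------------------------------

def generate_classification_set(
        config: SyntheticConfig,
        grammar: FragmentGrammar | None = None) -> list[MoleculeRecord]:
    """Generate a classification dataset with an exact active count.

    Actives carry >= 1 pharmacophore fragment (verified by substructure
    match); inactives match none.  With ``label_noise`` > 0 each label is
    independently flipped with that probability after construction.
    """
    if config.task != "classification":
        raise ValueError("config.task must be 'classification'")
    grammar = grammar or default_classification_grammar()
    streams = np.random.SeedSequence(config.seed).spawn(3)
    rng_mol = np.random.default_rng(streams[0])
    rng_noise = np.random.default_rng(streams[1])
    n_scaf = min(config.n_scaffolds or len(grammar.scaffolds),
                 len(grammar.scaffolds))
    n_active = round(config.n_molecules * config.active_fraction)
    n_inactive = config.n_molecules - n_active

    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    rejected = {"duplicate": 0, "mismatch": 0}
    for target_count, want_active in ((n_active, True), (n_inactive, False)):
        made = 0
        attempts = 0
        limit = 200 * max(target_count, 1)
        while made < target_count:
            attempts += 1
            if attempts > limit:
                raise GenerationError(
                    f"active_fraction={config.active_fraction} infeasible "
                    f"under grammar: produced {made}/{target_count} "
                    f"{'actives' if want_active else 'inactives'} after "
                    f"{attempts} attempts (rejections: {rejected})")
            scaffold_id = int(rng_mol.integers(n_scaf))
            if want_active:
                k = int(rng_mol.integers(1, min(3, len(grammar.pharmacophores)) + 1))
                pidx = tuple(int(i) for i in rng_mol.choice(
                    len(grammar.pharmacophores), size=k, replace=False))
            else:
                pidx = ()
            rec = assemble_molecule(rng_mol, grammar, scaffold_id, pidx)
            has_pharm = any(rec.planted_features)
            if has_pharm != want_active:
                rejected["mismatch"] += 1
                continue
            if rec.smiles in seen:
                rejected["duplicate"] += 1
                continue
            seen.add(rec.smiles)
            records.append(dataclasses.replace(rec, value=int(want_active)))
            made += 1
    if config.label_noise > 0:
        flips = rng_noise.random(len(records)) < config.label_noise
        records = [dataclasses.replace(r, value=int(r.value) ^ int(f))
                   for r, f in zip(records, flips)]
    order = rng_noise.permutation(len(records))
    records = [records[i] for i in order]
    logger.info("generated classification set: n=%d actives=%d (%s)",
                len(records), sum(any(r.planted_features) for r in records),
                rejected)
    return records


def generate_regression_set(
        config: SyntheticConfig,
        grammar: FragmentGrammar | None = None) -> list[MoleculeRecord]:
    """Generate analog series with a linear planted pKi signal.

    ``value = intercept + effect_sizes . planted_features + N(0, noise_sd)``
    where the indicator vector is shared within a series (the pharmacophore
    complement is a property of the series parent).
    """
    if config.task != "regression":
        raise ValueError("config.task must be 'regression'")
    grammar = grammar or default_regression_grammar()
    streams = np.random.SeedSequence(config.seed).spawn(3)
    rng_mol = np.random.default_rng(streams[0])
    rng_noise = np.random.default_rng(streams[1])
    n_scaf = min(config.n_scaffolds or len(grammar.scaffolds),
                 len(grammar.scaffolds))
    effects = np.asarray(config.effect_sizes, dtype=float)

    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    series_id = 0
    guard = 0
    while len(records) < config.n_molecules:
        guard += 1
        if guard > 50 * config.n_molecules:
            raise GenerationError(
                f"could not assemble {config.n_molecules} analogs "
                f"(got {len(records)}); grammar too narrow")
        base = grammar.scaffolds[int(rng_mol.integers(n_scaf))]
        parent = None
        for _ in range(50):
            mol = Chem.MolFromSmiles(base)
            ok = True
            for ci in rng_mol.choice(len(grammar.core_substituents), size=3,
                                     replace=False):
                attached = _attach(mol, grammar.core_substituents[int(ci)],
                                   rng_mol)
                if attached is None:
                    ok = False
                    break
                mol = attached
            if ok:
                parent = mol
                break
        if parent is None:
            continue
        for pi, frag in enumerate(grammar.pharmacophores):
            if rng_mol.random() < config.pharmacophore_prob:
                attached = _attach(parent, frag, rng_mol)
                if attached is not None:
                    parent = attached
        made, tries = 0, 0
        remaining = config.n_molecules - len(records)
        target = min(config.series_size, remaining)
        while made < target and tries < 60:
            tries += 1
            var = grammar.variable_substituents[
                int(rng_mol.integers(len(grammar.variable_substituents)))]
            mol = _attach(parent, var, rng_mol)
            if mol is None:
                continue
            smiles = Chem.MolToSmiles(mol)
            if smiles in seen:
                continue
            seen.add(smiles)
            features = _match_features(smiles, grammar)
            value = (config.intercept
                     + float(effects @ np.asarray(features))
                     + (rng_noise.normal(0.0, config.noise_sd)
                        if config.noise_sd > 0 else 0.0))
            records.append(MoleculeRecord(smiles, value, series_id, features))
            made += 1
        if made:
            series_id += 1
    logger.info("generated regression set: n=%d series=%d",
                len(records), series_id)
    return records


def generate(config: SyntheticConfig,
             grammar: FragmentGrammar | None = None) -> list[MoleculeRecord]:
    """Dispatch on ``config.task``."""
    if config.task == "classification":
        return generate_classification_set(config, grammar)
    return generate_regression_set(config, grammar)


# --- output ---------------------------------------------------------------

def records_to_frame(records: list[MoleculeRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "smiles": [r.smiles for r in records],
        "value": [r.value for r in records],
        "scaffold_id": [r.scaffold_id for r in records],
    })


def write_csv(records: list[MoleculeRecord], path: str | Path,
              config: SyntheticConfig | None = None) -> None:
    """Write `smiles,value,scaffold_id` CSV plus a sidecar config JSON."""
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    if config is not None:
        path.with_suffix(path.suffix + ".config.json").write_text(
            config.to_json())
    logger.info("wrote %d records to %s", len(records), path)


def write_smi(records: list[MoleculeRecord], path: str | Path) -> None:
    """Write a SMI file: one `smiles<TAB>id` per line."""
    lines = [f"{r.smiles}\tmol{i}" for i, r in enumerate(records)]
    Path(path).write_text("\n".join(lines) + "\n")
    logger.info("wrote %d records to %s", len(records), path)
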