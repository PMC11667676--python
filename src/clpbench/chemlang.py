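"""Molecular string handling: canonicalization, SMILES/SELFIES
interconversion, tokenization, length filtering, vocabulary and padding.

The preprocessing contract mirrors common chemical-language-processing
practice: molecules are sanitized, stripped of stereochemistry and
canonicalized; strings longer than 75 SMILES tokens are dropped; sequences
are right-padded to the corpus maximum with a dedicated pad token reserved
at index 0.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

from . import _selfies

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "TokenSequence", "Vocabulary", "CanonicalizationError", "TokenizationError",
    "canonicalize", "smiles_to_selfies", "selfies_to_smiles",
    "tokenize_smiles", "tokenize_selfies", "tokenize",
    "filter_by_length", "build_vocabulary", "pad", "unpad",
    "read_csv", "read_smi", "MAX_TOKENS_DEFAULT", "PAD_TOKEN",
]

MAX_TOKENS_DEFAULT = 75
PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"


class CanonicalizationError(ValueError):
    """Input string does not parse as a molecule."""


class TokenizationError(ValueError):
    """String contains characters outside the token grammar."""


@dataclass(frozen=True)
class TokenSequence:
    """A tokenized molecular string.

    Invariant: concatenating `tokens` reproduces the source notation string.
    """

    tokens: tuple[str, ...]
    notation: str                 # "SMILES" | "SELFIES"
    source_smiles: str

    def __post_init__(self):
        if len(self.tokens) < 1:
            raise ValueError("a token sequence must contain at least one token")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def string(self) -> str:
        return "".join(self.tokens)


def canonicalize(smiles: str) -> str:
    """Sanitize, strip stereochemistry, and return the canonical SMILES.

    Idempotent: applying it to its own output returns the same string.
    """
    if not isinstance(smiles, str) or not smiles:
        raise CanonicalizationError(f"not a molecular string: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CanonicalizationError(f"unparseable molecular string: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def smiles_to_selfies(smiles: str) -> str:
    """Encode a canonical SMILES as a SELFIES string (round-trip safe)."""
    if not smiles:
        raise CanonicalizationError("empty molecular string")
    return _selfies.encode(smiles)


def selfies_to_smiles(selfies: str) -> str:
    """Decode a SELFIES string and re-canonicalize."""
    return canonicalize(_selfies.decode(selfies))


# Greedy token grammar: bracket atoms as single tokens, two-character
# elements (Cl, Br) before single letters, %NN ring closures as one token.
_SMILES_TOKEN_RE = re.compile(
    r"\[[^\]]+\]|Br|Cl|%\d{2}|[BCNOPSFI]|[bcnops]|\d|[=#\-:/\\.()]|\+|\*"
)


def tokenize_smiles(smiles: str) -> TokenSequence:
    """Split a SMILES string into atom/bond/branch/ring tokens."""
    tokens, pos = [], 0
    for m in _SMILES_TOKEN_RE.finditer(smiles):
        if m.start() != pos:
            raise TokenizationError(
                f"character {smiles[pos]!r} at position {pos} is outside the "
                f"SMILES token grammar: {smiles!r}")
        tokens.append(m.group())
        pos = m.end()
    if pos != len(smiles):
        raise TokenizationError(
            f"character {smiles[pos]!r} at position {pos} is outside the "
            f"SMILES token grammar: {smiles!r}")
    return TokenSequence(tuple(tokens), "SMILES", smiles)


def tokenize_selfies(selfies: str) -> TokenSequence:
    """Split a SELFIES string into its bracketed symbols."""
    try:
        symbols = _selfies.split_symbols(selfies)
    except _selfies.SelfiesError as exc:
        raise TokenizationError(str(exc)) from exc
    return TokenSequence(tuple(symbols), "SELFIES",
                         source_smiles=selfies_to_smiles(selfies))


def tokenize(smiles: str, notation: str) -> TokenSequence:
    """Tokenize a canonical SMILES in the requested notation."""
    if notation == "SMILES":
        return tokenize_smiles(smiles)
    if notation == "SELFIES":
        seq = TokenSequence(
            tuple(_selfies.split_symbols(smiles_to_selfies(smiles))),
            "SELFIES", smiles)
        return seq
    raise ValueError(f"unknown notation {notation!r}")


def filter_by_length(records, max_tokens: int = MAX_TOKENS_DEFAULT,
                     tokenizer=tokenize_smiles):
    """Keep records whose SMILES token count is at most `max_tokens`.

    Accepts either plain SMILES strings or objects with a `.smiles`
    attribute.  The boundary is strict: a 75-token string is retained, a
    76-token string is removed.
    """
    retained = []
    removed = 0
    for rec in records:
        smiles = rec if isinstance(rec, str) else rec.smiles
        if len(tokenizer(smiles)) <= max_tokens:
            retained.append(rec)
        else:
            removed += 1
    if removed:
        logger.info("filter_by_length: removed %d of %d records (> %d tokens)",
                    removed, removed + len(retained), max_tokens)
    if not retained:
        logger.warning("filter_by_length: no records retained")
    return retained


@dataclass(frozen=True)
class Vocabulary:
    """Token <-> index bijection with the pad token fixed at index 0."""

    token_to_index: dict[str, int]
    notation: str
    pad_token: str = PAD_TOKEN
    unk_token: str | None = None

    @property
    def pad_index(self) -> int:
        return self.token_to_index[self.pad_token]

    @property
    def index_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_index.items()}

    def __len__(self) -> int:
        return len(self.token_to_index)

    def encode(self, seq: TokenSequence) -> list[int]:
        out = []
        for tok in seq.tokens:
            if tok in self.token_to_index:
                out.append(self.token_to_index[tok])
            elif self.unk_token is not None:
                out.append(self.token_to_index[self.unk_token])
            else:
                raise KeyError(
                    f"token {tok!r} absent from the vocabulary (closed "
                    f"vocabulary built before splitting; enable UNK for "
                    f"external data)")
        return out

    def decode(self, indices) -> list[str]:
        rev = self.index_to_token
        return [rev[int(i)] for i in indices if int(i) != self.pad_index]


def build_vocabulary(corpus: list[TokenSequence],
                     with_unk: bool = False) -> Vocabulary:
    """Build the token->index bijection over a corpus (pad at index 0).

    The vocabulary is fit on the full dataset before splitting so that no
    token encountered at evaluation time is unknown; only the token
    inventory (not labels) is shared across partitions.
    """
    if not corpus:
        raise ValueError("empty corpus")
    notations = {seq.notation for seq in corpus}
    if len(notations) != 1:
        raise ValueError(f"mixed notations in corpus: {sorted(notations)}")
    tokens = sorted({tok for seq in corpus for tok in seq.tokens})
    mapping = {PAD_TOKEN: 0}
    if with_unk:
        mapping[UNK_TOKEN] = 1
    for tok in tokens:
        mapping[tok] = len(mapping)
    return Vocabulary(mapping, notations.pop(),
                      unk_token=UNK_TOKEN if with_unk else None)


def pad(sequences: list[TokenSequence], vocab: Vocabulary,
        max_len: int | None = None) -> np.ndarray:
    """Right-pad encoded sequences to the corpus maximum length.

    Returns an int matrix (n, max_len) filled with the pad index.
    """
    if not sequences:
        raise ValueError("no sequences to pad")
    encoded = [vocab.encode(seq) for seq in sequences]
    width = max(len(e) for e in encoded)
    if max_len is not None:
        if max_len < width:
            raise ValueError(f"max_len={max_len} shorter than longest "
                             f"sequence ({width})")
        width = max_len
    out = np.full((len(encoded), width), vocab.pad_index, dtype=np.int64)
    for i, e in enumerate(encoded):
        out[i, :len(e)] = e
    return out


def unpad(matrix: np.ndarray, vocab: Vocabulary) -> list[list[str]]:
    """Invert :func:`pad`: decode each row and strip pad indices."""
    return [vocab.decode(row) for row in matrix]


# --- file readers ---------------------------------------------------------

def read_csv(path: str | Path, smiles_column: str = "smiles",
             value_column: str = "value") -> pd.DataFrame:
    """Read a molecule table; canonicalize; drop unparseable rows (logged)."""
    df = pd.read_csv(path)
    for col in (smiles_column, value_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not in {path}")
    return _canonicalize_frame(df, smiles_column, path)


def read_smi(path: str | Path) -> pd.DataFrame:
    """Read a SMI file (one SMILES per line, optional identifier)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        rows.append({"smiles": parts[0],
                     "id": parts[1] if len(parts) > 1 else ""})
    return _canonicalize_frame(pd.DataFrame(rows), "smiles", path)


def _canonicalize_frame(df: pd.DataFrame, smiles_column: str,
                        path) -> pd.DataFrame:
    keep, canon = [], []
    for i, smi in enumerate(df[smiles_column]):
        try:
            canon.append(canonicalize(smi))
            keep.append(i)
        except CanonicalizationError:
            logger.warning("dropping unparseable string %r (row %d of %s)",
                           smi, i, path)
    out = df.iloc[keep].copy().reset_index(drop=True)
    out[smiles_column] = canon
    logger.info("read %s: %d records in, %d retained", path, len(df), len(out))
    return out
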