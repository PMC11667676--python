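"""Token-encoding strategies: one-hot, fixed random, and learnable.

All three map token indices to vectors.  One-hot uses V-dimensional binary
basis vectors (mutually orthogonal); random encoding draws a fixed
continuous vector per token that never changes during training; learnable
encoding starts from the same initialization but is updated by gradient
descent.  The pad token's vector is all-zero under every strategy and is
never updated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemlang import Vocabulary
from .nn import Tensor

__all__ = ["EncodingSpec", "make_token_vectors", "EncodingSpecError"]

STRATEGIES = ("one_hot", "random", "learnable")


class EncodingSpecError(ValueError):
    """The encoding specification violates its invariants."""


@dataclass(frozen=True)
class EncodingSpec:
    """Strategy, dimension and seed for token vectorization.

    Invariants: one_hot forces dim = V and is not trainable; random is not
    trainable; learnable is trainable.
    """

    strategy: str
    dim: int | None = None        # one_hot: inferred as V
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise EncodingSpecError(f"unknown strategy {self.strategy!r}")
        if self.strategy != "one_hot" and (self.dim is None or self.dim < 1):
            raise EncodingSpecError(
                f"{self.strategy} encoding requires dim >= 1")

    @property
    def trainable(self) -> bool:
        return self.strategy == "learnable"

    def resolved_dim(self, vocab_size: int) -> int:
        if self.strategy == "one_hot":
            if self.dim is not None and self.dim != vocab_size:
                raise EncodingSpecError(
                    f"one_hot dim must equal the vocabulary size "
                    f"({vocab_size}), got {self.dim}")
            return vocab_size
        return int(self.dim)


def make_token_vectors(vocab: Vocabulary, spec: EncodingSpec) -> Tensor:
    """Build the (V, dim) token-vector table for a vocabulary.

    Continuous strategies initialize i.i.d. Normal(0, 1/dim) from
    ``spec.seed``; the same seed always gives the same table.  The returned
    Tensor has ``requires_grad`` set iff the strategy is learnable; the pad
    row is zero.
    """
    if len(vocab) == 0:
        raise EncodingSpecError("empty vocabulary")
    v = len(vocab)
    dim = spec.resolved_dim(v)
    if spec.strategy == "one_hot":
        table = np.eye(v)
    else:
        rng = np.random.default_rng(spec.seed)
        table = rng.normal(0.0, 1.0 / np.sqrt(dim), size=(v, dim))
    table[vocab.pad_index] = 0.0
    return Tensor(table, requires_grad=spec.trainable)
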