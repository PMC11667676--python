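"""Sequence architectures for bioactivity prediction and the
fingerprint-based gradient-boosting baseline.

Three encoders — a 1-D CNN, a bidirectional GRU, and a Transformer with
learnable positional embeddings — map a padded token-index matrix to a
fixed-width molecular representation; all three terminate in the same
three-layer perceptron head (widths 128/64/1, ReLU, dropout 0.25).  Pad
positions are excluded from pooling in every architecture, so predictions
are invariant to extra padding columns.  The baseline is XGBoost on
extended-connectivity fingerprints.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .chemlang import Vocabulary
from .encoding import EncodingSpec, make_token_vectors
from .nn import (GRU, Adam, LayerNorm, Linear, Module, Tensor, concat,
                 conv1d, dropout, embedding_lookup)
from .splits import SplitCriteria, morgan_fingerprints

__all__ = [
    "ModelConfig", "HyperparameterGrid", "ModelConstructionError",
    "build_model", "SequenceModel", "XGBoostModel", "count_parameters",
    "table2_grid", "reduced_grid", "EMBEDDING_DIMS",
]

ARCHITECTURES = ("CNN", "RNN", "Transformer", "XGBoost")

# Token-embedding dimension candidates searched alongside the architecture
# grids; four values sized to match the RNN hidden-dimension ladder.
EMBEDDING_DIMS = (16, 32, 64, 128)


class ModelConstructionError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """One architecture configuration (only the named architecture's
    fields are read)."""

    architecture: str
    task: str                       # "classification" | "regression"
    encoding: EncodingSpec
    n_layers: int = 1
    dropout: float = 0.25
    learning_rate: float = 1e-3
    cnn_n_filters: int = 32
    cnn_kernel_length: int = 5
    rnn_hidden_dim: int = 32
    transformer_n_heads: int = 2
    transformer_mlp_dim: int = 64
    max_len: int = 128
    xgb_n_trees: int = 2000
    xgb_max_depth: int = 4
    xgb_eta: float = 0.1
    xgb_col_fraction: float = 1.0
    xgb_sample_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ModelConstructionError(
                f"unknown architecture {self.architecture!r}")
        if self.task not in ("classification", "regression"):
            raise ModelConstructionError(f"unknown task {self.task!r}")
        if self.n_layers not in (1, 2, 3):
            raise ModelConstructionError("n_layers must be 1, 2 or 3")

    def short_label(self) -> str:
        bits = [self.architecture, self.encoding.strategy,
                f"L{self.n_layers}", f"lr{self.learning_rate:g}"]
        if self.architecture == "CNN":
            bits += [f"f{self.cnn_n_filters}", f"k{self.cnn_kernel_length}",
                     f"e{self.encoding.dim}"]
        elif self.architecture == "RNN":
            bits += [f"h{self.rnn_hidden_dim}", f"e{self.encoding.dim}"]
        elif self.architecture == "Transformer":
            bits += [f"H{self.transformer_n_heads}",
                     f"m{self.transformer_mlp_dim}", f"e{self.encoding.dim}"]
        else:
            bits = [self.architecture, f"d{self.xgb_max_depth}",
                    f"eta{self.xgb_eta:g}", f"c{self.xgb_col_fraction:g}",
                    f"s{self.xgb_sample_fraction:g}"]
        return "-".join(bits)


# --- hyperparameter grids (the benchmark's search spaces) -----------------

_TABLE2 = {
    "CNN": {
        "n_layers": [1, 2, 3],
        "cnn_n_filters": [32, 64, 128],
        "cnn_kernel_length": [3, 5, 7],
        "learning_rate": [1e-3, 5e-3, 1e-4, 5e-5],
    },
    "RNN": {
        "n_layers": [1, 2, 3],
        "rnn_hidden_dim": [16, 32, 64, 128],
        "learning_rate": [1e-2, 1e-3, 5e-3, 1e-4, 5e-5],
    },
    "Transformer": {
        "n_layers": [1, 2, 3],
        "transformer_n_heads": [1, 2, 4],
        "transformer_mlp_dim": [32, 64, 128],
        "learning_rate": [1e-3, 5e-3, 1e-4, 5e-5],
    },
    "XGBoost": {
        "xgb_max_depth": [3, 4, 5],
        "xgb_eta": [0.01, 0.05, 0.1, 0.2],
        "xgb_col_fraction": [0.5, 0.75, 1.0],
        "xgb_sample_fraction": [0.5, 0.75, 1.0],
    },
}

_REDUCED = {
    "CNN": {
        "n_layers": [1],
        "cnn_n_filters": [32, 64],
        "cnn_kernel_length": [5],
        "learning_rate": [1e-3, 5e-3],
    },
    "RNN": {
        "n_layers": [1],
        "rnn_hidden_dim": [16, 32],
        "learning_rate": [1e-2, 5e-3],
    },
    "Transformer": {
        "n_layers": [1],
        "transformer_n_heads": [2],
        "transformer_mlp_dim": [32, 64],
        "learning_rate": [1e-3, 5e-3],
    },
    "XGBoost": {
        "xgb_max_depth": [3, 5],
        "xgb_eta": [0.05, 0.2],
        "xgb_col_fraction": [1.0],
        "xgb_sample_fraction": [1.0],
    },
}


@dataclass(frozen=True)
class HyperparameterGrid:
    """Per-architecture candidate values plus embedding-dimension candidates.

    The full CNN space times the four embedding dimensions enumerates
    3 x 3 x 3 x 4 x 4 = 432 configurations.
    """

    spaces: dict = field(default_factory=lambda: _TABLE2)
    embedding_dims: tuple[int, ...] = EMBEDDING_DIMS

    def size(self, architecture: str, encoding_strategy: str = "learnable") -> int:
        space = self.spaces[architecture]
        total = 1
        for values in space.values():
            total *= len(values)
        if architecture != "XGBoost" and encoding_strategy != "one_hot":
            total *= len(self.embedding_dims)
        return total

    def configs(self, architecture: str, task: str,
                encoding_strategy: str = "learnable",
                seed: int = 0) -> list[ModelConfig]:
        """Enumerate the Cartesian product as ModelConfig objects."""
        space = self.spaces[architecture]
        keys = list(space)
        out = []
        if architecture == "XGBoost" or encoding_strategy == "one_hot":
            dims: tuple[int | None, ...] = (None,)
        else:
            dims = self.embedding_dims
        for dim in dims:
            enc = EncodingSpec("one_hot") if encoding_strategy == "one_hot" \
                else EncodingSpec(encoding_strategy, dim=dim or 32, seed=seed)
            for combo in itertools.product(*(space[k] for k in keys)):
                out.append(ModelConfig(architecture=architecture, task=task,
                                       encoding=enc, seed=seed,
                                       **dict(zip(keys, combo))))
        return out


def table2_grid() -> HyperparameterGrid:
    """The full benchmark search space."""
    return HyperparameterGrid(_TABLE2)


def reduced_grid() -> HyperparameterGrid:
    """A small declared subset of the full space for quick runs."""
    return HyperparameterGrid(_REDUCED, embedding_dims=(16, 32))


# --- encoders -------------------------------------------------------------

class _MLPHead(Module):
    """The shared three-layer perceptron prediction module."""

    def __init__(self, in_dim: int, drop: float, rng: np.random.Generator):
        self.fc1 = Linear(in_dim, 128, rng)
        self.fc2 = Linear(128, 64, rng)
        self.fc3 = Linear(64, 1, rng)
        self.drop = drop

    def __call__(self, x: Tensor, rng, training: bool) -> Tensor:
        x = dropout(self.fc1(x).relu(), self.drop, rng, training)
        x = dropout(self.fc2(x).relu(), self.drop, rng, training)
        return self.fc3(x)


class _CNNEncoder(Module):
    def __init__(self, cfg: ModelConfig, in_dim: int,
                 rng: np.random.Generator):
        self.kernel = cfg.cnn_kernel_length
        self.drop = cfg.dropout
        self.layers = []
        dim = in_dim
        for _ in range(cfg.n_layers):
            fan = dim * self.kernel
            limit = np.sqrt(6.0 / (fan + cfg.cnn_n_filters))
            w = Tensor(rng.uniform(-limit, limit,
                                   size=(self.kernel, dim, cfg.cnn_n_filters)),
                       requires_grad=True)
            b = Tensor(np.zeros(cfg.cnn_n_filters), requires_grad=True)
            self.layers.append((w, b))
            dim = cfg.cnn_n_filters
        self.params = [t for pair in self.layers for t in pair]
        self.out_dim = dim

    def __call__(self, x: Tensor, mask: np.ndarray, rng, training) -> Tensor:
        if self.kernel > x.shape[1]:
            raise ModelConstructionError(
                f"kernel length {self.kernel} exceeds sequence length "
                f"{x.shape[1]}")
        h = x
        m = Tensor(mask[:, :, None])
        for w, b in self.layers:
            # re-zero pad positions so stacked convolutions see the same
            # zeros as their own boundary padding
            h = dropout(conv1d(h, w, b).relu() * m, self.drop, rng, training)
        # masked global max pooling over valid positions
        neg = Tensor(((1.0 - mask) * -1e9)[:, :, None])
        return (h + neg).max(axis=1)


class _RNNEncoder(Module):
    """Stacked bidirectional GRU; pools the final fwd/bwd hidden states."""

    def __init__(self, cfg: ModelConfig, in_dim: int,
                 rng: np.random.Generator):
        self.drop = cfg.dropout
        self.forward_cells: list[GRU] = []
        self.backward_cells: list[GRU] = []
        dim = in_dim
        for _ in range(cfg.n_layers):
            self.forward_cells.append(GRU(dim, cfg.rnn_hidden_dim, rng))
            self.backward_cells.append(GRU(dim, cfg.rnn_hidden_dim, rng))
            dim = 2 * cfg.rnn_hidden_dim
        self.out_dim = dim

    @staticmethod
    def _run(cell: GRU, x: Tensor, mask: np.ndarray) -> tuple[list, Tensor]:
        bsz, length, _ = x.shape
        h = Tensor(np.zeros((bsz, cell.hidden_dim)))
        states = []
        for t in range(length):
            xt = x[:, t, :]
            m = Tensor(mask[:, t][:, None])
            xh = concat([xt, h], axis=-1)
            z = cell.w_z(xh).sigmoid()
            r = cell.w_r(xh).sigmoid()
            n = cell.w_n(concat([xt, r * h], axis=-1)).tanh()
            h_new = (1.0 - z) * n + z * h
            h = m * h_new + (1.0 - m) * h
            states.append(h)
        return states, h

    def __call__(self, x: Tensor, mask: np.ndarray, rng, training) -> Tensor:
        h = x
        final = None
        for li, (fw, bw) in enumerate(zip(self.forward_cells,
                                          self.backward_cells)):
            rev = h[:, ::-1, :]
            fw_states, fw_final = self._run(fw, h, mask)
            bw_states, bw_final = self._run(bw, rev, mask[:, ::-1])
            final = concat([fw_final, bw_final], axis=-1)
            if li < len(self.forward_cells) - 1:
                seq = concat(
                    [concat([s[:, None, :] for s in fw_states], axis=1),
                     concat([s[:, None, :] for s in bw_states[::-1]], axis=1)],
                    axis=-1)
                h = dropout(seq * Tensor(mask[:, :, None]), self.drop, rng,
                            training)
        return final


class _TransformerEncoder(Module):
    def __init__(self, cfg: ModelConfig, in_dim: int,
                 rng: np.random.Generator):
        if in_dim % cfg.transformer_n_heads != 0:
            raise ModelConstructionError(
                f"embedding dim {in_dim} not divisible by "
                f"{cfg.transformer_n_heads} heads")
        self.n_heads = cfg.transformer_n_heads
        self.drop = cfg.dropout
        self.dim = in_dim
        self.pos = Tensor(rng.normal(0, 0.02, size=(cfg.max_len, in_dim)),
                          requires_grad=True)
        self.blocks = []
        for _ in range(cfg.n_layers):
            blk = {
                "q": Linear(in_dim, in_dim, rng),
                "k": Linear(in_dim, in_dim, rng),
                "v": Linear(in_dim, in_dim, rng),
                "o": Linear(in_dim, in_dim, rng),
                "ff1": Linear(in_dim, cfg.transformer_mlp_dim, rng),
                "ff2": Linear(cfg.transformer_mlp_dim, in_dim, rng),
                "ln1": LayerNorm(in_dim),
                "ln2": LayerNorm(in_dim),
            }
            self.blocks.append(blk)
        self.block_modules = [m for blk in self.blocks for m in blk.values()]
        self.out_dim = in_dim

    def __call__(self, x: Tensor, mask: np.ndarray, rng, training) -> Tensor:
        bsz, length, dim = x.shape
        if length > self.pos.shape[0]:
            raise ModelConstructionError(
                f"sequence length {length} exceeds positional table "
                f"({self.pos.shape[0]})")
        h = x + self.pos[:length, :]
        dh = dim // self.n_heads
        key_mask = ((1.0 - mask) * -1e9)[:, None, None, :]   # (B,1,1,L)
        for blk in self.blocks:
            def heads(t: Tensor) -> Tensor:
                return t.reshape(bsz, length, self.n_heads, dh).transpose(0, 2, 1, 3)

            q, k, v = (heads(blk[name](h)) for name in ("q", "k", "v"))
            logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
            attn = (logits + Tensor(key_mask)).softmax(axis=-1)
            attn = dropout(attn, self.drop, rng, training)
            ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(bsz, length, dim)
            h = blk["ln1"](h + dropout(blk["o"](ctx), self.drop, rng, training))
            ff = blk["ff2"](blk["ff1"](h).relu())
            h = blk["ln2"](h + dropout(ff, self.drop, rng, training))
        m = Tensor(mask[:, :, None])
        denom = Tensor(np.maximum(mask.sum(axis=1), 1.0)[:, None])
        return (h * m).sum(axis=1) / denom


# --- the full models ------------------------------------------------------

class SequenceModel(Module):
    """Token table + encoder + shared MLP head."""

    def __init__(self, config: ModelConfig, vocab: Vocabulary):
        self.config = config
        self.vocab = vocab
        self.pad_index = vocab.pad_index
        rng = np.random.default_rng(config.seed)
        self.token_table = make_token_vectors(vocab, config.encoding)
        in_dim = self.token_table.shape[1]
        if config.architecture == "CNN":
            self.encoder = _CNNEncoder(config, in_dim, rng)
        elif config.architecture == "RNN":
            self.encoder = _RNNEncoder(config, in_dim, rng)
        elif config.architecture == "Transformer":
            self.encoder = _TransformerEncoder(config, in_dim, rng)
        else:
            raise ModelConstructionError(
                "use XGBoostModel for the XGBoost baseline")
        self.head = _MLPHead(self.encoder.out_dim, config.dropout, rng)

    def forward(self, indices: np.ndarray, rng: np.random.Generator | None = None,
                training: bool = False) -> Tensor:
        """Padded index matrix (B, L) -> raw outputs (B,).

        Classification outputs are logits; apply a sigmoid for
        probabilities (see :meth:`predict`).
        """
        indices = np.asarray(indices, dtype=np.int64)
        mask = (indices != self.pad_index).astype(np.float64)
        x = embedding_lookup(self.token_table, indices)
        pooled = self.encoder(x, mask, rng, training)
        return self.head(pooled, rng, training).reshape(indices.shape[0])

    def predict(self, indices: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = []
        for start in range(0, len(indices), batch_size):
            z = self.forward(indices[start:start + batch_size]).data
            outs.append(z)
        z = np.concatenate(outs) if outs else np.empty(0)
        if self.config.task == "classification":
            return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        return z

    def mask_pad_gradient(self) -> None:
        """Keep the pad token's vector frozen at zero."""
        if self.token_table.requires_grad and self.token_table.grad is not None:
            self.token_table.grad[self.pad_index] = 0.0

    def make_optimizer(self) -> Adam:
        return Adam(self.parameters(), lr=self.config.learning_rate)


class XGBoostModel:
    """Gradient-boosted trees on extended-connectivity fingerprints."""

    def __init__(self, config: ModelConfig,
                 criteria: SplitCriteria | None = None):
        if config.architecture != "XGBoost":
            raise ModelConstructionError("config is not an XGBoost config")
        self.config = config
        self.criteria = criteria or SplitCriteria()
        self.booster = None

    def featurize(self, smiles: list[str]) -> np.ndarray:
        return morgan_fingerprints(smiles, self.criteria).astype(np.float32)

    def fit(self, train_smiles: list[str], y_train: np.ndarray,
            val_smiles: list[str], y_val: np.ndarray,
            sample_weight: np.ndarray | None = None,
            patience: int = 5) -> "XGBoostModel":
        import xgboost as xgb

        cfg = self.config
        y_train = np.asarray(y_train, dtype=float)
        if cfg.task == "classification" and len(np.unique(y_train)) < 2:
            raise ValueError("degenerate single-class training set")
        params = dict(
            n_estimators=cfg.xgb_n_trees,
            max_depth=cfg.xgb_max_depth,
            learning_rate=cfg.xgb_eta,
            colsample_bytree=cfg.xgb_col_fraction,
            subsample=cfg.xgb_sample_fraction,
            random_state=cfg.seed,
            n_jobs=1,
            early_stopping_rounds=patience,
        )
        if cfg.task == "classification":
            model = xgb.XGBClassifier(eval_metric="logloss", **params)
        else:
            model = xgb.XGBRegressor(eval_metric="rmse", **params)
        model.fit(self.featurize(train_smiles), y_train,
                  sample_weight=sample_weight,
                  eval_set=[(self.featurize(val_smiles), y_val)],
                  verbose=False)
        self.booster = model
        return self

    def predict(self, smiles: list[str]) -> np.ndarray:
        if self.booster is None:
            raise RuntimeError("fit() first")
        X = self.featurize(smiles)
        if self.config.task == "classification":
            return self.booster.predict_proba(X)[:, 1]
        return self.booster.predict(X)

    @property
    def best_n_trees(self) -> int:
        return int(self.booster.best_iteration) + 1


def build_model(config: ModelConfig, vocab: Vocabulary | None = None):
    """Construct a predictor for the named architecture."""
    if config.architecture == "XGBoost":
        return XGBoostModel(config)
    if vocab is None:
        raise ModelConstructionError(
            f"{config.architecture} requires a vocabulary")
    return SequenceModel(config, vocab)


def count_parameters(model: SequenceModel) -> int:
    """Number of trainable scalar parameters."""
    return int(sum(p.data.size for p in model.parameters()))
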