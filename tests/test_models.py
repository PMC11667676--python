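"""Architecture contracts: masking, parameter counts, symmetries, baseline."""

from __future__ import annotations

import numpy as np
import pytest

from clpbench.chemlang import PAD_TOKEN, Vocabulary, build_vocabulary, pad, \
    tokenize_smiles
from clpbench.encoding import EncodingSpec
from clpbench.models import (EMBEDDING_DIMS, ModelConfig,
                             ModelConstructionError, SequenceModel,
                             XGBoostModel, build_model, count_parameters,
                             reduced_grid, table2_grid)


@pytest.fixture(scope="module")
def small_data(classification_records):
    seqs = [tokenize_smiles(r.smiles) for r in classification_records]
    vocab = build_vocabulary(seqs)
    X = pad(seqs, vocab)
    y = np.array([float(r.value) for r in classification_records])
    return vocab, X, y


def _config(arch, **kw):
    enc = kw.pop("encoding", EncodingSpec("learnable", dim=16, seed=1))
    return ModelConfig(arch, kw.pop("task", "classification"), enc, seed=2,
                       **kw)


class TestBuildModel:
    def test_cnn_first_conv_parameter_count(self):
        mapping = {PAD_TOKEN: 0, **{f"t{i}": i for i in range(1, 40)}}
        vocab40 = Vocabulary(mapping, "SMILES")
        cfg = _config("CNN", encoding=EncodingSpec("one_hot"), n_layers=1,
                      cnn_n_filters=32, cnn_kernel_length=5)
        model = build_model(cfg, vocab40)
        w, b = model.encoder.layers[0]
        assert w.data.size == 40 * 5 * 32 == 6400
        assert b.data.size == 32

    @pytest.mark.parametrize("arch", ["CNN", "RNN", "Transformer"])
    def test_parameter_counts_match_closed_form(self, arch, small_data):
        vocab, _, _ = small_data
        v = len(vocab)
        d = 16
        cfg = _config(arch, n_layers=1)
        model = build_model(cfg, vocab)
        head = lambda in_dim: (in_dim * 128 + 128) + (128 * 64 + 64) + 65
        if arch == "CNN":
            enc = 16 * 5 * 32 + 32
            expected = v * d + enc + head(32)
        elif arch == "RNN":
            h = cfg.rnn_hidden_dim
            per_cell = 3 * ((d + h) * h + h)
            expected = v * d + 2 * per_cell + head(2 * h)
        else:
            per_block = 4 * (d * d + d) + (d * cfg.transformer_mlp_dim
                                           + cfg.transformer_mlp_dim) \
                + (cfg.transformer_mlp_dim * d + d) + 2 * (2 * d)
            expected = v * d + cfg.max_len * d + per_block + head(d)
        assert count_parameters(model) == expected

    def test_one_hot_dim_mismatch_is_construction_error(self, small_data):
        vocab, _, _ = small_data
        cfg = _config("CNN", encoding=EncodingSpec("one_hot", dim=3))
        with pytest.raises(Exception, match="one_hot dim"):
            build_model(cfg, vocab)

    def test_head_dim_not_divisible_by_heads_rejected(self, small_data):
        vocab, _, _ = small_data
        cfg = _config("Transformer",
                      encoding=EncodingSpec("learnable", dim=30, seed=0),
                      transformer_n_heads=4)
        with pytest.raises(ModelConstructionError, match="divisible"):
            build_model(cfg, vocab)

    def test_missing_vocabulary_rejected(self):
        with pytest.raises(ModelConstructionError):
            build_model(_config("CNN"), None)


@pytest.mark.parametrize("arch,kw", [
    ("CNN", {"n_layers": 2}),
    ("RNN", {"rnn_hidden_dim": 8}),
    ("Transformer", {"transformer_n_heads": 2, "transformer_mlp_dim": 16}),
])
class TestMaskingContracts:
    def test_extra_pad_columns_leave_predictions_unchanged(self, arch, kw,
                                                           small_data):
        vocab, X, _ = small_data
        model = build_model(_config(arch, **kw), vocab)
        batch = X[:16]
        wider = np.concatenate(
            [batch, np.full((16, 6), vocab.pad_index, dtype=np.int64)],
            axis=1)
        np.testing.assert_allclose(model.forward(batch).data,
                                   model.forward(wider).data, atol=1e-9)

    def test_all_pad_rows_share_one_output(self, arch, kw, small_data):
        vocab, X, _ = small_data
        model = build_model(_config(arch, **kw), vocab)
        all_pad = np.full((3, X.shape[1]), vocab.pad_index, dtype=np.int64)
        out = model.forward(all_pad).data
        assert np.allclose(out, out[0])

    def test_batch_permutation_equivariance(self, arch, kw, small_data):
        vocab, X, _ = small_data
        model = build_model(_config(arch, **kw), vocab)
        batch = X[:12]
        perm = np.random.default_rng(0).permutation(12)
        np.testing.assert_allclose(model.forward(batch[perm]).data,
                                   model.forward(batch).data[perm],
                                   atol=1e-9)


class TestRNN:
    def test_pooled_width_is_twice_hidden_dim(self, small_data):
        vocab, X, _ = small_data
        model = build_model(_config("RNN", rnn_hidden_dim=16), vocab)
        mask = (X[:4] != vocab.pad_index).astype(float)
        from clpbench.nn import embedding_lookup

        emb = embedding_lookup(model.token_table, X[:4])
        pooled = model.encoder(emb, mask, None, False)
        assert pooled.shape == (4, 32)

    def test_reversal_swaps_direction_roles(self, small_data):
        """Reversing sequences and swapping fwd/bwd weights leaves the
        pooled representation identical (up to half swapping)."""
        vocab, X, _ = small_data
        model = build_model(_config("RNN", rnn_hidden_dim=8), vocab)
        enc = model.encoder
        from clpbench.nn import embedding_lookup

        batch = X[:6]
        mask = (batch != vocab.pad_index).astype(float)
        emb = embedding_lookup(model.token_table, batch)
        pooled = enc(emb, mask, None, False).data
        # swap the direction cells, feed reversed sequences
        enc.forward_cells, enc.backward_cells = (enc.backward_cells,
                                                 enc.forward_cells)
        emb_rev = embedding_lookup(model.token_table, batch[:, ::-1])
        pooled_rev = enc(emb_rev, mask[:, ::-1], None, False).data
        h = 8
        np.testing.assert_allclose(pooled[:, :h], pooled_rev[:, h:],
                                   atol=1e-10)
        np.testing.assert_allclose(pooled[:, h:], pooled_rev[:, :h],
                                   atol=1e-10)


class TestTransformer:
    def test_attention_rows_sum_to_one_over_valid_keys(self, small_data):
        vocab, X, _ = small_data
        cfg = _config("Transformer", n_layers=1, transformer_n_heads=1,
                      transformer_mlp_dim=16)
        model = build_model(cfg, vocab)
        batch = X[:4]
        mask = (batch != vocab.pad_index).astype(float)
        # recompute the first block's attention by hand
        from clpbench.nn import Tensor, embedding_lookup

        emb = embedding_lookup(model.token_table, batch)
        enc = model.encoder
        h = emb + enc.pos[:batch.shape[1], :]
        blk = enc.blocks[0]
        bsz, length, dim = h.shape
        q = blk["q"](h).data
        k = blk["k"](h).data
        logits = (q @ k.transpose(0, 2, 1)) / np.sqrt(dim)
        logits = logits + ((1 - mask) * -1e9)[:, None, :]
        attn = np.exp(logits - logits.max(-1, keepdims=True))
        attn /= attn.sum(-1, keepdims=True)
        np.testing.assert_allclose(attn.sum(-1), 1.0)
        # pad keys receive (numerically) zero attention from every query
        for b in range(bsz):
            pad_cols = attn[b][:, mask[b] == 0]
            if pad_cols.size:
                assert float(pad_cols.max()) < 1e-12

    def test_zero_positional_embeddings_give_permutation_invariance(
            self, small_data):
        vocab, X, _ = small_data
        cfg = _config("Transformer", n_layers=1, transformer_n_heads=2,
                      transformer_mlp_dim=16)
        model = build_model(cfg, vocab)
        model.encoder.pos.data[...] = 0.0
        row = X[1:2]
        valid = int((row != vocab.pad_index).sum())
        rng = np.random.default_rng(3)
        perm = np.concatenate([rng.permutation(valid),
                               np.arange(valid, row.shape[1])])
        np.testing.assert_allclose(model.forward(row).data,
                                   model.forward(row[:, perm]).data,
                                   atol=1e-9)


class TestXGBoostBaseline:
    def test_separable_substructure_labels_reach_training_ba_1(
            self, classification_records):
        from clpbench.evaluation import classification_suite

        smiles = [r.smiles for r in classification_records]
        y = np.array([float(r.value) for r in classification_records])
        cfg = ModelConfig("XGBoost", "classification",
                          EncodingSpec("learnable", dim=16, seed=0), seed=0)
        model = XGBoostModel(cfg).fit(smiles, y, smiles, y)
        report = classification_suite(y, model.predict(smiles))
        assert report.balanced_accuracy == 1.0

    def test_tree_cap_honored(self, classification_records):
        smiles = [r.smiles for r in classification_records]
        y = np.array([float(r.value) for r in classification_records])
        cfg = ModelConfig("XGBoost", "classification",
                          EncodingSpec("learnable", dim=16, seed=0), seed=0)
        model = XGBoostModel(cfg).fit(smiles, y, smiles, y)
        assert cfg.xgb_n_trees == 2000
        assert model.best_n_trees <= 2000

    def test_deterministic_given_seed(self, classification_records):
        smiles = [r.smiles for r in classification_records]
        y = np.array([float(r.value) for r in classification_records])
        cfg = ModelConfig("XGBoost", "classification",
                          EncodingSpec("learnable", dim=16, seed=0), seed=7)
        p1 = XGBoostModel(cfg).fit(smiles, y, smiles, y).predict(smiles)
        p2 = XGBoostModel(cfg).fit(smiles, y, smiles, y).predict(smiles)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_training_rejected(self, classification_records):
        inactive = [r for r in classification_records if r.value == 0][:50]
        smiles = [r.smiles for r in inactive]
        y = np.zeros(len(inactive))
        cfg = ModelConfig("XGBoost", "classification",
                          EncodingSpec("learnable", dim=16, seed=0), seed=0)
        with pytest.raises(ValueError, match="single-class"):
            XGBoostModel(cfg).fit(smiles, y, smiles, y)


class TestGrids:
    def test_cnn_space_is_432_configurations(self):
        grid = table2_grid()
        assert grid.size("CNN") == 432
        assert len(grid.configs("CNN", "classification")) == 432

    def test_embedding_dimension_candidates(self):
        assert EMBEDDING_DIMS == (16, 32, 64, 128)

    def test_reduced_grid_is_subset_of_full(self):
        full, red = table2_grid(), reduced_grid()
        for arch, space in red.spaces.items():
            for key, values in space.items():
                assert set(values) <= set(full.spaces[arch][key])

    def test_kernel_longer_than_sequence_rejected(self, small_data):
        vocab, X, _ = small_data
        cfg = _config("CNN", cnn_kernel_length=7)
        model = build_model(cfg, vocab)
        with pytest.raises(ModelConstructionError, match="kernel"):
            model.forward(X[:2, :5])
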