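"""Distances, dissimilarity selection, grouped splits, Monte Carlo folds."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clpbench.splits import (DataSplit, InfeasibleSplitError, SplitCriteria,
                             classification_split, grouped_regression_split,
                             levenshtein, monte_carlo_folds,
                             morgan_fingerprints, select_dissimilar, tanimoto,
                             tanimoto_matrix)


def brute_force_edit_distance(a: str, b: str) -> int:
    """Exhaustive memoized recursion: the independent oracle."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        return min(rec(i - 1, j) + 1, rec(i, j - 1) + 1,
                   rec(i - 1, j - 1) + cost)

    return rec(len(a), len(b))


class TestLevenshtein:
    @pytest.mark.parametrize("a,b,expected", [
        ("CCO", "CCO", 0),
        ("CCO", "CCCO", 1),
        ("", "CCO", 3),
        ("abc", "", 3),
    ])
    def test_known_values(self, a, b, expected):
        assert levenshtein(a, b) == expected

    @given(st.text(alphabet="CNO()=1c", max_size=12),
           st.text(alphabet="CNO()=1c", max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, a, b):
        assert levenshtein(a, b) == brute_force_edit_distance(a, b)

    @given(st.text(alphabet="CNOcl", max_size=10),
           st.text(alphabet="CNOcl", max_size=10),
           st.text(alphabet="CNOcl", max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_metric_properties(self, a, b, c):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert (levenshtein(a, b) == 0) == (a == b)
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


class TestTanimoto:
    def test_identical_nonempty_is_one(self):
        fp = np.zeros(64, dtype=bool)
        fp[[1, 5, 9]] = True
        assert tanimoto(fp, fp) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros(64, dtype=bool)
        b = np.zeros(64, dtype=bool)
        a[:4] = True
        b[10:14] = True
        assert tanimoto(a, b) == 0.0

    def test_both_empty_defined_as_zero(self):
        assert tanimoto(np.zeros(16, dtype=bool), np.zeros(16, dtype=bool)) == 0.0

    @given(st.integers(0, 2**32 - 1), st.integers(0, 2**32 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_popcount_oracle(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(64)], dtype=bool)
        b = np.array([(bits_b >> i) & 1 for i in range(64)], dtype=bool)
        inter = bin(bits_a & bits_b).count("1")
        union = bin(bits_a | bits_b).count("1")
        expected = inter / union if union else 0.0
        assert tanimoto(a, b) == pytest.approx(expected)

    def test_agrees_with_rdkit(self, classification_records):
        from rdkit.Chem import DataStructs, rdFingerprintGenerator
        from rdkit import Chem

        smiles = [r.smiles for r in classification_records[:30]]
        fps = morgan_fingerprints(smiles)
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)
        rd = [gen.GetFingerprint(Chem.MolFromSmiles(s)) for s in smiles]
        ours = tanimoto_matrix(fps, fps)
        for i in range(len(smiles)):
            expected = DataStructs.BulkTanimotoSimilarity(rd[i], rd)
            np.testing.assert_allclose(ours[i], expected, atol=1e-12)


class TestSelectDissimilar:
    def test_identical_molecule_never_selected(self, classification_records):
        pool = classification_records[:50]
        reference = [pool[0]]
        criteria = SplitCriteria(min_edit_distance=0, max_tanimoto=1.0)
        chosen = select_dissimilar(pool[1:] + [pool[0]], reference, criteria,
                                   n_active=0, n_inactive=1, seed=0)
        # with max_tanimoto=1.0 strict, the identical molecule (sim 1.0)
        # cannot be drawn no matter the seed
        smiles = [(pool[1:] + [pool[0]])[i].smiles for i in chosen]
        assert pool[0].smiles not in smiles

    def test_boundary_edit_distance_exactly_10_excluded(self):
        class R:
            def __init__(self, smiles, value):
                self.smiles, self.value = smiles, value

        ref = R("C" * 20, 0)
        near = R("C" * 30, 0)            # distance exactly 10
        far = R("C" * 20 + "N" * 11, 0)  # distance 11, same fingerprint? no
        criteria = SplitCriteria(min_edit_distance=10, max_tanimoto=1.0)
        with pytest.raises(InfeasibleSplitError):
            select_dissimilar([near], [ref], criteria, 0, 1, seed=0)
        assert select_dissimilar([far], [ref], criteria, 0, 1, seed=0) == [0]

    def test_equals_brute_force_filter(self, classification_records):
        pool = classification_records[:150]
        reference = classification_records[150:200]
        criteria = SplitCriteria()
        fp_pool = morgan_fingerprints([r.smiles for r in pool])
        fp_ref = morgan_fingerprints([r.smiles for r in reference])
        eligible = []
        for i, rec in enumerate(pool):
            med = min(brute_force_edit_distance(rec.smiles, r.smiles)
                      if max(len(rec.smiles), len(r.smiles)) <= 12
                      else levenshtein(rec.smiles, r.smiles)
                      for r in reference)
            mt = max(tanimoto(fp_pool[i], fp_ref[j])
                     for j in range(len(reference)))
            if med > criteria.min_edit_distance and mt < criteria.max_tanimoto:
                eligible.append(i)
        labels = np.array([int(r.value) for r in pool])
        n_act = min(2, int(labels[eligible].sum()))
        n_inact = min(10, int((labels[eligible] == 0).sum()))
        chosen = select_dissimilar(pool, reference, criteria, n_act, n_inact,
                                   seed=5)
        assert set(chosen) <= set(eligible)
        assert len(chosen) == n_act + n_inact


@pytest.fixture(scope="module")
def split_1k(classification_records_1k):
    sizes = ((35, 350), (8, 75), (8, 75))
    return classification_split(classification_records_1k, sizes=sizes,
                                seed=3)


class TestClassificationSplit:
    def test_partition_sizes_and_disjointness(self, split_1k):
        assert len(split_1k.train) == 385
        assert len(split_1k.validation) == 83
        assert len(split_1k.test) == 83
        all_idx = np.concatenate([split_1k.train, split_1k.validation,
                                  split_1k.test])
        assert len(set(all_idx)) == len(all_idx)

    def test_audit_recomputed_from_scratch(self, split_1k,
                                           classification_records_1k):
        records = classification_records_1k
        train_smiles = [records[i].smiles for i in split_1k.train]
        train_fps = morgan_fingerprints(train_smiles)
        test_smiles = [records[i].smiles for i in split_1k.test]
        test_fps = morgan_fingerprints(test_smiles)
        for k, (smi, fp) in enumerate(zip(test_smiles, test_fps)):
            med = min(levenshtein(smi, t) for t in train_smiles)
            mt = tanimoto_matrix(fp[None, :], train_fps).max()
            assert med > 10
            assert mt < 0.60
            assert med == split_1k.audit["test_min_train_edit_distance"][k]
            assert mt == pytest.approx(
                split_1k.audit["test_max_train_tanimoto"][k])

    def test_class_counts(self, split_1k, classification_records_1k):
        labels = np.array([int(r.value) for r in classification_records_1k])
        assert labels[split_1k.train].sum() == 35
        assert labels[split_1k.validation].sum() == 8
        assert labels[split_1k.test].sum() == 8

    def test_similarity_profile_mode_below_04(self, split_1k):
        sims = np.asarray(split_1k.audit["test_max_train_tanimoto"])
        hist, edges = np.histogram(sims, bins=np.arange(0, 1.05, 0.1))
        assert edges[int(np.argmax(hist))] < 0.4


class TestGroupedRegressionSplit:
    def test_fractions_within_one_group(self, regression_records):
        split = grouped_regression_split(regression_records, seed=1)
        n = len(regression_records)
        largest = split.audit["largest_group"]
        assert abs(len(split.train) - 0.70 * n) <= largest
        assert abs(len(split.validation) - 0.15 * n) <= largest
        assert abs(len(split.test) - 0.15 * n) <= largest
        assert len(split.train) + len(split.validation) + len(split.test) == n

    def test_groups_never_straddle_partitions(self, regression_records):
        from clpbench.splits import analog_groups

        split = grouped_regression_split(regression_records, seed=1)
        labels = analog_groups([r.smiles for r in regression_records])
        membership = {}
        for name, idx in (("train", split.train),
                          ("val", split.validation), ("test", split.test)):
            for i in idx:
                membership[int(i)] = name
        for g in np.unique(labels):
            parts = {membership[int(i)] for i in np.flatnonzero(labels == g)}
            assert len(parts) == 1

    def test_respects_generator_series_under_strict_threshold(self):
        from clpbench.synthetic_data import SyntheticConfig, \
            generate_regression_set

        cfg = SyntheticConfig(task="regression", n_molecules=50, seed=31)
        records = generate_regression_set(cfg)
        split = grouped_regression_split(records, seed=0, threshold=0.4)
        membership = {}
        for name, idx in (("train", split.train),
                          ("val", split.validation), ("test", split.test)):
            for i in idx:
                membership[int(i)] = name
        # under a strict (low) threshold, whole generator series cluster
        # together, so no series straddles partitions
        for sid in {r.scaffold_id for r in records}:
            parts = {membership[i] for i, r in enumerate(records)
                     if r.scaffold_id == sid}
            assert len(parts) == 1

    def test_too_small_dataset_rejected(self, regression_records):
        with pytest.raises(ValueError):
            grouped_regression_split(regression_records[:10])


class TestMonteCarloFolds:
    def test_five_folds_with_requested_sizes(self):
        pool = np.arange(100)
        folds = monte_carlo_folds(pool, k=5, val_fraction=0.2, seed=0)
        assert len(folds) == 5
        for train, val in folds:
            assert len(val) == 20
            assert len(train) == 80
            assert set(train).isdisjoint(val)
            assert set(train) | set(val) == set(range(100))

    def test_folds_differ(self):
        folds = monte_carlo_folds(np.arange(100), k=5, val_fraction=0.2,
                                  seed=0)
        val_sets = {tuple(sorted(v)) for _, v in folds}
        assert len(val_sets) >= 2

    def test_zero_val_fraction_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_folds(np.arange(100), k=5, val_fraction=0.0, seed=0)


class TestDataSplitSerialization:
    def test_json_round_trip(self, regression_records):
        split = grouped_regression_split(regression_records, seed=1)
        restored = DataSplit.from_json(split.to_json())
        np.testing.assert_array_equal(restored.train, split.train)
        np.testing.assert_array_equal(restored.test, split.test)
        assert restored.criteria == split.criteria

    def test_overlapping_partitions_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            DataSplit(np.array([0, 1]), np.array([1, 2]), np.array([3]))
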