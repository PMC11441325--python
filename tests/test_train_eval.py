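"""Cross-validation protocol, metrics, and training smoke behavior."""

import numpy as np
import pandas as pd
import pytest

from dhdmp.data_graph import build_graph_bundle
from dhdmp.model import DhdmpModel, ModelConfig
from dhdmp.synthetic_data import SyntheticSpec, generate_dataset
from dhdmp.train_eval import (
    TrainConfig,
    ablation_grid,
    compute_auc,
    compute_aupr,
    five_fold_split,
    topk_recall,
    train_model,
)

SMALL = ModelConfig(ne=8, category_dim=8, gcn_hidden=16, d_proj=8,
                    patch_size=10, ndim=6, heads=2, d_fuse=48,
                    conv_channels=(2, 3), pool=3)


def auc_pair_count_oracle(scores, labels):
    """O(n^2) pair enumeration; ties count one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = wins = 0.0
    for p in pos:
        for n in neg:
            total += 1
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / total


def aupr_threshold_oracle(scores, labels):
    """Step-interpolated area: sum over recall increments of precision."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    labels = np.asarray(labels)[order]
    npos = labels.sum()
    tp = fp = 0
    area = 0.0
    prev_recall = 0.0
    # walk distinct score thresholds
    scores_sorted = np.asarray(scores)[order]
    i = 0
    n = len(labels)
    while i < n:
        j = i
        while j < n and scores_sorted[j] == scores_sorted[i]:
            j += 1
        tp += labels[i:j].sum()
        fp += (j - i) - labels[i:j].sum()
        recall = tp / npos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


class TestFoldSplit:
    def test_partition_and_disjointness(self):
        ds, _ = generate_dataset(SyntheticSpec(seed=1))
        folds = five_fold_split(ds.R, seed=3)
        all_pos = np.flatnonzero(ds.R.ravel() == 1)
        test_union = np.concatenate([f.test_pos for f in folds])
        assert sorted(test_union) == sorted(all_pos)
        assert len(np.unique(test_union)) == len(test_union)
        for f in folds:
            assert np.intersect1d(f.train_pairs, f.test_pairs).size == 0
            assert len(f.train_neg) == len(f.train_pos)
            # training negatives are unknown pairs
            assert not ds.R.ravel()[f.train_neg].any()

    def test_real_scale_fold_sizes(self):
        rng = np.random.default_rng(0)
        R = np.zeros(1373 * 173)
        R[rng.choice(R.size, 2470, replace=False)] = 1
        R = R.reshape(1373, 173)
        folds = five_fold_split(R, seed=1)
        assert [len(f.test_pos) for f in folds] == [494] * 5

    def test_deterministic_given_seed(self):
        ds, _ = generate_dataset(SyntheticSpec(seed=1))
        a = five_fold_split(ds.R, seed=9)
        b = five_fold_split(ds.R, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.train_neg, fb.train_neg)
            np.testing.assert_array_equal(fa.test_pos, fb.test_pos)

    def test_too_few_positives(self):
        R = np.zeros((4, 4))
        R[0, 0] = 1
        with pytest.raises(ValueError):
            five_fold_split(R, seed=0)


class TestMetrics:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        assert compute_auc(scores, labels) == 1.0
        assert compute_aupr(scores, labels) == 1.0

    def test_hand_case_half_auc(self):
        # one of the two positive-negative pairs is correctly ordered
        assert compute_auc([0.9, 0.8, 0.3], [1, 0, 1]) == pytest.approx(0.5)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_oracles(self, trial):
        rng = np.random.default_rng(700 + trial)
        n = int(rng.integers(8, 50))
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[1] = 0, 1
        # quantized scores force ties
        scores = np.round(rng.random(n), 1)
        assert compute_auc(scores, labels) == pytest.approx(
            auc_pair_count_oracle(scores, labels), abs=1e-12)
        assert compute_aupr(scores, labels) == pytest.approx(
            aupr_threshold_oracle(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([0.5, 0.6], [1, 1])
        with pytest.raises(ValueError):
            compute_aupr([0.5, 0.6], [0, 0])


class TestTopkRecall:
    def test_direct_counts(self):
        # drug 0: positives ranked 1st and 4th among its 4 candidates
        scores = [0.9, 0.8, 0.7, 0.6]
        labels = [1, 0, 0, 1]
        drugs = [0, 0, 0, 0]
        table = topk_recall(scores, labels, drugs, k_list=[1, 3, 4])
        row = table[table["drug"] == 0].iloc[0]
        assert row["recall@1"] == 0.5
        assert row["recall@3"] == 0.5
        assert row["recall@4"] == 1.0

    def test_monotone_in_k_and_average_row(self):
        rng = np.random.default_rng(2)
        scores = rng.random(40)
        labels = rng.integers(0, 2, size=40)
        drugs = np.repeat(np.arange(4), 10)
        ks = [1, 2, 5, 10]
        table = topk_recall(scores, labels, drugs, k_list=ks)
        cols = [f"recall@{k}" for k in ks]
        vals = table[cols].to_numpy(dtype=float)
        assert (np.diff(vals, axis=1) >= -1e-12).all()
        assert table.iloc[-1]["drug"] == "average"

    def test_drugs_without_positives_excluded(self):
        table = topk_recall([0.5, 0.4], [1, 0], [0, 1], k_list=[1])
        assert list(table["drug"]) == [0, "average"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            topk_recall([], [], [], k_list=[1])


class TestTraining:
    def test_one_epoch_smoke_finite_loss(self):
        ds, _ = generate_dataset(SyntheticSpec(Nd=12, Nm=8, density=0.15, seed=3))
        bundle = build_graph_bundle(ds)
        model = DhdmpModel(bundle, SMALL, seed=0)
        pos = np.flatnonzero(ds.R.ravel() == 1)[:10]
        neg = np.flatnonzero(ds.R.ravel() == 0)[:10]
        pairs = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(10), np.zeros(10)])
        history = train_model(model, pairs, labels, ds.n_microbes,
                              TrainConfig(epochs=1, seed=0))
        assert len(history) == 1 and np.isfinite(history[0])

    def test_loss_decreases_over_training(self):
        ds, _ = generate_dataset(SyntheticSpec(Nd=20, Nm=10, density=0.12, seed=4))
        bundle = build_graph_bundle(ds)
        model = DhdmpModel(bundle, SMALL, seed=1)
        pos = np.flatnonzero(ds.R.ravel() == 1)
        rng = np.random.default_rng(0)
        neg = rng.choice(np.flatnonzero(ds.R.ravel() == 0), len(pos), replace=False)
        pairs = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
        history = train_model(model, pairs, labels, ds.n_microbes,
                              TrainConfig(epochs=10, weight_decay=0.0, seed=0))
        assert history[-1] < history[0]

    def test_training_deterministic_given_seed(self):
        ds, _ = generate_dataset(SyntheticSpec(Nd=12, Nm=8, density=0.15, seed=3))
        bundle = build_graph_bundle(ds)
        pos = np.flatnonzero(ds.R.ravel() == 1)[:8]
        neg = np.flatnonzero(ds.R.ravel() == 0)[:8]
        pairs = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(8), np.zeros(8)])
        runs = []
        for _ in range(2):
            model = DhdmpModel(bundle, SMALL, seed=5)
            runs.append(train_model(model, pairs, labels, ds.n_microbes,
                                    TrainConfig(epochs=2, seed=5)))
        assert runs[0] == runs[1]


class TestAblationGrid:
    def test_grid_has_six_distinct_configurations(self):
        grid = ablation_grid()
        assert len(grid) == 6
        labels = [c.ablation_label() for c in grid]
        assert len(set(labels)) == 6
        assert "full" in labels
        full = grid[-1]
        assert full.use_nhcn and full.use_gcnfp and full.use_sca
        # component removals imply their dependent switches
        no_nhcn = grid[0]
        assert not no_nhcn.use_nhcn and not no_nhcn.use_category
        no_gcnfp = grid[1]
        assert not no_gcnfp.use_gcnfp and not no_gcnfp.use_nfps
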