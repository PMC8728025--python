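"""Network forward pass, loss, clustering, training and gene weights."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from transtage import deepnet as dn


def _toy_separable(n=100, margin=3.0, seed=0):
    """Two Gaussian classes separated by ``margin`` sd along two genes."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0.0, 1.0], n // 2)
    X = rng.normal(size=(n, 2))
    X[y == 1] += margin
    return X, y


class TestInit:
    def test_deterministic(self):
        a = dn.init_network(30, 8, 1, seed=5)
        b = dn.init_network(30, 8, 1, seed=5)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.W2, b.W2)

    def test_biases_zero(self):
        p = dn.init_network(10, 4, 1, seed=0)
        assert not p.B1.any() and not p.B2.any()

    def test_fan_in_scale(self):
        p = dn.init_network(2000, 64, 1, seed=1)
        sd = p.W1.std()
        assert abs(sd - 1 / np.sqrt(2000)) < 0.1 / np.sqrt(2000)

    def test_bad_dims(self):
        with pytest.raises(ValueError):
            dn.init_network(0, 4, 1)


class TestForward:
    def test_zero_params_give_half(self):
        p = dn.NetworkParams(np.zeros((3, 4)), np.zeros(4),
                             np.zeros((4, 1)), np.zeros(1))
        h = dn.forward_hidden(p, np.random.default_rng(0).normal(size=(5, 3)))
        np.testing.assert_array_equal(h, 0.5)
        np.testing.assert_array_equal(dn.forward_output(p, h), 0.5)

    def test_upper_clip(self):
        p = dn.NetworkParams(np.array([[1000.0]]), np.zeros(1),
                             np.ones((1, 1)), np.zeros(1))
        h = dn.forward_hidden(p, np.array([[1.0]]))
        assert h[0, 0] == 1 - 1e-9

    def test_matches_matrix_oracle(self, rng):
        p = dn.init_network(20, 6, 1, seed=2)
        X = rng.normal(size=(15, 20))
        h = dn.forward_hidden(p, X)
        expected = np.clip(expit(X @ p.W1 + p.B1), 1e-9, 1 - 1e-9)
        np.testing.assert_allclose(h, expected, atol=1e-12)
        out = dn.forward_output(p, h)
        np.testing.assert_allclose(
            out, np.clip(expit(h @ p.W2 + p.B2)[:, 0], 1e-9, 1 - 1e-9),
            atol=1e-12)

    def test_monotone_in_hidden(self):
        p = dn.NetworkParams(np.zeros((1, 2)), np.zeros(2),
                             np.array([[1.0], [0.5]]), np.zeros(1))
        h = np.array([[0.2, 0.2], [0.4, 0.2]])
        out = dn.forward_output(p, h)
        assert out[1] > out[0]

    def test_dimension_mismatch(self, rng):
        p = dn.init_network(10, 4, 1, seed=0)
        with pytest.raises(ValueError, match="gene"):
            dn.forward_hidden(p, rng.normal(size=(3, 7)))

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(-50, 50), st.floats(-50, 50))
    def test_hidden_always_inside_clip_bounds(self, seed, scale, bias):
        rng = np.random.default_rng(seed)
        p = dn.init_network(5, 3, 1, seed=seed)
        p.W1 *= scale
        p.B1 += bias
        h = dn.forward_hidden(p, rng.normal(size=(4, 5)) * 10)
        assert (h >= 1e-9).all() and (h <= 1 - 1e-9).all()


class TestLoss:
    def test_components_match_oracle(self, rng):
        p = dn.init_network(12, 5, 1, seed=3)
        X = rng.normal(size=(20, 12))
        y = rng.integers(0, 2, 20).astype(float)
        clusters = dn.update_clusters(dn.forward_hidden(p, X), 2, seed=0)
        comps = dn.compute_loss(p, X, y, clusters, alpha=1.5, lambda_=0.01)
        h = np.clip(expit(X @ p.W1 + p.B1), 1e-9, 1 - 1e-9)
        prob = np.clip(expit(h @ p.W2 + p.B2)[:, 0], 1e-9, 1 - 1e-9)
        bce = -np.mean(y * np.log(prob) + (1 - y) * np.log(1 - prob))
        diff = h - clusters.centroids[clusters.assignments]
        cl = 1.5 / 2 * np.mean((diff ** 2).sum(axis=1))
        sp = 0.01 * np.sqrt((p.W1 ** 2).sum(axis=1)).sum()
        assert comps["bce"] == pytest.approx(bce, abs=1e-12)
        assert comps["cluster"] == pytest.approx(cl, abs=1e-12)
        assert comps["sparsity"] == pytest.approx(sp, abs=1e-12)
        assert comps["total"] == pytest.approx(bce + cl + sp, abs=1e-12)

    def test_zero_weights_zero_sparsity(self):
        p = dn.NetworkParams(np.zeros((4, 3)), np.zeros(3),
                             np.zeros((3, 1)), np.zeros(1))
        comps = dn.compute_loss(p, np.zeros((2, 4)), np.array([0.0, 1.0]),
                                None, 0.0, 0.5)
        assert comps["sparsity"] == 0.0

    def test_perfect_prediction_bce_is_clip_limited(self):
        # p clipped at 1 - 1e-9 for label 1 -> bce = -log(1 - 1e-9) ~ 1e-9
        p = dn.NetworkParams(np.zeros((1, 1)), np.full(1, 100.0),
                             np.full((1, 1), 100.0), np.zeros(1))
        comps = dn.compute_loss(p, np.zeros((1, 1)), np.array([1.0]),
                                None, 0.0, 0.0)
        assert comps["bce"] == pytest.approx(1e-9, rel=1e-3)


class TestClusters:
    def test_two_clouds_recovered(self, rng):
        a = rng.normal(size=(30, 4))
        b = rng.normal(size=(30, 4)) + 50
        state = dn.update_clusters(np.vstack([a, b]), 2, seed=1)
        first, second = state.assignments[:30], state.assignments[30:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_single_cluster_is_mean(self, rng):
        h = rng.normal(size=(10, 3))
        state = dn.update_clusters(h, 1, seed=0)
        np.testing.assert_allclose(state.centroids[0], h.mean(axis=0),
                                   atol=1e-10)

    def test_k_exceeds_samples(self, rng):
        with pytest.raises(ValueError):
            dn.update_clusters(rng.normal(size=(3, 2)), 5)


class TestTrain:
    def test_separable_toy_reaches_perfect_accuracy(self):
        X, y = _toy_separable(margin=5.0)
        cfg = dn.TrainingConfig(epochs_init=100, epochs_joint=200,
                                n_hidden=8, batch_size=50, seed=0,
                                learning_rate=3e-3)
        params, hist = dn.train(X, y, config=cfg)
        assert hist["train_accuracy"].iloc[-1] == 1.0

    def test_heavy_sparsity_kills_null_genes_keeps_signal(self):
        """With a strong penalty only the informative genes survive."""
        rng = np.random.default_rng(1)
        X, y = _toy_separable(n=100, margin=4.0)
        X = np.hstack([X, rng.normal(size=(100, 48))])  # 48 null genes
        cfg = dn.TrainingConfig(epochs_init=150, epochs_joint=150,
                                n_hidden=8, batch_size=50, seed=0,
                                learning_rate=1e-2, lambda_=0.3)
        params, _ = dn.train(X, y, config=cfg)
        w = dn.gene_weight_rss(params.W1, [f"g{i}" for i in range(50)])
        assert (w["weight"] < 0.01).mean() > 0.9
        assert set(w["weight"].nlargest(2).index) == {"g0", "g1"}

    def test_deterministic_rerun(self):
        X, y = _toy_separable(n=60)
        cfg = dn.TrainingConfig(epochs_init=30, epochs_joint=40, n_hidden=4,
                                batch_size=30, seed=7)
        p1, h1 = dn.train(X, y, config=cfg)
        p2, h2 = dn.train(X, y, config=cfg)
        assert h1["total"].iloc[-1] == h2["total"].iloc[-1]
        np.testing.assert_array_equal(p1.W1, p2.W1)

    def test_phase1_loss_decreases(self):
        X, y = _toy_separable(n=80)
        cfg = dn.TrainingConfig(epochs_init=100, epochs_joint=0, n_hidden=4,
                                batch_size=40, seed=2, learning_rate=1e-2)
        _, hist = dn.train(X, y, config=cfg, track_every=1)
        init = hist[hist["phase"] == "init"]
        assert init["total"].iloc[-1] <= init["total"].iloc[0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dn.train(np.zeros((10, 2)), np.zeros(10))


class TestCrossValidate:
    def test_default_grid_contains_canonical_optimum(self):
        assert (2, 2.0, 0.004) in dn.DEFAULT_CV_GRID

    def test_single_cell_grid_returned(self):
        X, y = _toy_separable(n=60)
        cfg = dn.TrainingConfig(epochs_init=20, epochs_joint=0, n_hidden=4,
                                batch_size=30, seed=0, learning_rate=1e-2)
        best, table = dn.cross_validate(X, y, [(2, 2.0, 0.004)], cfg,
                                        folds=3)
        assert best == (2, 2.0, 0.004)
        assert len(table) == 1

    def test_tie_breaks_toward_sparser_simpler(self):
        X, y = _toy_separable(n=60, margin=6.0)
        cfg = dn.TrainingConfig(epochs_init=40, epochs_joint=0, n_hidden=4,
                                batch_size=30, seed=0, learning_rate=1e-2)
        grid = [(2, 2.0, 0.001), (3, 2.0, 0.004), (2, 2.0, 0.004)]
        best, table = dn.cross_validate(X, y, grid, cfg, folds=3)
        assert table["mean_val_accuracy"].nunique() == 1  # all perfect
        assert best == (2, 2.0, 0.004)

    def test_accuracy_matches_refit(self):
        X, y = _toy_separable(n=60)
        cfg = dn.TrainingConfig(epochs_init=25, epochs_joint=0, n_hidden=4,
                                batch_size=30, seed=1, learning_rate=1e-2)
        _, table = dn.cross_validate(X, y, [(2, 0.0, 0.0)], cfg, folds=3)
        import dataclasses
        from sklearn.model_selection import StratifiedKFold
        cell_cfg = dataclasses.replace(cfg, K=2, alpha=0.0, lambda_=0.0)
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=cfg.seed)
        accs = []
        for tr, va in skf.split(X, y):
            params, _ = dn.train(X[tr], y[tr], config=cell_cfg,
                                 track_every=cfg.epochs_init)
            prob = dn.forward_output(params, dn.forward_hidden(params, X[va]))
            accs.append(np.mean((prob >= 0.5) == (y[va] >= 0.5)))
        assert table["mean_val_accuracy"].iloc[0] == \
            pytest.approx(np.mean(accs))

    def test_empty_grid(self):
        with pytest.raises(ValueError):
            dn.cross_validate(np.zeros((10, 2)), np.zeros(10), [])


class TestGeneWeights:
    def test_small_example(self):
        W1 = np.array([[3.0, 4.0], [6.0, 8.0]])  # rss 5 and 10
        w = dn.gene_weight_rss(W1, ["a", "b"])
        assert w.loc["a", "rss"] == pytest.approx(5.0)
        assert w.loc["a", "weight"] == pytest.approx(0.5)
        assert w.loc["b", "weight"] == pytest.approx(1.0)

    def test_zero_row(self):
        W1 = np.array([[0.0, 0.0], [1.0, 0.0]])
        w = dn.gene_weight_rss(W1, ["a", "b"])
        assert w.loc["a", "weight"] == 0.0

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            w = dn.gene_weight_rss(np.zeros((3, 2)), ["a", "b", "c"])
        assert (w["weight"] == 0).all()

    def test_matches_row_norm_oracle(self, rng):
        W1 = rng.normal(size=(30, 6))
        w = dn.gene_weight_rss(W1, [f"g{i}" for i in range(30)])
        expected = np.linalg.norm(W1, axis=1)
        np.testing.assert_allclose(w["rss"], expected, atol=1e-12)
        np.testing.assert_allclose(w["weight"], expected / expected.max(),
                                   atol=1e-12)
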