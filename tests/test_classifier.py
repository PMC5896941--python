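"""CNN primitives against brute-force oracles, and head training behavior."""

from __future__ import annotations

import numpy as np
import pytest

from ki67seg import classifier as clf


def brute_conv(image, kernel):
    h, w = image.shape
    kh, kw = kernel.shape
    out = np.zeros((h - kh + 1, w - kw + 1))
    for q in range(out.shape[0]):
        for r in range(out.shape[1]):
            s = 0.0
            for m in range(kh):
                for n in range(kw):
                    s += image[q + m, r + n] * kernel[m, n]
            out[q, r] = s
    return out


def brute_pool(x, window, stride):
    h, w = x.shape
    rows = range(0, h - window + 1, stride)
    cols = range(0, w - window + 1, stride)
    out = np.zeros((len(rows), len(cols)))
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            out[i, j] = max(x[r + a, c + b] for a in range(window) for b in range(window))
    return out


class TestConv2d:
    def test_identity_kernel(self, rng):
        image = rng.random((5, 5))
        assert np.array_equal(clf.conv2d_xcorr(image, np.array([[1.0]])), image)

    def test_hand_example(self):
        out = clf.conv2d_xcorr([[1, 2], [3, 4]], [[1, 0], [0, 1]])
        assert out.shape == (1, 1)
        assert out[0, 0] == 5  # 1*1 + 4*1

    def test_matches_bruteforce(self, rng):
        for _ in range(100):
            image = rng.random((6, 6))
            kernel = rng.random((3, 3))
            assert np.allclose(clf.conv2d_xcorr(image, kernel), brute_conv(image, kernel))

    def test_kernel_too_large(self):
        with pytest.raises(ValueError):
            clf.conv2d_xcorr(np.zeros((2, 2)), np.zeros((3, 3)))


class TestReluAndPool:
    def test_relu_values_and_idempotence(self, rng):
        assert list(clf.relu(np.array([-1.0, 0.0, 2.0]))) == [0.0, 0.0, 2.0]
        assert not clf.relu(-np.abs(rng.random(10))).any()
        x = rng.normal(size=20)
        assert np.array_equal(clf.relu(clf.relu(x)), clf.relu(x))

    def test_pool_hand_example(self):
        assert clf.max_pool(np.array([[1.0, 2], [3, 4]]), 2, 2) == np.array([[4.0]])

    def test_pool_constant_input(self):
        assert np.all(clf.max_pool(np.full((8, 8), 3.5), 2, 2) == 3.5)

    def test_pool_matches_bruteforce(self, rng):
        for _ in range(100):
            x = rng.random((8, 8))
            window = int(rng.integers(1, 4))
            stride = int(rng.integers(1, 4))
            assert np.array_equal(clf.max_pool(x, window, stride), brute_pool(x, window, stride))

    def test_pool_bad_stride(self):
        with pytest.raises(ValueError):
            clf.max_pool(np.zeros((4, 4)), 2, 0)


class TestDenseSoftmaxLabelsLoss:
    def test_dense_identity(self, rng):
        x = rng.random(4)
        assert np.allclose(clf.dense_forward(x, np.eye(4), np.zeros(4)), x)

    def test_dense_hand_example(self):
        y = clf.dense_forward([1.0, 1.0], [[2.0], [3.0]], [-1.0])
        assert np.allclose(y, [4.0])

    def test_dense_linearity(self, rng):
        x = rng.random(5)
        w = rng.random((5, 3))
        assert np.allclose(
            clf.dense_forward(3.7 * x, w, np.zeros(3)),
            3.7 * clf.dense_forward(x, w, np.zeros(3)),
        )

    def test_dense_dimension_mismatch(self):
        with pytest.raises(ValueError):
            clf.dense_forward(np.zeros(3), np.zeros((4, 2)), np.zeros(2))

    def test_softmax_symmetry_and_uniform(self):
        assert np.allclose(clf.softmax(np.array([0.0, 0.0])), [0.5, 0.5])
        assert np.allclose(clf.softmax(np.full(7, 42.0)), 1 / 7)

    def test_softmax_matches_unshifted_evaluation(self):
        z = np.array([1.0, 2.0, 3.0])
        direct = np.exp(z) / np.exp(z).sum()
        assert np.allclose(clf.softmax(z), direct, atol=1e-12)

    def test_softmax_shift_invariance_and_overflow(self, rng):
        z = rng.normal(size=6)
        assert np.allclose(clf.softmax(z), clf.softmax(z + 123.4), atol=1e-12)
        big = clf.softmax(np.array([1e4, 0.0]))
        assert np.isfinite(big).all() and big.sum() == pytest.approx(1.0)

    def test_smooth_labels(self):
        assert np.array_equal(clf.smooth_labels(np.array([0.0, 1.0]), 0.0), [0.0, 1.0])
        assert np.allclose(clf.smooth_labels(np.array([0.0, 1.0]), 0.1, 2), [0.05, 0.95])
        for k, eps in ((2, 0.1), (5, 0.3), (10, 0.05)):
            one_hot = np.eye(k)[0]
            assert clf.smooth_labels(one_hot, eps, k).sum() == pytest.approx(1.0)

    def test_smooth_labels_rejects_non_indicator(self):
        with pytest.raises(ValueError):
            clf.smooth_labels(np.array([0.2, 0.8]), 0.1)

    def test_cross_entropy_hand_value(self):
        loss = clf.cross_entropy([0.0, 1.0], [0.5, 0.5], 2)
        assert loss == pytest.approx(-0.5 * np.log(0.5))
        assert loss == pytest.approx(0.34657359, abs=1e-8)

    def test_cross_entropy_perfect_prediction_near_zero(self):
        assert clf.cross_entropy([0.0, 1.0], [1e-12, 1.0 - 1e-12], 2) < 1e-10

    def test_cross_entropy_matches_termwise_oracle(self, rng):
        for _ in range(50):
            m = int(rng.integers(2, 6))
            t = rng.random(m)
            t /= t.sum()
            p = rng.random(m) + 1e-3
            p /= p.sum()
            oracle = -sum(t[j] * np.log(p[j]) for j in range(m)) / m
            assert clf.cross_entropy(t, p, m) == pytest.approx(oracle, abs=1e-12)

    def test_cross_entropy_clamps_zero_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            loss = clf.cross_entropy([1.0, 0.0], [0.0, 1.0], 2)
        assert np.isfinite(loss)


class TestOptimizer:
    def test_zero_momentum_is_plain_gd(self, rng):
        p = rng.random(4)
        g = rng.random(4)
        p2, v2 = clf.sgd_momentum_step(p, g, np.zeros(4), lr=0.1, momentum=0.0)
        assert np.allclose(p2, p - 0.1 * g)
        assert np.allclose(v2, g)

    def test_momentum_accumulates(self):
        p, v = np.zeros(1), np.zeros(1)
        g = np.ones(1)
        p, v = clf.sgd_momentum_step(p, g, v, lr=1.0, momentum=0.9)
        p1 = p.copy()
        p, v = clf.sgd_momentum_step(p, g, v, lr=1.0, momentum=0.9)
        assert (p1 - p)[0] == pytest.approx(1.9)  # second step is 1 + 0.9

    def test_quadratic_descent_monotone(self):
        w, v = np.array([5.0]), np.zeros(1)
        prev = abs(w[0])
        for _ in range(20):
            w, v = clf.sgd_momentum_step(w, w.copy(), v, lr=0.05, momentum=0.0)
            assert abs(w[0]) < prev
            prev = abs(w[0])

    def test_exponential_decay(self):
        assert clf.apply_exponential_decay(0.5, 0.9, 0) == 0.5
        assert clf.apply_exponential_decay(0.01, 0.94, 2) == pytest.approx(0.008836)
        values = [clf.apply_exponential_decay(1.0, 0.7, e) for e in range(6)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_decay_factor_validated(self):
        with pytest.raises(ValueError):
            clf.apply_exponential_decay(1.0, 1.5, 1)


class TestHeadGradient:
    def test_analytic_matches_finite_differences(self, rng):
        d, m, n = 4, 2, 7
        w = rng.normal(size=(d, m))
        b = rng.normal(size=m)
        x = rng.normal(size=(n, d))
        t = clf.smooth_labels(np.eye(m)[rng.integers(0, m, n)], 0.1, m)
        _, dw, db = clf.head_loss_and_grad(w, b, x, t)
        eps = 1e-6

        def loss_at(wi, bi):
            return clf.head_loss_and_grad(wi, bi, x, t)[0]

        for idx in np.ndindex(*w.shape):
            wp, wm = w.copy(), w.copy()
            wp[idx] += eps
            wm[idx] -= eps
            fd = (loss_at(wp, b) - loss_at(wm, b)) / (2 * eps)
            assert dw[idx] == pytest.approx(fd, rel=1e-5, abs=1e-8)
        for j in range(m):
            bp, bm = b.copy(), b.copy()
            bp[j] += eps
            bm[j] -= eps
            fd = (loss_at(w, bp) - loss_at(w, bm)) / (2 * eps)
            assert db[j] == pytest.approx(fd, rel=1e-5, abs=1e-8)


def two_gaussians(n=500, sep=6.0, seed=7):
    rng = np.random.default_rng(seed)
    half = n // 2
    x = np.vstack(
        [rng.normal(0.0, 1.0, (half, 2)), rng.normal(sep, 1.0, (n - half, 2))]
    )
    y = np.array([0] * half + [1] * (n - half))
    return x, y


class TestTrainHead:
    def test_separable_features_high_validation_accuracy(self):
        x, y = two_gaussians()
        head, history = clf.train_head(x, y, clf.TrainingConfig(seed=7))
        assert history["val_accuracy"].iloc[-1] >= 0.95

    def test_shuffled_labels_chance_accuracy(self):
        x, y = two_gaussians()
        rng = np.random.default_rng(3)
        head, history = clf.train_head(x, rng.permutation(y), clf.TrainingConfig(seed=3))
        assert history["val_accuracy"].iloc[-1] == pytest.approx(0.5, abs=0.1)

    def test_training_is_seed_deterministic(self):
        x, y = two_gaussians(n=120)
        config = clf.TrainingConfig(seed=11, iterations=300)
        h1, _ = clf.train_head(x, y, config)
        h2, _ = clf.train_head(x, y, config)
        assert np.array_equal(h1.weights, h2.weights)
        assert np.array_equal(h1.bias, h2.bias)

    def test_loss_decreases_over_first_epoch(self):
        x, y = two_gaussians(n=300)
        config = clf.TrainingConfig(seed=5, iterations=300, eval_interval=10)
        _, history = clf.train_head(x, y, config)
        assert history["train_loss"].iloc[-1] < history["train_loss"].iloc[0]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            clf.train_head(np.random.default_rng(0).random((20, 2)), np.zeros(20, dtype=int))


class TestPredictTile:
    def test_zero_head_gives_even_split(self):
        backbone = clf.TinyBackbone(seed=0)
        head = clf.SoftmaxHead(weights=np.zeros((backbone.n_features, 2)), bias=np.zeros(2))
        tile = np.zeros((64, 64, 3), dtype=np.uint8)
        probs = clf.predict_tile(tile, backbone, head)
        assert probs.p_tumor == pytest.approx(0.5)
        assert probs.p_non_tumor == pytest.approx(0.5)

    def test_logit_shift_invariance(self, rng):
        backbone = clf.TinyBackbone(seed=0)
        w = rng.normal(size=(backbone.n_features, 2))
        tile = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        p1 = clf.predict_tile(tile, backbone, clf.SoftmaxHead(weights=w, bias=np.zeros(2)))
        p2 = clf.predict_tile(tile, backbone, clf.SoftmaxHead(weights=w, bias=np.full(2, 9.3)))
        assert p1.p_tumor == pytest.approx(p2.p_tumor, abs=1e-12)

    def test_feature_length_mismatch(self):
        backbone = clf.TinyBackbone(seed=0)
        head = clf.SoftmaxHead(weights=np.zeros((backbone.n_features + 1, 2)), bias=np.zeros(2))
        with pytest.raises(ValueError):
            clf.predict_tile(np.zeros((64, 64, 3)), backbone, head)

    def test_backbone_deterministic(self, rng):
        tile = rng.integers(0, 256, (64, 64, 3), dtype=np.uint8)
        b1 = clf.TinyBackbone(seed=4)
        b2 = clf.TinyBackbone(seed=4)
        assert np.array_equal(b1.embed(tile), b2.embed(tile))
        assert np.array_equal(b1.embed(tile), b1.embed(tile))


class TestFullFinetune:
    def _tiny_tiles(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        tiles = np.zeros((n, 64, 64, 3), dtype=np.uint8)
        labels = []
        for i in range(n):
            if i % 2 == 0:
                tiles[i, ..., 0] = rng.integers(150, 200)  # reddish -> tumor
                labels.append("tumor")
            else:
                tiles[i, ..., 2] = rng.integers(150, 200)  # bluish -> non_tumor
                labels.append("non_tumor")
        return tiles, labels

    def test_backbone_kernels_update_and_loss_decreases(self):
        tiles, labels = self._tiny_tiles()
        config = clf.TrainingConfig(
            mode="full_finetune", learning_rate=1e-3, lr_exp_decay=0.9,
            momentum_decay=0.9, batch_size=16, epochs=4, seed=0,
        )
        backbone = clf.TinyBackbone(seed=0)
        before = backbone.kernels1.copy()
        model, history = clf.train_full_finetune(tiles, labels, config, backbone)
        assert not np.array_equal(model.backbone.kernels1, before)
        assert history["train_loss"].iloc[-1] < history["train_loss"].iloc[0]

    def test_finetune_deterministic(self):
        tiles, labels = self._tiny_tiles()
        config = clf.TrainingConfig(
            mode="full_finetune", learning_rate=1e-3, batch_size=16, epochs=2, seed=1
        )
        m1, _ = clf.train_full_finetune(tiles, labels, config, clf.TinyBackbone(seed=0))
        m2, _ = clf.train_full_finetune(tiles, labels, config, clf.TinyBackbone(seed=0))
        assert np.array_equal(m1.head.weights, m2.head.weights)
        assert np.array_equal(m1.backbone.kernels2, m2.backbone.kernels2)

    def test_backbone_gradient_matches_finite_differences(self, rng):
        # check one kernel entry of each conv block through the full chain
        backbone = clf.TinyBackbone(channels1=2, channels2=3, kernel_size=3, seed=2)
        x = rng.random((2, 64, 64, 3))
        w = rng.normal(size=(backbone.n_features, 2))
        b = np.zeros(2)
        t = clf.smooth_labels(np.eye(2)[np.array([0, 1])], 0.1, 2)

        def loss():
            feats, _ = backbone._forward(x)
            return clf.head_loss_and_grad(w, b, feats, t)[0]

        feats, cache = backbone._forward(x)
        _, dw, db = clf.head_loss_and_grad(w, b, feats, t)
        p = clf.softmax(clf.dense_forward(feats, w, b))
        dz = (p - t) / (2 * 2)
        dk1, db1, dk2, db2 = backbone._backward(cache, dz @ w.T)
        eps = 1e-6
        for arr, grad, idx in (
            (backbone.kernels1, dk1, (1, 0, 2, 2)),
            (backbone.kernels2, dk2, (2, 1, 0, 1)),
            (backbone.bias1, db1, (0,)),
            (backbone.bias2, db2, (1,)),
        ):
            orig = arr[idx]
            arr[idx] = orig + eps
            up = loss()
            arr[idx] = orig - eps
            down = loss()
            arr[idx] = orig
            assert grad[idx] == pytest.approx((up - down) / (2 * eps), rel=1e-4, abs=1e-9)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        backbone = clf.TinyBackbone(seed=3)
        head = clf.SoftmaxHead(
            weights=rng.normal(size=(backbone.n_features, 2)),
            bias=rng.normal(size=2),
            feature_mean=rng.normal(size=backbone.n_features),
            feature_scale=np.abs(rng.normal(size=backbone.n_features)) + 0.1,
        )
        model = clf.TileClassifier(backbone=backbone, head=head)
        clf.save_model(model, tmp_path / "m.npz", clf.TrainingConfig())
        loaded = clf.load_model(tmp_path / "m.npz")
        tile = rng.integers(0, 256, (1, 64, 64, 3), dtype=np.uint8)
        assert np.allclose(model.predict_proba(tile), loaded.predict_proba(tile))
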