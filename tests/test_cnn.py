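"""CNN contracts: init bounds, layer shapes, gradient oracle, training."""

import numpy as np
import pytest

from semgfat import cnn as C


@pytest.fixture(scope="module")
def arch120():
    return C.CNNArchitecture(T=120)


@pytest.fixture(scope="module")
def arch160():
    return C.CNNArchitecture(T=160)


class TestInit:
    def test_bounds_follow_fan_in(self, arch120):
        model = C.init_model(arch120, seed=0)
        for name, bound in [
            ("k2", 1 / np.sqrt(6)),
            ("b2", 1 / np.sqrt(6)),
            ("k3", 1 / np.sqrt(10)),
            ("W4", 1 / np.sqrt(480)),
            ("W5", 1 / np.sqrt(100)),
        ]:
            p = model.params()[name]
            assert np.all(np.abs(p) <= bound), name

    def test_inverse_fan_in_mode(self, arch120):
        model = C.init_model(arch120, seed=0, init_mode="inv")
        assert np.all(np.abs(model.W4) <= 1 / 480)

    def test_seed_determinism(self, arch120):
        a = C.init_model(arch120, seed=7)
        b = C.init_model(arch120, seed=7)
        for k in a.params():
            np.testing.assert_array_equal(a.params()[k], b.params()[k])

    def test_seeds_differ(self, arch120):
        a = C.init_model(arch120, seed=7)
        b = C.init_model(arch120, seed=8)
        assert any(
            not np.array_equal(a.params()[k], b.params()[k]) for k in a.params()
        )


class TestForward:
    def test_layer_shapes_slow_speed(self, arch120, rng):
        model = C.init_model(arch120, seed=1)
        scores, cache = C.forward(model, rng.uniform(0, 100, (6, 120)))
        assert cache["y2"].shape == (1, 10, 120)  # 10 maps of 1 x 120
        assert cache["y3"].shape == (1, 10, 4, 12)  # 40 maps of 1 x 12
        assert cache["y4"].shape == (1, 100)
        assert scores.shape == (4,)
        assert np.all((scores > 0) & (scores < 1))

    def test_layer_shapes_fast_speed(self, arch160, rng):
        model = C.init_model(arch160, seed=1)
        _, cache = C.forward(model, rng.uniform(0, 100, (3, 6, 160)))
        assert cache["y2"].shape == (3, 10, 160)
        assert cache["y3"].shape == (3, 10, 4, 16)  # 40 maps of 1 x 16

    def test_zero_parameters_give_half_scores(self, arch120):
        model = C.init_model(arch120, seed=0)
        for p in model.params().values():
            p[...] = 0.0
        scores, _ = C.forward(model, np.random.default_rng(0).normal(size=(6, 120)))
        np.testing.assert_allclose(scores, 0.5)

    def test_shape_mismatch_rejected(self, arch120):
        model = C.init_model(arch120, seed=0)
        with pytest.raises(ValueError, match="expected windows"):
            C.forward(model, np.zeros((6, 160)))

    def test_stride_not_dividing_length_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            C.CNNArchitecture(T=125).validate()


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        scores = np.array([[0.0, 1.0, 0.0, 0.0]])
        assert C.loss(scores, np.array([1])) == 0.0

    def test_uniform_half_scores(self):
        scores = np.full((1, 4), 0.5)
        assert C.loss(scores, np.array([2])) == pytest.approx(0.25)

    def test_batch_loss_is_mean_of_singles(self, rng):
        scores = rng.uniform(0.01, 0.99, (5, 4))
        labels = rng.integers(0, 4, 5)
        singles = [C.loss(scores[i : i + 1], labels[i : i + 1]) for i in range(5)]
        assert C.loss(scores, labels) == pytest.approx(np.mean(singles))


def _finite_difference_check(arch, loss_kind, rng, n_per_group=12, tol=1e-4):
    model = C.init_model(arch, seed=2)
    X = rng.uniform(0, 100, (2, 6, arch.T))
    y = np.array([0, 3])
    _, cache = C.forward(model, X)
    grads = C.backward(model, cache, y, loss_kind)
    eps = 1e-5
    for name, p in model.params().items():
        flat = p.ravel()
        idxs = rng.choice(flat.size, size=min(n_per_group, flat.size), replace=False)
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + eps
            lp = C.loss(C.forward(model, X)[0], y, loss_kind)
            flat[i] = orig - eps
            lm = C.loss(C.forward(model, X)[0], y, loss_kind)
            flat[i] = orig
            fd = (lp - lm) / (2 * eps)
            an = grads[name].ravel()[i]
            assert abs(fd - an) <= tol * max(abs(fd), abs(an), 1e-6), (
                f"{name}[{i}]: analytic {an}, finite-difference {fd}"
            )


class TestBackward:
    def test_gradients_match_finite_differences_mse(self, arch120, rng):
        _finite_difference_check(arch120, "mse", rng)

    def test_gradients_match_finite_differences_cross_entropy(self, rng):
        arch = C.CNNArchitecture(T=120, output_activation="softmax")
        _finite_difference_check(arch, "cross_entropy", rng)

    def test_duplicated_sample_batch_equals_single(self, arch120, rng):
        model = C.init_model(arch120, seed=3)
        x = rng.uniform(0, 100, (6, 120))
        _, cache1 = C.forward(model, x[None])
        g1 = C.backward(model, cache1, np.array([2]))
        _, cache3 = C.forward(model, np.stack([x, x, x]))
        g3 = C.backward(model, cache3, np.array([2, 2, 2]))
        for k in g1:
            np.testing.assert_allclose(g3[k], g1[k], rtol=1e-10, atol=1e-14)


class TestLayerRates:
    def test_formulas(self, arch120):
        lam = 0.8
        rates = C.layer_rates(arch120, lam)
        assert rates["C2"] == pytest.approx(2 * lam / (120 * np.sqrt(6)))
        assert rates["C3"] == pytest.approx(2 * lam / (12 * np.sqrt(10)))
        assert rates["F4"] == pytest.approx(lam / np.sqrt(480))
        assert rates["O5"] == pytest.approx(lam / 10.0)

    def test_linearity_in_base_rate(self, arch120):
        r1 = C.layer_rates(arch120, 0.05)
        r2 = C.layer_rates(arch120, 0.10)
        for k in r1:
            assert r2[k] == pytest.approx(2 * r1[k])

    def test_nonpositive_rate_rejected(self, arch120):
        with pytest.raises(ValueError):
            C.layer_rates(arch120, 0.0)


def _toy_two_class(rng, n=60, T=120):
    """Linearly separable envelope-like windows: two amplitude levels."""
    X = np.empty((n, 6, T))
    y = np.empty(n, dtype=int)
    for i in range(n):
        lvl = 20.0 if i % 2 == 0 else 60.0
        X[i] = lvl + rng.normal(0, 2.0, (6, T))
        y[i] = 0 if i % 2 == 0 else 1
    return X, y


class TestTraining:
    def test_learns_separable_toy_problem(self, arch120, rng):
        X, y = _toy_two_class(rng)
        model = C.init_model(arch120, seed=0)
        best, hist = C.train(
            model, X, y, X, y, C.TrainConfig(base_rate=5.0, max_iterations=400, seed=0)
        )
        pred, _ = C.predict(best, X)
        assert np.mean(pred == y) >= 0.99
        assert hist.best_iteration <= 400

    def test_smoothed_training_loss_decreases(self, arch120, rng):
        X, y = _toy_two_class(rng)
        model = C.init_model(arch120, seed=0)
        _, hist = C.train(
            model, X, y, X, y, C.TrainConfig(base_rate=5.0, max_iterations=300, seed=0)
        )
        smooth = np.convolve(hist.train_loss, np.ones(100) / 100, mode="valid")
        assert smooth[-1] < smooth[0]

    def test_best_model_validation_loss_is_minimum(self, arch120, rng):
        X, y = _toy_two_class(rng)
        model = C.init_model(arch120, seed=0)
        best, hist = C.train(
            model, X, y, X, y, C.TrainConfig(base_rate=5.0, max_iterations=200, seed=0)
        )
        assert hist.best_val_loss == pytest.approx(hist.val_loss.min())
        v_scores, _ = C.forward(best, X)
        assert C.loss(v_scores, y) == pytest.approx(hist.best_val_loss)

    def test_training_determinism(self, arch120, rng):
        X, y = _toy_two_class(rng, n=20)
        cfg = C.TrainConfig(base_rate=1.0, max_iterations=50, seed=5)
        m1, _ = C.train(C.init_model(arch120, seed=5), X, y, X, y, cfg)
        m2, _ = C.train(C.init_model(arch120, seed=5), X, y, X, y, cfg)
        for k in m1.params():
            np.testing.assert_array_equal(m1.params()[k], m2.params()[k])

    def test_divergence_reported_with_iteration(self, arch120, rng):
        X, y = _toy_two_class(rng, n=10)
        model = C.init_model(arch120, seed=0)
        model.W5[...] = np.nan  # force non-finite loss immediately
        with pytest.raises(C.TrainingError, match="iteration"):
            C.train(model, X, y, X, y, C.TrainConfig(max_iterations=5))

    def test_empty_sets_rejected(self, arch120):
        with pytest.raises(ValueError):
            C.train(
                C.init_model(arch120, seed=0),
                np.empty((0, 6, 120)),
                np.empty(0, dtype=int),
                np.empty((0, 6, 120)),
                np.empty(0, dtype=int),
            )


class TestPredict:
    def test_argmax_and_tie_break(self, arch120):
        model = C.init_model(arch120, seed=0)
        for p in model.params().values():
            p[...] = 0.0
        # all scores 0.5: tie resolves to the lowest class index
        pred, scores = C.predict(model, np.zeros((2, 6, 120)))
        assert scores.shape == (2, 4)
        np.testing.assert_array_equal(pred, [0, 0])

    def test_batch_predict_equals_map_of_singles(self, arch120, rng):
        model = C.init_model(arch120, seed=4)
        X = rng.uniform(0, 100, (5, 6, 120))
        batch_pred, batch_scores = C.predict(model, X)
        for i in range(5):
            p, s = C.predict(model, X[i : i + 1])
            assert p[0] == batch_pred[i]
            np.testing.assert_allclose(s[0], batch_scores[i], rtol=1e-12)


class TestSerialization:
    def test_save_load_roundtrip(self, arch120, tmp_path, rng):
        model = C.init_model(arch120, seed=6)
        path = tmp_path / "model.npz"
        C.save_model(model, path)
        back = C.load_model(path)
        X = rng.uniform(0, 100, (3, 6, 120))
        np.testing.assert_allclose(
            C.forward(model, X)[0], C.forward(back, X)[0], rtol=1e-12
        )
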