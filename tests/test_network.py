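import numpy as np
import pytest

from skelact import (
    NetworkConfig,
    apply_update,
    backward,
    cross_entropy,
    forward,
    init_parameters,
    predict_proba,
    train,
)

from oracles import finite_difference_gradients


def small_config(**kw):
    defaults = dict(
        input_dim=6, hidden1=5, hidden2=4, output_dim=3, seed=3,
    )
    defaults.update(kw)
    return NetworkConfig(**defaults)


class TestConfig:
    def test_defaults_follow_reference_setting(self):
        cfg = NetworkConfig(output_dim=65)
        assert (cfg.input_dim, cfg.hidden1, cfg.hidden2) == (93, 85, 80)
        assert cfg.learning_rate == 0.01
        assert cfg.max_epochs == 1000
        assert cfg.min_gradient == 1e-6
        assert cfg.patience == 5

    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            NetworkConfig(output_dim=0)
        with pytest.raises(ValueError):
            NetworkConfig(output_dim=2, learning_rate=0.0)
        with pytest.raises(ValueError):
            NetworkConfig(output_dim=2, validation_fraction=1.0)


class TestInitParameters:
    def test_shapes_with_bias_rows(self):
        params = init_parameters(NetworkConfig(output_dim=65))
        assert params.w.shape == (94, 85)
        assert params.w_prime.shape == (86, 80)
        assert params.w_dprime.shape == (81, 65)

    def test_seeded_determinism(self):
        a = init_parameters(small_config())
        b = init_parameters(small_config())
        np.testing.assert_array_equal(a.w, b.w)
        np.testing.assert_array_equal(a.w_dprime, b.w_dprime)

    def test_zero_scale_gives_uniform_output(self, rng):
        params = init_parameters(small_config(init_scale=0.0))
        trace = forward(params, rng.normal(size=6))
        np.testing.assert_array_equal(trace.o, np.full(3, 1 / 3))

    def test_bounded_by_scale(self):
        params = init_parameters(small_config(init_scale=0.05))
        for m in (params.w, params.w_prime, params.w_dprime):
            assert np.abs(m).max() <= 0.05


class TestForward:
    def test_softmax_closed_form(self):
        # logits (1,2,3) through a network reduced to the output layer
        params = init_parameters(small_config(init_scale=0.0))
        params.w_dprime[0] = [1.0, 2.0, 3.0]  # bias row only => logits
        trace = forward(params, np.zeros(6))
        z = np.array([1.0, 2.0, 3.0])
        expected = np.exp(z) / np.exp(z).sum()
        np.testing.assert_allclose(trace.o, expected, atol=1e-12)
        np.testing.assert_allclose(
            trace.o, [0.09003057, 0.24472847, 0.66524096], atol=1e-8
        )

    def test_probabilities_sum_to_one(self, rng):
        params = init_parameters(small_config())
        for _ in range(10):
            trace = forward(params, rng.normal(0, 50, size=6))
            assert abs(trace.o.sum() - 1.0) < 1e-12
            assert (trace.o >= 0).all()

    def test_bias_units_fixed_to_one(self, rng):
        trace = forward(init_parameters(small_config()), rng.normal(size=6))
        assert trace.x[0] == trace.h[0] == trace.h_prime[0] == 1.0

    def test_hidden_activations_open_interval(self, rng):
        trace = forward(init_parameters(small_config()), rng.normal(size=6))
        assert ((trace.h[1:] > 0) & (trace.h[1:] < 1)).all()
        assert ((trace.h_prime[1:] > 0) & (trace.h_prime[1:] < 1)).all()

    def test_shift_invariance_of_softmax(self):
        params = init_parameters(small_config(init_scale=0.0))
        params.w_dprime[0] = [1.0, 2.0, 3.0]
        base = forward(params, np.zeros(6)).o
        params.w_dprime[0] = np.array([1.0, 2.0, 3.0]) + 500.0
        shifted = forward(params, np.zeros(6)).o
        np.testing.assert_allclose(shifted, base, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            forward(init_parameters(small_config()), np.zeros(7))


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        assert cross_entropy(np.array([0.0, 1.0, 0.0]), 1) == 0.0

    def test_half_probability_ln2(self):
        assert cross_entropy(np.array([0.5, 0.5]), 1) == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_non_negative(self, rng):
        for _ in range(20):
            o = rng.dirichlet(np.ones(4))
            assert cross_entropy(o, int(rng.integers(4))) >= 0

    def test_clamped_at_zero_probability(self):
        assert np.isfinite(cross_entropy(np.array([1.0, 0.0]), 1))

    def test_invalid_target(self):
        with pytest.raises(IndexError):
            cross_entropy(np.array([0.5, 0.5]), 2)


class TestBackward:
    def test_vanishing_gradients_at_correct_confident_prediction(self):
        params = init_parameters(small_config(init_scale=0.0))
        params.w_dprime[0] = [200.0, 0.0, 0.0]
        trace = forward(params, np.zeros(6))
        grads = backward(params, trace, 0)
        assert grads.max_abs() < 1e-12

    def test_deterministic(self, rng):
        params = init_parameters(small_config())
        x = rng.normal(size=6)
        trace = forward(params, x)
        g1 = backward(params, trace, 1)
        g2 = backward(params, trace, 1)
        np.testing.assert_array_equal(g1.d_w, g2.d_w)

    def test_matches_finite_differences_10_7_5_3(self, rng):
        cfg = NetworkConfig(input_dim=10, hidden1=7, hidden2=5, output_dim=3, seed=9)
        params = init_parameters(cfg)
        x = rng.normal(size=10)
        target = 2
        trace = forward(params, x)
        grads = backward(params, trace, target)

        def loss():
            return cross_entropy(forward(params, x).o, target)

        fd = finite_difference_gradients(
            loss, [params.w, params.w_prime, params.w_dprime]
        )
        for analytic, numeric in zip(
            (grads.d_w, grads.d_w_prime, grads.d_w_dprime), fd
        ):
            np.testing.assert_allclose(analytic, numeric, rtol=1e-6, atol=1e-9)


class TestApplyUpdate:
    def test_zero_gradients_no_change(self, rng):
        params = init_parameters(small_config())
        trace = forward(params, rng.normal(size=6))
        grads = backward(params, trace, 0)
        for m in (grads.d_w, grads.d_w_prime, grads.d_w_dprime):
            m[:] = 0.0
        out = apply_update(params, grads, 0.5)
        np.testing.assert_array_equal(out.w, params.w)

    def test_descent_direction_decreases_loss(self, rng):
        params = init_parameters(small_config())
        x = rng.normal(size=6)
        trace = forward(params, x)
        before = cross_entropy(trace.o, 1)
        grads = backward(params, trace, 1)
        after = cross_entropy(forward(apply_update(params, grads, 1e-4), x).o, 1)
        assert after < before

    def test_update_is_reversible(self, rng):
        params = init_parameters(small_config())
        trace = forward(params, rng.normal(size=6))
        grads = backward(params, trace, 2)
        stepped = apply_update(params, grads, 0.1)
        neg = backward(params, trace, 2)
        for m in (neg.d_w, neg.d_w_prime, neg.d_w_dprime):
            m *= -1.0
        back = apply_update(stepped, neg, 0.1)
        np.testing.assert_allclose(back.w, params.w, atol=1e-12)


def blobs(rng, n_per_class=20, dim=4, spread=6.0):
    means = np.eye(3, dim) * spread
    X = np.vstack([rng.normal(means[c], 0.5, size=(n_per_class, dim)) for c in range(3)])
    y = np.repeat(np.arange(3), n_per_class)
    return X, y


class TestTrain:
    def test_zero_epochs_returns_initial_weights(self, rng):
        X, y = blobs(rng)
        cfg = small_config(input_dim=4, max_epochs=0)
        params, report = train(X, y, cfg)
        np.testing.assert_array_equal(params.w, init_parameters(cfg).w)
        assert report.stop_reason == "max_epochs"
        assert report.epochs_run == 0
        assert report.train_loss_trace == []

    def test_seeded_determinism(self, rng):
        X, y = blobs(rng)
        cfg = small_config(input_dim=4, max_epochs=30)
        p1, r1 = train(X, y, cfg)
        p2, r2 = train(X, y, cfg)
        np.testing.assert_array_equal(p1.w, p2.w)
        assert r1.train_loss_trace == r2.train_loss_trace

    def test_trace_lengths_match_epochs(self, rng):
        X, y = blobs(rng)
        params, report = train(X, y, small_config(input_dim=4, max_epochs=25))
        assert len(report.train_loss_trace) == report.epochs_run
        assert len(report.validation_loss_trace) == report.epochs_run

    def test_loss_trace_non_increasing_at_small_lr(self, rng):
        X, y = blobs(rng)
        cfg = small_config(
            input_dim=4, max_epochs=50, learning_rate=1e-3, patience=50
        )
        _, report = train(X, y, cfg)
        diffs = np.diff(report.train_loss_trace)
        assert (diffs <= 1e-12).all()

    def test_rejects_single_class(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="2 classes"):
            train(X, np.zeros(10, dtype=int), small_config(input_dim=4))

    def test_falls_back_without_validation_on_tiny_classes(self, rng, caplog):
        X = rng.normal(size=(4, 4))
        y = np.array([0, 0, 1, 1])  # 15% of 2 rounds to 0 -> no split
        cfg = small_config(input_dim=4, output_dim=2, max_epochs=3)
        with caplog.at_level("WARNING"):
            _, report = train(X, y, cfg)
        assert "without validation" in caplog.text
        assert report.validation_loss_trace == []
        assert report.epochs_run == 3

    def test_stochastic_mode_runs_and_is_deterministic(self, rng):
        X, y = blobs(rng)
        cfg = small_config(input_dim=4, max_epochs=5, batch_mode="stochastic")
        p1, _ = train(X, y, cfg)
        p2, _ = train(X, y, cfg)
        np.testing.assert_array_equal(p1.w, p2.w)

    def test_patience_stop_restores_best_weights(self, rng):
        X, y = blobs(rng, n_per_class=10)
        # oversized learning rate forces validation deterioration
        cfg = small_config(
            input_dim=4, max_epochs=500, learning_rate=50.0, patience=3
        )
        params, report = train(X, y, cfg)
        if report.stop_reason == "patience":
            assert report.epochs_run < 500
            assert np.isfinite(params.w).all()

    def test_labels_out_of_range(self, rng):
        X, y = blobs(rng)
        with pytest.raises(ValueError, match="out of range"):
            train(X, y + 5, small_config(input_dim=4))


class TestPredictProba:
    def test_matches_forward(self, rng):
        params = init_parameters(small_config())
        params.class_names = ("a", "b", "c")
        x = rng.normal(size=6)
        out = predict_proba(params, x)
        np.testing.assert_array_equal(out.probabilities, forward(params, x).o)
        assert out.class_names == ("a", "b", "c")
        assert out.top_class() in out.class_names
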