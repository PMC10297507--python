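"""GRU cells, backpropagation vs the numerical oracle, Adam training."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heartrisk import mgru
from heartrisk.exceptions import ConfigError, DimensionError, ValidationError
from heartrisk.mgru import (
    ActivationConfig,
    AdamState,
    CellWeights,
    NetworkConfig,
    adam_step,
    backward,
    forward,
    gradient_check_error,
    init_model,
    load_model,
    loss_bce,
    modified_cell_step,
    numerical_gradients,
    predict,
    save_model,
    sigmoid,
    standard_cell_step,
    swish,
    train,
)

SIGMA_1 = 0.7310585786300049  # sigma(1) to high precision


def cell_weights(h, i, fill=0.0):
    shapes = {"W_zx": (h, i), "W_zh": (h, h), "W_rx": (h, i), "W_rh": (h, h),
              "W_cx": (h, i), "W_cr": (h, h), "W_ch": (h, h)}
    return CellWeights(**{k: np.full(s, fill) for k, s in shapes.items()})


class TestActivations:
    def test_swish_worked_values(self):
        assert swish(0.0) == 0.0
        assert swish(1.0) == pytest.approx(SIGMA_1, abs=1e-10)
        assert swish(-1.0) == pytest.approx(-(1.0 - SIGMA_1), abs=1e-10)

    def test_swish_approaches_identity_for_large_inputs(self):
        assert swish(30.0) == pytest.approx(30.0, abs=1e-10)

    def test_swish_beta_must_be_positive(self):
        with pytest.raises(ConfigError):
            swish(1.0, beta=0.0)

    def test_swish_gradient_matches_finite_differences(self):
        xs = np.linspace(-4, 4, 33)
        eps = 1e-6
        numeric = (swish(xs + eps, 1.7) - swish(xs - eps, 1.7)) / (2 * eps)
        assert mgru.swish_grad(xs, 1.7) == pytest.approx(numeric, abs=1e-8)

    def test_scalar_activation_basics(self):
        assert mgru.scalar_activations("sigmoid", 0.0) == 0.5
        assert mgru.scalar_activations("tanh", 0.0) == 0.0
        assert mgru.scalar_activations("relu", -3.0) == 0.0
        assert mgru.scalar_activations("relu", 3.0) == 3.0


class TestCellSteps:
    def test_standard_zero_weights_halve_previous_state(self):
        w = cell_weights(3, 2)
        h_prev = np.array([0.4, -0.6, 1.0])
        h = standard_cell_step(np.zeros(2), h_prev, w)
        # z = sigma(0) = 0.5 and the candidate is tanh(0) = 0
        assert h == pytest.approx(0.5 * h_prev)

    def test_standard_scalar_worked_example(self):
        w = cell_weights(1, 1, fill=1.0)
        h = standard_cell_step(np.array([1.0]), np.array([0.0]), w)
        expected = SIGMA_1 * np.tanh(1.0 + SIGMA_1)
        assert h[0] == pytest.approx(expected, abs=1e-9)

    def test_modified_zero_weights_is_identity(self):
        w = cell_weights(4, 3)
        h_prev = np.array([0.3, -0.2, 1.5, 0.0])
        h = modified_cell_step(np.ones(3), h_prev, w)
        assert np.array_equal(h, h_prev)  # z = swish(0) = 0, exactly

    def test_modified_scalar_worked_example(self):
        w = cell_weights(1, 1, fill=1.0)
        h = modified_cell_step(np.array([1.0]), np.array([0.0]), w)
        expected = SIGMA_1 * (1.0 + SIGMA_1)  # 1.2655052
        assert h[0] == pytest.approx(expected, abs=1e-7)

    def test_gate_clamp_is_noop_when_gate_inside_unit_interval(self):
        w = cell_weights(1, 1, fill=1.0)
        x, h0 = np.array([1.0]), np.array([0.0])
        plain = modified_cell_step(x, h0, w)
        clamped = modified_cell_step(x, h0, w, ActivationConfig(gate_clamp=True))
        assert np.array_equal(plain, clamped)

    def test_shape_mismatch_raises(self):
        w = cell_weights(3, 2)
        with pytest.raises(DimensionError):
            standard_cell_step(np.zeros(5), np.zeros(3), w)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_standard_hidden_state_is_bounded(self, seed):
        # tanh candidate + convex gate mixing: |h_t| <= max(|h_0|, 1)
        rng = np.random.default_rng(seed)
        h, i = 4, 3
        w = CellWeights(**{
            k: rng.normal(0, 2, size=(h, i if k.endswith("x") else h))
            for k in CellWeights.NAMES
        })
        state = rng.uniform(-2, 2, size=h)
        bound = max(np.max(np.abs(state)), 1.0)
        for t in range(10):
            state = standard_cell_step(rng.normal(0, 3, size=i), state, w)
            assert np.all(np.abs(state) <= bound + 1e-12)


class TestForwardAndLoss:
    def test_zero_weight_network_outputs_one_half(self):
        config = NetworkConfig(hidden_size=4, seed=0)
        model = init_model(config, 5)
        for key in model.params:
            model.params[key] = np.zeros_like(model.params[key])
        p, _ = forward(model, np.random.default_rng(0).random((6, 13, 5)))
        assert p == pytest.approx(np.full(6, 0.5))

    def test_inference_is_deterministic_and_in_unit_interval(self):
        config = NetworkConfig(hidden_size=4, seed=1)
        model = init_model(config, 5)
        X = np.random.default_rng(5).random((8, 13, 5))
        p1, _ = forward(model, X)
        p2, _ = forward(model, X)
        assert np.array_equal(p1, p2)
        assert np.all((p1 > 0) & (p1 < 1))

    def test_width_mismatch_raises(self):
        model = init_model(NetworkConfig(hidden_size=3), 5)
        with pytest.raises(DimensionError):
            forward(model, np.zeros((2, 13, 7)))

    def test_bce_worked_values_and_symmetry(self):
        assert loss_bce(0.5, 1) == pytest.approx(np.log(2), abs=1e-7)
        assert loss_bce(1 - 1e-12, 1) == pytest.approx(0.0, abs=1e-9)
        p = 0.37
        assert loss_bce(p, 0) == pytest.approx(loss_bce(1 - p, 1))

    def test_bce_rejects_non_binary_labels(self):
        with pytest.raises(ValidationError):
            loss_bce(0.5, 0.3)


class TestGradients:
    @pytest.mark.parametrize("cell", ["standard", "modified"])
    @pytest.mark.parametrize("candidate_form", ["additive", "cho"])
    def test_backward_matches_numerical_oracle(self, cell, candidate_form):
        # all-positive weights and inputs keep every ReLU/clamp
        # pre-activation away from its kink, where central differences
        # are valid
        config = NetworkConfig(
            hidden_size=3, dropout_rate=0.0, cell=cell,
            candidate_form=candidate_form, seed=11, init_mode="positive",
        )
        model = init_model(config, 5, np.random.default_rng(7))
        X = np.random.default_rng(5).random((2, 13, 5))
        y = np.array([1.0, 0.0])
        assert gradient_check_error(model, X, y) <= 1e-5

    def test_gradient_check_with_gate_clamp_active(self):
        config = NetworkConfig(
            hidden_size=3, dropout_rate=0.0, seed=3, init_mode="positive",
            activation=ActivationConfig(gate_clamp=True),
        )
        model = init_model(config, 5, np.random.default_rng(1))
        # large inputs drive gates well past the clamp boundary; the
        # clamped paths then carry near-zero gradients, so a slightly
        # larger eps keeps the central difference above roundoff
        X = np.random.default_rng(2).random((2, 13, 5)) * 8.0
        y = np.array([0.0, 1.0])
        assert gradient_check_error(model, X, y, eps=1e-5) <= 1e-5

    def test_zero_weight_network_pushes_probability_toward_label(self):
        config = NetworkConfig(hidden_size=3, dropout_rate=0.0, seed=0)
        model = init_model(config, 5)
        for key in model.params:
            model.params[key] = np.zeros_like(model.params[key])
        X = np.ones((1, 13, 5))
        p, caches = forward(model, X)
        grads = backward(model, caches, np.array([1.0]))
        # d loss / d logit = p - y = -0.5: output bias gradient is negative
        assert grads["out.b"][0] == pytest.approx(-0.5)

    def test_numerical_gradients_require_dropout_off(self):
        model = init_model(NetworkConfig(hidden_size=3, dropout_rate=0.16), 5)
        with pytest.raises(ValidationError):
            numerical_gradients(model, np.zeros((1, 13, 5)), np.array([1.0]))


class TestAdamAndTraining:
    def test_zero_gradients_leave_parameters_unchanged(self):
        model = init_model(NetworkConfig(hidden_size=3, seed=0), 5)
        before = {k: v.copy() for k, v in model.params.items()}
        grads = {k: np.zeros_like(v) for k, v in model.params.items()}
        adam_step(model.params, grads, AdamState.for_model(model), lr=0.01)
        for key in before:
            assert np.array_equal(model.params[key], before[key])

    def test_first_step_magnitude_is_learning_rate(self):
        params = {"w": np.array([1.0])}
        grads = {"w": np.array([0.3])}
        state = AdamState(m={"w": np.zeros(1)}, v={"w": np.zeros(1)})
        adam_step(params, grads, state, lr=0.01)
        # bias-corrected first step: lr * g / (|g| + eps) ~ lr
        assert params["w"][0] == pytest.approx(1.0 - 0.01, abs=1e-6)

    def test_learning_rate_decays_per_epoch(self, separable_cohort, schema_enc):
        X = schema_enc.encode_batch(separable_cohort.records[:128])
        y = separable_cohort.labels[:128].astype(float)
        config = NetworkConfig(hidden_size=3, seed=0)
        _, state = train(X, y, config, epochs=3)
        if state.restarts == 0:
            assert state.lr_history == pytest.approx(
                [0.018 * 0.94**e for e in range(3)]
            )

    def test_zero_epochs_returns_initialised_model(self):
        X = np.random.default_rng(0).random((4, 13, 5))
        y = np.array([0.0, 1.0, 0.0, 1.0])
        config = NetworkConfig(hidden_size=3, seed=9)
        model, state = train(X, y, config, epochs=0)
        reference = init_model(config, 5, np.random.default_rng(9))
        for key in model.params:
            assert np.array_equal(model.params[key], reference.params[key])
        assert state.epochs_run == 0

    def test_training_is_reproducible_from_the_seed(self, separable_cohort, schema_enc):
        X = schema_enc.encode_batch(separable_cohort.records[:300])
        y = separable_cohort.labels[:300].astype(float)
        config = NetworkConfig(hidden_size=4, seed=5)
        model_a, _ = train(X, y, config, epochs=3)
        model_b, _ = train(X, y, config, epochs=3)
        for key in model_a.params:
            assert np.array_equal(model_a.params[key], model_b.params[key])

    def test_recovers_separable_signal(self, separable_cohort, schema_enc):
        # scaled-down recovery run; the full-size run lives in the
        # acceptance suite
        X = schema_enc.encode_batch(separable_cohort.records[:800])
        y = separable_cohort.labels[:800].astype(float)
        model, _ = train(X, y, NetworkConfig(seed=0), epochs=40)
        labels, _ = predict(model, X)
        assert np.mean(labels == y) >= 0.85

    def test_init_modes_differ_only_in_sign_pattern(self):
        pos = init_model(NetworkConfig(hidden_size=3, init_mode="positive", seed=4), 5)
        mag = init_model(NetworkConfig(hidden_size=3, init_mode="magnitude", seed=4), 5)
        w_pos = pos.params["rnn0.W_zx"]
        w_mag = mag.params["rnn0.W_zx"]
        assert np.all((np.abs(w_pos) >= 0.1) & (np.abs(w_pos) <= 0.2))
        assert np.all((np.abs(w_mag) >= 0.1) & (np.abs(w_mag) <= 0.2))
        assert np.all(w_pos > 0)
        assert np.any(w_mag < 0)


class TestPredictAndCheckpoints:
    def test_probability_at_threshold_is_labelled_positive(self):
        model = init_model(NetworkConfig(hidden_size=3, seed=0), 5)
        for key in model.params:
            model.params[key] = np.zeros_like(model.params[key])
        labels, probs = predict(model, np.zeros((3, 13, 5)), threshold=0.5)
        assert np.all(probs == 0.5)
        assert np.all(labels == 1)  # tie rule: >= threshold

    def test_labels_invariant_to_record_order(self):
        model = init_model(NetworkConfig(hidden_size=4, seed=2), 5)
        X = np.random.default_rng(3).random((10, 13, 5))
        perm = np.random.default_rng(4).permutation(10)
        labels, _ = predict(model, X)
        labels_perm, _ = predict(model, X[perm])
        assert np.array_equal(labels[perm], labels_perm)

    def test_checkpoint_round_trip(self, tmp_path):
        model = init_model(NetworkConfig(hidden_size=3, seed=8), 5)
        path = save_model(model, tmp_path / "model.json")
        back = load_model(path)
        assert back.config == model.config
        assert back.input_width == model.input_width
        for key in model.params:
            assert np.array_equal(back.params[key], model.params[key])
        X = np.random.default_rng(1).random((4, 13, 5))
        assert np.array_equal(forward(back, X)[0], forward(model, X)[0])
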