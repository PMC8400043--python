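"""LSTM cell, training loops, prediction and evaluation."""

import numpy as np
import pytest

import sonouroflow as sf
from sonouroflow.dataset import Example
from sonouroflow.lstm_models import (
    CellState,
    _forward,
    _pack,
    _unpack,
    init_lstm_params,
    lstm_cell_step,
)


def _oracle_step(x, h, c, p):
    """Independent step-by-step evaluation of the gated recurrence, written
    directly from the defining equations (scalar loops, no shared code)."""
    H = p.hidden_size
    hx = np.concatenate([h, x])

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    f = np.array([sig(np.dot(p.W_f[j], hx) + p.b_f[j]) for j in range(H)])
    i = np.array([sig(np.dot(p.W_i[j], hx) + p.b_i[j]) for j in range(H)])
    g = np.array([np.tanh(np.dot(p.W_c[j], hx) + p.b_c[j]) for j in range(H)])
    o = np.array([sig(np.dot(p.W_o[j], hx) + p.b_o[j]) for j in range(H)])
    c_new = f * c + i * g
    h_new = o * np.tanh(c_new)
    return h_new, c_new


class TestCellStep:
    def test_all_zero_params_zero_state(self):
        p = sf.LSTMParams(
            *(np.zeros((3, 5)) for _ in range(4)), *(np.zeros(3) for _ in range(4))
        )
        out = lstm_cell_step(np.zeros(2), CellState(np.zeros(3), np.zeros(3)), p)
        # sigma(0) = 0.5, tanh(0) = 0 -> c = 0, h = 0
        assert np.allclose(out.c, 0.0)
        assert np.allclose(out.h, 0.0)

    def test_zero_params_unit_cell_state(self):
        p = sf.LSTMParams(
            *(np.zeros((3, 5)) for _ in range(4)), *(np.zeros(3) for _ in range(4))
        )
        out = lstm_cell_step(np.zeros(2), CellState(np.zeros(3), np.ones(3)), p)
        # c1 = f*c0 = 0.5; h1 = o*tanh(c1) = 0.5*tanh(0.5)
        assert np.allclose(out.c, 0.5)
        assert np.allclose(out.h, 0.5 * np.tanh(0.5))

    def test_matches_independent_oracle_over_random_draws(self):
        rng = np.random.default_rng(123)
        worst = 0.0
        for _ in range(100):
            H, I = int(rng.integers(1, 8)), int(rng.integers(1, 4))
            p = init_lstm_params(I, H, rng)
            h, c = np.zeros(H), np.zeros(H)
            state = CellState(h.copy(), c.copy())
            for _ in range(10):
                x = rng.normal(size=I)
                state = lstm_cell_step(x, state, p)
                h, c = _oracle_step(x, h, c, p)
                worst = max(worst, np.abs(state.h - h).max(), np.abs(state.c - c).max())
        assert worst < 1e-6

    def test_batched_kernel_matches_cell_step(self):
        rng = np.random.default_rng(7)
        p = init_lstm_params(2, 4, rng)
        X = rng.normal(size=(12, 1, 2))
        Hs, Cs, *_ = _forward(X, *_pack(p))
        state = CellState(np.zeros(4), np.zeros(4))
        for t in range(12):
            state = lstm_cell_step(X[t, 0], state, p)
            assert np.allclose(Hs[t + 1, 0], state.h, atol=1e-12)
            assert np.allclose(Cs[t + 1, 0], state.c, atol=1e-12)

    def test_gate_and_state_bounds(self):
        rng = np.random.default_rng(9)
        p = init_lstm_params(2, 6, rng)
        X = rng.normal(size=(50, 2, 2)) * 3
        Hs, Cs, F, Ig, G, O = _forward(X, *_pack(p))
        for gate in (F, Ig, O):
            assert np.all(gate > 0) and np.all(gate < 1)
        assert np.all(np.abs(Hs) < 1.0)

    def test_dimension_mismatch_rejected(self):
        p = init_lstm_params(2, 3, np.random.default_rng(0))
        with pytest.raises(ValueError):
            lstm_cell_step(np.zeros(5), CellState(np.zeros(3), np.zeros(3)), p)

    def test_pack_unpack_round_trip(self):
        p = init_lstm_params(3, 5, np.random.default_rng(1))
        q = _unpack(*_pack(p))
        assert np.allclose(q.W_f, p.W_f) and np.allclose(q.W_o, p.W_o)
        assert np.allclose(q.b_c, p.b_c)


class TestRegressor:
    def test_zero_weight_model_outputs_constant(self):
        p = sf.LSTMParams(
            *(np.zeros((5, 7)) for _ in range(4)), *(np.zeros(5) for _ in range(4))
        )
        m = sf.RegressorModel(
            params=p, head_w=np.zeros(5), head_b=0.7,
            feature_mean=np.zeros(2), feature_std=np.ones(2),
            target_mean=3.0, target_std=2.0,
        )
        fs = sf.FeatureSeries(np.arange(10.0), np.random.rand(10), np.random.rand(10))
        fc = m.predict(fs)
        # de-standardized head bias: 0.7*2 + 3 = 4.4
        assert np.allclose(fc.flowrate, 4.4)

    def test_recovers_noiseless_linear_mapping(self):
        # loudness/roughness noiselessly tied to flow -> near-perfect fit
        # (~50 events so the fixed 40-epoch budget sees enough batches)
        events = sf.gen_cohort(17, seed=21, fm=sf.ForwardModelSpec(observation_noise=0.0))
        examples = [
            Example(e.patient_id,
                    np.column_stack([e.features.loudness, e.features.roughness]),
                    target=e.flow.flowrate)
            for e in events
        ]
        ts = sf.build_training_set(examples, task="regression", split_fraction=0.8, seed=2)
        m = sf.train_regressor(ts, sf.RegressorTrainConfig(epochs=40, seed=0))
        errs = [
            sf.evaluate_error_rate(m.predict(e.features), e.flow)
            for e in events
            if e.patient_id in ts.patients_val
        ]
        assert np.mean(errs) < 2.0

    def test_training_reduces_loss(self, tiny_regression_set):
        m = sf.train_regressor(tiny_regression_set, sf.RegressorTrainConfig(epochs=10, seed=3))
        assert m.loss_history[-1] < m.loss_history[0]

    def test_loss_trend_mostly_decreasing(self, tiny_regression_set):
        m = sf.train_regressor(tiny_regression_set, sf.RegressorTrainConfig(epochs=15, seed=3))
        upticks = np.diff(m.loss_history) > 0.1 * m.loss_history[:-1]
        assert upticks.mean() <= 0.35  # optimizer sanity: few large upticks

    def test_deterministic_given_seed(self, tiny_regression_set):
        cfg = sf.RegressorTrainConfig(epochs=3, seed=5)
        m1 = sf.train_regressor(tiny_regression_set, cfg)
        m2 = sf.train_regressor(tiny_regression_set, cfg)
        assert np.array_equal(m1.head_w, m2.head_w)
        assert np.array_equal(m1.params.W_f, m2.params.W_f)

    def test_causality_time_reversal_changes_output(self, tiny_regression_set):
        m = sf.train_regressor(tiny_regression_set, sf.RegressorTrainConfig(epochs=5, seed=1))
        t = np.arange(0, 30, 0.1)
        ramp = np.linspace(0, 5, t.size)  # asymmetric input
        fs_fwd = sf.FeatureSeries(t, ramp, ramp * 0.1)
        fs_rev = sf.FeatureSeries(t, ramp[::-1].copy(), (ramp * 0.1)[::-1].copy())
        y_fwd = m.predict(fs_fwd).flowrate
        y_rev = m.predict(fs_rev).flowrate
        assert not np.allclose(y_fwd, y_rev[::-1], atol=1e-6)

    def test_roughness_only_mode(self, tiny_regression_set):
        m = sf.train_regressor(
            tiny_regression_set,
            sf.RegressorTrainConfig(epochs=3, seed=0, input_mode="roughness"),
        )
        assert m.params.input_size == 1
        fs = sf.FeatureSeries(np.arange(10.0), np.random.rand(10), np.random.rand(10))
        assert m.predict(fs).flowrate.size == 10

    def test_empty_set_rejected(self):
        ts = sf.TrainingSet("regression", [], [], [], [], [], [])
        with pytest.raises(ValueError):
            sf.train_regressor(ts)


class TestClassifier:
    def test_zero_weight_model_uniform_probabilities(self):
        p = sf.LSTMParams(
            *(np.zeros((4, 5)) for _ in range(4)), *(np.zeros(4) for _ in range(4))
        )
        m = sf.ClassifierModel(params=p, head_W=np.zeros((4, 3)), head_b=np.zeros(3))
        probs = m.classify(np.linspace(0, 1, 246))
        assert np.allclose(probs, 1 / 3)

    def test_probabilities_normalized(self, tiny_classification_set):
        m = sf.train_classifier(
            tiny_classification_set, sf.ClassifierTrainConfig(hidden_size=8, epochs=2, seed=0)
        )
        for x in tiny_classification_set.inputs_val[:5]:
            probs = m.classify(np.asarray(x).reshape(-1))
            assert np.all(probs >= 0)
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_wrong_length_rejected(self, tiny_classification_set):
        m = sf.train_classifier(
            tiny_classification_set, sf.ClassifierTrainConfig(hidden_size=4, epochs=1, seed=0)
        )
        with pytest.raises(ValueError):
            m.classify(np.zeros(100))

    def test_deterministic_given_seed(self, tiny_classification_set):
        cfg = sf.ClassifierTrainConfig(hidden_size=6, epochs=2, seed=8)
        m1 = sf.train_classifier(tiny_classification_set, cfg)
        m2 = sf.train_classifier(tiny_classification_set, cfg)
        x = np.asarray(tiny_classification_set.inputs_val[0]).reshape(-1)
        assert np.array_equal(m1.classify(x), m2.classify(x))

    def test_head_permutation_equivariance(self, tiny_classification_set):
        m = sf.train_classifier(
            tiny_classification_set, sf.ClassifierTrainConfig(hidden_size=6, epochs=2, seed=0)
        )
        x = np.asarray(tiny_classification_set.inputs_val[0]).reshape(-1)
        base = m.classify(x)
        perm = [2, 0, 1]
        m_perm = sf.ClassifierModel(
            params=m.params, head_W=m.head_W[:, perm], head_b=m.head_b[perm]
        )
        assert np.allclose(m_perm.classify(x), base[perm])

    def test_missing_class_rejected(self, tiny_classification_set):
        ts = tiny_classification_set
        keep = [i for i, lbl in enumerate(ts.targets_train) if lbl != "C"]
        bad = sf.TrainingSet(
            "classification",
            [ts.inputs_train[i] for i in keep],
            [ts.targets_train[i] for i in keep],
            ts.inputs_val, ts.targets_val, ts.patients_train, ts.patients_val,
        )
        with pytest.raises(ValueError):
            sf.train_classifier(bad)


class TestEvaluateErrorRate:
    def test_identical_curves_zero(self, bell_curve):
        assert sf.evaluate_error_rate(bell_curve, bell_curve) == 0.0

    def test_constant_offset_gives_offset_percentage(self, bell_curve):
        vmax = bell_curve.flowrate.max()
        shifted = sf.FlowrateCurve(bell_curve.times, bell_curve.flowrate + 0.05 * vmax)
        assert sf.evaluate_error_rate(shifted, bell_curve) == pytest.approx(5.0)

    def test_zero_prediction_vs_half_occupancy_pulse(self):
        t = np.arange(0, 10, 0.1)
        v = np.where(t < 5, 10.0, 0.0)
        meas = sf.FlowrateCurve(t, v)
        pred = sf.FlowrateCurve(t, np.zeros_like(t))
        assert sf.evaluate_error_rate(pred, meas) == pytest.approx(50.0)

    def test_mismatched_grids_rejected(self, bell_curve):
        other = sf.FlowrateCurve(bell_curve.times + 0.05, bell_curve.flowrate)
        with pytest.raises(ValueError):
            sf.evaluate_error_rate(other, bell_curve)

    def test_zero_measured_maximum_rejected(self):
        t = np.arange(0, 5, 0.1)
        z = sf.FlowrateCurve(t, np.zeros_like(t))
        with pytest.raises(ValueError):
            sf.evaluate_error_rate(z, z)


class TestSerialization:
    def test_regressor_round_trip(self, tmp_path, tiny_regression_set):
        m = sf.train_regressor(tiny_regression_set, sf.RegressorTrainConfig(epochs=2, seed=0))
        path = tmp_path / "reg.model.npz"
        sf.save_model(m, path)
        back = sf.load_model(path)
        fs = sf.FeatureSeries(np.arange(20.0), np.random.rand(20), np.random.rand(20))
        assert np.allclose(back.predict(fs).flowrate, m.predict(fs).flowrate)

    def test_classifier_round_trip(self, tmp_path, tiny_classification_set):
        m = sf.train_classifier(
            tiny_classification_set, sf.ClassifierTrainConfig(hidden_size=5, epochs=1, seed=0)
        )
        path = tmp_path / "clf.model.npz"
        sf.save_model(m, path)
        back = sf.load_model(path)
        x = np.asarray(tiny_classification_set.inputs_val[0]).reshape(-1)
        assert np.allclose(back.classify(x), m.classify(x))
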