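"""Feedforward fatigue predictor: scaling, forward pass, training, metrics."""

import copy
import math

import numpy as np
import pytest

from opfatigue import TrainConfig, crossvalidate, evaluate, forward, train
from opfatigue.mlp import (
    MLPParams,
    _init_params,
    gradients,
    predict,
    load_model,
    save_model,
    scale_apply,
    scale_fit,
    scale_invert,
)


class TestScaling:
    def test_endpoints_map_to_unit_interval(self):
        p = scale_fit(np.array([[0.0], [10.0]]))
        np.testing.assert_allclose(
            scale_apply(p, np.array([[0.0], [10.0]])), [[-1.0], [1.0]]
        )

    def test_linearity(self):
        p = scale_fit(np.array([[0.0], [5.0], [10.0]]))
        np.testing.assert_allclose(
            scale_apply(p, np.array([[0.0], [5.0], [10.0]])),
            [[-1.0], [0.0], [1.0]],
        )

    def test_roundtrip_identity(self, rng):
        x = rng.uniform(-5, 5, (20, 4))
        p = scale_fit(x)
        np.testing.assert_allclose(scale_invert(p, scale_apply(p, x)), x,
                                   atol=1e-12)

    def test_constant_feature_maps_to_zero(self):
        p = scale_fit(np.array([[3.0, 1.0], [3.0, 2.0]]))
        out = scale_apply(p, np.array([[3.0, 1.5]]))
        assert out[0, 0] == 0.0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            scale_fit(np.array([[1.0, 2.0]]))


class TestForward:
    def test_zero_weights_output_bias(self, rng):
        p = MLPParams(W1=np.zeros((8, 10)), b1=np.zeros(8),
                      W2=np.zeros((1, 8)), b2=0.3)
        x = rng.uniform(-1, 1, 10)
        assert forward(p, x) == pytest.approx(0.3)

    def test_zero_input_zero_hidden_bias_gives_output_bias(self, rng):
        p = _init_params(10, 8, rng)
        p.b1 = np.zeros(8)
        assert forward(p, np.zeros(10)) == pytest.approx(p.b2)

    def test_hand_sized_2_2_1_instance(self):
        # symbolic: y = w2 . tanh(W1 x + b1) + b2 evaluated by hand
        p = MLPParams(W1=np.array([[1.0, -1.0], [0.5, 0.5]]),
                      b1=np.array([0.0, 1.0]),
                      W2=np.array([[2.0, -3.0]]), b2=0.25)
        x = np.array([0.2, -0.4])
        expected = (2.0 * math.tanh(0.2 + 0.4)
                    - 3.0 * math.tanh(0.1 - 0.2 + 1.0) + 0.25)
        assert forward(p, x) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        p = _init_params(10, 8, rng)
        with pytest.raises(ValueError, match="features"):
            forward(p, np.zeros(7))


class TestGradients:
    def test_matches_central_finite_differences(self, rng):
        p = _init_params(10, 8, rng)
        X = rng.uniform(-1, 1, (12, 10))
        y = rng.uniform(-1, 1, 12)
        grads, _ = gradients(p, X, y)
        eps = 1e-6

        def loss_of(q):
            return float(np.mean((forward(q, X) - y) ** 2))

        for name in ("W1", "b1", "W2"):
            arr = getattr(p, name)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                q = copy.deepcopy(p)
                getattr(q, name)[idx] += eps
                up = loss_of(q)
                getattr(q, name)[idx] -= 2 * eps
                dn = loss_of(q)
                num = (up - dn) / (2 * eps)
                assert abs(num - grads[name][idx]) < 1e-6
        q = copy.deepcopy(p)
        q.b2 += eps
        up = loss_of(q)
        q.b2 -= 2 * eps
        dn = loss_of(q)
        assert abs((up - dn) / (2 * eps) - grads["b2"]) < 1e-6


class TestTraining:
    def test_noiseless_linear_target_fit(self, rng):
        X = rng.uniform(-1, 1, (38, 10))
        c = rng.uniform(-1, 1, 10)
        y = X @ c
        y01 = (y - y.min()) / (y.max() - y.min())
        _, history = train(X, y01, TrainConfig(seed=0))
        assert len(history) <= 1000
        assert history[-1] < 1e-4

    def test_history_monotone_nonincreasing(self, rng):
        X = rng.uniform(-1, 1, (30, 10))
        y = rng.uniform(0, 1, 30)
        _, history = train(X, y, TrainConfig(seed=1, max_epochs=200))
        assert all(b <= a + 1e-15 for a, b in zip(history, history[1:]))

    def test_identical_seeds_identical_weights(self, rng):
        X = rng.uniform(-1, 1, (30, 10))
        y = rng.uniform(0, 1, 30)
        cfg = TrainConfig(seed=4, max_epochs=50)
        p1, _ = train(X, y, cfg)
        p2, _ = train(X, y, cfg)
        np.testing.assert_array_equal(p1.W1, p2.W1)
        np.testing.assert_array_equal(p1.W2, p2.W2)

    def test_lm_optimizer_converges(self, rng):
        X = rng.uniform(-1, 1, (38, 10))
        y01 = (X @ rng.uniform(-1, 1, 10))
        y01 = (y01 - y01.min()) / (y01.max() - y01.min())
        _, history = train(X, y01, TrainConfig(seed=0, optimizer="lm"))
        assert history[-1] < 1e-6

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="hidden"):
            train(rng.uniform(-1, 1, (4, 10)), rng.uniform(0, 1, 4),
                  TrainConfig())

    def test_split_sizes(self):
        assert TrainConfig().split_sizes(42) == (38, 4)
        assert TrainConfig(train_ratio=9, test_ratio=1).split_sizes(40) == (36, 4)


class TestEvaluate:
    def test_perfect_predictions(self):
        r = evaluate(np.array([0.1, 0.5, 0.9]), np.array([0.1, 0.5, 0.9]))
        assert (r.mae, r.mse, r.rmse, r.r2) == (0.0, 0.0, 0.0, 1.0)

    def test_mean_prediction_gives_zero_r2(self):
        obs = np.array([0.0, 1.0, 0.5, 0.3])
        r = evaluate(np.full(4, obs.mean()), obs)
        assert r.r2 == pytest.approx(0.0)

    def test_direct_evaluation_example(self):
        r = evaluate(np.array([0.5, 0.5]), np.array([0.0, 1.0]))
        assert r.mae == pytest.approx(0.5)
        assert r.mse == pytest.approx(0.25)
        assert r.rmse == pytest.approx(0.5)
        assert r.r2 == pytest.approx(0.0)

    def test_rmse_mse_identity_and_mae_bound(self, rng):
        pred, obs = rng.uniform(0, 1, 30), rng.uniform(0, 1, 30)
        r = evaluate(pred, obs)
        assert r.rmse**2 == pytest.approx(r.mse, rel=1e-12)
        assert r.mae <= r.rmse + 1e-12

    def test_zero_variance_observations_flagged(self):
        r = evaluate(np.array([0.1, 0.2]), np.array([0.5, 0.5]))
        assert math.isnan(r.r2)


class TestCrossValidate:
    @staticmethod
    def _linear_data(rng, n=20):
        X = rng.uniform(-1, 1, (n, 10))
        y = X @ rng.uniform(-1, 1, 10)
        return X, (y - y.min()) / (y.max() - y.min())

    def test_leave_one_out_fold_count(self, rng):
        X, y = self._linear_data(rng, 12)
        report, _ = crossvalidate(X, y, folds=12,
                                  config=TrainConfig(seed=0, max_epochs=50),
                                  seed=0)
        assert len(report.folds) == 12

    def test_deterministic_under_seed(self, rng):
        X, y = self._linear_data(rng, 20)
        cfg = TrainConfig(seed=2, max_epochs=50)
        r1, p1 = crossvalidate(X, y, folds=4, config=cfg, seed=3)
        r2, p2 = crossvalidate(X, y, folds=4, config=cfg, seed=3)
        np.testing.assert_array_equal(p1, p2)
        assert r1.mae == r2.mae

    def test_noiseless_mapping_recovered(self, noiseless_cohort,
                                         noiseless_features):
        # at zero observation noise the latent fatigue is an exact,
        # continuous function the HRV features carry; held-out error is
        # then limited only by feature-extraction precision
        from opfatigue.hrv import FEATURE_NAMES

        _, obs, _ = noiseless_cohort
        X = noiseless_features[list(FEATURE_NAMES)].to_numpy()
        y = obs["true_fatigue"].to_numpy()
        report, _ = crossvalidate(X, y, folds=5, config=TrainConfig(seed=3),
                                  seed=3)
        fold_mean_mae = np.mean([f.mae for f in report.folds])
        assert fold_mean_mae < 0.02
        assert report.mae < 0.02

    def test_too_many_folds_rejected(self, rng):
        X, y = self._linear_data(rng, 10)
        with pytest.raises(ValueError, match="folds"):
            crossvalidate(X, y, folds=11)


class TestPersistence:
    def test_save_load_roundtrip(self, rng, tmp_path):
        X = rng.uniform(0, 10, (20, 10))
        y = rng.uniform(0, 1, 20)
        params, _ = train(X, y, TrainConfig(seed=0, max_epochs=50))
        path = tmp_path / "model.json"
        save_model(params, path)
        loaded = load_model(path)
        np.testing.assert_allclose(predict(loaded, X), predict(params, X),
                                   atol=1e-12)
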