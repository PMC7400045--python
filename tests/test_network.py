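"""Network forward pass, splitting, Bayesian-regularization training."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgbp.network import (
    CombinatorialModel,
    MLPRegressor,
    TrainConfig,
    fit_stage1_ppg_to_map,
    fit_stage2_map_to_bp,
    split_data,
    train_bayesian_regularization,
)


class TestSplit:
    def test_floor_rule_on_cohort_size(self):
        # 43,552 records: floor(0.70*n) = 30,486 train, remainder split evenly
        tr, va, te = split_data(43552, seed=0)
        assert len(tr) == 30486
        assert len(va) == 6533 and len(te) == 6533

    def test_small_n(self):
        tr, va, te = split_data(10, seed=0)
        assert (len(tr), len(va), len(te)) == (7, 1, 2)

    @given(n=st.integers(min_value=7, max_value=500), seed=st.integers(0, 2**31 - 1))
    def test_disjoint_and_exhaustive(self, n, seed):
        tr, va, te = split_data(n, seed=seed)
        union = np.concatenate([tr, va, te])
        assert len(union) == n
        assert len(np.unique(union)) == n

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            split_data(3, seed=0)  # remainder of 1 row cannot fill val and test

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_data(100, fractions=(0.5, 0.2, 0.2), seed=0)


def _identity_norm(model):
    model.in_min[:] = -1.0
    model.in_max[:] = 1.0
    model.out_min[:] = -1.0
    model.out_max[:] = 1.0


class TestForward:
    def test_zero_weights_returns_denormalized_bias(self):
        m = MLPRegressor(1, 4, 1)
        m.out_min[:] = 0.0
        m.out_max[:] = 100.0
        m.output_biases[:] = 0.5  # normalized bias 0.5 -> raw 75
        assert m.forward([[0.3]])[0, 0] == pytest.approx(75.0)
        assert m.forward([[-0.9]])[0, 0] == pytest.approx(75.0)

    def test_single_tanh_unit_at_zero_input(self):
        m = MLPRegressor(1, 1, 1)
        _identity_norm(m)
        m.hidden_weights[:] = 1.0
        m.output_weights[:] = 1.0
        # tanh midpoint: tanh(0) = 0
        assert m.forward([[0.0]])[0, 0] == pytest.approx(0.0)
        assert m.forward([[0.5]])[0, 0] == pytest.approx(np.tanh(0.5))

    def test_output_layer_is_linear_in_its_parameters(self):
        rng = np.random.default_rng(0)
        m = MLPRegressor(2, 5, 3)
        _identity_norm(m)
        m.init_weights(rng)
        x = rng.normal(size=(4, 2))
        y1 = m.forward(x)
        m.output_weights *= 2.0
        m.output_biases *= 2.0
        assert np.allclose(m.forward(x), 2.0 * y1)

    def test_dimension_mismatch_rejected(self):
        m = MLPRegressor(2, 3, 1)
        with pytest.raises(ValueError, match="features"):
            m.forward(np.zeros((5, 3)))

    def test_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        m = MLPRegressor(2, 3, 2)
        _identity_norm(m)
        m.init_weights(rng)
        Xn = rng.normal(size=(5, 2))
        J = m.jacobian(Xn)
        w0 = m.get_params()
        eps = 1e-6
        for j in range(w0.size):
            w = w0.copy()
            w[j] += eps
            m.set_params(w)
            up, _ = m._forward_normalized(Xn)
            w[j] -= 2 * eps
            m.set_params(w)
            dn, _ = m._forward_normalized(Xn)
            fd = ((up - dn) / (2 * eps)).ravel()
            assert np.allclose(J[:, j], fd, atol=1e-5)
            m.set_params(w0)


class TestTraining:
    def test_noiseless_affine_recovery(self):
        x = np.linspace(-2, 3, 50)[:, None]
        y = 2 * x + 1
        m, rec = train_bayesian_regularization(
            MLPRegressor(1, 10, 1), x, y, TrainConfig(seed=1)
        )
        mse = float(np.mean((m.forward(x[rec.test_idx]) - y[rec.test_idx]) ** 2))
        assert mse < 1e-4

    def test_sine_fit_heldout_correlation(self):
        rng = np.random.default_rng(0)
        x = np.linspace(-3, 3, 200)[:, None]
        y = np.sin(x) + rng.normal(0, 0.05, (200, 1))
        m, rec = train_bayesian_regularization(
            MLPRegressor(1, 10, 1), x, y, TrainConfig(seed=2)
        )
        yh = m.forward(x[rec.test_idx]).ravel()
        r = np.corrcoef(yh, y[rec.test_idx].ravel())[0, 1]
        assert r > 0.99

    def test_one_epoch_run_stops_at_max_epochs(self):
        x = np.linspace(0, 1, 40)[:, None]
        y = x**2
        _, rec = train_bayesian_regularization(
            MLPRegressor(1, 3, 1), x, y, TrainConfig(max_epochs=1, seed=0)
        )
        assert rec.n_epochs == 1
        assert rec.stop_reason == "max_epochs"

    def test_accepted_steps_never_increase_objective(self):
        rng = np.random.default_rng(1)
        x = np.linspace(-1, 1, 80)[:, None]
        y = np.cos(2 * x) + rng.normal(0, 0.1, (80, 1))
        _, rec = train_bayesian_regularization(
            MLPRegressor(1, 6, 1), x, y, TrainConfig(seed=3, max_epochs=100)
        )
        f_before = rec.series("F_before")
        f_after = rec.series("F")
        assert np.all(f_after <= f_before + 1e-12)

    def test_gamma_stays_within_parameter_count(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(60, 1))
        y = 0.5 * x + rng.normal(0, 0.2, (60, 1))
        m, rec = train_bayesian_regularization(
            MLPRegressor(1, 5, 1), x, y, TrainConfig(seed=4, max_epochs=80)
        )
        gamma = rec.series("gamma")
        assert np.all(gamma >= 0.0) and np.all(gamma <= m.n_params)

    def test_validation_stop_counts_consecutive_failures(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(100, 1))
        y = np.sin(3 * x) + rng.normal(0, 0.3, (100, 1))
        cfg = TrainConfig(seed=5, max_validation_failures=6)
        _, rec = train_bayesian_regularization(MLPRegressor(1, 8, 1), x, y, cfg)
        if rec.stop_reason == "validation_failures":
            val = rec.series("val_error")
            best_before_tail = val[: -cfg.max_validation_failures].min()
            assert np.all(val[-cfg.max_validation_failures :] >= best_before_tail)

    def test_training_is_reproducible(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(50, 1))
        y = x**3 + rng.normal(0, 0.1, (50, 1))
        m1, _ = train_bayesian_regularization(
            MLPRegressor(1, 5, 1), x, y, TrainConfig(seed=7)
        )
        m2, _ = train_bayesian_regularization(
            MLPRegressor(1, 5, 1), x, y, TrainConfig(seed=7)
        )
        assert np.array_equal(m1.get_params(), m2.get_params())

    def test_batch_objective_is_row_order_independent(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(60, 1))
        y = 2 * x + 1 + rng.normal(0, 0.05, (60, 1))
        idx = split_data(60, seed=1)
        m1, _ = train_bayesian_regularization(
            MLPRegressor(1, 4, 1), x, y, TrainConfig(seed=2), indices=idx
        )
        perm_train = np.random.default_rng(9).permutation(idx[0])
        m2, _ = train_bayesian_regularization(
            MLPRegressor(1, 4, 1), x, y, TrainConfig(seed=2),
            indices=(perm_train, idx[1], idx[2]),
        )
        grid = np.linspace(-2, 2, 20)[:, None]
        assert np.allclose(m1.forward(grid), m2.forward(grid), atol=1e-6)

    def test_regularization_self_tunes_under_larger_alpha_init(self):
        x = np.linspace(-2, 3, 60)[:, None]
        y = 2 * x + 1
        grid = np.linspace(-2, 3, 30)[:, None]
        preds = []
        for alpha0 in (0.01, 0.1):
            m, _ = train_bayesian_regularization(
                MLPRegressor(1, 6, 1), x, y,
                TrainConfig(seed=11, alpha_init=alpha0),
            )
            preds.append(m.forward(grid))
        assert np.allclose(preds[0], preds[1], atol=0.05)

    def test_serialization_round_trip_preserves_forward(self, tmp_path):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(40, 1))
        y = np.tanh(x) + rng.normal(0, 0.05, (40, 1))
        m, _ = train_bayesian_regularization(
            MLPRegressor(1, 4, 1), x, y, TrainConfig(seed=12)
        )
        path = tmp_path / "model.json"
        m.to_json(path)
        back = MLPRegressor.from_json(path)
        grid = np.linspace(-3, 3, 50)[:, None]
        assert np.array_equal(m.forward(grid), back.forward(grid))


class TestStages:
    def test_stage2_recovers_affine_pulse_pressure_structure(self):
        rng = np.random.default_rng(0)
        map_ = rng.uniform(70, 120, 400)
        pp0 = 45.0
        sbp = map_ + 2 * pp0 / 3
        dbp = map_ - pp0 / 3
        table = pd.DataFrame({"map": map_, "sbp": sbp, "dbp": dbp})
        model, rec = fit_stage2_map_to_bp(table, TrainConfig(seed=1))
        pred = model.forward(map_[rec.test_idx][:, None])
        for j, truth in enumerate((sbp, dbp)):
            r = np.corrcoef(pred[:, j], truth[rec.test_idx])[0, 1]
            assert r > 0.999

    def test_stage1_noiseless_affine_ground_truth(self):
        rng = np.random.default_rng(1)
        map_ = rng.uniform(70, 115, 150)
        ppg = 3500.0 + 6.7 * map_
        dbp = 0.88 * map_ + 5.0
        sbp = 3 * map_ - 2 * dbp
        table = pd.DataFrame({"ppg": ppg, "map": map_, "sbp": sbp, "dbp": dbp})
        model, rec = fit_stage1_ppg_to_map(table, TrainConfig(seed=2))
        pred = model.forward(ppg[rec.test_idx][:, None]).ravel()
        r = np.corrcoef(pred, map_[rec.test_idx])[0, 1]
        assert r > 0.999

    def test_stage1_requires_variance_and_enough_rows(self):
        table = pd.DataFrame({"ppg": np.full(150, 4100.0), "map": np.linspace(70, 120, 150)})
        with pytest.raises(ValueError, match="[Dd]egenerate"):
            fit_stage1_ppg_to_map(table)
        small = pd.DataFrame({"ppg": np.linspace(1, 2, 10), "map": np.linspace(70, 120, 10)})
        with pytest.raises(ValueError, match="30"):
            fit_stage1_ppg_to_map(small)

    def test_stage2_requires_map_variance(self):
        table = pd.DataFrame(
            {"map": np.full(100, 93.0), "sbp": np.linspace(110, 150, 100),
             "dbp": np.linspace(60, 90, 100)}
        )
        with pytest.raises(ValueError, match="[Dd]egenerate"):
            fit_stage2_map_to_bp(table)


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(3)
    map_c = rng.uniform(65, 125, 500)
    dbp = 0.88 * map_c - 7.5
    sbp = 3 * map_c - 2 * dbp
    cohort = pd.DataFrame({"map": map_c, "sbp": sbp, "dbp": dbp})
    stage2, _ = fit_stage2_map_to_bp(cohort, TrainConfig(seed=4))
    map_p = rng.uniform(70, 115, 150)
    ppg = 3500.0 + 6.7 * map_p
    paired = pd.DataFrame({"ppg": ppg, "map": map_p})
    stage1, _ = fit_stage1_ppg_to_map(paired, TrainConfig(seed=5))
    return CombinatorialModel(stage1, stage2), map_p, ppg


class TestCombinatorial:

    def test_noiseless_cascade_recovers_bp(self, trained):
        model, map_p, ppg = trained
        sbp_hat, dbp_hat, map_hat = model.predict_bp(ppg)
        dbp_true = 0.88 * map_p - 7.5
        sbp_true = 3 * map_p - 2 * dbp_true
        assert np.max(np.abs(map_hat - map_p)) < 0.5
        assert np.max(np.abs(sbp_hat - sbp_true)) < 0.5
        assert np.max(np.abs(dbp_hat - dbp_true)) < 0.5

    def test_predicted_sbp_exceeds_dbp(self, trained):
        model, _, ppg = trained
        sbp_hat, dbp_hat, _ = model.predict_bp(ppg)
        assert np.mean(sbp_hat > dbp_hat) >= 0.99

    def test_prediction_is_deterministic(self, trained):
        model, _, ppg = trained
        a = model.predict_bp(ppg)
        b = model.predict_bp(ppg)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_untrained_stage_rejected(self):
        model = CombinatorialModel(MLPRegressor(1, 10, 1), MLPRegressor(1, 30, 2))
        with pytest.raises(ValueError, match="trained"):
            model.predict_bp([4100.0])

    def test_stage_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            CombinatorialModel(MLPRegressor(1, 10, 2), MLPRegressor(1, 30, 2))

    def test_json_round_trip(self, trained, tmp_path):
        model, _, ppg = trained
        path = tmp_path / "combi.json"
        model.to_json(path)
        back = CombinatorialModel.from_json(path)
        for x, y in zip(model.predict_bp(ppg), back.predict_bp(ppg)):
            assert np.array_equal(x, y)
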