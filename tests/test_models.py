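"""Surrogate model families: fitting, prediction, scaling round-trips,
model comparison and hyperparameter search."""

import numpy as np
import pandas as pd
import pytest

from choopt.datastore import INPUT_FEATURES, OUTPUT_KPIS
from choopt.models import (
    FAMILIES,
    ModelSpec,
    compare_models,
    default_specs,
    fit_surrogate,
    predict_kpis,
    tune_hyperparameters,
)


def _linear_frame(seed=0, n=200, n_runs=10):
    """Noiseless linear map from the 9 inputs to 4 outputs."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1, 1, size=(n, 9))
    W = rng.normal(size=(9, 4))
    df = pd.DataFrame(X, columns=INPUT_FEATURES)
    for j, col in enumerate(OUTPUT_KPIS):
        df[col] = X @ W[:, j] + j
    df["run_id"] = [f"r{i % n_runs}" for i in range(n)]
    return df


class TestFitPredict:
    def test_linear_family_recovers_linear_truth(self):
        df = _linear_frame()
        model = fit_surrogate(df, ModelSpec(family="linear"))
        assert model.provenance["train_r2"] >= 0.999

    @pytest.mark.parametrize("family", FAMILIES)
    def test_deterministic_given_seed(self, family, full58_clean):
        spec = ModelSpec(family=family, hidden_layers=(20, 20), max_iter=300)
        sub = full58_clean.head(120)
        a = fit_surrogate(sub, spec, seed=7)
        b = fit_surrogate(sub, spec, seed=7)
        X = sub.head(15)
        pa, _ = predict_kpis(a, X)
        pb, _ = predict_kpis(b, X)
        pd.testing.assert_frame_equal(pa, pb)

    def test_prediction_shape_and_order(self):
        df = _linear_frame()
        model = fit_surrogate(df, ModelSpec(family="linear"))
        pred, flags = predict_kpis(model, df.head(7))
        assert pred.shape == (7, 4)
        assert list(pred.columns) == list(OUTPUT_KPIS)
        assert flags.shape == (7,)

    def test_training_point_predicted_within_residual(self):
        df = _linear_frame()
        model = fit_surrogate(df, ModelSpec(family="linear"))
        pred, _ = predict_kpis(model, df.head(1))
        truth = df.head(1)[list(OUTPUT_KPIS)].to_numpy()
        np.testing.assert_allclose(pred.to_numpy(), truth, atol=1e-6)

    def test_extrapolation_flagged(self):
        df = _linear_frame()
        model = fit_surrogate(df, ModelSpec(family="linear"))
        inside = df.head(1)[list(INPUT_FEATURES)]
        outside = inside.copy()
        outside["ph_setpoint"] = 99.0
        _, f_in = predict_kpis(model, inside)
        _, f_out = predict_kpis(model, outside)
        assert not f_in[0] and f_out[0]

    def test_feature_mismatch_error_lists_expectation(self):
        df = _linear_frame()
        model = fit_surrogate(df, ModelSpec(family="linear"))
        with pytest.raises(ValueError, match="ph_setpoint"):
            predict_kpis(model, df[["do_setpoint"]])

    def test_output_scaling_roundtrip(self):
        """Physical-unit predictions equal manually inverse-scaled scaled
        predictions."""
        from choopt.preprocess import apply_scaler, inverse_scaler
        df = _linear_frame()
        model = fit_surrogate(df, ModelSpec(family="linear"))
        X = df.head(5)[list(INPUT_FEATURES)].to_numpy()
        direct, _ = predict_kpis(model, X)
        scaled_pred = model.estimator.predict(apply_scaler(model.input_scaler, X))
        np.testing.assert_allclose(direct.to_numpy(),
                                   inverse_scaler(model.output_scaler, scaled_pred),
                                   atol=1e-9)

    def test_too_few_points_rejected(self):
        df = _linear_frame().head(10)
        with pytest.raises(ValueError, match="20"):
            fit_surrogate(df, ModelSpec(family="linear"))


class TestCompare:
    def test_all_families_master_linear_noiseless_data(self):
        """Noiseless linear truth through two inputs: every family should
        reach near-perfect held-out R² (the trees need enough estimators to
        average away partition granularity)."""
        rng = np.random.default_rng(0)
        n = 800
        X = rng.uniform(-1, 1, size=(n, 9))
        df = pd.DataFrame(X, columns=INPUT_FEATURES)
        for j, col in enumerate(OUTPUT_KPIS):
            df[col] = 2.0 * X[:, 0] - 1.5 * X[:, 1] + j
        df["run_id"] = [f"r{i % 20}" for i in range(n)]
        specs = {k: (ModelSpec(family=k, n_trees=100) if k == "tree_ensemble"
                     else ModelSpec(family=k, hidden_layers=(20, 20)))
                 for k in FAMILIES}
        res = compare_models(df, folds=3, specs=specs, seed=0,
                             learning_curve_fractions=(1.0,))
        for family, score in res.cv_r2.items():
            assert score >= 0.95, family

    def test_train_r2_at_least_cv_r2_on_average(self, full58_clean):
        specs = {"tree_ensemble": ModelSpec(family="tree_ensemble")}
        gaps = []
        for seed in range(10):
            res = compare_models(full58_clean, folds=3, specs=specs, seed=seed,
                                 learning_curve_fractions=(1.0,))
            gaps.append(res.train_r2["tree_ensemble"] - res.cv_r2["tree_ensemble"])
        assert np.mean(gaps) > 0

    def test_nonlinear_data_tree_beats_linear(self, full58_clean):
        specs = {"tree_ensemble": ModelSpec(family="tree_ensemble"),
                 "linear": ModelSpec(family="linear")}
        res = compare_models(full58_clean, folds=3, specs=specs, seed=0,
                             learning_curve_fractions=(1.0,))
        assert res.cv_r2["tree_ensemble"] > res.cv_r2["linear"]

    def test_folds_validation(self, full58_clean):
        with pytest.raises(ValueError, match="folds"):
            compare_models(full58_clean, folds=1)


class TestTune:
    def test_single_element_space(self, full58_clean):
        spec = ModelSpec(family="linear")
        best, trials = tune_hyperparameters(full58_clean.head(200), [spec], folds=2)
        assert best == spec
        assert len(trials) == 1

    def test_recovers_generating_architecture(self):
        """Grid containing the (near-)true model class wins or ties."""
        df = _linear_frame(n=300, n_runs=15)
        space = [ModelSpec(family="linear"),
                 ModelSpec(family="tree_ensemble", n_trees=4)]
        best, trials = tune_hyperparameters(df, space, folds=3, seed=0)
        assert best.family == "linear"

    def test_deterministic_trial_table(self, full58_clean):
        space = [ModelSpec(family="linear"),
                 ModelSpec(family="latent_projection")]
        _, a = tune_hyperparameters(full58_clean.head(300), space, folds=2, seed=3)
        _, b = tune_hyperparameters(full58_clean.head(300), space, folds=2, seed=3)
        pd.testing.assert_frame_equal(a.drop(columns="spec"), b.drop(columns="spec"))

    def test_empty_space_rejected(self, full58_clean):
        with pytest.raises(ValueError, match="empty"):
            tune_hyperparameters(full58_clean, [], folds=2)
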