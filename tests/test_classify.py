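from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from trfdr.classify import (
    ClassWeights,
    ConfusionMatrix,
    LogisticConfig,
    PipelineConfig,
    compute_class_weights,
    confusion,
    confusion_rates,
    decide,
    fit_weighted_logistic,
    patient_loocv,
    predict_posterior,
    sens_spec,
    stratify,
    threshold_sweep,
)

from conftest import make_feature_frame


class TestClassWeights:
    def test_printed_tumor_weight(self):
        assert round(compute_class_weights(4818, 1812), 2) == 1.33

    def test_printed_no_tumor_weight(self):
        assert round(compute_class_weights(4818, 3006), 2) == 0.80

    def test_balanced_classes(self):
        assert compute_class_weights(100, 50) == 1.0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            compute_class_weights(100, 0)

    @pytest.mark.parametrize("n1,n0", [(1812, 3006), (7, 13), (1, 999)])
    def test_weight_identity_exact_rational(self, n1, n0):
        w = ClassWeights.from_counts(n1, n0)
        assert w.check_identity(n1, n0)
        # same identity in floating point, loose tolerance
        assert n1 * w.w_tumor + n0 * w.w_no_tumor == pytest.approx(n1 + n0)


class TestFitWeightedLogistic:
    def test_symmetric_two_point_data_zero_intercept(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array([1.0, 0.0])
        model = fit_weighted_logistic(X, y)
        assert abs(model.intercept) < 1e-6
        # separable data: either the gradient tolerance is met with a large
        # (but finite) coefficient, or the norm cap trips the separation flag
        assert model.converged or model.separation

    def test_equal_weights_match_sklearn_reference(self):
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(0)
        X = rng.normal(size=(300, 3))
        logits = 0.3 + X @ np.array([1.0, -0.7, 0.2])
        y = (rng.random(300) < expit(logits)).astype(float)
        model = fit_weighted_logistic(X, y)
        ref = LogisticRegression(C=np.inf, tol=1e-12, max_iter=5000).fit(X, y)
        assert model.intercept == pytest.approx(ref.intercept_[0], abs=1e-6)
        np.testing.assert_allclose(model.coefficients, ref.coef_[0], atol=1e-6)
        assert model.converged and model.grad_norm <= 1e-8

    def test_weight_equals_replication(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(80, 2))
        y = (rng.random(80) < 0.4).astype(float)
        w = np.where(y == 0, 2.0, 1.0)
        m_weighted = fit_weighted_logistic(X, y, w)
        X_dup = np.vstack([X, X[y == 0]])
        y_dup = np.concatenate([y, y[y == 0]])
        m_dup = fit_weighted_logistic(X_dup, y_dup)
        assert m_weighted.intercept == pytest.approx(m_dup.intercept, abs=1e-8)
        np.testing.assert_allclose(m_weighted.coefficients, m_dup.coefficients, atol=1e-8)

    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(2)
        n = 2000
        X = rng.normal(size=(n, 4))
        beta = np.array([0.8, -0.5, 0.3, 0.0])
        intercept = -0.2
        y = (rng.random(n) < expit(intercept + X @ beta)).astype(float)
        model = fit_weighted_logistic(X, y)
        # standard errors from the inverse Fisher information at the fit
        D = np.column_stack([np.ones(n), X])
        p = expit(model.intercept + X @ model.coefficients)
        H = (D * (p * (1 - p))[:, None]).T @ D
        se = np.sqrt(np.diag(np.linalg.inv(H)))
        est = np.concatenate([[model.intercept], model.coefficients])
        truth = np.concatenate([[intercept], beta])
        assert np.all(np.abs(est - truth) <= 3 * se)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            fit_weighted_logistic(np.zeros((3, 1)), np.array([0.0, 0.5, 1.0]))


class TestPredictDecide:
    def test_zero_model_gives_half(self):
        from trfdr.classify import LogisticModel

        model = LogisticModel(0.0, np.zeros(3), True, 0, 0.0)
        np.testing.assert_array_equal(
            predict_posterior(model, np.random.default_rng(0).normal(size=(5, 3))), 0.5
        )

    def test_hand_computed_posterior(self):
        from trfdr.classify import LogisticModel

        model = LogisticModel(0.5, np.array([2.0]), True, 0, 0.0)
        p = predict_posterior(model, np.array([[1.0]]))
        assert p[0] == pytest.approx(1.0 / (1.0 + np.exp(-2.5)), rel=1e-12)
        assert round(float(p[0]), 4) == 0.9241

    def test_monotone_in_feature_with_positive_coefficient(self):
        from trfdr.classify import LogisticModel

        model = LogisticModel(0.1, np.array([1.5]), True, 0, 0.0)
        xs = np.linspace(-3, 3, 20)[:, None]
        assert np.all(np.diff(predict_posterior(model, xs)) > 0)

    def test_dimension_mismatch_rejected(self):
        from trfdr.classify import LogisticModel

        model = LogisticModel(0.0, np.zeros(3), True, 0, 0.0)
        with pytest.raises(ValueError):
            predict_posterior(model, np.zeros((2, 2)))

    def test_decision_boundary(self):
        assert decide(np.array([0.51]))[0] == "tumor"
        assert decide(np.array([0.49]))[0] == "no_tumor"
        assert decide(np.array([0.50]))[0] == "tumor"  # documented tie rule
        assert decide(np.array([0.50]), tie_is_tumor=False)[0] == "no_tumor"


class TestPatientLOOCV:
    def test_two_patients_two_folds_disjoint_exhaustive(self):
        rng = np.random.default_rng(3)
        df = make_feature_frame(rng, n_patients=2, per_patient=20)
        cv = patient_loocv(df, PipelineConfig(n_pcs=3))
        assert len(cv.folds) == 2
        assert len(cv.frame) == len(df)

    def test_every_region_predicted_exactly_once(self):
        rng = np.random.default_rng(4)
        df = make_feature_frame(rng, n_patients=5, per_patient=16)
        cv = patient_loocv(df, PipelineConfig(n_pcs=4))
        key = cv.frame[["patient_id", "sample", "row", "col"]]
        assert not key.duplicated().any()
        assert len(cv.frame) == len(df)

    def test_well_separated_classes_classified_almost_perfectly(self):
        rng = np.random.default_rng(5)
        df = make_feature_frame(rng, n_patients=6, per_patient=40, shift=3.0)
        cv = patient_loocv(df, PipelineConfig(n_pcs=4))
        cm = confusion(cv)
        sens, spec = sens_spec(cm)
        assert sens > 0.95 and spec > 0.95

    def test_single_class_training_fold_skipped(self):
        rng = np.random.default_rng(6)
        df = make_feature_frame(rng, n_patients=2, per_patient=20)
        # patient 0 becomes all-tumor: leaving patient 1 out trains on one class
        df.loc[df["patient_id"] == "P000", "label"] = "tumor"
        cv = patient_loocv(df, PipelineConfig(n_pcs=2))
        errors = [f for f in cv.folds if "error" in f]
        assert len(errors) == 1 and errors[0]["patient_id"] == "P001"

    def test_global_modes_run(self):
        rng = np.random.default_rng(7)
        df = make_feature_frame(rng, n_patients=3, per_patient=20)
        cv = patient_loocv(df, PipelineConfig(n_pcs=4, leakage_mode="global",
                                              weight_mode="global"))
        assert len(cv.frame) == len(df)

    def test_threshold_coherence_on_fixed_result(self):
        rng = np.random.default_rng(8)
        df = make_feature_frame(rng, n_patients=4, per_patient=30, shift=1.0)
        cv = patient_loocv(df, PipelineConfig(n_pcs=4))
        sweep = threshold_sweep(cv, np.linspace(0.0, 1.0, 21))
        assert np.all(np.diff(sweep["sensitivity"]) <= 1e-12)
        assert np.all(np.diff(sweep["specificity"]) >= -1e-12)


class TestStratify:
    def _frame(self):
        return pd.DataFrame([
            dict(patient_id="A", p_tumor=80, p_fibro=10, p_adipose=10, label="tumor"),
            dict(patient_id="A", p_tumor=75, p_fibro=25, p_adipose=0, label="tumor"),
            dict(patient_id="A", p_tumor=50, p_fibro=25, p_adipose=25, label="tumor"),
            dict(patient_id="A", p_tumor=10, p_fibro=45, p_adipose=45, label="tumor"),
            dict(patient_id="A", p_tumor=100, p_fibro=0, p_adipose=0, label="tumor"),
            dict(patient_id="B", p_tumor=0, p_fibro=50, p_adipose=50, label="no_tumor"),
            dict(patient_id="B", p_tumor=0, p_fibro=0, p_adipose=100, label="no_tumor"),
        ])

    def test_high_band(self):
        out = stratify(self._frame(), "high")
        assert set(out["p_tumor"]) == {80, 75, 100, 0}

    def test_medium_and_low_bands(self):
        assert set(stratify(self._frame(), "medium")["p_tumor"]) == {50, 0}
        assert set(stratify(self._frame(), "low")["p_tumor"]) == {10, 0}

    def test_no_tumor_records_kept_in_every_band(self):
        for subset in ("low", "medium", "high"):
            out = stratify(self._frame(), subset)
            assert (out["label"] == "no_tumor").sum() == 2

    def test_heterogeneous_only_excludes_homogeneous(self):
        out = stratify(self._frame(), "heterogeneous_only")
        assert 100 not in out[["p_tumor", "p_fibro", "p_adipose"]].to_numpy()

    def test_total_is_identity(self):
        df = self._frame()
        pd.testing.assert_frame_equal(stratify(df, "total"), df)

    def test_unknown_subset_rejected(self):
        with pytest.raises(ValueError):
            stratify(self._frame(), "bogus")


class TestConfusionAndMetrics:
    def test_all_correct_toy(self):
        df = pd.DataFrame({
            "label": ["tumor", "no_tumor"] * 3,
            "prediction": ["tumor", "no_tumor"] * 3,
        })
        cm = confusion(df)
        assert (cm.fn, cm.fp) == (0, 0)
        assert sens_spec(cm) == (1.0, 1.0)

    def test_six_region_hand_count(self):
        df = pd.DataFrame({
            "label": ["tumor", "tumor", "tumor", "no_tumor", "no_tumor", "no_tumor"],
            "prediction": ["tumor", "no_tumor", "tumor", "tumor", "no_tumor", "no_tumor"],
        })
        cm = confusion(df)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (2, 1, 1, 2)
        assert cm.n_tumor == 3 and cm.n_no_tumor == 3

    def test_printed_confusion_matrix_metrics(self):
        cm = ConfusionMatrix(tp=1399, fn=413, fp=963, tn=2043)
        sens, spec = sens_spec(cm)
        assert round(sens, 3) == 0.772
        assert round(spec, 3) == 0.680
        rates = confusion_rates(cm)
        assert round(100 * rates["precision_tumor"]) == 59
        assert round(100 * rates["precision_no_tumor"]) == 83
        assert round(100 * rates["fp_rate"]) == 32
        assert round(100 * rates["fn_rate"]) == 23

    def test_balanced_toy(self):
        assert sens_spec(ConfusionMatrix(1, 1, 1, 1)) == (0.5, 0.5)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            sens_spec(ConfusionMatrix(0, 0, 1, 1))
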