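import math

import numpy as np
import pandas as pd
import pytest

from trfdr.preprocess import (
    PCAModel,
    cumulative_variance,
    filter_eligibility,
    fit_pca,
    iqr_outlier_removal,
    log10_standardize,
    project,
)
from trfdr.types import FEATURE_COLUMNS

from conftest import make_feature_frame


def brute_force_quartile(values, q):
    """Linear-interpolation quantile coded independently of numpy."""
    s = sorted(values)
    pos = q * (len(s) - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def brute_force_iqr_keep(frame, columns, factor=1.5):
    keep = []
    bounds = {}
    for c in columns:
        q1 = brute_force_quartile(frame[c].tolist(), 0.25)
        q3 = brute_force_quartile(frame[c].tolist(), 0.75)
        bounds[c] = (q1 - factor * (q3 - q1), q3 + factor * (q3 - q1))
    for _, row in frame.iterrows():
        keep.append(all(bounds[c][0] <= row[c] <= bounds[c][1] for c in columns))
    return keep


class TestFilterEligibility:
    def test_bad_sum_removed(self):
        df = pd.DataFrame([
            dict(patient_id="A", p_tumor=40, p_fibro=40, p_adipose=30, label="tumor"),
            dict(patient_id="A", p_tumor=50, p_fibro=25, p_adipose=25, label="tumor"),
            dict(patient_id="A", p_tumor=0, p_fibro=50, p_adipose=50, label="no_tumor"),
        ])
        out = filter_eligibility(df)
        assert len(out) == 2
        assert (out[["p_tumor", "p_fibro", "p_adipose"]].sum(axis=1) == 100).all()

    def test_unpaired_patient_removed(self):
        df = pd.DataFrame([
            dict(patient_id="A", p_tumor=0, p_fibro=50, p_adipose=50, label="no_tumor"),
            dict(patient_id="A", p_tumor=0, p_fibro=0, p_adipose=100, label="no_tumor"),
            dict(patient_id="B", p_tumor=50, p_fibro=25, p_adipose=25, label="tumor"),
            dict(patient_id="B", p_tumor=0, p_fibro=50, p_adipose=50, label="no_tumor"),
        ])
        out, counts = filter_eligibility(df, return_counts=True)
        assert set(out["patient_id"]) == {"B"}
        assert counts["unpaired_patient"] == 2

    def test_multi_observer_removed(self):
        df = pd.DataFrame([
            dict(patient_id="A", p_tumor=50, p_fibro=25, p_adipose=25,
                 label="tumor", single_observer=True),
            dict(patient_id="A", p_tumor=0, p_fibro=50, p_adipose=50,
                 label="no_tumor", single_observer=True),
            dict(patient_id="A", p_tumor=0, p_fibro=0, p_adipose=100,
                 label="no_tumor", single_observer=False),
        ])
        assert len(filter_eligibility(df)) == 2

    def test_all_valid_unchanged_and_idempotent(self):
        rng = np.random.default_rng(0)
        df = make_feature_frame(rng)
        once = filter_eligibility(df)
        pd.testing.assert_frame_equal(once, df)
        pd.testing.assert_frame_equal(filter_eligibility(once), once)


class TestIQROutlierRemoval:
    def _frame(self, values, n_features=3):
        data = {c: [5.0] * len(values) for c in FEATURE_COLUMNS}
        data[FEATURE_COLUMNS[0]] = list(values)
        return pd.DataFrame(data)

    def test_single_outlier_removed(self):
        df = self._frame(list(range(1, 11)) + [100])
        out = iqr_outlier_removal(df)
        assert len(out) == 10
        assert 100 not in out[FEATURE_COLUMNS[0]].tolist()

    def test_identical_records_kept(self):
        df = self._frame([7.0] * 8)
        assert len(iqr_outlier_removal(df)) == 8

    def test_all_in_bounds_unchanged(self):
        df = self._frame([1, 2, 3, 4, 5, 6])
        pd.testing.assert_frame_equal(iqr_outlier_removal(df), df)

    def test_idempotent(self):
        df = self._frame(list(range(1, 11)) + [100])
        once = iqr_outlier_removal(df)
        pd.testing.assert_frame_equal(iqr_outlier_removal(once), once)

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(5)
        cols = FEATURE_COLUMNS[:3]
        for _ in range(20):
            df = pd.DataFrame(
                rng.lognormal(0, 1, size=(20, 3)), columns=cols
            )
            got = iqr_outlier_removal(df, columns=cols)
            expected = df[brute_force_iqr_keep(df, cols)]
            pd.testing.assert_frame_equal(got, expected)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            iqr_outlier_removal(self._frame([1, 2, 3]))


class TestLog10Standardize:
    def test_fit_set_becomes_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        X = rng.lognormal(0, 1, size=(50, 4))
        Z, stats = log10_standardize(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)

    def test_constant_column_rejected(self):
        X = np.column_stack([np.full(10, 100.0), np.arange(1.0, 11.0)])
        with pytest.raises(ValueError, match="zero variance"):
            log10_standardize(X)

    def test_nonpositive_rejected_with_location(self):
        X = np.ones((5, 2))
        X[3, 1] = 0.0
        with pytest.raises(ValueError, match="record 3"):
            log10_standardize(X)

    def test_held_out_row_matches_hand_computation(self):
        train = np.array([[1.0], [10.0], [100.0]])  # logs 0, 1, 2
        _, stats = log10_standardize(train)
        Z, _ = log10_standardize(np.array([[1000.0]]), stats)
        sd = math.sqrt(2.0 / 3.0)  # population sd of {0, 1, 2}
        assert Z[0, 0] == pytest.approx((3.0 - 1.0) / sd, rel=1e-12)


class TestPCA:
    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        Z, _ = log10_standardize(rng.lognormal(0, 1, size=(60, 13)))
        model = fit_pca(Z)
        assert model.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(model.variance_fractions >= 0)
        assert np.all(np.diff(model.variance_fractions) <= 1e-12)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(3)
        model = fit_pca(rng.normal(size=(40, 6)))
        np.testing.assert_allclose(model.loadings.T @ model.loadings, np.eye(6), atol=1e-8)

    def test_degenerate_direction_gives_zero_fraction(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        X3 = np.column_stack([X, X[:, 0] + X[:, 1]])  # linearly dependent
        model = fit_pca(X3)
        assert model.variance_fractions[-1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(5, 3))
        model = fit_pca(X)
        # oracle: SVD route, independently coded
        Xc = X - X.mean(axis=0)
        _, svals, vt = np.linalg.svd(Xc, full_matrices=True)
        var = svals**2 / (len(X) - 1)
        np.testing.assert_allclose(model.variance_fractions, var / var.sum(), atol=1e-10)
        for j in range(3):
            v = vt[j]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(model.loadings[:, j], v, atol=1e-8)

    def test_full_projection_reconstructs_input(self):
        rng = np.random.default_rng(7)
        Z, _ = log10_standardize(rng.lognormal(0, 0.5, size=(30, 13)))
        model = fit_pca(Z)
        scores = project(Z, model, 13)
        np.testing.assert_allclose(scores @ model.loadings.T, Z, atol=1e-8)

    def test_perfectly_correlated_pair_captured_by_one_component(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=40)
        model = fit_pca(np.column_stack([a, 2 * a]))
        assert cumulative_variance(model, 1) == pytest.approx(1.0, abs=1e-12)

    def test_projection_matches_brute_force(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(10, 4))
        model = fit_pca(X)
        k = 2
        np.testing.assert_allclose(project(X, model, k),
                                   np.dot(X, model.loadings[:, :k]), atol=1e-12)

    def test_k_out_of_range_rejected(self):
        model = fit_pca(np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(ValueError):
            project(np.zeros((2, 3)), model, 4)
        with pytest.raises(ValueError):
            cumulative_variance(model, 0)


class TestCumulativeVariancePrintedFractions:
    # printed per-component variance fractions from the published loading table
    PRINTED = [0.398, 0.209, 0.164, 0.076, 0.067, 0.032, 0.023, 0.019,
               0.007, 0.004, 0.0, 0.0, 0.0]

    def _model(self):
        return PCAModel(np.eye(13), np.array(self.PRINTED))

    def test_first_four_sum_to_0847(self):
        assert cumulative_variance(self._model(), 4) == pytest.approx(0.847, abs=1e-12)

    def test_first_two_sum_to_0607(self):
        assert cumulative_variance(self._model(), 2) == pytest.approx(0.607, abs=1e-12)

    def test_fitted_model_k13_is_exactly_one(self):
        rng = np.random.default_rng(10)
        Z, _ = log10_standardize(rng.lognormal(0, 1, size=(40, 13)))
        assert cumulative_variance(fit_pca(Z), 13) == pytest.approx(1.0, abs=1e-10)
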