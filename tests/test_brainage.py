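"""Model-fitting chain: deconfounder, SVD, bias correction, prediction
contract and the cross-validation protocol (with a brute-force oracle)."""

import numpy as np
import pandas as pd
import pytest

from neuroage.brainage import (
    BrainAgeModel,
    BrainAgeResults,
    SchemaError,
    cross_validate,
    fit_bias_correction,
    fit_deconfounder,
    fit_svd,
    performance_metrics,
)
from neuroage.config import SimulationConfig
from neuroage.simulate import generate_longitudinal_cohort, generate_training_cohort


class TestDeconfounder:
    def test_intercept_only_centres_features(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((30, 4)) + 5.0
        _, resid = fit_deconfounder(x, None)
        np.testing.assert_allclose(resid, x - x.mean(axis=0), atol=1e-12)

    def test_exact_linear_function_of_confounds_gives_zero_residuals(self):
        rng = np.random.default_rng(1)
        c = rng.standard_normal((40, 3))
        x = c @ rng.standard_normal((3, 6)) + 2.0
        _, resid = fit_deconfounder(x, c)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_residuals_uncorrelated_with_confounds(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((60, 8))
        c = rng.standard_normal((60, 4))
        _, resid = fit_deconfounder(x, c)
        corr = max(
            abs(np.corrcoef(resid[:, j], c[:, i])[0, 1])
            for j in range(8)
            for i in range(4)
        )
        assert corr < 1e-10

    def test_rank_deficient_confounds_warn(self):
        rng = np.random.default_rng(3)
        c = rng.standard_normal((20, 2))
        c = np.column_stack([c, c[:, 0]])  # duplicated column
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit_deconfounder(rng.standard_normal((20, 3)), c)


class TestSVD:
    def test_exact_rank_three_cumulative_variance_one(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((50, 3)) @ rng.standard_normal((3, 20))
        basis, var, _ = fit_svd(x, 3)
        assert var.sum() == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError, match="rank"):
            fit_svd(x, 10)

    def test_isotropic_noise_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((40, 25))
        basis, var, _ = fit_svd(x, 1)
        evals = np.linalg.eigvalsh(x.T @ x)
        assert var[0] == pytest.approx(evals.max() / evals.sum(), rel=1e-10)

    def test_full_rank_projection_reconstructs(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((15, 8))
        basis, _, _ = fit_svd(x, 8)
        np.testing.assert_allclose(x @ basis @ basis.T, x, atol=1e-10)


class TestBiasCorrection:
    def test_three_points_saturated_quadratic_zero_deltas(self):
        gamma, corrected = fit_bias_correction(
            np.array([1.0, -2.0, 5.0]), np.array([50.0, 60.0, 70.0])
        )
        np.testing.assert_allclose(corrected, 0.0, atol=1e-9)

    def test_corrected_deltas_orthogonal_to_age_basis(self):
        rng = np.random.default_rng(7)
        y = rng.uniform(45, 82, 200)
        _, corrected = fit_bias_correction(rng.standard_normal(200), y)
        assert abs(np.corrcoef(corrected, y)[0, 1]) < 1e-10
        assert abs(np.corrcoef(corrected, y**2)[0, 1]) < 1e-10


class TestFitAndPredict:
    def test_perfect_linear_age_signal_gives_zero_raw_delta(self):
        rng = np.random.default_rng(8)
        y = rng.uniform(45, 80, 40)
        x = np.outer(y - y.mean(), rng.standard_normal(10))
        res = BrainAgeModel(x, y, k=1).fit()
        np.testing.assert_allclose(res.train_delta_raw, 0.0, atol=1e-8)
        np.testing.assert_allclose(res.bias_coefficients, 0.0, atol=1e-8)

    def test_training_set_prediction_reproduces_in_sample(self, fitted_stratum):
        res, idp, ages = fitted_stratum
        rec = res.predict(idp.data, ages, idp.confounds)
        np.testing.assert_allclose(rec["Y_B"], res.train_predictions, atol=1e-8)
        np.testing.assert_allclose(rec["delta_raw"], rec["Y_B"] - rec["Y"], atol=1e-12)
        assert abs(rec["delta"].mean()) < 1e-8

    def test_duplicated_row_gives_identical_records(self, fitted_stratum):
        res, idp, ages = fitted_stratum
        x2 = pd.concat([idp.data.iloc[[0]], idp.data.iloc[[0]]])
        c2 = pd.concat([idp.confounds.iloc[[0]], idp.confounds.iloc[[0]]])
        rec = res.predict(x2, np.array([ages[0], ages[0]]), c2)
        assert rec["Y_B"].iloc[0] == rec["Y_B"].iloc[1]
        assert rec["delta"].iloc[0] == rec["delta"].iloc[1]

    def test_schema_errors(self, fitted_stratum):
        res, idp, ages = fitted_stratum
        renamed = idp.data.rename(columns={idp.data.columns[0]: "rogue"})
        with pytest.raises(SchemaError):
            res.predict(renamed, ages, idp.confounds)
        with pytest.raises(SchemaError):
            res.predict(idp.data.to_numpy()[:, :-1], ages)
        with pytest.raises(SchemaError):
            res.predict(idp.data, ages)  # missing confound columns

    def test_unseen_cohort_delta_uncorrelated_with_age(self, small_config):
        cohort, idps = generate_training_cohort(small_config)
        lon, lidps, _ = generate_longitudinal_cohort(small_config)
        idx = cohort.set_index("participant_id")
        lidx = lon.set_index("participant_id")
        deltas, ages = [], []
        for s in ("F", "M"):
            idp = idps[(s, "GM")]
            res = BrainAgeModel(
                idp.data,
                idx.loc[idp.data.index, "age"].to_numpy(float),
                idp.confounds,
                k=15,
            ).fit()
            new = lidps[(s, "GM", "t1")]
            a = lidx.loc[new.data.index, "age_t1"].to_numpy(float)
            rec = res.predict(new.data, a, new.confounds)
            deltas.append(rec["delta"].to_numpy())
            ages.append(a)
        delta = np.concatenate(deltas)
        age = np.concatenate(ages)
        assert abs(np.corrcoef(delta, age)[0, 1]) < 2 / np.sqrt(len(delta))

    def test_age_shift_equivariance(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((80, 12))
        y = rng.uniform(45, 80, 80)
        r1 = BrainAgeModel(x, y, k=4).fit()
        r2 = BrainAgeModel(x, y + 10.0, k=4).fit()
        np.testing.assert_allclose(
            r2.train_predictions, r1.train_predictions + 10.0, atol=1e-6
        )
        np.testing.assert_allclose(r2.train_delta, r1.train_delta, atol=1e-6)

    def test_degenerate_age_vector_raises(self):
        x = np.random.default_rng(0).standard_normal((20, 5))
        with pytest.raises(ValueError, match="degenerate"):
            BrainAgeModel(x, np.full(20, 60.0), k=2)

    def test_save_load_roundtrip(self, fitted_stratum, tmp_path):
        res, idp, ages = fitted_stratum
        path = tmp_path / "model.json"
        res.save(path)
        loaded = BrainAgeResults.load(path)
        rec1 = res.predict(idp.data, ages, idp.confounds)
        rec2 = loaded.predict(idp.data, ages, idp.confounds)
        np.testing.assert_allclose(rec1["delta"], rec2["delta"], atol=1e-12)
        assert loaded.model.stratum == ("F", "GM")

    def test_summary_mentions_stratum_and_metrics(self, fitted_stratum):
        res, _, _ = fitted_stratum
        text = res.summary()
        assert "GM" in text and "MAE" in text


class TestPerformanceMetrics:
    def test_hand_values(self):
        pm = performance_metrics([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert pm.r == pytest.approx(-1.0)
        assert pm.mae == pytest.approx(4.0 / 3.0)
        pm = performance_metrics([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert pm.r == pytest.approx(1.0)
        assert pm.mae == pytest.approx(1.0)

    def test_zero_variance_reported_as_nan(self):
        pm = performance_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(pm.r)
        assert pm.mae == pytest.approx(1.0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            performance_metrics([1.0], [1.0])
        with pytest.raises(ValueError):
            performance_metrics([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCrossValidation:
    def test_parameter_validation(self):
        x = np.random.default_rng(0).standard_normal((30, 5))
        y = np.arange(30.0)
        with pytest.raises(ValueError):
            cross_validate(x, y, folds=1, k=2)
        with pytest.raises(ValueError):
            cross_validate(x, y, repeats=0, k=2)

    def test_every_subject_predicted_once_per_repetition(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((40, 8))
        y = rng.uniform(45, 80, 40)
        cv = cross_validate(x, y, k=3, folds=5, repeats=3, seed=0)
        for rep in range(3):
            counts = np.bincount(cv.fold_assignments[rep], minlength=5)
            assert counts.sum() == 40 and (counts > 0).all()
        assert cv.oof_predictions.shape == (3, 40)

    def test_reduced_protocol_equals_brute_force_oracle(self):
        """Re-fit every fold with independent numpy code and compare."""
        rng = np.random.default_rng(2)
        n, m, k, folds = 60, 12, 4, 5
        x = rng.standard_normal((n, m))
        y = rng.uniform(45, 80, n)
        c = rng.standard_normal((n, 2))
        cv = cross_validate(
            x, y, c, k=k, folds=folds, repeats=2, seed=11, stratify_by_age=False
        )
        for rep in range(2):
            assign = cv.fold_assignments[rep]
            oracle = np.empty(n)
            for f in range(folds):
                te, tr = assign == f, assign != f
                dz = np.column_stack([np.ones(tr.sum()), c[tr]])
                w = np.linalg.pinv(dz) @ x[tr]
                xr = x[tr] - dz @ w
                mu, sd = xr.mean(0), xr.std(0)
                xs = (xr - mu) / sd
                _, _, vt = np.linalg.svd(xs, full_matrices=False)
                basis = vt[:k].T
                u = xs @ basis
                du = np.column_stack([np.ones(tr.sum()), u])
                beta = np.linalg.lstsq(du, y[tr], rcond=None)[0]
                dz_te = np.column_stack([np.ones(te.sum()), c[te]])
                xs_te = (x[te] - dz_te @ w - mu) / sd
                oracle[te] = (
                    np.column_stack([np.ones(te.sum()), xs_te @ basis]) @ beta
                )
            np.testing.assert_allclose(cv.oof_predictions[rep], oracle, atol=1e-8)

    def test_cv_r_monotone_in_signal_to_noise(self):
        rs = []
        for snr in (0.3, 1.5, 8.0):
            cfg = SimulationConfig(
                n_train=200, n_idps=30, signal_to_noise=snr, seed=21
            )
            cohort, idps = generate_training_cohort(cfg)
            idp = idps[("F", "WM")]
            ages = (
                cohort.set_index("participant_id")
                .loc[idp.data.index, "age"]
                .to_numpy(float)
            )
            cv = cross_validate(
                idp.data, ages, idp.confounds, k=8, folds=5, repeats=1, seed=3
            )
            rs.append(cv.r_mean)
        assert rs[0] < rs[1] < rs[2]
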