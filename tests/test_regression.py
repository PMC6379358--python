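"""Least-squares solver, prediction, error statistics, LOOCV, Bland-Altman."""

import numpy as np
import pandas as pd
import pytest

from lacest.errors import (FitError, FoldError, StratificationError,
                           ValidationError)
from lacest.features import (FeatureSpec, build_design_matrix,
                             fit_standardizer)
from lacest.regression import (RankDeficiencyWarning,
                               bland_altman, error_stats, fit_least_squares,
                               fit_stratified, load_model, loocv, predict,
                               save_model)
from lacest.synth import SynthConfig, generate_cohort


class TestFit:
    def test_exact_line(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
        m = fit_least_squares(X, [1.0, 3.0, 5.0])
        np.testing.assert_allclose(m.coefficients, [1.0, 2.0], atol=1e-12)
        assert m.rank == 2 and not m.rank_deficient

    def test_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            X = rng.standard_normal((50, 10))
            y = rng.standard_normal(50)
            m = fit_least_squares(X, y)
            oracle = np.linalg.pinv(X) @ y
            assert np.max(np.abs(m.coefficients - oracle)) < 1e-8

    def test_matches_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(40), rng.standard_normal((40, 5))])
        y = rng.standard_normal(40)
        m = fit_least_squares(X, y)
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(m.coefficients, ols.params, atol=1e-8)

    def test_duplicated_column_minimum_norm(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(30), rng.standard_normal(30)])
        y = 2.0 + 3.0 * X[:, 1] + rng.normal(0, 0.1, 30)
        Xdup = np.column_stack([X, X[:, 1]])
        with pytest.warns(RankDeficiencyWarning):
            m = fit_least_squares(Xdup, y)
        full = fit_least_squares(X, y)
        # minimum-norm solution splits the shared coefficient equally
        assert m.coefficients[1] == pytest.approx(m.coefficients[2])
        assert m.coefficients[1] * 2 == pytest.approx(full.coefficients[1])
        np.testing.assert_allclose(Xdup @ m.coefficients,
                                   X @ full.coefficients, atol=1e-10)
        assert m.rank_deficient

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(FitError):
            fit_least_squares(np.zeros((0, 2)), [])
        with pytest.raises(ValidationError):
            fit_least_squares(np.array([[1.0], [np.nan]]), [1.0, 2.0])

    def test_in_sample_residuals_sum_to_zero(self, cohort31):
        spec = FeatureSpec(variables=("vt", "bf", "ex_hr"))
        params = fit_standardizer(cohort31, spec)
        X = build_design_matrix(cohort31, spec, params)
        y = np.asarray(cohort31.lactate_vector())
        m = fit_least_squares(X, y)
        resid = y - X.values @ m.coefficients
        assert abs(resid.sum()) < 1e-9


class TestPredict:
    def test_interpolates_training_set(self):
        frame = pd.DataFrame({"vt": [0.5, 1.0, 1.5]})
        spec = FeatureSpec(variables=("vt",), degree=1, standardize=False)
        X = build_design_matrix(frame, spec)
        m = fit_least_squares(X, [1.0, 3.0, 5.0])
        np.testing.assert_allclose(predict(m, frame), [1.0, 3.0, 5.0],
                                   atol=1e-10)

    def test_intercept_only_is_constant(self, cohort31):
        spec = FeatureSpec(variables=(), standardize=False)
        X = build_design_matrix(cohort31, spec)
        m = fit_least_squares(X, np.asarray(cohort31.lactate_vector()))
        out = predict(m, cohort31)
        assert np.allclose(out, out[0])

    def test_matches_manual_dot_product(self, cohort31):
        spec = FeatureSpec(variables=("bf", "age"))
        params = fit_standardizer(cohort31, spec)
        X = build_design_matrix(cohort31, spec, params)
        y = np.asarray(cohort31.lactate_vector())
        m = fit_least_squares(X, y)
        # independently rebuild one design row and dot it with A
        t, s = cohort31.tests[7], cohort31.subject_map[
            cohort31.tests[7].subject_id]
        row = [1.0]
        for var, raw in (("bf", t.bf), ("age", s.age)):
            z = (raw - params.means[var]) / params.sds[var]
            row.extend([z, z ** 2, z ** 3])
        expected = float(np.dot(row, m.coefficients))
        assert predict(m, cohort31)[7] == pytest.approx(expected, abs=1e-10)

    def test_model_json_round_trip(self, cohort31, tmp_path):
        spec = FeatureSpec()
        params = fit_standardizer(cohort31, spec)
        X = build_design_matrix(cohort31, spec, params)
        m = fit_least_squares(X, np.asarray(cohort31.lactate_vector()))
        path = tmp_path / "model.json"
        save_model(m, path)
        m2 = load_model(path)
        np.testing.assert_allclose(predict(m, cohort31), predict(m2, cohort31),
                                   atol=1e-12)
        assert m2.stratum == m.stratum and m2.rank == m.rank


class TestErrorStats:
    def test_identical_vectors(self):
        st = error_stats([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert st.sum_squares == 0.0 and st.variance == 0.0

    def test_hand_computed(self):
        st = error_stats([2.0, 1.0], [1.0, 2.0])  # d = [1, -1]
        assert st.sum_squares == pytest.approx(2.0)
        assert st.variance == pytest.approx(2.0)  # D / (n-1) = 2/1
        assert st.sd ** 2 == pytest.approx(st.variance, abs=1e-12)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(4)
        y = rng.uniform(1.0, 10.0, 100)
        yhat = y + rng.normal(0, 0.5, 100)
        st = error_stats(y, yhat)
        D = sum((a - b) ** 2 for a, b in zip(y, yhat))
        assert abs(st.sum_squares - D) < 1e-12
        assert abs(st.variance - D / 99) < 1e-12
        np.testing.assert_allclose(st.percent_errors, (y - yhat) / y,
                                   atol=1e-12)

    def test_needs_two_observations(self):
        with pytest.raises(FitError):
            error_stats([1.0], [1.0])

    def test_rejects_nonpositive_measured(self):
        with pytest.raises(ValidationError):
            error_stats([0.0, 1.0], [1.0, 1.0])


class TestBlandAltman:
    def test_identical_vectors(self):
        ba = bland_altman([1.0, 2.0], [1.0, 2.0])
        assert ba.bias == 0.0
        assert ba.lower_loa == ba.upper_loa == 0.0

    def test_constant_difference(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.5, 2.5, 3.5])
        assert ba.bias == pytest.approx(0.5)
        assert ba.sd_diff == pytest.approx(0.0)
        assert ba.lower_loa == ba.upper_loa == pytest.approx(0.5)

    def test_limit_symmetry(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(2, 12, 500)
        yhat = y + rng.normal(0, 0.52, 500)
        ba = bland_altman(y, yhat)
        assert (ba.upper_loa - ba.bias) == pytest.approx(
            ba.bias - ba.lower_loa, abs=1e-12)
        assert (ba.upper_loa - ba.bias) == pytest.approx(
            1.96 * ba.sd_diff, abs=1e-12)

    def test_direction_is_estimated_minus_measured(self):
        ba = bland_altman([1.0, 1.0], [2.0, 2.0])
        assert ba.bias == pytest.approx(1.0)


class TestLoocv:
    def test_noiseless_linear_data_has_zero_mse(self):
        rng = np.random.default_rng(6)
        frame = pd.DataFrame({"vt": rng.uniform(1.0, 3.0, 10)})
        y = 2.0 + 1.5 * frame["vt"].to_numpy()
        spec = FeatureSpec(variables=("vt",), degree=1, standardize=False)
        # build a minimal Dataset carrying vt and lactate
        from conftest import make_subject, make_test
        from lacest.datamodel import Dataset, Intensity
        tests = [make_test(intensity=list(Intensity)[i % 3],
                           subject_id=f"S{i}", vt_l=v, lactate_mmol_l=yy)
                 for i, (v, yy) in enumerate(zip(frame["vt"], y))]
        subjects = [make_subject(subject_id=f"S{i}") for i in range(10)]
        ds = Dataset(subjects=subjects, tests=tests)
        res = loocv(ds, spec)
        assert res.mse < 1e-16
        np.testing.assert_allclose(res.predictions, y, atol=1e-8)

    def test_intercept_only_two_points(self):
        from conftest import make_subject, make_test
        from lacest.datamodel import Dataset, Intensity
        # measured lactate must be positive elsewhere, but loocv itself
        # only needs the lactate vector; use 0.0 and 2.0 per the identity
        subjects = [make_subject(subject_id=f"S{i}") for i in range(2)]
        tests = [make_test(subject_id=f"S{i}", lactate_mmol_l=v,
                           intensity=Intensity.LC)
                 for i, v in enumerate([0.0, 2.0])]
        ds = Dataset(subjects=subjects, tests=tests)
        spec = FeatureSpec(variables=(), standardize=False)
        res = loocv(ds, spec)
        np.testing.assert_allclose(res.predictions, [2.0, 0.0])
        assert res.mse == pytest.approx(4.0)

    def test_too_few_observations(self, trio_dataset):
        ds = trio_dataset.subset_tests([0])
        with pytest.raises(FoldError):
            loocv(ds, FeatureSpec(variables=(), standardize=False))

    def test_matches_hat_matrix_identity(self, cohort31):
        """With preprocessing fixed (no per-fold standardizer), refitting
        LOOCV equals the closed form e_i / (1 - h_ii) of the full fit."""
        spec = FeatureSpec(variables=("vt", "bf", "ex_hr", "age"),
                           standardize=False)
        X = build_design_matrix(cohort31, spec).values
        y = np.asarray(cohort31.lactate_vector())
        res = loocv(cohort31, spec)
        H = X @ np.linalg.pinv(X)
        e = y - H @ y
        loo_resid = e / (1.0 - np.diag(H))
        np.testing.assert_allclose(y - res.predictions, loo_resid, atol=1e-8)

    def test_loocv_mse_not_below_in_sample_mse(self):
        spec = FeatureSpec(variables=("vt", "bf", "ex_hr"))
        for seed in (0, 1, 2):
            ds = generate_cohort(SynthConfig(seed=seed))
            params = fit_standardizer(ds, spec)
            X = build_design_matrix(ds, spec, params)
            y = np.asarray(ds.lactate_vector())
            m = fit_least_squares(X, y)
            in_mse = float(np.mean((y - X.values @ m.coefficients) ** 2))
            assert loocv(ds, spec).mse >= in_mse - 1e-12


class TestStratified:
    def test_paper_strategy_bookkeeping(self, cohort31):
        res = fit_stratified(cohort31, FeatureSpec(), "paper",
                             run_loocv=False)
        assert set(res) == {"low_moderate", "high"}
        assert res["low_moderate"][0].n_train == 62
        assert res["high"][0].n_train == 31

    def test_combined_strategy_bookkeeping(self, cohort31):
        res = fit_stratified(cohort31, FeatureSpec(), "combined",
                             run_loocv=False)
        assert set(res) == {"combined"}
        assert res["combined"][0].n_train == 93

    def test_empty_stratum_rejected(self, cohort31):
        from lacest.datamodel import Intensity
        idx = [i for i, t in enumerate(cohort31.tests)
               if t.intensity is not Intensity.HC]
        with pytest.raises(StratificationError, match="high"):
            fit_stratified(cohort31.subset_tests(idx), FeatureSpec(), "paper")

    def test_report_invariants(self, cohort31):
        res = fit_stratified(cohort31, FeatureSpec(), "paper")
        for model, report in res.values():
            ba = report.bland_altman
            assert (ba.upper_loa - ba.bias) == pytest.approx(
                ba.bias - ba.lower_loa, abs=1e-12)
            d = report.loocv.predictions - report.measured
            assert report.loocv.mse == pytest.approx(float(np.mean(d ** 2)))
            assert report.in_sample.sd ** 2 == pytest.approx(
                report.in_sample.variance, abs=1e-12)
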