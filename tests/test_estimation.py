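"""ML fitting, fit indices, and the Satorra-Bentler scaling factor."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tractsem as ts
from tractsem.fitting import (ParameterIndex, delta_matrix, duplication_matrix,
                              loglikelihood, satorra_bentler_c)


class TestSampleMoments:
    def test_hand_computed_covariance(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 3.0]})
        S, N = ts.sample_moments(table)
        assert N == 3
        np.testing.assert_allclose(S.to_numpy(),
                                   [[1.0, 0.5], [0.5, 1.0]], atol=1e-15)

    def test_duplicated_column_warns_singular(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        table = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(30)})
        with pytest.warns(UserWarning, match="singular"):
            ts.sample_moments(table)

    def test_constant_column_errors(self):
        table = pd.DataFrame({"a": np.ones(20), "b": np.arange(20.0)})
        with pytest.raises(ValueError, match="zero-variance"):
            ts.sample_moments(table)

    def test_too_few_rows_errors(self):
        table = pd.DataFrame(np.random.default_rng(1).standard_normal((3, 4)))
        with pytest.raises(ValueError, match="more observations"):
            ts.sample_moments(table)

    def test_listwise_deletion(self):
        table = pd.DataFrame({"a": [1.0, 2, 3, np.nan, 5, 4, 2, 6, 1, 3],
                              "b": [2.0, 1, 4, 3, 2, 5, 6, 2, 3, 1]})
        _, N = ts.sample_moments(table)
        assert N == 9


class TestDiscrepancy:
    def test_zero_at_equality(self):
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert ts.f_ml(S, S) == pytest.approx(0.0, abs=1e-14)

    def test_hand_value(self):
        # S = I2, Sigma = 2 I2 -> 2 ln 2 + 1 - 2
        assert ts.f_ml(np.eye(2), 2 * np.eye(2)) == pytest.approx(
            2 * math.log(2) - 1, abs=1e-12)

    def test_nonnegative_on_random_pd_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            A = rng.standard_normal((4, 8))
            B = rng.standard_normal((4, 8))
            assert ts.f_ml(A @ A.T / 8, B @ B.T / 8) >= -1e-12

    def test_non_pd_sigma_raises(self):
        with pytest.raises(ValueError, match="positive definite"):
            ts.f_ml(np.eye(2), np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestChiSquarePvalue:
    def test_zero_discrepancy(self):
        assert ts.chi_square(0.0, 83) == 0.0
        assert ts.p_value(0.0, 1) == pytest.approx(1.0)

    def test_multiplier_conventions(self):
        assert ts.chi_square(0.1, 101) == pytest.approx(10.0)
        assert ts.chi_square(0.1, 101, "n") == pytest.approx(10.1)

    def test_df2_closed_form(self):
        # for df = 2 the survival function is exp(-x/2)
        assert ts.p_value(5.589, 2) == pytest.approx(math.exp(-5.589 / 2), rel=1e-12)
        assert round(ts.p_value(5.589, 2), 3) == 0.061

    def test_chi2_equal_df_against_distribution(self):
        for df in (1, 2, 5, 19):
            assert ts.p_value(df, df) == pytest.approx(stats.chi2.sf(df, df))


class TestRmsea:
    def test_point_formula(self):
        point, lo, _ = ts.rmsea(5.589, 2, 83)
        assert point == pytest.approx(math.sqrt((5.589 - 2) / (2 * 82)), rel=1e-12)
        assert lo == 0.0

    def test_chi2_below_df_gives_zero(self):
        point, lo, hi = ts.rmsea(0.189, 1, 83)
        assert point == 0.0 and lo == 0.0 and hi > 0.0

    def test_interval_against_brute_force_root_search(self):
        chi2, df, N = 23.4, 7, 150
        point, lo, hi = ts.rmsea(chi2, df, N)
        assert lo <= point <= hi
        for bound, target in ((lo, 0.95), (hi, 0.05)):
            # brute-force bisection on the noncentral CDF
            a, b = 0.0, 500.0
            for _ in range(200):
                mid = (a + b) / 2
                if stats.ncx2.cdf(chi2, df, mid) > target:
                    a = mid
                else:
                    b = mid
            assert bound == pytest.approx(math.sqrt(a / (df * (N - 1))), abs=1e-6)

    def test_df_zero_raises(self):
        with pytest.raises(ValueError):
            ts.rmsea(0.0, 0, 83)


class TestCfiSrmrBic:
    def test_cfi_arithmetic(self):
        assert ts.cfi(10, 5, 100, 6) == pytest.approx(1 - 5 / 94, rel=1e-12)
        assert ts.cfi(5, 5, 40, 6) == 1.0
        assert ts.cfi(40, 6, 40, 6) == 0.0

    def test_srmr_zero_and_hand_case(self):
        S = np.array([[1.0, 0.1], [0.1, 1.0]])
        assert ts.srmr(S, S) == 0.0
        assert ts.srmr(S, np.eye(2)) == pytest.approx(0.1 / math.sqrt(3), rel=1e-12)

    def test_srmr_invariant_to_joint_rescaling(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((3, 9))
        S = A @ A.T / 9
        B = rng.standard_normal((3, 9))
        sigma = B @ B.T / 9
        D = np.diag([10.0, 0.2, 1.0])
        assert ts.srmr(D @ S @ D, D @ sigma @ D) == pytest.approx(
            ts.srmr(S, sigma), rel=1e-12)

    def test_bic_arithmetic(self):
        assert ts.bic(-400.0, 9, 83) == pytest.approx(800 + 9 * math.log(83), rel=1e-12)
        assert ts.bic(-123.4, 0, 50) == pytest.approx(246.8)


class TestFitML:
    def test_saturated_model_zero_chi2(self):
        # three congeneric indicators: the one-factor model is
        # just-identified, so the fit is exact and chi2 vanishes
        rng = np.random.default_rng(5)
        eta = rng.standard_normal(200)
        y = np.outer(eta, [1.0, 0.8, 0.6]) + 0.5 * rng.standard_normal((200, 3))
        table = pd.DataFrame(y, columns=["a", "b", "c"])
        spec = ts.build_watershed_spec({"g": ["a", "b", "c"]})
        S, N = ts.sample_moments(table)
        res = ts.fit_ml(S, N, spec)
        assert res.df == 0
        assert res.chi_square == pytest.approx(0.0, abs=1e-6)
        assert res.f_ml >= -1e-12

    def test_two_factor_parameter_recovery_large_n(self):
        # independent generative code; all free parameters within 0.02
        rng = np.random.default_rng(2024)
        n = 100_000
        lam_true = {"PS~FI": 0.7, "WM~CI": 0.6}
        psi_true = {"psi[FI]": 1.0, "psi[CI]": 1.2, "psi[FI,CI]": 0.45}
        th_true = {"theta[PO]": 0.5, "theta[PS]": 0.9, "theta[VC]": 0.4,
                   "theta[WM]": 0.8}
        eta = rng.multivariate_normal([0, 0], [[1.0, 0.45], [0.45, 1.2]], size=n)
        y = np.column_stack([
            eta[:, 0], 0.7 * eta[:, 0], eta[:, 1], 0.6 * eta[:, 1],
        ]) + rng.standard_normal((n, 4)) * np.sqrt([0.5, 0.9, 0.4, 0.8])
        table = pd.DataFrame(y, columns=["PO", "PS", "VC", "WM"])
        spec = ts.build_watershed_spec({"FI": ["PO", "PS"], "CI": ["VC", "WM"]})
        S, N = ts.sample_moments(table)
        res = ts.fit_ml(S, N, spec)
        assert res.converged
        est = dict(zip(res.names, res.theta_natural))
        for truth in (lam_true, psi_true, th_true):
            for name, v in truth.items():
                assert est[name] == pytest.approx(v, abs=0.02), name

    def test_fixed_phi_untouched(self, study_table, watershed_spec):
        S, N = ts.sample_moments(study_table[list(watershed_spec.variables)])
        res = ts.fit_ml(S, N, watershed_spec, compute_baseline=False)
        p = watershed_spec.n_indicators
        np.testing.assert_array_equal(res.estimates.phi,
                                      S.to_numpy()[p:, p:])

    def test_scale_equivariance(self, study_table, two_factor_spec):
        cols = list(two_factor_spec.variables)
        S, N = ts.sample_moments(study_table[cols])
        res = ts.fit_ml(S, N, two_factor_spec)
        scaled = study_table[cols].copy()
        scaled["PS"] = scaled["PS"] * 10.0
        S2, _ = ts.sample_moments(scaled)
        res2 = ts.fit_ml(S2, N, two_factor_spec)
        for a, b in [(res.chi_square, res2.chi_square), (res.rmsea, res2.rmsea),
                     (res.cfi, res2.cfi), (res.srmr, res2.srmr)]:
            assert b == pytest.approx(a, abs=1e-6)
        est1 = dict(zip(res.names, res.theta_natural))
        est2 = dict(zip(res2.names, res2.theta_natural))
        assert est2["PS~FI"] == pytest.approx(10 * est1["PS~FI"], rel=1e-4)

    def test_nested_models_chi2_ordering(self, study_table):
        one = ts.MimicSEM(assignment={"g": ["PO", "PS", "VC", "WM"]},
                          predictors=(), compute_sb=False).fit(study_table)
        two = ts.MimicSEM(predictors=(), compute_sb=False).fit(study_table)
        assert one.chi_square_ >= two.chi_square_ - 1e-8

    def test_chi2_type_i_error_rate(self, two_factor_spec):
        # data simulated from the fitted spec: rejection rate near alpha
        rng = np.random.default_rng(99)
        lam = np.array([[1, 0], [0.7, 0], [0, 1], [0, 0.6]], dtype=float)
        psi = np.array([[1.0, 0.45], [0.45, 1.2]])
        theta = np.array([0.5, 0.9, 0.4, 0.8])
        sigma = lam @ psi @ lam.T + np.diag(theta)
        chol = np.linalg.cholesky(sigma)
        n, reps, rejections = 500, 500, 0
        for _ in range(reps):
            y = rng.standard_normal((n, 4)) @ chol.T
            S = np.cov(y, rowvar=False, ddof=1)
            res = ts.fit_ml(S, n, two_factor_spec, compute_baseline=False,
                            n_restarts=0)
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_heywood_flagged(self):
        # population covariance whose first indicator correlates with the
        # others more strongly than a nonnegative residual variance allows:
        # the ML solution pins that variance at the boundary
        lam = np.array([1.0, 0.9, 0.8, 0.7])
        sigma = np.outer(lam, lam) + np.diag([0.1, 0.5, 0.5, 0.5])
        S = sigma.copy()
        S[0, 1:] *= 1.25  # inflate the first row beyond admissibility
        S[1:, 0] = S[0, 1:]
        spec = ts.build_watershed_spec({"g": ["a", "b", "c", "d"]})
        res = ts.fit_ml(pd.DataFrame(S, index=list("abcd"), columns=list("abcd")),
                        200, spec, compute_baseline=False)
        assert res.heywood


class TestRSquared:
    def test_hand_case(self):
        spec = ts.build_watershed_spec({"F": ["y1", "y2"]})
        params = ts.ParameterSet(
            lam=np.array([[1.0], [1.0]]), gamma=np.zeros((1, 0)),
            psi=np.array([[0.8]]), theta=np.array([0.2, 0.8]),
            phi=np.zeros((0, 0)))
        r2 = ts.r_squared(params, spec)
        assert r2["y1"] == pytest.approx(0.8)
        assert r2["y2"] == pytest.approx(0.5)

    def test_zero_loading_gives_zero(self):
        spec = ts.build_watershed_spec({"F": ["y1", "y2"]},
                                       identification="unit_variance")
        params = ts.ParameterSet(
            lam=np.array([[0.0], [0.9]]), gamma=np.zeros((1, 0)),
            psi=np.array([[1.0]]), theta=np.array([0.7, 0.4]),
            phi=np.zeros((0, 0)))
        assert ts.r_squared(params, spec)["y1"] == pytest.approx(0.0)


class TestSatorraBentler:
    def test_delta_matches_finite_differences(self, tiny_mimic):
        spec, params = tiny_mimic
        idx = ParameterIndex(spec)
        theta = idx.pack(params)
        delta = delta_matrix(theta, idx, phi_fixed=params.phi)
        m = spec.n_indicators + spec.n_predictors
        rows, cols = np.tril_indices(m)
        fd = np.zeros_like(delta[:, : idx.n_free])
        for k in range(idx.n_free):
            e = np.zeros_like(theta)
            e[k] = 1e-6
            up = ts.implied_moments(spec, idx.unpack(theta + e, params.phi))
            dn = ts.implied_moments(spec, idx.unpack(theta - e, params.phi))
            fd[:, k] = (up - dn)[rows, cols] / 2e-6
        np.testing.assert_allclose(delta[:, : idx.n_free], fd, atol=1e-6)

    def test_duplication_matrix_identity(self):
        m = 4
        D = duplication_matrix(m)
        rng = np.random.default_rng(0)
        A = rng.standard_normal((m, m))
        A = A + A.T
        vech = A[np.tril_indices(m)]
        np.testing.assert_allclose(D @ vech, A.ravel())

    def test_near_one_under_normality(self):
        rng = np.random.default_rng(17)
        lam = np.array([[1, 0], [0.7, 0], [0, 1], [0, 0.6]], dtype=float)
        psi = np.array([[1.0, 0.45], [0.45, 1.2]])
        sigma = lam @ psi @ lam.T + np.diag([0.5, 0.9, 0.4, 0.8])
        chol = np.linalg.cholesky(sigma)
        spec = ts.build_watershed_spec({"FI": ["PO", "PS"], "CI": ["VC", "WM"]})
        cs = []
        for _ in range(10):
            y = rng.standard_normal((5000, 4)) @ chol.T
            table = pd.DataFrame(y, columns=["PO", "PS", "VC", "WM"])
            S, N = ts.sample_moments(table)
            res = ts.fit_ml(S, N, spec, compute_baseline=False)
            cs.append(satorra_bentler_c(table, res, spec))
        assert abs(np.mean(cs) - 1.0) < 0.1

    def test_df_zero_raises(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("abc"))
        spec = ts.build_watershed_spec({"g": ["a", "b", "c"]})
        S, N = ts.sample_moments(table)
        res = ts.fit_ml(S, N, spec, compute_baseline=False)
        with pytest.raises(ValueError, match="df = 0"):
            satorra_bentler_c(table, res, spec)


class TestLoglik:
    def test_loglik_matches_direct_sum(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal((50, 3))
        S = np.cov(y, rowvar=False, ddof=1)
        sigma = S + 0.1 * np.eye(3)
        # independent oracle: sum of per-observation normal log densities
        mu = y.mean(axis=0)
        direct = stats.multivariate_normal(mu, sigma).logpdf(y).sum()
        assert loglikelihood(S, sigma, 50) == pytest.approx(direct, rel=1e-10)
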