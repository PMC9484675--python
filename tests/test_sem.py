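"""Structured covariance engine: specification, ML fit, indices,
robust scaling, reliability, scores and modification indices."""

import numpy as np
import pytest

from trpsem.sem import (CovModelSpec, PatternMatrix, SemError,
                        baseline_independence, factor_scores, fit_ml,
                        gamma_adf, implied_sigma, latent_regression,
                        mod_indices, omega, sb_scale)
from trpsem.sem.fit import _objective_and_grad


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def one_factor_spec(p, *, fix_first=False):
    lam = PatternMatrix((p, 1))
    for i in range(p):
        if i == 0 and fix_first:
            lam.set_fixed(0, 0, 1.0)
        else:
            lam.set_free(i, 0)
    psi = PatternMatrix((1, 1), symmetric=True)
    if fix_first:
        psi.set_free(0, 0, 0.5)
    else:
        psi.set_fixed(0, 0, 1.0)
    theta = PatternMatrix((p, p), symmetric=True)
    for i in range(p):
        theta.set_free(i, i)
    return CovModelSpec(var_names=[f"x{i}" for i in range(p)],
                        factor_names=["f"], loadings=lam, psi=psi,
                        theta=theta, name="one_factor")


def random_cfa_sigma(p, rng):
    lam = rng.uniform(0.4, 0.9, size=p)
    theta = rng.uniform(0.3, 0.8, size=p)
    return np.outer(lam, lam) + np.diag(theta), lam, theta


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

class TestModelSpec:
    def test_df_accounting(self):
        spec = one_factor_spec(4)
        assert spec.n_free == 8
        assert spec.df() == 2

    def test_overparameterized_model_rejected(self):
        spec = one_factor_spec(3)
        spec.theta.set_free(1, 0)  # 7 free > 6 moments
        with pytest.raises(ValueError, match="free parameters"):
            spec.check_identification()

    def test_fixed_entries_survive_roundtrip(self, tmp_path):
        from trpsem.models import build_model
        spec = build_model("ss_fixedlinks")
        path = tmp_path / "model.yaml"
        spec.to_yaml(path)
        back = CovModelSpec.from_yaml(path)
        np.testing.assert_array_equal(back.loadings.values[:, 1],
                                      [0.0, 1.0, 2.0, 3.0])
        assert not back.psi.free[0, 1]
        assert back.psi.values[0, 1] == 0.0
        assert back.df() == spec.df()
        assert back.param_labels() == spec.param_labels()

    def test_beta_diagonal_must_be_zero(self):
        spec = one_factor_spec(3)
        bad = PatternMatrix((1, 1))
        bad.set_free(0, 0)
        with pytest.raises(ValueError, match="beta diagonal"):
            CovModelSpec(var_names=spec.var_names, factor_names=["f"],
                         loadings=spec.loadings, psi=spec.psi,
                         theta=spec.theta, beta=bad)


# ---------------------------------------------------------------------------
# maximum likelihood fit
# ---------------------------------------------------------------------------

class TestFitML:
    def test_analytic_gradient_matches_numeric(self, rng):
        from trpsem.models import build_model
        for name in ("trp_cfa", "ss_fixedlinks", "trp_g", "combined"):
            spec = build_model(name)
            p = spec.p
            A = rng.normal(size=(p, p + 3))
            S = A @ A.T / (p + 3) + 0.5 * np.eye(p)
            logdet_S = np.linalg.slogdet(S)[1]
            theta = np.abs(rng.normal(0.4, 0.1, size=spec.n_free))
            F0, g = _objective_and_grad(spec, theta, S, logdet_S)
            h = 1e-6
            for k in range(spec.n_free):
                tp = theta.copy(); tp[k] += h
                tm = theta.copy(); tm[k] -= h
                num = (_objective_and_grad(spec, tp, S, logdet_S)[0]
                       - _objective_and_grad(spec, tm, S, logdet_S)[0]) / (2 * h)
                assert g[k] == pytest.approx(num, abs=5e-6), (name, k)

    def test_perfect_fit_identity(self, rng):
        """S generated from interior parameters: F = 0 and recovery up to
        loading sign."""
        S, lam, theta = random_cfa_sigma(5, rng)
        fit = fit_ml(one_factor_spec(5), S, 200)
        assert fit.f_ml == pytest.approx(0.0, abs=1e-10)
        est_lam = np.array([fit.estimates[f"lambda[x{i},f]"] for i in range(5)])
        np.testing.assert_allclose(np.abs(est_lam), lam, atol=1e-5)

    def test_exactly_identified_three_indicator_model(self):
        from trpsem.datasets import bis_corr
        fit = fit_ml(one_factor_spec(3), bis_corr(), 273)
        assert fit.df == 0
        assert fit.T == pytest.approx(0.0, abs=1e-8)
        assert fit.cfi == 1.0 and fit.rmsea == 0.0

    def test_printed_timing_matrix_loading_range(self):
        """One-factor fit to the published timing-task correlations:
        standardized loadings bracket the printed .338-.632 range."""
        from trpsem.datasets import timing_corr
        fit = fit_ml(one_factor_spec(4), timing_corr(), 273)
        lam = fit.standardized["lambda"][:, 0]
        assert lam.min() == pytest.approx(0.338, abs=0.02)
        assert lam.max() == pytest.approx(0.632, abs=0.02)

    def test_oracle_equivalence_on_random_models(self):
        """fit_ml's optimum equals an independent generic minimization of
        the same discrepancy on 20 random small models."""
        rng = np.random.default_rng(12)
        from scipy.optimize import minimize
        for trial in range(20):
            p = int(rng.integers(4, 7))
            n = 150
            S_true, _, _ = random_cfa_sigma(p, rng)
            X = rng.multivariate_normal(np.zeros(p), S_true, size=n)
            S = np.cov(X, rowvar=False, ddof=1)
            fit = fit_ml(one_factor_spec(p), S, n)

            sign_det, logdet_S = np.linalg.slogdet(S)

            def F_generic(th):  # independent implementation of F_ML
                lam, tht = th[:p], th[p:]
                Sig = np.outer(lam, lam) + np.diag(tht)
                ev = np.linalg.eigvalsh(Sig)
                if ev.min() <= 1e-10:
                    return 1e8
                return (np.linalg.slogdet(Sig)[1] - logdet_S
                        + np.trace(S @ np.linalg.inv(Sig)) - p)

            best = np.inf
            for start in range(3):
                x0 = np.concatenate([
                    rng.uniform(0.3, 0.9, p) * np.sqrt(np.diag(S)),
                    0.5 * np.diag(S)])
                res = minimize(F_generic, x0, method="Nelder-Mead",
                               options={"xatol": 1e-12, "fatol": 1e-14,
                                        "maxiter": 20000, "maxfev": 40000})
                best = min(best, res.fun)
            assert abs(fit.f_ml - best) < 1e-8

    def test_scale_invariance_with_free_loadings(self, rng):
        """Free-loading models: standardized solutions from covariance and
        correlation input agree."""
        S_true, _, _ = random_cfa_sigma(4, rng)
        X = rng.multivariate_normal(np.zeros(4), S_true, size=400)
        X_scaled = X * np.array([1.0, 3.0, 0.2, 10.0])
        S = np.cov(X_scaled, rowvar=False, ddof=1)
        d = np.sqrt(np.diag(S))
        R = S / np.outer(d, d)
        f_cov = fit_ml(one_factor_spec(4), S, 400)
        f_cor = fit_ml(one_factor_spec(4), R, 400)
        np.testing.assert_allclose(np.abs(f_cov.standardized["lambda"]),
                                   np.abs(f_cor.standardized["lambda"]),
                                   atol=1e-6)
        assert f_cov.T == pytest.approx(f_cor.T, abs=1e-6)

    def test_fixed_links_not_scale_invariant(self, measure_data):
        """Fixed loadings bind the model to the measurement scale: fitting
        the correlation instead of the covariance matrix changes the
        standardized solution."""
        from trpsem.models import THRESHOLD_VARS, build_model
        D = measure_data[THRESHOLD_VARS].to_numpy()
        S = np.cov(D, rowvar=False, ddof=1)
        d = np.sqrt(np.diag(S))
        R = S / np.outer(d, d)
        f_cov = fit_ml(build_model("ss_fixedlinks"), S, 273)
        f_cor = fit_ml(build_model("ss_fixedlinks"), R, 273)
        diff = np.abs(f_cov.standardized["lambda"]
                      - f_cor.standardized["lambda"]).max()
        assert diff > 1e-3
        assert abs(f_cov.T - f_cor.T) > 1e-2

    def test_aic_differences_follow_chi_square_and_df(self, measure_data):
        from trpsem.models import THRESHOLD_VARS, build_model
        S = np.cov(measure_data[THRESHOLD_VARS].to_numpy(), rowvar=False,
                   ddof=1)
        f1 = fit_ml(build_model("ss_fixedlinks_base"), S, 273)
        f2 = fit_ml(build_model("ss_fixedlinks"), S, 273)  # nested superset
        d_aic = f1.aic - f2.aic
        d_expected = (f1.T - f2.T) - 2 * (f2.spec.n_free - f1.spec.n_free)
        assert d_aic == pytest.approx(d_expected, abs=1e-6)

    def test_non_pd_input_rejected(self):
        S = np.array([[1.0, 0.9, 0.9],
                      [0.9, 1.0, -0.9],
                      [0.9, -0.9, 1.0]])
        with pytest.raises(SemError, match="positive definite"):
            fit_ml(one_factor_spec(3), S, 50)

    def test_heywood_case_warned(self):
        """A residual variance driven negative at the optimum is reported."""
        R = np.array([[1.0, .85, .85, .20],
                      [.85, 1.0, .85, .20],
                      [.85, .85, 1.0, .20],
                      [.20, .20, .20, 1.0]])
        fit = fit_ml(one_factor_spec(4), R, 100)
        if any(v < 0 for k, v in fit.estimates.items() if "theta" in k):
            assert any("Heywood" in w for w in fit.warnings)

    def test_bounds_honored(self, measure_data):
        from trpsem.models import THRESHOLD_VARS, build_model
        S = np.cov(measure_data[THRESHOLD_VARS].to_numpy(), rowvar=False,
                   ddof=1)
        fit = fit_ml(build_model("ss_fixedlinks"), S, 273)
        assert fit.estimates["theta[thr_1.8,thr_1.8]"] >= 1e-6
        assert fit.estimates["theta[thr_7.2,thr_7.2]"] >= 1e-6

    def test_baseline_closed_form(self, rng):
        S_true, _, _ = random_cfa_sigma(4, rng)
        T_b, df_b = baseline_independence(S_true, 100)
        d = np.sqrt(np.diag(S_true))
        R = S_true / np.outer(d, d)
        assert T_b == pytest.approx(-99 * np.linalg.slogdet(R)[1])
        assert df_b == 6


class TestFitIndices:
    def test_saturated_and_perfect_values(self, rng):
        from trpsem.sem import fit_indices
        S, _, _ = random_cfa_sigma(4, rng)
        cfi, rmsea, srmr, _ = fit_indices(5.0, 5, 100.0, 6, 200, S, S, 8)
        assert cfi == 1.0 and rmsea == 0.0 and srmr == 0.0

    def test_hand_computed_fixture(self):
        from trpsem.sem import fit_indices
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        Sig = np.array([[1.0, 0.4], [0.4, 1.0]])
        T, df, T_b, df_b, n, q = 12.0, 4, 60.0, 6, 101, 2
        cfi, rmsea, srmr, aic = fit_indices(T, df, T_b, df_b, n, S, Sig, q)
        assert cfi == pytest.approx(1 - (12 - 4) / (60 - 6))
        assert rmsea == pytest.approx(np.sqrt((12 - 4) / (4 * 100)))
        assert srmr == pytest.approx(np.sqrt((0.1 ** 2) / 3))
        m2ll = 100 * (np.linalg.slogdet(Sig)[1] + np.trace(np.linalg.inv(Sig) @ S))
        assert aic == pytest.approx(m2ll + 4)


# ---------------------------------------------------------------------------
# latent regression
# ---------------------------------------------------------------------------

class TestLatentRegression:
    def test_r_squared_equals_beta_squared_single_predictor(self, measure_data):
        from trpsem.models import BIS_VARS, TIMING_VARS, build_model
        S = np.cov(measure_data[TIMING_VARS + BIS_VARS].to_numpy(),
                   rowvar=False, ddof=1)
        fit = latent_regression(build_model("trp_g"), S, 273)
        beta_std = fit.standardized["beta"][1, 0]
        assert fit.r_squared["g"] == pytest.approx(beta_std ** 2, abs=1e-8)

    def test_zero_latent_covariance_zero_beta(self, rng):
        """Data with independent factors: estimated path is near zero."""
        from trpsem.models import build_model, generate_measure_level_data
        data = generate_measure_level_data(
            4000, rng, true={"beta_trp_g": 0.0})
        from trpsem.models import BIS_VARS, TIMING_VARS
        S = np.cov(data[TIMING_VARS + BIS_VARS].to_numpy(), rowvar=False,
                   ddof=1)
        fit = latent_regression(build_model("trp_g"), S, 4000)
        assert fit.standardized["beta"][1, 0] == pytest.approx(0.0, abs=0.05)
        assert fit.r_squared["g"] == pytest.approx(0.0, abs=0.01)

    def test_requires_structural_paths(self):
        with pytest.raises(SemError, match="no structural paths"):
            latent_regression(one_factor_spec(4), np.eye(4), 100)

    def test_path_recovery_at_known_beta(self):
        """Mean standardized path over 60 measure-level replicates at
        n = 273 recovers the generative value -.535."""
        from trpsem.models import (BIS_VARS, TIMING_VARS, build_model,
                                   generate_measure_level_data)
        root = np.random.SeedSequence(55)
        betas = []
        for stream in root.spawn(60):
            r = np.random.default_rng(stream)
            data = generate_measure_level_data(273, r)
            S = np.cov(data[TIMING_VARS + BIS_VARS].to_numpy(), rowvar=False,
                       ddof=1)
            fit = fit_ml(build_model("trp_g"), S, 273)
            betas.append(fit.standardized["beta"][1, 0])
        se = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(betas) - (-0.535)) < max(3 * se, 0.02)


# ---------------------------------------------------------------------------
# Satorra-Bentler scaling
# ---------------------------------------------------------------------------

class TestRobustScaling:
    def test_normal_data_scaling_near_one(self):
        rng = np.random.default_rng(3)
        S_true, _, _ = random_cfa_sigma(4, rng)
        X = rng.multivariate_normal(np.zeros(4), S_true, size=5000)
        S = np.cov(X, rowvar=False, ddof=1)
        fit = fit_ml(one_factor_spec(4), S, 5000)
        c, T_sb = sb_scale(X, fit)
        assert c == pytest.approx(1.0, abs=0.05)
        assert T_sb * c == pytest.approx(fit.T, abs=1e-9)

    def test_heavy_tails_inflate_scaling_factor(self):
        """Elliptical multivariate t(5) data: mean scaling factor exceeds
        1 over replicates.  (With *independent* non-normal factors and
        errors the statistic is asymptotically robust and c stays near 1,
        so the heavy-tail check needs a common scale-mixing variable.)"""
        rng = np.random.default_rng(4)
        S_true, _, _ = random_cfa_sigma(4, rng)
        cs = []
        for _ in range(40):
            n = 500
            Z = rng.multivariate_normal(np.zeros(4), S_true, size=n)
            mix = np.sqrt(5.0 / rng.chisquare(5, size=n))[:, None]
            X = Z * mix
            S = np.cov(X, rowvar=False, ddof=1)
            try:
                fit = fit_ml(one_factor_spec(4), S, n)
            except SemError:
                continue
            cs.append(sb_scale(X, fit)[0])
        assert np.mean(cs) > 1.2

    def test_gamma_matches_normal_theory_at_scale(self):
        """ADF fourth-moment matrix approaches 2 sigma_ik sigma_jl form
        for Gaussian data."""
        rng = np.random.default_rng(9)
        X = rng.multivariate_normal([0, 0], [[1.0, 0.3], [0.3, 1.0]],
                                    size=20000)
        G = gamma_adf(X)
        S = np.cov(X, rowvar=False, ddof=0)
        idx = [(0, 0), (1, 0), (1, 1)]
        expect = np.array([[S[i, k] * S[j, l] + S[i, l] * S[j, k]
                            for k, l in idx] for i, j in idx])
        np.testing.assert_allclose(G, expect, atol=0.1)


# ---------------------------------------------------------------------------
# omega and factor scores
# ---------------------------------------------------------------------------

class TestOmega:
    def test_triad_closed_form(self):
        """Three-composite model: loadings and omega from the closed-form
        triad solution."""
        from trpsem.datasets import bis_corr
        fit = fit_ml(one_factor_spec(3), bis_corr(), 273)
        lam = np.sort(np.abs(fit.standardized["lambda"][:, 0]))[::-1]
        r12, r13, r23 = 0.51, 0.46, 0.39
        expect = np.sort([np.sqrt(r12 * r13 / r23), np.sqrt(r12 * r23 / r13),
                          np.sqrt(r13 * r23 / r12)])[::-1]
        np.testing.assert_allclose(lam, expect, atol=1e-6)
        w = omega(fit, "g" if "g" in fit.spec.factor_names else 0)
        s = expect.sum()
        assert w == pytest.approx(s ** 2 / (s ** 2 + (1 - expect ** 2).sum()),
                                  abs=1e-6)

    def test_factor_without_indicators_has_zero_omega(self, measure_data):
        from trpsem.models import THRESHOLD_VARS, build_model
        spec = build_model("ss_fixedlinks")
        S = np.cov(measure_data[THRESHOLD_VARS].to_numpy(), rowvar=False,
                   ddof=1)
        fit = fit_ml(spec, S, 273)
        # both factors have indicators here; omega positive and below 1
        for f in ("ssc", "ssi"):
            assert 0.0 < omega(fit, f) < 1.0


class TestFactorScores:
    def test_single_indicator_no_residual_recovers_indicator(self, rng):
        lam = PatternMatrix((1, 1)); lam.set_fixed(0, 0, 1.0)
        psi = PatternMatrix((1, 1), symmetric=True); psi.set_free(0, 0, 1.0)
        theta = PatternMatrix((1, 1), symmetric=True); theta.set_fixed(0, 0, 0.0)
        spec = CovModelSpec(var_names=["x"], factor_names=["f"],
                            loadings=lam, psi=psi, theta=theta)
        x = rng.normal(size=(100, 1))
        S = np.cov(x, rowvar=False, ddof=1).reshape(1, 1)
        fit = fit_ml(spec, S, 100)
        scores = factor_scores(fit, x)
        np.testing.assert_allclose(scores[:, 0], x[:, 0] - x[:, 0].mean(),
                                   atol=1e-6)

    def test_scores_centered_and_track_dominant_indicator(self, measure_data):
        from trpsem.models import BIS_VARS, build_model
        D = measure_data[BIS_VARS].to_numpy()
        S = np.cov(D, rowvar=False, ddof=1)
        fit = fit_ml(build_model("g_cfa"), S, 273)
        scores = factor_scores(fit, D)
        assert scores[:, 0].mean() == pytest.approx(0.0, abs=1e-10)
        dom = np.argmax(np.abs(fit.standardized["lambda"][:, 0]))
        sign = np.sign(fit.standardized["lambda"][dom, 0])
        assert sign * np.corrcoef(scores[:, 0], D[:, dom])[0, 1] > 0.5

    def test_bartlett_scores_available(self, measure_data):
        from trpsem.models import BIS_VARS, build_model
        D = measure_data[BIS_VARS].to_numpy()
        S = np.cov(D, rowvar=False, ddof=1)
        fit = fit_ml(build_model("g_cfa"), S, 273)
        sc = factor_scores(fit, D, method="bartlett")
        assert sc.shape == (273, 1)


# ---------------------------------------------------------------------------
# modification indices
# ---------------------------------------------------------------------------

class TestModIndices:
    def test_free_parameters_absent(self, measure_data):
        from trpsem.models import THRESHOLD_VARS, build_model
        S = np.cov(measure_data[THRESHOLD_VARS].to_numpy(), rowvar=False,
                   ddof=1)
        fit = fit_ml(build_model("ss_fixedlinks"), S, 273)
        mi = mod_indices(fit)
        assert "theta[thr_5.4,thr_3.6]" not in mi  # already free

    def test_mi_approximates_refit_drop(self, measure_data):
        """MI within 15% of the exact chi-square drop from actually
        freeing the parameter (well-conditioned candidates)."""
        from trpsem.models import THRESHOLD_VARS, build_model
        S = np.cov(measure_data[THRESHOLD_VARS].to_numpy(), rowvar=False,
                   ddof=1)
        base = build_model("ss_fixedlinks_base")
        fit = fit_ml(base, S, 273)
        mi = mod_indices(fit)
        label, value = max(mi.items(), key=lambda kv: kv[1])
        i = [f"thr_{s}" for s in ("1.8", "3.6", "5.4", "7.2")]
        # refit with that residual covariance freed
        freed = base.copy()
        vi, vj = label[len("theta["):-1].split(",")
        freed.theta.set_free(i.index(vi), i.index(vj))
        refit = fit_ml(freed, S, 273)
        drop = fit.T - refit.T
        assert value == pytest.approx(drop, rel=0.15)

    def test_planted_residual_covariance_found(self):
        """Largest MI identifies the residual covariance the generator
        actually contains (3.6-5.4 deg conditions)."""
        from trpsem.models import (THRESHOLD_VARS, build_model,
                                   generate_measure_level_data)
        rng = np.random.default_rng(13)
        data = generate_measure_level_data(2000, rng,
                                           true={"theta_23": 0.004})
        S = np.cov(data[THRESHOLD_VARS].to_numpy(), rowvar=False, ddof=1)
        fit = fit_ml(build_model("ss_fixedlinks_base"), S, 2000)
        mi = mod_indices(fit)
        assert max(mi, key=mi.get) == "theta[thr_5.4,thr_3.6]"

    def test_saturated_model_rejected(self):
        from trpsem.datasets import bis_corr
        fit = fit_ml(one_factor_spec(3), bis_corr(), 273)
        with pytest.raises(SemError, match="saturated"):
            mod_indices(fit)
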