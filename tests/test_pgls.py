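import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from altripgls import SyntheticConfig, simulate_traits, simulate_tree
from altripgls.pgls import (PGLSError, design_matrix, diagnostic_qq_and_fit_data,
                            fit_gls, profile_lambda, standardized_residuals,
                            studentized_phylo_residuals)
from altripgls.tree import VCVMatrix, lambda_transform, parse_newick, vcv
from oracles import contrasts_slope, gls_explicit


def _sim_xyC(n_tips=12, seed=0, lam=1.0, sigma2=1.0, beta=(0.5, 1.0)):
    cfg = SyntheticConfig(n_tips=n_tips, seed=seed, true_lambda=lam,
                          true_sigma2=sigma2, true_beta=beta)
    tree = simulate_tree(cfg)
    df = simulate_traits(tree, cfg)
    C = vcv(tree)
    X = design_matrix(C.species_order, x=df["x"].to_numpy())
    return tree, df["y"].to_numpy(), X, C


class TestFitGLS:
    def test_identity_covariance_reduces_to_ols(self, rng):
        import statsmodels.api as sm

        n = 20
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(size=n)
        labels = [f"s{i}" for i in range(n)]
        X = design_matrix(labels, x=x)
        fit = fit_gls(y, X, VCVMatrix(labels, np.eye(n)))
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert np.allclose(fit.coefficients, ols.params, atol=1e-10)
        assert np.allclose(fit.std_errors, ols.bse, atol=1e-10)
        assert np.allclose(fit.t_values, ols.tvalues, atol=1e-10)
        assert np.allclose(fit.p_values, ols.pvalues, atol=1e-10)
        assert fit.r2 == pytest.approx(ols.rsquared, abs=1e-10)
        assert fit.r2_adj == pytest.approx(ols.rsquared_adj, abs=1e-10)

    def test_three_taxon_phylogenetic_mean(self):
        # hand-derived: weights (1/3, 1/3, 1/2) give mean 16/7 for y=(1,1,4)
        C = vcv(parse_newick("((A:1,B:1):1,C:2);"))
        X = design_matrix(C.species_order)
        y = {"A": 1.0, "B": 1.0, "C": 4.0}
        fit = fit_gls([y[s] for s in C.species_order], X, C)
        assert fit.coefficients[0] == pytest.approx(16 / 7, abs=1e-12)

    def test_matches_explicit_inverse_oracle(self):
        tree, y, X, C = _sim_xyC(seed=5)
        fit = fit_gls(y, X, C)
        beta, se, t, s2ml = gls_explicit(y, X.values, C.values)
        assert np.allclose(fit.coefficients, beta, atol=1e-10)
        assert np.allclose(fit.std_errors, se, atol=1e-10)
        assert fit.sigma2_ml == pytest.approx(s2ml, rel=1e-10)

    def test_perfect_linear_fit(self):
        tree, _, X, C = _sim_xyC(seed=2)
        y = 3.0 - 2.0 * X.values[:, 1]
        fit = fit_gls(y, X, C)
        assert np.allclose(fit.resid_raw, 0, atol=1e-10)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.sigma2_ml == pytest.approx(0.0, abs=1e-20)
        assert np.allclose(fit.resid_std, 0.0)

    def test_normal_equations_orthogonality(self):
        for seed in range(4):
            tree, y, X, C = _sim_xyC(seed=seed, lam=0.6)
            fit = profile_lambda(y, X, C)
            V = lambda_transform(C, fit.lambda_hat).values
            grad = X.values.T @ np.linalg.solve(V, fit.resid_raw)
            assert np.allclose(grad, 0, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        labels = ["a", "b", "c", "d"]
        with pytest.raises(PGLSError, match="rank"):
            design_matrix(labels, x=[1.0, 1.0, 1.0, 1.0])

    def test_misaligned_orders_rejected(self):
        tree, y, X, C = _sim_xyC(seed=1)
        C_perm = C.reorder(list(reversed(C.species_order)))
        with pytest.raises(PGLSError, match="order"):
            fit_gls(y, X, C_perm)


class TestProfileLambda:
    def test_lambda_zero_equivalence_with_ols(self):
        tree, y, X, C = _sim_xyC(seed=7, lam=0.0, sigma2=2.0)
        fit0 = fit_gls(y, X, lambda_transform(C, 0.0), _lambda_hat=0.0)
        # OLS on variables weighted by 1/sqrt(tip depth): on a depth-1
        # ultrametric tree this is plain OLS
        beta, se, t, _ = gls_explicit(y, X.values, np.diag(np.diag(C.values)))
        assert np.allclose(fit0.coefficients, beta, atol=1e-8)
        assert np.allclose(fit0.std_errors, se, atol=1e-8)
        assert np.allclose(fit0.t_values, t, atol=1e-8)

    @pytest.mark.parametrize("seed", range(20))
    def test_lambda_one_equals_independent_contrasts_slope(self, seed):
        cfg = SyntheticConfig(n_tips=4 + seed % 16, seed=seed)
        tree = simulate_tree(cfg)
        df = simulate_traits(tree, cfg)
        C = vcv(tree)
        X = design_matrix(C.species_order, x=df["x"].to_numpy())
        fit = fit_gls(df["y"].to_numpy(), X, C)
        x_map = dict(zip(df["species"], df["x"]))
        y_map = dict(zip(df["species"], df["y"]))
        assert fit.coefficients[1] == pytest.approx(
            contrasts_slope(tree, x_map, y_map), abs=1e-8)

    @pytest.mark.parametrize("seed", range(20))
    def test_optimizer_matches_dense_grid(self, seed):
        tree, y, X, C = _sim_xyC(n_tips=20, seed=100 + seed,
                                 lam=[0.0, 0.5, 1.0][seed % 3])
        fit = profile_lambda(y, X, C)
        grid = np.arange(0.0, 1.0000001, 0.001)
        lls = [fit_gls(y, X, lambda_transform(C, l)).log_lik for l in grid]
        assert abs(fit.lambda_hat - grid[int(np.argmax(lls))]) <= 0.001

    def test_lambda_hat_beats_endpoints(self):
        tree, y, X, C = _sim_xyC(n_tips=30, seed=11, lam=0.5)
        fit = profile_lambda(y, X, C)
        ll0 = fit_gls(y, X, lambda_transform(C, 0.0)).log_lik
        ll1 = fit_gls(y, X, lambda_transform(C, 1.0)).log_lik
        assert fit.log_lik >= ll0 - 1e-6
        assert fit.log_lik >= ll1 - 1e-6

    def test_independent_noise_yields_low_lambda(self):
        hits = 0
        for seed in range(20):
            tree, y, X, C = _sim_xyC(n_tips=100, seed=200 + seed, lam=0.0)
            if profile_lambda(y, X, C).lambda_hat < 0.2:
                hits += 1
        assert hits >= 18

    def test_brownian_noise_yields_high_lambda(self):
        lams = []
        for seed in range(20):
            tree, y, X, C = _sim_xyC(n_tips=100, seed=300 + seed, lam=1.0)
            lams.append(profile_lambda(y, X, C).lambda_hat)
        assert np.median(lams) >= 0.9


class TestScaleInvariance:
    @pytest.mark.parametrize("k", [0.01, 1000.0])
    def test_tree_rescaling_leaves_inference_unchanged(self, k):
        tree, y, X, C = _sim_xyC(seed=9, lam=0.7)
        fit = profile_lambda(y, X, C)
        Ck = VCVMatrix(list(C.species_order), k * C.values)
        fitk = profile_lambda(y, X, Ck)
        assert np.allclose(fitk.coefficients, fit.coefficients, rtol=1e-6)
        assert np.allclose(fitk.std_errors, fit.std_errors, rtol=1e-6)
        assert np.allclose(fitk.t_values, fit.t_values, rtol=1e-6)
        assert np.allclose(fitk.p_values, fit.p_values, rtol=1e-6)
        assert fitk.r2 == pytest.approx(fit.r2, rel=1e-6)
        assert fitk.r2_adj == pytest.approx(fit.r2_adj, rel=1e-6)
        assert fitk.lambda_hat == pytest.approx(fit.lambda_hat, abs=1e-4)
        assert fitk.sigma2_ml == pytest.approx(fit.sigma2_ml / k, rel=1e-4)


class TestResidualDiagnostics:
    def test_studentized_matches_classical_ols(self, rng):
        import statsmodels.api as sm

        n = 15
        x = rng.normal(size=n)
        y = 0.5 + x + rng.normal(size=n)
        labels = [f"s{i}" for i in range(n)]
        X = design_matrix(labels, x=x)
        fit = fit_gls(y, X, VCVMatrix(labels, np.eye(n)))
        infl = sm.OLS(y, sm.add_constant(x)).fit().get_influence()
        assert np.allclose(fit.resid_phylo_student,
                           infl.resid_studentized_internal, atol=1e-10)

    def test_inflated_tip_is_flagged(self):
        tree, y, X, C = _sim_xyC(n_tips=40, seed=13, lam=1.0, sigma2=1.0)
        fit = fit_gls(y, X, C)
        y2 = y.copy()
        y2[5] += 10 * np.sqrt(fit.sigma2_resid * C.values[5, 5])
        fit2 = fit_gls(y2, X, C)
        assert fit2.outlier_flags[5]

    def test_standardization_modes_proportional_on_ultrametric(self):
        tree, y, X, C = _sim_xyC(seed=4)
        fit = fit_gls(y, X, C)
        a = standardized_residuals(fit, C, mode="tipvar")
        b = standardized_residuals(fit, C, mode="zscore")
        ratio = a / b
        assert np.allclose(ratio, ratio[0], rtol=1e-8)

    def test_downstream_fit_invariant_to_residual_rescaling(self):
        tree, y, X, C = _sim_xyC(seed=6)
        fit = fit_gls(y, X, C)
        z = np.asarray(fit.resid_std)
        resp = 0.3 * z + 0.1 * np.asarray(
            simulate_traits(tree, SyntheticConfig(n_tips=12, seed=99))["y"])
        f1 = profile_lambda(resp, design_matrix(C.species_order, a=z), C)
        f2 = profile_lambda(resp, design_matrix(C.species_order, a=10 * z), C)
        assert f1.t_values[1] == pytest.approx(f2.t_values[1], rel=1e-6)
        assert f1.p_values[1] == pytest.approx(f2.p_values[1], rel=1e-6)
        assert f1.r2 == pytest.approx(f2.r2, rel=1e-6)
        assert f1.lambda_hat == pytest.approx(f2.lambda_hat, abs=1e-3)
        assert f2.coefficients[1] == pytest.approx(f1.coefficients[1] / 10, rel=1e-6)


class TestQQData:
    def test_shapes_and_symmetry(self):
        tree, y, X, C = _sim_xyC(n_tips=31, seed=21)
        fit = fit_gls(y, X, C)
        qq, rvf = diagnostic_qq_and_fit_data(fit)
        assert qq.shape == (31, 2) and rvf.shape == (31, 2)
        assert np.allclose(qq[:, 0], -qq[::-1, 0], atol=1e-12)

    def test_near_normal_residuals_track_the_line(self):
        tree, y, X, C = _sim_xyC(n_tips=100, seed=22)
        fit = fit_gls(y, X, C)
        qq, _ = diagnostic_qq_and_fit_data(fit)
        assert np.corrcoef(qq[:, 0], qq[:, 1])[0, 1] > 0.97

    def test_constant_residuals_do_not_crash(self):
        tree, _, X, C = _sim_xyC(seed=2)
        y = 1.0 + 2.0 * X.values[:, 1]
        fit = fit_gls(y, X, C)
        qq, rvf = diagnostic_qq_and_fit_data(fit)
        assert np.allclose(qq[:, 1], 0.0)
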