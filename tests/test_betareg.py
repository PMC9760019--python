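import numpy as np
import pandas as pd
import pytest
from scipy import special

from isospec.betareg import (
    beta_log_likelihood,
    beta_score,
    build_design_matrix,
    compress_boundary,
    fit_beta_formula,
    fit_beta_regression,
)
from isospec.errors import DomainError, SchemaError


def simulate_beta(beta, phi, n, seed, ncov=None):
    rng = np.random.default_rng(seed)
    ncov = len(beta) - 1 if ncov is None else ncov
    X = np.column_stack([np.ones(n)] + [rng.normal(0, 1, n) for _ in range(ncov)])
    mu = special.expit(X @ np.asarray(beta))
    y = rng.beta(mu * phi, (1 - mu) * phi)
    return y, X


class TestCompressBoundary:
    @pytest.mark.parametrize("y,n,expected", [(1.0, 100, 0.995), (0.0, 10, 0.05)])
    def test_formula_values(self, y, n, expected):
        assert compress_boundary(np.array([y]), n)[0] == pytest.approx(expected)

    def test_half_is_fixed_point(self):
        for n in (2, 10, 1000):
            assert compress_boundary(np.array([0.5]), n)[0] == 0.5

    def test_output_strictly_interior(self):
        y = np.array([0.0, 1.0, 0.3])
        out = compress_boundary(y, 50)
        assert np.all((out > 0) & (out < 1))


class TestFit:
    def test_intercept_only_symmetric_response(self):
        y = np.tile([0.4, 0.5, 0.6], 30)
        fit = fit_beta_regression(y, np.ones((90, 1)), names=("Intercept",))
        assert abs(fit.coefficients[0]) < 1e-6

    def test_parameter_recovery_within_two_se(self):
        beta, phi = np.array([0.5, -0.3]), 30.0
        y, X = simulate_beta(beta, phi, n=2000, seed=7)
        fit = fit_beta_regression(y, X, names=("Intercept", "x"))
        assert fit.converged
        assert np.all(np.abs(fit.coefficients - beta) < 2 * fit.se)
        assert fit.phi == pytest.approx(phi, rel=0.15)

    def test_wald_z_is_coefficient_over_se(self):
        y, X = simulate_beta([0.2, 0.4], 20.0, n=150, seed=1)
        fit = fit_beta_regression(y, X)
        assert np.array_equal(fit.z, fit.coefficients / fit.se)
        assert np.all((fit.p >= 0) & (fit.p <= 1))

    def test_optimum_beats_least_squares_start(self):
        y, X = simulate_beta([0.3, -0.5], 15.0, n=300, seed=2)
        fit = fit_beta_regression(y, X)
        # least-squares start: OLS on the logit scale, moment estimate of φ
        beta_ls, *_ = np.linalg.lstsq(X, special.logit(y), rcond=None)
        mu = special.expit(X @ beta_ls)
        phi_ls = max(np.mean(mu * (1 - mu) / np.var(y - mu) - 1), 1.0)
        assert fit.loglik >= beta_log_likelihood(y, X, beta_ls, phi_ls)
        assert fit.loglik == pytest.approx(
            beta_log_likelihood(y, X, fit.coefficients, fit.phi))

    def test_gradient_vanishes_at_reported_optimum(self):
        y, X = simulate_beta([0.1, 0.3, -0.2], 25.0, n=400, seed=3)
        # covariates standardized by construction (standard normal draws)
        fit = fit_beta_regression(y, X)
        g = beta_score(y, X, fit.coefficients, fit.phi)
        assert np.max(np.abs(g)) < 1e-5

    def test_boundary_requires_explicit_compression(self):
        y = np.array([0.0, 0.3, 0.7, 1.0, 0.5, 0.2, 0.8, 0.4])
        X = np.ones((8, 1))
        with pytest.raises(DomainError, match="compress"):
            fit_beta_regression(y, X)
        fit = fit_beta_regression(y, X, compress=True)
        assert fit.n == 8

    def test_rank_deficient_design_named(self):
        y, X = simulate_beta([0.2, 0.4], 20.0, n=100, seed=4)
        X2 = np.column_stack([X, X[:, 1]])  # aliased copy
        with pytest.raises(SchemaError, match="rank deficient"):
            fit_beta_regression(y, X2, names=("Intercept", "x", "x_copy"))

    def test_too_few_observations(self):
        with pytest.raises(DomainError):
            fit_beta_regression(np.array([0.4, 0.5]), np.ones((2, 1)))

    def test_wald_interval_coverage_near_nominal(self):
        # 200 replicates from the model; 95% Wald CIs should cover ~95%
        beta_true = np.array([0.4, -0.3])
        covered = np.zeros(2)
        for rep in range(200):
            y, X = simulate_beta(beta_true, 20.0, n=100, seed=1000 + rep)
            fit = fit_beta_regression(y, X)
            lo = fit.coefficients - 1.96 * fit.se
            hi = fit.coefficients + 1.96 * fit.se
            covered += (lo <= beta_true) & (beta_true <= hi)
        coverage = covered / 200.0
        assert np.all(np.abs(coverage - 0.95) <= 0.05)


class TestFormula:
    def test_design_matrix_with_categorical_reference(self):
        df = pd.DataFrame({
            "psi": [0.9, 0.8, 0.85, 0.7], "tp": [3.0, 3.2, 3.5, 3.1],
            "site": ["Uatuma", "Jatapu", "Uatuma", "Jatapu"],
        })
        y, X, names = build_design_matrix(df, "psi ~ tp + site")
        assert names == ("Intercept", "tp", "site[Uatuma]")
        # first sorted level (Jatapu) is the reference
        assert np.array_equal(X[:, 2], [1.0, 0.0, 1.0, 0.0])

    def test_formula_fit_runs(self):
        rng = np.random.default_rng(6)
        n = 120
        site = np.where(rng.uniform(size=n) < 0.5, "Uatuma", "Jatapu")
        tp = rng.normal(3.5, 0.3, n)
        eta = 1.0 + 0.5 * (site == "Uatuma") - 0.2 * (tp - 3.5)
        y = rng.beta(special.expit(eta) * 25, (1 - special.expit(eta)) * 25)
        fit = fit_beta_formula(pd.DataFrame({"psi": y, "tp": tp, "site": site}),
                               "psi ~ tp + site")
        assert fit.names == ("Intercept", "tp", "site[Uatuma]")
        assert fit.converged

    def test_formula_errors(self):
        df = pd.DataFrame({"psi": [0.5, 0.6, 0.4], "tp": [1.0, 2.0, 3.0]})
        with pytest.raises(SchemaError):
            build_design_matrix(df, "psi + tp")
        with pytest.raises(SchemaError, match="nope"):
            build_design_matrix(df, "psi ~ nope")
        with pytest.raises(SchemaError, match="response"):
            build_design_matrix(df, "missing ~ tp")
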