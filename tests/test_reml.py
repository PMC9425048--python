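import numpy as np
import pandas as pd
import pytest

from rumigen.pedigree import build_A
from rumigen.reml import (
    build_mme,
    reml_bivariate,
    reml_eigen_additive,
    reml_linear_structure,
    reml_univariate,
    significance_flag,
)
from rumigen.simulate import simulate_trait_values
from tests.conftest import random_pedigree


class TestSignificanceFlag:
    @pytest.mark.parametrize(
        "est,se,expected",
        [
            (-0.41, 0.15, True),   # published RFI x methane-yield correlation
            (0.06, 0.18, False),   # published carcass-lean correlation
            (0.30, 0.15, False),   # exactly 2 SE: strict rule says no
        ],
    )
    def test_two_se_rule(self, est, se, expected):
        assert significance_flag(est, se) is expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            significance_flag(np.nan, 0.1)
        with pytest.raises(ValueError):
            significance_flag(0.3, 0.0)


class TestMixedModelEquations:
    def test_intercept_only_design(self):
        y = np.arange(6.0)
        X = np.ones((6, 1))
        Z = np.eye(6)
        mme = build_mme(y, X, [Z], [np.eye(6)], [1.0], 1.0, names=["animal"])
        beta, effects = mme.solve()
        assert beta.shape == (1,)
        assert effects["animal"].shape == (6,)

    def test_repeated_records_share_one_effect(self):
        # two records per animal map onto a single additive effect
        Z = np.kron(np.eye(3), np.ones((2, 1)))
        y = np.arange(6.0)
        mme = build_mme(y, np.ones((6, 1)), [Z], [np.eye(3)], [1.0], 1.0)
        _, effects = mme.solve()
        assert effects["term0"].shape == (3,)

    def test_toy_solution_matches_explicit_gls(self, rng):
        # 6-animal pedigree, animal model with known variances: MME BLUE and
        # BLUP must equal the dense GLS formulas
        ped = random_pedigree(6, rng, n_founders=3)
        A = build_A(ped).values
        n = 6
        sigma_a, sigma_e = 0.7, 1.3
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z = np.eye(n)
        mme = build_mme(y, X, [Z], [np.linalg.inv(A)], [sigma_a], sigma_e)
        beta, effects = mme.solve()
        V = sigma_a * A + sigma_e * np.eye(n)
        Vi = np.linalg.inv(V)
        beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u_gls = sigma_a * A @ Vi @ (y - X @ beta_gls)
        np.testing.assert_allclose(beta, beta_gls, atol=1e-8)
        np.testing.assert_allclose(effects["term0"], u_gls, atol=1e-8)


def _brute_force_h2(y, X, A, lo=1e-6, hi=1 - 1e-6):
    """Independent profile-likelihood oracle: dense grid plus refinement."""
    n, p = X.shape

    def neg_profile(h2):
        V0 = h2 * A + (1 - h2) * np.eye(n)
        Vi = np.linalg.inv(V0)
        B = X.T @ Vi @ X
        beta = np.linalg.solve(B, X.T @ Vi @ y)
        r = y - X @ beta
        quad = r @ Vi @ r
        sigma = quad / (n - p)
        _, logdetV = np.linalg.slogdet(V0)
        _, logdetB = np.linalg.slogdet(B)
        return (n - p) * np.log(sigma) + logdetV + logdetB

    grid = np.linspace(lo, hi, 400)
    vals = [neg_profile(h) for h in grid]
    k = int(np.argmin(vals))
    from scipy.optimize import minimize_scalar

    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(neg_profile, bounds=(a, b), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


class TestUnivariateREML:
    def test_null_heritability_rarely_exceeds_005(self, half_sib_design):
        # simulated sigma2_a = 0: estimated h2 < 0.05 in at least 19/20
        # replicates of n = 1000
        ped, A, pos = half_sib_design
        rng = np.random.default_rng(77)
        low = 0
        for _ in range(20):
            df = simulate_trait_values(ped, G=[[1e-12]], E=[[1.0]], rng=rng)
            idx = df["animal"].map(pos).to_numpy()
            vc = reml_univariate(df["y1"].to_numpy(), np.ones((len(df), 1)), A.values, idx)
            low += vc.h2_direct < 0.05
        assert low >= 19

    def test_dense_engine_matches_eigen_path(self, half_sib_design):
        ped, A, pos = half_sib_design
        rng = np.random.default_rng(15)
        df = simulate_trait_values(ped, G=[[0.4]], E=[[0.6]], rng=rng).iloc[:300]
        idx = df["animal"].map(pos).to_numpy()
        y = df["y1"].to_numpy()
        X = np.ones((len(y), 1))
        Asub = A.values[np.ix_(idx, idx)]
        eig = reml_eigen_additive(y, X, Asub)
        dense = reml_linear_structure(y, X, [Asub, np.eye(len(y))], ["additive", "residual"])
        h_eig = eig.theta[0] / eig.theta.sum()
        h_dense = dense.theta[0] / dense.theta.sum()
        assert h_dense == pytest.approx(h_eig, abs=1e-5)

    def test_matches_brute_force_profile_on_small_pedigree(self):
        # inbred 50-animal pedigree: dense AI-REML equals an independent
        # grid-plus-refinement profile likelihood within 1e-4 in h2
        rng = np.random.default_rng(21)
        ped = random_pedigree(50, rng)
        A = build_A(ped).values
        bvs = np.linalg.cholesky(A + 1e-10 * np.eye(50)) @ rng.standard_normal(50)
        y = 1.0 + np.sqrt(0.4) * bvs + np.sqrt(0.6) * rng.standard_normal(50)
        X = np.ones((50, 1))
        fit = reml_linear_structure(
            y, X, [A, np.eye(50)], ["additive", "residual"], tol_logl=1e-10, tol_theta=1e-7
        )
        h2 = fit.theta[0] / fit.theta.sum()
        h2_brute = _brute_force_h2(y, X, A)
        assert h2 == pytest.approx(h2_brute, abs=1e-4)

    def test_loglik_never_decreases_across_iterations(self, half_sib_design):
        ped, A, pos = half_sib_design
        rng = np.random.default_rng(31)
        df = simulate_trait_values(ped, G=[[0.3]], E=[[0.7]], rng=rng).iloc[:400]
        idx = df["animal"].map(pos).to_numpy()
        Asub = A.values[np.ix_(idx, idx)]
        fit = reml_linear_structure(
            df["y1"].to_numpy(), np.ones((len(df), 1)), [Asub, np.eye(len(df))],
            ["additive", "residual"],
        )
        lls = [ll for _, ll in fit.history]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_estimates_invariant_to_row_permutation(self, half_sib_design):
        ped, A, pos = half_sib_design
        rng = np.random.default_rng(41)
        df = simulate_trait_values(ped, G=[[0.4]], E=[[0.6]], rng=rng).iloc[:500]
        perm = rng.permutation(len(df))
        idx = df["animal"].map(pos).to_numpy()
        X = np.ones((len(df), 1))
        vc1 = reml_univariate(df["y1"].to_numpy(), X, A.values, idx)
        vc2 = reml_univariate(df["y1"].to_numpy()[perm], X, A.values, idx[perm])
        assert vc1.h2_direct == pytest.approx(vc2.h2_direct, abs=1e-6)

    def test_repeated_records_estimate_repeatability(self, rng):
        # 300 animals x 2 records; repeatability = (a + pe)/(a + pe + e)
        n = 300
        ped = random_pedigree(n, np.random.default_rng(8), n_founders=50)
        A = build_A(ped).values
        bvs = np.linalg.cholesky(A + 1e-10 * np.eye(n)) @ rng.standard_normal(n)
        a = np.sqrt(0.3) * bvs
        pe = np.sqrt(0.25) * rng.standard_normal(n)
        y = np.concatenate(
            [a + pe + np.sqrt(0.45) * rng.standard_normal(n) for _ in range(2)]
        )
        idx = np.concatenate([np.arange(n), np.arange(n)])
        vc = reml_univariate(y, np.ones((2 * n, 1)), A, idx, permanent_env=True)
        assert vc.repeatability == pytest.approx(0.55, abs=0.12)
        assert vc.converged


class TestBivariateREML:
    def test_duplicated_trait_hits_boundary(self, half_sib_design):
        ped, A, pos = half_sib_design
        rng = np.random.default_rng(51)
        df = simulate_trait_values(ped, G=[[0.4]], E=[[0.6]], rng=rng).iloc[:300]
        idx = df["animal"].map(pos).to_numpy()
        y = df["y1"].to_numpy()
        ce = reml_bivariate(y, y.copy(), np.ones((len(y), 1)), A.values, idx)
        assert ce.r_g == 1.0 and ce.r_p == 1.0 and ce.boundary

    def test_independent_traits_near_zero(self, half_sib_design):
        ped, A, pos = half_sib_design
        rng = np.random.default_rng(61)
        estimates = []
        for _ in range(5):
            df = simulate_trait_values(ped, G=np.diag([0.4, 0.4]), E=np.diag([0.6, 0.6]), rng=rng)
            idx = df["animal"].map(pos).to_numpy()
            ce = reml_bivariate(
                df["y1"].to_numpy(), df["y2"].to_numpy(), np.ones((len(df), 1)), A.values, idx
            )
            estimates.append(ce.r_g)
        assert abs(np.mean(estimates)) < 0.15

    def test_phenotypic_correlation_tracks_sample_correlation(self, half_sib_design):
        ped, A, pos = half_sib_design
        rng = np.random.default_rng(71)
        G = np.array([[0.4, 0.1], [0.1, 0.4]])
        E = np.array([[0.6, 0.3], [0.3, 0.6]])
        df = simulate_trait_values(ped, G, E, rng=rng)
        idx = df["animal"].map(pos).to_numpy()
        ce = reml_bivariate(
            df["y1"].to_numpy(), df["y2"].to_numpy(), np.ones((len(df), 1)), A.values, idx
        )
        sample_r = np.corrcoef(df["y1"], df["y2"])[0, 1]
        assert ce.r_p == pytest.approx(sample_r, abs=0.05)
        assert ce.r_g_se > 0 and ce.r_p_se > 0
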