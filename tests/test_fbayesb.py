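"""The ICE estimator: closed-form posterior mean, sweeps, convergence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from epibayes import design, fbayesb
from epibayes.fbayesb import (
    PriorSpec,
    derive_lambda,
    effect_summary,
    ice_fit,
    posterior_mean_effect,
    predict_dgv,
    truncated_normal_mean,
    update_residual_variance,
)


def quadrature_posterior_mean(Y, s2, lam, gamma):
    """Brute-force posterior mean under the point-mass/Laplace mixture.

    Independent oracle: numerically integrates the exact posterior over the
    effect, splitting the domain at the likelihood peak and at zero.
    """
    sd = np.sqrt(s2)
    lo = min(-60 / lam, Y - 60 * sd)
    hi = max(60 / lam, Y + 60 * sd)
    pts = sorted({lo, Y - 8 * sd, Y, Y + 8 * sd, 0.0, hi})
    pts = [p for p in pts if lo <= p <= hi]

    def slab(g):
        return norm.pdf(Y, loc=g, scale=sd) * 0.5 * lam * np.exp(-lam * abs(g))

    num = den = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        num += quad(lambda g: g * slab(g), a, b, limit=400,
                    epsabs=1e-14, epsrel=1e-12)[0]
        den += quad(slab, a, b, limit=400, epsabs=1e-14, epsrel=1e-12)[0]
    return gamma * num / (gamma * den + (1 - gamma) * norm.pdf(Y, 0, sd))


class TestPrior:
    def test_lambda_solves_unit_total_variance(self):
        for gamma, m in [(0.005, 5227), (1e-6, 13_658_151), (0.05, 523)]:
            lam = derive_lambda(gamma, m)
            assert m * gamma * 2.0 / lam**2 == pytest.approx(1.0)

    def test_reference_values(self):
        assert derive_lambda(0.005, 5227) == pytest.approx(np.sqrt(52.27))
        assert derive_lambda(1e-6, 13_658_151) == pytest.approx(np.sqrt(27.316302))

    def test_prior_variance_bookkeeping(self):
        p = PriorSpec.from_unit_variance(0.005, 5227)
        assert p.effect_variance * p.m == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            derive_lambda(0.0, 10)
        with pytest.raises(ValueError):
            derive_lambda(0.5, 0)


class TestTruncatedNormalMean:
    def test_half_normal_mean(self):
        assert truncated_normal_mean(0.0, 1.0, "above_zero") == pytest.approx(
            np.sqrt(2 / np.pi))

    @given(mu=st.floats(-30.0, 30.0), s2=st.floats(1e-4, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_sign(self, mu, s2):
        up = truncated_normal_mean(mu, s2, "above_zero")
        lo = truncated_normal_mean(-mu, s2, "below_zero")
        assert up == pytest.approx(-lo, rel=1e-9, abs=1e-12)
        assert up > 0.0
        assert truncated_normal_mean(mu, s2, "below_zero") < 0.0

    def test_negligible_truncation(self):
        assert truncated_normal_mean(5.0, 0.01, "above_zero") == pytest.approx(
            5.0, abs=1e-6)

    def test_extreme_standardized_mean_is_finite(self):
        # |mean|/sd = 35: must not overflow or hit 0/0
        val = truncated_normal_mean(-35.0, 1.0, "above_zero")
        assert 0 < val < 0.1

    def test_bad_variance(self):
        with pytest.raises(ValueError):
            truncated_normal_mean(0.0, 0.0, "above_zero")


class TestPosteriorMean:
    def test_antisymmetric_in_Y(self):
        assert posterior_mean_effect(0.0, 0.1, 2.0, 0.01) == pytest.approx(0.0, abs=1e-12)
        a = posterior_mean_effect(0.4, 0.05, 3.0, 0.01)
        b = posterior_mean_effect(-0.4, 0.05, 3.0, 0.01)
        assert a == pytest.approx(-b, rel=1e-10)

    def test_point_mass_dominates_as_gamma_vanishes(self):
        est = posterior_mean_effect(0.5, 0.01, 0.3, 1e-300)
        assert abs(est) < 1e-200

    def test_quadrature_oracle_spot_checks(self):
        for args in [(0.5, 0.01, 0.3, 0.005), (0.2, 0.02, 7.23, 0.005),
                     (-1.5, 0.5, 2.0, 1e-4), (0.05, 1e-3, 5.0, 0.5)]:
            assert posterior_mean_effect(*args) == pytest.approx(
                quadrature_posterior_mean(*args), rel=1e-6)

    @given(Y=st.floats(-20.0, 20.0), s2=st.floats(1e-4, 5.0),
           lam=st.floats(0.05, 15.0), gamma=st.floats(1e-8, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_monotone_shrinkage(self, Y, s2, lam, gamma):
        """|estimate| <= |Y| and the estimate carries the sign of Y."""
        est = posterior_mean_effect(Y, s2, lam, gamma)
        assert abs(est) <= abs(Y) + 1e-9
        assert est * Y >= -1e-12

    def test_numba_kernel_matches_public_function(self):
        from epibayes.fbayesb import _nb_post_mean
        rng = np.random.default_rng(3)
        for _ in range(200):
            Y = float(rng.normal(0, 2))
            s2 = float(10 ** rng.uniform(-4, 0.5))
            lam = float(10 ** rng.uniform(-1, 1.2))
            gamma = float(10 ** rng.uniform(-7, 0))
            assert _nb_post_mean(Y, s2, lam, gamma) == pytest.approx(
                posterior_mean_effect(Y, s2, lam, gamma), rel=1e-10, abs=1e-300)

    def test_pure_laplace_prior_allowed(self):
        est = posterior_mean_effect(1.0, 0.01, 2.0, 1.0)
        assert 0.9 < est < 1.0


class TestEffectSummary:
    def test_exact_recovery_of_scalar_coefficient(self, rng):
        col = rng.standard_normal(100)
        y = 2.5 * col
        Y, inv_xtx = effect_summary(y, 0.0, col)
        assert Y == pytest.approx(2.5)
        assert inv_xtx == pytest.approx(1.0 / (col @ col))

    def test_orthogonal_residual_gives_zero(self, rng):
        col = np.zeros(10)
        col[0] = 1.0
        resid = np.zeros(10)
        resid[1] = 3.0
        Y, _ = effect_summary(resid, 0.0, col)
        assert Y == 0.0

    def test_unit_variance_column_scaling(self, rng):
        col = rng.standard_normal(5000)
        col /= col.std()
        _, inv_xtx = effect_summary(rng.standard_normal(5000), 0.0, col)
        assert inv_xtx == pytest.approx(1.0 / 5000, rel=0.01)

    def test_inert_column_rejected(self):
        with pytest.raises(ValueError):
            effect_summary(np.ones(5), 0.0, np.zeros(5))


class TestResidualVariance:
    def test_examples(self):
        assert update_residual_variance(np.ones(3), np.ones(3)) == 0.0
        assert update_residual_variance(np.ones(3), np.zeros(3)) == pytest.approx(1.5)

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            update_residual_variance(np.ones(1), np.zeros(1))


def _blocks_from_genotypes(geno):
    from epibayes.popsim import compute_marker_stats, oriented_genotypes

    stats = compute_marker_stats(geno)
    oriented = oriented_genotypes(geno, stats)
    coding = design.orthogonal_coding(stats.p11, stats.p12, stats.p22)
    return design.build_design(oriented, coding)


class TestIceFit:
    def test_recovers_single_large_effect(self, rng):
        n, m = 500, 40
        geno = rng.binomial(2, 0.5, size=(n, m))
        blocks = _blocks_from_genotypes(geno)
        g_true = 1.2
        y = blocks.Xa[:, 7] * g_true + rng.normal(0, 0.3, n)
        fit = ice_fit(y, blocks, "M0", gammas={"a": 0.05})
        assert fit.converged
        est = fit.estimates["a"]
        post_sd = np.sqrt(fit.sigma_e2 / n)
        assert abs(est[7] - g_true) < 3 * post_sd + 0.05
        # null effects are shrunk to (near) zero; a few markers correlated
        # with the causal column by chance may retain slightly more
        others = np.abs(np.delete(est, 7))
        assert np.all(others < 0.01)
        assert np.median(others) < 1e-3

    def test_noise_only_with_vanishing_gamma(self, rng):
        n, m = 200, 30
        geno = rng.binomial(2, 0.4, size=(n, m))
        blocks = _blocks_from_genotypes(geno)
        y = rng.standard_normal(n)
        fit = ice_fit(y, blocks, "M1", gammas={"a": 1e-12, "d": 1e-12})
        # first sweep moves the (tiny) estimates off exact zero, so the
        # relative-change criterion needs one more sweep to certify
        assert fit.converged and fit.n_iter <= 2
        assert np.all(np.abs(fit.estimates["a"]) < 1e-8)
        assert np.all(np.abs(fit.estimates["d"]) < 1e-8)

    def test_noise_only_residual_variance_unbiased(self, rng):
        """With zero heritability, sigma_e2_hat tracks Var(y) on average."""
        vals = []
        for _ in range(5):
            geno = rng.binomial(2, 0.5, size=(300, 50))
            blocks = _blocks_from_genotypes(geno)
            y = rng.standard_normal(300)
            fit = ice_fit(y, blocks, "M1")
            vals.append(fit.sigma_e2 / np.var(y, ddof=1))
        assert abs(np.mean(vals) - 1.0) < 0.05

    def test_final_sigma_matches_residual_bookkeeping(self, rng):
        n, m = 150, 25
        geno = rng.binomial(2, 0.5, size=(n, m))
        blocks = _blocks_from_genotypes(geno)
        y = blocks.Xa[:, 3] - 0.5 * blocks.Xd[:, 8] + rng.normal(0, 0.5, n)
        fit = ice_fit(y, blocks, "M1", gammas={"a": 0.1, "d": 0.1})
        pred = predict_dgv(blocks, fit.estimates)
        y_c = y - fit.y_mean
        assert fit.sigma_e2 == pytest.approx(
            update_residual_variance(y_c, pred["total"]), rel=1e-8)

    def test_fixed_point_consistency(self, rng):
        """Re-running one sweep from a converged state stays converged."""
        n, m = 150, 25
        geno = rng.binomial(2, 0.5, size=(n, m))
        blocks = _blocks_from_genotypes(geno)
        y = blocks.Xa[:, 3] + rng.normal(0, 0.5, n)
        fit = ice_fit(y, blocks, "M1", gammas={"a": 0.1, "d": 0.1})
        assert fit.converged
        assert fit.criterion_trace[-1] <= 1e-8

    def test_m2_finds_planted_interaction(self, rng):
        n, m = 400, 12
        geno = rng.binomial(2, 0.5, size=(n, m))
        blocks = _blocks_from_genotypes(geno)
        col = design.interaction_column(blocks, "aa", 2, 9)
        y = 1.5 * col + rng.normal(0, 0.5, n)
        fit = ice_fit(y, blocks, "M2",
                      gammas={"a": 0.05, "d": 0.05, "epi": 0.01})
        g_aa = fit.estimates["aa"]
        top = np.argmax(np.abs(g_aa))
        assert top == design.pair_index(2, 9, m)
        assert g_aa[top] == pytest.approx(1.5, abs=0.15)

    def test_covariate_correction(self, rng):
        n, m = 300, 20
        geno = rng.binomial(2, 0.5, size=(n, m))
        blocks = _blocks_from_genotypes(geno)
        C = rng.standard_normal((n, 2))
        y = blocks.Xa[:, 5] + C @ np.array([3.0, -2.0]) + rng.normal(0, 0.3, n)
        fit = ice_fit(y, blocks, "M0", gammas={"a": 0.05}, covariates=C)
        assert fit.converged
        assert abs(fit.estimates["a"][5] - 1.0) < 0.15
        np.testing.assert_allclose(fit.covariate_coef, [3.0, -2.0], atol=0.1)

    def test_constant_phenotype_rejected(self, rng):
        geno = rng.binomial(2, 0.5, size=(20, 5))
        blocks = _blocks_from_genotypes(geno)
        with pytest.raises(ValueError):
            ice_fit(np.ones(20), blocks, "M1")


class TestPredictDgv:
    def test_zero_estimates_give_zero_dgv(self, rng):
        geno = rng.binomial(2, 0.5, size=(30, 8))
        blocks = _blocks_from_genotypes(geno)
        parts = predict_dgv(blocks, {"a": np.zeros(8), "d": np.zeros(8)})
        np.testing.assert_array_equal(parts["total"], 0.0)

    def test_single_effect_is_scaled_column(self, rng):
        geno = rng.binomial(2, 0.5, size=(30, 8))
        blocks = _blocks_from_genotypes(geno)
        g = np.zeros(8)
        g[2] = 0.7
        parts = predict_dgv(blocks, {"a": g})
        np.testing.assert_allclose(parts["total"], 0.7 * blocks.Xa[:, 2])

    def test_marker_mismatch_rejected(self, rng):
        geno = rng.binomial(2, 0.5, size=(30, 8))
        blocks = _blocks_from_genotypes(geno)
        with pytest.raises(ValueError):
            predict_dgv(blocks, {"a": np.zeros(9)})
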