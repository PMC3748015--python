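"""Trait simulation and F-infinity <-> orthogonal scale translation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epibayes import design, traitsim
from epibayes.design import S_FINF, noia_matrix, orthogonal_coding
from epibayes.traitsim import (
    EPISTASIS_PARAMS_23,
    TraitArchitecture,
    calibrate_residual_variance,
    genotypic_values_finf,
    marginal_main_effects,
    sample_epistatic_pairs,
    sample_main_effects,
    simulate_phenotypes,
    translate_pairwise,
    translate_single_locus,
)


def _freqs(rng):
    f = rng.dirichlet([3.0, 3.0, 3.0])
    return float(f[0]), float(f[1]), float(f[2])


class TestEffectSampling:
    def test_zero_degree_of_dominance_gives_zero_d(self, rng):
        _, d = sample_main_effects(50, rng, dom_mean=0.0, dom_sd=0.0)
        np.testing.assert_array_equal(d, 0.0)

    def test_gamma_mean_is_shape_over_rate(self, rng):
        a, _ = sample_main_effects(200_000, rng)
        assert abs(np.abs(a).mean() - 0.42 / 2.619) < 2e-3
        # signs equally likely
        assert abs((a > 0).mean() - 0.5) < 0.01

    def test_pair_sampling_counts_and_ordering(self, rng):
        qtl = np.arange(10, 33)
        pairs, effects = sample_epistatic_pairs(qtl, 6, EPISTASIS_PARAMS_23, rng)
        for s in ("aa", "ad", "da", "dd"):
            assert pairs[s].shape == (6, 2)
            assert effects[s].shape == (6,)
            assert np.all(pairs[s][:, 0] < pairs[s][:, 1])
            # no duplicated pair within a source
            assert len({tuple(p) for p in pairs[s]}) == 6

    def test_too_many_pairs_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_epistatic_pairs(np.arange(3), 10, EPISTASIS_PARAMS_23, rng)


class TestGenotypicValues:
    def test_single_heterozygous_qtl(self):
        arch = TraitArchitecture(qtl=np.array([0]), a=np.array([1.0]),
                                 d=np.array([0.5]))
        G = genotypic_values_finf(np.array([[1]]), arch)
        assert G[0] == 0.5

    def test_aa_pair_between_frequent_homozygotes(self):
        arch = TraitArchitecture(
            qtl=np.array([0, 1]), a=np.zeros(2), d=np.zeros(2),
            epi_pairs={"aa": np.array([[0, 1]])},
            epi_effects={"aa": np.array([0.7])})
        G = genotypic_values_finf(np.array([[2, 2], [0, 2], [1, 2]]), arch)
        np.testing.assert_allclose(G, [0.7, -0.7, 0.0])

    def test_all_zero_effects(self, rng):
        geno = rng.integers(0, 3, (20, 5))
        arch = TraitArchitecture(qtl=np.arange(5), a=np.zeros(5), d=np.zeros(5))
        np.testing.assert_array_equal(genotypic_values_finf(geno, arch), 0.0)


class TestCalibration:
    def test_residual_variance_from_heritability(self):
        g = np.array([0.0, 2.0])  # empirical variance 2
        assert calibrate_residual_variance(g, 0.5) == pytest.approx(2.0)
        assert calibrate_residual_variance(g, 0.1) == pytest.approx(18.0)

    def test_monomorphic_trait_rejected(self):
        with pytest.raises(ValueError):
            calibrate_residual_variance(np.ones(5), 0.5)

    def test_phenotype_variance_additivity(self, rng):
        g = rng.standard_normal(200_000)
        y = simulate_phenotypes(g, 1.0, rng)
        assert abs(np.var(y) - (np.var(g) + 1.0)) < 0.03


class TestSingleLocusTranslation:
    def test_symmetric_hwe_no_dominance(self):
        ga, gd = translate_single_locus(0.0, 1.3, 0.0, (0.25, 0.5, 0.25))
        assert gd == pytest.approx(0.0, abs=1e-12)
        assert ga != 0.0

    def test_three_genotypic_values_reconstructed(self, rng):
        """The translation is an exact change of basis per locus."""
        for _ in range(25):
            freqs = _freqs(rng)
            mu, a, d = rng.normal(size=3)
            SA = noia_matrix(*freqs)
            target = S_FINF @ np.array([mu, a, d])
            w = np.linalg.solve(SA, target)
            ga, gd = translate_single_locus(mu, a, d, freqs, standardize=False)
            np.testing.assert_allclose(SA @ np.array([w[0], ga, gd]), target,
                                       atol=1e-10)

    def test_matches_weighted_regression_oracle(self, rng):
        """(g_a, g_d) equal the frequency-weighted least-squares projection
        of the three genotypic values onto the orthogonal columns."""
        for _ in range(25):
            freqs = _freqs(rng)
            mu, a, d = rng.normal(size=3)
            G = S_FINF @ np.array([mu, a, d])
            SA = noia_matrix(*freqs)
            W = np.diag(freqs)
            beta = np.linalg.solve(SA.T @ W @ SA, SA.T @ W @ G)
            ga, gd = translate_single_locus(mu, a, d, freqs, standardize=False)
            np.testing.assert_allclose([ga, gd], beta[1:], atol=1e-10)


class TestPairwiseTranslation:
    def test_zero_in_zero_out(self):
        out = translate_pairwise(np.zeros(9), (0.3, 0.4, 0.3), (0.2, 0.5, 0.3))
        np.testing.assert_array_equal(out, 0.0)

    def test_pure_aa_at_symmetric_hwe_has_no_other_epistasis(self):
        alpha = np.zeros(9)
        alpha[4] = 1.0  # aa on the F-infinity scale
        hwe = (0.25, 0.5, 0.25)
        out = translate_pairwise(alpha, hwe, hwe)
        # da, ad, dd components vanish by allele-frequency symmetry
        assert abs(out[5]) < 1e-12 and abs(out[7]) < 1e-12 and abs(out[8]) < 1e-12
        assert out[4] != 0.0

    def test_nine_genotypic_values_identical_under_both_bases(self, rng):
        for _ in range(25):
            fj, fk = _freqs(rng), _freqs(rng)
            alpha = rng.normal(size=9)
            star = translate_pairwise(alpha, fj, fk)
            table_f = np.kron(S_FINF, S_FINF) @ alpha
            table_o = np.kron(noia_matrix(*fk), noia_matrix(*fj)) @ star
            np.testing.assert_allclose(table_o, table_f, atol=1e-9)

    def test_matches_weighted_regression_oracle(self, rng):
        """Orthogonal pair effects equal the 9-class weighted regression of
        the genotypic-value table on the Kronecker orthogonal basis."""
        fj, fk = _freqs(rng), _freqs(rng)
        alpha = rng.normal(size=9)
        table = np.kron(S_FINF, S_FINF) @ alpha
        B = np.kron(noia_matrix(*fk), noia_matrix(*fj))
        w = np.kron(np.array(fk), np.array(fj))
        W = np.diag(w)
        beta = np.linalg.solve(B.T @ W @ B, B.T @ W @ table)
        np.testing.assert_allclose(translate_pairwise(alpha, fj, fk), beta,
                                   atol=1e-9)


def _random_architecture(rng, m=12, n_qtl=6, epistasis=True):
    qtl = np.sort(rng.choice(m, size=n_qtl, replace=False))
    a, d = sample_main_effects(n_qtl, rng)
    arch = TraitArchitecture(qtl=qtl, a=a, d=d)
    if epistasis:
        arch.epi_pairs, arch.epi_effects = sample_epistatic_pairs(
            qtl, 3, EPISTASIS_PARAMS_23, rng)
    return arch


def _random_coding(rng, m=12):
    f = rng.dirichlet([3.0, 3.0, 3.0], size=m)
    return orthogonal_coding(f[:, 0], f[:, 1], f[:, 2])


class TestMarginalMainEffects:
    def test_without_epistasis_equals_single_locus_translation(self, rng):
        arch = _random_architecture(rng, epistasis=False)
        coding = _random_coding(rng)
        truth = marginal_main_effects(arch, coding)
        for q, a, d in zip(arch.qtl, arch.a, arch.d):
            q = int(q)
            ga, gd = translate_single_locus(
                0.0, a, d, (coding.p11[q], coding.p12[q], coding.p22[q]))
            assert truth.g_a[q] == pytest.approx(ga, abs=1e-12)
            assert truth.g_d[q] == pytest.approx(gd, abs=1e-12)

    def test_aa_pair_at_symmetric_hwe_leaves_no_marginal(self):
        arch = TraitArchitecture(
            qtl=np.array([0, 1]), a=np.zeros(2), d=np.zeros(2),
            epi_pairs={"aa": np.array([[0, 1]])},
            epi_effects={"aa": np.array([1.0])})
        coding = orthogonal_coding([0.25, 0.25], [0.5, 0.5], [0.25, 0.25])
        truth = marginal_main_effects(arch, coding)
        np.testing.assert_allclose(truth.g_a, 0.0, atol=1e-12)
        np.testing.assert_allclose(truth.g_d, 0.0, atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_representation_equivalence(self, seed):
        """F-infinity genotypic values equal the orthogonal reconstruction
        (marginal mains + all epistatic components) up to a constant."""
        from epibayes.workbench import true_genetic_values

        rng = np.random.default_rng(seed)
        m = 10
        geno = rng.integers(0, 3, size=(40, m))
        # use empirical class frequencies so every class has positive mass
        geno[:3] = [[0] * m, [1] * m, [2] * m]
        counts = np.stack([(geno == c).mean(0) for c in range(3)], axis=1)
        coding = orthogonal_coding(counts[:, 0], counts[:, 1], counts[:, 2])
        arch = _random_architecture(rng, m=m, n_qtl=5)
        truth = marginal_main_effects(arch, coding)
        parts = true_genetic_values(geno, coding, truth, arch)
        G = genotypic_values_finf(geno, arch)
        diff = G - parts["total"]
        scale = max(np.abs(G).max(), 1.0)
        assert np.ptp(diff) < 1e-8 * scale
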