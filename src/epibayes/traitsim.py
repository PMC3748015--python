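"""Trait architecture simulation and translation to the orthogonal scale.

A trait is defined on the F-infinity scale: each QTL carries an allele
substitution effect ``a_j`` (|a| gamma-distributed with random sign) and a
dominance effect ``d_j = |a_j| * degree-of-dominance`` with the degree drawn
from a normal distribution.  Optionally, pairs of QTL carry epistatic
effects (sources aa/ad/da/dd) applied to products of the F-infinity
covariates.  The residual variance is calibrated from the empirical variance
of the total genotypic values among the phenotyped individuals so the
configured broad-sense heritability is realized exactly.

Because estimation operates on the orthogonal, standardized scale, the true
effects are translated locus by locus (and pair by pair) through the change
of basis between the F-infinity matrix ``S`` and the frequency-dependent
orthogonal basis ``S_A``; main-effect truths additionally collect the
marginal contributions of every interaction a locus participates in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import (
    EPISTASIS_SOURCES,
    S_FINF,
    OrthogonalCoding,
    finf_design,
    noia_matrix,
)

__all__ = [
    "EPISTASIS_PARAMS_23",
    "EPISTASIS_PARAMS_230",
    "TraitArchitecture",
    "OrthogonalTruth",
    "sample_main_effects",
    "sample_epistatic_pairs",
    "sample_architecture",
    "genotypic_values_finf",
    "calibrate_residual_variance",
    "simulate_phenotypes",
    "translate_single_locus",
    "translate_pairwise",
    "marginal_main_effects",
]

# Normal (mean, variance) per epistatic source for the two QTL scenarios;
# chosen so epistasis explains roughly a quarter of the genetic variance.
EPISTASIS_PARAMS_23 = {
    "aa": (0.2, 0.3),
    "ad": (0.2, 0.3),
    "da": (0.2, 0.2),
    "dd": (0.2, 0.1),
}
EPISTASIS_PARAMS_230 = {
    "aa": (0.02, 0.03),
    "ad": (0.02, 0.03),
    "da": (0.02, 0.02),
    "dd": (0.02, 0.01),
}

# Index of each component in the 9-vector of pair effects
# (mu, a_j, d_j, a_k, aa, da, d_k, ad, dd), i.e. the Kronecker ordering
# (locus-k basis) x (locus-j basis).
_PAIR_SLOT = {"aa": 4, "da": 5, "ad": 7, "dd": 8}


@dataclass
class TraitArchitecture:
    """True genetic architecture on the F-infinity scale.

    ``qtl`` holds marker (panel column) indices; ``a``/``d`` are the per-QTL
    allele substitution and dominance effects in trait units.  ``epi_pairs``
    maps each source to an (n_pairs, 2) array of marker indices (j < k) and
    ``epi_effects`` to the corresponding effect sizes.
    """

    qtl: np.ndarray
    a: np.ndarray
    d: np.ndarray
    epi_pairs: dict[str, np.ndarray] = field(default_factory=dict)
    epi_effects: dict[str, np.ndarray] = field(default_factory=dict)
    h2_broad: float | None = None
    sigma_e2: float | None = None

    @property
    def has_epistasis(self) -> bool:
        return any(len(v) for v in self.epi_effects.values())

    @property
    def n_qtl(self) -> int:
        return len(self.qtl)


def sample_main_effects(n_qtl, rng, gamma_shape=0.42, gamma_rate=2.619,
                        dom_mean=0.193, dom_sd=0.312):
    """Draw allele substitution and dominance effects for ``n_qtl`` loci.

    |a_j| ~ Gamma(shape, rate) with the sign equally likely positive or
    negative; d_j is |a_j| times a N(dom_mean, dom_sd**2) degree of
    dominance.  The gamma's second parameter is a rate (scale = 1/rate).
    """
    if gamma_shape <= 0 or gamma_rate <= 0:
        raise ValueError("gamma shape and rate must be positive")
    mag = rng.gamma(gamma_shape, 1.0 / gamma_rate, size=n_qtl)
    sign = rng.choice([-1.0, 1.0], size=n_qtl)
    a = sign * mag
    degree = rng.normal(dom_mean, dom_sd, size=n_qtl)
    d = mag * degree
    return a, d


def sample_epistatic_pairs(qtl_indices, n_pairs_per_source, source_params, rng):
    """Sample interacting QTL pairs and their effects, per source.

    Pairs are drawn without replacement within a source (independently
    across sources, so a pair may recur in different sources); the effect of
    a pair in source ``s`` is N(m_s, tau_s^2) with ``source_params[s] =
    (m_s, tau_s^2)``.  Returned pair indices satisfy j < k.
    """
    qtl = np.asarray(qtl_indices)
    nq = len(qtl)
    total = nq * (nq - 1) // 2
    if n_pairs_per_source > total:
        raise ValueError(
            f"cannot draw {n_pairs_per_source} distinct pairs from {nq} QTL"
        )
    jj, kk = np.triu_indices(nq, k=1)
    pairs_out, effects_out = {}, {}
    for source in EPISTASIS_SOURCES:
        mean, tau2 = source_params[source]
        pick = rng.choice(total, size=n_pairs_per_source, replace=False)
        p = np.stack([qtl[jj[pick]], qtl[kk[pick]]], axis=1)
        p.sort(axis=1)  # qtl indices ascending => j < k preserved
        pairs_out[source] = p
        effects_out[source] = rng.normal(mean, np.sqrt(tau2), size=n_pairs_per_source)
    return pairs_out, effects_out


def sample_architecture(candidate_markers, n_qtl, rng, *, epistasis=False,
                        scenario_params=None, n_pairs_per_source=None,
                        gamma_rate=None) -> TraitArchitecture:
    """Sample a full 23- or 230-QTL style architecture.

    ``candidate_markers`` are panel indices eligible to become QTL (callers
    apply the MAF > 0.02 eligibility rule).  Scenario defaults follow the
    QTL count: 23 QTL use gamma rate 2.619 and 6 pairs per epistatic source,
    230 QTL use rate 8.282 and 57 pairs.
    """
    candidate_markers = np.asarray(candidate_markers)
    if len(candidate_markers) < n_qtl:
        raise ValueError("not enough eligible markers to place the QTL")
    if gamma_rate is None:
        gamma_rate = 2.619 if n_qtl <= 100 else 8.282
    if scenario_params is None:
        scenario_params = EPISTASIS_PARAMS_23 if n_qtl <= 100 else EPISTASIS_PARAMS_230
    if n_pairs_per_source is None:
        n_pairs_per_source = 6 if n_qtl <= 100 else 57
    qtl = np.sort(rng.choice(candidate_markers, size=n_qtl, replace=False))
    a, d = sample_main_effects(n_qtl, rng, gamma_rate=gamma_rate)
    arch = TraitArchitecture(qtl=qtl, a=a, d=d)
    if epistasis:
        arch.epi_pairs, arch.epi_effects = sample_epistatic_pairs(
            qtl, n_pairs_per_source, scenario_params, rng
        )
    return arch


def genotypic_values_finf(class_genotypes: np.ndarray,
                          arch: TraitArchitecture) -> np.ndarray:
    """Total genotypic value per individual on the F-infinity scale.

    ``class_genotypes`` is the full (individual x panel-marker) matrix of
    frequent-allele counts; only the QTL columns contribute.
    """
    G = np.asarray(class_genotypes)
    col = {int(q): i for i, q in enumerate(arch.qtl)}
    X, D = finf_design(G[:, arch.qtl])
    g = X @ arch.a + D @ arch.d
    for source in EPISTASIS_SOURCES:
        pairs = arch.epi_pairs.get(source)
        if pairs is None or len(pairs) == 0:
            continue
        eff = arch.epi_effects[source]
        for (j, k), e in zip(pairs, eff):
            cj, ck = col[int(j)], col[int(k)]
            left = X[:, cj] if source[0] == "a" else D[:, cj]
            right = X[:, ck] if source[1] == "a" else D[:, ck]
            g = g + e * left * right
    return g


def calibrate_residual_variance(genotypic_values: np.ndarray, h2: float) -> float:
    """Residual variance reproducing broad-sense heritability ``h2``.

    Uses the empirical variance of the genotypic values of the phenotyped
    individuals (epistatic part included when simulated), so the realized
    H^2 matches the configured value replicate by replicate.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("broad-sense heritability must be in (0, 1)")
    var_g = float(np.var(genotypic_values, ddof=1))
    if var_g <= 0.0:
        raise ValueError("genotypic values are constant: trait is monomorphic")
    return var_g * (1.0 - h2) / h2


def simulate_phenotypes(genotypic_values, sigma_e2, rng):
    if sigma_e2 <= 0:
        raise ValueError("residual variance must be positive")
    g = np.asarray(genotypic_values, dtype=float)
    return g + rng.normal(0.0, np.sqrt(sigma_e2), size=g.shape)


# ---------------------------------------------------------------------------
# Translation between the F-infinity and the orthogonal, standardized scale
# ---------------------------------------------------------------------------

def translate_single_locus(mu, a_j, d_j, genotype_freqs, *, standardize=True):
    """Translate (mu, a, d) into orthogonal effects (g_a, g_d) at one locus.

    Applies ``S_A^{-1} S`` to the F-infinity effect vector; when
    ``standardize`` is true the returned effects are multiplied by the
    frequency-weighted standard deviation of the corresponding orthogonal
    column, matching columns that were divided by that factor.
    """
    p11, p12, p22 = genotype_freqs
    SA = noia_matrix(p11, p12, p22)
    w = np.linalg.solve(SA, S_FINF @ np.array([mu, a_j, d_j], dtype=float))
    if standardize:
        freqs = np.array([p11, p12, p22])
        sd_a = np.sqrt(freqs @ SA[:, 1] ** 2)
        sd_d = np.sqrt(freqs @ SA[:, 2] ** 2)
        return w[1] * sd_a, w[2] * sd_d
    return w[1], w[2]


def translate_pairwise(alpha_jk, freqs_j, freqs_k):
    """Kronecker change of basis for one locus pair.

    ``alpha_jk`` is the 9-vector (mu, a_j, d_j, a_k, aa, da, d_k, ad, dd) on
    the F-infinity scale; the result is the corresponding 9-vector on the
    (unstandardized) orthogonal scale, obtained from
    ``(S_A,k^{-1} (x) S_A,j^{-1}) (S (x) S) alpha``.
    """
    alpha = np.asarray(alpha_jk, dtype=float)
    if alpha.shape != (9,):
        raise ValueError("expected a 9-vector of pair effects")
    SAj = noia_matrix(*freqs_j)
    SAk = noia_matrix(*freqs_k)
    table = np.kron(S_FINF, S_FINF) @ alpha  # 9 genotypic values, k-major
    return np.linalg.solve(np.kron(SAk, SAj), table)


@dataclass
class OrthogonalTruth:
    """True effects on the orthogonal, standardized scale.

    ``g_a``/``g_d`` are dense vectors over the panel (nonzero only at QTL),
    marginal with respect to any simulated interactions; ``epi`` maps each
    source to (pairs, standardized effects).  ``components`` are the true
    per-source variance components under linkage equilibrium (sums of
    squared standardized effects).
    """

    g_a: np.ndarray
    g_d: np.ndarray
    epi_pairs: dict[str, np.ndarray]
    epi_effects: dict[str, np.ndarray]

    @property
    def components(self) -> dict[str, float]:
        out = {"a": float(self.g_a @ self.g_a), "d": float(self.g_d @ self.g_d)}
        for s in EPISTASIS_SOURCES:
            e = self.epi_effects.get(s)
            out[s] = float(e @ e) if e is not None and len(e) else 0.0
        return out

    @property
    def total_genetic_variance(self) -> float:
        return float(sum(self.components.values()))

    @property
    def additive_ratio(self) -> float:
        return self.components["a"] / self.total_genetic_variance


def marginal_main_effects(arch: TraitArchitecture,
                          coding: OrthogonalCoding) -> OrthogonalTruth:
    """True standardized orthogonal effects, marginalized over interactions.

    The main-effect truth at locus j is its single-locus translation plus,
    for every pair the locus participates in, the (g_a,j, g_d,j) components
    of the pairwise transform evaluated with all main effects zeroed.  The
    coding supplies the genotype frequencies and standardization factors
    (normally estimated from the training individuals).
    """
    m = coding.n_markers
    g_a = np.zeros(m)
    g_d = np.zeros(m)

    # loci whose orthogonal basis is undefined (monomorphic under the coding
    # frequencies) carry no representable variation: skip their translation,
    # their standardized truth is zero anyway
    usable = {int(q) for q in arch.qtl if coding.v[int(q)] > 1e-12}
    freqs = {q: (coding.p11[q], coding.p12[q], coding.p22[q]) for q in usable}

    for q, a_j, d_j in zip(arch.qtl, arch.a, arch.d):
        q = int(q)
        if q not in usable:
            continue
        ga, gd = translate_single_locus(0.0, a_j, d_j, freqs[q], standardize=False)
        g_a[q] += ga
        g_d[q] += gd

    # Collect the F-infinity epistatic effects per pair (a pair may carry
    # effects from several simulated sources), then transform each pair once.
    # The transform of a single-source effect generally spreads over all four
    # orthogonal epistatic components as well as the main effects of both loci.
    pair_alpha: dict[tuple[int, int], np.ndarray] = {}
    for source in EPISTASIS_SOURCES:
        pairs = arch.epi_pairs.get(source)
        if pairs is None or len(pairs) == 0:
            continue
        for (j, k), e in zip(pairs, arch.epi_effects[source]):
            alpha = pair_alpha.setdefault((int(j), int(k)), np.zeros(9))
            alpha[_PAIR_SLOT[source]] += e

    accum: dict[str, dict[tuple[int, int], float]] = {s: {} for s in EPISTASIS_SOURCES}
    for (j, k), alpha in sorted(pair_alpha.items()):
        if j not in usable or k not in usable:
            continue
        star = translate_pairwise(alpha, freqs[j], freqs[k])
        # marginal main-effect contributions of this interaction
        g_a[j] += star[1]
        g_d[j] += star[2]
        g_a[k] += star[3]
        g_d[k] += star[6]
        for source, slot in _PAIR_SLOT.items():
            sd_j = coding.sd_a[j] if source[0] == "a" else coding.sd_d[j]
            sd_k = coding.sd_a[k] if source[1] == "a" else coding.sd_d[k]
            accum[source][(j, k)] = star[slot] * sd_j * sd_k

    epi_pairs_out: dict[str, np.ndarray] = {}
    epi_eff_out: dict[str, np.ndarray] = {}
    for source, entries in accum.items():
        if not entries:
            continue
        keys = sorted(entries)
        epi_pairs_out[source] = np.asarray(keys, dtype=np.int64)
        epi_eff_out[source] = np.array([entries[key] for key in keys])

    g_a *= coding.sd_a
    g_d *= coding.sd_d
    return OrthogonalTruth(g_a, g_d, epi_pairs_out, epi_eff_out)
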