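"""Genotype coding for genome-wide regression on marker effects.

Two parameterizations of single-locus genotypic values are used throughout:

* the F-infinity coding, where the additive covariate is -1/0/+1 for the
  rare homozygote / heterozygote / frequent homozygote and the dominance
  covariate is the heterozygote indicator, and
* the orthogonal (NOIA "statistical") coding of Alvarez-Castro & Carlborg,
  built from the observed genotype-class frequencies, which makes the
  additive and dominance covariates uncorrelated at every locus without
  assuming Hardy-Weinberg proportions.

Genotype classes are labelled 11/12/22 with class 22 the homozygote of the
more frequent allele, so the positive additive coefficient is attached to
the frequent allele.  Orthogonal columns are additionally divided by their
own frequency-weighted standard deviation so every active column has unit
variance under the frequencies used to build the coding.

Pairwise epistatic covariates (sources aa, ad, da, dd) are element-wise
products of the standardized main-effect columns and are never materialized
genome-wide: :func:`interaction_column` builds one column on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "S_FINF",
    "EPISTASIS_SOURCES",
    "OrthogonalCoding",
    "DesignBlocks",
    "finf_design",
    "orthogonal_coding",
    "noia_matrix",
    "build_design",
    "interaction_column",
    "model_design",
    "n_pairs",
    "pair_index",
    "pair_indices",
]

#: F-infinity basis: rows are genotype classes (11, 12, 22), columns are the
#: coefficients of (mu, a, d).
S_FINF = np.array([[1.0, -1.0, 0.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])

#: Order in which epistatic sources are processed.
EPISTASIS_SOURCES = ("aa", "ad", "da", "dd")

#: For each source, which main-effect block provides the first (locus j) and
#: second (locus k) factor of the product column.
SOURCE_FACTORS = {"aa": ("a", "a"), "ad": ("a", "d"), "da": ("d", "a"), "dd": ("d", "d")}

_SD_TOL = 1e-12


@dataclass
class OrthogonalCoding:
    """Per-marker orthogonal coding coefficients and standardization factors.

    ``coeff_a[j]``/``coeff_d[j]`` hold the three coefficients (one per
    genotype class 11/12/22) of the additive and dominance column of marker
    ``j`` before standardization.  ``sd_a``/``sd_d`` are the frequency-
    weighted standard deviations of those columns; active columns are later
    divided by them.  Markers whose column is constant under the coding
    frequencies (e.g. monomorphic in training) are flagged inert instead of
    dropped, so marker indices stay stable, and their effects are pinned to
    zero by the estimator.
    """

    p11: np.ndarray
    p12: np.ndarray
    p22: np.ndarray
    v: np.ndarray
    coeff_a: np.ndarray  # (m, 3)
    coeff_d: np.ndarray  # (m, 3)
    sd_a: np.ndarray
    sd_d: np.ndarray
    active_a: np.ndarray  # bool
    active_d: np.ndarray  # bool

    @property
    def n_markers(self) -> int:
        return self.p11.shape[0]

    def subset(self, idx: np.ndarray) -> "OrthogonalCoding":
        return OrthogonalCoding(
            self.p11[idx], self.p12[idx], self.p22[idx], self.v[idx],
            self.coeff_a[idx], self.coeff_d[idx], self.sd_a[idx], self.sd_d[idx],
            self.active_a[idx], self.active_d[idx],
        )


def orthogonal_coding(p11, p12, p22) -> OrthogonalCoding:
    """Build the orthogonal coding from genotype-class frequencies.

    Accepts scalars or arrays (one entry per marker).  The additive
    coefficients for classes (11, 12, 22) are the centered counts of the
    frequent allele, ``(0, 1, 2) - (p12 + 2 p22)``; the dominance
    coefficients are ``(-2 p12 p22, 4 p11 p22, -2 p11 p12) / v`` with
    ``v = p11 + p22 - (p11 - p22)**2``.  Both columns have zero
    frequency-weighted mean and zero frequency-weighted cross-moment for
    arbitrary (non-HWE) frequencies.
    """
    p11 = np.atleast_1d(np.asarray(p11, dtype=float))
    p12 = np.atleast_1d(np.asarray(p12, dtype=float))
    p22 = np.atleast_1d(np.asarray(p22, dtype=float))
    tot = p11 + p12 + p22
    if not np.allclose(tot, 1.0, atol=1e-8):
        raise ValueError("genotype-class frequencies must sum to 1 per marker")

    mean_count = p12 + 2.0 * p22
    coeff_a = np.stack([-mean_count, 1.0 - mean_count, 2.0 - mean_count], axis=1)

    v = p11 + p22 - (p11 - p22) ** 2
    ok_v = v > _SD_TOL
    v_safe = np.where(ok_v, v, 1.0)
    coeff_d = np.stack(
        [-2.0 * p12 * p22, 4.0 * p11 * p22, -2.0 * p11 * p12], axis=1
    ) / v_safe[:, None]
    coeff_d[~ok_v] = 0.0

    freqs = np.stack([p11, p12, p22], axis=1)
    sd_a = np.sqrt(np.sum(freqs * coeff_a**2, axis=1))
    sd_d = np.sqrt(np.sum(freqs * coeff_d**2, axis=1))
    active_a = sd_a > _SD_TOL
    active_d = (sd_d > _SD_TOL) & ok_v
    # inert columns carry zero coefficients so the coded column is exactly 0
    coeff_a[~active_a] = 0.0
    coeff_d[~active_d] = 0.0
    return OrthogonalCoding(p11, p12, p22, v, coeff_a, coeff_d,
                            sd_a, sd_d, active_a, active_d)


def noia_matrix(p11: float, p12: float, p22: float) -> np.ndarray:
    """3x3 orthogonal basis S_A for one marker (rows: classes 11/12/22).

    Requires ``v > 0`` (the dominance denominator), which holds whenever at
    least two genotype classes have positive frequency.
    """
    v = p11 + p22 - (p11 - p22) ** 2
    if v <= _SD_TOL:
        raise ValueError("degenerate genotype frequencies: orthogonal basis undefined")
    mean_count = p12 + 2.0 * p22
    coeff_a = np.arange(3.0) - mean_count
    coeff_d = np.array([-2.0 * p12 * p22, 4.0 * p11 * p22, -2.0 * p11 * p12]) / v
    return np.column_stack([np.ones(3), coeff_a, coeff_d])


def finf_design(class_genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """F-infinity design matrices from frequent-allele counts (0/1/2).

    Returns ``(X, D)`` with ``X`` in {-1, 0, 1} (positive for the frequent
    homozygote) and ``D`` the heterozygote indicator.
    """
    g = np.asarray(class_genotypes)
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotypes must be coded 0/1/2")
    X = g.astype(np.float64) - 1.0
    D = (g == 1).astype(np.float64)
    return X, D


@dataclass
class DesignBlocks:
    """Standardized orthogonal main-effect covariates for a set of individuals.

    ``Xa``/``Xd`` are (individual x marker) matrices of the standardized
    orthogonal columns; interaction columns are built on demand so storage
    never scales with the square of the marker count.
    """

    Xa: np.ndarray
    Xd: np.ndarray
    coding: OrthogonalCoding

    @property
    def n_individuals(self) -> int:
        return self.Xa.shape[0]

    @property
    def n_markers(self) -> int:
        return self.Xa.shape[1]

    def interaction(self, source: str, j: int, k: int) -> np.ndarray:
        return interaction_column(self, source, j, k)


def build_design(class_genotypes: np.ndarray, coding: OrthogonalCoding) -> DesignBlocks:
    """Code genotypes (frequent-allele counts 0/1/2) with a fixed coding.

    The coding is typically derived from the training individuals and reused
    unchanged for validation individuals, so prediction never peeks at the
    validation genotype frequencies.
    """
    g = np.asarray(class_genotypes)
    if g.ndim != 2:
        raise ValueError("expected an (individuals x markers) genotype matrix")
    if g.shape[1] != coding.n_markers:
        raise ValueError(
            f"marker mismatch: {g.shape[1]} genotype columns vs "
            f"{coding.n_markers} coded markers"
        )
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotypes must be coded 0/1/2 (missing values not allowed)")
    rows = np.arange(coding.n_markers)
    sd_a = np.where(coding.active_a, coding.sd_a, 1.0)
    sd_d = np.where(coding.active_d, coding.sd_d, 1.0)
    Xa = coding.coeff_a[rows, g] / sd_a
    Xd = coding.coeff_d[rows, g] / sd_d
    return DesignBlocks(np.ascontiguousarray(Xa), np.ascontiguousarray(Xd), coding)


def interaction_column(blocks: DesignBlocks, source: str, j: int, k: int) -> np.ndarray:
    """Element-wise product column for the epistatic effect (source, j, k), j < k."""
    if source not in SOURCE_FACTORS:
        raise ValueError(f"unknown epistatic source {source!r}")
    if not j < k:
        raise ValueError(f"epistatic pairs require j < k, got ({j}, {k})")
    fj, fk = SOURCE_FACTORS[source]
    left = blocks.Xa[:, j] if fj == "a" else blocks.Xd[:, j]
    right = blocks.Xa[:, k] if fk == "a" else blocks.Xd[:, k]
    return left * right


def n_pairs(m: int) -> int:
    return m * (m - 1) // 2


def pair_index(j: int, k: int, m: int) -> int:
    """Position of pair (j, k), j < k, in row-major upper-triangle order."""
    if not 0 <= j < k < m:
        raise ValueError(f"invalid pair ({j}, {k}) for {m} markers")
    return j * (2 * m - j - 1) // 2 + (k - j - 1)


def pair_indices(m: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays (j, k) of all pairs in upper-triangle order."""
    j, k = np.triu_indices(m, k=1)
    return j, k


def model_design(m: int, model: str) -> dict[str, int]:
    """Ordered sources and effect counts for model M0, M1 or M2."""
    if model == "M0":
        return {"a": m}
    if model == "M1":
        return {"a": m, "d": m}
    if model == "M2":
        out = {"a": m, "d": m}
        for s in EPISTASIS_SOURCES:
            out[s] = n_pairs(m)
        return out
    raise ValueError(f"unknown model {model!r}; expected M0, M1 or M2")
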