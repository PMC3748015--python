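"""Fast Bayesian marker-effect estimation by iterated conditional expectation.

Each genetic effect carries the mixture prior L*(gamma, lambda): a point
mass at zero with probability 1 - gamma and a zero-mean Laplace distribution
with rate lambda otherwise.  Conditional on the phenotypes corrected for all
other effects, the posterior mean of a single effect has a closed form in
terms of the univariate least-squares summary (Y_j, sigma_j^2), the expected
values of upper/lower zero-truncated normals, and three mixture weights:

    T1 = exp(-lam Y) * P(N(Y-, s2) > 0)
    T2 = exp(+lam Y) * P(N(Y+, s2) < 0)
    T3 = 2 (1 - gamma) / (gamma lam) * exp(-lam^2 s2 / 2) * phi(Y; 0, s2)

with Y+- = Y +- lam * s2.  The estimator cycles over all effects source by
source (a, d, then aa/ad/da/dd pair sources in upper-triangle order),
setting each to its posterior mean given the running residual, updates the
residual variance once per outer iteration from the residual sum of
squares, and stops when the relative squared change of the concatenated
estimate vector falls below the threshold L.

All three mixture terms are evaluated in the log domain: exp(lam |Y|)
overflows double precision for moderately large standardized effects, which
routinely occur at the causal loci.  Pair-source sweeps stream the product
columns from the two parent main-effect columns, so peak storage never
scales with the square of the marker count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import log_ndtr, logsumexp

from .design import (
    EPISTASIS_SOURCES,
    SOURCE_FACTORS,
    DesignBlocks,
    model_design,
    n_pairs,
)

__all__ = [
    "PriorSpec",
    "FitResult",
    "derive_lambda",
    "truncated_normal_mean",
    "posterior_mean_effect",
    "effect_summary",
    "update_residual_variance",
    "ice_fit",
    "predict_dgv",
]

_LOG_2PI = math.log(2.0 * math.pi)
_INV_SQRT2 = 1.0 / math.sqrt(2.0)


def derive_lambda(gamma: float, m: int) -> float:
    """Laplace rate giving unit total prior variance for a source.

    Solves 1 = sum_j Var(g_j) = m * gamma * 2 / lambda^2, i.e.
    lambda = sqrt(2 * m * gamma).
    """
    if not 0.0 < gamma <= 1.0:
        raise ValueError("mixing probability gamma must be in (0, 1]")
    if m < 1:
        raise ValueError("effect count must be at least 1")
    return math.sqrt(2.0 * m * gamma)


@dataclass(frozen=True)
class PriorSpec:
    """Mixture prior for one source: P(g != 0) = gamma, Laplace rate lam."""

    gamma: float
    lam: float
    m: int

    @classmethod
    def from_unit_variance(cls, gamma: float, m: int) -> "PriorSpec":
        return cls(gamma=gamma, lam=derive_lambda(gamma, m), m=m)

    @property
    def effect_variance(self) -> float:
        return self.gamma * 2.0 / self.lam**2


# ---------------------------------------------------------------------------
# scalar kernels (numba) -- used inside the sweeps
# ---------------------------------------------------------------------------

@njit(cache=True)
def _nb_log_ndtr(x):
    if x > -37.0:
        return math.log(0.5 * math.erfc(-x * _INV_SQRT2))
    xsq = x * x
    return (-0.5 * xsq - math.log(-x) - 0.5 * _LOG_2PI
            + math.log1p(-1.0 / xsq + 3.0 / (xsq * xsq)))


@njit(cache=True)
def _nb_post_mean(Y, sig2, lam, gamma):
    sig = math.sqrt(sig2)
    Ym = Y - lam * sig2
    Yp = Y + lam * sig2
    lcdf_m = _nb_log_ndtr(Ym / sig)       # log P(N(Ym, s2) > 0)
    lcdf_p = _nb_log_ndtr(-Yp / sig)      # log P(N(Yp, s2) < 0)
    lT1 = -lam * Y + lcdf_m
    lT2 = lam * Y + lcdf_p
    if gamma >= 1.0:
        lT3 = -np.inf
    else:
        lT3 = (math.log(2.0 * (1.0 - gamma) / (gamma * lam))
               - 0.5 * lam * lam * sig2
               - 0.5 * (Y / sig) ** 2 - 0.5 * _LOG_2PI - math.log(sig))
    M = lT1 if lT1 > lT2 else lT2
    if lT3 > M:
        M = lT3
    w1 = math.exp(lT1 - M)
    w2 = math.exp(lT2 - M)
    w3 = math.exp(lT3 - M) if np.isfinite(lT3) else 0.0
    # E[Z | Z > 0], Z ~ N(Ym, s2) and E[Z | Z < 0], Z ~ N(Yp, s2)
    tm = Ym / sig
    tp = Yp / sig
    theta_u = Ym + sig * math.exp(-0.5 * tm * tm - 0.5 * _LOG_2PI - lcdf_m)
    theta_l = Yp - sig * math.exp(-0.5 * tp * tp - 0.5 * _LOG_2PI - lcdf_p)
    return (w1 * theta_u + w2 * theta_l) / (w1 + w2 + w3)


@njit(cache=True)
def _sweep_dense(Xt, xtx, g, r, lam, gamma, sigma_e2):
    m, n = Xt.shape
    for j in range(m):
        xx = xtx[j]
        if xx <= 1e-12:
            continue
        x = Xt[j]
        xy = 0.0
        for i in range(n):
            xy += x[i] * r[i]
        Y = (xy + xx * g[j]) / xx
        new = _nb_post_mean(Y, sigma_e2 / xx, lam, gamma)
        diff = new - g[j]
        if diff != 0.0:
            for i in range(n):
                r[i] -= x[i] * diff
        g[j] = new


@njit(cache=True)
def _sweep_pairs(At, Bt, g, r, lam, gamma, sigma_e2):
    m, n = At.shape
    idx = 0
    for j in range(m - 1):
        a = At[j]
        for k in range(j + 1, m):
            b = Bt[k]
            xx = 0.0
            xy = 0.0
            for i in range(n):
                c = a[i] * b[i]
                xx += c * c
                xy += c * r[i]
            if xx <= 1e-12:
                idx += 1
                continue
            Y = (xy + xx * g[idx]) / xx
            new = _nb_post_mean(Y, sigma_e2 / xx, lam, gamma)
            diff = new - g[idx]
            if diff != 0.0:
                for i in range(n):
                    r[i] -= a[i] * b[i] * diff
            g[idx] = new
            idx += 1


@njit(cache=True)
def _pair_values(At, Bt, g, out):
    m, n = At.shape
    idx = 0
    for j in range(m - 1):
        a = At[j]
        for k in range(j + 1, m):
            gi = g[idx]
            if gi != 0.0:
                b = Bt[k]
                for i in range(n):
                    out[i] += gi * a[i] * b[i]
            idx += 1


# ---------------------------------------------------------------------------
# public closed-form pieces (vectorized, scipy-based)
# ---------------------------------------------------------------------------

def truncated_normal_mean(mean, variance, side: str):
    """E[Z | Z > 0] or E[Z | Z < 0] for Z ~ N(mean, variance).

    Evaluated through log-domain Mills ratios so it stays accurate for
    |mean|/sd of 30 and beyond.
    """
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    if np.any(variance <= 0):
        raise ValueError("variance must be positive")
    sd = np.sqrt(variance)
    t = mean / sd
    log_phi = -0.5 * t**2 - 0.5 * _LOG_2PI
    if side == "above_zero":
        out = mean + sd * np.exp(log_phi - log_ndtr(t))
    elif side == "below_zero":
        out = mean - sd * np.exp(log_phi - log_ndtr(-t))
    else:
        raise ValueError("side must be 'above_zero' or 'below_zero'")
    return out if out.ndim else float(out)


def posterior_mean_effect(Y, sigma2, lam, gamma):
    """Closed-form posterior mean of one effect under the L* mixture prior.

    ``Y`` is the single-effect least-squares estimate of the corrected
    phenotypes on the effect's column and ``sigma2`` its sampling variance.
    Vectorized over all arguments.
    """
    Y, sigma2, lam, gamma = np.broadcast_arrays(
        np.asarray(Y, dtype=float), np.asarray(sigma2, dtype=float),
        np.asarray(lam, dtype=float), np.asarray(gamma, dtype=float))
    if np.any(sigma2 <= 0) or not np.all(np.isfinite(Y)):
        raise ValueError("need finite Y and positive sigma2")
    sd = np.sqrt(sigma2)
    Ym = Y - lam * sigma2
    Yp = Y + lam * sigma2
    lcdf_m = log_ndtr(Ym / sd)
    lcdf_p = log_ndtr(-Yp / sd)
    lT1 = -lam * Y + lcdf_m
    lT2 = lam * Y + lcdf_p
    with np.errstate(divide="ignore"):
        lT3 = np.where(
            gamma >= 1.0,
            -np.inf,
            np.log(2.0 * (1.0 - gamma) / (gamma * lam))
            - 0.5 * lam**2 * sigma2
            - 0.5 * (Y / sd) ** 2 - 0.5 * _LOG_2PI - np.log(sd),
        )
    lden = logsumexp(np.stack([lT1, lT2, lT3]), axis=0)
    theta_u = truncated_normal_mean(Ym, sigma2, "above_zero")
    theta_l = truncated_normal_mean(Yp, sigma2, "below_zero")
    out = np.exp(lT1 - lden) * theta_u + np.exp(lT2 - lden) * theta_l
    return out if out.ndim else float(out)


def effect_summary(residual, current_estimate, column):
    """Least-squares summary (Y_j, sigma_j^2 / sigma_e^2 scale factor).

    Realizes the corrected phenotypes as residual + column * estimate and
    returns (Y_j, 1 / X'X); the caller multiplies the second entry by the
    current residual variance to get sigma_j^2.
    """
    column = np.asarray(column, dtype=float)
    xtx = float(column @ column)
    if xtx <= 0:
        raise ValueError("inert column: X'X is zero")
    y_minus_j = np.asarray(residual, dtype=float) + column * current_estimate
    return float(column @ y_minus_j) / xtx, 1.0 / xtx


def update_residual_variance(y, fitted, n=None):
    """Residual sum of squares divided by (n - 1)."""
    resid = np.asarray(y, dtype=float) - np.asarray(fitted, dtype=float)
    if n is None:
        n = resid.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")
    return float(resid @ resid) / (n - 1)


# ---------------------------------------------------------------------------
# the ICE loop
# ---------------------------------------------------------------------------

DEFAULT_GAMMAS = {"a": 0.005, "d": 0.005, "epi": 1e-6}
DEFAULT_CONVERGENCE = {"M0": (1e-8, 1000), "M1": (1e-8, 1000), "M2": (1e-6, 200)}


@dataclass
class FitResult:
    """Outcome of one ICE fit."""

    estimates: dict[str, np.ndarray]
    sigma_e2: float
    n_iter: int
    converged: bool
    criterion_trace: list[float]
    sigma_e2_trace: list[float]
    y_mean: float
    model: str
    priors: dict[str, PriorSpec]
    covariate_coef: np.ndarray | None = None

    def variance_components(self) -> dict[str, float]:
        """Per-source variance components under linkage equilibrium."""
        return {s: float(g @ g) for s, g in self.estimates.items()}


def _source_gamma(source: str, gammas: dict[str, float]) -> float:
    if source in gammas:
        return gammas[source]
    if source in EPISTASIS_SOURCES:
        return gammas["epi"]
    raise KeyError(f"no mixing probability for source {source!r}")


def ice_fit(y, blocks: DesignBlocks, model: str = "M1", *,
            gammas: dict[str, float] | None = None,
            priors: dict[str, PriorSpec] | None = None,
            L: float | None = None, k_max: int | None = None,
            covariates: np.ndarray | None = None) -> FitResult:
    """Fit marker effects by iterated conditional expectation.

    Phenotypes are centered once up front; if ``covariates`` are given their
    ordinary least-squares effect on the running residual is removed at the
    start of every outer iteration (covariates are never shrunk).  Effects
    are processed source by source in the order a, d, aa, ad, da, dd and
    within a source in index (upper-triangle) order, Gauss-Seidel style: the
    running residual always reflects the latest estimates.  Non-convergence
    within ``k_max`` iterations is reported via the ``converged`` flag, not
    an error; a non-finite residual variance aborts with a diagnostic.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotypes must be finite")
    n = y.shape[0]
    m = blocks.n_markers
    counts = model_design(m, model)
    defaults_L, defaults_k = DEFAULT_CONVERGENCE[model]
    L = defaults_L if L is None else L
    k_max = defaults_k if k_max is None else k_max

    if priors is None:
        gam = dict(DEFAULT_GAMMAS)
        if gammas:
            gam.update(gammas)
        priors = {s: PriorSpec.from_unit_variance(_source_gamma(s, gam), ms)
                  for s, ms in counts.items()}

    y_mean = float(y.mean())
    y_work = y - y_mean

    C = None
    cov_coef = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        C = C - C.mean(axis=0)
        cov_coef = np.zeros(C.shape[1])

    Xa_t = np.ascontiguousarray(blocks.Xa.T)
    Xd_t = np.ascontiguousarray(blocks.Xd.T)
    xtx_a = np.einsum("ji,ji->j", Xa_t, Xa_t)
    xtx_d = np.einsum("ji,ji->j", Xd_t, Xd_t)
    block_t = {"a": Xa_t, "d": Xd_t}

    g = {s: np.zeros(ms) for s, ms in counts.items()}
    r = y_work.copy()
    sigma_e2 = float(np.var(y_work, ddof=1))
    if sigma_e2 <= 0:
        raise ValueError("phenotypes are constant")

    def fitted_values() -> np.ndarray:
        f = blocks.Xa @ g["a"]
        if "d" in g:
            f += blocks.Xd @ g["d"]
        for s in EPISTASIS_SOURCES:
            if s in g:
                fj, fk = SOURCE_FACTORS[s]
                _pair_values(block_t[fj], block_t[fk], g[s], f)
        return f

    g_prev = np.zeros(sum(counts.values()))
    crit_trace: list[float] = []
    sig_trace: list[float] = []
    converged = False
    k = 0
    for k in range(1, k_max + 1):
        if C is not None:
            beta, *_ = np.linalg.lstsq(C, r, rcond=None)
            r -= C @ beta
            y_work = y_work - C @ beta
            cov_coef += beta
        for s in counts:
            p = priors[s]
            if s == "a":
                _sweep_dense(Xa_t, xtx_a, g["a"], r, p.lam, p.gamma, sigma_e2)
            elif s == "d":
                _sweep_dense(Xd_t, xtx_d, g["d"], r, p.lam, p.gamma, sigma_e2)
            else:
                fj, fk = SOURCE_FACTORS[s]
                _sweep_pairs(block_t[fj], block_t[fk], g[s], r,
                             p.lam, p.gamma, sigma_e2)
        sigma_e2 = float(r @ r) / (n - 1)
        if not np.isfinite(sigma_e2) or sigma_e2 <= 0:
            raise FloatingPointError(
                f"residual variance diverged at iteration {k}: {sigma_e2!r}"
            )
        sig_trace.append(sigma_e2)

        g_cat = np.concatenate([g[s] for s in counts])
        num = float(np.sum((g_cat - g_prev) ** 2))
        den = float(g_cat @ g_cat)
        crit = num / den if den > 0 else (0.0 if num == 0.0 else np.inf)
        crit_trace.append(crit)
        g_prev = g_cat
        if crit <= L:
            converged = True
            break

        if k % 10 == 0:
            # guard against drift of the running residual
            r_exact = y_work - fitted_values()
            scale = max(float(np.linalg.norm(y_work)), 1.0)
            if np.linalg.norm(r - r_exact) > 1e-6 * scale:
                raise FloatingPointError("running residual lost accuracy")
            r = r_exact

    return FitResult(estimates=g, sigma_e2=sigma_e2, n_iter=k,
                     converged=converged, criterion_trace=crit_trace,
                     sigma_e2_trace=sig_trace, y_mean=y_mean, model=model,
                     priors=priors, covariate_coef=cov_coef)


def predict_dgv(blocks: DesignBlocks, estimates: dict[str, np.ndarray],
                *, pooled_epistasis: bool = False) -> dict[str, np.ndarray]:
    """Direct genetic values for a set of individuals.

    ``blocks`` must be coded and standardized with the training-population
    frequencies.  Returns per-source parts plus their sum under ``"total"``;
    with ``pooled_epistasis`` the four pair sources are collapsed into one
    ``"epi"`` part.
    """
    n = blocks.n_individuals
    parts: dict[str, np.ndarray] = {}
    for s, gs in estimates.items():
        if s == "a":
            if gs.shape[0] != blocks.n_markers:
                raise ValueError("marker mismatch between fit and target panel")
            parts["a"] = blocks.Xa @ gs
        elif s == "d":
            parts["d"] = blocks.Xd @ gs
        elif s in EPISTASIS_SOURCES:
            if gs.shape[0] != n_pairs(blocks.n_markers):
                raise ValueError("pair-count mismatch between fit and target panel")
            fj, fk = SOURCE_FACTORS[s]
            left = np.ascontiguousarray((blocks.Xa if fj == "a" else blocks.Xd).T)
            right = np.ascontiguousarray((blocks.Xa if fk == "a" else blocks.Xd).T)
            out = np.zeros(n)
            _pair_values(left, right, gs, out)
            parts[s] = out
        else:
            raise ValueError(f"unknown source {s!r}")
    total = np.zeros(n)
    for v in parts.values():
        total += v
    if pooled_epistasis:
        epi = np.zeros(n)
        for s in EPISTASIS_SOURCES:
            if s in parts:
                epi += parts.pop(s)
        parts["epi"] = epi
    parts["total"] = total
    return parts
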