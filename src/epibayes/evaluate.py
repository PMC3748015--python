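"""Accuracy and variance-component reporting for genetic value prediction.

Accuracy is the empirical Pearson correlation between predicted and
simulated direct genetic values (DGV) in a validation set.  Variance
components come in two flavours: the linkage-equilibrium approximation
(sum of squared standardized effect estimates per source, exact only when
marker covariates are uncorrelated) and empirical variances of the
per-source predicted genetic values in the validation set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import EPISTASIS_SOURCES

__all__ = [
    "EvaluationReport",
    "accuracy",
    "variance_components_le",
    "empirical_variance_components",
    "additive_ratio",
    "top_fraction_accuracy",
]


def accuracy(predicted_dgv, true_dgv) -> float:
    """Pearson correlation of predicted and simulated DGV.

    Returns NaN if either vector is (numerically) constant or shorter than
    three individuals, mirroring how undefined correlations are reported.
    """
    p = np.asarray(predicted_dgv, dtype=float)
    t = np.asarray(true_dgv, dtype=float)
    if p.shape != t.shape:
        raise ValueError("prediction and truth must have equal length")
    if p.size < 3 or np.std(p) == 0 or np.std(t) == 0:
        return float("nan")
    return float(np.corrcoef(p, t)[0, 1])


def variance_components_le(estimates: dict[str, np.ndarray]) -> dict[str, float]:
    """Per-source sum of squared estimates (LE approximation)."""
    return {s: float(np.asarray(g) @ np.asarray(g)) for s, g in estimates.items()}


def empirical_variance_components(per_source_values: dict[str, np.ndarray],
                                  pooled_epistasis: bool = True) -> dict[str, float]:
    """Empirical variances of per-source predicted values in a validation set.

    With ``pooled_epistasis`` the four pair sources are summed into one
    epistatic value per individual before taking the variance.
    """
    values = {s: np.asarray(v, dtype=float) for s, v in per_source_values.items()
              if s != "total"}
    for v in values.values():
        if v.size < 2:
            raise ValueError("variance undefined for fewer than two individuals")
    if pooled_epistasis:
        epi_parts = [values.pop(s) for s in EPISTASIS_SOURCES if s in values]
        if epi_parts:
            values["epi"] = np.sum(epi_parts, axis=0)
    return {s: float(np.var(v, ddof=1)) for s, v in values.items()}


def additive_ratio(components: dict[str, float]) -> float:
    """Share of additive variance in the total genetic variance.

    Only genetic sources enter the total (any residual entry is ignored).
    """
    total = sum(v for s, v in components.items() if s != "e")
    if total <= 0:
        raise ValueError("total genetic variance is zero")
    return components["a"] / total


def top_fraction_accuracy(predicted_additive, true_additive,
                          fraction: float = 0.1) -> float:
    """Accuracy among the animals with the best predicted breeding values.

    Selects ceil(fraction * n) individuals by predicted additive genetic
    value and returns the correlation of predicted and true additive values
    within the selection; NaN when the selection is smaller than three.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    p = np.asarray(predicted_additive, dtype=float)
    t = np.asarray(true_additive, dtype=float)
    n_sel = int(np.ceil(fraction * p.size))
    if n_sel < 3:
        return float("nan")
    sel = np.argsort(p)[::-1][:n_sel]
    return accuracy(p[sel], t[sel])


@dataclass
class EvaluationReport:
    """Per-replicate, per-model evaluation summary."""

    scenario: str
    model: str
    replicate: int
    seed: int
    accuracy: float
    top10_accuracy: float
    components_le: dict[str, float]
    components_empirical: dict[str, float]
    true_components: dict[str, float]
    sigma_e2_hat: float
    sigma_e2_true: float
    h2_realized: float
    converged: bool
    n_iter: int

    def to_row(self) -> dict:
        row = {
            "scenario": self.scenario,
            "model": self.model,
            "replicate": self.replicate,
            "seed": self.seed,
            "accuracy": self.accuracy,
            "top10_accuracy": self.top10_accuracy,
            "sigma_e2_hat": self.sigma_e2_hat,
            "sigma_e2_true": self.sigma_e2_true,
            "h2_realized": self.h2_realized,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        for s, v in self.components_le.items():
            row[f"var_{s}_le"] = v
        for s, v in self.components_empirical.items():
            row[f"var_{s}_emp"] = v
        for s, v in self.true_components.items():
            row[f"var_{s}_true"] = v
        try:
            row["additive_ratio_hat"] = additive_ratio(self.components_le)
        except (ValueError, KeyError):
            row["additive_ratio_hat"] = float("nan")
        try:
            row["additive_ratio_true"] = additive_ratio(self.true_components)
        except (ValueError, KeyError):
            row["additive_ratio_true"] = float("nan")
        return row
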