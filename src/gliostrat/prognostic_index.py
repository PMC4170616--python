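"""The beta-weighted DNA-repair prognostic index (PI) and year-survival curves.

The PI for a patient is Σ over model genes of indicator(high expression at the
gene's cutpoint) × β, where β is the log hazard ratio from the final
multivariate Cox model. Per-cohort indices use that cohort's β; the combined
index averages the two cohorts' β per gene. Patients are stratified into k
prognostic groups on the score, and percent survival at a horizon (1/2/3
years) is interpolated against median group score with an exact quadratic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .survival_core import KMCurve, LogRankResult, SurvivalData, km_estimate, logrank_test

__all__ = [
    "PIGene",
    "PIModel",
    "RiskGroups",
    "SurvivalCurveFit",
    "combine_betas",
    "compute_pi",
    "assign_risk_groups",
    "fit_year_survival_curve",
    "predict_survival",
]


@dataclass(frozen=True)
class PIGene:
    gene: str
    probe_id: str
    cutpoint: float
    direction: str
    beta_test: float
    beta_validation: float

    @property
    def beta_combined(self) -> float:
        return combine_betas(self.beta_test, self.beta_validation)


@dataclass(frozen=True)
class PIModel:
    """Per-gene cutpoints and β coefficients defining the prognostic index."""

    genes: tuple[PIGene, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if not self.genes:
            raise ValueError("PI model needs at least one gene")
        if any(not np.isfinite(g.beta_combined) for g in self.genes):
            raise ValueError("combined beta must be finite")

    @property
    def score_bounds(self) -> tuple[float, float]:
        """Attainable PI range: sum of negative / positive combined betas."""
        betas = np.array([g.beta_combined for g in self.genes])
        return float(betas[betas < 0].sum()), float(betas[betas > 0].sum())

    def to_json(self, path) -> None:
        payload = [
            {
                "gene": g.gene,
                "probe_id": g.probe_id,
                "cutpoint": g.cutpoint,
                "direction": g.direction,
                "beta_test": g.beta_test,
                "beta_validation": g.beta_validation,
                "beta_combined": g.beta_combined,
            }
            for g in self.genes
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PIModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            genes=tuple(
                PIGene(
                    gene=g["gene"],
                    probe_id=g["probe_id"],
                    cutpoint=g["cutpoint"],
                    direction=g["direction"],
                    beta_test=g["beta_test"],
                    beta_validation=g["beta_validation"],
                )
                for g in payload
            )
        )


def combine_betas(beta_test: float, beta_validation: float) -> float:
    """Combined coefficient: arithmetic mean of the two cohorts' ln(HR)."""
    if not (np.isfinite(beta_test) and np.isfinite(beta_validation)):
        raise ValueError("both betas must be finite")
    return (beta_test + beta_validation) / 2.0


def compute_pi(model: PIModel, patient_expression: Mapping[str, float]) -> float:
    """PI score = Σ indicator(expression > cutpoint) × combined β."""
    score = 0.0
    for g in model.genes:
        if g.probe_id not in patient_expression:
            raise KeyError(f"missing expression for gene {g.gene} (probe {g.probe_id})")
        high = float(patient_expression[g.probe_id]) > g.cutpoint
        score += g.beta_combined * float(high)
    return score


@dataclass(frozen=True)
class RiskGroups:
    """Patients binned into k prognostic groups on the PI score."""

    scores: np.ndarray
    labels: np.ndarray  # group per patient, 1..k, ascending median score
    boundaries: np.ndarray  # k-1 interior quantile boundaries
    km_curves: tuple[KMCurve, ...]
    median_scores: np.ndarray
    extreme_logrank: LogRankResult | None

    @property
    def k(self) -> int:
        return len(self.km_curves)


def assign_risk_groups(
    scores: Sequence[float],
    data: SurvivalData,
    k: int = 3,
) -> RiskGroups:
    """Quantile-bin patients into k prognostic groups (ties kept together).

    Groups are labeled 1..k by ascending median score; per-group KM curves
    and the log-rank test between the two extreme groups are attached.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != len(data):
        raise ValueError("scores and survival lengths differ")
    if np.unique(scores).size < k:
        raise ValueError(f"need at least {k} distinct scores to form {k} groups")
    boundaries = np.quantile(scores, np.arange(1, k) / k)
    labels = np.searchsorted(boundaries, scores, side="left") + 1
    # quantile boundaries can collide on heavily tied scores; relabel compactly
    present = np.unique(labels)
    relabel = {old: i + 1 for i, old in enumerate(present)}
    labels = np.array([relabel[v] for v in labels])
    if len(present) < k:
        raise ValueError("tied scores collapse the requested number of groups")

    curves, medians = [], []
    for g in range(1, k + 1):
        mask = labels == g
        curves.append(km_estimate(SurvivalData(data.time[mask], data.event[mask])))
        medians.append(float(np.median(scores[mask])))

    extreme = None
    mask = (labels == 1) | (labels == k)
    sub = SurvivalData(data.time[mask], data.event[mask], group=labels[mask])
    if sub.n_events > 0:
        extreme = logrank_test(sub)

    return RiskGroups(
        scores=scores,
        labels=labels,
        boundaries=boundaries,
        km_curves=tuple(curves),
        median_scores=np.asarray(medians),
        extreme_logrank=extreme,
    )


@dataclass(frozen=True)
class SurvivalCurveFit:
    """Exact quadratic through the three (median PI, percent survival) anchors."""

    horizon_days: float
    coefficients: tuple[float, float, float]  # a, b, c of a·x² + b·x + c
    anchors: tuple[tuple[float, float], ...]

    def __call__(self, score: float) -> float:
        a, b, c = self.coefficients
        return a * score**2 + b * score + c


def fit_year_survival_curve(
    groups: RiskGroups, horizon_days: float
) -> SurvivalCurveFit:
    """Interpolating quadratic: percent survival at horizon vs median group PI."""
    if groups.k != 3:
        raise ValueError("year-survival curve requires exactly 3 prognostic groups")
    x = groups.median_scores
    if np.unique(x).size != 3:
        raise ValueError("group median scores must be distinct")
    y = np.array([100.0 * c.survival_at(horizon_days) for c in groups.km_curves])
    vander = np.vander(x, 3)  # columns x², x, 1
    a, b, c = np.linalg.solve(vander, y)
    return SurvivalCurveFit(
        horizon_days=float(horizon_days),
        coefficients=(float(a), float(b), float(c)),
        anchors=tuple((float(xi), float(yi)) for xi, yi in zip(x, y)),
    )


def predict_survival(fit: SurvivalCurveFit, score: float) -> tuple[float, bool]:
    """Percent survival at the fit's horizon, clamped to [0, 100].

    Returns ``(percent, extrapolated)``; ``extrapolated`` is True when the
    score lies outside the anchor range or the raw value needed clamping.
    """
    raw = fit(score)
    xs = [a[0] for a in fit.anchors]
    outside = score < min(xs) or score > max(xs)
    clamped = float(np.clip(raw, 0.0, 100.0))
    return clamped, bool(outside or clamped != raw)
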