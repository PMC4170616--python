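"""Optimal-cutpoint survival screening and cross-cohort Cox model reduction.

Stage 1–2 of the pipeline: each probe is dichotomized at the expression value
maximizing the two-group log-rank statistic (an X-tile-style minimum-p scan over
the 10th–90th percentile band), the panel is screened with Benjamini–Hochberg
control, probes prognostic in both cohorts with a concordant worse-survival
direction form the consensus set, and an iterative multivariate Cox reduction
yields the final cross-dataset model.

Because the scan picks the best of many correlated log-rank tests, the minimum
p-value is anti-conservative; the Miller–Siegmund correction for a selected
minimum p is applied before the BH step so the panel-wide error rate is
controlled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionDataset, GenePanel
from .survival_core import CoxFit, SurvivalData, adjust_pvalues, cox_fit

logger = logging.getLogger("gliostrat")

__all__ = [
    "CutpointResult",
    "ScreenResult",
    "EliminationResult",
    "optimal_cutpoint",
    "logrank_scan",
    "miller_siegmund",
    "screen_probes",
    "consensus_probes",
    "dichotomize",
    "backward_eliminate",
]


@dataclass(frozen=True)
class CutpointResult:
    """Best split for one probe: value, worse-survival side, log-rank statistic."""

    probe_id: str
    cutpoint: float
    direction: str  # level associated with worse survival: "low" | "high"
    chi_square: float
    p_value: float  # uncorrected log-rank p at the selected split
    p_corrected: float  # Miller–Siegmund selected-minimum-p correction


@dataclass(frozen=True)
class ScreenResult:
    """Panel-wide screen for one cohort; ``table`` has one row per probe."""

    table: pd.DataFrame
    alpha: float = 0.05
    failures: dict = field(default_factory=dict)

    @property
    def significant_probes(self) -> list[str]:
        mask = self.table["p_adjusted"] <= self.alpha
        return list(self.table.loc[mask, "probe_id"])

    def cutpoints(self) -> dict[str, float]:
        return dict(zip(self.table["probe_id"], self.table["cutpoint"]))

    def directions(self) -> dict[str, str]:
        return dict(zip(self.table["probe_id"], self.table["direction"]))


def logrank_scan(
    expression: np.ndarray,
    data: SurvivalData,
    quantile_bounds: tuple[float, float] = (0.1, 0.9),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-group log-rank chi-square for every candidate split of one probe.

    Candidates are the unique expression values inside the quantile band;
    the split is ``x > c`` (high) vs ``x <= c`` (low). Returns
    ``(candidates, chi_square, observed_minus_expected_high)`` with one
    entry per candidate that leaves both groups nonempty.
    """
    x = np.asarray(expression, dtype=float)
    n = x.shape[0]
    if n != len(data):
        raise ValueError("expression and survival lengths differ")
    lo, hi = np.quantile(x, quantile_bounds)
    candidates = np.unique(x[(x >= lo) & (x <= hi)])
    candidates = candidates[candidates < x.max()]  # both sides nonempty
    if candidates.size == 0:
        raise ValueError("no valid split leaves both groups nonempty")

    order = np.argsort(data.time, kind="stable")
    t = data.time[order]
    e = data.event[order].astype(float)
    high = (x[order][:, None] > candidates[None, :]).astype(float)  # n × S

    _, first_idx = np.unique(t, return_index=True)
    n_at = n - first_idx  # at risk per distinct time
    suffix = np.cumsum(high[::-1], axis=0)[::-1]
    n1_at = suffix[first_idx]  # J × S, at risk in high group
    d_total = np.add.reduceat(e, first_idx)  # J
    d1 = np.add.reduceat(e[:, None] * high, first_idx, axis=0)  # J × S

    keep = d_total > 0
    d = d_total[keep]
    nn = n_at[keep].astype(float)
    n1 = n1_at[keep]
    d1 = d1[keep]

    frac = n1 / nn[:, None]
    O = d1.sum(axis=0)
    E = (d[:, None] * frac).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vterm = d[:, None] * frac * (1.0 - frac) * ((nn - d) / np.maximum(nn - 1.0, 1.0))[:, None]
    V = vterm.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = np.where(V > 0, (O - E) ** 2 / V, 0.0)
    return candidates, chi, O - E


def miller_siegmund(
    p_min: float, quantile_bounds: tuple[float, float] = (0.1, 0.9)
) -> float:
    """Correct a minimum p-value selected by scanning cutpoints over a band.

    Asymptotic formula for the supremum of the squared standardized log-rank
    process over the band (eps_low, eps_high); conservative for moderate n.
    """
    eps_lo, eps_hi = quantile_bounds
    p_min = min(max(p_min, 1e-300), 1.0)
    z = stats.norm.isf(p_min / 2.0)
    if z <= 1e-8:
        return 1.0
    phi = stats.norm.pdf(z)
    span = np.log((eps_hi * (1.0 - eps_lo)) / ((1.0 - eps_hi) * eps_lo))
    corrected = phi * (z - 1.0 / z) * span + 4.0 * phi / z
    return float(np.clip(corrected, p_min, 1.0))


def optimal_cutpoint(
    expression: np.ndarray,
    data: SurvivalData,
    quantile_bounds: tuple[float, float] = (0.1, 0.9),
    probe_id: str = "",
) -> CutpointResult:
    """X-tile-style optimal dichotomization of one probe against survival.

    Exhaustively scans every unique expression value inside the quantile
    band, maximizes the two-group log-rank chi-square, and reports the
    level (low/high) with worse survival. Ties among equally maximal
    splits break toward the split closest to the cohort median.
    """
    x = np.asarray(expression, dtype=float)
    if x.shape[0] < 10:
        raise ValueError("optimal_cutpoint needs at least 10 samples")
    if np.all(x == x[0]):
        raise ValueError(f"expression is constant for probe {probe_id!r}")
    candidates, chi, ome_high = logrank_scan(x, data, quantile_bounds)

    best = chi.max()
    ties = np.flatnonzero(np.isclose(chi, best, rtol=1e-12, atol=0.0))
    med = np.median(x)
    pick = ties[np.argmin(np.abs(candidates[ties] - med))]

    p_raw = float(stats.chi2.sf(chi[pick], 1))
    return CutpointResult(
        probe_id=probe_id,
        cutpoint=float(candidates[pick]),
        direction="high" if ome_high[pick] > 0 else "low",
        chi_square=float(chi[pick]),
        p_value=p_raw,
        p_corrected=miller_siegmund(p_raw, quantile_bounds),
    )


def screen_probes(
    dataset: ExpressionDataset,
    data: SurvivalData,
    panel: GenePanel | None = None,
    quantile_bounds: tuple[float, float] = (0.1, 0.9),
    alpha: float = 0.05,
) -> ScreenResult:
    """Per-probe optimal cutpoint + BH adjustment across the panel.

    BH is applied to the Miller–Siegmund corrected minimum p so the scan's
    selection optimism does not leak into the FDR control. Probes whose
    scan fails (constant expression, no valid split) are skipped with a
    warning and recorded in ``failures``.
    """
    probes = panel.probe_ids if panel is not None else list(dataset.probe_ids)
    probes = [p for p in probes if p in set(dataset.probe_ids)]
    gene_of = (lambda p: panel.gene_of(p)) if panel is not None else (lambda p: p)

    rows, failures = [], {}
    for probe in probes:
        try:
            res = optimal_cutpoint(
                dataset.probe_values(probe), data, quantile_bounds, probe_id=probe
            )
        except ValueError as exc:
            logger.warning("skipping probe %s: %s", probe, exc)
            failures[probe] = str(exc)
            continue
        rows.append(
            {
                "probe_id": probe,
                "gene": gene_of(probe),
                "cutpoint": res.cutpoint,
                "direction": res.direction,
                "chi_square": res.chi_square,
                "p_value": res.p_value,
                "p_corrected": res.p_corrected,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "probe_id",
            "gene",
            "cutpoint",
            "direction",
            "chi_square",
            "p_value",
            "p_corrected",
        ],
    )
    table["p_adjusted"] = (
        adjust_pvalues(table["p_corrected"], "BH") if len(table) else []
    )
    return ScreenResult(table=table, alpha=alpha, failures=failures)


def consensus_probes(screen_a: ScreenResult, screen_b: ScreenResult) -> list[str]:
    """Probes significant in both cohorts with the same worse-survival level."""
    sig_a, sig_b = set(screen_a.significant_probes), set(screen_b.significant_probes)
    dir_a, dir_b = screen_a.directions(), screen_b.directions()
    return [p for p in screen_a.table["probe_id"] if p in sig_a and p in sig_b and dir_a[p] == dir_b[p]]


def dichotomize(
    dataset: ExpressionDataset, cutpoints: Mapping[str, float]
) -> pd.DataFrame:
    """0/1 high-expression indicators (samples × probes) at the given cutpoints."""
    cols = {}
    for probe, cut in cutpoints.items():
        cols[probe] = (dataset.probe_values(probe) > cut).astype(float)
    return pd.DataFrame(cols, index=dataset.sample_ids)


@dataclass(frozen=True)
class EliminationResult:
    final_probes: list[str]
    fits: list[CoxFit | None]
    empty: bool
    history: list[list[str]]

    def betas(self) -> pd.DataFrame:
        """Per-cohort log hazard ratios for the final probe set."""
        data = {}
        for i, fit in enumerate(self.fits):
            if fit is None:
                continue
            data[f"beta_{i}"] = {p: fit.beta_of(p) for p in self.final_probes}
        return pd.DataFrame(data)


def backward_eliminate(
    cohorts: Sequence[tuple[pd.DataFrame, SurvivalData]],
    probes: Sequence[str],
    alpha: float = 0.05,
) -> EliminationResult:
    """Iterative multivariate Cox reduction, optionally with cross-cohort consensus.

    Per cohort: fit a multivariate Cox model on the dichotomized probes, drop
    every covariate with Wald p > alpha in one batch, refit; repeat until all
    remaining probes are significant (or none remain). With two cohorts the
    per-cohort survivors are intersected and both models refit once on the
    common set — the cross-dataset consensus model.
    """
    if not probes:
        raise ValueError("backward_eliminate needs at least one probe")
    if len(cohorts) not in (1, 2):
        raise ValueError("backward_eliminate supports one or two cohorts")

    history: list[list[str]] = []
    survivors: list[list[str]] = []
    for indicators, data in cohorts:
        current = [p for p in probes]
        while current:
            fit = cox_fit(indicators[current], data)
            keep = [p for p in current if fit.p_of(p) <= alpha]
            history.append(list(keep))
            if keep == current:
                break
            current = keep
        survivors.append(current)

    if len(cohorts) == 2:
        common = [p for p in survivors[0] if p in set(survivors[1])]
    else:
        common = survivors[0]

    if not common:
        return EliminationResult(final_probes=[], fits=[None] * len(cohorts), empty=True, history=history)

    fits = [cox_fit(ind[common], data) for ind, data in cohorts]
    return EliminationResult(final_probes=common, fits=fits, empty=False, history=history)
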