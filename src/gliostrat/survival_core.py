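"""Survival-analysis primitives shared by every pipeline stage.

Kaplan–Meier estimation, the log-rank test, Cox proportional-hazards
fitting and multiplicity adjustment. The heavy lifting is delegated to
lifelines / statsmodels; this module pins down the containers and the
conventions (Efron tie handling, Wald confidence intervals, BH step-up)
the rest of the package relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurvivalData",
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "adjust_pvalues",
]


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored follow-up: per-sample time (days), event flag, optional group."""

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray | None = None

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", np.asarray(event, dtype=int))
        if time.ndim != 1:
            raise ValueError("time must be one-dimensional")
        if time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("survival times must be positive and finite")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        if self.group is not None:
            group = np.asarray(self.group)
            if group.shape != time.shape:
                raise ValueError("group labels must match sample count")
            object.__setattr__(self, "group", group)

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: S(t) evaluated at the observed event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t) of the step function (right-continuous; S(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


@dataclass(frozen=True)
class CoxFit:
    """Multivariate Cox proportional-hazards fit (Efron ties, Wald inference)."""

    covariates: tuple[str, ...]
    beta: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    summary: pd.DataFrame = field(repr=False)

    def beta_of(self, name: str) -> float:
        return float(self.beta[self.covariates.index(name)])

    def p_of(self, name: str) -> float:
        return float(self.p_values[self.covariates.index(name)])


def km_estimate(data: SurvivalData) -> KMCurve:
    """Kaplan–Meier product-limit estimator of the survival function."""
    if len(data) == 0:
        raise ValueError("cannot estimate survival from an empty sample")
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, event_observed=data.event)
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    times = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[times, kmf.survival_function_.columns[0]].to_numpy()
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
    )


def logrank_test(data: SurvivalData) -> LogRankResult:
    """k-sample log-rank test over ``data.group`` (df = k − 1)."""
    if data.group is None:
        raise ValueError("logrank_test requires group labels")
    labels, counts = np.unique(data.group, return_counts=True)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least two groups")
    if counts.min() < 1:
        raise ValueError("every group must contain at least one subject")
    if data.n_events == 0:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(data.time, data.group, data.event)
    return LogRankResult(
        chi_square=float(res.test_statistic),
        df=len(labels) - 1,
        p_value=float(res.p_value),
    )


def cox_fit(
    covariates: pd.DataFrame | np.ndarray,
    data: SurvivalData,
    *,
    penalizer: float = 0.0,
    max_steps: int = 50,
) -> CoxFit:
    """Maximum-partial-likelihood Cox regression.

    Efron handling of tied event times; 95% Wald intervals
    ``exp(beta ± 1.96·se)``. Constant covariate columns are rejected up
    front because the partial likelihood cannot identify them.
    """
    X = pd.DataFrame(covariates).copy()
    X.columns = [str(c) for c in X.columns]
    if X.shape[0] != len(data):
        raise ValueError("covariate rows must match the survival sample")
    nunique = X.nunique()
    if (nunique <= 1).any():
        bad = nunique.index[nunique <= 1][0]
        raise ValueError(f"covariate {bad!r} is constant across all samples")
    if data.n_events < X.shape[1]:
        raise ValueError("fewer events than covariates; fit is unidentifiable")

    frame = X.copy()
    frame["_time"] = data.time
    frame["_event"] = data.event
    cph = CoxPHFitter(penalizer=penalizer)
    cph.fit(
        frame,
        duration_col="_time",
        event_col="_event",
        fit_options={"max_steps": max_steps},
    )
    summ = cph.summary
    return CoxFit(
        covariates=tuple(X.columns),
        beta=summ["coef"].to_numpy(),
        hr=summ["exp(coef)"].to_numpy(),
        ci_low=summ["exp(coef) lower 95%"].to_numpy(),
        ci_high=summ["exp(coef) upper 95%"].to_numpy(),
        p_values=summ["p"].to_numpy(),
        log_likelihood=float(cph.log_likelihood_),
        summary=summ,
    )


def adjust_pvalues(p: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiplicity adjustment: Benjamini–Hochberg step-up or Bonferroni."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1 or not np.all(np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    method = method.upper()
    if method == "BH":
        return multipletests(p, method="fdr_bh")[1]
    if method == "BONFERRONI":
        return multipletests(p, method="bonferroni")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def chi2_p(chi_square: float, df: int) -> float:
    """Upper-tail chi-square p-value (shared helper for scan statistics)."""
    return float(stats.chi2.sf(chi_square, df))
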