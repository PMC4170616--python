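"""Synthetic expression cohorts with planted survival, network and class structure.

The generator emulates the statistical shape of a microarray glioma cohort:
log2-scale expression (Gaussian marginals), Weibull/exponential survival with
proportional-hazards effects planted on median-dichotomized probes, independent
exponential censoring tuned to a target censoring fraction, a hub-driven
correlated block for network-inference testing, and a two-class shift block for
classifier testing. Every draw is deterministic given the spec seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .data_io import ExpressionDataset
from .survival_core import SurvivalData

__all__ = [
    "CohortSpec",
    "HubBlock",
    "DEBlock",
    "SyntheticCohort",
    "generate_cohort",
    "generate_survival_times",
    "plant_network_block",
]

_LINKS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear": lambda z: z,
    "quadratic": lambda z: z**2,
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
}


@dataclass(frozen=True)
class HubBlock:
    """One hub probe driving a set of targets through a link function."""

    hub: str
    targets: tuple[str, ...]
    link: str = "linear"
    coupling: float = 1.0
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(self.targets))
        if self.link not in _LINKS:
            raise ValueError(f"unknown link-function tag {self.link!r}")
        if not np.isfinite(self.coupling) or not np.isfinite(self.noise_sd):
            raise ValueError("coupling and noise sd must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass(frozen=True)
class DEBlock:
    """Two-class differential-expression structure for classifier testing."""

    probes: tuple[str, ...]
    shift: float = 1.0
    class_proportion: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "probes", tuple(self.probes))
        if not 0 < self.class_proportion < 1:
            raise ValueError("class_proportion must lie in (0, 1)")
        if not np.isfinite(self.shift):
            raise ValueError("shift must be finite")


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to draw one cohort; defaults are desk-scale.

    ``baseline`` is either ``("exponential", rate)`` or
    ``("weibull", shape, scale)`` with time in days. Prognostic effects are
    log hazard ratios attached to the probe's high (above cohort median)
    level.
    """

    n_samples: int = 200
    n_probes: int = 2000
    prognostic_effects: Mapping[str, float] = field(default_factory=dict)
    baseline: tuple = ("exponential", 1.0 / 400.0)
    censoring_rate: float = 0.2
    treatment_assignment: float = 0.7
    hub_block: tuple[HubBlock, ...] = ()
    de_block: DEBlock | None = None
    expression_mean: float = 8.0
    expression_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hub_block", tuple(self.hub_block))
        object.__setattr__(
            self, "prognostic_effects", dict(self.prognostic_effects)
        )
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.n_probes < 1:
            raise ValueError("n_probes must be positive")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not 0 <= self.treatment_assignment <= 1:
            raise ValueError("treatment_assignment must lie in [0, 1]")
        if self.expression_noise_sd <= 0:
            raise ValueError("expression_noise_sd must be > 0")
        if self.baseline[0] not in ("exponential", "weibull"):
            raise ValueError(f"unknown baseline family {self.baseline[0]!r}")
        if any(not np.isfinite(v) for v in self.prognostic_effects.values()):
            raise ValueError("prognostic effects must be finite")
        known = set(self.probe_ids)
        for probe in self.prognostic_effects:
            if probe not in known:
                raise ValueError(f"prognostic_effects references unknown probe {probe!r}")
        for block in self.hub_block:
            for probe in (block.hub, *block.targets):
                if probe not in known:
                    raise ValueError(f"hub_block references unknown probe {probe!r}")
        if self.de_block is not None:
            for probe in self.de_block.probes:
                if probe not in known:
                    raise ValueError(f"de_block references unknown probe {probe!r}")

    @property
    def probe_ids(self) -> list[str]:
        return [f"probe_{i:05d}" for i in range(self.n_probes)]

    def truth_record(self) -> dict:
        """JSON-serializable copy of the planted structure."""
        return {
            "prognostic_effects": dict(self.prognostic_effects),
            "baseline": list(self.baseline),
            "censoring_rate": self.censoring_rate,
            "hub_block": [
                {
                    "hub": b.hub,
                    "targets": list(b.targets),
                    "link": b.link,
                    "coupling": b.coupling,
                    "noise_sd": b.noise_sd,
                }
                for b in self.hub_block
            ],
            "de_block": None
            if self.de_block is None
            else {
                "probes": list(self.de_block.probes),
                "shift": self.de_block.shift,
                "class_proportion": self.de_block.class_proportion,
            },
            "seed": self.seed,
        }


@dataclass(frozen=True)
class SyntheticCohort:
    expression: ExpressionDataset
    survival: SurvivalData
    treatment: np.ndarray  # 1 = treated arm
    class_labels: np.ndarray | None
    truth: dict

    def clinical_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sample_id": self.expression.sample_ids,
                "survival_time": self.survival.time,
                "event": self.survival.event,
                "chemotherapy": np.where(self.treatment == 1, "yes", "no"),
            }
        )


def _baseline_times(u: np.ndarray, lp: np.ndarray, baseline: tuple) -> np.ndarray:
    """Invert S(t)^exp(lp) = u for the configured baseline family."""
    expo = np.exp(lp)
    if baseline[0] == "exponential":
        rate = float(baseline[1])
        return -np.log(u) / (rate * expo)
    shape, scale = float(baseline[1]), float(baseline[2])
    return scale * (-np.log(u) / expo) ** (1.0 / shape)


def generate_survival_times(
    linear_predictor: Sequence[float],
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> SurvivalData:
    """Draw proportional-hazards survival with independent exponential censoring.

    The censoring rate is solved so that the expected censored fraction,
    given the realized event times, matches ``spec.censoring_rate``.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor must be finite")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    u = rng.uniform(size=lp.shape[0])
    death = _baseline_times(u, lp, spec.baseline)

    if spec.censoring_rate == 0:
        return SurvivalData(time=death, event=np.ones_like(death, dtype=int))

    target = spec.censoring_rate

    def expected_censored(rate: float) -> float:
        # C ~ Exp(rate); P(C < t) = 1 - exp(-rate t)
        return float(np.mean(-np.expm1(-rate * death))) - target

    hi = 1.0 / max(np.median(death), 1e-12)
    while expected_censored(hi) < 0:
        hi *= 4.0
    lo = hi * 1e-12
    while expected_censored(lo) > 0:
        lo /= 4.0
    rate = brentq(expected_censored, lo, hi)
    censor = rng.exponential(scale=1.0 / rate, size=death.shape[0])
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    return SurvivalData(time=np.maximum(time, 1e-9), event=event)


def plant_network_block(
    spec: CohortSpec, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Draw the hub-driven sub-matrix: probe id -> centered signal vector."""
    if not spec.hub_block:
        raise ValueError("hub_block is empty")
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    signals: dict[str, np.ndarray] = {}
    for block in spec.hub_block:
        hub = rng.normal(size=spec.n_samples)
        signals[block.hub] = hub
        link = _LINKS[block.link]
        for target in block.targets:
            signals[target] = link(block.coupling * hub) + rng.normal(
                scale=block.noise_sd, size=spec.n_samples
            )
    return signals


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a full cohort per the planted-structure recipe; deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    probes = spec.probe_ids
    n, p = spec.n_samples, spec.n_probes

    values = rng.normal(
        loc=spec.expression_mean, scale=spec.expression_noise_sd, size=(p, n)
    )
    probe_index = {probe: i for i, probe in enumerate(probes)}

    if spec.hub_block:
        for probe, signal in plant_network_block(spec, rng).items():
            values[probe_index[probe]] = spec.expression_mean + signal

    class_labels = None
    if spec.de_block is not None:
        class_labels = (
            rng.uniform(size=n) < spec.de_block.class_proportion
        ).astype(int)
        for probe in spec.de_block.probes:
            values[probe_index[probe], class_labels == 1] += spec.de_block.shift

    lp = np.zeros(n)
    for probe, beta in spec.prognostic_effects.items():
        row = values[probe_index[probe]]
        lp += beta * (row > np.median(row)).astype(float)

    survival = generate_survival_times(lp, spec, rng)
    treatment = (rng.uniform(size=n) < spec.treatment_assignment).astype(int)

    expression = ExpressionDataset(
        probe_ids=probes,
        sample_ids=[f"sample_{i:04d}" for i in range(n)],
        values=values,
        platform_tag="synthetic-log2",
    )
    return SyntheticCohort(
        expression=expression,
        survival=survival,
        treatment=treatment,
        class_labels=class_labels,
        truth=spec.truth_record(),
    )


def write_truth(cohort: SyntheticCohort, path) -> None:
    with open(path, "w") as fh:
        json.dump(cohort.truth, fh, indent=2)
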