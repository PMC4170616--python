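"""Immunohistochemistry H-scoring and fixed-threshold dichotomization.

An H-score weights the percentage of tumour cells at each staining intensity
(0 = none, 1 = weak, 2 = moderate, 3 = strong): H = 1·p1 + 2·p2 + 3·p3,
range 0–300. Markers are dichotomized at fixed, cohort-derived thresholds
(strictly above the threshold = high); the defaults are the glioma-cohort
values for APE1, NBN, nuclear/cytoplasmic PTEN and PMS2, and can be
re-derived for a new cohort with ``biomarker_screen.optimal_cutpoint``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = ["StainRecord", "DEFAULT_THRESHOLDS", "h_score", "average_h_score", "dichotomize_marker"]

_SUM_TOLERANCE = 0.5  # percent; absorbs pathologist rounding

# (marker, compartment) -> low/high threshold; strictly greater = high
DEFAULT_THRESHOLDS: dict[tuple[str, str], float] = {
    ("APE1", "nuclear"): 160.0,
    ("NBN", "nuclear"): 85.0,
    ("PTEN", "nuclear"): 50.0,
    ("PTEN", "cytoplasmic"): 10.0,
    ("PMS2", "nuclear"): 120.0,
}


@dataclass(frozen=True)
class StainRecord:
    """Percentage of cells at each staining intensity for one section."""

    sample_id: str
    marker: str
    compartment: str  # "nuclear" | "cytoplasmic"
    p0: float
    p1: float
    p2: float
    p3: float

    def __post_init__(self) -> None:
        if self.compartment not in ("nuclear", "cytoplasmic"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        for name in ("p0", "p1", "p2", "p3"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        total = self.p0 + self.p1 + self.p2 + self.p3
        if abs(total - 100.0) > _SUM_TOLERANCE:
            raise ValueError(f"intensity percentages sum to {total}, expected 100")


def h_score(record: StainRecord) -> float:
    """Intensity-weighted score H = 1·p1 + 2·p2 + 3·p3 (range 0–300)."""
    return 1.0 * record.p1 + 2.0 * record.p2 + 3.0 * record.p3


def average_h_score(records: Iterable[StainRecord]) -> float:
    """Mean H-score over repeat sections of one sample/marker."""
    scores = [h_score(r) for r in records]
    if not scores:
        raise ValueError("no stain records supplied")
    key = {(r.sample_id, r.marker, r.compartment) for r in records}
    if len(key) > 1:
        raise ValueError("records mix samples, markers or compartments")
    return sum(scores) / len(scores)


def dichotomize_marker(
    h: float,
    marker: str,
    compartment: str = "nuclear",
    thresholds: dict[tuple[str, str], float] | None = None,
) -> str:
    """'high' when the H-score is strictly above the marker threshold, else 'low'."""
    table = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    key = (marker, compartment)
    if key not in table:
        raise KeyError(f"no threshold configured for marker {marker!r} ({compartment})")
    return "high" if h > table[key] else "low"


def read_stain_records(path) -> list[StainRecord]:
    """StainRecord TSV with columns sample_id, marker, compartment, p0..p3."""
    frame = pd.read_csv(path, sep="\t")
    return [
        StainRecord(
            sample_id=str(r.sample_id),
            marker=str(r.marker),
            compartment=str(r.compartment),
            p0=float(r.p0),
            p1=float(r.p1),
            p2=float(r.p2),
            p3=float(r.p3),
        )
        for r in frame.itertuples(index=False)
    ]
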