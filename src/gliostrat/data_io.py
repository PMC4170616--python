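"""Readers/writers for expression matrices, clinical tables, gene panels and networks.

The canonical on-disk formats are tab-delimited text (GEO series-matrix style):
expression as probes × samples with a header row of sample IDs, clinical tables
with one row per sample, gene panels as (gene, probe) pairs. Networks export to
SIF (for Cytoscape) and GraphML (lossless round-trip).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("gliostrat")

__all__ = [
    "ExpressionDataset",
    "ClinicalTable",
    "GenePanel",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_gene_panel",
    "intersect_probes",
    "export_network",
    "import_graphml",
]


@dataclass(frozen=True)
class ExpressionDataset:
    """Probes × samples log-scale expression matrix with aligned ID lists."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    platform_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_ids", [str(p) for p in self.probe_ids])
        object.__setattr__(self, "sample_ids", [str(s) for s in self.sample_ids])
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError("matrix dimensions do not match ID lists")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_values(self, probe_id: str) -> np.ndarray:
        return self.values[self.probe_ids.index(probe_id)]

    def subset_probes(self, probes: Iterable[str]) -> "ExpressionDataset":
        probes = list(probes)
        index = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probes if p not in index]
        if missing:
            raise KeyError(f"probes not in dataset: {missing[:5]}")
        rows = [index[p] for p in probes]
        return ExpressionDataset(
            probe_ids=probes,
            sample_ids=self.sample_ids,
            values=self.values[rows],
            platform_tag=self.platform_tag,
        )

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionDataset":
        samples = list(samples)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in samples]
        return ExpressionDataset(
            probe_ids=self.probe_ids,
            sample_ids=samples,
            values=self.values[:, cols],
            platform_tag=self.platform_tag,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample follow-up and covariates, aligned to an ExpressionDataset by ID."""

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "survival_time", "event")

    def __post_init__(self) -> None:
        frame = self.frame.copy()
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        if frame["sample_id"].duplicated().any():
            dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample ID {dup!r} in clinical table")
        if (frame["survival_time"] < 0).any():
            raise ValueError("survival_time must be >= 0")
        if not frame["event"].isin((0, 1)).all():
            raise ValueError("event must be 0/1")
        object.__setattr__(self, "frame", frame)

    def aligned_to(self, dataset: ExpressionDataset) -> "ClinicalTable":
        """Restrict to the dataset's samples, dataset order; log dropped samples."""
        indexed = self.frame.set_index("sample_id")
        present = [s for s in dataset.sample_ids if s in indexed.index]
        missing = set(dataset.sample_ids) - set(present)
        if missing:
            logger.warning(
                "dropping %d expression samples without clinical records", len(missing)
            )
        return ClinicalTable(indexed.loc[present].reset_index())


@dataclass(frozen=True)
class GenePanel:
    """Gene symbol → probe IDs mapping (e.g. a DNA-repair gene panel)."""

    genes: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene panel is empty")
        probes = self.probe_ids
        if len(set(probes)) != len(probes):
            raise ValueError("duplicate probe IDs within panel")

    @property
    def probe_ids(self) -> list[str]:
        return [p for plist in self.genes.values() for p in plist]

    def gene_of(self, probe_id: str) -> str:
        for gene, plist in self.genes.items():
            if probe_id in plist:
                return gene
        raise KeyError(probe_id)

    def restrict(self, probes: Iterable[str]) -> "GenePanel":
        keep = set(probes)
        genes = {
            g: [p for p in plist if p in keep]
            for g, plist in self.genes.items()
        }
        return GenePanel({g: pl for g, pl in genes.items() if pl})


def read_expression_matrix(path) -> ExpressionDataset:
    """Parse a probes × samples TSV (header = sample IDs, first column = probe IDs)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicated probe row {dup!r} in {path.name}")
    if frame.columns.duplicated().any():
        dup = frame.columns[frame.columns.duplicated()][0]
        raise ValueError(f"duplicated sample column {dup!r} in {path.name}")
    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        try:
            values[:, j] = pd.to_numeric(frame[col], errors="raise").to_numpy()
        except (ValueError, TypeError) as exc:
            bad = frame[frame[col].isna() | pd.to_numeric(frame[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric or blank cell at probe {row!r}, sample {col!r} in {path.name}"
            ) from exc
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"non-numeric or blank cell at probe {frame.index[i]!r}, "
            f"sample {frame.columns[j]!r} in {path.name}"
        )
    return ExpressionDataset(
        probe_ids=list(frame.index),
        sample_ids=list(frame.columns),
        values=values,
    )


def write_expression_matrix(dataset: ExpressionDataset, path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index_label="probe_id")


def read_clinical_table(path) -> ClinicalTable:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return ClinicalTable(frame)


def write_clinical_table(table: ClinicalTable, path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def read_gene_panel(path) -> GenePanel:
    """Gene-panel TSV with columns (gene, probe)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError("gene panel needs (gene, probe) columns")
    gene_col, probe_col = frame.columns[:2]
    genes: dict[str, list[str]] = {}
    for gene, probe in zip(frame[gene_col], frame[probe_col]):
        genes.setdefault(str(gene), []).append(str(probe))
    return GenePanel(genes)


def write_gene_panel(panel: GenePanel, path) -> None:
    rows = [(g, p) for g, plist in panel.genes.items() for p in plist]
    pd.DataFrame(rows, columns=["gene", "probe"]).to_csv(path, sep="\t", index=False)


def intersect_probes(
    dataset_a: ExpressionDataset,
    dataset_b: ExpressionDataset,
    panel: GenePanel,
) -> tuple[ExpressionDataset, ExpressionDataset, GenePanel]:
    """Restrict both cohorts to panel probes measured in both, identical order."""
    common = [
        p
        for p in panel.probe_ids
        if p in set(dataset_a.probe_ids) and p in set(dataset_b.probe_ids)
    ]
    if not common:
        raise ValueError("no panel probe is present in both datasets")
    return (
        dataset_a.subset_probes(common),
        dataset_b.subset_probes(common),
        panel.restrict(common),
    )


_SIGN_TAG = {1: "activates", -1: "inhibits", 0: "interacts"}


def export_network(net, path, fmt: str = "SIF") -> None:
    """Write an interaction network as SIF or GraphML.

    ``net`` is any object with an ``edges`` iterable of
    (source, target, weight) triples, or a networkx DiGraph with ``weight``
    edge attributes.
    """
    graph = _as_digraph(net)
    fmt = fmt.upper()
    path = Path(path)
    if fmt == "SIF":
        with open(path, "w") as fh:
            for u, v, attrs in graph.edges(data=True):
                w = attrs.get("weight", 0.0)
                fh.write(f"{u}\t{_SIGN_TAG[int(np.sign(w))]}\t{v}\n")
    elif fmt == "GRAPHML":
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def import_graphml(path) -> nx.DiGraph:
    graph = nx.read_graphml(path)
    return nx.DiGraph(graph)


def _as_digraph(net) -> nx.DiGraph:
    if isinstance(net, nx.DiGraph):
        return net
    graph = nx.DiGraph()
    for source, target, weight in net.edges:
        if not np.isfinite(weight):
            raise ValueError(f"non-finite weight on edge {source}->{target}")
        graph.add_edge(source, target, weight=float(weight), sign=int(np.sign(weight)))
    return graph
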