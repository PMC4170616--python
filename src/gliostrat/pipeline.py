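"""End-to-end two-cohort workflow: screen → consensus → Cox reduction → PI → ANN.

`run_full_analysis` executes the stages in order on a pair of cohorts (read
from disk or generated synthetically), writing every stage's output as
TSV/JSON/SIF under the configured output directory together with a
reproducibility manifest. Identical config + seed reproduces identical
outputs; each stage's files are sufficient to resume later stages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ann_interactome import (
    MLPConfig,
    infer_pairwise_interactions,
    rank_probes_by_prediction,
    select_top_edges_and_hubs,
)
from .biomarker_screen import backward_eliminate, consensus_probes, dichotomize, screen_probes
from .data_io import (
    ClinicalTable,
    ExpressionDataset,
    GenePanel,
    export_network,
    intersect_probes,
    read_clinical_table,
    read_expression_matrix,
    read_gene_panel,
)
from .ensemble_classifier import loocv_ensemble_classify, rank_genes_by_selection_frequency
from .prognostic_index import (
    PIGene,
    PIModel,
    assign_risk_groups,
    compute_pi,
    fit_year_survival_curve,
)
from .survival_core import SurvivalData, logrank_test
from .synthetic_cohort import CohortSpec, generate_cohort

logger = logging.getLogger("gliostrat")

__all__ = ["RunConfig", "run_full_analysis"]

YEAR_DAYS = 365.25


@dataclass
class RunConfig:
    """Configuration for the full pipeline run.

    Each cohort is either a (expression TSV, clinical TSV) pair or a
    synthetic `CohortSpec`; exactly one of the two per cohort.
    """

    out_dir: str
    cohort_a: dict = field(default_factory=dict)  # {"expression":…, "clinical":…} or {"synthetic": CohortSpec}
    cohort_b: dict = field(default_factory=dict)
    panel_path: str | None = None
    alpha: float = 0.05
    pi_groups: int = 3
    stratify_treatment: bool = False
    run_ann: bool = True
    run_ensemble: bool = True
    ann: MLPConfig = field(default_factory=MLPConfig)
    ann_top_m: int = 20
    ann_top_edges: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name, cohort in (("cohort_a", self.cohort_a), ("cohort_b", self.cohort_b)):
            has_files = "expression" in cohort
            has_spec = "synthetic" in cohort
            if has_files == has_spec:
                raise ValueError(f"{name} needs exactly one of file paths or a synthetic spec")


def _load_cohort(entry: dict) -> tuple[ExpressionDataset, SurvivalData, np.ndarray | None]:
    if "synthetic" in entry:
        spec = entry["synthetic"]
        if isinstance(spec, dict):
            spec = CohortSpec(**spec)
        cohort = generate_cohort(spec)
        return cohort.expression, cohort.survival, cohort.treatment
    expr = read_expression_matrix(entry["expression"])
    clin = read_clinical_table(entry["clinical"]).aligned_to(expr)
    expr = expr.subset_samples(list(clin.frame["sample_id"]))
    frame = clin.frame
    keep = frame["survival_time"] > 0
    if not keep.all():
        logger.warning("dropping %d samples with non-positive follow-up", int((~keep).sum()))
        frame = frame[keep]
        expr = expr.subset_samples(list(frame["sample_id"]))
    surv = SurvivalData(frame["survival_time"].to_numpy(float), frame["event"].to_numpy(int))
    treatment = None
    if "chemotherapy" in frame.columns:
        treatment = (frame["chemotherapy"] == "yes").to_numpy().astype(int)
    return expr, surv, treatment


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every pipeline stage in order; returns the report bundle paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def _save(name: str, path: Path):
        artifacts[name] = str(path)
        return path

    expr_a, surv_a, treat_a = _load_cohort(config.cohort_a)
    expr_b, surv_b, treat_b = _load_cohort(config.cohort_b)
    if surv_a.n_events == 0 or surv_b.n_events == 0:
        raise RuntimeError("stage screening: a cohort has zero events")

    panel = read_gene_panel(config.panel_path) if config.panel_path else None
    if panel is not None:
        expr_a, expr_b, panel = intersect_probes(expr_a, expr_b, panel)
    else:
        common = [p for p in expr_a.probe_ids if p in set(expr_b.probe_ids)]
        expr_a, expr_b = expr_a.subset_probes(common), expr_b.subset_probes(common)

    # Stage 1: per-cohort optimal-cutpoint screening with BH control
    screen_a = screen_probes(expr_a, surv_a, panel, alpha=config.alpha)
    screen_b = screen_probes(expr_b, surv_b, panel, alpha=config.alpha)
    screen_a.table.to_csv(_save("screen_a", out / "screen_a.tsv"), sep="\t", index=False)
    screen_b.table.to_csv(_save("screen_b", out / "screen_b.tsv"), sep="\t", index=False)

    # Stage 2: cross-cohort consensus and multivariate reduction
    consensus = consensus_probes(screen_a, screen_b)
    (out / "consensus_probes.txt").write_text("\n".join(consensus) + "\n")
    artifacts["consensus"] = str(out / "consensus_probes.txt")

    result: dict = {"consensus_probes": consensus, "artifacts": artifacts}

    if not consensus:
        logger.warning("empty consensus set; skipping PI and ANN stages")
        _write_manifest(config, out, artifacts)
        result["final_probes"] = []
        return result

    cuts_a = {p: screen_a.cutpoints()[p] for p in consensus}
    cuts_b = {p: screen_b.cutpoints()[p] for p in consensus}
    ind_a = dichotomize(expr_a, cuts_a)
    ind_b = dichotomize(expr_b, cuts_b)
    elim = backward_eliminate([(ind_a, surv_a), (ind_b, surv_b)], consensus, alpha=config.alpha)
    result["final_probes"] = elim.final_probes
    if elim.empty:
        logger.warning("empty final multivariate model; skipping PI and ANN stages")
        _write_manifest(config, out, artifacts)
        return result

    elim.betas().to_csv(_save("final_model", out / "final_model_betas.tsv"), sep="\t")

    # Stage 3: prognostic index, risk groups, year-survival curves
    gene_of = (lambda p: panel.gene_of(p)) if panel is not None else (lambda p: p)
    genes = tuple(
        PIGene(
            gene=gene_of(p),
            probe_id=p,
            cutpoint=cuts_a[p],
            direction=screen_a.directions()[p],
            beta_test=elim.fits[0].beta_of(p),
            beta_validation=elim.fits[1].beta_of(p),
        )
        for p in elim.final_probes
    )
    pi_model = PIModel(genes=genes)
    pi_model.to_json(_save("pi_model", out / "pi_model.json"))

    scores = ind_a[elim.final_probes].to_numpy() @ np.array([g.beta_combined for g in genes])
    result["pi_scores_a"] = scores
    try:
        groups = assign_risk_groups(scores, surv_a, k=config.pi_groups)
    except ValueError as exc:
        logger.warning("risk grouping skipped: %s", exc)
        groups = None
    if groups is not None:
        pd.DataFrame(
            {"sample_id": expr_a.sample_ids, "pi_score": scores, "group": groups.labels}
        ).to_csv(_save("risk_groups", out / "risk_groups_a.tsv"), sep="\t", index=False)
        curves = {}
        if groups.k == 3:
            for years in (1, 2, 3):
                try:
                    fit = fit_year_survival_curve(groups, years * YEAR_DAYS)
                except ValueError as exc:
                    logger.warning("%d-year curve skipped: %s", years, exc)
                    continue
                curves[f"{years}y"] = {
                    "coefficients": list(fit.coefficients),
                    "anchors": [list(a) for a in fit.anchors],
                }
        with open(_save("year_curves", out / "year_curves.json"), "w") as fh:
            json.dump(curves, fh, indent=2)
        result["risk_groups"] = groups

    # Stage 4 (optional): KM re-analysis within treatment strata, fixed cutpoints
    if config.stratify_treatment and treat_a is not None:
        rows = []
        for probe in elim.final_probes:
            level = ind_a[probe].to_numpy()
            for arm, label in ((1, "treated"), (0, "untreated")):
                mask = treat_a == arm
                sub = SurvivalData(surv_a.time[mask], surv_a.event[mask], group=level[mask])
                if len(np.unique(level[mask])) < 2 or sub.n_events == 0:
                    continue
                res = logrank_test(sub)
                rows.append((probe, label, res.chi_square, res.p_value))
        pd.DataFrame(rows, columns=["probe_id", "stratum", "chi_square", "p_value"]).to_csv(
            _save("treatment_strata", out / "treatment_strata.tsv"), sep="\t", index=False
        )

    # Stage 5 (optional): ANN screening + interactome per final-model gene
    if config.run_ann:
        for probe in elim.final_probes:
            ranking = rank_probes_by_prediction(expr_b, probe, config.ann)
            ranking.table.to_csv(
                _save(f"ann_rank_{probe}", out / f"ann_ranking_{probe}.tsv"),
                sep="\t",
                index=False,
            )
            top = ranking.top(config.ann_top_m)
            net = infer_pairwise_interactions(expr_b.subset_probes(top), config.ann)
            pruned, hubs = select_top_edges_and_hubs(net, top_k=config.ann_top_edges)
            export_network(pruned, _save(f"ann_net_{probe}", out / f"interactome_{probe}.sif"), "SIF")
            hubs.to_csv(_save(f"ann_hubs_{probe}", out / f"hubs_{probe}.tsv"), sep="\t", index=False)

    # Stage 6 (optional): ensemble LOOCV gene ranking on the first final gene's
    # high/low status in cohort B
    if config.run_ensemble and elim.final_probes:
        probe = elim.final_probes[0]
        labels = ind_b[probe].to_numpy().astype(int)
        if len(np.unique(labels)) == 2:
            cv = loocv_ensemble_classify(
                expr_b.values, labels, genes=list(expr_b.probe_ids), seed=config.seed
            )
            ranking = rank_genes_by_selection_frequency(cv, genes=list(expr_b.probe_ids))
            ranking.table.to_csv(
                _save("ensemble_ranking", out / "ensemble_ranking.tsv"), sep="\t", index=False
            )
            result["ensemble_accuracy"] = cv.accuracy

    _write_manifest(config, out, artifacts)
    result["artifacts"] = artifacts
    return result


def _write_manifest(config: RunConfig, out: Path, artifacts: dict) -> None:
    def _jsonable(obj):
        if isinstance(obj, MLPConfig):
            return obj.__dict__ | {"split_fractions": list(obj.split_fractions)}
        if isinstance(obj, CohortSpec):
            return obj.truth_record() | {"n_samples": obj.n_samples, "n_probes": obj.n_probes}
        return str(obj)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "pi_groups": config.pi_groups,
        "cohort_a": {k: _jsonable(v) for k, v in config.cohort_a.items()},
        "cohort_b": {k: _jsonable(v) for k, v in config.cohort_b.items()},
        "ann": _jsonable(config.ann),
        "artifacts": sorted(artifacts),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
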