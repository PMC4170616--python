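"""LOOCV majority-vote ensemble classification with moderated-t gene selection.

For a binary phenotype (e.g. marker-high vs marker-low samples), each
leave-one-out fold selects differentially expressed genes on the training
portion only, using an empirical-Bayes moderated t-statistic (per-gene
variances shrunk toward a scaled-inverse-chi-square prior whose
hyperparameters are moment-matched on log s²). Four base learners — a linear
max-margin classifier, a randomized decision-tree ensemble, k-nearest
neighbours and a nearest-shrunken-centroid classifier — are tuned by grid
search within an inner cross-validation and combined by majority vote. Genes
are ranked by how often they are selected across folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.svm import SVC

logger = logging.getLogger("gliostrat")

__all__ = [
    "ModeratedTResult",
    "EnsembleCVResult",
    "GeneRanking",
    "moderated_t",
    "loocv_ensemble_classify",
    "rank_genes_by_selection_frequency",
]

_D0_CAP = 1e6  # "effectively infinite" prior degrees of freedom


@dataclass(frozen=True)
class ModeratedTResult:
    """Per-gene moderated two-class contrast plus the global prior (d0, s0²)."""

    table: pd.DataFrame  # gene, mean_diff, s2, s2_tilde, t, p_value
    d0: float
    s0_sq: float
    residual_df: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 1e-8:
        return 1.0 / y if y > 0 else np.inf
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + step
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0²) of the scaled-F marginal of the sample variances.

    Works on z = log s²: E[z] = log s0² + ψ(d0/2) − log(d0/2) + ψ(d/2) − log(d/2)
    offsets, Var[z] = ψ'(d/2) + ψ'(d0/2). When the observed spread of z is no
    larger than the chi-square sampling noise, d0 is effectively infinite.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    n = z.size
    evar = np.var(e, ddof=1) - polygamma(1, df / 2.0) if n > 1 else 0.0
    if evar <= 0:
        d0 = _D0_CAP
    else:
        d0 = min(2.0 * _trigamma_inverse(float(evar)), _D0_CAP)
    s0_sq = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def moderated_t(
    expression: np.ndarray,
    classes: np.ndarray,
    genes: list[str] | None = None,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> ModeratedTResult:
    """Empirical-Bayes moderated two-sample t-test, one row per gene.

    ``expression`` is genes × samples; ``classes`` a binary label per sample.
    Posterior variance s̃² = (d0·s0² + d·s²)/(d0 + d) with residual df
    d = n − 2; p-values use d + d0 degrees of freedom. Pass explicit
    ``d0``/``s0_sq`` to bypass the moment-matching estimate (d0 = 0
    recovers the ordinary pooled t-test).
    """
    X = np.asarray(expression, dtype=float)
    y = np.asarray(classes)
    labels = np.unique(y)
    if labels.size != 2:
        raise ValueError("exactly two classes required")
    m0, m1 = y == labels[0], y == labels[1]
    n0, n1 = int(m0.sum()), int(m1.sum())
    if n0 < 2 or n1 < 2:
        raise ValueError("each class needs at least 2 samples")

    mean_diff = X[:, m1].mean(axis=1) - X[:, m0].mean(axis=1)
    ss = ((X[:, m0] - X[:, m0].mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (X[:, m1] - X[:, m1].mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n0 + n1 - 2
    s2 = ss / df

    if d0 is None or s0_sq is None:
        d0_est, s0_est = estimate_variance_prior(s2, df)
        d0 = d0_est if d0 is None else d0
        s0_sq = s0_est if s0_sq is None else s0_sq

    s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df) if np.isfinite(d0) else np.full_like(s2, s0_sq)
    scale = np.sqrt(s2_tilde * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(scale > 0, mean_diff / scale, 0.0)
    total_df = min(d0 + df, _D0_CAP)
    p = 2.0 * stats.t.sf(np.abs(t), total_df)

    table = pd.DataFrame(
        {
            "gene": genes if genes is not None else [f"g{i}" for i in range(X.shape[0])],
            "mean_diff": mean_diff,
            "s2": s2,
            "s2_tilde": s2_tilde,
            "t": t,
            "p_value": p,
        }
    )
    return ModeratedTResult(table=table, d0=float(d0), s0_sq=float(s0_sq), residual_df=float(df))


@dataclass(frozen=True)
class LearnerSpec:
    """One base learner and its hyperparameter grid for the inner CV search."""

    name: str
    make: object  # callable(seed) -> estimator
    grid: dict


def default_learners(seed: int = 0) -> list[LearnerSpec]:
    return [
        LearnerSpec(
            "svm",
            lambda s: SVC(kernel="linear", random_state=s),
            {"C": [0.01, 0.1, 1.0, 10.0]},
        ),
        LearnerSpec(
            # forest size is not a regularization parameter; fixed at 100 trees
            # with default feature subsampling instead of nested tuning
            "forest",
            lambda s: RandomForestClassifier(n_estimators=100, random_state=s),
            {},
        ),
        LearnerSpec(
            "knn",
            lambda s: KNeighborsClassifier(),
            {"n_neighbors": [1, 3, 5, 7]},
        ),
        LearnerSpec(
            "centroid",
            lambda s: NearestCentroid(),
            {"shrink_threshold": None},  # grid filled per fold from centroid offsets
        ),
    ]


def _centroid_shrink_grid(X: np.ndarray, y: np.ndarray) -> list[float | None]:
    """Shrinkage grid: 10 quantiles of the standardized centroid offsets."""
    overall = X.mean(axis=0)
    offsets = []
    for label in np.unique(y):
        offsets.append(np.abs(X[y == label].mean(axis=0) - overall))
    offsets = np.concatenate(offsets)
    qs = np.quantile(offsets[offsets > 0], np.linspace(0.05, 0.95, 10)) if (offsets > 0).any() else []
    grid: list[float | None] = [None]
    grid.extend(float(q) for q in np.unique(qs))
    return grid


def _score(estimator, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Per-class score for the tie-break (higher = more support for class)."""
    if hasattr(estimator, "predict_proba"):
        proba = estimator.predict_proba(X)[0]
        return proba
    if hasattr(estimator, "decision_function"):
        d = float(estimator.decision_function(X)[0])
        return np.array([-d, d])
    # nearest-centroid: negative distance to each class centroid
    centroids = estimator.centroids_
    dists = np.linalg.norm(centroids - X[0], axis=1)
    return -dists


def majority_vote(
    votes: dict[str, object],
    scores: dict[str, np.ndarray],
    class_labels: np.ndarray,
):
    """Combine base-learner votes; ties go to the class with higher mean score,
    then lexicographically. Invariant to learner order."""
    counts = {c: sum(1 for v in votes.values() if v == c) for c in class_labels}
    top_count = max(counts.values())
    tied = sorted([c for c, cnt in counts.items() if cnt == top_count])
    if len(tied) == 1:
        return tied[0]
    order = {c: k for k, c in enumerate(class_labels)}
    mean_scores = {
        c: float(np.mean([scores[s][order[c]] for s in scores])) for c in tied
    }
    best = max(mean_scores.values())
    return sorted([c for c in tied if mean_scores[c] == best])[0]


def run_fold(
    X: np.ndarray,
    y: np.ndarray,
    i: int,
    genes: list[str],
    specs: list["LearnerSpec"],
    class_labels: np.ndarray,
    alpha: float = 0.05,
    inner_folds: int = 5,
    fallback_top: int = 10,
    seed: int = 0,
):
    """One leave-one-out fold: selection, tuning and prediction for sample ``i``.

    Sample ``i``'s label is never read; only its expression column is, and
    only at prediction time.
    """
    n = X.shape[1]
    train = np.ones(n, dtype=bool)
    train[i] = False
    mt = moderated_t(X[:, train], y[train], genes=genes)
    selected = list(mt.table.loc[mt.table["p_value"] < alpha, "gene"])
    if not selected:
        top = mt.table.reindex(mt.table["t"].abs().sort_values(ascending=False).index)
        selected = list(top["gene"].head(fallback_top))
        logger.warning(
            "fold %d selected zero genes; falling back to top %d by |t|", i, fallback_top
        )
    idx = [genes.index(g) for g in selected]

    Xtr = X[np.ix_(idx, np.flatnonzero(train))].T
    Xte = X[idx, i][None, :]
    ytr = y[train]

    votes, scores = {}, {}
    for spec in specs:
        grid = dict(spec.grid)
        if spec.name == "centroid":
            grid = {"shrink_threshold": _centroid_shrink_grid(Xtr, ytr)}
        est = spec.make(seed)
        n_splits = min(inner_folds, np.bincount(pd.factorize(ytr)[0]).min())
        n_candidates = int(np.prod([len(v) for v in grid.values()])) if grid else 1
        if n_splits >= 2 and n_candidates > 1:
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            search = GridSearchCV(est, grid, cv=cv, n_jobs=1)
            search.fit(Xtr, ytr)
            fitted = search.best_estimator_
        else:
            fitted = est.fit(Xtr, ytr)
        votes[spec.name] = fitted.predict(Xte)[0]
        scores[spec.name] = _score(fitted, Xte, class_labels)

    vote = majority_vote(votes, scores, class_labels)
    return votes, vote, selected, mt.table["p_value"].to_numpy()


@dataclass(frozen=True)
class EnsembleCVResult:
    """LOOCV record: per-fold base votes, ensemble vote, truth, selected genes."""

    predictions: pd.DataFrame  # sample, truth, vote, + one column per learner
    accuracy: float
    fold_genes: list[list[str]]
    classes: tuple
    learner_names: tuple[str, ...] = field(default=())
    fold_pvalues: pd.DataFrame | None = field(default=None, repr=False)  # folds × genes


def loocv_ensemble_classify(
    expression: np.ndarray,
    classes: np.ndarray,
    genes: list[str] | None = None,
    alpha: float = 0.05,
    inner_folds: int = 5,
    fallback_top: int = 10,
    seed: int = 0,
    learners: list[LearnerSpec] | None = None,
) -> EnsembleCVResult:
    """Leave-one-out ensemble classification with in-fold gene selection.

    Everything that touches the data — moderated-t selection (p < alpha),
    hyperparameter tuning (grid search within ``inner_folds``-fold
    stratified CV) and model fitting — happens on the training portion of
    each fold; the left-out sample only ever receives a prediction. A fold
    selecting zero genes falls back to the ``fallback_top`` genes by |t|.
    Majority vote ties break toward the class with the higher mean predicted
    score, then lexicographically.
    """
    X = np.asarray(expression, dtype=float)
    y = np.asarray(classes)
    n = X.shape[1]
    if n < 10:
        raise ValueError("LOOCV needs at least 10 samples")
    class_labels = np.unique(y)
    if class_labels.size != 2:
        raise ValueError("two classes required")
    if genes is None:
        genes = [f"g{i}" for i in range(X.shape[0])]
    specs = default_learners(seed) if learners is None else learners

    rows = []
    fold_genes: list[list[str]] = []
    fold_p = np.empty((n, len(genes)))
    for i in range(n):
        votes, vote, selected, pvals = run_fold(
            X, y, i, genes, specs, class_labels,
            alpha=alpha, inner_folds=inner_folds,
            fallback_top=fallback_top, seed=seed,
        )
        fold_p[i] = pvals
        fold_genes.append(selected)
        rows.append({"sample": i, "truth": y[i], "vote": vote, **votes})

    predictions = pd.DataFrame(rows)
    accuracy = float((predictions["vote"] == predictions["truth"]).mean())
    return EnsembleCVResult(
        predictions=predictions,
        accuracy=accuracy,
        fold_genes=fold_genes,
        classes=tuple(class_labels),
        learner_names=tuple(s.name for s in specs),
        fold_pvalues=pd.DataFrame(fold_p, columns=genes),
    )


@dataclass(frozen=True)
class GeneRanking:
    table: pd.DataFrame  # gene, frequency, mean_p, rank

    def top(self, m: int) -> list[str]:
        return list(self.table.sort_values("rank")["gene"].head(m))


def rank_genes_by_selection_frequency(
    result: EnsembleCVResult, genes: list[str] | None = None
) -> GeneRanking:
    """Frequency of appearance in the per-fold selected-gene lists, ranked.

    Ties in frequency break toward the smaller mean fold p-value.
    """
    if not result.fold_genes:
        raise ValueError("no folds recorded")
    if genes is None:
        genes = sorted({g for fold in result.fold_genes for g in fold})
    n_folds = len(result.fold_genes)
    counts = {g: 0 for g in genes}
    for fold in result.fold_genes:
        for g in fold:
            if g in counts:
                counts[g] += 1
    mean_p = (
        result.fold_pvalues.reindex(columns=genes).mean(axis=0)
        if result.fold_pvalues is not None
        else pd.Series(np.nan, index=genes)
    )
    table = pd.DataFrame(
        {
            "gene": genes,
            "frequency": [counts[g] / n_folds for g in genes],
            "mean_p": [float(mean_p[g]) for g in genes],
        }
    )
    table = table.sort_values(
        ["frequency", "mean_p", "gene"], ascending=[False, True, True], kind="stable"
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return GeneRanking(table=table.reset_index(drop=True))
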