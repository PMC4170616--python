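"""Neural-network gene-interaction inference: MLP screening, pairwise links, hubs.

A deliberately small, fully deterministic multilayer perceptron (one sigmoid
hidden layer, sigmoid output, batch gradient descent with momentum) is used
two ways:

* **screening** — every candidate probe is used singly to predict a target
  gene's high/low (median-split) status over Monte-Carlo 60/20/20 resamples;
  candidates are ranked by mean validation RMSE;
* **interaction inference** — over the top-m probes, an MLP is trained per
  target on the remaining m−1 inputs, and the signed influence of input i on
  target j is the connection-weight product Σ_h w(i→h)·w(h→out), averaged over
  resamples. Positive weights are excitatory, negative inhibitory.

Hubs are nodes with ≥5 incident edges among the retained strongest edges,
ranked by the summed absolute weight of those edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import ExpressionDataset

__all__ = [
    "MLPConfig",
    "MLPModel",
    "ProbeRanking",
    "InteractionNetwork",
    "train_mlp",
    "rank_probes_by_prediction",
    "infer_pairwise_interactions",
    "select_top_edges_and_hubs",
]


@dataclass(frozen=True)
class MLPConfig:
    """Architecture and training schedule for the screening/inference MLP."""

    hidden_nodes: int = 2
    learning_rate: float = 0.5
    momentum: float = 0.1
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    bootstraps: int = 50
    max_epochs: int = 500
    patience: int = 25
    init_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_nodes < 1:
            raise ValueError("hidden_nodes must be >= 1")
        if self.learning_rate < 0 or self.learning_rate > 1:
            raise ValueError("learning_rate must lie in [0, 1]")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.bootstraps < 1 or self.max_epochs < 1:
            raise ValueError("bootstraps and max_epochs must be positive")


@dataclass
class MLPModel:
    """Trained weights plus the per-epoch train/test error history."""

    w_hidden: np.ndarray  # inputs × hidden
    b_hidden: np.ndarray
    w_out: np.ndarray  # hidden
    b_out: float
    history: pd.DataFrame = field(repr=False)

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        hidden = _sigmoid(inputs @ self.w_hidden + self.b_hidden)
        return _sigmoid(hidden @ self.w_out + self.b_out)

    def connection_weights(self) -> np.ndarray:
        """Signed input influence: Σ over hidden of w(in→h)·w(h→out)."""
        return self.w_hidden @ self.w_out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _init_weights(n_in: int, config: MLPConfig, rng: np.random.Generator):
    s = config.init_scale
    w1 = rng.uniform(-s, s, size=(n_in, config.hidden_nodes))
    b1 = rng.uniform(-s, s, size=config.hidden_nodes)
    w2 = rng.uniform(-s, s, size=config.hidden_nodes)
    b2 = float(rng.uniform(-s, s))
    return w1, b1, w2, b2


def mlp_gradients(
    w1: np.ndarray,
    b1: np.ndarray,
    w2: np.ndarray,
    b2: float,
    X: np.ndarray,
    y: np.ndarray,
):
    """Analytic gradients of the mean-squared error (exposed for verification)."""
    n = X.shape[0]
    a1 = _sigmoid(X @ w1 + b1)
    yhat = _sigmoid(a1 @ w2 + b2)
    d2 = (2.0 / n) * (yhat - y) * yhat * (1.0 - yhat)
    g_w2 = a1.T @ d2
    g_b2 = float(d2.sum())
    d1 = np.outer(d2, w2) * a1 * (1.0 - a1)
    g_w1 = X.T @ d1
    g_b1 = d1.sum(axis=0)
    loss = float(np.mean((yhat - y) ** 2))
    return g_w1, g_b1, g_w2, g_b2, loss


def mlp_loss(w1, b1, w2, b2, X, y) -> float:
    a1 = _sigmoid(X @ w1 + b1)
    yhat = _sigmoid(a1 @ w2 + b2)
    return float(np.mean((yhat - y) ** 2))


def train_mlp(
    inputs: np.ndarray,
    targets: np.ndarray,
    config: MLPConfig,
    rng: np.random.Generator | None = None,
    test_inputs: np.ndarray | None = None,
    test_targets: np.ndarray | None = None,
) -> MLPModel:
    """Batch feed-forward/back-propagation with momentum; deterministic in seed.

    Weights update once per epoch on the full training batch. When a test
    split is supplied, training stops after ``patience`` epochs without
    improvement of test-set error and the best-epoch weights are kept.
    Targets must already be coded into [0, 1].
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[0] != np.asarray(targets).shape[0]:
        X = X.T
    y = np.asarray(targets, dtype=float)
    if y.min() < 0 or y.max() > 1:
        raise ValueError("targets must lie in [0, 1]")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    w1, b1, w2, b2 = _init_weights(X.shape[1], config, rng)
    v1 = np.zeros_like(w1)
    vb1 = np.zeros_like(b1)
    v2 = np.zeros_like(w2)
    vb2 = 0.0

    lr, mom = config.learning_rate, config.momentum
    best = (np.inf, w1, b1, w2, b2)
    stall = 0
    rows = []
    for epoch in range(config.max_epochs):
        g_w1, g_b1, g_w2, g_b2, train_err = mlp_gradients(w1, b1, w2, b2, X, y)
        if not np.isfinite(train_err):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        v1 = mom * v1 - lr * g_w1
        vb1 = mom * vb1 - lr * g_b1
        v2 = mom * v2 - lr * g_w2
        vb2 = mom * vb2 - lr * g_b2
        w1 = w1 + v1
        b1 = b1 + vb1
        w2 = w2 + v2
        b2 = b2 + vb2

        test_err = np.nan
        if test_inputs is not None:
            test_err = mlp_loss(w1, b1, w2, b2, np.atleast_2d(test_inputs), test_targets)
            if test_err < best[0] - 1e-12:
                best = (test_err, w1.copy(), b1.copy(), w2.copy(), b2)
                stall = 0
            else:
                stall += 1
        rows.append((epoch, train_err, test_err))
        if test_inputs is not None and stall >= config.patience:
            break

    if test_inputs is not None and np.isfinite(best[0]):
        _, w1, b1, w2, b2 = best
    history = pd.DataFrame(rows, columns=["epoch", "train_error", "test_error"])
    return MLPModel(w_hidden=w1, b_hidden=b1, w_out=w2, b_out=b2, history=history)


@dataclass(frozen=True)
class ProbeRanking:
    """Candidates ordered by mean validation RMSE (rank 1 = best predictor)."""

    table: pd.DataFrame  # probe_id, mean_rmse, sd_rmse, misclassification, rank

    def top(self, m: int) -> list[str]:
        ordered = self.table.sort_values("rank")
        return list(ordered["probe_id"].head(m))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _splits(n: int, fractions, bootstraps: int, rng: np.random.Generator):
    n_train = int(round(fractions[0] * n))
    n_test = int(round(fractions[1] * n))
    out = []
    for _ in range(bootstraps):
        perm = rng.permutation(n)
        out.append(
            (perm[:n_train], perm[n_train : n_train + n_test], perm[n_train + n_test :])
        )
    return out


def rank_probes_by_prediction(
    dataset: ExpressionDataset,
    target_probe: str,
    config: MLPConfig,
    candidates: Sequence[str] | None = None,
) -> ProbeRanking:
    """Rank every candidate probe by its single-input ability to predict the target.

    The target is coded 0 (below cohort median) / 1 (above); each candidate is
    standardized and trained singly over ``config.bootstraps`` Monte-Carlo
    60/20/20 resamples; the score is the mean validation-split RMSE.
    Misclassification rate at a 0.5 threshold is reported as a secondary
    column. Identical resample splits are reused across candidates.
    """
    if dataset.n_samples < 30:
        raise ValueError("probe ranking needs at least 30 samples")
    if candidates is None:
        candidates = list(dataset.probe_ids)
    if not candidates:
        raise ValueError("candidate probe set is empty")

    target = dataset.probe_values(target_probe)
    y = (target > np.median(target)).astype(float)

    split_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    splits = _splits(dataset.n_samples, config.split_fractions, config.bootstraps, split_rng)

    rows = []
    for idx, probe in enumerate(candidates):
        x = _standardize(dataset.probe_values(probe))[:, None]
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, idx]))
        rmses, miscls = [], []
        for tr, te, va in splits:
            model = train_mlp(
                x[tr], y[tr], config, rng=rng,
                test_inputs=x[te], test_targets=y[te],
            )
            pred = model.predict(x[va])
            rmses.append(float(np.sqrt(np.mean((pred - y[va]) ** 2))))
            miscls.append(float(np.mean((pred > 0.5) != (y[va] > 0.5))))
        rows.append((probe, float(np.mean(rmses)), float(np.std(rmses)), float(np.mean(miscls))))

    table = pd.DataFrame(rows, columns=["probe_id", "mean_rmse", "sd_rmse", "misclassification"])
    table["rank"] = table["mean_rmse"].rank(method="first").astype(int)
    return ProbeRanking(table=table.sort_values("rank").reset_index(drop=True))


@dataclass(frozen=True)
class InteractionNetwork:
    """Directed, signed, weighted probe-interaction edges."""

    edges: tuple[tuple[str, str, float], ...]
    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(self.edges))
        object.__setattr__(self, "nodes", tuple(self.nodes))
        if any(s == t for s, t, _ in self.edges):
            raise ValueError("self-edges are not allowed")
        n = len(self.nodes)
        if len(self.edges) > n * (n - 1):
            raise ValueError("more edges than ordered pairs")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["source", "target", "weight"])


def infer_pairwise_interactions(
    dataset: ExpressionDataset,
    config: MLPConfig,
    probes: Sequence[str] | None = None,
) -> InteractionNetwork:
    """Signed influence weight for every ordered probe pair (m(m−1) edges).

    For each target probe, an MLP is trained on the remaining m−1
    standardized inputs over Monte-Carlo resamples (continuous target,
    min-max coded into [0, 1] on the training split); the influence of
    input i on target j is the resample-mean connection-weight product.
    """
    probes = list(dataset.probe_ids if probes is None else probes)
    m = len(probes)
    if m < 2:
        raise ValueError("interaction inference needs at least 2 probes")

    Z = np.vstack([_standardize(dataset.probe_values(p)) for p in probes])  # m × n
    n = Z.shape[1]
    split_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    splits = _splits(n, config.split_fractions, config.bootstraps, split_rng)

    edges = []
    for j, target in enumerate(probes):
        others = [i for i in range(m) if i != j]
        X = Z[others].T  # n × (m−1)
        z = Z[j]
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3, j]))
        cw = np.zeros(m - 1)
        for tr, te, va in splits:
            lo, hi = z[tr].min(), z[tr].max()
            span = hi - lo if hi > lo else 1.0
            y = np.clip((z - lo) / span, 0.0, 1.0)
            model = train_mlp(
                X[tr], y[tr], config, rng=rng,
                test_inputs=X[te], test_targets=y[te],
            )
            cw += model.connection_weights()
        cw /= len(splits)
        for pos, i in enumerate(others):
            edges.append((probes[i], target, float(cw[pos])))

    return InteractionNetwork(edges=tuple(edges), nodes=tuple(probes))


def select_top_edges_and_hubs(
    net: InteractionNetwork,
    top_k: int = 100,
    hub_degree: int = 5,
    n_top_hubs: int = 3,
) -> tuple[InteractionNetwork, pd.DataFrame]:
    """Keep the top_k strongest edges; flag hubs (≥ hub_degree incident edges).

    Hub strength is the summed |weight| over incident retained edges (in or
    out); the ``n_top_hubs`` strongest hubs are flagged ``top_hub``.
    """
    if net.n_edges == 0:
        raise ValueError("network has no edges")
    frame = net.to_frame()
    frame["abs_weight"] = frame["weight"].abs()
    kept = frame.sort_values("abs_weight", ascending=False, kind="stable").head(top_k)

    pruned = InteractionNetwork(
        edges=tuple(
            (r.source, r.target, r.weight) for r in kept.itertuples(index=False)
        ),
        nodes=net.nodes,
    )

    degree: dict[str, int] = {}
    strength: dict[str, float] = {}
    for source, target, weight in pruned.edges:
        for node in (source, target):
            degree[node] = degree.get(node, 0) + 1
            strength[node] = strength.get(node, 0.0) + abs(weight)

    hubs = pd.DataFrame(
        [
            {"node": node, "degree": deg, "strength": strength[node]}
            for node, deg in degree.items()
            if deg >= hub_degree
        ],
        columns=["node", "degree", "strength"],
    )
    hubs = hubs.sort_values("strength", ascending=False, kind="stable").reset_index(drop=True)
    hubs["rank"] = np.arange(1, len(hubs) + 1)
    hubs["top_hub"] = hubs["rank"] <= n_top_hubs
    return pruned, hubs
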