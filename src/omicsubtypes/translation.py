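"""Genomics-to-protein translation with per-view graph convolutional networks.

Each genomics view v gets its own two-layer GCN operating on the view's
patient similarity graph; the per-view outputs Y_v (all in protein space)
are fused by a (by default unweighted) mean into the predicted protein
matrix. Training is transductive: forward passes run over all N samples,
while the mean-squared loss is restricted to the n samples whose protein
expression is observed. After training, protein expression is predicted
for every sample, including those lacking measured protein data.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Adam, Tensor
from .datamodel import MultiOmicsDataset, OmicsMatrix
from .graph import SimilarityGraph, build_adjacency, default_neighbor_count
from .nn import GCNParams, gcn_layer, glorot_uniform, normalize_adjacency

__all__ = [
    "TranslationConfig",
    "TranslationModel",
    "view_forward",
    "fuse_views",
    "translation_loss",
    "train_translation",
    "predict_proteins",
]


@dataclasses.dataclass
class TranslationConfig:
    """Training settings for the translation module."""

    hidden_dim: int = 256
    epochs: int = 500
    learning_rate: float = 1e-3
    n_neighbors: int | None = None  # override the default K rule
    n_clusters: int | None = None  # feeds the K rule when n_neighbors is None
    fusion_weights: list[float] | None = None  # default: unweighted mean
    min_train_samples: int = 1


@dataclasses.dataclass
class TranslationModel:
    """Trained per-view GCNs plus the graphs and training log."""

    per_view_gcns: list[GCNParams]
    graphs: list[SimilarityGraph]
    fusion_weights: np.ndarray
    protein_feature_ids: list[str]
    training_log: list[float]
    seed: int


def view_forward(X_v, graph: SimilarityGraph, params: GCNParams):
    """Run one view through its two-layer GCN (numpy or Tensor input)."""
    A_norm = normalize_adjacency(graph.adjacency)
    values = X_v.values if isinstance(X_v, OmicsMatrix) else X_v
    return params.forward(values, A_norm)


def fuse_views(Ys: list[np.ndarray], weights=None) -> np.ndarray:
    """Weighted mean of per-view protein-space outputs (uniform by default)."""
    if not Ys:
        raise ValueError("no view outputs to fuse")
    shapes = {tuple(y.shape) for y in Ys}
    if len(shapes) > 1:
        raise ValueError(f"view outputs disagree in shape: {sorted(shapes)}")
    if weights is None:
        weights = np.full(len(Ys), 1.0 / len(Ys))
    else:
        weights = np.asarray(weights, dtype=np.float64)
        if weights.shape != (len(Ys),):
            raise ValueError("one fusion weight per view is required")
        weights = weights / weights.sum()
    out = weights[0] * Ys[0]
    for w, y in zip(weights[1:], Ys[1:]):
        out = out + w * y
    return out


def translation_loss(P: np.ndarray, P_hat: np.ndarray, mask: np.ndarray) -> float:
    """(1/n) * squared Frobenius norm of (P - P_hat) over masked rows only."""
    P = np.asarray(P, dtype=np.float64)
    P_hat = np.asarray(P_hat, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if P.shape != P_hat.shape:
        raise ValueError("P and P_hat must have the same shape")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no protein-observed samples: the loss is undefined")
    diff = P[mask] - P_hat[mask]
    return float(np.sum(diff * diff) / n)


def _resolve_k(n_samples: int, config: TranslationConfig) -> int:
    if config.n_neighbors is not None:
        return int(config.n_neighbors)
    return default_neighbor_count(n_samples, config.n_clusters)


def train_translation(
    dataset: MultiOmicsDataset,
    config: TranslationConfig | None = None,
    seed: int = 0,
) -> TranslationModel:
    """Jointly train all per-view GCNs against the masked translation loss.

    All graphs and forward passes include every sample (transductive);
    only protein-observed samples contribute to the loss. Weights are
    Glorot-uniform initialized from `seed`, optimized with Adam.
    """
    config = config or TranslationConfig()
    n = dataset.n_observed
    if n < config.min_train_samples:
        raise ValueError(
            f"only {n} protein-observed samples; need >= {config.min_train_samples}"
        )
    N = dataset.n_samples
    d_protein = dataset.protein.n_features
    K = _resolve_k(N, config)
    rng = np.random.default_rng(seed)

    graphs = [build_adjacency(v.values, K) for v in dataset.views]
    A_norms = [normalize_adjacency(g.adjacency) for g in graphs]
    Xs = [v.values for v in dataset.views]

    params: list[tuple[Tensor, Tensor]] = []
    for v in dataset.views:
        W1 = Tensor(glorot_uniform(rng, v.n_features, config.hidden_dim), requires_grad=True)
        W2 = Tensor(glorot_uniform(rng, config.hidden_dim, d_protein), requires_grad=True)
        params.append((W1, W2))

    if config.fusion_weights is None:
        fusion = np.full(len(Xs), 1.0 / len(Xs))
    else:
        fusion = np.asarray(config.fusion_weights, dtype=np.float64)
        if fusion.shape != (len(Xs),):
            raise ValueError("one fusion weight per view is required")
        fusion = fusion / fusion.sum()

    mask_col = dataset.protein_mask.astype(np.float64)[:, None]
    P = dataset.protein.values

    opt = Adam([w for pair in params for w in pair], lr=config.learning_rate)
    log: list[float] = []
    for epoch in range(config.epochs):
        opt.zero_grad()
        P_hat = None
        for (W1, W2), A_norm, X, w in zip(params, A_norms, Xs, fusion):
            H = gcn_layer(X, A_norm, W1, "relu")
            Y = gcn_layer(H, A_norm, W2, "identity")
            P_hat = w * Y if P_hat is None else P_hat + w * Y
        diff = (P_hat - P) * mask_col
        loss = (diff * diff).sum() / n
        value = loss.item()
        if not np.isfinite(value):
            raise FloatingPointError(
                f"translation loss became non-finite at epoch {epoch}"
            )
        log.append(value)
        loss.backward()
        opt.step()

    gcns = [
        GCNParams([W1.data.copy(), W2.data.copy()], ("relu", "identity"))
        for (W1, W2) in params
    ]
    return TranslationModel(
        per_view_gcns=gcns,
        graphs=graphs,
        fusion_weights=fusion,
        protein_feature_ids=list(dataset.protein.feature_ids),
        training_log=log,
        seed=int(seed),
    )


def predict_proteins(model: TranslationModel, dataset: MultiOmicsDataset) -> OmicsMatrix:
    """Predict protein expression for ALL samples (mask-independent)."""
    if not model.per_view_gcns:
        raise ValueError("model has no trained GCNs")
    Ys = [
        view_forward(v, g, p)
        for v, g, p in zip(dataset.views, model.graphs, model.per_view_gcns)
    ]
    P_hat = fuse_views(Ys, model.fusion_weights)
    return OmicsMatrix(
        "predicted_protein",
        list(dataset.sample_ids),
        list(model.protein_feature_ids),
        P_hat,
    )


def write_training_log(log: list[float], path) -> None:
    """Per-epoch loss log as `epoch<TAB>loss`."""
    with open(path, "w") as fh:
        fh.write("epoch\tloss\n")
        for i, v in enumerate(log):
            fh.write(f"{i}\t{v:.10g}\n")
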