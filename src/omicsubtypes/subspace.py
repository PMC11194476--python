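"""Deep subspace clustering with a contrastive self-expression layer.

A two-layer GCN encoder embeds the predicted protein matrix as Z; a
fully connected self-expression layer (no bias, no activation, zero
diagonal) re-expresses each embedded sample as a linear combination of
the others, Zhat = C Z; a mirrored GCN decoder reconstructs the input
from Zhat. Training minimizes

    lambda1 * L_rec + lambda2 * ||C||_F^2 + lambda3 * sum_i l_i

where L_rec = (1/N) ||P - decoded||_F^2 and l_i is a contrastive loss
treating (z_i, zhat_i) as the positive pair and (z_i, zhat_j), j != i,
as negatives. The learned coefficients C are symmetrized into an
affinity S = (|C| + |C^T|)/2, from which the normalized Laplacian
L = I - D^{-1/2} S D^{-1/2} and a spectral clustering of its k smallest
eigenvectors produce the final subtype labels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .autodiff import Adam, Tensor
from .datamodel import OmicsMatrix
from .graph import SimilarityGraph, build_adjacency, default_neighbor_count
from .nn import GCNParams, gcn_layer, glorot_uniform, normalize_adjacency

__all__ = [
    "DsccConfig",
    "SelfExpressionModel",
    "ClusterResult",
    "encode",
    "self_express",
    "reconstruction_loss",
    "contrastive_self_expression_loss",
    "joint_loss",
    "train_dscc",
    "ridge_self_expression_oracle",
    "affinity_from_coefficients",
    "normalized_laplacian",
    "spectral_cluster",
    "cluster_coefficients",
]


@dataclasses.dataclass
class DsccConfig:
    """Settings for deep subspace contrastive clustering training."""

    encoder_dims: tuple[int, int] = (200, 100)
    # reconstruction-only pretraining is available but off by default: a
    # reconstruction-optimal encoder initializes the joint phase in a basin
    # where C settles into a diffuse minimum with poor cluster contrast
    pretrain_epochs: int = 0
    joint_epochs: int = 500
    learning_rate: float = 1e-3
    lambda1: float = 0.01
    lambda2: float = 1.0
    lambda3: float = 1.0
    n_neighbors: int | None = None
    n_clusters: int | None = None  # feeds the default K rule
    kmeans_restarts: int = 50
    c_init_scale: float = 1e-4
    # ReLU on the encoder output keeps the embedding nonnegative, so
    # cosine-based losses and the |C| affinity cannot conflate a cluster
    # with the negation of another (z-scored inputs are sign-symmetric)
    encoder_final_activation: str = "relu"
    identity_autoencoder: bool = False  # freeze encoder/decoder to identity maps
    inclusive_contrastive: bool = False  # include j=i in the denominator


@dataclasses.dataclass
class SelfExpressionModel:
    """Trained encoder/decoder, coefficient matrix C, and training history."""

    encoder: GCNParams | None
    decoder: GCNParams | None
    C: np.ndarray
    lambdas: tuple[float, float, float]
    graph: SimilarityGraph
    training_log: list[dict]
    seed: int

    def __post_init__(self) -> None:
        if not np.all(np.diag(self.C) == 0):
            raise ValueError("C must have a zero diagonal")
        if any(l < 0 for l in self.lambdas):
            raise ValueError("lambda weights must be nonnegative")


@dataclasses.dataclass
class ClusterResult:
    """Subtype labels (1..k) with the spectral intermediates."""

    labels: np.ndarray
    affinity: np.ndarray
    laplacian: np.ndarray
    embedding: np.ndarray
    k: int
    seed: int


# ---------------------------------------------------------------------------
# forward operations
# ---------------------------------------------------------------------------


def encode(P, graph: SimilarityGraph, encoder: GCNParams):
    """Embed the (predicted) protein matrix with the two-layer GCN encoder."""
    values = P.values if isinstance(P, OmicsMatrix) else P
    return encoder.forward(values, normalize_adjacency(graph.adjacency))


def self_express(Z: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Zhat = C @ Z with the zero-diagonal constraint enforced."""
    Z = np.asarray(Z, dtype=np.float64)
    C = np.asarray(C, dtype=np.float64)
    if C.shape != (Z.shape[0], Z.shape[0]):
        raise ValueError("C must be N x N for N samples")
    if np.any(np.diag(C) != 0):
        raise ValueError("self-expression requires diag(C) = 0")
    return C @ Z


def reconstruction_loss(P: np.ndarray, decoded: np.ndarray) -> float:
    """(1/N) * squared Frobenius norm of (P - decoded), N = all samples."""
    P = np.asarray(P, dtype=np.float64)
    decoded = np.asarray(decoded, dtype=np.float64)
    if P.shape != decoded.shape:
        raise ValueError("P and decoded must have the same shape")
    diff = P - decoded
    return float(np.sum(diff * diff) / P.shape[0])


def _contrastive_core(Z: Tensor, Zhat: Tensor, inclusive: bool, eps: float) -> Tensor:
    """Tensor-graph contrastive self-expression loss (sum over samples).

    l_i = -s(z_i, zhat_i) + log sum_{j != i} exp(s(z_i, zhat_j)),
    numerically stabilized by subtracting the row maximum (a constant).
    """
    zn = Z / ((Z * Z).sum(axis=1, keepdims=True) + eps).sqrt()
    hn = Zhat / ((Zhat * Zhat).sum(axis=1, keepdims=True) + eps).sqrt()
    S = zn @ hn.T
    n = S.data.shape[0]
    eye = np.eye(n)
    row_max = S.data.max(axis=1, keepdims=True)  # detached constant
    ex = (S - row_max).exp()
    if not inclusive:
        ex = ex * (1.0 - eye)
    lse = ex.sum(axis=1, keepdims=True).log() + row_max
    pos = (S * eye).sum(axis=1, keepdims=True)
    return (lse - pos).sum()


def contrastive_self_expression_loss(
    Z: np.ndarray, Zhat: np.ndarray, inclusive: bool = False
) -> float:
    """Sum over samples of the contrastive loss on cosine similarities.

    The denominator runs over j != i (the positive pair is excluded)
    unless `inclusive` is set.
    """
    Z = np.asarray(Z, dtype=np.float64)
    Zhat = np.asarray(Zhat, dtype=np.float64)
    if Z.shape != Zhat.shape:
        raise ValueError("Z and Zhat must have the same shape")
    if Z.shape[0] < 2:
        raise ValueError("the contrastive loss needs at least two samples")
    for name, M in (("Z", Z), ("Zhat", Zhat)):
        norms = np.linalg.norm(M, axis=1)
        if np.any(norms == 0):
            raise ValueError(f"{name} has zero rows; cosine similarity undefined")
    return _contrastive_core(Tensor(Z), Tensor(Zhat), inclusive, 0.0).item()


def joint_loss(
    P: np.ndarray,
    decoded: np.ndarray,
    Z: np.ndarray,
    Zhat: np.ndarray,
    C: np.ndarray,
    lambdas: tuple[float, float, float] = (0.01, 1.0, 1.0),
) -> float:
    """lambda1 * L_rec + lambda2 * ||C||_F^2 + lambda3 * sum_i l_i."""
    l1, l2, l3 = lambdas
    total = l1 * reconstruction_loss(P, decoded) + l2 * float(np.sum(C * C))
    if l3 != 0:
        total += l3 * contrastive_self_expression_loss(Z, Zhat)
    return float(total)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _resolve_k(n_samples: int, config: DsccConfig) -> int:
    if config.n_neighbors is not None:
        return int(config.n_neighbors)
    return default_neighbor_count(n_samples, config.n_clusters)


def train_dscc(
    P, config: DsccConfig | None = None, seed: int = 0
) -> SelfExpressionModel:
    """Train the deep subspace contrastive clustering model on a feature matrix.

    Optionally starts with autoencoder pretraining on the reconstruction
    term alone (decoder fed directly from Z; off by default), then jointly
    trains encoder, decoder and C on the full objective, with diag(C)
    hard-masked to zero throughout. With `identity_autoencoder` the
    encoder and decoder are frozen identity maps and only C is trained
    (used for oracle checks).

    The patient graph is rebuilt from `P` with the weighted-KNN rule;
    the predicted protein matrix is the intended input.
    """
    config = config or DsccConfig()
    values = P.values if isinstance(P, OmicsMatrix) else np.asarray(P, dtype=np.float64)
    N = values.shape[0]
    if N < 4:
        raise ValueError("deep subspace clustering needs at least 4 samples")
    rng = np.random.default_rng(seed)
    K = _resolve_k(N, config)
    graph = build_adjacency(values, K)
    A_norm = normalize_adjacency(graph.adjacency)
    lambdas = (config.lambda1, config.lambda2, config.lambda3)
    off_diag = 1.0 - np.eye(N)
    log: list[dict] = []

    if config.identity_autoencoder:
        enc_params = dec_params = None
        trainable: list[Tensor] = []
    else:
        d_in = values.shape[1]
        d1, d2 = config.encoder_dims
        We1 = Tensor(glorot_uniform(rng, d_in, d1), requires_grad=True)
        We2 = Tensor(glorot_uniform(rng, d1, d2), requires_grad=True)
        Wd1 = Tensor(glorot_uniform(rng, d2, d1), requires_grad=True)
        Wd2 = Tensor(glorot_uniform(rng, d1, d_in), requires_grad=True)
        trainable = [We1, We2, Wd1, Wd2]

    C = Tensor(
        config.c_init_scale * rng.standard_normal((N, N)) * off_diag,
        requires_grad=True,
    )

    def encode_t():
        if config.identity_autoencoder:
            return Tensor(values)
        H = gcn_layer(values, A_norm, We1, "relu")
        return gcn_layer(H, A_norm, We2, config.encoder_final_activation)

    def decode_t(Zlike):
        if config.identity_autoencoder:
            return Zlike
        H = gcn_layer(Zlike, A_norm, Wd1, "relu")
        return gcn_layer(H, A_norm, Wd2, "identity")

    def check_finite(name, value, epoch, phase):
        if not np.isfinite(value):
            raise FloatingPointError(
                f"{name} became non-finite at {phase} epoch {epoch}"
            )

    # phase 1: reconstruction-only pretraining of the autoencoder
    if not config.identity_autoencoder and config.pretrain_epochs > 0:
        opt = Adam(trainable, lr=config.learning_rate)
        for epoch in range(config.pretrain_epochs):
            opt.zero_grad()
            Z = encode_t()
            decoded = decode_t(Z)
            diff = decoded - values
            rec = (diff * diff).sum() / N
            loss = config.lambda1 * rec
            check_finite("reconstruction loss", loss.item(), epoch, "pretraining")
            log.append(
                {"phase": "pretrain", "epoch": epoch, "total": loss.item(),
                 "rec": rec.item(), "cnorm": 0.0, "contrastive": 0.0}
            )
            loss.backward()
            opt.step()

    # phase 2: joint training of encoder, decoder and C
    opt = Adam(trainable + [C], lr=config.learning_rate)
    for epoch in range(config.joint_epochs):
        opt.zero_grad()
        C_masked = C * off_diag
        Z = encode_t()
        Zhat = C_masked @ Z
        decoded = decode_t(Zhat)
        diff = decoded - values
        rec = (diff * diff).sum() / N
        cnorm = (C_masked * C_masked).sum()
        loss = config.lambda1 * rec + config.lambda2 * cnorm
        contrastive_value = 0.0
        if config.lambda3 != 0:
            # eps keeps row norms positive while C is still near zero
            contr = _contrastive_core(Z, Zhat, config.inclusive_contrastive, 1e-12)
            contrastive_value = contr.item()
            loss = loss + config.lambda3 * contr
        check_finite("joint loss", loss.item(), epoch, "joint")
        check_finite("reconstruction term", rec.item(), epoch, "joint")
        check_finite("contrastive term", contrastive_value, epoch, "joint")
        log.append(
            {"phase": "joint", "epoch": epoch, "total": loss.item(),
             "rec": rec.item(), "cnorm": cnorm.item(),
             "contrastive": contrastive_value}
        )
        loss.backward()
        opt.step()
        C.data *= off_diag  # re-assert the zero diagonal after each update

    encoder = decoder = None
    if not config.identity_autoencoder:
        encoder = GCNParams(
            [We1.data.copy(), We2.data.copy()],
            ("relu", config.encoder_final_activation),
        )
        decoder = GCNParams([Wd1.data.copy(), Wd2.data.copy()])
    return SelfExpressionModel(
        encoder=encoder,
        decoder=decoder,
        C=C.data * off_diag,
        lambdas=lambdas,
        graph=graph,
        training_log=log,
        seed=int(seed),
    )


def ridge_self_expression_oracle(Z: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge self-expression: independent per-row solutions of

        min_c ||c||^2 + lam * ||z_i - sum_{j != i} c_j z_j||^2

    arranged into a zero-diagonal N x N matrix. Serves as an independent
    oracle for the trained C when the contrastive term is switched off.
    """
    Z = np.asarray(Z, dtype=np.float64)
    N = Z.shape[0]
    if N < 2:
        raise ValueError("need at least two samples")
    if lam <= 0:
        raise ValueError("lam must be positive")
    C = np.zeros((N, N))
    for i in range(N):
        others = np.delete(np.arange(N), i)
        G = Z[others]  # (N-1) x d
        c = lam * np.linalg.solve(np.eye(N - 1) + lam * (G @ G.T), G @ Z[i])
        C[i, others] = c
    return C


# ---------------------------------------------------------------------------
# spectral clustering
# ---------------------------------------------------------------------------


def affinity_from_coefficients(C: np.ndarray) -> np.ndarray:
    """S_ij = (|C_ij| + |C_ji|) / 2: symmetric, nonnegative."""
    C = np.asarray(C, dtype=np.float64)
    return (np.abs(C) + np.abs(C.T)) / 2.0


def normalized_laplacian(S: np.ndarray) -> np.ndarray:
    """L = I - D^{-1/2} S D^{-1/2} with D the diagonal of row sums.

    Zero-degree rows keep D^{-1/2} = 0, so isolated samples stay isolated.
    """
    S = np.asarray(S, dtype=np.float64)
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if np.any(S < 0):
        raise ValueError("affinity must be nonnegative")
    d = S.sum(axis=1)
    inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    L = np.eye(S.shape[0]) - S * inv_sqrt[:, None] * inv_sqrt[None, :]
    return (L + L.T) / 2.0  # kill asymmetric round-off


def spectral_cluster(
    S: np.ndarray, k: int, seed: int = 0, kmeans_restarts: int = 50
) -> ClusterResult:
    """Spectral clustering of an affinity matrix into k subtypes.

    The embedding B holds the eigenvectors of the normalized Laplacian
    for its k smallest eigenvalues (minimizing trace(B^T L B) under
    B^T B = I); rows are unit-normalized and clustered with seeded
    k-means (multiple restarts). Labels are numbered from 1.
    """
    S = np.asarray(S, dtype=np.float64)
    N = S.shape[0]
    if not 1 <= k <= N:
        raise ValueError(f"k={k} outside [1, {N}]")
    L = normalized_laplacian(S)
    eigvals, eigvecs = eigh(L)
    B = eigvecs[:, :k]
    norms = np.linalg.norm(B, axis=1)
    B_rows = B / np.where(norms > 0, norms, 1.0)[:, None]
    if k == 1:
        labels = np.ones(N, dtype=int)
    else:
        km = KMeans(
            n_clusters=k,
            n_init=kmeans_restarts,
            random_state=int(seed) % (2**31),
        ).fit(B_rows)
        labels = km.labels_.astype(int) + 1
    return ClusterResult(
        labels=labels,
        affinity=S,
        laplacian=L,
        embedding=B,
        k=int(k),
        seed=int(seed),
    )


def cluster_coefficients(
    model: SelfExpressionModel, k: int, seed: int = 0, kmeans_restarts: int = 50
) -> ClusterResult:
    """Affinity -> Laplacian -> spectral clustering of a trained model's C."""
    return spectral_cluster(
        affinity_from_coefficients(model.C), k, seed=seed, kmeans_restarts=kmeans_restarts
    )
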