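"""Graph-convolutional network primitives shared by translation and clustering.

A GCN layer propagates node features through the renormalized adjacency
operator D^{-1/2} (A + I) D^{-1/2}; every network in this package is two
layers deep (ReLU on the hidden layer, identity on the output layer).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor

__all__ = ["GCNParams", "normalize_adjacency", "gcn_layer", "glorot_uniform"]

_ACTIVATIONS = ("relu", "identity")


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Return D^{-1/2} (A + I) D^{-1/2} for a symmetric nonnegative adjacency.

    Self-loops (the added identity) guarantee every degree is >= 1, so the
    inverse square root is always finite.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.any(A < 0):
        raise ValueError("adjacency must be nonnegative")
    A_hat = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_hat.sum(axis=1))
    return A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_layer(H, A_norm, W, activation: str = "identity"):
    """One graph-convolution layer: activation(A_norm @ H @ W).

    Accepts numpy arrays (inference) or autodiff Tensors (training) for
    any argument; the result is a Tensor iff any input is a Tensor.
    """
    if activation not in _ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    h_cols = H.shape[1]
    w_rows = W.shape[0]
    if A_norm.shape[1] != H.shape[0] or h_cols != w_rows:
        raise ValueError(
            f"shape mismatch: A_norm {A_norm.shape}, H {H.shape}, W {W.shape}"
        )
    out = A_norm @ (H @ W)
    if activation == "relu":
        out = out.relu() if isinstance(out, Tensor) else np.maximum(out, 0.0)
    return out


@dataclasses.dataclass
class GCNParams:
    """Weights of a two-layer GCN: input -> hidden (ReLU) -> output (identity)."""

    layer_weights: list[np.ndarray]
    activations: tuple[str, str] = ("relu", "identity")

    def __post_init__(self) -> None:
        if len(self.layer_weights) != 2:
            raise ValueError("a GCN comprises exactly two layers")
        self.layer_weights = [np.asarray(w, dtype=np.float64) for w in self.layer_weights]
        w1, w2 = self.layer_weights
        if w1.shape[1] != w2.shape[0]:
            raise ValueError("layer shapes do not chain: "
                             f"{w1.shape} then {w2.shape}")
        for a in self.activations:
            if a not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}")

    @property
    def input_dim(self) -> int:
        return self.layer_weights[0].shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.layer_weights[0].shape[1]

    @property
    def output_dim(self) -> int:
        return self.layer_weights[1].shape[1]

    def forward(self, H, A_norm):
        """Two chained gcn_layer calls (numpy or Tensor inputs)."""
        out = gcn_layer(H, A_norm, self.layer_weights[0], self.activations[0])
        return gcn_layer(out, A_norm, self.layer_weights[1], self.activations[1])


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))
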