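"""Node-adaptive feature smoothing (NAFS): training-free local embeddings.

Features are propagated with the generalized normalized adjacency
``G_hat = D~^(r-1) G~ D~^(-r)`` of the self-looped graph.  Repeated
propagation converges to a rank-one stationary limit and erases node
identity (over-smoothing); NAFS weights each smoothing depth per node by a
softmax over the node's Euclidean distance to that stationary limit, so
nodes keep the depths at which they are still distinguishable.  An
ensemble over several ``r`` values is combined by mean / max /
concatenation, or a single ``r`` is used ("simple").
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

__all__ = [
    "NafsConfig",
    "normalized_adjacency",
    "stationary_limit",
    "nafs_smooth",
    "nafs_ensemble",
    "project_and_stack",
]


@dataclass
class NafsConfig:
    """Smoothing depth, normalization exponents and ensemble mode."""

    k: int = 7
    r_list: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    combine: str = "mean"  # mean | max | concat | simple
    # Smooth over the weighted heterogeneous network itself by default: the
    # integrated similarities are strictly positive almost everywhere (GIP
    # fallback), so a >0-binarized graph is near-complete and structureless.
    weighted_gtilde: bool = True

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("max smoothing steps must be >= 0")
        if not self.r_list:
            raise ValueError("r-list must be nonempty")
        if any(not (0.0 <= r <= 1.0) for r in self.r_list):
            raise ValueError("every r must lie in [0, 1]")
        if self.combine not in ("mean", "max", "concat", "simple"):
            raise ValueError(f"unknown combine mode {self.combine!r}")


def _self_looped(adj: np.ndarray, weighted: bool = False) -> np.ndarray:
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {adj.shape}")
    if weighted:
        return adj
    G = adj.copy()
    np.fill_diagonal(G, 1.0)
    return G


def normalized_adjacency(
    adj: np.ndarray, r: float, weighted: bool = False
) -> np.ndarray:
    """G_hat = D~^(r-1) G~ D~^(-r) over the self-looped graph."""
    G = _self_looped(adj, weighted)
    deg = G.sum(axis=1)
    return (deg[:, None] ** (r - 1.0)) * G * (deg[None, :] ** (-r))


def stationary_limit(
    adj: np.ndarray, r: float, weighted: bool = False
) -> np.ndarray:
    """Closed-form limit of G_hat^k: rank-one in the self-looped degrees.

    Entry (i, j) is ``(d_i + 1)^r (d_j + 1)^(1-r) / (2m + n)`` for a simple
    graph with degrees d, m edges and n nodes; implemented through the
    self-looped degree vector so the weighted variant is consistent.
    """
    G = _self_looped(adj, weighted)
    deg = G.sum(axis=1)  # = d_i + 1 for a binary simple graph
    return (deg[:, None] ** r) * (deg[None, :] ** (1.0 - r)) / deg.sum()


def nafs_smooth(
    adj: np.ndarray,
    X: np.ndarray,
    k: int,
    r: float,
    weighted: bool = False,
    return_weights: bool = False,
):
    """Adaptively weighted sum of the 0..k-step smoothed features.

    Per node i, depth k gets weight softmax_k(D_i(k)) where D_i(k) is the
    Euclidean distance between the k-step smoothed row and the stationary
    limit row; the weighted sum over depths is the smoothed feature matrix.
    """
    if k < 0:
        raise ValueError("max smoothing steps must be >= 0")
    X = np.asarray(X, dtype=float)
    G_hat = normalized_adjacency(adj, r, weighted)
    if X.shape[0] != G_hat.shape[0]:
        raise ValueError("feature row count must equal node count")
    X_inf = stationary_limit(adj, r, weighted) @ X

    levels = [X]
    for _ in range(k):
        levels.append(G_hat @ levels[-1])
    # distances to the over-smoothed limit, one column per depth
    dist = np.stack(
        [np.linalg.norm(Xl - X_inf, axis=1) for Xl in levels], axis=1
    )
    shifted = dist - dist.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    weights = expd / expd.sum(axis=1, keepdims=True)

    X_hat = np.zeros_like(X)
    for l, Xl in enumerate(levels):
        X_hat += weights[:, l][:, None] * Xl
    if return_weights:
        return X_hat, weights
    return X_hat


def nafs_ensemble(
    adj: np.ndarray, X: np.ndarray, cfg: NafsConfig
) -> np.ndarray:
    """Combine the smoothed features over the configured r-list."""
    if cfg.combine == "simple":
        return nafs_smooth(adj, X, cfg.k, cfg.r_list[0], cfg.weighted_gtilde)
    smoothed = [
        nafs_smooth(adj, X, cfg.k, r, cfg.weighted_gtilde) for r in cfg.r_list
    ]
    if cfg.combine == "mean":
        return np.mean(smoothed, axis=0)
    if cfg.combine == "max":
        return np.max(smoothed, axis=0)
    return np.concatenate(smoothed, axis=1)  # concat


def project_and_stack(Z_L, Z_D, W_LD, b_LD):
    """Affine-map lncRNA rows to disease width and stack with disease rows.

    Row i of the top block is ``W_LD @ Z_L[i] + b_LD``; the bottom block is
    Z_D unchanged.  Differentiable in (W_LD, b_LD), which are trained with
    the rest of the model.
    """
    if Z_L.shape[1] != W_LD.shape[1] or Z_D.shape[1] != W_LD.shape[0]:
        raise ValueError(
            f"affine shapes inconsistent: Z_L {Z_L.shape}, Z_D {Z_D.shape}, "
            f"W_LD {W_LD.shape}"
        )
    top = anp.dot(Z_L, anp.transpose(W_LD)) + b_LD
    return anp.concatenate([top, Z_D], axis=0)
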