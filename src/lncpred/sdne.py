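"""Structural deep network embedding (SDNE) of the similarity networks.

A logistic-activation autoencoder maps each node's adjacency row down to a
low-dimensional code and reconstructs it.  The loss couples

* second-order proximity: a reconstruction error in which observed edges
  are over-weighted by ``beta > 1`` so the sparse 1-entries are not drowned
  out by the zeros,
* first-order proximity: adjacent nodes are pulled together in code space,
* an L2 penalty on the encoder / decoder weights.

One autoencoder per similarity network (lncRNA and disease); their codes
are stacked into the structural bias SF handed to the fusion Transformer,
and their losses join the global objective rather than being minimized
privately.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

__all__ = [
    "SdneConfig",
    "init_sdne_params",
    "sdne_forward",
    "sdne_loss",
    "build_structure_bias",
]


@dataclass
class SdneConfig:
    """Widths and loss weights of one SDNE autoencoder."""

    nhid1: int = 64
    n_p: int = 32
    alpha: float = 1e-6  # first-order proximity weight
    beta: float = 5.0  # reconstruction over-weight of observed edges
    nu1: float = 1e-5  # encoder L2 weight
    nu2: float = 1e-4  # decoder L2 weight

    def __post_init__(self) -> None:
        if self.beta <= 1:
            raise ValueError("beta must exceed 1 (edge over-weighting)")
        if min(self.nhid1, self.n_p) < 1:
            raise ValueError("layer widths must be positive")


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def init_sdne_params(
    n_nodes: int, cfg: SdneConfig, rng: np.random.Generator
) -> dict:
    """Two-layer encoder (n -> nhid1 -> n_p) with a mirrored decoder."""
    return {
        "W1": _glorot(rng, n_nodes, cfg.nhid1),
        "b1": np.zeros(cfg.nhid1),
        "W2": _glorot(rng, cfg.nhid1, cfg.n_p),
        "b2": np.zeros(cfg.n_p),
        "W3": _glorot(rng, cfg.n_p, cfg.nhid1),
        "b3": np.zeros(cfg.nhid1),
        "W4": _glorot(rng, cfg.nhid1, n_nodes),
        "b4": np.zeros(n_nodes),
    }


def _sigmoid(x):
    return 1.0 / (1.0 + anp.exp(-x))


def sdne_forward(M, params):
    """Encode adjacency rows to codes Y and decode a reconstruction.

    Returns ``(Y, M_rec)`` with Y of shape (n_nodes, n_p) and M_rec in
    (0, 1) elementwise (logistic output layer).
    """
    M = M * 1.0
    if params["W1"].shape[0] != M.shape[1]:
        raise ValueError(
            f"input width {M.shape[1]} inconsistent with encoder "
            f"({params['W1'].shape[0]} expected)"
        )
    h = _sigmoid(anp.dot(M, params["W1"]) + params["b1"])
    Y = _sigmoid(anp.dot(h, params["W2"]) + params["b2"])
    g = _sigmoid(anp.dot(Y, params["W3"]) + params["b3"])
    M_rec = _sigmoid(anp.dot(g, params["W4"]) + params["b4"])
    return Y, M_rec


def sdne_loss(M, M_rec, Y, params, cfg: SdneConfig) -> dict:
    """Second-order, first-order, regularization and total SDNE losses."""
    M = M * 1.0
    B = 1.0 + (cfg.beta - 1.0) * M  # beta where an edge exists, 1 elsewhere
    l_2nd = anp.sum(((M_rec - M) * B) ** 2)
    # sum_ij M_ij ||y_i - y_j||^2 = 2 tr(Y^T (D - M) Y)
    deg = anp.sum(M, axis=1)
    lap_y = deg[:, None] * Y - anp.dot(M, Y)
    l_1st = 2.0 * anp.sum(Y * lap_y)
    enc = anp.sum(params["W1"] ** 2) + anp.sum(params["W2"] ** 2)
    dec = anp.sum(params["W3"] ** 2) + anp.sum(params["W4"] ** 2)
    l_reg = 0.5 * (cfg.nu1 * enc + cfg.nu2 * dec)
    total = l_2nd + cfg.alpha * l_1st + l_reg
    return {"l_2nd": l_2nd, "l_1st": l_1st, "l_reg": l_reg, "total": total}


def build_structure_bias(I_net, D_net, params_l, params_d, cfg: SdneConfig):
    """Stacked structural bias SF = [codes of I_net; codes of D_net].

    Returns ``(SF, loss_l, loss_d)`` where the two loss dicts are meant to
    be added to the global training objective.
    """
    Y_l, rec_l = sdne_forward(I_net, params_l)
    Y_d, rec_d = sdne_forward(D_net, params_d)
    loss_l = sdne_loss(I_net, rec_l, Y_l, params_l, cfg)
    loss_d = sdne_loss(D_net, rec_d, Y_d, params_d, cfg)
    SF = anp.concatenate([Y_l, Y_d], axis=0)
    return SF, loss_l, loss_d
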