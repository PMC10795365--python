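"""Global-level Transformer embedding and two-attention-layer fusion.

The global encoder runs stacked multi-head self-attention + feed-forward
blocks (post-norm residual sub-layers) over the NAFS-smoothed heterogeneous
network features.  The fusion stage then merges three node-aligned inputs
-- the global embedding X, the stacked local embedding Z_LD, and the SDNE
structural bias SF -- with blocks that contain *two* attention sub-layers:
the first attends over the current embedding, the second over the current
embedding concatenated with (a projection of) SF, injecting network
structure into an architecture that has no message-passing of its own.

No positional encodings are used: node identity enters only through the
inputs, so every block is permutation-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np

__all__ = [
    "EncoderConfig",
    "multi_head_attention",
    "attention_weights",
    "feed_forward",
    "global_encode",
    "fuse",
    "init_global_params",
    "init_fusion_params",
]


@dataclass
class EncoderConfig:
    """Depths, head counts and widths of the two Transformer stages."""

    l1: int = 10  # global encoder depth
    l2: int = 20  # fusion depth
    h1: int = 8  # global heads
    h2: int = 64  # fusion heads
    width: int = 64  # n_h = n_h': model width of both stages
    ffn_width: int = 128
    out_dim: int = 64  # f: final embedding size
    dropout: float = 0.4
    leaky_slope: float = 0.01
    two_stacks: bool = False
    paper_softmax: bool = False

    def __post_init__(self) -> None:
        if self.width % self.h1 or self.width % self.h2:
            raise ValueError(
                f"model width {self.width} must be divisible by both head "
                f"counts ({self.h1}, {self.h2})"
            )
        if self.out_dim < 1:
            raise ValueError("out_dim must be >= 1")


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


def leaky_relu(x, slope: float = 0.01):
    return anp.where(x >= 0, x, slope * x)


def layer_norm(x, g, b, eps: float = 1e-6):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return g * (x - mu) / anp.sqrt(var + eps) + b


def dropout(x, rate: float, rng: np.random.Generator | None):
    """Inverted dropout; identity when rng is None (evaluation mode)."""
    if rng is None or rate <= 0.0:
        return x
    mask = (rng.random(np.shape(x)) >= rate) / (1.0 - rate)
    return x * mask


def attention_weights(Z, params, n_head: int, paper_softmax: bool = False):
    """Per-head attention weight tensor of shape (n_head, n, n)."""
    n = Z.shape[0]
    d_model = params["Wq"].shape[1]
    if d_model % n_head:
        raise ValueError(
            f"attention width {d_model} not divisible by {n_head} heads"
        )
    d_head = d_model // n_head
    Q = anp.swapaxes(
        anp.reshape(anp.dot(Z, params["Wq"]), (n, n_head, d_head)), 0, 1
    )
    K = anp.swapaxes(
        anp.reshape(anp.dot(Z, params["Wk"]), (n, n_head, d_head)), 0, 1
    )
    logits = anp.matmul(Q, anp.swapaxes(K, 1, 2)) / anp.sqrt(d_head)
    if paper_softmax:
        # normalize the exponentiated logits across heads, as an alternative
        # reading of the attention normalization; not row-stochastic
        expl = anp.exp(logits - anp.max(logits))
        return expl / anp.sum(expl, axis=0, keepdims=True)
    shifted = logits - anp.max(logits, axis=2, keepdims=True)
    expl = anp.exp(shifted)
    return expl / anp.sum(expl, axis=2, keepdims=True)


def multi_head_attention(
    Z, params, n_head: int, paper_softmax: bool = False
):
    """Scaled dot-product multi-head self-attention with output projection."""
    n = Z.shape[0]
    d_model = params["Wv"].shape[1]
    d_head = d_model // n_head
    W = attention_weights(Z, params, n_head, paper_softmax)
    V = anp.swapaxes(
        anp.reshape(anp.dot(Z, params["Wv"]), (n, n_head, d_head)), 0, 1
    )
    heads = anp.swapaxes(anp.matmul(W, V), 0, 1)  # back to (n, head, d_head)
    concat = anp.reshape(heads, (n, d_model))
    return anp.dot(concat, params["Wh"])


def feed_forward(T, params, slope: float = 0.01):
    """Two LeakyReLU-activated affine layers."""
    h = leaky_relu(anp.dot(T, params["W1"]) + params["b1"], slope)
    return leaky_relu(anp.dot(h, params["W2"]) + params["b2"], slope)


# Residual-branch output projections start near zero so every block is close
# to the identity at initialization; deep post-norm stacks then train from a
# well-conditioned starting point without a warmup schedule.
_BRANCH_SCALE = 0.1


def _init_attn(rng, d_in: int, d_model: int) -> dict:
    return {
        "Wq": _glorot(rng, d_in, d_model),
        "Wk": _glorot(rng, d_in, d_model),
        "Wv": _glorot(rng, d_in, d_model),
        "Wh": _BRANCH_SCALE * _glorot(rng, d_model, d_model),
    }


def _init_ffn(rng, d_model: int, d_ffn: int) -> dict:
    return {
        "W1": _glorot(rng, d_model, d_ffn),
        "b1": np.zeros(d_ffn),
        "W2": _BRANCH_SCALE * _glorot(rng, d_ffn, d_model),
        "b2": np.zeros(d_model),
    }


def _init_block(rng, cfg: EncoderConfig) -> dict:
    w = cfg.width
    return {
        "attn": _init_attn(rng, w, w),
        "ln1_g": np.ones(w),
        "ln1_b": np.zeros(w),
        "ffn": _init_ffn(rng, w, cfg.ffn_width),
        "ln2_g": np.ones(w),
        "ln2_b": np.zeros(w),
    }


def init_global_params(
    n_nodes: int, cfg: EncoderConfig, rng: np.random.Generator
) -> dict:
    return {
        "in_W": _glorot(rng, n_nodes, cfg.width),
        "in_b": np.zeros(cfg.width),
        "blocks": [_init_block(rng, cfg) for _ in range(cfg.l1)],
    }


def _encoder_block(x, p, n_head, cfg, rng):
    a = multi_head_attention(x, p["attn"], n_head, cfg.paper_softmax)
    x = layer_norm(x + dropout(a, cfg.dropout, rng), p["ln1_g"], p["ln1_b"])
    f = feed_forward(x, p["ffn"], cfg.leaky_slope)
    return layer_norm(x + dropout(f, cfg.dropout, rng), p["ln2_g"], p["ln2_b"])


def global_encode(Z_G, params, cfg: EncoderConfig, rng=None):
    """Global-level node embedding of the NAFS output of the heterogeneous net.

    ``rng`` enables dropout (training); pass None for deterministic
    evaluation.
    """
    x = anp.dot(Z_G, params["in_W"]) + params["in_b"]
    for p in params["blocks"]:
        x = _encoder_block(x, p, cfg.h1, cfg, rng)
    return x


def _init_fusion_block(rng, cfg: EncoderConfig, kind: str) -> dict:
    w = cfg.width
    p: dict = {
        "ffn": _init_ffn(rng, w, cfg.ffn_width),
        "ln3_g": np.ones(w),
        "ln3_b": np.zeros(w),
    }
    if kind in ("both", "plain"):
        p["attn1"] = _init_attn(rng, w, w)
        p["ln1_g"] = np.ones(w)
        p["ln1_b"] = np.zeros(w)
    if kind in ("both", "bias"):
        p["cat_W"] = _glorot(rng, 2 * w, w)
        p["cat_b"] = np.zeros(w)
        p["attn2"] = _init_attn(rng, w, w)
        p["ln2_g"] = np.ones(w)
        p["ln2_b"] = np.zeros(w)
    return p


def _fusion_block_kinds(cfg: EncoderConfig) -> list[str]:
    if not cfg.two_stacks:
        return ["both"] * cfg.l2
    first = (cfg.l2 + 1) // 2
    return ["plain"] * first + ["bias"] * (cfg.l2 - first)


def init_fusion_params(
    d_global: int, n_dis: int, n_p: int, cfg: EncoderConfig,
    rng: np.random.Generator,
) -> dict:
    return {
        "in_W": _glorot(rng, d_global + n_dis, cfg.width),
        "in_b": np.zeros(cfg.width),
        "sf_W": _glorot(rng, n_p, cfg.width),
        "sf_b": np.zeros(cfg.width),
        "blocks": [
            _init_fusion_block(rng, cfg, kind)
            for kind in _fusion_block_kinds(cfg)
        ],
        "out_W": _glorot(rng, cfg.width, cfg.out_dim),
        "out_b": np.zeros(cfg.out_dim),
    }


def fuse(X, Z_LD, SF, params, cfg: EncoderConfig, rng=None):
    """Fuse global, local and structural embeddings into X^S.

    Each fusion block applies (i) self-attention over the current
    embedding, (ii) attention over the current embedding concatenated with
    the projected structural bias SF, (iii) a feed-forward sub-layer; all
    with post-norm residuals.  With ``cfg.two_stacks`` the two attention
    types instead form two sequential half-depth stacks.
    """
    if not (X.shape[0] == Z_LD.shape[0] == SF.shape[0]):
        raise ValueError("X, Z_LD and SF must share the node count")
    x = anp.dot(anp.concatenate([X, Z_LD], axis=1), params["in_W"])
    x = x + params["in_b"]
    sf = anp.dot(SF, params["sf_W"]) + params["sf_b"]
    for kind, p in zip(_fusion_block_kinds(cfg), params["blocks"]):
        if kind in ("both", "plain"):
            a1 = multi_head_attention(x, p["attn1"], cfg.h2, cfg.paper_softmax)
            x = layer_norm(
                x + dropout(a1, cfg.dropout, rng), p["ln1_g"], p["ln1_b"]
            )
        if kind in ("both", "bias"):
            z = anp.dot(anp.concatenate([x, sf], axis=1), p["cat_W"])
            z = z + p["cat_b"]
            a2 = multi_head_attention(z, p["attn2"], cfg.h2, cfg.paper_softmax)
            x = layer_norm(
                x + dropout(a2, cfg.dropout, rng), p["ln2_g"], p["ln2_b"]
            )
        f = feed_forward(x, p["ffn"], cfg.leaky_slope)
        x = layer_norm(
            x + dropout(f, cfg.dropout, rng), p["ln3_g"], p["ln3_b"]
        )
    return anp.dot(x, params["out_W"]) + params["out_b"]
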