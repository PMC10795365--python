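"""Joint training, cross-validation and evaluation of the link predictor.

One Adam optimizer drives every trainable block -- the local-embedding
affine map, both SDNE autoencoders, the global Transformer, the fusion
stage and the bilinear decoder -- under the composite objective

    L_m = L_link + L_sdne(lncRNA net) + L_sdne(disease net)

where L_link is binary cross-entropy over the sampled positive and
negative pairs.  Cross-validation is leakage-safe: each fold masks its
held-out positives to zero and recomputes every A-derived similarity
matrix (functional similarity, GIP kernels, integrated networks, initial
features) from the masked matrix before any embedding is built.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.misc.flatten import flatten
from sklearn.metrics import average_precision_score, roc_auc_score

from .data_io import AssociationDataset, DiseaseOntology
from .fusion import (
    EncoderConfig,
    dropout as _dropout,
    fuse,
    global_encode,
    init_fusion_params,
    init_global_params,
)
from .nafs import NafsConfig, nafs_ensemble, project_and_stack
from .sdne import SdneConfig, init_sdne_params, sdne_forward, sdne_loss
from .similarity import (
    SemanticSimilarity,
    build_similarity_bundle,
    semantic_similarity,
)

__all__ = [
    "TrainConfig",
    "CvReport",
    "bilinear_scores",
    "link_loss",
    "sample_negatives",
    "make_folds",
    "train_fold",
    "evaluate",
    "run_cv",
    "fit_full",
    "predict_scores",
]

ABLATIONS = (
    "remove_T1",
    "remove_lnc_nafs",
    "remove_dis_nafs",
    "remove_lnc_sdne",
    "remove_dis_sdne",
)


@dataclass
class TrainConfig:
    """Optimization, sampling and architecture settings for one run."""

    lr: float = 1e-3
    weight_decay: float = 5e-3
    epochs: int = 150
    seed: int = 50
    ratio: float | str = 1.0  # negatives per positive, or "random"
    k_folds: int = 5
    threshold: float = 0.5
    resample_negatives: bool = True
    # regularization against memorizing individual association cells: the
    # heterogeneous-view features contain the raw A entries, so they are
    # dropped out at the input during training
    input_dropout: float = 0.5
    # tail weight averaging and a small deep ensemble stabilize the scores
    # reachable within a fixed full-batch epoch budget
    swa_fraction: float = 0.4
    n_ensembles: int = 3
    ablations: tuple[str, ...] = ()
    gamma: float = 0.5
    alpha: float = 0.6  # lncRNA network threshold
    beta: float = 0.6  # disease network threshold
    gip_baseline: float = 1.0
    nafs: NafsConfig = field(default_factory=NafsConfig)
    sdne: SdneConfig = field(default_factory=SdneConfig)
    enc: EncoderConfig = field(default_factory=EncoderConfig)

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if isinstance(self.ratio, str):
            if self.ratio != "random":
                raise ValueError("ratio must be a positive number or 'random'")
        elif self.ratio <= 0:
            raise ValueError("ratio must be a positive number or 'random'")
        unknown = set(self.ablations) - set(ABLATIONS)
        if unknown:
            raise ValueError(f"unknown ablation flags: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ablations"] = list(self.ablations)
        d["nafs"]["r_list"] = list(self.nafs.r_list)
        return d


def bilinear_logits(X_L, X_D, W_B):
    """Bilinear decoder logits x_l^T W_B x_d (pre-sigmoid)."""
    if X_L.shape[1] != W_B.shape[0] or X_D.shape[1] != W_B.shape[1]:
        raise ValueError(
            f"embedding widths {X_L.shape[1]}/{X_D.shape[1]} do not match "
            f"decoder shape {W_B.shape}"
        )
    return anp.dot(anp.dot(X_L, W_B), anp.transpose(X_D))


def bilinear_scores(X_L, X_D, W_B):
    """Sigmoid bilinear decoder: score(l, d) = sigmoid(x_l^T W_B x_d)."""
    return 1.0 / (1.0 + anp.exp(-bilinear_logits(X_L, X_D, W_B)))


def link_loss(A, A_hat, pos_idx, neg_idx):
    """Binary cross-entropy summed over the sampled pairs (clipped at 1e-12)."""
    pos_idx = np.asarray(pos_idx).reshape(-1, 2)
    neg_idx = np.asarray(neg_idx).reshape(-1, 2)
    idx = np.concatenate([pos_idx, neg_idx], axis=0)
    if idx.size == 0:
        raise ValueError("no pairs to score: positive and negative sets empty")
    labels = np.concatenate(
        [np.ones(len(pos_idx)), np.zeros(len(neg_idx))]
    )
    p = anp.clip(A_hat[idx[:, 0], idx[:, 1]], 1e-12, 1.0 - 1e-12)
    return -anp.sum(labels * anp.log(p) + (1.0 - labels) * anp.log(1.0 - p))


def link_loss_logits(logits, pos_idx, neg_idx):
    """BCE computed from logits; equals ``link_loss`` on sigmoid(logits)
    but keeps a nonzero gradient in saturation."""
    pos_idx = np.asarray(pos_idx).reshape(-1, 2)
    neg_idx = np.asarray(neg_idx).reshape(-1, 2)
    idx = np.concatenate([pos_idx, neg_idx], axis=0)
    if idx.size == 0:
        raise ValueError("no pairs to score: positive and negative sets empty")
    labels = np.concatenate(
        [np.ones(len(pos_idx)), np.zeros(len(neg_idx))]
    )
    z = logits[idx[:, 0], idx[:, 1]]
    # -[y log s(z) + (1-y) log(1-s(z))] = softplus(z) - y z, stably:
    return anp.sum(anp.maximum(z, 0.0) - labels * z + anp.log1p(anp.exp(-anp.abs(z))))


def sample_negatives(
    A: np.ndarray,
    n: int,
    rng: np.random.Generator,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Uniformly sample n distinct zero entries of A, minus excluded pairs."""
    avail = np.asarray(A) == 0
    if exclude is not None and len(exclude):
        exclude = np.asarray(exclude).reshape(-1, 2)
        avail[exclude[:, 0], exclude[:, 1]] = False
    zeros = np.argwhere(avail)
    if n > len(zeros):
        raise ValueError(
            f"requested {n} negatives but only {len(zeros)} zero entries "
            "are available"
        )
    pick = rng.choice(len(zeros), size=n, replace=False)
    return zeros[pick]


def make_folds(
    pos_pairs: np.ndarray, k: int, rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random k-way partition of the positives into (train, test) splits."""
    if k < 2:
        raise ValueError("fold count must be >= 2")
    pos_pairs = np.asarray(pos_pairs).reshape(-1, 2)
    if len(pos_pairs) < k:
        raise ValueError("fewer positives than folds")
    perm = rng.permutation(len(pos_pairs))
    parts = np.array_split(perm, k)
    folds = []
    for i in range(k):
        test = pos_pairs[parts[i]]
        train = pos_pairs[np.concatenate(parts[:i] + parts[i + 1 :])]
        folds.append((train, test))
    return folds


def evaluate(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict:
    """AUC, AUPR and thresholded confusion-matrix metrics."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class; AUC/AUPR undefined")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
        "f1": f1,
        "acc": (tp + tn) / len(labels),
        "recall": recall,
        "specificity": specificity,
        "precision": precision,
    }


def _neg_count(
    ratio: float | str, n_pos: int, n_avail: int, rng: np.random.Generator
) -> int:
    if ratio == "random":
        return int(rng.integers(n_pos, n_avail + 1))
    return min(int(round(float(ratio) * n_pos)), n_avail)


def init_model_params(
    dims: dict, cfg: TrainConfig, rng: np.random.Generator
) -> dict:
    """All trainable parameters; unused blocks under an ablation get zero grad."""

    def glorot(n_in, n_out):
        limit = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-limit, limit, size=(n_in, n_out))

    return {
        "W_LD": glorot(dims["d_ZD"], dims["d_ZL"]),
        "b_LD": np.zeros(dims["d_ZD"]),
        "sdne_l": init_sdne_params(dims["n_l"], cfg.sdne, rng),
        "sdne_d": init_sdne_params(dims["n_d"], cfg.sdne, rng),
        "global": init_global_params(dims["d_ZG"], cfg.enc, rng),
        "t1_W": glorot(dims["d_ZG"], cfg.enc.width),
        "t1_b": np.zeros(cfg.enc.width),
        "fusion": init_fusion_params(
            cfg.enc.width, dims["d_ZD"], cfg.sdne.n_p, cfg.enc, rng
        ),
        # small decoder init keeps initial logits near zero (unsaturated BCE)
        "W_B": 0.1 * glorot(cfg.enc.out_dim, cfg.enc.out_dim),
    }


def model_forward(params, inputs, cfg: TrainConfig, rng=None):
    """Full forward pass: returns (score logits, SDNE loss lnc, SDNE loss dis).

    ``rng`` turns on training-time stochasticity (dropout); evaluation
    passes None and is deterministic.
    """
    abl = set(cfg.ablations)
    n_l = inputs["n_l"]
    if rng is not None and cfg.input_dropout > 0:
        inputs = dict(inputs)
        inputs["Z_G"] = _dropout(inputs["Z_G"], cfg.input_dropout, rng)
    Z_LD = project_and_stack(
        inputs["Z_L"], inputs["Z_D"], params["W_LD"], params["b_LD"]
    )
    if "remove_lnc_sdne" in abl:
        Y_l, L_l = anp.zeros((n_l, cfg.sdne.n_p)), 0.0
    else:
        Y_l, rec_l = sdne_forward(inputs["I_net"], params["sdne_l"])
        L_l = sdne_loss(inputs["I_net"], rec_l, Y_l, params["sdne_l"], cfg.sdne)[
            "total"
        ]
    if "remove_dis_sdne" in abl:
        Y_d, L_d = anp.zeros((inputs["n_d"], cfg.sdne.n_p)), 0.0
    else:
        Y_d, rec_d = sdne_forward(inputs["D_net"], params["sdne_d"])
        L_d = sdne_loss(inputs["D_net"], rec_d, Y_d, params["sdne_d"], cfg.sdne)[
            "total"
        ]
    SF = anp.concatenate([Y_l, Y_d], axis=0)
    if "remove_T1" in abl:
        X = anp.dot(inputs["Z_G"], params["t1_W"]) + params["t1_b"]
    else:
        X = global_encode(inputs["Z_G"], params["global"], cfg.enc, rng)
    X_S = fuse(X, Z_LD, SF, params["fusion"], cfg.enc, rng)
    logits = bilinear_logits(X_S[:n_l], X_S[n_l:], params["W_B"])
    return logits, L_l, L_d


def _build_inputs(bundle, cfg: TrainConfig) -> dict:
    """NAFS embeddings and networks for one (fold-masked) similarity bundle."""
    abl = set(cfg.ablations)
    n_l = bundle.IL.shape[0]
    n_d = bundle.ID.shape[0]
    adj_G = bundle.G_net if cfg.nafs.weighted_gtilde else (
        (bundle.G_net > 0).astype(float)
    )
    Z_G = nafs_ensemble(adj_G, bundle.X0, cfg.nafs)
    # the thresholded similarity networks are binary by construction
    net_cfg = dataclasses.replace(cfg.nafs, weighted_gtilde=False)
    Z_L = (
        bundle.IL
        if "remove_lnc_nafs" in abl
        else nafs_ensemble(bundle.I_net, bundle.IL, net_cfg)
    )
    Z_D = (
        bundle.ID
        if "remove_dis_nafs" in abl
        else nafs_ensemble(bundle.D_net, bundle.ID, net_cfg)
    )
    return {
        "Z_G": Z_G,
        "Z_L": Z_L,
        "Z_D": Z_D,
        "I_net": bundle.I_net.astype(float),
        "D_net": bundle.D_net.astype(float),
        "n_l": n_l,
        "n_d": n_d,
    }


def _assert_no_leakage(masked, bundle, test_pos) -> None:
    """Held-out positives must be zero in every A-derived pair matrix."""
    test_pos = np.asarray(test_pos).reshape(-1, 2)
    if not len(test_pos):
        return
    i, j = test_pos[:, 0], test_pos[:, 1]
    n_l = masked.n_lnc
    if masked.A[i, j].any():
        raise AssertionError("test positive present in training matrix")
    if bundle.X0[i, n_l + j].any() or bundle.X0[n_l + j, i].any():
        raise AssertionError("test positive leaked into initial features")
    if bundle.G_net[i, n_l + j].any() or bundle.G_net[n_l + j, i].any():
        raise AssertionError("test positive leaked into heterogeneous network")


def _unbox(x) -> float:
    while hasattr(x, "_value"):
        x = x._value
    return float(x)


def _adam_fit(params, make_objective, cfg: TrainConfig, trace: list) -> dict:
    """Joint Adam loop with L2 weight decay over the flattened parameters.

    The returned parameters are the average of the last ``swa_fraction`` of
    the epochs' iterates (plain stochastic weight averaging), which gives a
    markedly more stable endpoint under per-epoch negative re-sampling and
    dropout than the final iterate alone.
    """
    flat, unflatten = flatten(params)
    m = np.zeros_like(flat)
    v = np.zeros_like(flat)
    b1, b2, eps = 0.9, 0.999, 1e-8
    swa_start = int(np.ceil(cfg.epochs * (1.0 - cfg.swa_fraction)))
    swa_sum = None
    swa_n = 0
    for epoch in range(cfg.epochs):
        objective, parts = make_objective(unflatten, epoch)
        loss, grad_flat = value_and_grad(objective)(flat)
        grad_flat = grad_flat + cfg.weight_decay * flat
        t = epoch + 1
        m = b1 * m + (1 - b1) * grad_flat
        v = b2 * v + (1 - b2) * grad_flat**2
        mh = m / (1 - b1**t)
        vh = v / (1 - b2**t)
        flat = flat - cfg.lr * mh / (np.sqrt(vh) + eps)
        if epoch >= swa_start:
            swa_sum = flat.copy() if swa_sum is None else swa_sum + flat
            swa_n += 1
        trace.append(
            {
                "epoch": epoch,
                "l_m": float(loss),
                **{k: _unbox(x) for k, x in parts.items()},
            }
        )
    if swa_n:
        flat = swa_sum / swa_n
    return unflatten(flat)


def _fit_on(
    dataset: AssociationDataset,
    sem: SemanticSimilarity,
    train_pos: np.ndarray,
    test_pos: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
):
    """Shared fitting path for one fold (or the full data when test is empty)."""
    masked = dataset.masked(test_pos)
    bundle = build_similarity_bundle(
        masked, sem, cfg.alpha, cfg.beta, cfg.gip_baseline
    )
    _assert_no_leakage(masked, bundle, test_pos)
    inputs = _build_inputs(bundle, cfg)
    dims = {
        "n_l": dataset.n_lnc,
        "n_d": dataset.n_dis,
        "d_ZG": inputs["Z_G"].shape[1],
        "d_ZL": inputs["Z_L"].shape[1],
        "d_ZD": inputs["Z_D"].shape[1],
    }
    n_zero_total = int((dataset.A == 0).sum())
    test_pos = np.asarray(test_pos).reshape(-1, 2)
    if len(test_pos):
        n_test_neg = _neg_count(
            cfg.ratio, len(test_pos), n_zero_total - len(test_pos), rng
        )
        test_neg = sample_negatives(dataset.A, n_test_neg, rng)
    else:
        test_neg = np.empty((0, 2), dtype=int)
    n_avail = n_zero_total - len(test_neg)

    def fit_member(member_rng, trace):
        params = init_model_params(dims, cfg, member_rng)
        drop_rng = np.random.default_rng(member_rng.integers(2**31))
        fixed_neg = None

        def make_objective(unflatten, epoch):
            nonlocal fixed_neg
            if fixed_neg is None or cfg.resample_negatives:
                n_neg = _neg_count(cfg.ratio, len(train_pos), n_avail, member_rng)
                fixed_neg = sample_negatives(
                    dataset.A, n_neg, member_rng, exclude=test_neg
                )
            train_neg = fixed_neg
            parts: dict = {}

            def objective(flat_params):
                p = unflatten(flat_params)
                logits, L_l, L_d = model_forward(p, inputs, cfg, drop_rng)
                L_link = link_loss_logits(logits, train_pos, train_neg)
                parts["l_link"] = L_link
                parts["l_sdne_l"] = L_l
                parts["l_sdne_d"] = L_d
                return L_link + L_l + L_d

            return objective, parts

        params = _adam_fit(params, make_objective, cfg, trace)
        logits, _, _ = model_forward(params, inputs, cfg, rng=None)
        return params, 1.0 / (1.0 + np.exp(-np.asarray(logits)))

    # small deep ensemble: average the sigmoid score matrices of
    # independently initialized and independently trained members
    member_params = []
    traces: list[list[dict]] = []
    A_hat = np.zeros((dataset.n_lnc, dataset.n_dis))
    for member_rng in rng.spawn(max(1, cfg.n_ensembles)):
        trace: list[dict] = []
        params, member_scores = fit_member(member_rng, trace)
        member_params.append(params)
        traces.append(trace)
        A_hat += member_scores
    A_hat /= len(member_params)
    return member_params, A_hat, test_neg, traces[0]


def train_fold(
    dataset: AssociationDataset,
    sem: SemanticSimilarity,
    fold: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
    rng: np.random.Generator | None = None,
):
    """Fit on one fold's training positives and score its held-out test set."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    train_pos, test_pos = fold
    params, A_hat, test_neg, trace = _fit_on(
        dataset, sem, train_pos, test_pos, cfg, rng
    )
    test_idx = np.concatenate([np.asarray(test_pos), test_neg], axis=0)
    labels = np.concatenate(
        [np.ones(len(test_pos), dtype=int), np.zeros(len(test_neg), dtype=int)]
    )
    scores = A_hat[test_idx[:, 0], test_idx[:, 1]]
    metrics = evaluate(scores, labels, cfg.threshold)
    return params, metrics, trace


@dataclass
class CvReport:
    """Per-fold metrics, their arithmetic mean, and run metadata."""

    folds: list[dict]
    mean: dict
    config: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "folds": self.folds,
            "mean": self.mean,
            "config": self.config,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def run_cv(
    dataset: AssociationDataset,
    onto: DiseaseOntology,
    cfg: TrainConfig,
) -> CvReport:
    """k-fold cross-validation with per-fold feature recomputation."""
    sem = semantic_similarity(onto, dataset.disease_ids, cfg.gamma)
    fold_rng = np.random.default_rng(cfg.seed)
    folds = make_folds(dataset.positives(), cfg.k_folds, fold_rng)
    fold_metrics = []
    for i, fold in enumerate(folds):
        rng = np.random.default_rng([cfg.seed, i])
        _, metrics, _ = train_fold(dataset, sem, fold, cfg, rng)
        fold_metrics.append(metrics)
    keys = fold_metrics[0].keys()
    mean = {k: float(np.mean([f[k] for f in fold_metrics])) for k in keys}
    return CvReport(fold_metrics, mean, cfg.to_dict(), cfg.seed)


def fit_full(
    dataset: AssociationDataset,
    onto: DiseaseOntology,
    cfg: TrainConfig,
):
    """Train on all known positives; returns (params, full score matrix)."""
    sem = semantic_similarity(onto, dataset.disease_ids, cfg.gamma)
    rng = np.random.default_rng(cfg.seed)
    empty = np.empty((0, 2), dtype=int)
    params, A_hat, _, trace = _fit_on(
        dataset, sem, dataset.positives(), empty, cfg, rng
    )
    return params, A_hat, trace


def predict_scores(
    dataset: AssociationDataset,
    A_hat: np.ndarray,
    top_k: int | None = None,
    novel_only: bool = True,
):
    """Ranked (lncrna_id, disease_id, score, rank) rows per disease."""
    rows = []
    for j, disease in enumerate(dataset.disease_ids):
        col = A_hat[:, j]
        order = np.argsort(-col, kind="stable")
        rank = 0
        for i in order:
            if novel_only and dataset.A[i, j] == 1:
                continue
            rank += 1
            if top_k is not None and rank > top_k:
                break
            rows.append((dataset.lncrna_ids[i], disease, float(col[i]), rank))
    return rows
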