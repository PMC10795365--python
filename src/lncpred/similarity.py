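"""Similarity matrices and the heterogeneous lncRNA-disease network.

Four similarity sources feed the model:

* **DS** — DAG-based disease semantic similarity with exponentially decaying
  ancestor contributions (decay ``gamma``);
* **LF** — lncRNA functional similarity: each lncRNA is represented by the
  set of diseases it associates with, and two lncRNAs are compared through
  the best semantic matches between their disease sets;
* **LK / DK** — Gaussian interaction-profile (GIP) kernels over the rows
  (lncRNAs) and columns (diseases) of the association matrix;
* integrated matrices **IL / ID** that fall back on the GIP kernel for
  pairs whose functional / semantic similarity is unavailable.

Thresholding IL and ID gives the binary similarity networks I_net and
D_net; the heterogeneous network G_net = [[IL, A], [A^T, ID]] joins them
through the known associations, with initial features X0 = [[0, A], [A^T, 0]].
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .data_io import AssociationDataset, DiseaseOntology

__all__ = [
    "SemanticSimilarity",
    "FunctionalSimilarity",
    "SimilarityBundle",
    "semantic_similarity",
    "functional_similarity",
    "gip_kernel",
    "integrate",
    "threshold_network",
    "assemble_heterogeneous",
    "build_similarity_bundle",
]


@dataclass
class SemanticSimilarity:
    """DS matrix plus the per-disease ancestor contribution maps."""

    disease_ids: list[str]
    DS: np.ndarray
    contributions: list[dict[str, float]]
    semantic_values: np.ndarray
    gamma: float


def _contribution_map(
    onto: DiseaseOntology, disease: str, gamma: float
) -> dict[str, float]:
    """Ancestor contributions within DAG(d).

    The disease's own term contributes 1; any ancestor contributes
    gamma * (best contribution among its children inside T(d)), so the
    contribution decays with distance from the disease term.
    """
    term = onto.term_of(disease)
    closure = onto.ancestor_closure(disease)
    sub = onto.graph.subgraph(closure)
    contrib: dict[str, float] = {}
    # children before parents: topological order of the child->parent graph
    for node in nx.topological_sort(sub.reverse(copy=False)):
        if node == term:
            contrib[node] = 1.0
        else:
            contrib[node] = gamma * max(
                contrib[c] for c in sub.successors(node) if c in contrib
            )
    return contrib


def semantic_similarity(
    onto: DiseaseOntology,
    disease_ids: list[str],
    gamma: float = 0.5,
) -> SemanticSimilarity:
    """Pairwise DAG semantic similarity over the given diseases."""
    if not (0.0 < gamma <= 1.0):
        raise ValueError(f"gamma must lie in (0, 1], got {gamma}")
    contribs = [_contribution_map(onto, d, gamma) for d in disease_ids]
    dv = np.array([sum(c.values()) for c in contribs])
    n = len(disease_ids)
    DS = np.zeros((n, n))
    for i in range(n):
        ci = contribs[i]
        for j in range(i, n):
            cj = contribs[j]
            common = ci.keys() & cj.keys()
            num = sum(ci[t] + cj[t] for t in common)
            DS[i, j] = DS[j, i] = num / (dv[i] + dv[j])
    return SemanticSimilarity(list(disease_ids), DS, contribs, dv, gamma)


@dataclass
class FunctionalSimilarity:
    """LF matrix plus a mask of pairs where LF was actually computable."""

    lncrna_ids: list[str]
    LF: np.ndarray
    defined: np.ndarray  # bool, False where a side has no associated disease


def functional_similarity(
    assoc: AssociationDataset, sem: SemanticSimilarity
) -> FunctionalSimilarity:
    """Functional similarity of lncRNAs via their associated-disease sets.

    For lncRNAs with disease sets D(i), D(j), each disease in one set is
    matched to its best semantic counterpart in the other, and the matched
    scores from both directions are averaged over n + m set members.
    Pairs where either set is empty get LF = 0 and ``defined = False``.
    """
    if sem.disease_ids != assoc.disease_ids:
        raise ValueError("semantic similarity indexed differently from dataset")
    DS = sem.DS
    n_l = assoc.n_lnc
    dsets = [np.flatnonzero(assoc.A[i]) for i in range(n_l)]
    LF = np.zeros((n_l, n_l))
    defined = np.zeros((n_l, n_l), dtype=bool)
    for i in range(n_l):
        Di = dsets[i]
        if Di.size == 0:
            continue
        for j in range(i, n_l):
            Dj = dsets[j]
            if Dj.size == 0:
                continue
            # best match of each of D(i)'s diseases within D(j), and vice versa
            fwd = DS[np.ix_(Di, Dj)].max(axis=1).sum()
            bwd = DS[np.ix_(Dj, Di)].max(axis=1).sum()
            LF[i, j] = LF[j, i] = (fwd + bwd) / (Di.size + Dj.size)
            defined[i, j] = defined[j, i] = True
    return FunctionalSimilarity(list(assoc.lncrna_ids), LF, defined)


def gip_kernel(
    assoc: AssociationDataset, axis: str, baseline: float = 1.0
) -> np.ndarray:
    """Gaussian interaction-profile kernel over rows or columns of A.

    The bandwidth is ``baseline`` divided by the mean squared profile norm,
    so the kernel adapts to the density of the association matrix.
    """
    if axis == "lncrna":
        profiles = assoc.A.astype(float)
    elif axis == "disease":
        profiles = assoc.A.T.astype(float)
    else:
        raise ValueError(f"axis must be 'lncrna' or 'disease', got {axis!r}")
    if baseline <= 0:
        raise ValueError("baseline bandwidth must be positive")
    mean_sq = np.mean((profiles**2).sum(axis=1))
    if mean_sq == 0:
        raise ValueError("zero mean profile norm: association matrix is all-zero")
    r = baseline / mean_sq
    sq = ((profiles[:, None, :] - profiles[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-r * sq)


def integrate(
    primary: np.ndarray,
    fallback: np.ndarray,
    defined: np.ndarray | None = None,
) -> np.ndarray:
    """Primary similarity where available (> 0 and computable), else kernel."""
    primary = np.asarray(primary, dtype=float)
    fallback = np.asarray(fallback, dtype=float)
    if primary.shape != fallback.shape:
        raise ValueError(
            f"shape mismatch: {primary.shape} vs {fallback.shape}"
        )
    if defined is None:
        defined = np.ones(primary.shape, dtype=bool)
    out = np.where(defined & (primary > 0), primary, fallback)
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return out


def threshold_network(S: np.ndarray, t: float) -> np.ndarray:
    """Binary network: edge wherever similarity >= t (boundary included)."""
    return (np.asarray(S) >= t).astype(np.int8)


def assemble_heterogeneous(
    IL: np.ndarray, ID: np.ndarray, assoc: AssociationDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Block heterogeneous network G_net and initial features X0."""
    A = assoc.A.astype(float)
    if IL.shape != (assoc.n_lnc, assoc.n_lnc) or ID.shape != (
        assoc.n_dis,
        assoc.n_dis,
    ):
        raise ValueError("similarity block shapes inconsistent with dataset")
    G_net = np.block([[IL, A], [A.T, ID]])
    Z_l = np.zeros((assoc.n_lnc, assoc.n_lnc))
    Z_d = np.zeros((assoc.n_dis, assoc.n_dis))
    X0 = np.block([[Z_l, A], [A.T, Z_d]])
    return G_net, X0


@dataclass
class SimilarityBundle:
    """Everything derived from one (possibly fold-masked) association matrix."""

    DS: np.ndarray
    LF: np.ndarray
    LF_defined: np.ndarray
    LK: np.ndarray
    DK: np.ndarray
    IL: np.ndarray
    ID: np.ndarray
    I_net: np.ndarray
    D_net: np.ndarray
    G_net: np.ndarray
    X0: np.ndarray


def build_similarity_bundle(
    assoc: AssociationDataset,
    sem: SemanticSimilarity,
    alpha: float = 0.6,
    beta: float = 0.6,
    gip_baseline: float = 1.0,
) -> SimilarityBundle:
    """Compute all A-derived similarity structure for one association matrix.

    ``sem`` is passed in because disease semantic similarity depends only on
    the ontology, not on A, and so can be shared across cross-validation
    folds; everything else here is recomputed from the given (masked) A.
    """
    fun = functional_similarity(assoc, sem)
    LK = gip_kernel(assoc, "lncrna", gip_baseline)
    DK = gip_kernel(assoc, "disease", gip_baseline)
    IL = integrate(fun.LF, LK, fun.defined)
    ID = integrate(sem.DS, DK)
    I_net = threshold_network(IL, alpha)
    D_net = threshold_network(ID, beta)
    G_net, X0 = assemble_heterogeneous(IL, ID, assoc)
    return SimilarityBundle(
        DS=sem.DS,
        LF=fun.LF,
        LF_defined=fun.defined,
        LK=LK,
        DK=DK,
        IL=IL,
        ID=ID,
        I_net=I_net,
        D_net=D_net,
        G_net=G_net,
        X0=X0,
    )
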