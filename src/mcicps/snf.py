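"""Similarity network fusion, spectral subtyping, and label propagation.

Patients are nodes; each modality contributes a patient-by-patient affinity
network built with a scaled exponential similarity kernel.  The fusion step
is the nonlinear cross-diffusion update: each network's sparse K-nearest-
neighbor kernel repeatedly "passes messages" through the average of the
other networks, so edges supported by several modalities are reinforced and
modality-specific noise decays.  The fused network is partitioned by the
spectral relaxation of RatioCut (eigenvectors of the unnormalized graph
Laplacian, then k-means).  New patients are assigned subtypes by clamped
label propagation over a joint fused network built on train + new samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .datatypes import ModalityMatrix, SchemaError


@dataclass
class AffinityNetwork:
    """N x N symmetric nonnegative patient-similarity matrix."""

    W: np.ndarray
    sample_ids: list[str]
    K: int
    mu: float

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if not np.isfinite(W).all():
            raise ValueError("affinity contains non-finite entries")
        if np.abs(W - W.T).max() > 1e-12:
            raise ValueError("affinity not symmetric")
        if W.min() < 0:
            raise ValueError("affinity has negative entries")
        self.W = W


@dataclass
class FusedNetwork:
    W: np.ndarray
    sample_ids: list[str]
    T: int
    change_norms: list[float] = field(default_factory=list)


@dataclass
class SubtypeAssignment:
    """Subtype label per sample, 1..C, with provenance and soft scores."""

    labels: np.ndarray              # values in 1..C
    C: int
    source: str                     # "clustered" | "propagated"
    sample_ids: list[str]
    scores: np.ndarray | None = None  # (N, C), rows sum to 1
    laplacian_spectrum: np.ndarray | None = None  # eigengap diagnostic


def _pairwise_dist(x: np.ndarray, y: np.ndarray | None = None,
                   metric: str = "euclidean") -> np.ndarray:
    y = x if y is None else y
    if metric == "euclidean":
        return cdist(x, y, metric="euclidean")
    if metric == "chi2":
        # symmetric chi-squared distance on shifted-nonnegative codes
        xs = x - min(x.min(), y.min()) + 1e-9
        ys = y - min(x.min(), y.min()) + 1e-9
        num = (xs[:, None, :] - ys[None, :, :]) ** 2
        den = xs[:, None, :] + ys[None, :, :]
        return np.sqrt(0.5 * (num / den).sum(axis=-1))
    raise ValueError(f"unknown metric {metric!r}")


def affinity_from_distance(D: np.ndarray, K: int, mu: float) -> np.ndarray:
    """Scaled exponential kernel W_ij = exp(-d_ij^2 / (mu * eps_ij)).

    eps_ij averages each sample's mean distance to its K nearest neighbors
    with the pair distance itself: eps_ij = (m_i + m_j + d_ij) / 3.
    """
    n = D.shape[0]
    if K >= n:
        raise ValueError(f"K={K} must be smaller than the sample count {n}")
    Ds = np.sort(D, axis=1)
    # column 0 is the self-distance 0; neighbors are the next K entries
    m = Ds[:, 1 : K + 1].mean(axis=1)
    eps = (m[:, None] + m[None, :] + D) / 3.0
    eps = np.maximum(eps, 1e-12)
    W = np.exp(-(D**2) / (mu * eps))
    return (W + W.T) / 2.0


def build_affinity(x: ModalityMatrix, K: int = 20, mu: float = 0.5,
                   metric: str | None = None) -> AffinityNetwork:
    """Per-modality patient affinity network from standardized features.

    Euclidean distance by default; ``metric="chi2"`` is available for the
    genotype layer's count-like 0/1/2 codes.
    """
    metric = metric or "euclidean"
    D = _pairwise_dist(x.values, metric=metric)
    W = affinity_from_distance(D, K=K, mu=mu)
    ids = [str(i) for i in range(x.n_samples)]
    return AffinityNetwork(W, ids, K, mu)


def _full_transition(W: np.ndarray) -> np.ndarray:
    """Full-kernel normalization: off-diagonal mass 1/2, diagonal 1/2."""
    P = W.copy()
    np.fill_diagonal(P, 0.0)
    rs = P.sum(axis=1)
    rs[rs == 0] = 1.0
    P = P / (2.0 * rs[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def _knn_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """Row-normalized kernel restricted to each sample's K nearest neighbors."""
    n = W.shape[0]
    S = np.zeros_like(W)
    Woff = W.copy()
    np.fill_diagonal(Woff, -np.inf)
    nn = np.argsort(-Woff, axis=1)[:, :K]
    rows = np.repeat(np.arange(n), K)
    S[rows, nn.ravel()] = W[rows, nn.ravel()]
    rs = S.sum(axis=1)
    rs[rs == 0] = 1.0
    return S / rs[:, None]


def snf_fuse(affinities: list[AffinityNetwork], K: int = 20,
             T: int = 20) -> FusedNetwork:
    """Cross-diffusion fusion of two or more affinity networks.

    Each network's full kernel is normalized to a transition form P_v, its
    sparse KNN kernel S_v kept local; for T iterations every P_v is replaced
    by S_v (mean of the other P_u) S_v^T and renormalized.  The fused
    network is the average of the converged P_v, symmetrized.  Per-iteration
    mean change norms are kept as a convergence diagnostic.
    """
    if len(affinities) < 2:
        raise ValueError("need at least 2 networks to fuse")
    ids = affinities[0].sample_ids
    for a in affinities[1:]:
        if a.sample_ids != ids:
            raise SchemaError("affinity networks built on different sample sets")
    P = [_full_transition(a.W) for a in affinities]
    S = [_knn_kernel(a.W, min(K, len(ids) - 1)) for a in affinities]
    M = len(P)
    norms: list[float] = []
    for _ in range(T):
        newP = []
        for v in range(M):
            others = sum(P[u] for u in range(M) if u != v) / (M - 1)
            Q = S[v] @ others @ S[v].T
            Q = _full_transition((Q + Q.T) / 2.0)
            newP.append(Q)
        norms.append(float(np.mean([np.linalg.norm(newP[v] - P[v], "fro")
                                    for v in range(M)])))
        P = newP
    W = sum(P) / M
    W = (W + W.T) / 2.0
    return FusedNetwork(W, list(ids), T, norms)


def spectral_cluster(net: FusedNetwork, C: int = 2,
                     seed: int = 0) -> SubtypeAssignment:
    """RatioCut spectral relaxation: L = D - W, then k-means on eigenvectors.

    Deterministic given the seed (k-means uses multiple restarts).  If the
    graph splits into more connected components than C, a warning is issued
    and the components themselves are returned as clusters.
    """
    if C < 2:
        raise ValueError("C must be >= 2")
    W = net.W.copy()
    np.fill_diagonal(W, 0.0)
    n_comp, comp = connected_components((W > 1e-15).astype(float), directed=False)
    if n_comp > C:
        warnings.warn(
            f"graph has {n_comp} components > C={C}; returning components",
            stacklevel=2,
        )
        return SubtypeAssignment(comp + 1, n_comp, "clustered",
                                 list(net.sample_ids),
                                 _one_hot(comp, n_comp))
    L = np.diag(W.sum(axis=1)) - W
    eigvals, eigvecs = np.linalg.eigh(L)
    U = eigvecs[:, :C]
    km = KMeans(n_clusters=C, n_init=20, random_state=seed)
    labels = km.fit_predict(U)
    # stable relabeling: order clusters by first occurrence
    remap, nxt = {}, 1
    out = np.zeros_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = nxt
            nxt += 1
        out[i] = remap[lab]
    return SubtypeAssignment(out, C, "clustered", list(net.sample_ids),
                             _one_hot(out - 1, C),
                             laplacian_spectrum=eigvals[: min(10, len(eigvals))])


def _one_hot(idx: np.ndarray, C: int) -> np.ndarray:
    Y = np.zeros((len(idx), C))
    Y[np.arange(len(idx)), idx] = 1.0
    return Y


class PropagationError(RuntimeError):
    pass


def label_propagate(train_blocks: dict[str, ModalityMatrix],
                    train_labels: SubtypeAssignment,
                    new_blocks: dict[str, ModalityMatrix],
                    K: int = 20, mu: float = 0.5, T: int = 20,
                    alpha: float = 0.99, tol: float = 1e-6,
                    max_iter: int = 1000) -> SubtypeAssignment:
    """Assign subtypes to new samples by clamped propagation on a joint graph.

    A fused network is built over the stacked train + new samples from the
    given modality blocks (the subtyping layers), row-normalized into a
    transition matrix P, and F <- alpha * P F + (1 - alpha) * Y is iterated
    with the training rows clamped to their one-hot labels until the largest
    row change falls below ``tol``.  New labels are the row argmax; the
    returned score rows sum to 1.
    """
    tags = sorted(train_blocks)
    if sorted(new_blocks) != tags:
        raise SchemaError("train and new modality sets differ")
    n_tr = next(iter(train_blocks.values())).n_samples
    n_new = next(iter(new_blocks.values())).n_samples
    aff = []
    for t in tags:
        if train_blocks[t].feature_ids != new_blocks[t].feature_ids:
            raise SchemaError(f"feature mismatch in modality {t!r}")
        stacked = np.vstack([train_blocks[t].values, new_blocks[t].values])
        block = ModalityMatrix(stacked, train_blocks[t].feature_ids, t)
        aff.append(build_affinity(block, K=min(K, n_tr + n_new - 1), mu=mu))
    if len(aff) >= 2:
        W = snf_fuse(aff, K=min(K, n_tr + n_new - 1), T=T).W
    else:
        W = aff[0].W
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    rs = W.sum(axis=1)
    rs[rs == 0] = 1.0
    P = W / rs[:, None]
    C = train_labels.C
    Y = np.zeros((n_tr + n_new, C))
    Y[:n_tr] = _one_hot(np.asarray(train_labels.labels) - 1, C)
    F = Y.copy()
    for _ in range(max_iter):
        F_new = alpha * (P @ F) + (1 - alpha) * Y
        F_new[:n_tr] = Y[:n_tr]
        delta = float(np.abs(F_new - F).max())
        F = F_new
        if delta < tol:
            break
    else:
        raise PropagationError(
            f"label propagation did not converge in {max_iter} iterations "
            f"(last change {delta:.3e})"
        )
    scores = F[n_tr:]
    row_sums = scores.sum(axis=1, keepdims=True)
    # isolated new samples get a uniform score row
    uniform = np.full((1, C), 1.0 / C)
    scores = np.where(row_sums > 0, scores / np.maximum(row_sums, 1e-300), uniform)
    labels = scores.argmax(axis=1) + 1
    ids = [f"new{i}" for i in range(n_new)]
    return SubtypeAssignment(labels, C, "propagated", ids, scores)
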