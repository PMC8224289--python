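"""Variational-Bayes probabilistic multiple-kernel-learning classifier.

Multinomial-probit model with auxiliary variables: for sample n with
composite kernel column k_n, latent scores y_n = W k_n + eps (eps standard
normal per class dimension) and the observed class is t_n = argmax_c y_nc.
Each class row of the regressor W has a Gaussian prior with precision phi.
The factorized variational posterior Q(W) Q(Y) is iterated:

* Q(W): Gaussian, with shared covariance (phi I + K K^T)^-1 and per-class
  mean given the current auxiliary expectations E[Y];
* Q(Y): a cone-truncated Gaussian (y_ni must exceed all other y_nj); its
  moments reduce to 1-D integrals over a standard-normal variable, computed
  here by Gauss-Hermite quadrature.

The posterior predictive for a new sample is

    P(t = i | W, k) = E_{u~N(0,1)} [ prod_{j != i} Phi(u + (w_i - w_j) k) ]

evaluated with the posterior mean of W by the same quadrature; in the
binary case it collapses to the closed form Phi((w_1 - w_2) k / sqrt(2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

from .kernels import (BaseKernelSpec, KernelSet, composite_kernel,
                      compute_gram, median_heuristic)

_SQRT2PI = np.sqrt(2.0 * np.pi)


class FitError(RuntimeError):
    pass


@dataclass
class VBpMKLModel:
    W_mean: np.ndarray            # (C, N) posterior mean regressors
    Sigma: np.ndarray             # (N, N) shared posterior covariance
    beta: np.ndarray              # (M,) kernel weights on the simplex
    specs: list[BaseKernelSpec]
    class_values: np.ndarray      # original label values, index = class id
    phi: float
    expected_Y: np.ndarray        # (N, C) final auxiliary expectations
    trace: list[float] = field(default_factory=list)
    converged: bool = False
    train_blocks: list[np.ndarray] | None = None  # per-modality features
    quad_nodes: int = 64


@dataclass
class PredictiveDistribution:
    proba: np.ndarray             # (N_test, C), rows sum to 1
    class_values: np.ndarray

    @property
    def calls(self) -> np.ndarray:
        # argmax with ties resolved to the lower class index
        return self.class_values[self.proba.argmax(axis=1)]


def _gh_rule(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights so that E_{u~N(0,1)} f(u) ~= sum w_i f(u_i)."""
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    return np.sqrt(2.0) * x, w / np.sqrt(np.pi)


def _truncated_moments(m: np.ndarray, t_idx: np.ndarray,
                       u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """E[y] of the cone-truncated Gaussian, per sample, via quadrature.

    ``m`` is (N, C) latent means, ``t_idx`` the observed class per sample.
    """
    N, C = m.shape
    Ey = np.empty_like(m)
    for i in range(C):
        rows = np.flatnonzero(t_idx == i)
        if rows.size == 0:
            continue
        mi = m[rows]                                   # (n_i, C)
        delta = mi[:, i][:, None] - mi                 # m_i - m_j
        a = u[None, :, None] + delta[:, None, :]       # (n_i, G, C)
        Phi = ndtr(a)
        Phi[:, :, i] = 1.0
        Phi = np.clip(Phi, 1e-300, None)
        prod = Phi.prod(axis=2)                        # (n_i, G)
        Z = np.maximum(prod @ w, 1e-300)               # (n_i,)
        pdf = np.exp(-0.5 * a**2) / _SQRT2PI
        corr_sum = np.zeros(rows.size)
        for j in range(C):
            if j == i:
                continue
            num = (pdf[:, :, j] * prod / Phi[:, :, j]) @ w
            corr = num / Z
            Ey[rows, j] = mi[:, j] - corr
            corr_sum += corr
        Ey[rows, i] = mi[:, i] + corr_sum
    return Ey


def _proba_from_means(m: np.ndarray, u: np.ndarray,
                      w: np.ndarray) -> np.ndarray:
    """Class probabilities from latent means via the predictive quadrature."""
    N, C = m.shape
    proba = np.empty_like(m)
    for i in range(C):
        delta = m[:, i][:, None] - m
        a = u[None, :, None] + delta[:, None, :]
        Phi = ndtr(a)
        Phi[:, :, i] = 1.0
        proba[:, i] = Phi.prod(axis=2) @ w
    proba = np.maximum(proba, 0.0)
    return proba / proba.sum(axis=1, keepdims=True)


def _w_factor(K: np.ndarray, phi: float, jitter: float = 1e-8) -> np.ndarray:
    """Cholesky factor of the W-posterior precision phi*I + K K^T.

    Independent of E[Y], so it is computed once per kernel configuration.
    """
    N = K.shape[0]
    H = phi * np.eye(N) + K @ K.T + jitter * np.eye(N)
    try:
        return np.linalg.cholesky(H)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise FitError(
            "kernel system is singular; increase the jitter or phi"
        ) from exc


def _posterior_w_mean(L: np.ndarray, K: np.ndarray,
                      Ey: np.ndarray) -> np.ndarray:
    rhs = K @ Ey                                       # (N, C)
    return np.linalg.solve(L.T, np.linalg.solve(L, rhs)).T  # (C, N)


def _update_beta(grams: list[np.ndarray], phi: float,
                 Ey: np.ndarray) -> np.ndarray:
    """Simplex reweighting of the base kernels by per-kernel fit to E[Y].

    Each kernel's fit is its Gaussian marginal likelihood of the current
    auxiliary expectations, E[Y]_c ~ N(0, K_m K_m^T / phi + I): a kernel
    must explain the class structure, and a near-identity noise kernel pays
    an Occam penalty for memorizing it.  Weights are the softmax of the
    per-kernel log evidence (the posterior over kernels under a flat prior).
    """
    N = Ey.shape[0]
    logev = np.empty(len(grams))
    for m, K in enumerate(grams):
        Cov = K @ K.T / phi + (1.0 + 1e-8) * np.eye(N)
        L = np.linalg.cholesky(Cov)
        alpha = np.linalg.solve(L, Ey)                # (N, C) whitened
        logdet = 2.0 * np.log(np.diag(L)).sum()
        C = Ey.shape[1]
        logev[m] = -0.5 * float((alpha**2).sum()) - 0.5 * C * logdet
    z = np.exp(logev - logev.max())
    return z / z.sum()


def fit_vbpmkl(ks: KernelSet, labels: np.ndarray, phi: float = 1.0,
               max_iter: int = 5000, tol: float = 1e-5, seed: int = 0,
               update_beta: bool = False,
               quad_nodes: int = 64) -> VBpMKLModel:
    """Variational fit of the multinomial-probit MKL model.

    Iterates the Q(W) Gaussian update and the truncated-Gaussian E[Y]
    update until the fit stabilizes: the largest change in E[Y] or in the
    training class probabilities drops below ``tol``.  (On separable data
    the auxiliary means grow without bound while the probabilities
    saturate, so the probability criterion is the one that fires there.)
    With ``update_beta`` the kernel weights are refit each iteration by
    nonnegative least squares on the simplex; otherwise beta stays at the
    mean-kernel weights it was constructed with.
    """
    labels = np.asarray(labels)
    class_values, t_idx = np.unique(labels, return_inverse=True)
    C = len(class_values)
    if C < 2:
        raise FitError("need at least two classes")
    counts = np.bincount(t_idx)
    if counts.min() < 2:
        raise FitError(
            f"class {class_values[counts.argmin()]!r} has fewer than 2 samples"
        )
    N = ks.grams[0].shape[0]
    if len(labels) != N:
        raise ValueError("labels length must match the training Gram size")
    beta = ks.beta.copy()
    K = composite_kernel(KernelSet(ks.grams, beta, ks.specs))
    Ey = np.zeros((N, C))
    Ey[np.arange(N), t_idx] = 1.0
    u, w = _gh_rule(quad_nodes)
    trace: list[float] = []
    converged = False
    proba_prev = None
    L = _w_factor(K, phi)
    for _ in range(max_iter):
        W = _posterior_w_mean(L, K, Ey)
        if update_beta:
            beta = _update_beta(ks.grams, phi, Ey)
            K = composite_kernel(KernelSet(ks.grams, beta, ks.specs))
            L = _w_factor(K, phi)
            W = _posterior_w_mean(L, K, Ey)
        m = (W @ K).T                                  # (N, C) latent means
        Ey_new = _truncated_moments(m, t_idx, u, w)
        delta_y = float(np.abs(Ey_new - Ey).max())
        proba = _proba_from_means(m, u, w)
        delta_p = (np.inf if proba_prev is None
                   else float(np.abs(proba - proba_prev).max()))
        proba_prev = proba
        delta = min(delta_y, delta_p)
        trace.append(delta)
        Ey = Ey_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise FitError(
            f"VB iteration did not converge in {max_iter} steps; "
            f"trace tail {trace[-3:]}"
        )
    W = _posterior_w_mean(L, K, Ey)
    if update_beta:
        beta = _update_beta(ks.grams, phi, Ey)
    Sigma = np.linalg.inv(L @ L.T)
    return VBpMKLModel(W, Sigma, beta, list(ks.specs), class_values, phi, Ey,
                       trace, converged, quad_nodes=quad_nodes)


def predict_proba(model: VBpMKLModel,
                  test_grams: list[np.ndarray]) -> PredictiveDistribution:
    """Posterior predictive class probabilities for test kernel columns.

    ``test_grams`` are the M cross-Gram blocks K_m(test, train) computed
    with the training kernel specs.
    """
    if len(test_grams) != len(model.beta):
        raise ValueError("wrong number of test Gram blocks for this model")
    Kt = np.zeros_like(test_grams[0])
    for b, g in zip(model.beta, test_grams):
        Kt += b * g
    m = Kt @ model.W_mean.T                            # (N_test, C)
    C = m.shape[1]
    u, w = _gh_rule(model.quad_nodes)
    proba = np.empty_like(m)
    for i in range(C):
        delta = m[:, i][:, None] - m                   # (N_test, C)
        a = u[None, :, None] + delta[:, None, :]
        Phi = ndtr(a)
        Phi[:, :, i] = 1.0
        proba[:, i] = Phi.prod(axis=2) @ w
    proba = np.maximum(proba, 0.0)
    proba /= proba.sum(axis=1, keepdims=True)
    return PredictiveDistribution(proba, model.class_values)


def decision_threshold(dist: PredictiveDistribution,
                       tau: float = 0.5) -> np.ndarray:
    """Binary calls: positive class (larger class value) iff P >= tau."""
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    if dist.proba.shape[1] != 2:
        raise ValueError("decision_threshold applies to binary tasks only")
    pos_col = int(np.argmax(dist.class_values))
    return np.where(dist.proba[:, pos_col] >= tau,
                    dist.class_values[pos_col],
                    dist.class_values[1 - pos_col])


# -- convenience layer over raw feature blocks ------------------------------

def make_kernel_set(blocks: list[np.ndarray], family: str = "gaussian",
                    beta: np.ndarray | None = None) -> KernelSet:
    """Training KernelSet with median-heuristic Gaussian bandwidths."""
    specs = []
    grams = []
    for x in blocks:
        theta = median_heuristic(x) if family == "gaussian" else 1.0
        spec = BaseKernelSpec(family, theta)
        specs.append(spec)
        grams.append(compute_gram(x, None, spec))
    M = len(blocks)
    if beta is None:
        beta = np.full(M, 1.0 / M)
    return KernelSet(grams, beta, specs)


def fit_on_features(blocks: list[np.ndarray], labels: np.ndarray,
                    family: str = "gaussian", **kwargs) -> VBpMKLModel:
    ks = make_kernel_set(blocks, family=family)
    model = fit_vbpmkl(ks, labels, **kwargs)
    model.train_blocks = [np.asarray(b, dtype=float) for b in blocks]
    return model


def predict_on_features(model: VBpMKLModel,
                        test_blocks: list[np.ndarray]) -> PredictiveDistribution:
    if model.train_blocks is None:
        raise ValueError("model was not fitted with stored feature blocks")
    grams = [compute_gram(tr, te, spec)
             for tr, te, spec in zip(model.train_blocks, test_blocks,
                                     model.specs)]
    return predict_proba(model, grams)
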