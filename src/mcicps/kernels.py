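"""Base kernels per modality and their convex (composite) combination.

Each modality's selected, standardized feature block is embedded in a
reproducing-kernel Hilbert space via a Gaussian or linear Gram matrix, and
the M per-modality kernels are combined as K = sum_m beta_m K_m with beta
on the probability simplex.  The default is the mean composite kernel,
beta_m = 1/M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .datatypes import SchemaError


@dataclass
class BaseKernelSpec:
    family: str          # "gaussian" | "linear"
    theta: float = 1.0   # Gaussian bandwidth (level of smoothing); unused for linear

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "linear"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family == "gaussian" and not self.theta > 0:
            raise ValueError("gaussian bandwidth theta must be positive")


def median_heuristic(x: np.ndarray) -> float:
    """Median pairwise Euclidean distance; default Gaussian bandwidth."""
    d = cdist(x, x)
    iu = np.triu_indices_from(d, k=1)
    med = float(np.median(d[iu])) if iu[0].size else 1.0
    return med if med > 0 else 1.0


def compute_gram(train_x: np.ndarray, other_x: np.ndarray | None,
                 spec: BaseKernelSpec) -> np.ndarray:
    """Gram block K(other, train); symmetric training Gram when other is None.

    Gaussian: K(i,j) = exp(-||x_i - x_j||^2 / (2 theta^2)); linear: <x_i, x_j>.
    """
    train_x = np.asarray(train_x, dtype=float)
    left = train_x if other_x is None else np.asarray(other_x, dtype=float)
    if left.shape[1] != train_x.shape[1]:
        raise SchemaError(
            f"kernel dimension mismatch: {left.shape[1]} vs {train_x.shape[1]}"
        )
    if spec.family == "linear":
        return left @ train_x.T
    d2 = cdist(left, train_x, metric="sqeuclidean")
    K = np.exp(-d2 / (2.0 * spec.theta**2))
    if other_x is None:
        K = (K + K.T) / 2.0
    return K


@dataclass
class KernelSet:
    """M Gram matrices with simplex weights beta."""

    grams: list[np.ndarray]
    beta: np.ndarray
    specs: list[BaseKernelSpec]

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.grams) != len(self.beta) or len(self.grams) != len(self.specs):
            raise ValueError("grams, beta and specs must have equal length")
        shape = self.grams[0].shape
        for g in self.grams[1:]:
            if g.shape != shape:
                raise ValueError("Gram matrices have mismatched shapes")
        _check_simplex(self.beta)

    @property
    def M(self) -> int:
        return len(self.grams)


def _check_simplex(beta: np.ndarray) -> None:
    if (beta < -1e-12).any() or abs(beta.sum() - 1.0) > 1e-8:
        raise ValueError("beta must be nonnegative and sum to 1")


def composite_kernel(ks: KernelSet) -> np.ndarray:
    """Weighted sum sum_m beta_m K_m (the mean kernel for uniform beta)."""
    out = np.zeros_like(ks.grams[0])
    for b, g in zip(ks.beta, ks.grams):
        out += b * g
    return out
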