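"""Undersampled stability selection with the screened Lasso.

Conversion-informative features are selected per modality by repeatedly
solving the L1 problem on balanced undersamples: every inner run keeps all
minority-class samples, draws an equal-sized random majority subset,
standardizes the subdesign, draws a penalty fraction from the configured
grid of lambda/lambda_max values spanning (0.05, 0.5), and solves the Lasso
(EDPP-screened from the zero solution at lambda_max).  Features with
nonzero coefficients are marked; counts accumulate over all outer x inner
runs.  The outer layer re-seeds the undersampler so the scheme matches the
nested repetition design (1000 inner x 50 outer by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import ModalityMatrix
from .lasso import LassoProblem, LassoSolution, edpp_screen, lambda_max, solve_lasso
from .metrics import rank_auc


def lambda_fraction_grid(low: float = 0.05, high: float = 0.5,
                         size: int = 10) -> np.ndarray:
    """Evenly spaced penalty fractions of lambda_max spanning (low, high)."""
    return np.linspace(low, high, size)


@dataclass
class SelectionProfile:
    """Per-feature selection counts from repeated undersampled Lasso."""

    feature_ids: list[str]
    counts: np.ndarray           # times selected, 0..inner*outer
    coef_abs_mean: np.ndarray    # mean |coefficient| across all runs
    inner: int
    outer: int
    tag: str
    lambda_fracs: np.ndarray

    @property
    def total_runs(self) -> int:
        return self.inner * self.outer


@dataclass
class FeatureRanking:
    """Features ordered by descending count; ties broken by mean |coef|,
    then lexicographic feature id."""

    ordered_ids: list[str]
    counts: np.ndarray           # aligned with ordered_ids
    tag: str
    chosen_n: int | None = None

    def top(self, n: int) -> list[str]:
        return self.ordered_ids[: min(n, len(self.ordered_ids))]


def _standardize_cols(A: np.ndarray) -> np.ndarray:
    mu = A.mean(axis=0)
    sd = A.std(axis=0)
    sd[sd == 0] = 1.0
    return (A - mu) / sd


def _one_run(A: np.ndarray, y: np.ndarray, frac: float,
             tol: float = 1e-8) -> LassoSolution:
    lmax = lambda_max(A, y)
    lam = frac * lmax
    zero = LassoSolution(np.zeros(A.shape[1]), 0.5 * float(y @ y), 0.0,
                         lmax, 0)
    rejected = edpp_screen(zero, lam, A, y)
    return solve_lasso(LassoProblem(A, y, lam), tol=tol,
                       keep=np.flatnonzero(~rejected))


def run_stability_selection(x: ModalityMatrix, labels: np.ndarray,
                            lambda_fracs: np.ndarray | None = None,
                            inner: int = 1000, outer: int = 50,
                            seed: int = 0) -> SelectionProfile:
    """Accumulate selection counts over outer x inner balanced-undersample runs.

    Deterministic given the seed; the outer layer spawns one substream per
    repetition.  Requires both conversion classes with at least 2 minority
    samples.
    """
    labels = np.asarray(labels, dtype=int)
    if lambda_fracs is None:
        lambda_fracs = lambda_fraction_grid()
    lambda_fracs = np.asarray(lambda_fracs, dtype=float)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if min(len(pos), len(neg)) < 2:
        raise ValueError(
            f"minority class has {min(len(pos), len(neg))} sample(s); need >= 2"
        )
    minority, majority = (pos, neg) if len(pos) <= len(neg) else (neg, pos)
    X = x.dense()
    if np.isnan(X).any():
        raise ValueError("impute missing entries before stability selection")
    n_feat = x.n_features
    counts = np.zeros(n_feat, dtype=int)
    coef_sum = np.zeros(n_feat)
    streams = np.random.SeedSequence(seed).spawn(outer)
    for ss in streams:
        rng = np.random.default_rng(ss)
        for _ in range(inner):
            maj_draw = rng.choice(majority, size=len(minority), replace=False)
            rows = np.concatenate([minority, maj_draw])
            A = _standardize_cols(X[rows])
            y = labels[rows].astype(float)
            y = y - y.mean()
            frac = float(rng.choice(lambda_fracs))
            sol = _one_run(A, y, frac)
            nz = sol.x != 0.0
            counts[nz] += 1
            coef_sum += np.abs(sol.x)
    total = inner * outer
    return SelectionProfile(list(x.feature_ids), counts, coef_sum / total,
                            inner, outer, x.tag, lambda_fracs)


def rank_features(profile: SelectionProfile) -> FeatureRanking:
    """Deterministic ranking: count desc, mean |coef| desc, id asc."""
    order = sorted(
        range(len(profile.feature_ids)),
        key=lambda j: (-profile.counts[j], -profile.coef_abs_mean[j],
                       profile.feature_ids[j]),
    )
    return FeatureRanking([profile.feature_ids[j] for j in order],
                          profile.counts[np.asarray(order)], profile.tag)


def choose_n_features(blocks: dict[str, ModalityMatrix], labels: np.ndarray,
                      n_grid_max: int = 100, cv_folds: int = 5,
                      cv_repeats: int = 50, inner: int = 100, outer: int = 5,
                      lambda_fracs: np.ndarray | None = None,
                      kernel_family: str = "gaussian",
                      seed: int = 0) -> tuple[int, np.ndarray]:
    """Pick the feature count maximizing mean CV AUC of the classifier.

    For each repetition and fold, rankings are recomputed on the training
    fold only (no leakage), the classifier is fit on the top-n features of
    every modality, and held-out scores are pooled per n.  Returns the
    chosen n (ties -> smallest) and the mean AUC per grid point.
    """
    from sklearn.model_selection import StratifiedKFold

    from .vbpmkl import fit_on_features, predict_on_features

    labels = np.asarray(labels, dtype=int)
    max_avail = min(b.n_features for b in blocks.values())
    if n_grid_max > max_avail:
        warnings.warn(
            f"n grid truncated to {max_avail} available features",
            stacklevel=2,
        )
        n_grid_max = max_avail
    n_grid = np.arange(1, n_grid_max + 1)
    aucs = np.zeros((cv_repeats, len(n_grid)))
    root = np.random.SeedSequence(seed)
    for rep, ss in enumerate(root.spawn(cv_repeats)):
        rep_seed = int(ss.generate_state(1)[0] % (2**31))
        skf = StratifiedKFold(cv_folds, shuffle=True, random_state=rep_seed)
        scores = np.full((len(n_grid), len(labels)), np.nan)
        for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)),
                                                  labels)):
            rankings = {}
            for tag, block in blocks.items():
                prof = run_stability_selection(
                    block.take_samples(tr), labels[tr],
                    lambda_fracs=lambda_fracs, inner=inner, outer=outer,
                    seed=rep_seed + 7919 * fold + sum(ord(c) for c in tag),
                )
                rankings[tag] = rank_features(prof)
            for gi, n in enumerate(n_grid):
                tr_blocks, te_blocks = [], []
                for tag, block in blocks.items():
                    ids = rankings[tag].top(int(n))
                    sub = block.select_features(ids)
                    mu = sub.values[tr].mean(axis=0)
                    sd = sub.values[tr].std(axis=0)
                    sd[sd == 0] = 1.0
                    tr_blocks.append((sub.values[tr] - mu) / sd)
                    te_blocks.append((sub.values[te] - mu) / sd)
                model = fit_on_features(tr_blocks, labels[tr],
                                        family=kernel_family)
                dist = predict_on_features(model, te_blocks)
                pos_col = int(np.argmax(model.class_values))
                scores[gi, te] = dist.proba[:, pos_col]
        for gi in range(len(n_grid)):
            aucs[rep, gi] = rank_auc(scores[gi], labels)
    mean_auc = aucs.mean(axis=0)
    best = int(n_grid[int(np.argmax(mean_auc))])  # argmax takes first max
    return best, mean_auc
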