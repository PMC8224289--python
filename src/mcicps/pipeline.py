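"""MCI-CPS: subtype-aware conversion prediction, end to end.

Training: genotype QC -> ICV adjustment -> z-scoring -> SNF subtyping on
the SNP + expression layers -> per subtype: undersampled stability-Lasso
feature selection per modality, Gaussian base kernels on the top-n
features, mean composite kernel, VBpMKL fit.  Prediction: a new patient is
assigned a subtype by label propagation over a joint fused network and
scored by that subtype's classifier.  The "Raw" classifier is the same
pipeline with the subtyping stage removed (one bundle for everyone).

All fitted statistics (QC decisions, imputation means, ICV slopes,
standardization parameters, selection counts, kernel bandwidths, VB
posteriors) derive from training data only.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .config import PipelineConfig
from .datatypes import Cohort, ModalityMatrix
from .metrics import EvaluationReport, evaluate
from .preprocess import (ICVAdjuster, MeanImputer, Standardizer,
                         apply_icv_adjuster, apply_standardizer,
                         fit_icv_adjuster, fit_standardizer, qc_genotypes)
from .selection import (lambda_fraction_grid, rank_features,
                        run_stability_selection)
from .snf import (SubtypeAssignment, build_affinity, label_propagate,
                  snf_fuse, spectral_cluster)
from .vbpmkl import (VBpMKLModel, fit_on_features, predict_on_features)

MODALITIES = ("snp", "expr", "roi")


@dataclass
class SubtypeBundle:
    """Everything a subtype-specific classifier needs at prediction time."""

    subtype: int
    icv_adjuster: ICVAdjuster
    standardizers: dict[str, Standardizer]
    selected: dict[str, list[str]]
    model: VBpMKLModel
    selection_counts: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class CPSModel:
    bundles: dict[int, SubtypeBundle]
    qc_kept: list[str]
    imputer: MeanImputer
    global_standardizers: dict[str, Standardizer]
    train_subtyping_blocks: dict[str, ModalityMatrix]
    train_subtypes: SubtypeAssignment
    config: PipelineConfig
    seed: int
    fused_change_norms: list[float] = field(default_factory=list)

    @property
    def C(self) -> int:
        return len(self.bundles)


def _bundle_blocks(cohort: Cohort, snp_imp: ModalityMatrix,
                   adjuster: ICVAdjuster,
                   standardizers: dict[str, Standardizer],
                   idx: np.ndarray | None = None) -> dict[str, ModalityMatrix]:
    """Apply a bundle's (or the global) preprocessing to cohort rows."""
    take = (lambda b: b if idx is None else b.take_samples(idx))
    icv = cohort.icv if idx is None else cohort.icv[idx]
    roi_adj = apply_icv_adjuster(adjuster, take(cohort.modalities["roi"]), icv)
    raw = {"snp": take(snp_imp), "expr": take(cohort.modalities["expr"]),
           "roi": roi_adj}
    return {t: apply_standardizer(standardizers[t], raw[t]) for t in MODALITIES}


def _fit_bundle(subtype: int, cohort: Cohort, snp_imp: ModalityMatrix,
                idx: np.ndarray, config: PipelineConfig,
                seed: int) -> SubtypeBundle:
    labels = cohort.labels[idx]
    if len(idx) < config.min_subtype_size:
        raise ValueError(
            f"subtype {subtype}: only {len(idx)} training samples "
            f"(need >= {config.min_subtype_size})"
        )
    if len(np.unique(labels)) < 2:
        raise ValueError(f"subtype {subtype}: a conversion class is missing")
    roi_sub = cohort.modalities["roi"].take_samples(idx)
    adjuster = fit_icv_adjuster(roi_sub, cohort.icv[idx])
    raw = {"snp": snp_imp.take_samples(idx),
           "expr": cohort.modalities["expr"].take_samples(idx),
           "roi": apply_icv_adjuster(adjuster, roi_sub, cohort.icv[idx])}
    standardizers = {t: fit_standardizer(raw[t]) for t in MODALITIES}
    std = {t: apply_standardizer(standardizers[t], raw[t]) for t in MODALITIES}
    fracs = lambda_fraction_grid(config.lambda_frac_low,
                                 config.lambda_frac_high,
                                 config.lambda_grid_size)
    selected: dict[str, list[str]] = {}
    counts: dict[str, np.ndarray] = {}
    for k, tag in enumerate(MODALITIES):
        profile = run_stability_selection(
            std[tag], labels, lambda_fracs=fracs,
            inner=config.inner_reps, outer=config.outer_reps,
            seed=seed + 101 * subtype + k,
        )
        ranking = rank_features(profile)
        n = min(config.n_features.get(tag, 20), std[tag].n_features)
        selected[tag] = ranking.top(n)
        counts[tag] = profile.counts
    blocks = [std[t].select_features(selected[t]).values for t in MODALITIES]
    model = fit_on_features(
        blocks, labels, family=config.kernel, phi=config.vb_phi,
        max_iter=config.vb_max_iter, tol=config.vb_tol,
        update_beta=config.update_beta, quad_nodes=config.vb_quadrature_nodes,
        seed=seed,
    )
    return SubtypeBundle(subtype, adjuster, standardizers, selected, model,
                         counts)


def _global_preprocess(train: Cohort, config: PipelineConfig):
    snp_qc, _report = qc_genotypes(train.modalities["snp"],
                                   config.qc_max_missing, config.qc_min_maf,
                                   config.qc_hwe_alpha)
    imputer = MeanImputer().fit(snp_qc)
    snp_imp = imputer.transform(snp_qc)
    adjuster = fit_icv_adjuster(train.modalities["roi"], train.icv)
    roi_adj = apply_icv_adjuster(adjuster, train.modalities["roi"], train.icv)
    raw = {"snp": snp_imp, "expr": train.modalities["expr"], "roi": roi_adj}
    standardizers = {t: fit_standardizer(raw[t]) for t in MODALITIES}
    std = {t: apply_standardizer(standardizers[t], raw[t]) for t in MODALITIES}
    return snp_qc, imputer, snp_imp, adjuster, standardizers, std


def train_mci_cps(train: Cohort, config: PipelineConfig | None = None) -> CPSModel:
    """Fit the subtyping-based conversion predictor on a training cohort."""
    config = config or PipelineConfig()
    seed = config.seed
    snp_qc, imputer, snp_imp, _adj, standardizers, std = _global_preprocess(
        train, config)
    K = min(config.snf_K, max(train.n_samples // 3, 2))
    aff = [build_affinity(std[t], K=K, mu=config.snf_mu)
           for t in ("snp", "expr")]
    fused = snf_fuse(aff, K=K, T=config.snf_T)
    assignment = spectral_cluster(fused, C=config.n_subtypes, seed=seed)
    bundles = {}
    for s in range(1, assignment.C + 1):
        idx = np.flatnonzero(assignment.labels == s)
        bundles[s] = _fit_bundle(s, train, snp_imp, idx, config, seed)
    return CPSModel(
        bundles=bundles, qc_kept=list(snp_qc.feature_ids), imputer=imputer,
        global_standardizers={t: standardizers[t] for t in ("snp", "expr")},
        train_subtyping_blocks={t: std[t] for t in ("snp", "expr")},
        train_subtypes=assignment, config=config, seed=seed,
        fused_change_norms=fused.change_norms,
    )


def train_raw_classifier(train: Cohort,
                         config: PipelineConfig | None = None) -> CPSModel:
    """Same pipeline without subtyping: a single bundle for all patients."""
    config = config or PipelineConfig()
    seed = config.seed
    snp_qc, imputer, snp_imp, _adj, standardizers, std = _global_preprocess(
        train, config)
    idx = np.arange(train.n_samples)
    bundle = _fit_bundle(1, train, snp_imp, idx, config, seed)
    assignment = SubtypeAssignment(np.ones(train.n_samples, dtype=int), 1,
                                   "clustered", list(train.sample_ids),
                                   np.ones((train.n_samples, 1)))
    return CPSModel(
        bundles={1: bundle}, qc_kept=list(snp_qc.feature_ids),
        imputer=imputer,
        global_standardizers={t: standardizers[t] for t in ("snp", "expr")},
        train_subtyping_blocks={t: std[t] for t in ("snp", "expr")},
        train_subtypes=assignment, config=config, seed=seed,
    )


def _new_processed_snp(model: CPSModel, new: Cohort) -> ModalityMatrix:
    snp = new.modalities["snp"].select_features(model.qc_kept)
    return model.imputer.transform(snp)


def predict_mci_cps(model: CPSModel,
                    new: Cohort) -> tuple[SubtypeAssignment, np.ndarray]:
    """Route new patients to subtype bundles and score P(P-MCI).

    Returns the propagated subtype assignment and an (N, 2) probability
    array over (S-MCI, P-MCI), rows in the input sample order.
    """
    cfg = model.config
    snp_imp = _new_processed_snp(model, new)
    if model.C == 1:
        assignment = SubtypeAssignment(
            np.ones(new.n_samples, dtype=int), 1, "propagated",
            list(new.sample_ids), np.ones((new.n_samples, 1)))
    else:
        new_raw = {"snp": snp_imp, "expr": new.modalities["expr"]}
        new_std = {t: apply_standardizer(model.global_standardizers[t],
                                         new_raw[t]) for t in ("snp", "expr")}
        K = min(cfg.snf_K,
                max((new.n_samples + model.train_subtypes.labels.size) // 3, 2))
        assignment = label_propagate(
            model.train_subtyping_blocks, model.train_subtypes, new_std,
            K=K, mu=cfg.snf_mu, T=cfg.snf_T, alpha=cfg.lp_alpha,
            tol=cfg.lp_tol, max_iter=cfg.lp_max_iter,
        )
        assignment.sample_ids = list(new.sample_ids)
    proba = np.zeros((new.n_samples, 2))
    for s, bundle in model.bundles.items():
        idx = np.flatnonzero(assignment.labels == s)
        if idx.size == 0:
            continue
        blocks_std = _bundle_blocks(new, snp_imp, bundle.icv_adjuster,
                                    bundle.standardizers, idx)
        te = [blocks_std[t].select_features(bundle.selected[t]).values
              for t in MODALITIES]
        dist = predict_on_features(bundle.model, te)
        pos_col = int(np.argmax(bundle.model.class_values))
        proba[idx, 1] = dist.proba[:, pos_col]
        proba[idx, 0] = 1.0 - proba[idx, 1]
    return assignment, proba


def cross_validate(cohort: Cohort, kind: str = "cps", folds: int = 5,
                   repeats: int = 1, seed: int = 0,
                   config: PipelineConfig | None = None) -> EvaluationReport:
    """Repeated stratified k-fold evaluation with all fitting inside folds.

    Subtyping, feature selection, and every fitted statistic are recomputed
    on each training fold; test-fold patients are subtyped by propagation.
    Out-of-fold scores are pooled (across repeats as well) into one report.
    """
    if kind not in ("cps", "raw"):
        raise ValueError("kind must be 'cps' or 'raw'")
    config = config or PipelineConfig()
    strata = cohort.labels.astype(str)
    if cohort.subtype_truth is not None:
        strata = np.char.add(strata,
                             np.char.add("_", cohort.subtype_truth.astype(str)))
    strata_codes = pd.factorize(strata)[0]
    all_scores, all_labels, all_subtypes = [], [], []
    root = np.random.SeedSequence(seed)
    for ss in root.spawn(repeats):
        rep_seed = int(ss.generate_state(1)[0] % (2**31))
        skf = StratifiedKFold(folds, shuffle=True, random_state=rep_seed)
        scores = np.full(cohort.n_samples, np.nan)
        subs = np.zeros(cohort.n_samples, dtype=int)
        for tr, te in skf.split(np.zeros(cohort.n_samples), strata_codes):
            train_c, test_c = cohort.take(tr), cohort.take(te)
            fold_cfg = dataclasses.replace(config, seed=rep_seed)
            if kind == "cps":
                model = train_mci_cps(train_c, fold_cfg)
            else:
                model = train_raw_classifier(train_c, fold_cfg)
            assignment, proba = predict_mci_cps(model, test_c)
            scores[te] = proba[:, 1]
            subs[te] = assignment.labels
        all_scores.append(scores)
        all_labels.append(cohort.labels)
        all_subtypes.append(subs)
    return evaluate(np.concatenate(all_scores), np.concatenate(all_labels),
                    tau=config.threshold,
                    subtypes=np.concatenate(all_subtypes))


@dataclass
class GiniImportanceReport:
    table: pd.DataFrame            # feature_id, source, importance (desc)
    per_source: dict[str, float]


def gini_importance(blocks: dict[str, np.ndarray],
                    feature_ids: dict[str, list[str]], labels: np.ndarray,
                    n_trees: int = 500, repeats: int = 10,
                    seed: int = 0) -> GiniImportanceReport:
    """Random-forest mean decrease in Gini impurity over the selected features.

    Features from all modalities are concatenated; importances are averaged
    over trees and over ``repeats`` forest seeds, then reported per feature
    (with source tag) and averaged per source.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes for importance estimation")
    X = np.hstack([blocks[t] for t in sorted(blocks)])
    ids, sources = [], []
    for t in sorted(blocks):
        ids.extend(feature_ids[t])
        sources.extend([t] * blocks[t].shape[1])
    imp = np.zeros(X.shape[1])
    for r in range(repeats):
        rf = RandomForestClassifier(
            n_estimators=n_trees, criterion="gini", max_features="sqrt",
            random_state=seed + r, n_jobs=1,
        ).fit(X, labels)
        imp += rf.feature_importances_
    imp /= repeats
    table = (pd.DataFrame({"feature_id": ids, "source": sources,
                           "importance": imp})
             .sort_values("importance", ascending=False)
             .reset_index(drop=True))
    per_source = table.groupby("source")["importance"].mean().to_dict()
    return GiniImportanceReport(table, per_source)


def model_param_hash(model: CPSModel) -> str:
    """Digest of every fitted parameter; used by leakage self-checks."""
    h = hashlib.sha256()
    for s in sorted(model.bundles):
        b = model.bundles[s]
        h.update(np.ascontiguousarray(b.icv_adjuster.theta).tobytes())
        for t in MODALITIES:
            std = b.standardizers[t]
            h.update(np.ascontiguousarray(std.mean).tobytes())
            h.update(np.ascontiguousarray(std.sd).tobytes())
            h.update(",".join(b.selected[t]).encode())
        h.update(np.ascontiguousarray(b.model.W_mean).tobytes())
        h.update(np.ascontiguousarray(b.model.beta).tobytes())
    h.update(np.ascontiguousarray(model.imputer.means).tobytes())
    h.update(np.ascontiguousarray(model.train_subtypes.labels).tobytes())
    return h.hexdigest()
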