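"""Synthetic multi-modal MCI cohorts with known ground truth.

The generator plants two latent molecular subtypes in the genotype and
expression layers, subtype-specific conversion-informative features in all
three layers (disjoint sets per subtype within each modality), and regional
brain volumes linearly confounded by intracranial volume.  Every injected
signal is returned as ground-truth annotations so downstream stages
(subtyping, feature selection, classification) can be scored against truth.

Signal model per sample with subtype z in {1, 2}:

* SNP ``j``: genotype ~ Binomial(2, p_j) with base minor-allele frequency
  p_j ~ U(0.05, 0.5).  Subtype-informative SNPs shift p_j by +/- the allele
  frequency effect depending on z.  Conversion-informative SNPs of the
  sample's own subtype shift p_j for converters so the genotype mean moves
  by ``conversion_effect`` genotype SDs.
* Expression: Normal noise around 0; subtype-informative genes are
  mean-shifted +/- ``subtype_effect_expr`` SDs by subtype; converters get an
  extra ``conversion_effect`` SD shift on their own subtype's
  conversion-informative genes.
* ROI volume (mL): baseline_j + theta_j * ICV + conversion shift + noise,
  ICV ~ Normal(icv_mean, icv_sd^2).  theta_j are the known per-ROI
  ICV-confounding slopes.

Conversion labels are drawn Bernoulli(rate of the sample's subtype) and the
conversion shifts are additive after the label draw, so per-feature effect
sizes are exactly the configured values.
"""

from __future__ import annotations

import numpy as np

from .config import ConfigError, SyntheticConfig
from .datatypes import Cohort, ModalityMatrix


def _snp_ids(n):
    return [f"rs{i:05d}" for i in range(n)]


def _expr_ids(n):
    return [f"gene_{i:04d}" for i in range(n)]


def _roi_ids(n):
    return [f"roi_{i:03d}" for i in range(n)]


def generate_cohort(config: SyntheticConfig, n_samples: int | None = None,
                    seed: int | None = None) -> Cohort:
    """Generate one cohort of ``n_samples`` (default n_train + n_test).

    Ground truth (informative feature sets per subtype, allele frequencies,
    ROI slopes and baselines, subtype assignment) is attached as
    ``cohort.truth`` and ``cohort.subtype_truth``.  Deterministic given the
    seed (``config.seed`` unless overridden).
    """
    if not isinstance(config, SyntheticConfig):
        raise ConfigError("config: expected a SyntheticConfig")
    n = int(n_samples) if n_samples is not None else config.n_train + config.n_test
    if n < 2:
        raise ConfigError("n_samples: need at least 2 samples")
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    # fixed spawn order -> stages can be regenerated independently
    r_sub, r_lab, r_icv, r_snp, r_expr, r_roi, r_miss = (
        np.random.default_rng(s) for s in root.spawn(7)
    )

    subtype = r_sub.integers(1, 3, size=n)  # z ~ Bernoulli(0.5) over {1,2}
    rates = np.where(subtype == 1, config.conversion_rate_subtype1,
                     config.conversion_rate_subtype2)
    labels = (r_lab.random(n) < rates).astype(int)
    icv = r_icv.normal(config.icv_mean, config.icv_sd, size=n)
    icv = np.clip(icv, 0.5 * config.icv_mean, None)  # keep strictly positive

    k = config.n_conv_informative_per_modality
    conv_mask = {}  # tag -> (n, n_feat) bool: sample gets conversion shift here

    def _conv_columns(n_feat: int, start: int) -> tuple[list[int], list[int]]:
        c1 = list(range(start, start + k))
        c2 = list(range(start + k, start + 2 * k))
        return c1, c2

    def _conv_shift_mask(n_feat, c1, c2):
        m = np.zeros((n, n_feat), dtype=bool)
        conv = labels == 1
        m[np.ix_(conv & (subtype == 1), c1)] = True
        m[np.ix_(conv & (subtype == 2), c2)] = True
        return m

    # ---- SNP layer -------------------------------------------------------
    nsnp = config.n_snp
    sub_snp = list(range(config.n_subtype_informative_snp))
    c1_snp, c2_snp = _conv_columns(nsnp, config.n_subtype_informative_snp)
    p_base = r_snp.uniform(0.05, 0.5, size=nsnp)
    P = np.tile(p_base, (n, 1))
    e = config.subtype_effect_snp
    shift = np.zeros((n, nsnp))
    shift[np.ix_(subtype == 1, sub_snp)] = +e
    shift[np.ix_(subtype == 2, sub_snp)] = -e
    P = np.clip(P + shift, 0.05, 0.95)
    # converters: move genotype mean by conversion_effect genotype SDs
    cm = _conv_shift_mask(nsnp, c1_snp, c2_snp)
    dp = config.conversion_effect * np.sqrt(2 * P * (1 - P)) / 2.0
    P = np.clip(P + np.where(cm, dp, 0.0), 0.01, 0.99)
    snp_vals = r_snp.binomial(2, P).astype(float)
    miss = r_miss.random((n, nsnp)) < config.snp_missing_rate
    snp_vals[miss] = np.nan
    conv_mask["snp"] = cm

    # ---- expression layer ------------------------------------------------
    nexpr = config.n_expr
    sub_expr = list(range(config.n_subtype_informative_expr))
    c1_expr, c2_expr = _conv_columns(nexpr, config.n_subtype_informative_expr)
    mu = np.zeros((n, nexpr))
    ee = config.subtype_effect_expr * config.noise_sd
    mu[np.ix_(subtype == 1, sub_expr)] = +ee
    mu[np.ix_(subtype == 2, sub_expr)] = -ee
    cm = _conv_shift_mask(nexpr, c1_expr, c2_expr)
    mu += np.where(cm, config.conversion_effect * config.noise_sd, 0.0)
    expr_vals = mu + r_expr.normal(0.0, config.noise_sd, size=(n, nexpr))
    conv_mask["expr"] = cm

    # ---- ROI layer -------------------------------------------------------
    nroi = config.n_roi
    c1_roi, c2_roi = _conv_columns(nroi, 0)
    lo, hi = config.roi_icv_slope_range
    theta = r_roi.uniform(lo, hi, size=nroi)
    baseline = r_roi.uniform(3.0, 60.0, size=nroi)
    cm = _conv_shift_mask(nroi, c1_roi, c2_roi)
    roi_vals = (
        baseline[None, :]
        + np.outer(icv, theta)
        + np.where(cm, config.conversion_effect * config.noise_sd, 0.0)
        + r_roi.normal(0.0, config.noise_sd, size=(n, nroi))
    )
    conv_mask["roi"] = cm

    snp_ids, expr_ids, roi_ids = _snp_ids(nsnp), _expr_ids(nexpr), _roi_ids(nroi)
    truth = {
        "subtype_informative": {
            "snp": [snp_ids[i] for i in sub_snp],
            "expr": [expr_ids[i] for i in sub_expr],
        },
        "conv_informative": {
            1: {"snp": [snp_ids[i] for i in c1_snp],
                "expr": [expr_ids[i] for i in c1_expr],
                "roi": [roi_ids[i] for i in c1_roi]},
            2: {"snp": [snp_ids[i] for i in c2_snp],
                "expr": [expr_ids[i] for i in c2_expr],
                "roi": [roi_ids[i] for i in c2_roi]},
        },
        "snp_base_maf": p_base,
        "roi_icv_slopes": theta,
        "roi_baselines": baseline,
    }
    return Cohort(
        modalities={
            "snp": ModalityMatrix(snp_vals, snp_ids, "snp"),
            "expr": ModalityMatrix(expr_vals, expr_ids, "expr"),
            "roi": ModalityMatrix(roi_vals, roi_ids, "roi"),
        },
        sample_ids=[f"S{i:04d}" for i in range(n)],
        labels=labels,
        icv=icv,
        subtype_truth=subtype,
        truth=truth,
    )


def generate_train_test(config: SyntheticConfig,
                        seed: int | None = None) -> tuple[Cohort, Cohort]:
    """One draw of the study: first ``n_train`` samples train, rest test."""
    full = generate_cohort(config, seed=seed)
    idx = np.arange(full.n_samples)
    return full.take(idx[: config.n_train]), full.take(idx[config.n_train:])


def split_cohort(cohort: Cohort, fraction: float, stratify_on=None,
                 seed: int = 0) -> tuple[Cohort, Cohort]:
    """Stratified disjoint split into (first, second) parts.

    ``fraction`` of the samples (floor of fraction * N overall) go to the
    first part.  Per-stratum sizes use the largest-remainder rule: each
    stratum contributes floor(fraction * n_s), and the leftover slots are
    given to the strata with the largest fractional parts, so stated label
    proportions are preserved within +/- 1 sample per stratum.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    strata = (np.asarray(stratify_on) if stratify_on is not None
              else cohort.labels)
    if strata.shape != (cohort.n_samples,):
        raise ValueError("stratify_on length must match cohort size")
    rng = np.random.default_rng(seed)
    total_first = int(np.floor(fraction * cohort.n_samples))
    uniq = [u for u in np.unique(strata)]
    sizes = {u: int((strata == u).sum()) for u in uniq}
    for u, ns in sizes.items():
        if ns < 2:
            raise ValueError(f"stratum {u!r} has {ns} sample(s); need >= 2")
    exact = {u: fraction * sizes[u] for u in uniq}
    base = {u: int(np.floor(exact[u])) for u in uniq}
    leftover = total_first - sum(base.values())
    order = sorted(uniq, key=lambda u: (-(exact[u] - base[u]), str(u)))
    for u in order[: max(leftover, 0)]:
        base[u] += 1
    first_idx = []
    for u in uniq:
        members = np.flatnonzero(strata == u)
        perm = rng.permutation(members)
        first_idx.extend(perm[: base[u]].tolist())
    first_idx = np.sort(np.asarray(first_idx, dtype=int))
    second_idx = np.setdiff1d(np.arange(cohort.n_samples), first_idx)
    return cohort.take(first_idx), cohort.take(second_idx)
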