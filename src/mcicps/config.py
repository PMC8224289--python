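"""Configuration objects for the synthetic generator and the pipeline.

Both are plain dataclasses with eager validation; YAML round-trip helpers
reject unknown keys so a typo in a config file fails before any compute.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

CONFIG_SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid configuration value; the message names the offending field."""


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{fieldname}: {msg}")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic multi-modal MCI cohort.

    The generator emulates a cohort with two latent molecular subtypes
    expressed in the SNP and expression layers, subtype-specific
    conversion-informative features in all three layers, and regional brain
    volumes linearly confounded by intracranial volume (ICV).

    Effect-size conventions: ``subtype_effect_snp`` is an allele-frequency
    shift (+/- by subtype), ``subtype_effect_expr`` and ``conversion_effect``
    are standardized mean shifts (units of the feature's noise SD).
    """

    n_train: int = 150
    n_test: int = 100
    n_snp: int = 100
    n_expr: int = 100
    n_roi: int = 60
    n_subtype_informative_snp: int = 40
    n_subtype_informative_expr: int = 30
    n_conv_informative_per_modality: int = 10
    subtype_effect_snp: float = 0.15
    subtype_effect_expr: float = 1.0
    conversion_effect: float = 1.0
    conversion_rate_subtype1: float = 0.45
    conversion_rate_subtype2: float = 0.33
    icv_mean: float = 1500.0
    icv_sd: float = 120.0
    roi_icv_slope_range: tuple[float, float] = (0.002, 0.02)
    noise_sd: float = 1.0
    snp_missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (
            "n_train", "n_test", "n_snp", "n_expr", "n_roi",
            "n_subtype_informative_snp", "n_subtype_informative_expr",
            "n_conv_informative_per_modality",
        ):
            _check(int(getattr(self, f)) > 0, f, "must be a positive count")
        for f in (
            "conversion_rate_subtype1", "conversion_rate_subtype2",
            "snp_missing_rate",
        ):
            _check(0.0 <= getattr(self, f) <= 1.0, f, "must lie in [0, 1]")
        _check(self.icv_mean > 0, "icv_mean", "must be positive (mL)")
        _check(self.icv_sd > 0, "icv_sd", "must be positive (mL)")
        _check(self.noise_sd > 0, "noise_sd", "must be positive")
        _check(self.subtype_effect_snp >= 0, "subtype_effect_snp", "must be >= 0")
        _check(self.subtype_effect_expr >= 0, "subtype_effect_expr", "must be >= 0")
        lo, hi = self.roi_icv_slope_range
        _check(lo <= hi, "roi_icv_slope_range", "lower bound exceeds upper")
        # informative sets must fit: subtype block + two disjoint
        # conversion-informative blocks per modality
        k = self.n_conv_informative_per_modality
        _check(
            self.n_subtype_informative_snp + 2 * k <= self.n_snp,
            "n_subtype_informative_snp",
            "subtype + 2x conversion informative SNP sets exceed n_snp",
        )
        _check(
            self.n_subtype_informative_expr + 2 * k <= self.n_expr,
            "n_subtype_informative_expr",
            "subtype + 2x conversion informative expr sets exceed n_expr",
        )
        _check(2 * k <= self.n_roi, "n_conv_informative_per_modality",
               "2x conversion informative ROI sets exceed n_roi")


@dataclass
class PipelineConfig:
    """Parameters of the full subtyping + prediction pipeline.

    Defaults follow the method description: genotype QC thresholds
    0.05 / 0.05 / 1e-3 (missing rate, minor allele frequency, HWE p);
    Lasso penalty fractions spanning (0.05, 0.5) of lambda_max with the
    inner/outer undersampled repetition scheme; two subtypes; three
    Gaussian base kernels combined as the mean composite kernel; fivefold
    cross-validation.
    """

    # genotype QC
    qc_max_missing: float = 0.05
    qc_min_maf: float = 0.05
    qc_hwe_alpha: float = 1e-3
    # SNF / subtyping
    snf_K: int = 20
    snf_mu: float = 0.5
    snf_T: int = 20
    n_subtypes: int = 2
    # label propagation
    lp_alpha: float = 0.99
    lp_tol: float = 1e-6
    lp_max_iter: int = 1000
    # stability Lasso
    lambda_frac_low: float = 0.05
    lambda_frac_high: float = 0.5
    lambda_grid_size: int = 10
    inner_reps: int = 1000
    outer_reps: int = 50
    n_features_grid_max: int = 100
    n_features: dict = field(
        default_factory=lambda: {"snp": 20, "expr": 20, "roi": 20}
    )
    # VBpMKL
    kernel: str = "gaussian"
    vb_phi: float = 1.0
    vb_max_iter: int = 5000
    vb_tol: float = 1e-5
    vb_quadrature_nodes: int = 64
    update_beta: bool = False
    # evaluation
    cv_folds: int = 5
    cv_repeats: int = 1
    threshold: float = 0.5
    min_subtype_size: int = 10
    seed: int = 0
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        _check(0 < self.qc_max_missing < 1, "qc_max_missing", "must be in (0,1)")
        _check(0 <= self.qc_min_maf <= 0.5, "qc_min_maf", "must be in [0,0.5]")
        _check(0 < self.qc_hwe_alpha < 1, "qc_hwe_alpha", "must be in (0,1)")
        _check(self.snf_K >= 2, "snf_K", "needs at least 2 neighbors")
        _check(self.snf_mu > 0, "snf_mu", "must be positive")
        _check(self.n_subtypes >= 1, "n_subtypes", "must be >= 1")
        _check(0 < self.lp_alpha < 1, "lp_alpha", "must be in (0,1)")
        _check(
            0 < self.lambda_frac_low < self.lambda_frac_high < 1,
            "lambda_frac_low", "need 0 < low < high < 1",
        )
        _check(self.inner_reps >= 1, "inner_reps", "must be >= 1")
        _check(self.outer_reps >= 1, "outer_reps", "must be >= 1")
        _check(self.kernel in ("gaussian", "linear"), "kernel",
               "must be 'gaussian' or 'linear'")
        _check(self.vb_phi > 0, "vb_phi", "must be positive")
        _check(0 < self.threshold < 1, "threshold", "must be in (0,1)")
        _check(self.cv_folds >= 2, "cv_folds", "must be >= 2")


def _from_mapping(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "roi_icv_slope_range" in data and isinstance(
        data["roi_icv_slope_range"], list
    ):
        data = dict(data)
        data["roi_icv_slope_range"] = tuple(data["roi_icv_slope_range"])
    return cls(**data)


def load_config(path: str | Path, kind: str = "pipeline"):
    """Load a YAML config; ``kind`` is 'pipeline' or 'synthetic'."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    cls = {"pipeline": PipelineConfig, "synthetic": SyntheticConfig}[kind]
    return _from_mapping(cls, data)


def dump_config(cfg, path: str | Path) -> None:
    data = dataclasses.asdict(cfg)
    if "roi_icv_slope_range" in data:
        data["roi_icv_slope_range"] = list(data["roi_icv_slope_range"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
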