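"""Training-fitted preprocessing: genotype QC, ICV adjustment, z-scoring.

All transformers follow the fit-on-train / apply-to-test discipline; no
statistic is ever computed from data the transformer is applied to.

Genotype QC drops SNPs with missing rate > 0.05, minor allele frequency
< 0.05, or Hardy-Weinberg equilibrium p < 1e-3 (defaults; strict
inequalities).  HWE is a 1-df chi-square of the observed genotype counts
against the Hardy-Weinberg expectation at the observed allele frequency.

ICV adjustment removes the head-size confound from regional brain volumes:

    ROI_adjusted_i = ROI_raw_i - theta_i * (ICV - ICV_mean)

with theta_i the OLS slope of ROI i on ICV over the training samples and
ICV_mean the training-set mean ICV.  Only the slope component about
ICV_mean is removed, so each ROI keeps its natural volume scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ModalityMatrix, SchemaError


class CodingError(ValueError):
    """Genotype matrix contains values outside {0, 1, 2, missing}."""


@dataclass
class GenotypeQCReport:
    """Per-SNP QC statistics and keep/drop decisions."""

    table: pd.DataFrame  # feature_id, missing_rate, maf, hwe_chi2, hwe_p, keep, reason

    @property
    def kept(self) -> list[str]:
        return self.table.loc[self.table["keep"], "feature_id"].tolist()

    @property
    def dropped(self) -> pd.DataFrame:
        return self.table.loc[~self.table["keep"]]


def hwe_chi2(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """1-df chi-square HWE test on genotype counts (AA, Aa, aa).

    Expected counts use the observed allele frequency; no continuity
    correction.  Monomorphic input gives (0.0, 1.0) — it is in exact HWE.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 0.0, 1.0
    p = (2 * n_bb + n_ab) / (2 * n)  # frequency of the 'a' allele (coded 2)
    if p <= 0.0 or p >= 1.0:
        return 0.0, 1.0
    exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def qc_genotypes(snp: ModalityMatrix, max_missing: float = 0.05,
                 min_maf: float = 0.05,
                 hwe_alpha: float = 1e-3) -> tuple[ModalityMatrix, GenotypeQCReport]:
    """Filter SNP columns by missing rate, MAF, then HWE (in that order).

    Each filter is evaluated on non-missing calls; a SNP is dropped at the
    first stage it fails (reason in {'missing', 'maf', 'hwe'}), and later
    statistics are still reported for reference.  Strict inequalities:
    drop iff missing rate > max_missing, MAF < min_maf, or HWE p < hwe_alpha.
    """
    if snp.tag != "snp":
        raise SchemaError("qc_genotypes expects the snp modality")
    vals = snp.values
    ok = snp.mask | np.isin(np.nan_to_num(vals, nan=-1.0), [0.0, 1.0, 2.0])
    if not ok.all():
        bad = vals[~ok]
        raise CodingError(
            f"genotypes must be coded 0/1/2/missing; found e.g. {bad.flat[0]!r}"
        )
    n, m = vals.shape
    rows = []
    for j in range(m):
        obs = vals[~snp.mask[:, j], j]
        miss_rate = float(snp.mask[:, j].mean())
        n_aa = int((obs == 0).sum())
        n_ab = int((obs == 1).sum())
        n_bb = int((obs == 2).sum())
        tot = max(n_aa + n_ab + n_bb, 1)
        p = (2 * n_bb + n_ab) / (2 * tot)
        maf = float(min(p, 1 - p))
        chi2, hwe_p = hwe_chi2(n_aa, n_ab, n_bb)
        if miss_rate > max_missing:
            keep, reason = False, "missing"
        elif maf < min_maf:
            keep, reason = False, "maf"
        elif hwe_p < hwe_alpha:
            keep, reason = False, "hwe"
        else:
            keep, reason = True, ""
        rows.append((snp.feature_ids[j], miss_rate, maf, chi2, hwe_p, keep, reason))
    table = pd.DataFrame(
        rows,
        columns=["feature_id", "missing_rate", "maf", "hwe_chi2", "hwe_p",
                 "keep", "reason"],
    )
    report = GenotypeQCReport(table)
    return snp.select_features(report.kept), report


@dataclass
class MeanImputer:
    """Per-feature mean imputation of missing genotype calls, fit on train."""

    feature_ids: list[str] | None = None
    means: np.ndarray | None = None

    def fit(self, x: ModalityMatrix) -> "MeanImputer":
        dense = x.dense()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing cols
            self.means = np.nanmean(dense, axis=0)
        self.means = np.nan_to_num(self.means, nan=0.0)
        self.feature_ids = list(x.feature_ids)
        return self

    def transform(self, x: ModalityMatrix) -> ModalityMatrix:
        if self.means is None or x.feature_ids != self.feature_ids:
            raise SchemaError("imputer fitted on different features")
        vals = x.values.copy()
        fill = np.broadcast_to(self.means, vals.shape)
        vals[x.mask] = fill[x.mask]
        return ModalityMatrix(vals, list(x.feature_ids), x.tag,
                              np.zeros_like(x.mask))


@dataclass
class ICVAdjuster:
    """Per-ROI OLS slopes on ICV plus the training mean ICV."""

    feature_ids: list[str]
    theta: np.ndarray       # slope of ROI_i on ICV (mL volume per mL ICV)
    icv_mean: float
    intercepts: np.ndarray  # diagnostics only; not used by apply


def fit_icv_adjuster(roi: ModalityMatrix, icv: np.ndarray) -> ICVAdjuster:
    """OLS slope of each ROI volume on ICV over the training samples."""
    icv = np.asarray(icv, dtype=float)
    if roi.n_samples < 3:
        raise ValueError("need at least 3 samples to fit the ICV regression")
    ic = icv - icv.mean()
    var = float(ic @ ic)
    if var <= 0:
        raise ValueError("ICV is constant; regression on ICV is degenerate")
    theta = (roi.values - roi.values.mean(axis=0)).T @ ic / var
    intercepts = roi.values.mean(axis=0) - theta * icv.mean()
    return ICVAdjuster(list(roi.feature_ids), theta, float(icv.mean()), intercepts)


def apply_icv_adjuster(adj: ICVAdjuster, roi: ModalityMatrix,
                       icv: np.ndarray) -> ModalityMatrix:
    """Remove the ICV slope component about the training mean ICV."""
    if list(roi.feature_ids) != adj.feature_ids:
        raise SchemaError("ROI columns differ from those the adjuster was fit on")
    icv = np.asarray(icv, dtype=float)
    vals = roi.values - np.outer(icv - adj.icv_mean, adj.theta)
    return ModalityMatrix(vals, list(roi.feature_ids), roi.tag, roi.mask.copy())


@dataclass
class Standardizer:
    """Per-feature z-scoring with training mean/SD; zero-variance columns dropped."""

    feature_ids: list[str] | None = None
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None


def fit_standardizer(x: ModalityMatrix) -> Standardizer:
    mean = x.values.mean(axis=0)
    sd = x.values.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(x.feature_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s): {dropped[:5]}...",
            stacklevel=2,
        )
    ids = [f for f, k in zip(x.feature_ids, keep) if k]
    return Standardizer(ids, mean[keep], sd[keep])


def apply_standardizer(s: Standardizer, x: ModalityMatrix) -> ModalityMatrix:
    if s.feature_ids is None:
        raise SchemaError("standardizer not fitted")
    sub = x.select_features(s.feature_ids)
    vals = (sub.values - s.mean) / s.sd
    return ModalityMatrix(vals, list(s.feature_ids), x.tag, sub.mask.copy())
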