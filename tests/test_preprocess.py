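"""Genotype QC, ICV adjustment, and standardization contracts."""

import numpy as np
import pytest

from mcicps.datatypes import ModalityMatrix
from mcicps.preprocess import (MeanImputer, apply_icv_adjuster,
                               apply_standardizer, fit_icv_adjuster,
                               fit_standardizer, hwe_chi2, qc_genotypes)


def _snp(values):
    values = np.asarray(values, dtype=float)
    return ModalityMatrix(values,
                          [f"rs{j}" for j in range(values.shape[1])], "snp")


class TestGenotypeQC:
    def test_missing_rate_filter(self, rng):
        vals = rng.integers(0, 2, size=(100, 2)).astype(float)
        vals[:, 0] = rng.binomial(2, 0.3, 100)  # healthy column
        vals[:6, 1] = np.nan                    # 6% missing -> dropped
        kept, report = qc_genotypes(_snp(vals))
        row = report.table.set_index("feature_id").loc["rs1"]
        assert not row["keep"] and row["reason"] == "missing"

    def test_exact_threshold_kept(self, rng):
        # missing rate exactly 0.05 is NOT above the threshold
        vals = np.tile(rng.binomial(2, 0.4, 100)[:, None], (1, 1)).astype(float)
        vals[:5, 0] = np.nan
        _, report = qc_genotypes(_snp(vals))
        assert report.table.loc[0, "reason"] != "missing"

    def test_monomorphic_dropped_as_maf(self):
        vals = np.zeros((50, 1))
        kept, report = qc_genotypes(_snp(vals))
        assert kept.n_features == 0
        assert report.table.loc[0, "reason"] == "maf"
        assert report.table.loc[0, "maf"] == 0.0

    def test_hwe_hand_example(self):
        """(AA,Aa,aa)=(50,0,50): p=0.5, expected (25,50,25), chi2=100."""
        chi2, p = hwe_chi2(50, 0, 50)
        assert chi2 == pytest.approx(100.0)
        assert p < 1e-3
        chi2_eq, p_eq = hwe_chi2(25, 50, 25)
        assert chi2_eq == pytest.approx(0.0)
        assert p_eq == pytest.approx(1.0)

    def test_hwe_column_dropped(self):
        col = np.concatenate([np.zeros(50), 2 * np.ones(50)])
        kept, report = qc_genotypes(_snp(col[:, None]))
        assert report.table.loc[0, "reason"] == "hwe"
        assert report.table.loc[0, "hwe_chi2"] == pytest.approx(100.0)

    def test_qc_idempotent(self, cohort):
        kept1, _ = qc_genotypes(cohort.modalities["snp"])
        kept2, _ = qc_genotypes(kept1)
        assert kept1.feature_ids == kept2.feature_ids

    def test_bad_coding_rejected(self):
        with pytest.raises(ValueError, match="coded"):
            qc_genotypes(_snp([[0, 3.0], [1, 1]]))


class TestICVAdjustment:
    def test_exact_slope_recovery(self, rng):
        icv = rng.normal(1500, 100, 40)
        roi = np.column_stack([2.0 * icv + 5.0, rng.normal(size=40)])
        adj = fit_icv_adjuster(
            ModalityMatrix(roi, ["a", "b"], "roi"), icv)
        assert adj.theta[0] == pytest.approx(2.0)
        assert abs(adj.theta[1]) < 0.01  # uncorrelated -> slope ~ 0
        assert adj.icv_mean == pytest.approx(icv.mean())

    def test_known_synthetic_slopes_recovered(self, cohort):
        adj = fit_icv_adjuster(cohort.modalities["roi"], cohort.icv)
        theta_true = cohort.truth["roi_icv_slopes"]
        resid_sd = cohort.modalities["roi"].values.std(axis=0)
        se = resid_sd / (cohort.icv.std() * np.sqrt(cohort.n_samples))
        assert (np.abs(adj.theta - theta_true) < 3 * se).all()

    def test_adjusted_roi_orthogonal_to_icv(self, cohort):
        adj = fit_icv_adjuster(cohort.modalities["roi"], cohort.icv)
        out = apply_icv_adjuster(adj, cohort.modalities["roi"], cohort.icv)
        ic = cohort.icv - cohort.icv.mean()
        x = out.values - out.values.mean(axis=0)
        corr = (x.T @ ic) / (np.linalg.norm(x, axis=0)
                             * np.linalg.norm(ic))
        assert np.abs(corr).max() < 1e-10

    def test_sample_at_mean_icv_unchanged(self, rng):
        icv = np.array([1400.0, 1500.0, 1600.0])
        roi = rng.normal(size=(3, 2)) + 0.01 * icv[:, None]
        block = ModalityMatrix(roi, ["a", "b"], "roi")
        adj = fit_icv_adjuster(block, icv)
        out = apply_icv_adjuster(adj, block, icv)
        np.testing.assert_allclose(out.values[1], roi[1])  # ICV == mean

    def test_zero_slope_leaves_column_unchanged(self, rng):
        icv = rng.normal(1500, 100, 30)
        roi = ModalityMatrix(rng.normal(size=(30, 1)), ["a"], "roi")
        adj = fit_icv_adjuster(roi, icv)
        adj.theta[0] = 0.0
        out = apply_icv_adjuster(adj, roi, icv)
        np.testing.assert_array_equal(out.values, roi.values)

    def test_adjustment_is_linear(self, rng):
        icv = rng.normal(1500, 100, 30)
        vals = rng.normal(size=(30, 3)) + 0.02 * icv[:, None]
        roi = ModalityMatrix(vals, list("abc"), "roi")
        adj = fit_icv_adjuster(roi, icv)
        scaled = ModalityMatrix(3.0 * vals + 2.0, list("abc"), "roi")
        adj2 = fit_icv_adjuster(scaled, icv)
        out1 = apply_icv_adjuster(adj, roi, icv).values
        out2 = apply_icv_adjuster(adj2, scaled, icv).values
        np.testing.assert_allclose(out2, 3.0 * out1 + 2.0, atol=1e-8)

    def test_constant_icv_rejected(self, rng):
        roi = ModalityMatrix(rng.normal(size=(10, 2)), ["a", "b"], "roi")
        with pytest.raises(ValueError, match="constant"):
            fit_icv_adjuster(roi, np.full(10, 1500.0))


class TestStandardizer:
    def test_train_mean_zero_sd_one(self, rng):
        x = ModalityMatrix(rng.normal(3, 2, size=(50, 4)),
                           list("abcd"), "expr")
        s = fit_standardizer(x)
        out = apply_standardizer(s, x)
        np.testing.assert_allclose(out.values.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(out.values.std(axis=0), 1, atol=1e-10)

    def test_location_invariance(self, rng):
        vals = rng.normal(size=(30, 3))
        x1 = ModalityMatrix(vals, list("abc"), "expr")
        x2 = ModalityMatrix(vals + 7.0, list("abc"), "expr")
        out1 = apply_standardizer(fit_standardizer(x1), x1)
        out2 = apply_standardizer(fit_standardizer(x2), x2)
        np.testing.assert_allclose(out1.values, out2.values, atol=1e-10)

    def test_test_data_uses_train_parameters(self, rng):
        tr = ModalityMatrix(rng.normal(0, 1, size=(50, 2)), ["a", "b"], "expr")
        te = ModalityMatrix(rng.normal(5, 3, size=(20, 2)), ["a", "b"], "expr")
        s = fit_standardizer(tr)
        out = apply_standardizer(s, te)
        expected = (te.values - tr.values.mean(axis=0)) / tr.values.std(axis=0)
        np.testing.assert_allclose(out.values, expected)
        assert abs(out.values.mean()) > 0.5  # clearly not self-standardized

    def test_zero_variance_dropped_with_warning(self, rng):
        vals = np.column_stack([rng.normal(size=20), np.full(20, 3.0)])
        x = ModalityMatrix(vals, ["a", "b"], "expr")
        with pytest.warns(UserWarning, match="zero-variance"):
            s = fit_standardizer(x)
        assert s.feature_ids == ["a"]


def test_mean_imputer_fits_on_train_only(rng):
    tr_vals = rng.binomial(2, 0.5, size=(30, 2)).astype(float)
    tr_vals[0, 0] = np.nan
    tr = ModalityMatrix(tr_vals, ["a", "b"], "snp")
    imp = MeanImputer().fit(tr)
    te_vals = np.full((4, 2), np.nan)
    te = ModalityMatrix(te_vals, ["a", "b"], "snp")
    out = imp.transform(te)
    np.testing.assert_allclose(out.values[:, 0], np.nanmean(tr_vals[:, 0]))
    assert not out.mask.any()


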