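"""Kernels, composite combination, VB fit, and the predictive integral."""

import numpy as np
import pytest
from scipy.special import ndtr

from mcicps.kernels import (BaseKernelSpec, KernelSet, composite_kernel,
                            compute_gram, median_heuristic)
from mcicps.metrics import rank_auc
from mcicps.vbpmkl import (PredictiveDistribution, decision_threshold,
                           fit_on_features, fit_vbpmkl, make_kernel_set,
                           predict_on_features, predict_proba, _gh_rule)


class TestGram:
    def test_gaussian_diagonal_and_duplicates(self, rng):
        x = rng.normal(size=(20, 4))
        x[1] = x[0]
        K = compute_gram(x, None, BaseKernelSpec("gaussian", 2.0))
        np.testing.assert_allclose(np.diag(K), 1.0)
        assert K[0, 1] == pytest.approx(1.0)

    def test_gaussian_gram_psd(self, rng):
        x = rng.normal(size=(50, 6))
        K = compute_gram(x, None, BaseKernelSpec("gaussian", 1.5))
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_linear_is_inner_product(self, rng):
        x = rng.normal(size=(10, 3))
        K = compute_gram(x, None, BaseKernelSpec("linear"))
        np.testing.assert_allclose(K, x @ x.T)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(Exception, match="dimension"):
            compute_gram(rng.normal(size=(5, 3)), rng.normal(size=(4, 2)),
                         BaseKernelSpec("linear"))

    def test_median_heuristic_positive(self, rng):
        assert median_heuristic(rng.normal(size=(30, 5))) > 0


class TestComposite:
    def test_unit_weight_returns_single_kernel(self, rng):
        grams = [rng.normal(size=(5, 5)) for _ in range(3)]
        grams = [g @ g.T for g in grams]
        ks = KernelSet(grams, np.array([1.0, 0.0, 0.0]),
                       [BaseKernelSpec("linear")] * 3)
        np.testing.assert_array_equal(composite_kernel(ks), grams[0])

    def test_equal_weights_give_elementwise_mean(self, rng):
        grams = [np.abs(rng.normal(size=(4, 4))) for _ in range(3)]
        grams = [(g + g.T) / 2 for g in grams]
        ks = KernelSet(grams, np.full(3, 1 / 3),
                       [BaseKernelSpec("linear")] * 3)
        np.testing.assert_allclose(composite_kernel(ks),
                                   np.mean(grams, axis=0))

    def test_composite_of_psd_kernels_is_psd(self, rng):
        xs = [rng.normal(size=(30, 4)) for _ in range(3)]
        ks = make_kernel_set(xs)
        assert np.linalg.eigvalsh(composite_kernel(ks)).min() >= -1e-8

    def test_off_simplex_beta_rejected(self, rng):
        g = np.eye(3)
        with pytest.raises(ValueError, match="beta"):
            KernelSet([g, g], np.array([0.7, 0.7]),
                      [BaseKernelSpec("linear")] * 2)


class TestFit:
    def test_separable_training_accuracy(self, rng):
        x = rng.normal(size=(40, 3))
        labels = np.repeat([0, 1], 20)
        x[:, 0] += np.where(labels == 1, 2.0, -2.0)  # margin >= ~1
        model = fit_on_features([x], labels, family="linear")
        dist = predict_on_features(model, [x])
        assert (dist.calls == labels).mean() == 1.0
        assert model.converged

    def test_trace_monotone_near_convergence(self, rng):
        x = rng.normal(size=(50, 4))
        labels = (x[:, 0] + 0.7 * rng.normal(size=50) > 0).astype(int)
        model = fit_on_features([x], labels)
        tail = model.trace[-5:]
        assert all(b <= a + 1e-6 for a, b in zip(tail, tail[1:]))

    def test_class_swap_symmetry(self, rng):
        """Mirrored data with swapped labels swaps predicted probabilities."""
        x = rng.normal(size=(30, 3)) + 1.0
        X = np.vstack([x, -x])
        labels = np.repeat([0, 1], 30)
        model = fit_on_features([X], labels, family="linear")
        dist = predict_on_features(model, [X])
        np.testing.assert_allclose(dist.proba[:30, 0], dist.proba[30:, 1],
                                   atol=1e-6)

    def test_three_class_blobs_accuracy(self, rng):
        X = np.vstack([rng.normal(c, 0.6, size=(20, 4))
                       for c in (-3.0, 0.0, 3.0)])
        labels = np.repeat([0, 1, 2], 20)
        model = fit_on_features([X], labels)
        dist = predict_on_features(model, [X])
        assert (dist.calls == labels).mean() >= 0.95

    def test_single_class_rejected(self, rng):
        x = rng.normal(size=(10, 2))
        with pytest.raises(Exception, match="class"):
            fit_on_features([x], np.zeros(10, dtype=int))


class TestPredictive:
    def test_zero_regressors_give_uniform_probabilities(self, rng):
        x = rng.normal(size=(20, 3))
        labels = rng.integers(0, 3, 20)
        labels[:6] = [0, 0, 1, 1, 2, 2]
        model = fit_on_features([x], labels)
        model.W_mean = np.zeros_like(model.W_mean)
        dist = predict_on_features(model, [x])
        np.testing.assert_allclose(dist.proba, 1.0 / 3.0, atol=1e-8)

    def test_binary_closed_form(self, rng):
        """Quadrature equals Phi((w1-w2)k/sqrt(2)) in the binary case."""
        x = rng.normal(size=(40, 3))
        labels = (x[:, 0] + rng.normal(size=40) > 0).astype(int)
        model = fit_on_features([x], labels)
        te = rng.normal(size=(25, 3))
        dist = predict_on_features(model, [te])
        spec = model.specs[0]
        Kt = compute_gram(model.train_blocks[0], te, spec)
        m = Kt @ model.W_mean.T
        closed = ndtr((m[:, 1] - m[:, 0]) / np.sqrt(2.0))
        np.testing.assert_allclose(dist.proba[:, 1], closed, atol=1e-6)

    def test_quadrature_matches_monte_carlo(self, rng):
        """GH quadrature within 3 SE of a large MC draw of the integral."""
        C, G = 3, 64
        u, w = _gh_rule(G)
        for trial in range(5):
            m = rng.normal(0, 1.5, size=C)
            mc_u = rng.standard_normal(200_000)
            for i in range(C):
                others = [j for j in range(C) if j != i]
                quad = float(
                    (np.prod(ndtr(u[:, None] + (m[i] - m[others])[None, :]),
                             axis=1) @ w))
                draws = np.prod(
                    ndtr(mc_u[:, None] + (m[i] - m[others])[None, :]), axis=1)
                se = draws.std(ddof=1) / np.sqrt(len(draws))
                assert abs(quad - draws.mean()) < 3 * se + 1e-12

    def test_rows_sum_to_one(self, rng):
        x = rng.normal(size=(30, 4))
        labels = rng.integers(0, 2, 30)
        labels[:4] = [0, 0, 1, 1]
        model = fit_on_features([x], labels)
        dist = predict_on_features(model, [rng.normal(size=(50, 4))])
        np.testing.assert_allclose(dist.proba.sum(axis=1), 1.0, atol=1e-8)


class TestDecisionThreshold:
    def test_tie_goes_to_positive_class(self):
        dist = PredictiveDistribution(np.array([[0.5, 0.5]]),
                                      np.array([0, 1]))
        assert decision_threshold(dist, 0.5)[0] == 1

    def test_tau_extremes(self):
        dist = PredictiveDistribution(
            np.array([[0.9, 0.1], [0.2, 0.8]]), np.array([0, 1]))
        assert (decision_threshold(dist, 0.001) == 1).all()
        assert (decision_threshold(dist, 0.999) == 0).all()

    def test_invalid_tau_rejected(self):
        dist = PredictiveDistribution(np.array([[0.5, 0.5]]),
                                      np.array([0, 1]))
        with pytest.raises(ValueError):
            decision_threshold(dist, 1.5)

    def test_threshold_sweep_traces_roc(self, rng):
        """Sweeping tau reproduces the ROC the evaluator integrates."""
        scores = rng.random(50)
        labels = (scores + 0.4 * rng.normal(size=50) > 0.5).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        dist = PredictiveDistribution(
            np.column_stack([1 - scores, scores]), np.array([0, 1]))
        fprs, tprs = [0.0], [0.0]
        for tau in np.sort(np.unique(scores))[::-1]:
            calls = decision_threshold(dist, float(tau))
            tprs.append(((calls == 1) & (labels == 1)).sum()
                        / (labels == 1).sum())
            fprs.append(((calls == 1) & (labels == 0)).sum()
                        / (labels == 0).sum())
        auc_sweep = float(np.trapezoid(tprs, fprs))
        assert auc_sweep == pytest.approx(rank_auc(scores, labels),
                                          abs=1e-12)
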