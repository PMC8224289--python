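"""Affinity construction, cross-diffusion fusion, spectral cut, propagation."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mcicps.datatypes import ModalityMatrix
from mcicps.snf import (AffinityNetwork, FusedNetwork, SubtypeAssignment,
                        build_affinity, label_propagate, snf_fuse,
                        spectral_cluster)


def _blobs(rng, n_per=20, d=5, sep=4.0):
    a = rng.normal(0, 1, size=(n_per, d))
    b = rng.normal(sep, 1, size=(n_per, d))
    return np.vstack([a, b]), np.repeat([0, 1], n_per)


def _block(x, tag="expr"):
    return ModalityMatrix(x, [f"f{j}" for j in range(x.shape[1])], tag)


def _block_diag_net(n_per=10, n_blocks=2):
    n = n_per * n_blocks
    W = np.zeros((n, n))
    for b in range(n_blocks):
        W[b * n_per:(b + 1) * n_per, b * n_per:(b + 1) * n_per] = 1.0
    np.fill_diagonal(W, 1.0)
    return W


class TestAffinity:
    def test_symmetric_positive(self, rng):
        x, _ = _blobs(rng)
        net = build_affinity(_block(x), K=5)
        assert np.abs(net.W - net.W.T).max() < 1e-12
        assert (net.W > 0).all()

    def test_duplicate_rows_are_most_similar(self, rng):
        x, _ = _blobs(rng)
        x[1] = x[0]
        net = build_affinity(_block(x), K=5)
        row = net.W[0].copy()
        row[0] = -np.inf
        assert np.argmax(row) == 1

    def test_within_blob_exceeds_between(self, rng):
        x, lab = _blobs(rng)
        W = build_affinity(_block(x), K=5).W
        within = W[np.ix_(lab == 0, lab == 0)].mean()
        between = W[np.ix_(lab == 0, lab == 1)].mean()
        assert within > between

    def test_k_too_large_rejected(self, rng):
        x, _ = _blobs(rng, n_per=5)
        with pytest.raises(ValueError, match="K"):
            build_affinity(_block(x), K=10)


class TestFusion:
    def test_output_symmetric_nonnegative(self, rng):
        x1, _ = _blobs(rng)
        x2, _ = _blobs(rng)
        fused = snf_fuse([build_affinity(_block(x1), K=5),
                          build_affinity(_block(x2), K=5)], K=5, T=10)
        assert np.abs(fused.W - fused.W.T).max() < 1e-12
        assert fused.W.min() >= 0

    def test_identical_block_structure_preserved(self):
        W = _block_diag_net()
        ids = [str(i) for i in range(W.shape[0])]
        nets = [AffinityNetwork(W, ids, 3, 0.5) for _ in range(2)]
        fused = snf_fuse(nets, K=3, T=10)
        labels = spectral_cluster(fused, 2, seed=0).labels
        truth = np.repeat([0, 1], 10)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_change_norms_decrease_after_burn_in(self, rng):
        x1, _ = _blobs(rng)
        x2, _ = _blobs(rng)
        fused = snf_fuse([build_affinity(_block(x1), K=5),
                          build_affinity(_block(x2), K=5)], K=5, T=15)
        tail = fused.change_norms[3:]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(tail, tail[1:]))

    def test_permutation_equivariance(self, rng):
        x1, _ = _blobs(rng, n_per=10)
        x2, _ = _blobs(rng, n_per=10)
        perm = rng.permutation(20)
        f1 = snf_fuse([build_affinity(_block(x1), K=4),
                       build_affinity(_block(x2), K=4)], K=4, T=8).W
        f2 = snf_fuse([build_affinity(_block(x1[perm]), K=4),
                       build_affinity(_block(x2[perm]), K=4)], K=4, T=8).W
        np.testing.assert_allclose(f2, f1[np.ix_(perm, perm)], atol=1e-10)

    def test_fusing_copies_matches_single_network_cut(self, rng):
        x, lab = _blobs(rng)
        net = build_affinity(_block(x), K=5)
        fused = snf_fuse([net, net, net], K=5, T=10)
        single = FusedNetwork(net.W, net.sample_ids, 0)
        c_single = spectral_cluster(single, 2, seed=0).labels
        c_fused = spectral_cluster(fused, 2, seed=0).labels
        assert adjusted_rand_score(c_single, c_fused) == 1.0

    def test_sample_mismatch_rejected(self, rng):
        x, _ = _blobs(rng)
        a = build_affinity(_block(x), K=5)
        b = build_affinity(_block(x[:-1]), K=5)
        with pytest.raises(Exception, match="sample"):
            snf_fuse([a, b], K=5)


class TestSpectralCluster:
    def test_exact_two_block_partition(self):
        net = FusedNetwork(_block_diag_net(), [str(i) for i in range(20)], 0)
        out = spectral_cluster(net, 2, seed=0)
        assert adjusted_rand_score(np.repeat([0, 1], 10), out.labels) == 1.0
        assert out.scores.sum(axis=1) == pytest.approx(1.0)

    def test_ari_invariant_to_relabeling(self):
        net = FusedNetwork(_block_diag_net(), [str(i) for i in range(20)], 0)
        lab = spectral_cluster(net, 2, seed=0).labels
        truth = np.repeat([0, 1], 10)
        assert (adjusted_rand_score(truth, lab)
                == adjusted_rand_score(truth, 3 - lab))

    def test_deterministic_given_seed(self, rng):
        x1, _ = _blobs(rng)
        fused = snf_fuse([build_affinity(_block(x1), K=5)] * 2, K=5, T=8)
        a = spectral_cluster(fused, 2, seed=4).labels
        b = spectral_cluster(fused, 2, seed=4).labels
        np.testing.assert_array_equal(a, b)

    def test_more_components_than_C_warns(self):
        W = _block_diag_net(n_per=5, n_blocks=3)
        net = FusedNetwork(W, [str(i) for i in range(15)], 0)
        with pytest.warns(UserWarning, match="components"):
            out = spectral_cluster(net, 2, seed=0)
        assert out.C == 3


class TestLabelPropagation:
    def test_identical_sample_inherits_subtype(self, rng):
        x1, lab = _blobs(rng)
        x2, _ = _blobs(rng)
        train = {"snp": _block(x1, "snp"), "expr": _block(x2, "expr")}
        assign = SubtypeAssignment(lab + 1, 2, "clustered",
                                   [str(i) for i in range(len(lab))])
        new = {"snp": _block(x1[[0, 25]], "snp"),
               "expr": _block(x2[[0, 25]], "expr")}
        out = label_propagate(train, assign, new, K=5)
        assert out.labels[0] == assign.labels[0]
        assert out.labels[1] == assign.labels[25]

    def test_scores_rows_sum_to_one(self, rng):
        x1, lab = _blobs(rng)
        x2, _ = _blobs(rng)
        train = {"expr": _block(x1, "expr"), "snp": _block(x2, "snp")}
        assign = SubtypeAssignment(lab + 1, 2, "clustered",
                                   [str(i) for i in range(len(lab))])
        new = {"expr": _block(rng.normal(size=(7, x1.shape[1])), "expr"),
               "snp": _block(rng.normal(size=(7, x2.shape[1])), "snp")}
        out = label_propagate(train, assign, new, K=5)
        np.testing.assert_allclose(out.scores.sum(axis=1), 1.0, atol=1e-8)

    def test_heldout_synthetic_agreement(self, train_test):
        """Propagated subtypes match the generator's truth on held-out data."""
        from mcicps.config import PipelineConfig
        from mcicps.pipeline import _global_preprocess
        from mcicps.preprocess import apply_standardizer
        tr, te = train_test
        cfg = PipelineConfig()
        _, imp, _, _, stds, std = _global_preprocess(tr, cfg)
        snp_te = imp.transform(
            te.modalities["snp"].select_features(imp.feature_ids))
        new_std = {
            "snp": apply_standardizer(stds["snp"], snp_te),
            "expr": apply_standardizer(stds["expr"], te.modalities["expr"]),
        }
        train_std = {t: std[t] for t in ("snp", "expr")}
        assign = SubtypeAssignment(tr.subtype_truth, 2, "clustered",
                                   list(tr.sample_ids))
        out = label_propagate(train_std, assign, new_std, K=20)
        agree = (out.labels == te.subtype_truth).mean()
        assert agree >= 0.9
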