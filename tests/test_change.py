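"""Sparse-AE penalties, DEC machinery and bi-temporal change detection."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from postfire import (ClassMap, IndexRaster, InputError, SparseAEConfig,
                      binary_map_metrics, detect_change, extract_patches,
                      overlay_change, soft_assignment, sparse_ae_loss,
                      target_distribution, train_sparse_ae)
from postfire.change import (ChangeDetectConfig, DECConfig, _kl_pq,
                             dec_gradients, load_dec, save_dec, train_dec)


def best_permutation_accuracy(pred, labels, k):
    return max(np.mean(np.asarray(p)[pred] == labels)
               for p in permutations(range(k)))


class TestExtractPatches:
    def test_patch_one_is_identity(self):
        vals = np.arange(16, dtype=float).reshape(4, 4) / 16
        r = IndexRaster(vals)
        np.testing.assert_array_equal(extract_patches(r, 1).ravel(), vals.ravel())

    def test_row_count_and_width(self):
        r = IndexRaster(np.zeros((4, 4)))
        assert extract_patches(r, 3).shape == (16, 9)

    def test_fully_masked_gives_zero_rows(self):
        r = IndexRaster(np.zeros((4, 4)), nodata_mask=np.ones((4, 4), bool))
        assert extract_patches(r, 3).shape[0] == 0

    def test_even_patch_rejected(self):
        with pytest.raises(InputError):
            extract_patches(IndexRaster(np.zeros((4, 4))), 2)

    def test_classmap_scaled_to_unit(self):
        cm = ClassMap(np.full((4, 4), 4), np.zeros((4, 4), bool))
        assert extract_patches(cm, 1).max() == pytest.approx(1.0)


class TestSparseLoss:
    def test_zero_at_identity_without_penalty(self):
        cfg = SparseAEConfig(sparsity_mode="l1", lam=0.0)
        x = np.ones((3, 4))
        assert sparse_ae_loss(x, x, np.ones((3, 2)), cfg) == 0.0

    def test_l1_sum_of_absolutes(self):
        cfg = SparseAEConfig(sparsity_mode="l1", lam=1.0)
        assert sparse_ae_loss(np.zeros(2), np.zeros(2), np.array([1.0, -2.0]),
                              cfg) == pytest.approx(3.0)

    def test_kl_matches_bernoulli_divergence(self):
        # independent oracle: rho ln(rho/rho_hat) + (1-rho) ln((1-rho)/(1-rho_hat))
        rho, rho_hat = 0.2, 0.5
        expected = rho * np.log(rho / rho_hat) + (1 - rho) * np.log((1 - rho) / (1 - rho_hat))
        cfg = SparseAEConfig(sparsity_mode="kl", rho=rho, kl_weight=1.0)
        got = sparse_ae_loss(np.zeros(2), np.zeros(2), np.array([rho_hat]), cfg)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.1927, abs=1e-4)

    def test_kl_zero_at_target_rate(self):
        cfg = SparseAEConfig(sparsity_mode="kl", rho=0.3, kl_weight=1.0)
        assert sparse_ae_loss(np.zeros(2), np.zeros(2), np.array([0.3, 0.3]),
                              cfg) == pytest.approx(0.0, abs=1e-12)

    def test_zero_weights_reduce_to_plain_autoencoder(self):
        x = np.array([[0.2, 0.4], [0.1, 0.9]])
        x_hat = np.array([[0.3, 0.3], [0.2, 0.8]])
        acts = np.array([[0.5, 0.7]])
        plain = float(np.mean((x - x_hat) ** 2))
        for mode, kw in (("l1", {"lam": 0.0}), ("kl", {"kl_weight": 0.0})):
            cfg = SparseAEConfig(sparsity_mode=mode, **kw)
            assert sparse_ae_loss(x, x_hat, acts, cfg) == pytest.approx(plain)

    def test_config_validation(self):
        with pytest.raises(InputError):
            SparseAEConfig(rho=1.5)
        with pytest.raises(InputError):
            SparseAEConfig(lam=-1.0)


class TestSparseAETraining:
    def test_constant_input_reconstructed(self):
        x = np.tile([0.3, 0.7, 0.5], (64, 1))
        cfg = SparseAEConfig(layer_widths=(4, 2), epochs=200, sparsity_mode="l1",
                             lam=0.0, seed=0)
        ae = train_sparse_ae(x, cfg)
        assert ae.loss_history[-1] < 1e-3
        assert ae.loss_history[-1] <= ae.loss_history[0]

    def test_seeded_determinism_bitwise(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, (128, 6))
        cfg = SparseAEConfig(layer_widths=(8, 3), epochs=20, seed=9)
        a = train_sparse_ae(x, cfg)
        b = train_sparse_ae(x, cfg)
        assert a.loss_history == b.loss_history

    def test_kl_pulls_mean_activation_to_rho(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, (256, 8))
        cfg = SparseAEConfig(layer_widths=(6, 4), epochs=300, sparsity_mode="kl",
                             rho=0.2, kl_weight=5.0, seed=1)
        ae = train_sparse_ae(x, cfg)
        mean_act = ae.encode(x).mean()
        assert abs(mean_act - 0.2) < 0.1

    def test_bottleneck_must_compress(self):
        with pytest.raises(InputError):
            train_sparse_ae(np.zeros((10, 3)),
                            SparseAEConfig(layer_widths=(8, 4)))


class TestSoftAssignment:
    def test_equidistant_point_splits_evenly(self):
        q = soft_assignment(np.array([[0.0, 0.0]]),
                            np.array([[1.0, 0.0], [-1.0, 0.0]]))
        np.testing.assert_allclose(q, [[0.5, 0.5]])

    def test_single_centroid_normalizes_to_one(self):
        q = soft_assignment(np.random.default_rng(0).normal(size=(5, 3)),
                            np.zeros((1, 3)))
        np.testing.assert_allclose(q, 1.0)

    def test_near_centroid_dominates(self):
        q = soft_assignment(np.array([[0.0, 0.0]]),
                            np.array([[0.0, 0.0], [50.0, 0.0]]))
        assert q[0, 0] > 0.99

    def test_no_centroids_rejected(self):
        with pytest.raises(InputError):
            soft_assignment(np.zeros((2, 2)), np.zeros((0, 2)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        q = soft_assignment(rng.normal(size=(7, 3)), rng.normal(size=(4, 3)))
        np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((q >= 0) & (q <= 1))


class TestTargetDistribution:
    def test_symmetric_row_is_fixed_point(self):
        q = np.array([[0.5, 0.5], [0.5, 0.5]])
        np.testing.assert_allclose(target_distribution(q), q)

    def test_sharpens_confident_row(self):
        q = np.array([[0.9, 0.1], [0.1, 0.9]])  # equal cluster frequencies
        p = target_distribution(q)
        assert p[0, 0] == pytest.approx(0.81 / 0.82, abs=1e-6)
        assert p[0, 0] == pytest.approx(0.988, abs=1e-3)

    def test_one_hot_is_idempotent(self):
        q = np.eye(3)
        np.testing.assert_allclose(target_distribution(q), q)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rows_stay_stochastic_and_sharper(self, seed):
        rng = np.random.default_rng(seed)
        row = rng.dirichlet(np.ones(4))
        q = np.tile(row, (6, 1))  # equal cluster frequencies
        p = target_distribution(q)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        ent = lambda r: -np.sum(r * np.log(np.maximum(r, 1e-12)))
        assert ent(p[0]) <= ent(q[0]) + 1e-9


class TestDECGradients:
    def test_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(6, 3))
        mu = rng.normal(size=(3, 3))
        q = soft_assignment(z, mu)
        p = target_distribution(q)
        dz, dmu = dec_gradients(z, mu, p, q, 1.0)
        eps = 1e-6
        for idx in [(0, 0), (3, 2)]:
            zp, zm = z.copy(), z.copy()
            zp[idx] += eps
            zm[idx] -= eps
            num = (_kl_pq(p, soft_assignment(zp, mu))
                   - _kl_pq(p, soft_assignment(zm, mu))) / (2 * eps)
            assert dz[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)
        for idx in [(0, 1), (2, 2)]:
            mp, mm = mu.copy(), mu.copy()
            mp[idx] += eps
            mm[idx] -= eps
            num = (_kl_pq(p, soft_assignment(z, mp))
                   - _kl_pq(p, soft_assignment(z, mm))) / (2 * eps)
            assert dmu[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestTrainDEC:
    def test_blobs_recovered(self, dec_blobs):
        state, labels = dec_blobs
        pred = np.argmax(state.soft_assign, axis=1)
        assert best_permutation_accuracy(pred, labels, 3) >= 0.95

    def test_q_and_p_rows_sum_to_one(self, dec_blobs):
        state, _ = dec_blobs
        np.testing.assert_allclose(state.soft_assign.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(state.target.sum(axis=1), 1.0, atol=1e-6)

    def test_kl_decreases_within_target_interval(self, dec_blobs):
        state, _ = dec_blobs
        interval = DECConfig().update_interval
        hist = state.kl_history[:-1]  # last entry is under a fresh target
        for start in range(0, len(hist), interval):
            chunk = hist[start:start + interval]
            if len(chunk) >= 2:
                assert chunk[-1] <= chunk[0] + 1e-9

    def test_each_distinct_point_its_own_cluster(self):
        x = np.array([[0.0, 0.0], [0.5, 0.5], [1.0, 0.0]])
        cfg = DECConfig(ae=SparseAEConfig(layer_widths=(1,), epochs=30, seed=0),
                        max_epochs=10)
        state = train_dec(x, 3, cfg)
        assert len(set(state.assign(x))) == 3


class TestDetectChange:
    def test_identical_inputs_give_empty_map(self, burn_scene):
        pre, _, _ = burn_scene
        cm = detect_change(pre, pre)
        assert cm.binary.sum() == 0

    def test_burn_scar_recovered(self, change_result):
        cm, truth = change_result
        m = binary_map_metrics(cm.binary, truth)
        assert m["iou"] >= 0.8

    def test_swap_symmetry(self, burn_scene):
        pre, post, _ = burn_scene
        small = ChangeDetectConfig()
        a = detect_change(pre, post, small)
        b = detect_change(post, pre, small)
        np.testing.assert_array_equal(a.binary, b.binary)

    def test_changed_subset_of_unmasked(self, change_result):
        cm, _ = change_result
        assert not np.any(cm.binary & cm.nodata_mask)

    def test_misaligned_shapes_rejected(self, burn_scene):
        pre, _, _ = burn_scene
        other = IndexRaster(np.zeros((8, 8)), pixel_size_m=pre.pixel_size_m)
        with pytest.raises(InputError):
            detect_change(pre, other)


class TestOverlay:
    def test_no_change_renders_grayscale(self, burn_scene):
        pre, _, _ = burn_scene
        cm = detect_change(pre, pre)
        img = overlay_change(pre, cm)
        gray = np.round(np.clip((pre.values + 1) * 127.5, 0, 255)).astype(np.uint8)
        np.testing.assert_array_equal(img[..., 0], gray)
        np.testing.assert_array_equal(img[..., 0], img[..., 1])

    def test_full_alpha_paints_exact_color(self):
        pre = IndexRaster(np.zeros((2, 2)))
        cm_mask = np.array([[True, False], [False, False]])
        from postfire.change import ChangeMap
        from postfire.raster import ClassMap, ClassScheme
        labels = ClassMap(np.zeros((2, 2), int), np.zeros((2, 2), bool))
        cm = ChangeMap(cm_mask, labels, labels, np.zeros((2, 2), bool), 250.0)
        img = overlay_change(pre, cm, color=(10, 200, 30), alpha=1.0)
        assert tuple(img[0, 0]) == (10, 200, 30)

    def test_half_alpha_blends_to_midgray(self):
        pre = IndexRaster(np.full((1, 1), -1.0))  # black pixel
        from postfire.change import ChangeMap
        from postfire.raster import ClassMap
        labels = ClassMap(np.zeros((1, 1), int), np.zeros((1, 1), bool))
        cm = ChangeMap(np.array([[True]]), labels, labels,
                       np.zeros((1, 1), bool), 250.0)
        img = overlay_change(pre, cm, color=(255, 255, 255), alpha=0.5)
        assert np.all(np.abs(img[0, 0].astype(int) - 128) <= 1)

    def test_alpha_out_of_range(self, burn_scene):
        pre, _, _ = burn_scene
        cm = detect_change(pre, pre)
        with pytest.raises(InputError):
            overlay_change(pre, cm, alpha=1.5)


class TestBinaryMetrics:
    def test_f1_identity_holds_exactly(self, change_result):
        cm, truth = change_result
        m = binary_map_metrics(cm.binary, truth)
        if m["precision"] + m["recall"] > 0:
            assert m["f1"] == pytest.approx(
                2 * m["precision"] * m["recall"] / (m["precision"] + m["recall"]))

    def test_hand_counted_confusion(self):
        # TP=9, FP=1, FN=3, TN=7
        truth = np.array([1] * 12 + [0] * 8, bool)
        pred = np.array([1] * 9 + [0] * 3 + [1] * 1 + [0] * 7, bool)
        m = binary_map_metrics(pred, truth)
        assert m["precision"] == pytest.approx(0.9)
        assert m["recall"] == pytest.approx(0.75)
        assert m["f1"] == pytest.approx(2 * 0.9 * 0.75 / 1.65)
        assert m["accuracy"] == pytest.approx(0.8)


class TestPersistence:
    def test_round_trip_preserves_assignment(self, dec_blobs, blob_features, tmp_path):
        state, _ = dec_blobs
        x, _ = blob_features
        p = tmp_path / "dec.npz"
        save_dec(state, str(p))
        back = load_dec(str(p))
        np.testing.assert_array_equal(state.assign(x), back.assign(x))
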