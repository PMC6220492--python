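from itertools import combinations

import numpy as np
import pytest

from sute_ac.evaluation import (dice, dice_as_printed, diff_stats,
                                fp_fn_rates, mann_whitney_u, regional_stats,
                                relative_error_map, representative_histogram)
from sute_ac.volume import LabelMask, Volume


def _vol(data, units="intensity"):
    return Volume(np.asarray(data, float), (1, 1, 1), units=units)


class TestDice:
    def test_identical_nonempty_masks(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3] = True
        assert dice(m, m) == 1.0

    def test_half_overlap(self):
        a = np.zeros((1, 1, 20), bool)
        b = np.zeros((1, 1, 20), bool)
        a[0, 0, :10] = True
        b[0, 0, 5:15] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_disjoint_masks(self):
        a = np.zeros((2, 2, 2), bool)
        b = np.zeros((2, 2, 2), bool)
        a[0] = True
        b[1] = True
        assert dice(a, b) == 0.0

    def test_empty_vs_empty_is_one_empty_vs_nonempty_is_zero(self):
        e = np.zeros((2, 2, 2), bool)
        f = np.ones((2, 2, 2), bool)
        assert dice(e, e) == 1.0
        assert dice(e, f) == 0.0

    def test_symmetry_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.random((5, 5, 5)) > 0.5
            b = rng.random((5, 5, 5)) > 0.5
            assert dice(a, b) == dice(b, a)

    def test_as_printed_variant_gives_two_for_identical_masks(self):
        m = np.ones((2, 2, 2), bool)
        assert dice_as_printed(m, m) == 2.0

    def test_matches_exhaustive_voxel_counting(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a = rng.random((4, 4, 4)) > rng.random()
            b = rng.random((4, 4, 4)) > rng.random()
            inter = sum(1 for x, y in zip(a.ravel(), b.ravel()) if x and y)
            na, nb = int(a.sum()), int(b.sum())
            expected = 1.0 if na + nb == 0 else 2 * inter / (na + nb)
            assert dice(a, b) == pytest.approx(expected, abs=1e-15)


class TestFpFn:
    def test_perfect_prediction(self):
        m = np.zeros((3, 3, 3), bool)
        m[1] = True
        assert fp_fn_rates(m, m) == (0.0, 0.0)

    def test_superset_prediction(self):
        ref = np.zeros((1, 1, 20), bool)
        pred = np.zeros((1, 1, 20), bool)
        ref[0, 0, :10] = True
        pred[0, 0, :20] = True
        fp, fn = fp_fn_rates(pred, ref)
        assert (fp, fn) == (0.5, 0.0)

    def test_empty_prediction(self):
        ref = np.ones((2, 2, 2), bool)
        pred = np.zeros((2, 2, 2), bool)
        assert fp_fn_rates(pred, ref) == (0.0, 1.0)

    def test_matches_exhaustive_counting(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            pred = rng.random((4, 4, 4)) > rng.random()
            ref = rng.random((4, 4, 4)) > rng.random()
            fp_count = int((pred & ~ref).sum())
            fn_count = int((ref & ~pred).sum())
            e_fp = fp_count / pred.sum() if pred.sum() else 0.0
            e_fn = fn_count / ref.sum() if ref.sum() else 0.0
            assert fp_fn_rates(pred, ref) == pytest.approx((e_fp, e_fn))


class TestDiffStats:
    def test_identical_maps_are_all_zero(self):
        a = _vol(np.random.default_rng(3).random((4, 4, 4)) * 0.1, "mu_cm_inv")
        mask = np.ones((4, 4, 4), bool)
        assert diff_stats(a, a, mask) == (0.0, 0.0, 0.0, 0.0)

    def test_constant_offset(self):
        a = _vol(np.full((3, 3, 3), 0.10), "mu_cm_inv")
        b = _vol(np.full((3, 3, 3), 0.11), "mu_cm_inv")
        d_mean, d_sd, a_mean, a_sd = diff_stats(a, b, np.ones((3, 3, 3), bool))
        assert d_mean == pytest.approx(-0.01)
        assert a_mean == pytest.approx(0.01)
        assert d_sd == pytest.approx(0.0, abs=1e-12)

    def test_absdiff_dominates_diff_on_random_pairs(self):
        rng = np.random.default_rng(4)
        mask = np.ones((4, 4, 4), bool)
        for _ in range(25):
            a = _vol(rng.random((4, 4, 4)))
            b = _vol(rng.random((4, 4, 4)))
            d_mean, _, a_mean, _ = diff_stats(a, b, mask)
            assert a_mean >= abs(d_mean) - 1e-12

    def test_empty_mask_rejected(self):
        a = _vol(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="empty"):
            diff_stats(a, a, np.zeros((2, 2, 2), bool))


class TestRelativeError:
    def test_identical_images_give_zero(self):
        ref = _vol(np.random.default_rng(5).random((3, 3, 3)) + 1)
        mask = np.ones((3, 3, 3), bool)
        re = relative_error_map(ref, ref, mask)
        np.testing.assert_allclose(re.data[mask], 0.0)

    def test_ten_percent_reduction(self):
        ref = _vol(np.full((3, 3, 3), 5.0))
        x = _vol(np.full((3, 3, 3), 4.5))
        re = relative_error_map(ref, x, np.ones((3, 3, 3), bool))
        np.testing.assert_allclose(re.data, 10.0)

    def test_sign_convention_overestimate_is_negative(self):
        ref = _vol(np.full((2, 2, 2), 1.0))
        x = _vol(np.full((2, 2, 2), 1.2))
        re = relative_error_map(ref, x, np.ones((2, 2, 2), bool))
        assert np.all(re.data < 0)

    def test_near_zero_reference_voxels_are_undefined(self):
        ref = _vol(np.array([[[1.0, 1e-12]]]))
        x = _vol(np.array([[[1.0, 1.0]]]))
        re = relative_error_map(ref, x, np.ones((1, 1, 2), bool))
        assert np.isnan(re.data[0, 0, 1]) and re.data[0, 0, 0] == 0.0


class TestRegionalStats:
    def _atlas(self, labels):
        return LabelMask(np.asarray(labels, dtype=np.int16),
                         {0: "background", 1: "a", 2: "b"})

    def test_constant_map_gives_constant_regions(self):
        re = _vol(np.full((2, 2, 2), 3.5))
        atlas = self._atlas(np.ones((2, 2, 2)))
        atlas.label_table.pop(2)
        table = regional_stats(re, atlas)
        assert (table["mean"] == 3.5).all()
        assert (table["sd"] == 0.0).all()

    def test_two_region_means(self):
        data = np.zeros((1, 1, 4))
        data[0, 0, :2] = 1.0
        data[0, 0, 2:] = 3.0
        labels = np.zeros((1, 1, 4))
        labels[0, 0, :2] = 1
        labels[0, 0, 2:] = 2
        table = regional_stats(_vol(data), self._atlas(labels)).set_index("region")
        assert table.loc["a", "mean"] == 1.0
        assert table.loc["b", "mean"] == 3.0

    def test_full_brain_row_is_count_weighted_mean_of_partition(self):
        rng = np.random.default_rng(6)
        data = rng.random((4, 4, 4))
        labels = rng.integers(1, 3, (4, 4, 4))
        table = regional_stats(_vol(data), self._atlas(labels)).set_index("region")
        w = table.loc[["a", "b"], "n_voxels"]
        m = table.loc[["a", "b"], "mean"]
        assert table.loc["full_brain", "mean"] == pytest.approx(
            (w * m).sum() / w.sum())


class TestRepresentativeHistogram:
    def _subjects(self, n=4, seed=7):
        rng = np.random.default_rng(seed)
        imgs = [_vol(rng.normal(10 + i, 2, (6, 6, 6))) for i in range(n)]
        masks = [np.ones((6, 6, 6), bool)] * n
        return imgs, masks

    def test_identical_subjects_give_their_common_histogram(self):
        imgs, masks = self._subjects(1)
        imgs = imgs * 3
        masks = masks * 3
        edges, rep = representative_histogram(imgs, masks, n_bins=50)
        h, _ = np.histogram(imgs[0].data.ravel(), bins=50)
        cos = rep @ h / np.linalg.norm(rep) / np.linalg.norm(h)
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_matches_power_iteration_principal_component(self):
        imgs, masks = self._subjects()
        edges, rep = representative_histogram(imgs, masks, n_bins=40)
        hists = np.stack([np.histogram(i.data.ravel(), bins=40)[0]
                          for i in imgs]).astype(float)
        # independent oracle: power iteration on H^T H
        v = np.ones(40)
        for _ in range(2000):
            v = hists.T @ (hists @ v)
            v /= np.linalg.norm(v)
        if v.sum() < 0:
            v = -v
        direction = rep / np.linalg.norm(rep)
        np.testing.assert_allclose(direction, v, atol=1e-8)

    def test_permutation_invariance(self):
        imgs, masks = self._subjects()
        _, rep1 = representative_histogram(imgs, masks, n_bins=30)
        _, rep2 = representative_histogram(imgs[::-1], masks[::-1], n_bins=30)
        np.testing.assert_allclose(rep1, rep2, atol=1e-10)

    def test_requires_two_subjects(self):
        imgs, masks = self._subjects(1)
        with pytest.raises(ValueError, match="2"):
            representative_histogram(imgs, masks)


def brute_force_mwu(a, b):
    """Full-enumeration oracle using pairwise counting for U."""
    pooled = np.concatenate([a, b])
    n, na = pooled.size, len(a)

    def u_of(idx):
        sa = pooled[list(idx)]
        sb = np.delete(pooled, list(idx))
        return sum(np.sum(x > sb) + 0.5 * np.sum(x == sb) for x in sa)

    u_obs = u_of(range(na))
    us = [u_of(idx) for idx in combinations(range(n), na)]
    us = np.asarray(us)
    p_le = np.mean(us <= u_obs + 1e-9)
    p_ge = np.mean(us >= u_obs - 1e-9)
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_fully_separated_triples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_symmetric_interleaving_is_null(self):
        u, p = mann_whitney_u([1, 4, 5, 8], [2, 3, 6, 7])
        assert p >= 0.99

    def test_matches_full_enumeration_for_small_samples(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            na, nb = rng.integers(1, 6, 2)
            a = rng.integers(0, 6, na).astype(float)   # ties likely
            b = rng.integers(0, 6, nb).astype(float)
            u_ref, p_ref = brute_force_mwu(a, b)
            u, p = mann_whitney_u(a, b)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref)

    def test_large_samples_use_consistent_normal_approximation(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 30)
        b = rng.normal(1, 1, 30)
        u, p = mann_whitney_u(a, b)
        assert 0 < p < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney_u([], [1.0])
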