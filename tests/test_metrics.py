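import numpy as np
import pytest
from scipy.spatial.distance import cdist

from snapseg.metrics import (
    boundary_voxels,
    compare_methods,
    dsc,
    evaluate_volume,
    surface_distance_pool,
    surface_distances,
)
from snapseg.volume_io import onehot_encode


def exhaustive_surface_distances(pred, ref, spacing=(1.0, 1.0, 1.0)):
    """All-pairs oracle for HD95/ASD on small masks."""
    scale = np.array([spacing[2], spacing[0], spacing[1]])
    bp = boundary_voxels(pred) * scale
    br = boundary_voxels(ref) * scale
    d = cdist(bp, br)
    pool = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(np.percentile(pool, 95)), float(pool.mean())


def _rand_mask(rng, shape=(2, 12, 12)):
    m = np.zeros(shape, dtype=bool)
    # a random blob per slice
    for s in range(shape[0]):
        r0, c0 = rng.integers(2, shape[1] - 4, size=2)
        h, w = rng.integers(2, 5, size=2)
        m[s, r0:r0 + h, c0:c0 + w] = True
    return m


class TestDsc:
    def test_identical_and_disjoint(self):
        a = np.zeros((1, 4, 4), bool)
        a[0, :2] = True
        assert dsc(a, a) == 100.0
        assert dsc(a, ~a) == 0.0

    def test_hand_value(self):
        a = np.zeros((1, 20, 10), bool)
        b = np.zeros((1, 20, 10), bool)
        a[0, :10] = True           # |A| = 100
        b[0, 5:15] = True          # |B| = 100, overlap 50
        assert dsc(a, b) == pytest.approx(100 * 2 * 50 / 200)

    def test_both_empty_is_perfect_one_empty_is_zero(self):
        z = np.zeros((1, 3, 3), bool)
        o = z.copy()
        o[0, 1, 1] = True
        assert dsc(z, z) == 100.0
        assert dsc(z, o) == 0.0

    def test_symmetry_and_translation_invariance(self, rng):
        for _ in range(100):
            a, b = _rand_mask(rng), _rand_mask(rng)
            assert dsc(a, b) == pytest.approx(dsc(b, a))
            assert dsc(np.roll(a, 2, axis=1), np.roll(b, 2, axis=1)) == \
                   pytest.approx(dsc(a, b))


class TestSurfaceDistances:
    def test_identical_masks_are_zero(self, rng):
        m = _rand_mask(rng)
        hd, asd = surface_distances(m, m)
        assert hd == 0.0 and asd == 0.0

    def test_two_single_voxels(self):
        a = np.zeros((1, 10, 10), bool)
        b = np.zeros((1, 10, 10), bool)
        a[0, 2, 2] = True
        b[0, 2, 7] = True
        hd, asd = surface_distances(a, b, (1.0, 1.0, 1.0))
        assert hd == pytest.approx(5.0)
        assert asd == pytest.approx(5.0)

    def test_translated_square_bounds(self):
        a = np.zeros((1, 16, 16), bool)
        a[0, 4:10, 4:10] = True
        b = np.roll(a, 1, axis=1)
        hd, asd = surface_distances(a, b)
        assert asd <= 1.0 + 1e-9
        assert hd <= np.sqrt(2) + 1e-9

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(20):
            a, b = _rand_mask(rng), _rand_mask(rng)
            got = surface_distances(a, b, (0.31, 0.31, 2.0))
            want = exhaustive_surface_distances(a, b, (0.31, 0.31, 2.0))
            assert got[0] == pytest.approx(want[0], abs=1e-9)
            assert got[1] == pytest.approx(want[1], abs=1e-9)

    def test_hd95_at_least_asd_on_shared_pool(self, rng):
        for _ in range(20):
            pool = surface_distance_pool(_rand_mask(rng), _rand_mask(rng),
                                         (1.0, 1.0, 1.0))
            assert np.percentile(pool, 95) >= pool.mean() or \
                   np.isclose(np.percentile(pool, 95), pool.mean())

    def test_empty_mask_rejected(self):
        a = np.zeros((1, 4, 4), bool)
        b = a.copy()
        b[0, 1, 1] = True
        with pytest.raises(ValueError):
            surface_distances(a, b)

    def test_anisotropic_spacing_scales_slice_axis(self):
        a = np.zeros((2, 5, 5), bool)
        b = np.zeros((2, 5, 5), bool)
        a[0, 2, 2] = True
        b[1, 2, 2] = True   # one slice apart
        hd, asd = surface_distances(a, b, (0.31, 0.31, 2.0))
        assert hd == pytest.approx(2.0)


class TestEvaluateVolume:
    def _ring_label(self):
        cmap = np.full((2, 16, 16), 2)
        rr, cc = np.mgrid[0:16, 0:16]
        d = np.hypot(rr - 8, cc - 8)
        cmap[:, :, :][np.broadcast_to(d < 6, (2, 16, 16))] = 1
        cmap[:, :, :][np.broadcast_to(d < 3, (2, 16, 16))] = 0
        return cmap

    def test_perfect_prediction(self):
        cmap = self._ring_label()
        ref = onehot_encode(cmap)
        rec = evaluate_volume(cmap, ref)
        assert rec.dsc_wall == rec.dsc_lumen == rec.dsc_outer == 100.0
        assert rec.hd95_lumen == rec.asd_outer == 0.0

    def test_outer_wall_is_union(self):
        cmap = self._ring_label()
        ref = onehot_encode(cmap)
        pred = cmap.copy()
        pred[pred == 1] = 0  # whole outer region called lumen
        rec = evaluate_volume(pred, ref)
        assert rec.dsc_outer == 100.0
        assert rec.dsc_wall == 0.0
        assert rec.dsc_lumen < 100.0

    def test_dsc_avg_is_mean_of_lumen_and_outer(self):
        cmap = self._ring_label()
        rec = evaluate_volume(cmap, onehot_encode(cmap))
        rec.dsc_lumen, rec.dsc_outer = 90.0, 80.0
        assert rec.dsc_avg == 85.0

    def test_empty_prediction_yields_missing_distances(self):
        cmap = self._ring_label()
        ref = onehot_encode(cmap)
        pred = np.full_like(cmap, 2)
        rec = evaluate_volume(pred, ref)
        assert rec.dsc_lumen == 0.0
        assert rec.hd95_lumen is None and rec.asd_outer is None


class TestCompareMethods:
    def _perm_pvalue(self, a, b, n=5000, seed=0):
        rng = np.random.default_rng(seed)
        a, b = np.asarray(a), np.asarray(b)
        obs = abs(a.mean() - b.mean())
        pooled = np.concatenate([a, b])
        hits = 0
        for _ in range(n):
            rng.shuffle(pooled)
            if abs(pooled[:len(a)].mean() - pooled[len(a):].mean()) >= obs:
                hits += 1
        return hits / n

    def test_identical_groups_not_significant(self, rng):
        g = rng.normal(70, 5, size=20)
        table = compare_methods({"a": list(g), "b": list(g)})
        assert table["p-adj"].iloc[0] > 0.99

    def test_separated_groups_significant(self, rng):
        a = rng.normal(0, 0.1, 20)
        b = rng.normal(10, 0.1, 20)
        table = compare_methods({"a": list(a), "b": list(b)})
        assert table["p-adj"].iloc[0] < 1e-6
        assert self._perm_pvalue(a, b) < 0.01  # permutation oracle agrees

    def test_three_groups_only_shifted_pairs_significant(self, rng):
        base = rng.normal(70, 1.0, 20)
        shifted = rng.normal(80, 1.0, 20)
        table = compare_methods({"a": list(base), "b": list(base + rng.normal(0, 0.01, 20)),
                                 "c": list(shifted)})
        table = table.set_index(["group1", "group2"])
        assert table.loc[("a", "b"), "p-adj"] > 0.5
        assert table.loc[("a", "c"), "p-adj"] < 1e-4
        assert table.loc[("b", "c"), "p-adj"] < 1e-4

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_methods({"a": [1.0], "b": [1.0, 2.0]})
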