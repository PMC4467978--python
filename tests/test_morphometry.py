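"""Morphometric cleanup chain, thickness, registration and shrinkage."""

from collections import deque

import numpy as np
import pytest

from ctneoquant import morphometry as morph
from ctneoquant.quality import MismatchReport


def flood_fill_sizes(mask: np.ndarray, connectivity: int = 26) -> list[int]:
    """Brute-force BFS component labeling (independent oracle)."""
    offsets = [(dz, dy, dx)
               for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
               if (dz, dy, dx) != (0, 0, 0)
               and (connectivity == 26 or abs(dz) + abs(dy) + abs(dx) == 1)]
    seen = np.zeros_like(mask, bool)
    sizes = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        q = deque([start])
        seen[start] = True
        size = 0
        while q:
            z, y, x = q.popleft()
            size += 1
            for dz, dy, dx in offsets:
                p = (z + dz, y + dy, x + dx)
                if all(0 <= c < s for c, s in zip(p, mask.shape)) \
                        and mask[p] and not seen[p]:
                    seen[p] = True
                    q.append(p)
        sizes.append(size)
    return sizes


class TestRemoveScaffoldMargin:
    def test_radius_zero_is_set_difference(self, rng):
        neo = rng.random((8, 8, 8)) > 0.4
        scaf = rng.random((8, 8, 8)) > 0.7
        out = morph.remove_scaffold_margin(neo, scaf, 0)
        assert np.array_equal(out, neo & ~scaf)

    def test_euclidean_ball_semantics(self):
        scaf = np.zeros((11, 11, 11), bool)
        scaf[5, 5, 5] = True
        neo = np.zeros_like(scaf)
        neo[5, 5, 7] = True   # distance 2 -> removed
        neo[5, 5, 8] = True   # distance 3 -> kept
        out = morph.remove_scaffold_margin(neo, scaf, 2)
        assert not out[5, 5, 7] and out[5, 5, 8]

    def test_matches_distance_transform_oracle(self, rng):
        neo = rng.random((16, 16, 16)) > 0.5
        scaf = rng.random((16, 16, 16)) > 0.8
        out = morph.remove_scaffold_margin(neo, scaf, 2)
        # oracle: explicit distance to every scaffold voxel
        pts = np.argwhere(scaf)
        for v in np.argwhere(neo):
            d2 = ((pts - v) ** 2).sum(axis=1).min()
            assert out[tuple(v)] == (neo[tuple(v)] and d2 > 4)

    def test_empty_scaffold_is_identity(self, rng):
        neo = rng.random((6, 6, 6)) > 0.5
        out = morph.remove_scaffold_margin(neo, np.zeros_like(neo), 2)
        assert np.array_equal(out, neo)

    def test_anti_extensive(self, rng):
        neo = rng.random((10, 10, 10)) > 0.4
        scaf = rng.random((10, 10, 10)) > 0.85
        out = morph.remove_scaffold_margin(neo, scaf, 2)
        assert not (out & ~neo).any()


class TestDespeckle:
    def test_strictly_smaller_than_min_size(self):
        mask = np.zeros((8, 30, 30), bool)
        mask[0:2, 0:10, 0:10] = True       # 200 voxels: kept
        mask[4:5, 15:25, 10:20] = True     # 100 voxels
        mask[4:5, 15:25, 10:20][0, 0, 0] = False  # 99... adjust below
        mask[6, 0, 0] = True               # 1 voxel: removed
        out = morph.despeckle(mask, 200)
        assert out[0:2, 0:10, 0:10].all()
        assert not out[4:5, 15:25, 10:20].any()
        assert not out[6, 0, 0]

    def test_199_removed_200_kept(self):
        mask = np.zeros((4, 25, 25), bool)
        mask[0, 0:10, 0:20] = True          # 200 voxels
        mask[2, 12:22, 3:23] = True
        mask[2, 12, 3] = False              # 199 voxels
        out = morph.despeckle(mask, 200)
        assert out[0, 0:10, 0:20].all()
        assert not out[2, 12:22, 3:23].any()

    def test_small_cavity_filled(self):
        mask = np.ones((12, 12, 12), bool)
        mask[5:7, 5:10, 5:10] = False  # 50-voxel internal cavity
        out = morph.despeckle(mask, 200)
        assert out.all()

    def test_survivors_match_flood_fill_oracle(self, rng):
        mask = rng.random((12, 12, 12)) > 0.6
        out = morph.despeckle(mask, 20)
        # surviving white components (within the original mask) are exactly
        # the >= min_size components found by the BFS oracle
        oracle_keep = sorted(s for s in flood_fill_sizes(mask) if s >= 20)
        assert sorted(flood_fill_sizes(out & mask)) == oracle_keep
        # and no white component below min_size remains anywhere
        assert all(s >= 20 for s in flood_fill_sizes(out))


class TestCloseMask:
    def test_radius_zero_identity(self, rng):
        m = rng.random((8, 8, 8)) > 0.5
        assert np.array_equal(morph.close_mask(m, 0), m)

    def test_bridges_three_voxel_gap(self):
        m = np.zeros((12, 20, 20), bool)
        m[2:4, 2:18, 2:18] = True
        m[7:9, 2:18, 2:18] = True  # slabs 3 voxels apart (z = 4,5,6 empty)
        out = morph.close_mask(m, 2)
        assert out[4:7, 8, 8].all()

    def test_extensive_and_idempotent(self, rng):
        for seed in range(20):
            m = np.random.default_rng(seed).random((10, 14, 14)) > 0.5
            c = morph.close_mask(m, 2)
            assert (c | m).sum() == c.sum()        # extensive
            assert np.array_equal(morph.close_mask(c, 2), c)  # idempotent

    def test_matches_dilate_erode_composition(self, rng):
        from scipy import ndimage

        m = rng.random((12, 12, 12)) > 0.55
        out = morph.close_mask(m, 2)
        dil = ndimage.distance_transform_edt(~m) <= 2
        pad = np.pad(dil, 3, constant_values=True)
        ero = ndimage.distance_transform_edt(pad) > 2
        expected = ero[3:-3, 3:-3, 3:-3]
        assert np.array_equal(out, expected)


class TestSliceAreaAndSelection:
    def test_area_in_physical_units(self):
        mask = np.zeros((3, 20, 20), bool)
        mask[1].ravel()[:100] = True
        assert morph.slice_area(mask, 1, 3.75) == pytest.approx(1406.25)

    def test_empty_slice_zero(self):
        assert morph.slice_area(np.zeros((2, 5, 5), bool), 0) == 0.0

    def test_area_conservation_over_slices(self, rng):
        mask = rng.random((7, 9, 9)) > 0.5
        total = sum(morph.slice_area(mask, z, 2.0) for z in range(7))
        assert total == pytest.approx(mask.sum() * 4.0)

    def test_quartile_slices(self):
        assert morph.select_analysis_slices(np.zeros((120, 4, 4)), 3) == [30, 60, 90]

    def test_middle_slice_for_n1(self):
        assert morph.select_analysis_slices(np.zeros((121, 4, 4)), 1) == [60]

    def test_flagged_slice_substituted(self):
        rep = MismatchReport(slice_fractions=np.zeros(120),
                             flagged_slices=[60], mismatched_slice_fraction=1 / 120,
                             threshold=0.01)
        picks = morph.select_analysis_slices(np.zeros((120, 4, 4)), 3, rep)
        assert picks[0] == 30 and picks[2] == 90
        assert picks[1] in (59, 61)

    def test_all_flagged_raises(self):
        rep = MismatchReport(slice_fractions=np.ones(10),
                             flagged_slices=list(range(10)),
                             mismatched_slice_fraction=1.0, threshold=0.01)
        with pytest.raises(ValueError, match="flagged"):
            morph.select_analysis_slices(np.zeros((10, 4, 4)), 3, rep)


class TestThickness:
    def test_slab_interior_thickness(self):
        slab = np.zeros((20, 16, 16), bool)
        slab[5:15] = True
        res = morph.thickness_3d(slab, voxel_size_um=3.75)
        center = res.thickness_map_um[10, 8, 8]
        assert center == pytest.approx(10 * 3.75, abs=3.75)
        assert center == pytest.approx(37.5, abs=1e-9)

    def test_sphere_max_thickness_is_diameter(self):
        zz, yy, xx = np.mgrid[0:29, 0:29, 0:29]
        for r in (6, 10):
            sph = (zz - 14) ** 2 + (yy - 14) ** 2 + (xx - 14) ** 2 <= r * r
            res = morph.thickness_3d(sph, 1.0)
            assert abs(res.thickness_map_um.max() - 2 * r) <= 1.0

    def test_thickness_bounded_by_brute_force_inscribed_sphere(self, rng):
        mask = np.zeros((16, 16, 16), bool)
        mask[4:12, 3:13, 5:14] = True
        mask[rng.random((16, 16, 16)) > 0.97] = True
        res = morph.thickness_3d(mask, 1.0)
        # oracle: largest ball (voxel-center metric) containing each voxel
        radii = np.zeros(mask.shape)
        coords = np.argwhere(mask)
        bg = np.argwhere(~mask)
        for q in coords:
            d = np.sqrt(((bg - q) ** 2).sum(axis=1).min()) if len(bg) else np.inf
            radii[tuple(q)] = d
        for p in coords[:: max(1, len(coords) // 60)]:
            best = 0.0
            for q in coords:
                r = radii[tuple(q)]
                if ((p - q) ** 2).sum() <= r * r:
                    best = max(best, 2 * r)
            assert res.thickness_map_um[tuple(p)] <= best + 1.0

    def test_2d_disc_thickness(self):
        yy, xx = np.mgrid[0:16, 0:16]
        disc = ((yy - 8) ** 2 + (xx - 8) ** 2 <= 25)[None]
        res = morph.thickness_2d(disc, 0, 1.0)
        assert res.thickness_map_um.max() >= 9.0
        assert res.thickness_map_um.max() <= 11.0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            morph.thickness_3d(np.zeros((4, 4, 4), bool))


class TestRegistration:
    @staticmethod
    def smooth_volume(seed=1, shape=(36, 36, 36)):
        from scipy import ndimage

        rng = np.random.default_rng(seed)
        return ndimage.gaussian_filter(rng.normal(100, 20, shape), 2)

    def test_recovers_constructed_shift(self):
        a = self.smooth_volume()
        b = morph.apply_shift(a, (2, -3, 1), fill=float(a.mean()))
        assert morph.register_rigid(a, b, 5).shift == (2, -3, 1)

    def test_identity_gives_zero_shift_full_correlation(self):
        a = self.smooth_volume()
        res = morph.register_rigid(a, a, 4)
        assert res.shift == (0, 0, 0)
        assert res.correlation == pytest.approx(1.0, abs=1e-9)

    def test_robust_to_five_percent_noise(self):
        a = self.smooth_volume()
        span = a.max() - a.min()
        shifted = morph.apply_shift(a, (1, -2, 3), fill=float(a.mean()))
        good = 0
        for s in range(100):
            noisy = shifted + np.random.default_rng(s).normal(0, 0.05 * span,
                                                              a.shape)
            good += morph.register_rigid(a, noisy, 5).shift == (1, -2, 3)
        assert good >= 95

    def test_flat_volume_raises(self):
        with pytest.raises(ValueError, match="flat"):
            morph.register_rigid(np.ones((16, 16, 16)), np.ones((16, 16, 16)), 3)


class TestShrinkageStatistics:
    def test_direct_evaluation(self):
        assert morph.degree_of_shrinkage(100.0, 71.0) == pytest.approx(0.29)
        assert morph.degree_of_shrinkage(50.0, 50.0) == 0.0

    def test_negative_allowed_with_warning(self, caplog):
        out = morph.degree_of_shrinkage(100.0, 110.0)
        assert out == pytest.approx(-0.1)

    def test_nonpositive_reference_area_raises(self):
        with pytest.raises(ValueError):
            morph.degree_of_shrinkage(0.0, 10.0)

    def test_volume_difference_identical_masks(self, rng):
        m = rng.random((6, 6, 6)) > 0.5
        assert morph.volume_difference_fraction(m, m) == 0.0

    def test_volume_difference_29_percent_removed(self, rng):
        m = np.zeros((10, 10, 10), bool)
        m.ravel()[:400] = True
        b = m.copy()
        drop = rng.choice(400, size=116, replace=False)
        b.ravel()[drop] = False
        assert morph.volume_difference_fraction(m, b) == pytest.approx(0.29)

    def test_volume_difference_matches_elementwise_oracle(self, rng):
        a = rng.random((5, 8, 8)) > 0.3
        b = rng.random((5, 8, 8)) > 0.5
        count = sum(1 for x, y in zip(a.ravel(), b.ravel()) if x != y)
        assert morph.volume_difference_fraction(a, b) \
            == pytest.approx(count / a.sum())

    def test_empty_first_mask_raises(self, rng):
        with pytest.raises(ValueError):
            morph.volume_difference_fraction(np.zeros((4, 4, 4), bool),
                                             rng.random((4, 4, 4)) > 0.5)


def test_cleanup_chain_near_idempotent(noisy_phantom):
    out = noisy_phantom
    once = morph.clean_neo_mask(out.neo_mask, out.scaffold_mask)
    twice = morph.clean_neo_mask(once, out.scaffold_mask)
    changed = (once ^ twice).sum()
    assert changed < 0.01 * max(once.sum(), 1)
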