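"""Spatial normalisation, blurring, and maxT permutation inference."""

import itertools

import numpy as np
import pytest
from scipy import ndimage

from dosemine.dose_accum import DoseGrid
from dosemine.ibdm import (
    ReferenceTransform,
    blur_map,
    extract_region,
    map_to_reference,
    permutation_test,
    region_dose_summary,
)


def grid(vals, spacing=4.0):
    return DoseGrid(np.asarray(vals, dtype=float), [spacing] * 3)


class TestMapToReference:
    def test_identity_transform_is_exact(self, smooth_grid):
        mapped, valid = map_to_reference(smooth_grid, ReferenceTransform())
        np.testing.assert_array_equal(mapped.values, smooth_grid.values)
        assert valid.all()

    def test_integer_translation_matches_index_shift(self, rng):
        vals = rng.random((10, 9, 8)) * 10
        g = grid(vals)
        # x_ref = x_pat + 8 mm in x: reference voxel i samples patient i - 2vox
        tr = ReferenceTransform(translation=np.array([8.0, 0.0, 0.0]))
        mapped, valid = map_to_reference(g, tr)
        np.testing.assert_allclose(mapped.values[2:, :, :], vals[:-2, :, :], atol=1e-6)
        assert not valid[:2, :, :].any() and valid[2:, :, :].all()

    def test_affine_branch_agrees_with_translation_fast_path(self, smooth_grid):
        t = np.array([5.0, -3.0, 2.0])
        fast, vfast = map_to_reference(smooth_grid, ReferenceTransform(translation=t))
        # force the general affine path with an imperceptibly different matrix
        m = np.eye(3) + 1e-13
        slow, vslow = map_to_reference(smooth_grid, ReferenceTransform(matrix=m, translation=t))
        np.testing.assert_allclose(
            fast.values[vfast & vslow], slow.values[vfast & vslow], atol=1e-5
        )

    def test_qa_rule(self):
        tr = ReferenceTransform(heart_com_deviation=20.0, qa_tolerance=10.0)
        assert not tr.qa_passed
        tr2 = ReferenceTransform(heart_com_deviation=3.0, qa_tolerance=10.0)
        assert tr2.qa_passed

    def test_singular_transform_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            ReferenceTransform(matrix=np.zeros((3, 3)))


class TestBlur:
    def test_zero_sigma_is_identity(self, smooth_grid):
        out = blur_map(smooth_grid, 0.0)
        np.testing.assert_array_equal(out.values, smooth_grid.values)

    def test_unit_impulse_kernel_normalised(self):
        vals = np.zeros((15, 15, 15))
        vals[7, 7, 7] = 1.0
        out = blur_map(grid(vals), 6.0)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_constant_map_preserved(self):
        out = blur_map(grid(np.full((12, 12, 12), 3.7)), 5.0)
        np.testing.assert_allclose(out.values, 3.7, atol=1e-9)

    def test_negative_sigma_rejected(self, smooth_grid):
        with pytest.raises(ValueError):
            blur_map(smooth_grid, -1.0)


def exhaustive_two_vs_two(maps, n_perm_sd_from="all"):
    """Enumerate all 6 dead/alive splits of 4 patients, 2 per group.

    Returns the exhaustive global p for the observed labelling
    (patients 0,1 dead), using the SD over all 6 permuted difference
    maps, mirroring the estimator's construction.
    """
    X = np.stack([m.ravel() for m in maps]).astype(float)
    splits = [s for s in itertools.combinations(range(4), 2)]
    diffs = []
    for s in splits:
        w = np.full(4, -0.5)
        w[list(s)] = 0.5
        diffs.append(w @ X)
    diffs = np.array(diffs)
    sd = diffs.std(axis=0, ddof=1)
    ok = sd > 0
    obs = diffs[splits.index((0, 1))]
    t_obs = np.max(obs[ok] / sd[ok])
    maxes = np.max(np.abs(diffs[:, ok]) / sd[ok], axis=1)
    return np.mean(maxes >= t_obs)


class TestPermutationTest:
    def test_constant_equal_maps_are_degenerate(self):
        maps = [grid(np.full((3, 3, 2), 5.0)) for _ in range(8)]
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
        res = permutation_test(maps, labels, n_perm=50, seed=0)
        assert not res.diff_map.any()
        assert res.global_p == 1.0
        assert res.max_t == 0.0

    def test_agrees_with_exhaustive_enumeration(self, rng):
        maps = [rng.normal(0, 1, (2, 2, 1)) for _ in range(4)]
        labels = np.array([1, 1, 0, 0], dtype=bool)
        res = permutation_test([grid(m) for m in maps], labels, n_perm=4000, seed=3)
        p_exact = exhaustive_two_vs_two(maps)
        # Monte-Carlo binomial error at 4000 draws is well under 0.05
        assert res.global_p == pytest.approx(p_exact, abs=0.05)

    def test_planted_block_t_magnitude(self, rng):
        # two-sample analytic approximation: t ~= delta / (sd*sqrt(1/n1+1/n2))
        n = 100
        maps = [rng.normal(0, 1, (12, 12, 12)) for _ in range(2 * n)]
        for m in maps[:n]:
            m[4:9, 4:9, 4:9] += 1.0
        labels = np.r_[np.ones(n, bool), np.zeros(n, bool)]
        res = permutation_test([grid(m) for m in maps], labels, n_perm=500, seed=1)
        block_t = res.t_values[4:9, 4:9, 4:9].mean()
        expected = 1.0 / np.sqrt(2.0 / n)
        assert block_t == pytest.approx(expected, rel=0.2)

    def test_identity_permutation_reproduces_observed_diff(self, rng):
        maps = [rng.normal(0, 1, (4, 4, 2)) for _ in range(10)]
        labels = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0], bool)
        res = permutation_test([grid(m) for m in maps], labels, n_perm=100, seed=0)
        dead = np.mean([m for m, l in zip(maps, labels) if l], axis=0)
        alive = np.mean([m for m, l in zip(maps, labels) if not l], axis=0)
        np.testing.assert_allclose(res.diff_map, dead - alive, atol=1e-5)

    def test_label_swap_antisymmetry(self, rng):
        maps = [grid(rng.normal(0, 1, (4, 4, 2))) for _ in range(10)]
        labels = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0], bool)
        a = permutation_test(maps, labels, n_perm=100, seed=7)
        b = permutation_test(maps, ~labels, n_perm=100, seed=7)
        np.testing.assert_allclose(a.diff_map, -b.diff_map, atol=1e-5)
        np.testing.assert_allclose(a.t_values, -b.t_values, atol=1e-4)

    def test_null_global_p_calibration(self, rng):
        # under label exchangeability the global p is (discretely) uniform
        hits = 0
        for _ in range(100):
            maps = [grid(rng.normal(0, 1, (6, 6, 4))) for _ in range(40)]
            labels = np.r_[np.ones(20, bool), np.zeros(20, bool)]
            res = permutation_test(maps, labels, n_perm=200,
                                   seed=rng.integers(2**31))
            hits += res.global_p <= 0.05
        # exact binomial 95% acceptance region around 0.05 at 100 draws
        assert 1 <= hits <= 10

    def test_small_group_rejected(self, rng):
        maps = [grid(rng.normal(0, 1, (3, 3, 2))) for _ in range(5)]
        with pytest.raises(ValueError, match=">= 2"):
            permutation_test(maps, np.array([1, 0, 0, 0, 0], bool), n_perm=50, seed=0)

    def test_too_few_permutations_rejected(self, rng):
        maps = [grid(rng.normal(0, 1, (3, 3, 2))) for _ in range(6)]
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(maps, np.array([1, 1, 1, 0, 0, 0], bool), n_perm=5, seed=0)


def tmap_from_values(tvals, mask=None):
    """Build a TStatMap-like input for region extraction via the estimator."""
    from dosemine.ibdm import TStatMap

    tvals = np.asarray(tvals, dtype=float)
    if mask is None:
        mask = np.ones_like(tvals, dtype=bool)
    j = np.unravel_index(np.argmax(np.where(mask, tvals, -np.inf)), tvals.shape)
    return TStatMap(
        t_values=tvals, diff_map=tvals, perm_sd=np.ones_like(tvals),
        analysis_mask=mask, max_t=float(tvals[j]), global_p=0.01, n_perm=100,
        argmax_index=tuple(int(v) for v in j), spacing=np.full(3, 4.0),
    )


class TestRegionExtraction:
    def test_contour_level_is_fraction_of_max(self):
        t = np.zeros((5, 5, 3))
        t[2, 2, 1] = 4.34
        region = extract_region(tmap_from_values(t), fraction=0.8)
        assert region.threshold_t == pytest.approx(0.8 * 4.34)

    def test_constant_positive_map_selects_everything(self):
        t = np.full((4, 4, 2), 2.0)
        region = extract_region(tmap_from_values(t))
        assert region.mask.all()

    def test_disjoint_blob_not_included(self):
        t = np.zeros((12, 6, 3))
        t[1:3, 1:3, 1] = 4.5  # blob A holds the global max
        t[1, 1, 1] = 5.0
        t[8:10, 1:3, 1] = 4.2  # blob B is suprathreshold but disconnected
        region = extract_region(tmap_from_values(t), fraction=0.8)
        assert region.mask[1:3, 1:3, 1].all()
        assert not region.mask[8:10, 1:3, 1].any()

    def test_connectivity_6_vs_26(self):
        t = np.zeros((6, 6, 3))
        t[1, 1, 1] = 5.0
        t[2, 2, 1] = 4.5  # diagonal neighbour
        r26 = extract_region(tmap_from_values(t), connectivity=26)
        r6 = extract_region(tmap_from_values(t), connectivity=6)
        assert r26.mask[2, 2, 1]
        assert not r6.mask[2, 2, 1]

    def test_region_invariants(self, rng):
        t = ndimage.gaussian_filter(rng.normal(0, 1, (14, 14, 10)), 1.5)
        tm = tmap_from_values(t)
        region = extract_region(tm, fraction=0.8)
        assert region.mask[tm.argmax_index]
        assert (tm.t_values[region.mask] >= 0.8 * tm.max_t - 1e-12).all()

    def test_nonpositive_max_rejected(self):
        t = -np.ones((4, 4, 2))
        with pytest.raises(ValueError, match="max_t"):
            extract_region(tmap_from_values(t))


class TestRegionSummary:
    def test_single_voxel_region(self):
        from dosemine.ibdm import Region

        mask = np.zeros((3, 3, 2), bool)
        mask[1, 2, 0] = True
        maps = [grid(np.arange(18).reshape(3, 3, 2))]
        df = region_dose_summary(Region(mask, 1.0), maps, maps, ["P0"])
        assert df.loc[0, "mean_delta_region_gy"] == maps[0].values[1, 2, 0]

    def test_uniform_map_mean(self):
        from dosemine.ibdm import Region

        mask = np.zeros((4, 4, 2), bool)
        mask[1:3, 1:3, :] = True
        maps = [grid(np.full((4, 4, 2), 7.5))]
        df = region_dose_summary(Region(mask, 1.0), maps, maps)
        assert df.loc[0, "mean_planned_region_gy"] == pytest.approx(7.5)

    def test_hand_built_mean(self):
        from dosemine.ibdm import Region

        mask = np.zeros((2, 2, 1), bool)
        mask[:, :, 0] = True
        vals = np.array([[[1.0], [2.0]], [[3.0], [4.0]]])
        df = region_dose_summary(Region(mask, 1.0), [grid(vals)], [grid(vals)])
        assert df.loc[0, "mean_delta_region_gy"] == pytest.approx(2.5)

    def test_region_outside_valid_field_flagged(self):
        from dosemine.ibdm import Region

        mask = np.zeros((3, 3, 2), bool)
        mask[0, 0, 0] = True
        maps = [grid(np.ones((3, 3, 2)))]
        valid = [np.zeros((3, 3, 2), bool)]
        with pytest.raises(ValueError, match="outside"):
            region_dose_summary(Region(mask, 1.0), maps, maps, valid_masks=valid)
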