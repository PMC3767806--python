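import math

import numpy as np
import pytest

from wmfractal import (
    BoxCountCurve,
    FractalError,
    PhantomSpec,
    VoxelGrid,
    auto_scales,
    box_count,
    estimate_fd,
    fd_of_mask,
    feature_fd,
    make_phantom,
    select_scaling_range,
)
from wmfractal.morphology import ShapeFeatureSet

from conftest import random_blob_mask

MENGER_FD = math.log(20) / math.log(3)


def brute_force_box_count(mask: np.ndarray, r: int) -> int:
    """Independent oracle: scan every r-cell and test occupancy."""
    n = 0
    for z0 in range(0, mask.shape[0], r):
        for y0 in range(0, mask.shape[1], r):
            for x0 in range(0, mask.shape[2], r):
                if mask[z0:z0 + r, y0:y0 + r, x0:x0 + r].any():
                    n += 1
    return n


def menger_counts_by_recursion(level: int):
    """N(3^j) for a level-`level` sponge, from the recursive construction:
    at scale 3^j each occupied cell is a level-(level-j) sponge cell, so
    N = 20^(level - j)."""
    return {3**j: 20 ** (level - j) for j in range(level + 1)}


class TestBoxCount:
    def test_single_voxel_counts_one_at_every_scale(self):
        data = np.zeros((8, 8, 8), dtype=bool)
        data[3, 3, 3] = True
        curve = box_count(VoxelGrid(data=data), scales=[1, 2, 4])
        np.testing.assert_array_equal(curve.counts, [1, 1, 1])

    def test_solid_block_analytic(self):
        block = make_phantom(PhantomSpec(kind="solid_block", level_or_size=4))
        curve = box_count(block, scales=[1, 2, 4])
        np.testing.assert_array_equal(curve.counts, [64, 8, 1])

    def test_menger_matches_recursive_construction(self, menger3):
        expected = menger_counts_by_recursion(3)
        curve = box_count(menger3, scales=sorted(expected))
        np.testing.assert_array_equal(curve.counts, [8000, 400, 20, 1])
        np.testing.assert_array_equal(
            curve.counts, [expected[s] for s in curve.scales]
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_cell_scan(self, seed):
        r = np.random.default_rng(seed)
        shape = tuple(r.integers(8, 33, 3))
        mask = r.random(shape) < r.uniform(0.02, 0.3)
        if not mask.any():
            mask[0, 0, 0] = True
        scales = [1, 2, 4, 8, 16]
        curve = box_count(VoxelGrid(data=mask), scales=scales)
        expected = [brute_force_box_count(mask, s) for s in scales]
        np.testing.assert_array_equal(curve.counts, expected)

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_and_bounded(self, seed):
        r = np.random.default_rng(100 + seed)
        mask = r.random((24, 24, 24)) < 0.1
        mask[0, 0, 0] = True
        curve = box_count(VoxelGrid(data=mask))  # auto ladder (chain)
        v = int(mask.sum())
        assert np.all(np.diff(curve.counts) <= 0)
        for s, n in zip(curve.scales, curve.counts):
            assert math.ceil(v / s**3) <= n <= v

    def test_scale_invariance_under_upsampling(self):
        mask = random_blob_mask(5, size=16)
        big = np.repeat(np.repeat(np.repeat(mask, 2, 0), 2, 1), 2, 2)
        scales = [1, 2, 4, 8]
        small_curve = box_count(VoxelGrid(data=mask), scales=scales)
        big_curve = box_count(VoxelGrid(data=big), scales=[2 * s for s in scales])
        np.testing.assert_array_equal(small_curve.counts, big_curve.counts)

    def test_r1_count_equals_voxel_count(self, menger3):
        curve = box_count(menger3, scales=[1, 3])
        assert curve.counts[0] == menger3.count()

    def test_empty_mask_rejected(self):
        with pytest.raises(FractalError, match="empty"):
            box_count(VoxelGrid(data=np.zeros((4, 4, 4))), scales=[1, 2])

    def test_bad_scales_rejected(self):
        g = VoxelGrid(data=np.ones((4, 4, 4)))
        with pytest.raises(FractalError):
            box_count(g, scales=[2, 2, 4])
        with pytest.raises(FractalError):
            box_count(g, scales=[1, 8])  # exceeds grid dimension


class TestBoxCountProperties:
    """Structural invariants over arbitrary masks (hypothesis-driven)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(seed=st.integers(0, 10_000), density=st.floats(0.01, 0.9))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bounds_and_monotonicity_hold_for_any_mask(self, seed, density):
        r = np.random.default_rng(seed)
        mask = r.random((16, 16, 16)) < density
        if not mask.any():
            mask[0, 0, 0] = True
        curve = box_count(VoxelGrid(data=mask), scales=[1, 2, 4, 8, 16])
        v = int(mask.sum())
        assert curve.counts[0] == v
        assert np.all(np.diff(curve.counts) <= 0)
        for s, n in zip(curve.scales, curve.counts):
            assert math.ceil(v / s**3) <= n <= v


class TestAutoScales:
    @pytest.mark.parametrize("dim", [27, 64, 40, 100, 81])
    def test_divisor_chain_property(self, dim):
        scales = auto_scales((dim, dim, dim))
        assert scales[0] == 1
        for a, b in zip(scales, scales[1:]):
            assert b % a == 0, "ladder is not a divisor chain"
        assert scales[-1] <= dim

    def test_prime_dimension_falls_back_to_powers_of_two(self):
        scales = auto_scales((97, 97, 97))
        assert scales == [1, 2, 4, 8, 16, 32, 64]


class TestScalingRange:
    def test_collinear_curve_keeps_full_range(self):
        scales = [1, 2, 4, 8, 16]
        counts = [4096 * s**-2.0 for s in scales]
        curve = BoxCountCurve(scales=tuple(scales), counts=np.array(counts))
        assert select_scaling_range(curve) == (1, 16)

    def test_corrupted_endpoint_excluded(self):
        """Exhaustive-window oracle: the corrupt largest scale must drop."""
        scales = [1, 2, 4, 8, 16]
        counts = np.array([4096.0, 1024.0, 256.0, 64.0, 50.0])  # last point off
        curve = BoxCountCurve(scales=tuple(scales), counts=counts)
        assert select_scaling_range(curve, min_points=4) == (1, 8)

    def test_too_few_points_rejected(self):
        curve = BoxCountCurve(scales=(1, 2), counts=np.array([8.0, 2.0]))
        with pytest.raises(FractalError):
            select_scaling_range(curve, min_points=3)

    def test_non_powerlaw_curve_rejected_by_floor(self):
        scales = (1, 2, 4, 8)
        counts = np.array([1000.0, 900.0, 80.0, 70.0])
        curve = BoxCountCurve(scales=scales, counts=counts)
        with pytest.raises(FractalError, match="non-fractal"):
            select_scaling_range(curve, min_points=4, r2_floor=0.995)


class TestEstimateFd:
    def test_menger_curve_analytic_slope(self):
        curve = BoxCountCurve(
            scales=(1, 3, 9, 27), counts=np.array([8000.0, 400.0, 20.0, 1.0])
        )
        est = estimate_fd(curve)
        assert abs(est.fd - MENGER_FD) < 1e-12
        assert abs(est.r_squared - 1.0) < 1e-12

    def test_exact_power_law_any_prefactor(self):
        for c0 in (1.0, 17.0, 123.456):
            scales = (1, 2, 4, 8)
            counts = np.array([c0 * s**-2.0 for s in scales])
            est = estimate_fd(BoxCountCurve(scales=scales, counts=counts))
            assert abs(est.fd - 2.0) < 1e-12
            assert abs(math.exp(est.k) - c0) < 1e-9 * c0

    def test_solid_block_curve(self):
        est = estimate_fd(
            BoxCountCurve(scales=(1, 2, 4), counts=np.array([64.0, 8.0, 1.0]))
        )
        assert abs(est.fd - 3.0) < 1e-12

    def test_increasing_counts_rejected(self):
        with pytest.raises(FractalError, match="non-increasing"):
            BoxCountCurve(scales=(1, 2, 4), counts=np.array([1.0, 2.0, 4.0]))

    def test_flat_curve_is_dimension_zero(self):
        curve = BoxCountCurve(scales=(1, 2, 4), counts=np.array([4.0, 4.0, 4.0]))
        est = estimate_fd(curve)  # a point set seen at all scales
        assert est.fd == 0.0 and est.r_squared == 1.0

    def test_range_with_too_few_points_rejected(self):
        curve = BoxCountCurve(
            scales=(1, 2, 4, 8), counts=np.array([512.0, 64.0, 8.0, 1.0])
        )
        with pytest.raises(FractalError):
            estimate_fd(curve, scale_range=(4, 8))


class TestAnalyticRecovery:
    def test_menger_sponge_dimension(self, menger3):
        assert abs(fd_of_mask(menger3).fd - MENGER_FD) <= 0.05

    @pytest.mark.parametrize(
        "kind, size, truth",
        [("solid_block", 64, 3.0), ("plane", 64, 2.0), ("line", 64, 1.0)],
    )
    def test_euclidean_sets(self, kind, size, truth):
        g = make_phantom(PhantomSpec(kind=kind, level_or_size=size))
        assert abs(fd_of_mask(g).fd - truth) <= 0.05

    def test_feature_fd_on_analytic_shapes(self):
        """Ball: volume ~3, surface ~2; rod skeleton: curve ~1.

        A smooth ball needs room before its box counts reach the
        asymptotic regimes (fine scales track the digitized volume,
        coarse scales saturate to the embedding dimension), hence the
        128-voxel grid and 3-point minimum window.
        """
        n = 128
        zz, yy, xx = np.ogrid[:n, :n, :n]
        c = (n - 1) / 2
        ball = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= (0.45 * n) ** 2
        from wmfractal import extract_surface, skeletonize_3d

        g = VoxelGrid(data=ball)
        fs = ShapeFeatureSet(
            general=g,
            skeleton=skeletonize_3d(g),
            surface=extract_surface(g, 6),
            hemisphere_label="whole",
        )
        est = feature_fd(fs, min_points=3)
        assert abs(est["general"].fd - 3.0) <= 0.1
        assert abs(est["surface"].fd - 2.0) <= 0.15

        rod = make_phantom(PhantomSpec(kind="rod", level_or_size=60))
        skel = skeletonize_3d(rod)
        assert abs(fd_of_mask(skel).fd - 1.0) <= 0.1

    def test_ball_skeleton_survives_as_a_point(self):
        """Thinning a topologically trivial ball must not lose the component."""
        n = 64
        zz, yy, xx = np.ogrid[:n, :n, :n]
        c = (n - 1) / 2
        ball = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= (0.42 * n) ** 2
        from wmfractal import skeletonize_3d

        sk = skeletonize_3d(VoxelGrid(data=ball))
        assert sk.count() >= 1
        assert not np.any(sk.data & ~ball)

    def test_empty_feature_reported_by_name(self, menger3):
        fs = ShapeFeatureSet(
            general=menger3,
            skeleton=menger3.with_data(np.zeros_like(menger3.data)),
            surface=menger3,
            hemisphere_label="whole",
        )
        with pytest.raises(FractalError, match="skeleton"):
            feature_fd(fs)
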