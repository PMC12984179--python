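"""Feature matching, homography recovery, B-spline basis and FFD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vstain.fixtures import SyntheticSlideSpec, generate_slide_pair
from vstain.registration import (KeypointSet, MatchSet, detect_sift, detect_orb,
                                 match_descriptors, accept_slide_pair,
                                 HomographyTransform, estimate_homography,
                                 apply_homography, warp_homography,
                                 bspline_basis, uniform_knots,
                                 mattes_mi, mi_from_joint, register_ffd,
                                 warp_ffd, register_pair)
from vstain.tiling import to_grayscale


def _kpset(xy, desc):
    xy = np.asarray(xy, float)
    kp = np.column_stack([xy, np.ones(len(xy)), np.zeros(len(xy))])
    return KeypointSet(kp, np.asarray(desc))


class TestMatching:
    def test_identical_binary_descriptors_distance_zero(self):
        d = np.array([[1, 0, 1, 1, 0], [0, 1, 0, 0, 1], [1, 1, 1, 0, 0]], bool)
        a = _kpset([(0, 0), (1, 1), (2, 2)], d)
        m = match_descriptors(a, a, metric="hamming", ratio_threshold=0.9)
        assert all(m.pairs[:, 2] == 0)
        assert all(m.pairs[:, 0] == m.pairs[:, 1])

    def test_hamming_by_hand(self):
        # 10110 vs 10011 -> XOR popcount 2
        a = _kpset([(0, 0)], np.array([[1, 0, 1, 1, 0]], bool))
        b = _kpset([(0, 0), (5, 5)],
                   np.array([[1, 0, 0, 1, 1], [0, 1, 0, 0, 0]], bool))
        m = match_descriptors(a, b, metric="hamming", ratio_threshold=0.99)
        assert len(m) == 1
        assert m.pairs[0, 2] == 2

    def test_tied_distances_rejected(self):
        """Equal best/second-best distances give ratio 1: never kept."""
        a = _kpset([(0, 0)], np.array([[1.0, 0.0]]))
        b = _kpset([(0, 0), (1, 1)], np.array([[1.0, 1.0], [1.0, -1.0]]))
        m = match_descriptors(a, b, metric="euclidean", ratio_threshold=0.999)
        assert len(m) == 0

    def test_metric_descriptor_mismatch(self):
        a = _kpset([(0, 0)], np.array([[1.0, 0.0]]))
        b = _kpset([(0, 0)], np.array([[True, False]]))
        with pytest.raises(ValueError):
            match_descriptors(a, b, metric="hamming")

    def test_sift_self_match(self, slide_pair):
        kp = detect_sift(to_grayscale(slide_pair.he_image))
        assert len(kp) > 10
        m = match_descriptors(kp, kp, ratio_threshold=0.9)
        zero = m.pairs[m.pairs[:, 2] == 0]
        assert len(zero) > 0 and all(zero[:, 0] == zero[:, 1])


class TestAcceptance:
    def test_self_match_accepts(self, slide_pair):
        kp = detect_sift(to_grayscale(slide_pair.he_image))
        m = match_descriptors(kp, kp, ratio_threshold=0.9)
        ok, frac = accept_slide_pair(m, (len(kp), len(kp)))
        assert ok and frac > 0.5

    def test_unrelated_noise_rejected(self, rng):
        a = detect_sift(rng.random((256, 256)))
        b = detect_sift(rng.random((256, 256)))
        m = match_descriptors(a, b)
        ok, frac = accept_slide_pair(m, (len(a), len(b)))
        assert not ok and frac < 0.10

    def test_zero_threshold_always_accepts(self):
        m = MatchSet(np.empty((0, 3)), "euclidean", 0.75)
        ok, _ = accept_slide_pair(m, (10, 10), threshold=0.0)
        assert ok

    def test_zero_keypoints_rejected(self):
        m = MatchSet(np.empty((0, 3)), "euclidean", 0.75)
        ok, frac = accept_slide_pair(m, (0, 5))
        assert not ok and frac == 0.0


def _matches_from_points(src, dst):
    n = len(src)
    pairs = np.column_stack([np.arange(n), np.arange(n), np.zeros(n)])
    a = _kpset(src, np.zeros((n, 2)))
    b = _kpset(dst, np.zeros((n, 2)))
    return MatchSet(pairs, "euclidean", 0.75), a, b


class TestHomography:
    H_TRUE = np.array([[1.05, 0.08, 12.0],
                       [-0.06, 0.97, -7.0],
                       [1e-4, -2e-4, 1.0]])

    def test_exact_recovery_from_noiseless_points(self, rng):
        src = rng.uniform(0, 300, (25, 2))
        dst = apply_homography(self.H_TRUE, src)
        m, a, b = _matches_from_points(src, dst)
        H = estimate_homography(m, a, b, seed=0)
        assert np.abs(H.H - self.H_TRUE / self.H_TRUE[2, 2]).max() < 1e-6

    def test_identity_correspondences(self, rng):
        src = rng.uniform(0, 100, (12, 2))
        m, a, b = _matches_from_points(src, src)
        H = estimate_homography(m, a, b, seed=0)
        assert np.abs(H.H - np.eye(3)).max() < 1e-9

    def test_outlier_rejection(self, rng):
        src = rng.uniform(0, 300, (60, 2))
        dst = apply_homography(self.H_TRUE, src)
        n_out = 18       # 30% gross outliers
        idx = rng.choice(60, n_out, replace=False)
        dst[idx] += rng.uniform(40, 120, (n_out, 2))
        m, a, b = _matches_from_points(src, dst)
        H = estimate_homography(m, a, b, seed=3)
        assert (~H.inlier_mask[idx]).mean() >= 0.95
        assert np.abs(H.H - self.H_TRUE / self.H_TRUE[2, 2]).max() < 1e-6

    def test_insufficient_matches(self):
        m, a, b = _matches_from_points(np.zeros((3, 2)), np.zeros((3, 2)))
        with pytest.raises(ValueError, match="insufficient"):
            estimate_homography(m, a, b)

    def test_point_mapping_by_hand(self):
        H = HomographyTransform(np.array([[1.0, 0, 5], [0, 1, -3], [0, 0, 1]]))
        np.testing.assert_allclose(apply_homography(H, [(1.0, 2.0)]),
                                   [[6.0, -1.0]])

    def test_degenerate_h_rejected(self):
        with pytest.raises(ValueError):
            HomographyTransform(np.array([[1.0, 0, 0], [2.0, 0, 0], [0, 0, 1]]))

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_recovery_property(self, seed):
        """Random moderate-perspective H from 20 noiseless points: 1e-6."""
        r = np.random.default_rng(seed)
        H_true = np.eye(3)
        H_true[:2, :2] += r.uniform(-0.1, 0.1, (2, 2))
        H_true[:2, 2] = r.uniform(-20, 20, 2)
        H_true[2, :2] = r.uniform(-2e-4, 2e-4, 2)
        src = r.uniform(0, 400, (20, 2))
        dst = apply_homography(H_true, src)
        m, a, b = _matches_from_points(src, dst)
        H = estimate_homography(m, a, b, seed=0)
        assert np.abs(H.H - H_true / H_true[2, 2]).max() < 1e-6


class TestWarp:
    def test_identity_bit_identical(self, textured_patch):
        out = warp_homography(textured_patch, HomographyTransform.identity())
        np.testing.assert_array_equal(out, textured_patch)

    def test_integer_translation_pixel_exact(self, textured_patch):
        H = HomographyTransform(np.array([[1.0, 0, 7], [0, 1, 4], [0, 0, 1]]))
        out = warp_homography(textured_patch, H)
        rolled = np.roll(textured_patch, (4, 7), axis=(0, 1))
        np.testing.assert_array_equal(out[4:, 7:], rolled[4:, 7:])

    def test_out_of_bounds_zero_filled(self, textured_patch):
        H = HomographyTransform(np.array([[1.0, 0, 20], [0, 1, 0], [0, 0, 1]]))
        out = warp_homography(textured_patch, H)
        assert np.all(out[:, :20] == 0)


class TestBsplineBasis:
    def test_order_zero_indicator(self):
        knots = uniform_knots(4, 0)
        assert bspline_basis(1, 0, 1.5, knots) == 1.0
        assert bspline_basis(1, 0, 2.5, knots) == 0.0

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_partition_of_unity(self, k):
        n_basis = 8
        knots = uniform_knots(n_basis, k)
        for x in np.linspace(k + 0.01, n_basis - 0.01, 17):
            total = sum(bspline_basis(i, k, x, knots) for i in range(n_basis))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_cubic_against_scipy(self):
        """Independent oracle: scipy's BSpline basis elements."""
        from scipy.interpolate import BSpline
        knots = uniform_knots(6, 3)
        for i in range(6):
            oracle = BSpline.basis_element(knots[i:i + 5], extrapolate=False)
            for x in [knots[i] + 0.5, knots[i] + 1.7, knots[i] + 3.2]:
                assert bspline_basis(i, 3, x, knots) == pytest.approx(
                    float(oracle(x)), abs=1e-12)

    def test_x_outside_span_errors(self):
        with pytest.raises(ValueError):
            bspline_basis(0, 2, 99.0, uniform_knots(4, 2))


class TestMattesMi:
    def test_self_mi_equals_entropy(self, textured_patch):
        g = np.round(to_grayscale(textured_patch))
        n_bins = 50
        lo, hi = g.min(), g.max()
        idx = np.minimum(((g - lo) / (hi - lo) * n_bins).astype(int), n_bins - 1)
        p = np.bincount(idx.ravel(), minlength=n_bins) / idx.size
        p = p[p > 0]
        h = float(-(p * np.log(p)).sum())
        assert mattes_mi(g, g) == pytest.approx(h, abs=1e-9)

    def test_independent_noise_near_zero(self):
        r = np.random.default_rng(0)
        a = r.integers(0, 256, (256, 256)).astype(float)
        b = r.integers(0, 256, (256, 256)).astype(float)
        assert mattes_mi(a, b) < 0.05

    def test_constant_image_zero_by_convention(self):
        assert mattes_mi(np.full((8, 8), 7.0), np.arange(64.0).reshape(8, 8)) == 0.0

    def test_toy_joint_distribution(self):
        p = np.array([[0.5, 0.0], [0.0, 0.5]])
        assert mi_from_joint(p, base=2.0) == pytest.approx(1.0)
        assert mi_from_joint(p) == pytest.approx(np.log(2.0))


class TestFfd:
    def test_identical_images_no_displacement(self, slide_pair):
        g = to_grayscale(slide_pair.mt_image)
        res = register_ffd(g, g, max_iter=30)
        assert res.transform.mean_control_displacement() < 0.5

    def test_known_warp_error_halves(self):
        spec = SyntheticSlideSpec(global_shift=(0.0, 0.0), global_rotation=0.0,
                                  warp_amplitude=6.0, artifact_fraction=0.0,
                                  seed=17)
        pair = generate_slide_pair(spec)
        lm = pair.landmark_set
        before = np.linalg.norm(lm.mt_points - lm.he_points, axis=1).mean()
        res = register_ffd(to_grayscale(pair.he_image),
                           to_grayscale(pair.mt_image),
                           max_iter=80, sampling_fraction=0.3, seed=5)
        mapped = res.transform.transform_points(lm.mt_points)
        after = np.linalg.norm(mapped - lm.he_points, axis=1).mean()
        assert after < 0.5 * before

    def test_objective_trace_improves(self, slide_pair):
        """Dense-metric trace: final MMI similarity >= initial."""
        res = register_pair(slide_pair, seed=0, run_ffd=False)
        mov = to_grayscale(res.aligned_he)
        fix = to_grayscale(slide_pair.mt_image)
        ffd = register_ffd(mov, fix, max_iter=40)
        assert ffd.final_mmi >= ffd.initial_mmi
        assert ffd.iterations == len(ffd.mmi_trace)

    def test_grid_too_small_rejected(self, textured_patch):
        g = to_grayscale(textured_patch)
        with pytest.raises(ValueError):
            register_ffd(g, g, grid_dims=(3, 3))

    def test_warp_ffd_identity_shape(self, textured_patch):
        g = to_grayscale(textured_patch)
        res = register_ffd(g, g, max_iter=5)
        out = warp_ffd(textured_patch, res.transform)
        assert out.shape == textured_patch.shape


class TestCascade:
    def test_stagewise_error_reduction(self):
        """SIFT accept -> homography -> FFD shrinks landmark error monotonically."""
        spec = SyntheticSlideSpec(global_shift=(22.0, -15.0), global_rotation=3.0,
                                  warp_amplitude=6.0, seed=61)
        pair = generate_slide_pair(spec)
        res = register_pair(pair, seed=1)
        assert res.accepted
        e = res.stage_errors
        assert len(e) == 3
        assert e[1] < e[0] and e[2] < e[1]
        assert e[2] < 2.0

    def test_rotated_fixture_matches_map_to_landmarks(self):
        """Ratio-test survivors on a rotated pair align with the known motion."""
        spec = SyntheticSlideSpec(global_shift=(0.0, 0.0), global_rotation=15.0,
                                  warp_amplitude=0.0, artifact_fraction=0.0,
                                  seed=27)
        pair = generate_slide_pair(spec)
        kp_he = detect_sift(to_grayscale(pair.he_image))
        kp_mt = detect_sift(to_grayscale(pair.mt_image))
        m = match_descriptors(kp_he, kp_mt)
        assert len(m) >= 8
        src = kp_he.xy[m.pairs[:, 0].astype(int)]
        dst = kp_mt.xy[m.pairs[:, 1].astype(int)]
        # the true map sends MT points to H&E points; invert it on src
        expected = pair.true_transform.inverse_points(src)
        ok = np.linalg.norm(expected - dst, axis=1) < 3.0
        assert ok.mean() >= 0.6


class TestOrb:
    def test_orb_detects_binary_descriptors(self, slide_pair):
        kp = detect_orb(to_grayscale(slide_pair.he_image))
        assert kp.descriptors.dtype == bool
        assert kp.descriptors.shape[1] == 256

    def test_orb_patch_alignment(self, aligned_pair):
        he = to_grayscale(aligned_pair.he_image)
        mt = to_grayscale(aligned_pair.mt_image)
        a, b = detect_orb(he), detect_orb(mt)
        m = match_descriptors(a, b, metric="hamming")
        if len(m) >= 4:
            H = estimate_homography(m, a, b, seed=0)
            # aligned fixture: recovered homography near identity
            assert np.abs(H.H[:2, 2]).max() < 3.0
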