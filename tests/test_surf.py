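"""Detector and descriptor checks against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from dtisurf import surf

from conftest import make_pssm


# ---------------------------------------------------------------------------
# normalisation and integral image
# ---------------------------------------------------------------------------


class TestNormalize:
    def test_linear_map_hits_midpoint(self, rng):
        scores = rng.integers(-5, 6, (30, 20)).astype(float)
        scores[0, 0], scores[0, 1] = -5, 5
        scores[1, 0] = 0
        grid = surf.normalize_pssm(make_pssm(scores))
        assert grid.values[1, 0] == pytest.approx(0.5)
        assert grid.values.min() == 0 and grid.values.max() == 1

    def test_constant_maps_to_half(self):
        grid = surf.normalize_pssm(make_pssm(np.full((5, 20), 3.0)))
        assert np.all(grid.values == 0.5)


class TestIntegralImage:
    def test_corner_of_ones(self):
        ii = surf.integral_image(np.ones((2, 2)))
        assert ii[2, 2] == 4
        assert np.all(surf.integral_image(np.zeros((3, 4))) == 0)

    def test_random_rectangles_match_brute_force(self, rng):
        grid = rng.random((12, 20))
        ii = surf.integral_image(grid)
        for _ in range(100):
            r0, r1 = sorted(rng.integers(0, 13, 2))
            c0, c1 = sorted(rng.integers(0, 21, 2))
            brute = sum(
                grid[r, c] for r in range(r0, r1) for c in range(c0, c1)
            )
            assert surf.rect_sum(ii, r0, c0, r1, c1) == pytest.approx(
                brute, abs=1e-10
            )

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(derandomize=True, max_examples=25)
    def test_any_rectangle_matches_slice_sum(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.random((10, 14))
        ii = surf.integral_image(grid)
        r0, r1 = sorted(rng.integers(0, 11, 2))
        c0, c1 = sorted(rng.integers(0, 15, 2))
        assert surf.rect_sum(ii, r0, c0, r1, c1) == pytest.approx(
            grid[r0:r1, c0:c1].sum(), abs=1e-10
        )


# ---------------------------------------------------------------------------
# Hessian responses
# ---------------------------------------------------------------------------


def _box_kernels(fs):
    """Dense convolution kernels equivalent to the box-filter Hessian."""
    lobe, border, half = fs // 3, (fs - 1) // 2, (fs // 3) // 2
    kxx = np.zeros((fs, fs))
    kxx[border - lobe + 1 : border + lobe, :] += 1
    kxx[border - lobe + 1 : border + lobe, border - half : border + half + 1] -= 3
    kyy = kxx.T.copy()
    kxy = np.zeros((fs, fs))
    kxy[border - lobe : border, border + 1 : border + 1 + lobe] += 1
    kxy[border + 1 : border + 1 + lobe, border - lobe : border] += 1
    kxy[border - lobe : border, border - lobe : border] -= 1
    kxy[border + 1 : border + 1 + lobe, border + 1 : border + 1 + lobe] -= 1
    return kxx / fs**2, kyy / fs**2, kxy / fs**2


class TestHessianResponse:
    def test_constant_grid_vanishes(self):
        ii = surf.integral_image(np.full((25, 25), 0.7))
        det, _ = surf.hessian_response(ii, 9)
        assert np.allclose(det, 0.0, atol=1e-12)

    @pytest.mark.parametrize("fs", [9, 15])
    def test_matches_dense_convolution(self, rng, fs):
        grid = rng.random((30, 30))
        det, _ = surf.hessian_response(surf.integral_image(grid), fs)
        kxx, kyy, kxy = _box_kernels(fs)
        dxx = ndimage.correlate(grid, kxx, mode="constant")
        dyy = ndimage.correlate(grid, kyy, mode="constant")
        dxy = ndimage.correlate(grid, kxy, mode="constant")
        oracle = dxx * dyy - (0.9 * dxy) ** 2
        b = (fs - 1) // 2
        np.testing.assert_allclose(
            det[b:-b, b:-b], oracle[b:-b, b:-b], atol=1e-10
        )

    def test_bright_blob_has_negative_laplacian(self, blob_grid):
        grid, (r0, c0) = blob_grid
        _, lap = surf.hessian_response(surf.integral_image(grid), 15)
        assert lap[r0, c0] == -1

    def test_oversized_filter_warns_and_is_empty(self, caplog):
        ii = surf.integral_image(np.ones((6, 6)))
        with caplog.at_level("WARNING"):
            det, _ = surf.hessian_response(ii, 9)
        assert np.all(det == 0)
        assert "larger" in caplog.text


class TestFilterScale:
    @pytest.mark.parametrize("fs,sigma", [(9, 1.2), (27, 3.6), (18, 2.4)])
    def test_known_values(self, fs, sigma):
        assert surf.filter_scale(fs) == pytest.approx(sigma)

    def test_linearity(self):
        for s in (9, 15, 21):
            assert surf.filter_scale(2 * s) == pytest.approx(2 * surf.filter_scale(s))

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            surf.filter_scale(0)

    @given(st.integers(min_value=9, max_value=999), st.integers(min_value=1, max_value=8))
    @settings(derandomize=True, max_examples=50)
    def test_homogeneity(self, fs, k):
        assert surf.filter_scale(k * fs) == pytest.approx(k * surf.filter_scale(fs))


class TestScaleSpace:
    def test_filter_size_sequence(self, rng):
        ii = surf.integral_image(rng.random((40, 40)))
        stack = surf.build_scale_space(ii, 4)
        assert [lv.filter_size for lv in stack] == [9, 15, 21, 27]
        sigmas = [lv.sigma for lv in stack]
        assert sigmas == sorted(sigmas) and len(set(sigmas)) == 4
        for lv in stack:
            assert lv.sigma == pytest.approx(surf.filter_scale(lv.filter_size))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


class TestDetectKeypoints:
    def test_constant_grid_yields_none(self):
        ii = surf.integral_image(np.full((40, 40), 0.5))
        assert surf.detect_keypoints(surf.build_scale_space(ii, 4)) == []

    def test_planted_blob_single_keypoint_at_centre(self, padded_blob):
        ii, pad, (r0, c0) = padded_blob
        kps = [
            kp
            for kp in surf.detect_keypoints(surf.build_scale_space(ii, 4))
            if pad <= kp.row < pad + 40 and pad <= kp.col < pad + 40
        ]
        assert len(kps) == 1
        assert (kps[0].row - pad, kps[0].col - pad) == (r0, c0)
        assert kps[0].laplacian_sign == -1  # bright blob

    def test_keypoints_dominate_26_neighbours(self, rng):
        grid = rng.random((35, 35))
        stack = surf.build_scale_space(surf.integral_image(grid), 4)
        dets = np.stack([lv.det for lv in stack])
        levels = {lv.filter_size: i for i, lv in enumerate(stack)}
        kps = surf.detect_keypoints(stack)
        assert kps, "random grid should produce at least one keypoint"
        for kp in kps:
            li = levels[kp.filter_size]
            centre = dets[li, kp.row, kp.col]
            for dl in (-1, 0, 1):
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dl == dr == dc == 0:
                            continue
                        assert centre > dets[li + dl, kp.row + dr, kp.col + dc]


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------


class TestOrientation:
    def _ramp_keypoint(self):
        # smooth left-to-right ramp; keypoint placed mid-grid
        grid = np.tile(np.linspace(0, 1, 80), (80, 1))
        ii = surf.integral_image(grid)
        kp = surf.Keypoint(40, 40, 15, surf.filter_scale(15), 1.0, 1)
        return ii, kp, grid

    def test_ramp_points_along_positive_x(self):
        ii, kp, _ = self._ramp_keypoint()
        theta = surf.assign_orientation(ii, kp)
        assert min(theta, 2 * math.pi - theta) < math.pi / 8

    def test_mirrored_grid_reflects_orientation(self, rng):
        grid = ndimage.gaussian_filter(rng.random((80, 80)), 2.0)
        ii = surf.integral_image(grid)
        kp = surf.Keypoint(40, 40, 15, surf.filter_scale(15), 1.0, 1)
        theta = surf.assign_orientation(ii, kp)
        mirrored = surf.integral_image(grid[:, ::-1])
        kp_m = surf.Keypoint(40, 79 - 40, 15, surf.filter_scale(15), 1.0, 1)
        theta_m = surf.assign_orientation(mirrored, kp_m)
        expected = (math.pi - theta) % (2 * math.pi)
        diff = abs(theta_m - expected)
        assert min(diff, 2 * math.pi - diff) < 0.25

    def test_out_of_reach_returns_zero_with_warning(self, caplog):
        ii = surf.integral_image(np.random.default_rng(0).random((20, 20)))
        kp = surf.Keypoint(1, 1, 15, surf.filter_scale(15), 1.0, 1)
        with caplog.at_level("WARNING"):
            assert surf.assign_orientation(ii, kp) == 0.0
        assert "exceeds grid" in caplog.text


# ---------------------------------------------------------------------------
# descriptor
# ---------------------------------------------------------------------------


class TestDescriptor:
    def test_constant_window_is_zero_vector(self):
        ii = surf.integral_image(np.full((120, 120), 0.4))
        kp = surf.Keypoint(60, 60, 15, surf.filter_scale(15), 1.0, 1)
        desc = surf.compute_descriptor(ii, kp, 0.0)
        assert desc.vector.shape == (64,)
        assert np.all(desc.vector == 0)

    def test_unit_norm_on_structure(self, padded_blob):
        ii, pad, (r0, c0) = padded_blob
        kp = surf.Keypoint(pad + r0, pad + c0, 15, surf.filter_scale(15), 1.0, -1)
        desc = surf.compute_descriptor(ii, kp, 0.7)
        assert desc.vector.shape == (64,)
        assert np.linalg.norm(desc.vector) == pytest.approx(1.0)

    def test_translation_equivariance(self):
        rows, cols = np.mgrid[0:90, 0:90]
        base = np.exp(-((rows - 40) ** 2 + (cols - 45) ** 2) / (2 * 2.5**2))
        shifted = np.exp(-((rows - 43) ** 2 + (cols - 45) ** 2) / (2 * 2.5**2))
        sigma = surf.filter_scale(15)
        d0 = surf.compute_descriptor(
            surf.integral_image(base),
            surf.Keypoint(40, 45, 15, sigma, 1.0, -1),
            0.9,
        )
        d1 = surf.compute_descriptor(
            surf.integral_image(shifted),
            surf.Keypoint(43, 45, 15, sigma, 1.0, -1),
            0.9,
        )
        np.testing.assert_allclose(d0.vector, d1.vector, atol=1e-9)


# ---------------------------------------------------------------------------
# pooling and end-to-end extraction
# ---------------------------------------------------------------------------


def _descriptor(vec):
    kp = surf.Keypoint(0, 0, 15, 2.0, 1.0, 1)
    return surf.Descriptor(np.asarray(vec, dtype=float), kp)


class TestPooling:
    def test_mean_of_single_descriptor_is_identity(self, rng):
        v = rng.normal(size=64)
        feat = surf.pool_descriptors([_descriptor(v)], method="mean")
        np.testing.assert_allclose(feat.vector, v)
        assert feat.n_keypoints == 1

    def test_empty_set_gives_zero_vector(self):
        feat = surf.pool_descriptors([], method="mean")
        assert np.all(feat.vector == 0) and feat.n_keypoints == 0

    def test_bovw_histogram_matches_cluster_sizes(self, rng):
        a = [_descriptor(rng.normal(0, 0.05, 64) + 5) for _ in range(6)]
        b = [_descriptor(rng.normal(0, 0.05, 64) - 5) for _ in range(2)]
        codebook = surf.fit_codebook(a + b, K=2, seed=0)
        feat = surf.pool_descriptors(a + b, method="bovw", codebook=codebook)
        assert sorted(feat.vector.tolist()) == pytest.approx([0.25, 0.75])

    def test_bovw_without_codebook_raises(self):
        with pytest.raises(ValueError, match="codebook"):
            surf.pool_descriptors([_descriptor(np.ones(64))], method="bovw")


class TestExtractProteinFeatures:
    def test_constant_pssm_zero_feature(self):
        feat = surf.extract_protein_features(make_pssm(np.full((40, 20), 2.0)))
        assert np.all(feat.vector == 0) and feat.n_keypoints == 0

    def test_default_output_length_64(self, rng):
        feat = surf.extract_protein_features(make_pssm(rng.integers(-6, 9, (50, 20))))
        assert feat.vector.shape == (64,)

    def test_deterministic_across_runs(self, rng):
        pssm = make_pssm(rng.integers(-6, 9, (60, 20)))
        f1 = surf.extract_protein_features(pssm)
        f2 = surf.extract_protein_features(pssm)
        np.testing.assert_array_equal(f1.vector, f2.vector)
        assert f1.n_keypoints == f2.n_keypoints

    def test_pooled_length_constant_across_proteins(self, rng):
        pssms = {
            f"T{i}": make_pssm(rng.integers(-6, 9, (30 + 7 * i, 20)))
            for i in range(4)
        }
        feats = surf.extract_features_batch(pssms)
        lengths = {f.vector.shape for f in feats.values()}
        assert lengths == {(64,)}
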