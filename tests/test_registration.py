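"""Feature registration: grayscale, matching, homography, warping, overlay."""

import numpy as np
import pytest

from fundus2cfi.errors import (
    DegenerateGeometryError,
    InsufficientMatchesError,
    RegistrationStageError,
)
from fundus2cfi.image import FundusImage
from fundus2cfi.odscale import map_point_to_scaled
from fundus2cfi.registration import (
    Homography,
    MatchSet,
    checkerboard_overlay,
    estimate_homography,
    extract_and_match,
    register,
    to_grayscale,
    warp_and_mask,
)
from conftest import random_homography


def _apply(H, pts):
    P = np.hstack([pts, np.ones((len(pts), 1))]) @ H.T
    return P[:, :2] / P[:, 2:3]


def _matchset(ps, pt):
    return MatchSet(ps=np.asarray(ps, float), pt=np.asarray(pt, float),
                    scores=np.ones(len(ps)))


class TestGrayscale:
    @pytest.mark.parametrize(
        "color,expected",
        [((1, 1, 1), 1.0), ((0, 1, 0), 0.587), ((0.3, 0.3, 0.3), 0.3)],
    )
    def test_bt601_weights(self, color, expected):
        img = np.ones((4, 4, 3)) * np.array(color)
        assert to_grayscale(img)[0, 0] == pytest.approx(expected, abs=1e-12)


class TestMatching:
    def test_self_match(self, pair3):
        gray = to_grayscale(pair3.cfi)
        m = extract_and_match(gray, gray, backend="orb")
        assert len(m) >= 4
        disp = np.sqrt(((m.ps - m.pt) ** 2).sum(axis=1))
        assert np.median(disp) < 1.0

    def test_featureless_raises(self):
        flat = np.full((128, 128), 0.5)
        with pytest.raises(InsufficientMatchesError):
            extract_and_match(flat, flat, backend="orb")

    def test_phantom_matches_agree_with_ground_truth(self, pair3, scaled3):
        m = extract_and_match(
            to_grayscale(scaled3.image), to_grayscale(pair3.cfi), backend="orb"
        )
        assert len(m) >= 8
        mapped = _apply(pair3.H_true, m.ps)
        d = np.sqrt(((mapped - m.pt) ** 2).sum(axis=1))
        assert (d < 3.0).mean() >= 0.5

    def test_unknown_backend(self):
        with pytest.raises(ValueError):
            extract_and_match(np.zeros((64, 64)), np.zeros((64, 64)), backend="nope")


class TestHomographyEstimation:
    def test_identity_correspondences(self, rng):
        pts = rng.uniform(10, 110, (10, 2))
        H, inl = estimate_homography(_matchset(pts, pts))
        assert np.abs(H.m - np.eye(3)).max() < 1e-9
        assert inl.all()

    def test_minimal_noiseless_recovery(self, rng):
        Ht = random_homography(rng)
        ps = np.array([[10.0, 10.0], [100.0, 15.0], [20.0, 95.0], [105.0, 100.0]])
        H, _ = estimate_homography(_matchset(ps, _apply(Ht, ps)))
        assert np.abs(H.m - Ht).max() < 1e-6

    def test_outlier_rejection(self, rng):
        Ht = random_homography(rng)
        inliers = rng.uniform(0, 120, (20, 2))
        outl_s = rng.uniform(0, 120, (10, 2))
        outl_t = rng.uniform(0, 120, (10, 2))
        ps = np.vstack([inliers, outl_s])
        pt = np.vstack([_apply(Ht, inliers), outl_t])
        H, flags = estimate_homography(_matchset(ps, pt), seed=7)
        err = np.sqrt(((_apply(H.m, inliers) - _apply(Ht, inliers)) ** 2).sum(axis=1))
        assert err.max() < 1.0
        assert flags[:20].sum() >= 18

    def test_too_few_matches(self):
        with pytest.raises(InsufficientMatchesError):
            estimate_homography(_matchset(np.zeros((3, 2)), np.zeros((3, 2))))

    def test_cross_check_against_skimage(self, rng):
        """Independent oracle: skimage's projective estimator on clean data."""
        from skimage.transform import ProjectiveTransform

        Ht = random_homography(rng)
        ps = rng.uniform(0, 120, (12, 2))
        pt = _apply(Ht, ps)
        H, _ = estimate_homography(_matchset(ps, pt))
        ref = ProjectiveTransform()
        assert ref.estimate(ps, pt)
        ref_m = ref.params / ref.params[2, 2]
        assert np.abs(H.m - ref_m).max() < 1e-6


class TestWarpAndMask:
    def test_identity(self, pair3):
        warped, mask = warp_and_mask(pair3.cfi, Homography(np.eye(3)), (128, 128))
        assert mask.all()
        assert np.allclose(warped.pixels, pair3.cfi.pixels, atol=1e-12)

    def test_translation_footprint(self, pair3):
        T = np.eye(3)
        T[0, 2] = 10.0
        warped, mask = warp_and_mask(pair3.cfi, Homography(T), (128, 128))
        assert not mask[:, :9].any()
        assert mask[:, 12:].all()

    def test_scale_up_covers_target(self, pair3):
        S = np.diag([2.0, 2.0, 1.0])
        warped, mask = warp_and_mask(pair3.cfi, Homography(S), (128, 128))
        assert mask.all()

    def test_no_nonzero_pixels_outside_mask(self, pair3):
        T = np.eye(3)
        T[:2, 2] = (30.0, -15.0)
        warped, mask = warp_and_mask(pair3.cfi, Homography(T), (128, 128))
        assert warped.pixels[~mask].max() == 0.0

    def test_singular_matrix_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            Homography(np.array([[1, 0, 0], [2, 0, 0], [0, 0, 1.0]]))


class TestRegister:
    def test_self_registration_is_identity(self, pair3):
        res = register(pair3.cfi, pair3.cfi, backend="orb", seed=0)
        assert np.abs(res.H.m - np.eye(3)).max() < 0.01

    def test_phantom_recovery(self, pair3, scaled3):
        res = register(scaled3, pair3.cfi, backend="orb", seed=3)
        kp_s = np.array(
            [map_point_to_scaled(tuple(k), scaled3)[0] for k in pair3.kp_ufi]
        )
        d = np.sqrt(((res.H.apply(kp_s) - pair3.kp_cfi) ** 2).sum(axis=1))
        assert d.mean() < 2.0

    def test_uniform_target_fails_at_matching(self, pair3):
        flat = FundusImage(np.full((128, 128, 3), 0.5))
        with pytest.raises(RegistrationStageError) as exc:
            register(pair3.cfi, flat, backend="orb")
        assert exc.value.stage == "matching"

    def test_equivariance_under_known_pre_warp(self, pair3, scaled3):
        """Registering a pre-warped source composes with the pre-warp."""
        T = np.eye(3)
        T[:2, 2] = (6.0, -4.0)
        pre, _ = warp_and_mask(scaled3.image, Homography(T), (128, 128))
        res_direct = register(scaled3, pair3.cfi, backend="orb", seed=3)
        res_pre = register(pre, pair3.cfi, backend="orb", seed=3)
        # res_pre maps pre-warped coords; composing with T should match direct
        composed = res_pre.H.m @ T
        composed /= composed[2, 2]
        grid = np.array([[20.0, 20.0], [100.0, 30.0], [40.0, 100.0], [90.0, 90.0]])
        d = np.sqrt(((_apply(composed, grid) - _apply(res_direct.H.m, grid)) ** 2).sum(1))
        assert d.max() < 2.0


class TestCheckerboard:
    def test_identical_inputs(self, pair3):
        out = checkerboard_overlay(pair3.cfi, pair3.cfi, 8)
        assert np.array_equal(out.pixels, pair3.cfi.pixels)

    def test_half_and_half(self):
        white = FundusImage(np.ones((128, 128, 3)))
        black = FundusImage(np.zeros((128, 128, 3)))
        out = checkerboard_overlay(white, black, 2)
        assert out.pixels.mean() == pytest.approx(0.5, abs=0.01)

    def test_cell_size(self):
        a = FundusImage(np.ones((128, 128, 3)))
        b = FundusImage(np.zeros((128, 128, 3)))
        out = checkerboard_overlay(a, b, 8)
        # first cell is a's (white), the next along x is b's
        assert out.pixels[0, 15, 0] == 1.0 and out.pixels[0, 16, 0] == 0.0

    def test_shape_mismatch(self):
        a = FundusImage(np.ones((128, 128, 3)))
        b = FundusImage(np.ones((64, 64, 3)))
        with pytest.raises(ValueError):
            checkerboard_overlay(a, b, 4)
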