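"""OD scale adjustment: crop arithmetic, detection, point mapping."""

import numpy as np
import pytest

from fundus2cfi.errors import ODDetectionError
from fundus2cfi.image import FundusImage
from fundus2cfi.odscale import (
    BrightBlobDetector,
    ODInfo,
    OracleDetector,
    extract_crop_box,
    localize_od,
    map_point_from_scaled,
    map_point_to_scaled,
    od_scale_adjust,
)
from fundus2cfi.phantom import PhantomSpec, generate_phantom_pair


def crop_box_oracle(od, W, H):
    """Direct re-statement of the 6x-window-with-shift-clamp arithmetic."""
    w = min(round(6 * od.w * W), W)
    h = min(round(6 * od.h * H), H)
    x0 = min(max(round(od.cx * W - w / 2), 0), W - w)
    y0 = min(max(round(od.cy * H - h / 2), 0), H - h)
    return (x0, y0, w, h)


class TestExtractCropBox:
    def test_centered_window(self):
        box = extract_crop_box(ODInfo(0.5, 0.5, 0.1, 0.1), 512, 512)
        assert box[2] == box[3] == 307  # round(6 * 0.1 * 512)
        assert box[0] + box[2] / 2 == pytest.approx(256, abs=1)
        assert box[1] + box[3] / 2 == pytest.approx(256, abs=1)

    def test_corner_od_shifts_not_shrinks(self):
        box = extract_crop_box(ODInfo(0.02, 0.02, 0.1, 0.1), 512, 512)
        assert (box[0], box[1]) == (0, 0)
        assert box[2] == box[3] == 307

    def test_oversize_window_clamps_to_image(self):
        box = extract_crop_box(ODInfo(0.5, 0.5, 0.2, 0.1), 512, 512)
        assert box[2] == 512

    def test_randomized_against_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            od = ODInfo(
                cx=rng.uniform(0, 1),
                cy=rng.uniform(0, 1),
                w=rng.uniform(0.02, 0.4),
                h=rng.uniform(0.02, 0.4),
            )
            W = int(rng.integers(64, 1024))
            H = int(rng.integers(64, 1024))
            box = extract_crop_box(od, W, H)
            assert box == crop_box_oracle(od, W, H)
            x0, y0, w, h = box
            assert 0 <= x0 and x0 + w <= W and 0 <= y0 and y0 + h <= H


class TestLocalize:
    def test_oracle_detector_round_trips_the_box(self, pair3):
        od = localize_od(pair3.ufi, OracleDetector(pair3.od_box_ufi))
        assert od.cx == pytest.approx(pair3.od_box_ufi.cx, abs=1e-6)
        assert od.w == pytest.approx(pair3.od_box_ufi.w, abs=1e-6)

    def test_blob_detector_finds_phantom_od(self):
        hits = 0
        for seed in range(20):
            pair = generate_phantom_pair(PhantomSpec(seed=seed))
            od = localize_od(pair.ufi, BrightBlobDetector())
            err = np.hypot(od.cx - pair.od_box_ufi.cx, od.cy - pair.od_box_ufi.cy)
            hits += err < 0.05
        assert hits >= 18  # the disc is the brightest blob in nearly every render

    def test_black_image_raises(self):
        with pytest.raises(ODDetectionError):
            localize_od(FundusImage(np.zeros((64, 64, 3))), BrightBlobDetector())


class TestScaleAdjust:
    def test_identity_resize_preserves_pixels(self, pair3):
        box = extract_crop_box(pair3.od_box_ufi, 128, 128)
        od = pair3.od_box_ufi
        scaled = od_scale_adjust(pair3.ufi, od, box[2]) if box[2] == box[3] else None
        if scaled is not None:
            x0, y0, w, h = scaled.crop_box
            assert np.array_equal(
                scaled.image.pixels, pair3.ufi.pixels[y0 : y0 + h, x0 : x0 + w]
            )

    def test_keypoints_land_inside_scaled_frame(self, pair3, scaled3):
        for kp in pair3.kp_ufi:
            (sx, sy), out = map_point_to_scaled(tuple(kp), scaled3)
            assert not out
            assert 0 <= sx < 128 and 0 <= sy < 128

    def test_downscale_preserves_checker_mean(self):
        checker = np.indices((128, 128)).sum(axis=0) % 2
        img = FundusImage(np.repeat(checker[..., None], 3, axis=2).astype(float))
        od = ODInfo(0.5, 0.5, 1.0 / 6.0, 1.0 / 6.0)  # crop = whole image
        scaled = od_scale_adjust(img, od, 64)
        assert scaled.image.pixels.mean() == pytest.approx(img.pixels.mean(), abs=1e-3)

    def test_od_lands_near_scaled_center(self, pair3, scaled3):
        od_px = (pair3.od_box_ufi.cx * 128, pair3.od_box_ufi.cy * 128)
        (sx, sy), _ = map_point_to_scaled(od_px, scaled3)
        assert np.hypot(sx - 64, sy - 64) <= 128 / 6 + 2


class TestPointMapping:
    def test_affine_example(self):
        scaled = _fake_scaled(crop=(100, 50, 300, 300), l=150)
        (x, y), out = map_point_to_scaled((250, 200), scaled)
        assert (x, y) == (75.0, 75.0) and not out

    def test_crop_origin_maps_to_zero(self):
        scaled = _fake_scaled(crop=(100, 50, 300, 300), l=150)
        assert map_point_to_scaled((100, 50), scaled)[0] == (0.0, 0.0)

    def test_round_trip_is_identity(self):
        scaled = _fake_scaled(crop=(17, 23, 211, 190), l=128)
        p = (119.25, 101.5)
        (sx, sy), _ = map_point_to_scaled(p, scaled)
        back = map_point_from_scaled((sx, sy), scaled)
        assert np.allclose(back, p, atol=1e-9)

    def test_out_of_view_flagged(self):
        scaled = _fake_scaled(crop=(100, 50, 300, 300), l=150)
        _, out = map_point_to_scaled((50, 50), scaled)
        assert out


def _fake_scaled(crop, l):
    from fundus2cfi.odscale import ScaledUFI

    img = FundusImage(np.zeros((l, l, 3)))
    return ScaledUFI(image=img, crop_box=crop, target_side=l)
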