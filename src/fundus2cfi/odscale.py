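"""Optic-disc scale adjustment (step 1 of scaled feature registration).

An ultrawidefield fundus image (UFI) covers ~200 degrees of retina while a
conventional fundus image (CFI) covers ~45 degrees centered between macula and
optic disc (OD). Before feature registration the UFI is rescaled so that its
anatomy appears at roughly CFI scale, using the OD -- the most stable bright
landmark in the fundus -- as the anchor: detect the OD, crop a window six
times the OD width/height centered on it, and resize the crop to the target
CFI resolution ``l``.

Coordinates are 0-based with ``x`` = column, ``y`` = row and pixel centers at
integers, consistently across the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from scipy import ndimage

from .errors import ODDetectionError
from .image import FundusImage

__all__ = [
    "ODInfo",
    "ScaledUFI",
    "ODDetector",
    "OracleDetector",
    "BrightBlobDetector",
    "localize_od",
    "extract_crop_box",
    "od_scale_adjust",
    "map_point_to_scaled",
    "map_point_from_scaled",
    "scaled_to_source_affine",
]


@dataclass(frozen=True)
class ODInfo:
    """Normalized optic-disc location and size.

    ``cx, cy`` are the box center and ``w, h`` the box width/height, all
    normalized to ``[0, 1]`` by the image width/height respectively.
    """

    cx: float
    cy: float
    w: float
    h: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"ODInfo.{name}={v} outside [0, 1]")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("ODInfo box must have positive width and height")

    def to_dict(self) -> dict:
        return {
            "cx": self.cx,
            "cy": self.cy,
            "w": self.w,
            "h": self.h,
            "confidence": self.confidence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ODInfo":
        return cls(d["cx"], d["cy"], d["w"], d["h"], d.get("confidence", 1.0))


@dataclass(frozen=True)
class ScaledUFI:
    """A scale-adjusted UFI: the 6x-OD crop resized to an l-by-l raster.

    ``crop_box`` is ``(x0, y0, width, height)`` in source-image pixels; it is
    kept so that annotated points can be mapped into (and out of) the scaled
    frame.
    """

    image: FundusImage
    crop_box: tuple[int, int, int, int]
    target_side: int

    def __post_init__(self) -> None:
        if self.image.height != self.target_side or self.image.width != self.target_side:
            raise ValueError("scaled image must be square with side target_side")


class ODDetector(Protocol):
    """Single-method detection contract: image -> zero or more scored boxes.

    Each box is ``(cx, cy, w, h, score)`` in *pixel* units of the input image.
    """

    def detect(self, image: FundusImage) -> list[tuple[float, float, float, float, float]]:
        ...


class OracleDetector:
    """Detector that returns a known ground-truth box (phantom / annotation)."""

    def __init__(self, od: ODInfo):
        self._od = od

    def detect(self, image: FundusImage):
        W, H = image.width, image.height
        o = self._od
        return [(o.cx * W, o.cy * H, o.w * W, o.h * H, o.confidence)]


class BrightBlobDetector:
    """Classical OD detector: the optic disc is the brightest compact blob.

    Grayscale -> Gaussian smooth -> threshold at a high brightness percentile
    -> largest connected component -> bounding box. Confidence is the blob's
    mean brightness relative to the image maximum. Suitable for phantoms and
    clean fundus photographs; not a replacement for a learned detector on
    pathological images.
    """

    def __init__(self, sigma: float = 2.0, percentile: float = 99.0):
        self.sigma = sigma
        self.percentile = percentile

    def detect(self, image: FundusImage):
        gray = image.pixels.mean(axis=2)
        smooth = ndimage.gaussian_filter(gray, self.sigma)
        if smooth.max() <= 1e-6:
            return []
        thresh = np.percentile(smooth, self.percentile)
        binary = smooth >= max(thresh, 1e-6)
        labels, n = ndimage.label(binary)
        if n == 0:
            return []
        boxes = []
        peak = smooth.max()
        for lbl in range(1, n + 1):
            ys, xs = np.nonzero(labels == lbl)
            x0, x1 = xs.min(), xs.max()
            y0, y1 = ys.min(), ys.max()
            w = float(x1 - x0 + 1)
            h = float(y1 - y0 + 1)
            score = float(smooth[ys, xs].mean() / peak)
            boxes.append(((x0 + x1) / 2.0, (y0 + y1) / 2.0, w, h, score))
        return boxes


def localize_od(image: FundusImage, detector: ODDetector) -> ODInfo:
    """Detect the optic disc and return its box normalized to [0, 1].

    The highest-confidence detection wins; ties break toward larger area,
    then smaller (y, x) center, so the result is deterministic.
    """
    boxes = detector.detect(image)
    if not boxes:
        raise ODDetectionError("optic-disc detector returned no detections")
    boxes = sorted(boxes, key=lambda b: (-b[4], -(b[2] * b[3]), b[1], b[0]))
    cx, cy, w, h, score = boxes[0]
    W, H = image.width, image.height
    return ODInfo(
        cx=float(np.clip(cx / W, 0, 1)),
        cy=float(np.clip(cy / H, 0, 1)),
        w=float(min(max(w / W, 1e-6), 1.0)),
        h=float(min(max(h / H, 1e-6), 1.0)),
        confidence=float(np.clip(score, 0, 1)),
    )


def extract_crop_box(od: ODInfo, image_w: int, image_h: int) -> tuple[int, int, int, int]:
    """Pixel rectangle (x0, y0, w, h): a 6x-OD window centered on the OD.

    The window width is ``round(6 * od.w * image_w)`` (height analogous),
    clamped to the image dimension. If the centered window crosses a border
    it is shifted inside, not shrunk, preserving the OD-relative scale.
    """
    win_w = min(int(round(6.0 * od.w * image_w)), image_w)
    win_h = min(int(round(6.0 * od.h * image_h)), image_h)
    win_w = max(win_w, 1)
    win_h = max(win_h, 1)
    x0 = int(round(od.cx * image_w - win_w / 2.0))
    y0 = int(round(od.cy * image_h - win_h / 2.0))
    x0 = min(max(x0, 0), image_w - win_w)
    y0 = min(max(y0, 0), image_h - win_h)
    return (x0, y0, win_w, win_h)


def od_scale_adjust(image: FundusImage, od: ODInfo, l: int) -> ScaledUFI:
    """Crop the 6x-OD window and bilinearly resize it to an l-by-l image.

    The resample uses the same corner-anchored affine as
    :func:`map_point_to_scaled` (output pixel ``s`` reads the crop at
    ``s * crop_side / l``), so points mapped through the affine land exactly
    on the features they index in the scaled raster. When a dimension is
    downscaled a Gaussian anti-alias filter (sigma = factor / 2) is applied
    first.
    """
    if l < 32:
        raise ValueError("target side l must be >= 32")
    x0, y0, w, h = extract_crop_box(od, image.width, image.height)
    crop = image.pixels[y0 : y0 + h, x0 : x0 + w]
    if (h, w) == (l, l):
        out = crop.copy()
    else:
        fy, fx = h / l, w / l
        src = crop
        sig_y = fy / 2.0 if fy > 1.05 else 0.0
        sig_x = fx / 2.0 if fx > 1.05 else 0.0
        if sig_y > 0 or sig_x > 0:
            src = ndimage.gaussian_filter(src, (sig_y, sig_x, 0.0))
        yy, xx = np.mgrid[0:l, 0:l]
        coords = np.stack([yy * fy, xx * fx])
        out = np.stack(
            [
                ndimage.map_coordinates(src[..., c], coords, order=1, mode="nearest")
                for c in range(3)
            ],
            axis=-1,
        )
    out = np.clip(out, 0.0, 1.0)
    return ScaledUFI(image=FundusImage(out), crop_box=(x0, y0, w, h), target_side=l)


def map_point_to_scaled(
    p: tuple[float, float], scaled: ScaledUFI
) -> tuple[tuple[float, float], bool]:
    """Map a source-image point into the scaled frame.

    Returns ``((x, y), out_of_view)`` where ``out_of_view`` is True when the
    point lies outside the crop window.
    """
    x0, y0, w, h = scaled.crop_box
    l = scaled.target_side
    x, y = p
    sx = (x - x0) * (l / w)
    sy = (y - y0) * (l / h)
    out = not (x0 <= x < x0 + w and y0 <= y < y0 + h)
    return (sx, sy), out


def map_point_from_scaled(p: tuple[float, float], scaled: ScaledUFI) -> tuple[float, float]:
    """Inverse of :func:`map_point_to_scaled` (exact affine inverse)."""
    x0, y0, w, h = scaled.crop_box
    l = scaled.target_side
    return (p[0] * (w / l) + x0, p[1] * (h / l) + y0)


def scaled_to_source_affine(scaled: ScaledUFI) -> np.ndarray:
    """3x3 affine taking scaled-frame coordinates to source-image pixels."""
    x0, y0, w, h = scaled.crop_box
    l = scaled.target_side
    return np.array(
        [[w / l, 0.0, float(x0)], [0.0, h / l, float(y0)], [0.0, 0.0, 1.0]]
    )
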