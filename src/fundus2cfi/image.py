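"""Fundus image container and PNG I/O.

All images in this package are RGB rasters with float values in ``[0, 1]``,
0-based pixel coordinates, ``x`` = column, ``y`` = row, and pixel centers at
integer coordinates. Every stage of the pipeline carries images in this form;
8-bit quantization happens only at the PNG boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["FundusImage", "load_image", "save_image"]

_MIN_SIDE = 32


@dataclass(frozen=True)
class FundusImage:
    """An RGB fundus raster with values in [0, 1].

    Parameters
    ----------
    pixels : ndarray of shape (H, W, 3)
        Float pixel values in ``[0, 1]``, RGB channel order.
    """

    pixels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB array, got shape {px.shape}")
        if px.shape[0] < _MIN_SIDE or px.shape[1] < _MIN_SIDE:
            raise ValueError(f"image sides must be >= {_MIN_SIDE}, got {px.shape[:2]}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel values must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) spatial shape."""
        return self.pixels.shape[:2]


def load_image(path: str | Path) -> FundusImage:
    """Read an 8- or 16-bit PNG/TIFF into a FundusImage."""
    raw = iio.imread(path)
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    if raw.shape[2] == 4:  # drop alpha
        raw = raw[:, :, :3]
    if raw.dtype == np.uint8:
        px = raw.astype(np.float64) / 255.0
    elif raw.dtype == np.uint16:
        px = raw.astype(np.float64) / 65535.0
    else:
        px = np.clip(raw.astype(np.float64), 0.0, 1.0)
    return FundusImage(px)


def save_image(image: FundusImage | np.ndarray, path: str | Path) -> None:
    """Write an image (or a single-channel [0,1] raster) as an 8-bit PNG."""
    px = image.pixels if isinstance(image, FundusImage) else np.asarray(image)
    q = np.clip(np.rint(px * 255.0), 0, 255).astype(np.uint8)
    try:
        iio.imwrite(path, q)
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise OSError(f"failed to write image file {path!s}: {exc}") from exc
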