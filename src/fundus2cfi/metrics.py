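"""Image-quality metrics for translation assessment: MSE, PSNR, SSIM, MS-SSIM.

All metrics are computed on the 0-255 intensity scale (images stored in
[0, 1] are multiplied by 255 without re-quantization), so MSE and PSNR
magnitudes are comparable across implementations that operate on 8-bit
images. SSIM follows the standard structural-similarity formulation
(11x11 Gaussian window, sigma 1.5, K1=0.01, K2=0.03, dynamic range 255,
channel-averaged); MS-SSIM uses up to 5 dyadic scales with the standard
weights, reducing the scale count (with a warning) when the image is too
small to support all five.

A registration mask restricts evaluation to the valid overlap region; this
matters because warped images contain zero-filled exteriors that would
otherwise dominate pixel metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .image import FundusImage

__all__ = ["MetricReport", "compute_metrics", "ms_ssim", "PSNR_INF"]

PSNR_INF = float("inf")

# standard 5-scale MS-SSIM weights (Wang et al. exponents)
_MSSSIM_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])
_C1 = (0.01 * 255) ** 2
_C2 = (0.03 * 255) ** 2


@dataclass(frozen=True)
class MetricReport:
    """mse/psnr on the 0-255 scale; ssim and ms_ssim reported in percent."""

    mse: float
    psnr: float
    ssim: float
    ms_ssim: float
    n_pairs: int = 1

    def __post_init__(self) -> None:
        if self.mse > 0 and np.isfinite(self.psnr):
            expected = 10.0 * np.log10(255.0**2 / self.mse)
            if abs(expected - self.psnr) > 1e-6:
                raise ValueError("psnr inconsistent with mse")

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "psnr": self.psnr,
            "ssim": self.ssim,
            "ms_ssim": self.ms_ssim,
            "n_pairs": self.n_pairs,
        }


def _as255(img: FundusImage | np.ndarray) -> np.ndarray:
    px = img.pixels if isinstance(img, FundusImage) else np.asarray(img, float)
    return px * 255.0


def _ssim_l_cs(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel luminance and contrast-structure SSIM components.

    Gaussian window sigma 1.5 truncated at 11x11, sample statistics without
    Bessel correction - the reference formulation.
    """
    filt = dict(sigma=1.5, truncate=3.5, mode="reflect")
    mu_a = ndimage.gaussian_filter(a, **filt)
    mu_b = ndimage.gaussian_filter(b, **filt)
    var_a = ndimage.gaussian_filter(a * a, **filt) - mu_a**2
    var_b = ndimage.gaussian_filter(b * b, **filt) - mu_b**2
    cov = ndimage.gaussian_filter(a * b, **filt) - mu_a * mu_b
    lum = (2 * mu_a * mu_b + _C1) / (mu_a**2 + mu_b**2 + _C1)
    cs = (2 * cov + _C2) / (var_a + var_b + _C2)
    return lum, cs


def _downsample2(a: np.ndarray) -> np.ndarray:
    """2x2 average pooling (odd trailing row/col dropped)."""
    h, w = a.shape[0] // 2 * 2, a.shape[1] // 2 * 2
    a = a[:h, :w]
    return 0.25 * (a[0::2, 0::2] + a[1::2, 0::2] + a[0::2, 1::2] + a[1::2, 1::2])


def ms_ssim(y: FundusImage | np.ndarray, y_hat: FundusImage | np.ndarray) -> float:
    """Multi-scale SSIM in [-1, 1] (not percent), channel-averaged.

    Contrast-structure terms are accumulated over dyadic scales and the
    luminance term enters at the coarsest scale, with the standard weights
    renormalized if fewer than 5 scales fit (min side 11 at the last scale).
    """
    a = _as255(y)
    b = _as255(y_hat)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    min_side = min(a.shape[0], a.shape[1])
    n_scales = 1
    while n_scales < 5 and (min_side // (2**n_scales)) >= 11:
        n_scales += 1
    if n_scales < 5:
        warnings.warn(
            f"image too small for 5 MS-SSIM scales; using {n_scales}",
            stacklevel=2,
        )
    weights = _MSSSIM_WEIGHTS[:n_scales] / _MSSSIM_WEIGHTS[:n_scales].sum()

    vals = []
    for c in range(a.shape[2] if a.ndim == 3 else 1):
        ca = a[..., c] if a.ndim == 3 else a
        cb = b[..., c] if b.ndim == 3 else b
        score = 1.0
        for s in range(n_scales):
            lum, cs = _ssim_l_cs(ca, cb)
            mcs = float(cs.mean())
            if s == n_scales - 1:
                score *= np.sign(float((lum * cs).mean())) * abs(
                    float((lum * cs).mean())
                ) ** weights[s]
            else:
                score *= np.sign(mcs) * abs(mcs) ** weights[s]
                ca, cb = _downsample2(ca), _downsample2(cb)
        vals.append(score)
    return float(np.mean(vals))


def compute_metrics(
    y: FundusImage | np.ndarray,
    y_hat: FundusImage | np.ndarray,
    mask: np.ndarray | None = None,
) -> MetricReport:
    """Compare a generated image against its target.

    MSE and PSNR are restricted to ``mask`` when given (SSIM statistics are
    windowed, so masking applies to the averaging of the per-pixel SSIM
    map). Identical images report MSE 0 and an infinite-PSNR sentinel.
    """
    a = _as255(y)
    b = _as255(y_hat)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")

    if mask is not None:
        m = np.asarray(mask, bool)
        sq = (a - b) ** 2
        mse = float(sq[m].mean()) if a.ndim == 2 else float(sq[m, :].mean())
    else:
        mse = float(((a - b) ** 2).mean())
    psnr = PSNR_INF if mse == 0 else 10.0 * float(np.log10(255.0**2 / mse))

    ssim_vals = []
    for c in range(a.shape[2] if a.ndim == 3 else 1):
        ca = a[..., c] if a.ndim == 3 else a
        cb = b[..., c] if b.ndim == 3 else b
        _, smap = structural_similarity(
            ca,
            cb,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=255.0,
            full=True,
        )
        if mask is not None:
            ssim_vals.append(float(smap[np.asarray(mask, bool)].mean()))
        else:
            ssim_vals.append(float(smap.mean()))
    ssim = float(np.mean(ssim_vals))
    ms = ms_ssim(a / 255.0, b / 255.0)
    return MetricReport(
        mse=mse, psnr=psnr, ssim=100.0 * ssim, ms_ssim=100.0 * ms, n_pairs=1
    )
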