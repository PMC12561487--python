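"""Percentage of correct keypoints (PCK) for registration accuracy.

PCK is the fraction of annotated source keypoints that, after mapping
through the estimated registration transform, land strictly within a
distance threshold tau of their annotated target partners. The threshold is
anatomy-relative: tau = theta * r, where r is the mean optic-disc radius of
the evaluation set (pixels) and theta an adjustable strictness coefficient
(typical values 0.05, 0.1, 0.15).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .odscale import ODInfo
from .registration import Homography

__all__ = [
    "PCKConfig",
    "transform_keypoints",
    "compute_tau",
    "compute_pck",
    "mean_od_radius",
]


@dataclass(frozen=True)
class PCKConfig:
    """theta: strictness coefficient (>0); r: mean OD radius in pixels (>0)."""

    theta: float
    r: float

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.r <= 0:
            raise ValueError("r must be > 0")


def mean_od_radius(boxes: Sequence[ODInfo], image_width: int) -> float:
    """Mean OD radius in pixels over an evaluation set: mean of (w * W) / 2.

    The "average OD radius in the dataset" admits several estimators; this
    package fixes it as the mean half-width of the OD boxes in pixels.
    """
    if not boxes:
        raise ValueError("need at least one OD box")
    return float(np.mean([b.w * image_width / 2.0 for b in boxes]))


def transform_keypoints(kp: np.ndarray, H: Homography | np.ndarray) -> np.ndarray:
    """Map (n, 2) keypoints through a homography (homogeneous, dehomogenized).

    Points whose homogeneous w collapses (|w| < 1e-12) come back non-finite;
    :func:`compute_pck` counts them as incorrect.
    """
    m = H.m if isinstance(H, Homography) else np.asarray(H, dtype=np.float64)
    kp = np.atleast_2d(np.asarray(kp, dtype=np.float64))
    P = np.hstack([kp, np.ones((len(kp), 1))]) @ m.T
    w = P[:, 2]
    out = np.full((len(kp), 2), np.nan)
    ok = np.abs(w) >= 1e-12
    out[ok] = P[ok, :2] / w[ok, None]
    return out


def compute_tau(cfg: PCKConfig) -> float:
    """tau = theta * r, in pixels."""
    return cfg.theta * cfg.r


def compute_pck(
    kp_src: np.ndarray,
    kp_tgt: np.ndarray,
    H: Homography | np.ndarray,
    cfg: PCKConfig,
) -> float:
    """PCK = (1/n) |{i : d(phi(kp_src_i), kp_tgt_i) < tau}|.

    ``kp_src`` and ``kp_tgt`` are index-matched (n, 2) arrays; the inequality
    is strict, so a keypoint displaced by exactly tau counts incorrect.
    Non-finite mapped points count incorrect.
    """
    kp_src = np.atleast_2d(np.asarray(kp_src, dtype=np.float64))
    kp_tgt = np.atleast_2d(np.asarray(kp_tgt, dtype=np.float64))
    if len(kp_src) != len(kp_tgt):
        raise ValueError("kp_src and kp_tgt must be index-matched")
    if len(kp_src) == 0:
        raise ValueError("PCK undefined for empty keypoint sets")
    tau = compute_tau(cfg)
    mapped = transform_keypoints(kp_src, H)
    d = np.sqrt(((mapped - kp_tgt) ** 2).sum(axis=1))
    correct = np.isfinite(d) & (d < tau)
    return float(correct.mean())
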