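"""Feature-based registration of the scale-adjusted UFI onto the CFI.

Step 2 of scaled feature registration: both images are converted to
grayscale, keypoints are detected and matched (ORB by default, SIFT
optional, plus a pluggable interface for learned matchers), a homography is
estimated by seeded RANSAC over normalized-DLT minimal solves with a final
least-squares refit on the inliers, and the source is warped into the target
frame with a validity mask marking the warped footprint.

The homography solver is written here rather than delegated so that its
numerics (Hartley normalization, reprojection threshold, refit) are explicit
and testable against independent references.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Protocol

import numpy as np
from skimage.feature import ORB, SIFT, match_descriptors
from skimage.transform import ProjectiveTransform, warp

from .errors import (
    DegenerateGeometryError,
    InsufficientMatchesError,
    RegistrationStageError,
)
from .image import FundusImage
from .odscale import ScaledUFI

__all__ = [
    "MatchSet",
    "Homography",
    "RegistrationResult",
    "MatcherBackend",
    "to_grayscale",
    "extract_and_match",
    "estimate_homography",
    "warp_and_mask",
    "register",
    "checkerboard_overlay",
]

logger = logging.getLogger(__name__)

# RANSAC configuration (the source method leaves these unspecified)
RANSAC_THRESHOLD_PX = 3.0
RANSAC_MAX_ITERS = 2000
RANSAC_CONFIDENCE = 0.995


@dataclass(frozen=True)
class MatchSet:
    """Index-matched keypoint correspondences with per-match confidence."""

    ps: np.ndarray  # (n, 2) source (scaled-UFI frame) x, y
    pt: np.ndarray  # (n, 2) target (CFI frame) x, y
    scores: np.ndarray  # (n,) descending

    def __post_init__(self) -> None:
        if not (len(self.ps) == len(self.pt) == len(self.scores)):
            raise ValueError("ps, pt and scores must have equal length")

    def __len__(self) -> int:
        return len(self.ps)


@dataclass(frozen=True)
class Homography:
    """3x3 projective transform normalized so m[2][2] == 1."""

    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if not np.all(np.isfinite(m)):
            raise ValueError("homography entries must be finite")
        if abs(m[2, 2]) < 1e-12:
            raise DegenerateGeometryError("homography cannot be normalized (m[2,2] ~ 0)")
        m = m / m[2, 2]
        if abs(np.linalg.det(m)) <= 1e-10:
            raise DegenerateGeometryError("homography is singular")
        object.__setattr__(self, "m", m)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """Map (n, 2) points through the homography (dehomogenized)."""
        pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
        P = np.hstack([pts, np.ones((len(pts), 1))]) @ self.m.T
        return P[:, :2] / P[:, 2:3]

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.m))


@dataclass(frozen=True)
class RegistrationResult:
    warped: FundusImage
    mask: np.ndarray  # (H, W) bool, warped-source footprint
    H: Homography
    matches: MatchSet
    inlier_flags: np.ndarray


class MatcherBackend(Protocol):
    """Contract for pluggable feature matchers.

    ``__call__(src_gray, tgt_gray)`` returns ``(ps, pt, scores)`` arrays.
    The package ships classical ORB and SIFT backends; a learned graph-based
    matcher can be plugged in through this interface without code changes.
    """

    def __call__(self, src_gray: np.ndarray, tgt_gray: np.ndarray):
        ...


def to_grayscale(image: FundusImage | np.ndarray) -> np.ndarray:
    """BT.601 luma: 0.299 R + 0.587 G + 0.114 B, values in [0, 1]."""
    px = image.pixels if isinstance(image, FundusImage) else np.asarray(image)
    return px[..., 0] * 0.299 + px[..., 1] * 0.587 + px[..., 2] * 0.114


def _orb_backend(src_gray: np.ndarray, tgt_gray: np.ndarray):
    """ORB keypoints + binary descriptors, Hamming cross-check matching."""
    det_s = ORB(n_keypoints=800, fast_threshold=0.02)
    det_t = ORB(n_keypoints=800, fast_threshold=0.02)
    try:
        det_s.detect_and_extract(src_gray)
        det_t.detect_and_extract(tgt_gray)
    except (RuntimeError, ValueError) as exc:
        raise InsufficientMatchesError(f"ORB found no usable keypoints: {exc}") from exc
    idx = match_descriptors(
        det_s.descriptors, det_t.descriptors, metric="hamming", cross_check=True
    )
    if len(idx) == 0:
        raise InsufficientMatchesError("no cross-checked ORB matches")
    d = np.array(
        [
            np.count_nonzero(det_s.descriptors[i] != det_t.descriptors[j])
            for i, j in idx
        ],
        dtype=float,
    )
    scores = 1.0 - d / det_s.descriptors.shape[1]
    ps = det_s.keypoints[idx[:, 0]][:, ::-1]  # row,col -> x,y
    pt = det_t.keypoints[idx[:, 1]][:, ::-1]
    return ps, pt, scores


def _sift_backend(src_gray: np.ndarray, tgt_gray: np.ndarray):
    """SIFT with Lowe ratio filtering (0.75) and cross-check."""
    det_s, det_t = SIFT(), SIFT()
    try:
        det_s.detect_and_extract(src_gray)
        det_t.detect_and_extract(tgt_gray)
    except (RuntimeError, ValueError) as exc:
        raise InsufficientMatchesError(f"SIFT found no usable keypoints: {exc}") from exc
    idx = match_descriptors(
        det_s.descriptors, det_t.descriptors, cross_check=True, max_ratio=0.75
    )
    if len(idx) == 0:
        raise InsufficientMatchesError("no SIFT matches survive the ratio test")
    a = det_s.descriptors[idx[:, 0]].astype(float)
    b = det_t.descriptors[idx[:, 1]].astype(float)
    dist = np.linalg.norm(a - b, axis=1)
    scores = 1.0 / (1.0 + dist)
    ps = det_s.keypoints[idx[:, 0]][:, ::-1]
    pt = det_t.keypoints[idx[:, 1]][:, ::-1]
    return ps, pt, scores


_BACKENDS: dict[str, Callable] = {"orb": _orb_backend, "sift": _sift_backend}


def extract_and_match(
    src_gray: np.ndarray, tgt_gray: np.ndarray, backend: str | MatcherBackend = "orb"
) -> MatchSet:
    """Detect keypoints in both rasters and return matches sorted by score.

    ``backend`` may be ``"orb"``, ``"sift"``, or any callable satisfying
    :class:`MatcherBackend` (e.g. a learned matcher adapter).
    """
    fn = _BACKENDS.get(backend) if isinstance(backend, str) else backend
    if fn is None:
        raise ValueError(f"unknown matcher backend {backend!r}")
    ps, pt, scores = fn(np.asarray(src_gray, float), np.asarray(tgt_gray, float))
    if len(ps) < 4:
        raise InsufficientMatchesError(
            f"only {len(ps)} matches; at least 4 are required for a homography"
        )
    order = np.argsort(-np.asarray(scores))
    return MatchSet(
        ps=np.asarray(ps, float)[order],
        pt=np.asarray(pt, float)[order],
        scores=np.asarray(scores, float)[order],
    )


# ----------------------------------------------------------------------------
# homography estimation: normalized DLT + RANSAC + least-squares refit


def _hartley_normalize(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Similarity transform taking pts to zero centroid, mean distance sqrt(2)."""
    c = pts.mean(axis=0)
    d = np.sqrt(((pts - c) ** 2).sum(axis=1)).mean()
    s = math.sqrt(2.0) / max(d, 1e-12)
    T = np.array([[s, 0.0, -s * c[0]], [0.0, s, -s * c[1]], [0.0, 0.0, 1.0]])
    return (pts - c) * s, T


def _dlt(ps: np.ndarray, pt: np.ndarray) -> np.ndarray:
    """Direct linear transform on >= 4 correspondences (unnormalized input).

    Applies Hartley normalization internally; returns the 3x3 matrix with
    unit Frobenius scale (not yet normalized to m[2,2] = 1).
    """
    psn, Ts = _hartley_normalize(ps)
    ptn, Tt = _hartley_normalize(pt)
    n = len(ps)
    A = np.zeros((2 * n, 9))
    x, y = psn[:, 0], psn[:, 1]
    u, v = ptn[:, 0], ptn[:, 1]
    A[0::2, 0] = x
    A[0::2, 1] = y
    A[0::2, 2] = 1.0
    A[0::2, 6] = -u * x
    A[0::2, 7] = -u * y
    A[0::2, 8] = -u
    A[1::2, 3] = x
    A[1::2, 4] = y
    A[1::2, 5] = 1.0
    A[1::2, 6] = -v * x
    A[1::2, 7] = -v * y
    A[1::2, 8] = -v
    _, _, Vt = np.linalg.svd(A)
    Hn = Vt[-1].reshape(3, 3)
    return np.linalg.inv(Tt) @ Hn @ Ts


def _reprojection_errors(H: np.ndarray, ps: np.ndarray, pt: np.ndarray) -> np.ndarray:
    P = np.hstack([ps, np.ones((len(ps), 1))]) @ H.T
    w = P[:, 2]
    bad = np.abs(w) < 1e-12
    w = np.where(bad, 1.0, w)
    proj = P[:, :2] / w[:, None]
    err = np.sqrt(((proj - pt) ** 2).sum(axis=1))
    err[bad] = np.inf
    return err


def estimate_homography(
    matches: MatchSet,
    threshold: float = RANSAC_THRESHOLD_PX,
    max_iters: int = RANSAC_MAX_ITERS,
    confidence: float = RANSAC_CONFIDENCE,
    seed: int = 0,
) -> tuple[Homography, np.ndarray]:
    """RANSAC homography from matched keypoints.

    Minimal 4-point samples are solved with the normalized DLT; the model
    with the most inliers (reprojection error below ``threshold`` pixels)
    wins and is refit by least squares on its inlier set. Four exact
    correspondences are mathematically sufficient; more high-quality matches
    improve robustness, which is what the RANSAC loop exploits.

    Returns ``(H, inlier_flags)``.
    """
    ps, pt = matches.ps, matches.pt
    n = len(ps)
    if n < 4:
        raise InsufficientMatchesError(f"need >= 4 matches, got {n}")

    rng = np.random.default_rng(seed)
    best_inliers: np.ndarray | None = None
    best_count = 0
    iters = max_iters
    i = 0
    while i < iters:
        i += 1
        idx = rng.choice(n, size=4, replace=False)
        sample_s, sample_t = ps[idx], pt[idx]
        # reject near-collinear minimal samples
        if _min_triangle_area(sample_s) < 1e-6 or _min_triangle_area(sample_t) < 1e-6:
            continue
        try:
            Hc = _dlt(sample_s, sample_t)
        except np.linalg.LinAlgError:
            continue
        if abs(Hc[2, 2]) < 1e-12:
            continue
        err = _reprojection_errors(Hc / Hc[2, 2], ps, pt)
        inl = err < threshold
        count = int(inl.sum())
        if count > best_count:
            best_count = count
            best_inliers = inl
            # adaptive iteration bound
            ratio = count / n
            if ratio > 0:
                denom = math.log(max(1.0 - ratio**4, 1e-12))
                if denom < 0:
                    iters = min(
                        max_iters, int(math.ceil(math.log(1 - confidence) / denom))
                    )

    if best_inliers is None or best_count < 4:
        raise DegenerateGeometryError(
            f"RANSAC found only {best_count} inliers (need >= 4)"
        )

    H = _dlt(ps[best_inliers], pt[best_inliers])
    H /= H[2, 2]
    # final inlier set under the refit model
    err = _reprojection_errors(H, ps, pt)
    inlier_flags = err < threshold
    logger.debug(
        "homography: %d/%d inliers, inlier RMS %.3f px",
        inlier_flags.sum(),
        n,
        float(np.sqrt((err[inlier_flags] ** 2).mean())) if inlier_flags.any() else -1,
    )
    return Homography(H), inlier_flags


def _min_triangle_area(pts4: np.ndarray) -> float:
    """Smallest triangle area among the 4 triples of a minimal sample."""
    areas = []
    for k in range(4):
        tri = np.delete(pts4, k, axis=0)
        a = abs(
            (tri[1, 0] - tri[0, 0]) * (tri[2, 1] - tri[0, 1])
            - (tri[2, 0] - tri[0, 0]) * (tri[1, 1] - tri[0, 1])
        )
        areas.append(a / 2.0)
    return min(areas)


# ----------------------------------------------------------------------------
# intensity-based sub-pixel refinement


def _refine_stage(
    H: Homography,
    src_gray: np.ndarray,
    tgt_gray: np.ndarray,
    half: int,
    step: int,
    cap: float,
    iterations: int,
    tol: float,
) -> Homography:
    """One coarse-or-fine refinement pass (see :func:`refine_homography`)."""
    from skimage.registration import phase_cross_correlation

    h, w = tgt_gray.shape
    win = np.outer(np.hanning(2 * half), np.hanning(2 * half))
    for _ in range(iterations):
        Hinv = np.linalg.inv(H.m)
        tform = ProjectiveTransform(matrix=Hinv)
        warped = warp(src_gray, tform, output_shape=(h, w), order=1)
        valid = warp(np.ones_like(src_gray), tform, output_shape=(h, w), order=1) > 0.99
        src_pts, tgt_pts, mags = [], [], []
        for cy in range(half + 2, h - half - 2, step):
            for cx in range(half + 2, w - half - 2, step):
                if not valid[cy - half : cy + half, cx - half : cx + half].all():
                    continue
                wp = warped[cy - half : cy + half, cx - half : cx + half]
                tp = tgt_gray[cy - half : cy + half, cx - half : cx + half]
                if tp.std() < 0.01:  # untextured patch: no signal
                    continue
                (dy, dx), _, _ = phase_cross_correlation(
                    (tp - tp.mean()) * win,
                    (wp - wp.mean()) * win,
                    upsample_factor=20,
                    normalization=None,
                )
                if abs(dx) > cap or abs(dy) > cap:
                    continue
                # warped(x - d) aligns with target(x): the source point seen
                # at (cx - dx, cy - dy) corresponds to target (cx, cy)
                p = Hinv @ np.array([cx - dx, cy - dy, 1.0])
                src_pts.append((p[0] / p[2], p[1] / p[2]))
                tgt_pts.append((float(cx), float(cy)))
                mags.append(math.hypot(dx, dy))
        if len(src_pts) < 8:
            return H
        sp, tp_ = np.array(src_pts), np.array(tgt_pts)
        Hm = _dlt(sp, tp_)
        if abs(Hm[2, 2]) < 1e-12:
            return H
        cand = Homography(Hm / Hm[2, 2])
        # trim control points that disagree with the consensus fit
        err = _reprojection_errors(cand.m, sp, tp_)
        keep = err <= max(2.0 * float(np.median(err)), 0.3)
        if keep.sum() >= 8:
            Hm = _dlt(sp[keep], tp_[keep])
            if abs(Hm[2, 2]) > 1e-12:
                cand = Homography(Hm / Hm[2, 2])
        H = cand
        if float(np.mean(mags)) < tol:
            break
    return H


def refine_homography(
    src_gray: np.ndarray, tgt_gray: np.ndarray, H0: Homography
) -> Homography:
    """Refine a homography by local phase correlation on a control-point grid.

    Feature detectors localize keypoints to roughly a pixel, which bounds the
    accuracy of a purely point-based estimate. This routine warps the source
    under the current estimate, measures the residual sub-pixel shift between
    Hann-windowed warped-source and target patches at textured control
    points, converts each shift into a correspondence, and refits the
    homography by trimmed least squares. A coarse pass (32 px patches, wide
    search) absorbs initializations several pixels off; a fine pass (16 px
    patches) then converges to well below half a pixel when the projective
    model holds.
    """
    H = _refine_stage(H0, src_gray, tgt_gray, half=16, step=10, cap=8.0,
                      iterations=3, tol=0.05)
    return _refine_stage(H, src_gray, tgt_gray, half=8, step=5, cap=3.0,
                         iterations=8, tol=0.03)


# ----------------------------------------------------------------------------
# warping


def warp_and_mask(
    src: FundusImage, H: Homography, target_shape: tuple[int, int]
) -> tuple[FundusImage, np.ndarray]:
    """Warp ``src`` into the target frame under ``H`` (source -> target).

    Inverse-map bilinear warp; the validity mask is the warp of an all-ones
    raster thresholded at 0.5, and warped pixels outside the mask are zeroed.
    """
    try:
        Hinv = np.linalg.inv(H.m)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by type
        raise DegenerateGeometryError("homography is not invertible") from exc
    tform = ProjectiveTransform(matrix=Hinv)
    warped = warp(
        src.pixels, tform, output_shape=target_shape, order=1, mode="constant", cval=0.0
    )
    ones = np.ones(src.shape)
    m = warp(ones, tform, output_shape=target_shape, order=1, mode="constant", cval=0.0)
    mask = m > 0.5
    warped = np.clip(warped, 0.0, 1.0) * mask[..., None]
    return FundusImage(warped), mask


def register(
    scaled_ufi: ScaledUFI | FundusImage,
    cfi: FundusImage,
    backend: str | MatcherBackend = "orb",
    seed: int = 0,
    refine: bool = True,
) -> RegistrationResult:
    """Full step-2 registration: gray -> match -> homography -> warp+mask.

    With ``refine`` (default) the RANSAC estimate is polished by intensity-
    based sub-pixel refinement (:func:`refine_homography`).

    Errors from each stage are re-raised as :class:`RegistrationStageError`
    annotated with the failing stage name (``matching``, ``estimation``,
    ``warping``).
    """
    src_img = scaled_ufi.image if isinstance(scaled_ufi, ScaledUFI) else scaled_ufi
    src_gray = to_grayscale(src_img)
    tgt_gray = to_grayscale(cfi)
    try:
        matches = extract_and_match(src_gray, tgt_gray, backend=backend)
    except (InsufficientMatchesError, ValueError) as exc:
        raise RegistrationStageError("matching", exc) from exc
    try:
        H, inliers = estimate_homography(matches, seed=seed)
        if refine:
            H = refine_homography(src_gray, tgt_gray, H)
    except (InsufficientMatchesError, DegenerateGeometryError) as exc:
        raise RegistrationStageError("estimation", exc) from exc
    try:
        warped, mask = warp_and_mask(src_img, H, cfi.shape)
    except DegenerateGeometryError as exc:
        raise RegistrationStageError("warping", exc) from exc
    err = _reprojection_errors(H.m, matches.ps, matches.pt)
    logger.info(
        "register: %d matches, %.0f%% inliers, inlier reprojection RMS %.3f px",
        len(matches),
        100.0 * inliers.mean(),
        float(np.sqrt((err[inliers] ** 2).mean())) if inliers.any() else float("nan"),
    )
    return RegistrationResult(
        warped=warped, mask=mask, H=H, matches=matches, inlier_flags=inliers
    )


def checkerboard_overlay(a: FundusImage, b: FundusImage, cells: int = 8) -> FundusImage:
    """Interleave two registered images in alternating grid cells.

    The standard qualitative check: anatomy continuous across cell borders
    means good alignment.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if cells < 2:
        raise ValueError("cells must be >= 2")
    h, w = a.shape
    ch, cw = h // cells, w // cells
    yy, xx = np.mgrid[0:h, 0:w]
    parity = ((yy // max(ch, 1)) + (xx // max(cw, 1))) % 2
    out = np.where(parity[..., None] == 0, a.pixels, b.pixels)
    return FundusImage(out)
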