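"""Synthetic paired UFI/CFI fundus phantoms with known geometry.

Paired ultrawidefield (UFI) / conventional (CFI) fundus datasets are clinical
and private, so every geometric claim in this package is exercised on
phantoms: a conventional-fundus-like scene (bright optic disc, darker macula,
branching vessel tree, low-frequency choroidal mottling) rendered once in the
CFI coordinate frame, plus an ultrawidefield view of the same scene produced
by embedding that frame into a wider field through a sampled projective
transform and applying UFI-specific degradations (green-shifted pseudo-color,
macular blur, additive noise, dark peripheral arc artifacts, field-of-view
vignetting).

Because the scene is rendered analytically in one frame and resampled into
the other, the generator knows the exact homography relating the two views
and the exact coordinates of every vessel bifurcation in both frames - the
ground truth that real studies obtain by manual annotation.

The ground-truth homography ``H_true`` maps *scale-adjusted* UFI coordinates
(the 6x-optic-disc crop resized to the CFI side, as produced by
:mod:`fundus2cfi.odscale` from the ground-truth OD box) to CFI coordinates.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import ProjectiveTransform, warp

from .image import FundusImage, save_image, load_image
from .odscale import ODInfo, extract_crop_box

__all__ = [
    "TransformParams",
    "PhantomSpec",
    "PhantomPair",
    "generate_phantom_pair",
    "export_fixture",
    "load_fixture",
]

# UFI pseudo-color channel gains (Optos-style green/red laser rendering).
# Internal constants, not claims about any real device.
_UFI_GAINS = (0.9, 1.1, 0.5)

_MIN_KEYPOINTS = 8
_MAX_KEYPOINTS = 24


@dataclass(frozen=True)
class TransformParams:
    """Projective embedding of the CFI frame into the UFI frame.

    ``scale`` is the magnification from UFI pixels to CFI pixels (a scene
    feature spanning ``d`` CFI pixels spans ``d / scale`` UFI pixels); a
    scalar fixes it, a ``(lo, hi)`` tuple samples uniformly. Valid range
    [1.5, 4]. ``rotation_deg`` likewise (valid [-15, 15]).
    ``perspective_jitter`` (>= 0) scales the random projective (third-row)
    terms; 0 yields an exact similarity/affinity.
    """

    scale: float | tuple[float, float] = (1.6, 2.2)
    rotation_deg: float | tuple[float, float] = (-15.0, 15.0)
    perspective_jitter: float = 0.15

    def __post_init__(self) -> None:
        lo, hi = self._range(self.scale)
        if not (1.5 <= lo <= hi <= 4.0):
            raise ValueError("scale must lie within [1.5, 4]")
        lo, hi = self._range(self.rotation_deg)
        if not (-15.0 <= lo <= hi <= 15.0):
            raise ValueError("rotation_deg must lie within [-15, 15]")
        if self.perspective_jitter < 0:
            raise ValueError("perspective_jitter must be >= 0")

    @staticmethod
    def _range(v) -> tuple[float, float]:
        if isinstance(v, (tuple, list)):
            return float(v[0]), float(v[1])
        return float(v), float(v)

    def sample(self, rng: np.random.Generator) -> tuple[float, float]:
        slo, shi = self._range(self.scale)
        rlo, rhi = self._range(self.rotation_deg)
        s = slo if slo == shi else float(rng.uniform(slo, shi))
        r = rlo if rlo == rhi else float(rng.uniform(rlo, rhi))
        return s, r


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic pair. Identical specs give identical pairs."""

    seed: int
    size: int = 128
    n_vessels: int = 6
    branch_prob: float = 0.12
    noise_sigma: float = 0.01
    od_radius_frac: float = 0.06
    transform_params: TransformParams = field(default_factory=TransformParams)
    artifact_level: float = 0.3

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("size must be >= 32")
        if self.n_vessels < 1:
            raise ValueError("n_vessels must be >= 1")
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0.0 < self.od_radius_frac < 0.25):
            raise ValueError("od_radius_frac must lie in (0, 0.25)")
        if not (0.0 <= self.artifact_level <= 1.0):
            raise ValueError("artifact_level must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomPair:
    """A synthetic UFI/CFI pair with full geometric ground truth."""

    ufi: FundusImage
    cfi: FundusImage
    H_true: np.ndarray  # scale-adjusted-UFI coords -> CFI coords, [2,2] == 1
    kp_ufi: np.ndarray  # (n, 2) x,y in UFI pixels
    kp_cfi: np.ndarray  # (n, 2) x,y in CFI pixels, index-matched
    od_box_ufi: ODInfo
    od_box_cfi: ODInfo
    vessel_mask_cfi: np.ndarray  # (l, l) bool

    def __post_init__(self) -> None:
        if len(self.kp_ufi) != len(self.kp_cfi):
            raise ValueError("kp_ufi and kp_cfi must be index-matched")
        if not (_MIN_KEYPOINTS <= len(self.kp_cfi) <= _MAX_KEYPOINTS):
            raise ValueError("keypoint count must lie in [8, 24]")
        if abs(self.H_true[2, 2] - 1.0) > 1e-12:
            raise ValueError("H_true must be normalized with H[2,2] == 1")


# ----------------------------------------------------------------------------
# scene rendering (CFI frame, extended canvas)


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean unit-ish-amplitude low-frequency field (choroidal mottling)."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma)
    amp = np.abs(sm).max()
    return sm / amp if amp > 0 else sm


def _grow_vessel_tree(
    rng: np.random.Generator,
    l: int,
    od_center: np.ndarray,
    od_radius: float,
    n_vessels: int,
    branch_prob: float,
) -> tuple[list[tuple[np.ndarray, np.ndarray, float]], list[np.ndarray]]:
    """Recursive branching random walk from the optic-disc rim.

    Returns drawn segments ``(p0, p1, width)`` in CFI coordinates and the
    recorded bifurcation points. Vessel widths taper with depth; bifurcation
    = point where a child branch is spawned.
    """
    segments: list[tuple[np.ndarray, np.ndarray, float]] = []
    bifurcations: list[np.ndarray] = []
    scale = l / 128.0
    step = 2.0 * scale
    max_extent = 1.35 * l  # stay on the extended canvas
    budget = [int(550 * scale)]  # global step budget keeps coverage in range

    # seed directions spread around the disc rim
    base_angles = rng.uniform(0, 2 * math.pi) + np.linspace(
        0, 2 * math.pi, n_vessels, endpoint=False
    )

    def walk(pos: np.ndarray, ang: float, width: float, depth: int, steps: int) -> None:
        since_branch = 0
        for _ in range(steps):
            if budget[0] <= 0:
                return
            budget[0] -= 1
            since_branch += 1
            ang += rng.normal(0.0, 0.12)
            new = pos + step * np.array([math.cos(ang), math.sin(ang)])
            if np.hypot(*(new - l / 2.0)) > max_extent or width < 0.45 * scale:
                return
            segments.append((pos.copy(), new.copy(), width))
            pos = new
            width *= 0.995
            # bifurcate more often near the disc, where real arcades divide
            near = np.hypot(*(pos - od_center)) < 0.33 * l
            p_branch = branch_prob * (3.0 if near else 0.5)
            if depth < 3 and since_branch >= 3 and rng.random() < p_branch:
                since_branch = 0
                bifurcations.append(pos.copy())
                split = rng.uniform(0.35, 0.7) * rng.choice([-1.0, 1.0])
                walk(pos.copy(), ang + split, width * 0.78, depth + 1, int(steps * 0.6))
                ang -= 0.35 * split

    for a in base_angles:
        start = od_center + od_radius * np.array([math.cos(a), math.sin(a)])
        walk(start, float(a), 2.2 * scale, 0, int(55 * scale))
    return segments, bifurcations


def _stamp_segments(alpha: np.ndarray, segments, offset: float) -> None:
    """Rasterize soft-edged vessel segments into an alpha map (in place)."""
    h, w = alpha.shape
    for p0, p1, width in segments:
        n = max(int(np.hypot(*(p1 - p0)) * 2), 1)
        rad = width / 2.0 + 0.8
        ir = int(math.ceil(rad))
        for t in np.linspace(0.0, 1.0, n + 1):
            c = p0 + t * (p1 - p0) + offset
            cx, cy = c
            x0, x1 = int(cx) - ir, int(cx) + ir + 1
            y0, y1 = int(cy) - ir, int(cy) + ir + 1
            if x1 <= 0 or y1 <= 0 or x0 >= w or y0 >= h:
                continue
            x0c, y0c = max(x0, 0), max(y0, 0)
            x1c, y1c = min(x1, w), min(y1, h)
            yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
            d = np.hypot(xx - cx, yy - cy)
            a = np.clip(width / 2.0 + 0.5 - d, 0.0, 1.0)
            np.maximum(alpha[y0c:y1c, x0c:x1c], a, out=alpha[y0c:y1c, x0c:x1c])


def _render_scene(spec: PhantomSpec, rng: np.random.Generator):
    """Render the extended master canvas in CFI coordinates.

    The canvas spans CFI coordinates [-l, 2l) at CFI resolution so that the
    ultrawidefield view (which sees beyond the CFI frame) can be resampled
    from it. Returns the canvas, vessel alpha map, OD geometry, macula
    center, and bifurcation list.
    """
    l = spec.size
    big = 3 * l
    off = float(l)  # canvas index = CFI coordinate + l

    yy, xx = np.mgrid[0:big, 0:big]
    cx_cfi = xx - off
    cy_cfi = yy - off

    # fundus background: orange-red base, gentle radial falloff, mottling
    rad = np.hypot(cx_cfi - l / 2.0, cy_cfi - l / 2.0) / l
    base = np.empty((big, big, 3))
    mott = _smooth_noise(rng, (big, big), 4.0 * l / 128.0)
    mott2 = _smooth_noise(rng, (big, big), 1.5 * l / 128.0)
    tex = 0.10 * mott + 0.035 * mott2
    base[..., 0] = 0.78 - 0.10 * rad + tex
    base[..., 1] = 0.38 - 0.08 * rad + 0.8 * tex
    base[..., 2] = 0.16 - 0.05 * rad + 0.4 * tex

    # scattered punctate features (drusen-like bright spots and pigment
    # clumps): small high-contrast blobs that give feature detectors
    # well-localized anchors across the field, as real fundi do
    n_spots = 70
    spot_xy = rng.uniform(-0.35 * l, 1.35 * l, size=(n_spots, 2)) + off
    spot_r = rng.uniform(2.5, 5.0, n_spots) * (l / 128.0)
    spot_amp = rng.uniform(0.12, 0.25, n_spots) * rng.choice([-1.0, 1.0], n_spots)
    spot_field = np.zeros((big, big))
    for (sx, sy), sr, sa in zip(spot_xy, spot_r, spot_amp):
        ir = int(3 * sr) + 1
        x0s, x1s = int(sx) - ir, int(sx) + ir + 1
        y0s, y1s = int(sy) - ir, int(sy) + ir + 1
        if x1s <= 0 or y1s <= 0 or x0s >= big or y0s >= big:
            continue
        x0c, y0c = max(x0s, 0), max(y0s, 0)
        x1c, y1c = min(x1s, big), min(y1s, big)
        ys2, xs2 = np.mgrid[y0c:y1c, x0c:x1c]
        g = np.exp(-0.5 * (np.hypot(xs2 - sx, ys2 - sy) / sr) ** 2)
        spot_field[y0c:y1c, x0c:x1c] += sa * g
    base[..., 0] += spot_field
    base[..., 1] += 0.9 * spot_field
    base[..., 2] += 0.35 * np.clip(spot_field, 0, None)  # bright spots yellowish

    # optic disc: bright ellipse, slightly nasal of center
    od_center = np.array(
        [
            l * (0.62 + rng.uniform(-0.04, 0.04)),
            l * (0.50 + rng.uniform(-0.05, 0.05)),
        ]
    )
    od_radius = spec.od_radius_frac * l
    d_od = np.hypot(cx_cfi - od_center[0], cy_cfi - od_center[1])
    w_od = np.clip((od_radius - d_od) / 1.5 + 0.5, 0.0, 1.0)
    od_color = np.array([0.97, 0.88, 0.55])
    base = base * (1 - w_od[..., None]) + od_color * w_od[..., None]
    # pale cup inside the disc
    d_cup = np.hypot(cx_cfi - od_center[0], cy_cfi - od_center[1])
    w_cup = np.clip((0.45 * od_radius - d_cup) / 1.0 + 0.5, 0.0, 1.0) * 0.5
    base = base * (1 - w_cup[..., None]) + np.array([1.0, 0.97, 0.80]) * w_cup[..., None]

    # macula: darker blob temporal of center
    mac_center = np.array(
        [
            l * (0.32 + rng.uniform(-0.03, 0.03)),
            l * (0.52 + rng.uniform(-0.04, 0.04)),
        ]
    )
    d_mac = np.hypot(cx_cfi - mac_center[0], cy_cfi - mac_center[1])
    w_mac = np.exp(-0.5 * (d_mac / (0.11 * l)) ** 2)
    base *= 1.0 - 0.35 * w_mac[..., None]

    segments, bifurcations = _grow_vessel_tree(
        rng, l, od_center, od_radius, spec.n_vessels, spec.branch_prob
    )
    alpha = np.zeros((big, big))
    _stamp_segments(alpha, segments, off)
    vessel_color = np.array([0.42, 0.11, 0.09])
    a = (0.85 * alpha)[..., None]
    base = base * (1 - a) + vessel_color * a

    base = ndimage.gaussian_filter(base, (0.6, 0.6, 0.0))
    base = np.clip(base, 0.0, 1.0)
    return base, alpha, od_center, od_radius, mac_center, bifurcations


# ----------------------------------------------------------------------------
# projective embedding and UFI degradation


def _sample_embedding(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Sample M: UFI pixel coords -> CFI coords (normalized, M[2,2] = 1)."""
    l = spec.size
    for _ in range(20):
        s, rot = spec.transform_params.sample(rng)
        th = math.radians(rot)
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        # CFI frame center lands near the UFI center with a small offset
        u_center = np.array([l / 2.0, l / 2.0]) + rng.uniform(-0.05 * l, 0.05 * l, 2)
        c_center = np.array([l / 2.0, l / 2.0])
        # affine CFI -> UFI: u = u_center + (1/s) R (c - c_center); invert
        A = np.eye(3)
        A[:2, :2] = R.T * s
        A[:2, 2] = c_center - s * (R.T @ u_center)
        M = A.copy()
        j = spec.transform_params.perspective_jitter
        if j > 0:
            M[2, :2] = rng.uniform(-1.0, 1.0, 2) * j / (2.0 * l)
        M /= M[2, 2]
        if abs(np.linalg.det(M[:2, :2])) >= 1e-6:
            return M
    raise RuntimeError("could not sample a non-degenerate embedding")  # pragma: no cover


def _apply_h(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    P = np.hstack([pts, np.ones((len(pts), 1))]) @ H.T
    return P[:, :2] / P[:, 2:3]


def _render_ufi(
    spec: PhantomSpec,
    rng: np.random.Generator,
    canvas: np.ndarray,
    M: np.ndarray,
    mac_center_cfi: np.ndarray,
) -> np.ndarray:
    """Resample the scene into the UFI frame and apply UFI degradations."""
    l = spec.size
    # UFI px -> canvas px: add the canvas offset after mapping to CFI coords
    off = np.array([[1.0, 0.0, l], [0.0, 1.0, l], [0.0, 0.0, 1.0]])
    tform = ProjectiveTransform(matrix=off @ M)
    ufi = warp(canvas, tform, output_shape=(l, l), order=1, mode="edge")

    yy, xx = np.mgrid[0:l, 0:l]
    r = np.hypot(xx - l / 2.0, yy - l / 2.0)

    # macular blur: UFIs lose effective resolution at the macula
    Minv = np.linalg.inv(M)
    mac_u = _apply_h(Minv, mac_center_cfi[None, :])[0]
    s_eff = math.sqrt(abs(np.linalg.det(M[:2, :2])))
    mac_r = 0.20 * l / s_eff
    blur = ndimage.gaussian_filter(ufi, (1.3, 1.3, 0.0))
    w_mac = np.exp(-0.5 * (np.hypot(xx - mac_u[0], yy - mac_u[1]) / mac_r) ** 2)
    ufi = ufi * (1 - w_mac[..., None]) + blur * w_mac[..., None]

    # pseudo-color gains
    ufi = ufi * np.array(_UFI_GAINS)

    # dark peripheral arc artifacts (eyelash / lid shadows)
    if spec.artifact_level > 0:
        ang = np.arctan2(yy - l / 2.0, xx - l / 2.0)
        arc = np.zeros((l, l))
        for _ in range(rng.integers(2, 5)):
            a0 = rng.uniform(-math.pi, math.pi)
            width = rng.uniform(0.3, 0.9)
            da = np.abs(np.angle(np.exp(1j * (ang - a0))))
            band = (da < width) & (r > 0.36 * l) & (r < 0.48 * l)
            arc = np.maximum(arc, band.astype(float))
        arc = ndimage.gaussian_filter(arc, 1.5)
        ufi *= 1.0 - (0.5 * spec.artifact_level * arc)[..., None]

    # field-of-view vignette and surround
    fov = np.clip((0.48 * l - r) / 2.0 + 0.5, 0.0, 1.0)
    ufi = ufi * fov[..., None] + 0.02 * (1 - fov[..., None])

    if spec.noise_sigma > 0:
        ufi = ufi + rng.normal(0.0, spec.noise_sigma, ufi.shape)
    return np.clip(ufi, 0.0, 1.0)


# ----------------------------------------------------------------------------
# pair assembly


def generate_phantom_pair(spec: PhantomSpec) -> PhantomPair:
    """Generate one synthetic UFI/CFI pair with ground-truth geometry.

    The CFI is a crop of the analytically rendered scene; the UFI is the same
    scene resampled through a sampled projective embedding plus UFI-specific
    degradations. If vessel growth yields fewer than 8 usable bifurcations
    the tree is regrown (up to 10 attempts) with fresh randomness from the
    same seeded stream, so equal specs still give identical output.
    """
    rng = np.random.default_rng(spec.seed)
    l = spec.size
    for attempt in range(10):
        canvas, alpha, od_center, od_radius, mac_center, bifs = _render_scene(spec, rng)
        M = _sample_embedding(spec, rng)
        Minv = np.linalg.inv(M)  # CFI coords -> UFI px

        cfi_px = canvas[l : 2 * l, l : 2 * l]
        vessel_mask = alpha[l : 2 * l, l : 2 * l] > 0.35
        ufi_px = _render_ufi(spec, rng, canvas, M, mac_center)

        # optic-disc boxes in both frames (normalized)
        od_box_cfi = ODInfo(
            cx=od_center[0] / l,
            cy=od_center[1] / l,
            w=2 * od_radius / l,
            h=2 * od_radius / l,
        )
        rim = od_center + od_radius * np.array(
            [[1, 0], [-1, 0], [0, 1], [0, -1], [0.707, 0.707], [-0.707, -0.707]]
        )
        rim_u = _apply_h(Minv, rim)
        od_u = _apply_h(Minv, od_center[None, :])[0]
        w_u = 2 * np.abs(rim_u[:, 0] - od_u[0]).max()
        h_u = 2 * np.abs(rim_u[:, 1] - od_u[1]).max()
        od_box_ufi = ODInfo(
            cx=float(np.clip(od_u[0] / l, 0, 1)),
            cy=float(np.clip(od_u[1] / l, 0, 1)),
            w=float(np.clip(w_u / l, 1e-3, 1)),
            h=float(np.clip(h_u / l, 1e-3, 1)),
        )

        # ground-truth homography: scaled-UFI frame -> CFI frame
        x0, y0, cw, ch = extract_crop_box(od_box_ufi, l, l)
        A = np.array(
            [[cw / l, 0.0, x0], [0.0, ch / l, y0], [0.0, 0.0, 1.0]]
        )  # scaled px -> UFI px
        H_true = M @ A
        H_true /= H_true[2, 2]

        # keep bifurcations visible in CFI, in the UFI field of view, and
        # inside the 6x-OD crop window
        keep_c, keep_u = [], []
        for b in bifs:
            if not (2.0 <= b[0] <= l - 3.0 and 2.0 <= b[1] <= l - 3.0):
                continue
            u = _apply_h(Minv, b[None, :])[0]
            if np.hypot(u[0] - l / 2.0, u[1] - l / 2.0) > 0.45 * l:
                continue
            if not (x0 + 2 <= u[0] < x0 + cw - 2 and y0 + 2 <= u[1] < y0 + ch - 2):
                continue
            keep_c.append(b)
            keep_u.append(u)

        if len(keep_c) < _MIN_KEYPOINTS:
            continue
        kp_cfi = np.array(keep_c)
        kp_ufi = np.array(keep_u)
        if len(kp_cfi) > _MAX_KEYPOINTS:
            idx = np.sort(
                rng.choice(len(kp_cfi), size=_MAX_KEYPOINTS, replace=False)
            )
            kp_cfi = kp_cfi[idx]
            kp_ufi = kp_ufi[idx]

        return PhantomPair(
            ufi=FundusImage(ufi_px),
            cfi=FundusImage(cfi_px),
            H_true=H_true,
            kp_ufi=kp_ufi,
            kp_cfi=kp_cfi,
            od_box_ufi=od_box_ufi,
            od_box_cfi=od_box_cfi,
            vessel_mask_cfi=vessel_mask,
        )
    raise RuntimeError(
        f"vessel growth yielded < {_MIN_KEYPOINTS} usable bifurcations after 10 attempts"
    )


# ----------------------------------------------------------------------------
# fixture I/O


def export_fixture(pair: PhantomPair, dir_path: str | Path) -> dict:
    """Write a pair to disk (5 files) and return a manifest with checksums.

    Files: ``ufi.png``, ``cfi.png``, ``keypoints.json``, ``h_true.json``,
    ``od_boxes.json``.
    """
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    save_image(pair.ufi, d / "ufi.png")
    save_image(pair.cfi, d / "cfi.png")
    with open(d / "keypoints.json", "w") as fh:
        json.dump(
            {"kp_ufi": pair.kp_ufi.tolist(), "kp_cfi": pair.kp_cfi.tolist()}, fh
        )
    with open(d / "h_true.json", "w") as fh:
        json.dump({"h": pair.H_true.tolist()}, fh)
    with open(d / "od_boxes.json", "w") as fh:
        json.dump(
            {"ufi": pair.od_box_ufi.to_dict(), "cfi": pair.od_box_cfi.to_dict()}, fh
        )
    manifest = {"dir": str(d), "files": {}}
    for name in ("ufi.png", "cfi.png", "keypoints.json", "h_true.json", "od_boxes.json"):
        path = d / name
        if not path.exists():  # pragma: no cover - defensive
            raise OSError(f"fixture file missing after write: {path}")
        manifest["files"][name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return manifest


def load_fixture(dir_path: str | Path) -> dict:
    """Reload an exported fixture; inverse of :func:`export_fixture`."""
    d = Path(dir_path)
    with open(d / "keypoints.json") as fh:
        kps = json.load(fh)
    with open(d / "h_true.json") as fh:
        h = np.array(json.load(fh)["h"])
    with open(d / "od_boxes.json") as fh:
        boxes = json.load(fh)
    return {
        "ufi": load_image(d / "ufi.png"),
        "cfi": load_image(d / "cfi.png"),
        "kp_ufi": np.array(kps["kp_ufi"]),
        "kp_cfi": np.array(kps["kp_cfi"]),
        "H_true": h,
        "od_box_ufi": ODInfo.from_dict(boxes["ufi"]),
        "od_box_cfi": ODInfo.from_dict(boxes["cfi"]),
    }
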