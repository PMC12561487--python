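"""End-to-end orchestration of the two-phase workflow.

Training phase: for every (UFI, CFI) pair, OD scale adjustment brings the
UFI to CFI scale, feature registration aligns it onto the CFI, and the
translation model is trained on the registered pairs (with the footprint
mask applied to the L1 term so zero-filled exteriors do not dominate).
Pairs that fail registration are reported, never silently dropped.

Testing phase: only UFIs are read - OD scale adjustment, then the trained
correction branch and generator synthesize the CFI. No target CFI is
touched at test time.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ODDetectionError, RegistrationStageError
from .image import load_image, save_image
from .odscale import (
    BrightBlobDetector,
    ODInfo,
    localize_od,
    map_point_to_scaled,
    od_scale_adjust,
)
from .pck import PCKConfig, compute_pck, mean_od_radius
from .registration import register
from .training import LossWeights, TrainConfig, train
from .translator import (
    ModelConfig,
    TranslationModel,
    correction_forward,
    generator_forward,
)

__all__ = ["PipelineConfig", "run_train_phase", "run_test_phase", "load_pair_dirs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration shared by both phases."""

    phase: str  # "train" | "test"
    data_dir: str
    out_dir: str
    model_path: str = "model"
    backend: str = "orb"
    target_side: int = 64
    theta_list: tuple[float, ...] = (0.05, 0.1, 0.15)
    seed: int = 0
    model: ModelConfig | None = None
    train_cfg: TrainConfig | None = None
    weights: LossWeights = field(default_factory=LossWeights)
    mask_l1: bool = True

    def __post_init__(self) -> None:
        if self.phase not in ("train", "test"):
            raise ValueError("phase must be 'train' or 'test'")
        if not self.theta_list or any(t <= 0 for t in self.theta_list):
            raise ValueError("theta_list must be non-empty with positive entries")


def load_pair_dirs(data_dir: str | Path) -> list[dict]:
    """Load a dataset laid out as one fixture directory per pair.

    Each subdirectory must hold ``ufi.png``; ``cfi.png``, ``od_boxes.json``
    and ``keypoints.json`` are optional (test-phase data has no CFI).
    """
    root = Path(data_dir)
    items = []
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        if not (sub / "ufi.png").exists():
            continue
        item: dict = {"name": sub.name, "ufi": load_image(sub / "ufi.png")}
        if (sub / "cfi.png").exists():
            item["cfi"] = load_image(sub / "cfi.png")
        if (sub / "od_boxes.json").exists():
            with open(sub / "od_boxes.json") as fh:
                boxes = json.load(fh)
            item["od_ufi"] = ODInfo.from_dict(boxes["ufi"])
            if "cfi" in boxes:
                item["od_cfi"] = ODInfo.from_dict(boxes["cfi"])
        if (sub / "keypoints.json").exists():
            with open(sub / "keypoints.json") as fh:
                kps = json.load(fh)
            item["kp_ufi"] = np.array(kps["kp_ufi"])
            item["kp_cfi"] = np.array(kps["kp_cfi"])
        items.append(item)
    return items


def _resolve_od(item: dict) -> ODInfo:
    if "od_ufi" in item:
        return item["od_ufi"]
    return localize_od(item["ufi"], BrightBlobDetector())


def run_train_phase(cfg: PipelineConfig, dataset: list[dict] | None = None) -> dict:
    """Register every pair, train the translator, and write artifacts.

    Returns a summary dict with the rejects report, per-theta PCK summary
    (when keypoint annotations are present), loss history, and checkpoint
    path. All randomness derives from ``cfg.seed``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    items = load_pair_dirs(cfg.data_dir) if dataset is None else dataset

    registered = []
    rejects = []
    pck_rows: list[dict] = []
    od_boxes_cfi: list[ODInfo] = []
    for item in items:
        name = item.get("name", "?")
        if "cfi" not in item:
            rejects.append({"name": name, "stage": "input", "reason": "missing CFI"})
            continue
        try:
            od = _resolve_od(item)
        except ODDetectionError as exc:
            rejects.append({"name": name, "stage": "od_detection", "reason": str(exc)})
            continue
        cfi = item["cfi"]
        # evaluate at the CFI's own resolution, then downscale for training
        scaled = od_scale_adjust(item["ufi"], od, cfi.width)
        try:
            res = register(scaled, cfi, backend=cfg.backend, seed=cfg.seed)
        except RegistrationStageError as exc:
            rejects.append({"name": name, "stage": exc.stage, "reason": str(exc.cause)})
            continue
        if "kp_ufi" in item and "od_cfi" in item:
            kp_s = np.array(
                [map_point_to_scaled(tuple(k), scaled)[0] for k in item["kp_ufi"]]
            )
            od_boxes_cfi.append(item["od_cfi"])
            r = mean_od_radius([item["od_cfi"]], cfi.width)
            row = {"name": name}
            for theta in cfg.theta_list:
                row[f"pck@{theta}"] = compute_pck(
                    kp_s, item["kp_cfi"], res.H, PCKConfig(theta=theta, r=r)
                )
            pck_rows.append(row)
        registered.append((res.warped, cfi, res.mask, name))

    if not registered:
        raise RuntimeError("no pairs survived registration; nothing to train on")

    side = cfg.target_side
    model_cfg = cfg.model or ModelConfig.desk(input_side=side)
    train_cfg = cfg.train_cfg or TrainConfig(
        epochs_total=20, epochs_constant_lr=10, input_side=side, seed=cfg.seed
    )
    pairs = []
    for warped, cfi, mask, _name in registered:
        xw = _resize_img(warped.pixels, side)
        yw = _resize_img(cfi.pixels, side)
        mw = _resize_img(mask.astype(float)[..., None], side)[..., 0] > 0.5
        pairs.append((xw, yw, mw.astype(float) if cfg.mask_l1 else None))

    model = TranslationModel(model_cfg, seed=cfg.seed)
    history = train(pairs, model, train_cfg, cfg.weights)
    ckpt = out / cfg.model_path
    model.save(ckpt)

    with open(out / "rejects.json", "w") as fh:
        json.dump(rejects, fh, indent=1)
    with open(out / "loss_history.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        keys = list(history.keys())
        writer.writerow(keys)
        for i in range(len(history["epoch"])):
            writer.writerow([history[k][i] for k in keys])
    pck_summary = {}
    if pck_rows:
        for theta in cfg.theta_list:
            pck_summary[str(theta)] = float(
                np.mean([r[f"pck@{theta}"] for r in pck_rows])
            )
        with open(out / "registration_pck.json", "w") as fh:
            json.dump({"per_pair": pck_rows, "mean": pck_summary}, fh, indent=1)
    logger.info(
        "train phase: %d registered, %d rejected", len(registered), len(rejects)
    )
    return {
        "n_registered": len(registered),
        "rejects": rejects,
        "pck_summary": pck_summary,
        "history": history,
        "checkpoint": str(ckpt),
    }


def run_test_phase(cfg: PipelineConfig, dataset: list[dict] | None = None) -> list[str]:
    """Translate UFIs to CFIs with a trained checkpoint; returns output paths."""
    ckpt = Path(cfg.out_dir) / cfg.model_path
    if not ckpt.with_suffix(".npz").exists():
        raise FileNotFoundError(f"missing checkpoint {ckpt}.npz; train first")
    model = TranslationModel.load(ckpt)
    items = load_pair_dirs(cfg.data_dir) if dataset is None else dataset
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for item in items:
        od = _resolve_od(item)
        scaled = od_scale_adjust(item["ufi"], od, model.config.input_side)
        edge = correction_forward(model, scaled.image)
        gen = generator_forward(model, scaled.image, edge)
        path = out / f"{item.get('name', 'ufi')}_cfi.png"
        save_image(gen, path)
        written.append(str(path))
    return written


def _resize_img(img: np.ndarray, side: int) -> np.ndarray:
    """Corner-anchored bilinear resize to side x side (anti-aliased down)."""
    from scipy import ndimage

    h, w = img.shape[:2]
    if (h, w) == (side, side):
        return img.copy()
    fy, fx = h / side, w / side
    src = img
    if fy > 1.05 or fx > 1.05:
        src = ndimage.gaussian_filter(
            src, (max(fy, 1.0) / 2.0, max(fx, 1.0) / 2.0) + (0.0,) * (img.ndim - 2)
        )
    yy, xx = np.mgrid[0:side, 0:side]
    coords = np.stack([yy * fy, xx * fx])
    if img.ndim == 2:
        return ndimage.map_coordinates(src, coords, order=1, mode="nearest")
    return np.stack(
        [
            ndimage.map_coordinates(src[..., c], coords, order=1, mode="nearest")
            for c in range(img.shape[2])
        ],
        axis=-1,
    )
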