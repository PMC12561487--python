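"""Losses and the adversarial training loop.

The generator-plus-correction-branch objective is

    L = L_cGAN + lambda1 * L1 + lambda2 * L_corr

where L_cGAN is the conditional adversarial loss in its log (binary
cross-entropy) form, L1 the mean absolute pixel difference between target
and synthesized CFI, and L_corr the mean squared difference between the
correction branch's edge prediction and the Laplacian-filtered target CFI.
The discriminator trains on its own cGAN term. Optimization is Adam
(beta1 = 0.5) with a constant learning rate followed by linear decay to
zero.

The loss weights are configuration; lambda1 = 100 follows paired image-to-
image convention and lambda2 = 10 places the (small-magnitude) edge MSE one
order below it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image import FundusImage
from .metrics import compute_metrics
from .odscale import od_scale_adjust
from .registration import Homography, to_grayscale, warp_and_mask
from .translator import ModelConfig, TranslationModel
from ._nn import Adam

__all__ = [
    "LossWeights",
    "TrainConfig",
    "laplacian_target",
    "cgan_loss",
    "l1_loss",
    "correction_loss",
    "total_loss",
    "lr_schedule",
    "train",
    "run_ablation",
]

# 4-neighbour Laplacian; |response| / 4 maps a unit step's peak to 1
_LAPLACIAN = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass(frozen=True)
class LossWeights:
    lambda1: float = 100.0
    lambda2: float = 10.0

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.lambda1)
            and math.isfinite(self.lambda2)
            and self.lambda1 >= 0
            and self.lambda2 >= 0
        ):
            raise ValueError("loss weights must be finite and non-negative")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule; reference values 200/100 epochs, lr 2e-4."""

    epochs_total: int = 200
    epochs_constant_lr: int = 100
    lr: float = 2e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    batch_size: int = 4
    seed: int = 0
    input_side: int = 64

    def __post_init__(self) -> None:
        if self.epochs_constant_lr > self.epochs_total:
            raise ValueError("epochs_constant_lr must be <= epochs_total")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")


# ----------------------------------------------------------------------------
# supervision target and loss terms


def laplacian_target(y: FundusImage | np.ndarray) -> np.ndarray:
    """Edge supervision target h(y): |Laplacian of grayscale(y)| / 4, clipped.

    Reflect padding at the border; the 1/4 scaling is the kernel's maximum
    response to a unit step, so the target lives in [0, 1] like the
    correction branch's output.
    """
    px = y.pixels if isinstance(y, FundusImage) else np.asarray(y, float)
    gray = to_grayscale(px) if px.ndim == 3 else px
    resp = ndimage.convolve(gray, _LAPLACIAN, mode="reflect")
    return np.clip(np.abs(resp) / 4.0, 0.0, 1.0)


def _bce_with_logits(z: np.ndarray, target: float) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy over a logit map; returns (loss, dloss/dz)."""
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite discriminator scores")
    # stable softplus: max(z,0) - t z + log(1 + exp(-|z|))
    loss = float((np.maximum(z, 0.0) - target * z + np.log1p(np.exp(-np.abs(z)))).mean())
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    grad = (sig - target) / z.size
    return loss, grad


def cgan_loss(
    d_real_scores: np.ndarray | None,
    d_fake_scores: np.ndarray,
    side: str,
) -> float:
    """Conditional-GAN loss (log form, mean over the patch grid).

    discriminator side: -E[log D(x,y)] - E[log(1 - D(x, y_hat))];
    generator side: -E[log D(x, y_hat)]. Scores are logits.
    """
    if side == "discriminator":
        if d_real_scores is None:
            raise ValueError("discriminator side needs real scores")
        lr_, _ = _bce_with_logits(np.asarray(d_real_scores, float), 1.0)
        lf, _ = _bce_with_logits(np.asarray(d_fake_scores, float), 0.0)
        return lr_ + lf
    if side == "generator":
        lg, _ = _bce_with_logits(np.asarray(d_fake_scores, float), 1.0)
        return lg
    raise ValueError(f"side must be 'generator' or 'discriminator', got {side!r}")


def l1_loss(y: FundusImage | np.ndarray, y_hat: FundusImage | np.ndarray) -> float:
    """Mean absolute difference over all pixels and channels."""
    a = y.pixels if isinstance(y, FundusImage) else np.asarray(y, float)
    b = y_hat.pixels if isinstance(y_hat, FundusImage) else np.asarray(y_hat, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).mean())


def correction_loss(y: FundusImage | np.ndarray, edge_pred: np.ndarray) -> float:
    """Mean squared difference between h(y) and the predicted edge map."""
    target = laplacian_target(y)
    pred = np.asarray(edge_pred, float)
    if target.shape != pred.shape:
        raise ValueError(f"shape mismatch: {target.shape} vs {pred.shape}")
    return float(((target - pred) ** 2).mean())


def total_loss(parts: tuple[float, float, float], w: LossWeights) -> float:
    """L = L_cGAN + lambda1 * L1 + lambda2 * L_corr."""
    lcgan, l1, lcorr = parts
    return float(lcgan + w.lambda1 * l1 + w.lambda2 * lcorr)


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Constant for the first phase, then linear decay reaching 0 at the end."""
    if not (0 <= epoch < cfg.epochs_total):
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs_total})")
    if epoch < cfg.epochs_constant_lr:
        return cfg.lr
    remaining = cfg.epochs_total - cfg.epochs_constant_lr
    return cfg.lr * (cfg.epochs_total - epoch) / remaining


# ----------------------------------------------------------------------------
# training loop


def _as_batch(images: list[np.ndarray]) -> np.ndarray:
    return np.stack([im.transpose(2, 0, 1) for im in images])


def _normalize_pairs(pairs) -> list[tuple[np.ndarray, np.ndarray, np.ndarray | None]]:
    out = []
    for item in pairs:
        x, y = item[0], item[1]
        mask = item[2] if len(item) > 2 else None
        xa = x.pixels if isinstance(x, FundusImage) else np.asarray(x, float)
        ya = y.pixels if isinstance(y, FundusImage) else np.asarray(y, float)
        ma = None if mask is None else np.asarray(mask, float)
        out.append((xa, ya, ma))
    return out


def _masked_l1_grad(
    yb: np.ndarray, fake: np.ndarray, mb: np.ndarray | None
) -> tuple[float, np.ndarray]:
    diff = fake - yb
    if mb is None:
        loss = float(np.abs(diff).mean())
        grad = np.sign(diff) / diff.size
    else:
        m = mb[:, None]  # (N,1,H,W) broadcast over channels
        denom = max(float(m.sum()) * diff.shape[1], 1.0)
        loss = float((np.abs(diff) * m).sum() / denom)
        grad = np.sign(diff) * m / denom
    return loss, grad


def _check_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise FloatingPointError(f"non-finite loss term {name!r}: {value}")


def train(
    pairs,
    model: TranslationModel,
    cfg: TrainConfig,
    w: LossWeights = LossWeights(),
    iterations_per_epoch: int | None = None,
    checkpoint_path: str | Path | None = None,
    resume_from: str | Path | None = None,
) -> dict:
    """Adversarial training on pre-registered (x, y[, mask]) pairs.

    Per batch: one discriminator update (real pair vs detached fake), then
    one generator+correction update against ``total_loss``. The mask, when
    present, restricts the L1 term to the valid registration overlap so
    zero-filled exteriors do not dominate. Returns a history dict with
    per-epoch means of every loss term; optionally checkpoints each epoch.
    """
    data = _normalize_pairs(pairs)
    if not data:
        raise ValueError("need at least one training pair")
    lap = [laplacian_target(y) for _, y, _ in data]

    optG = Adam(model.generator_layers(), lr=cfg.lr, beta1=cfg.adam_beta1,
                beta2=cfg.adam_beta2)
    optD = Adam([model.D], lr=cfg.lr, beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)

    start_epoch = 0
    if resume_from is not None:
        start_epoch = _load_checkpoint(resume_from, model, optG, optD)

    history: dict[str, list[float]] = {
        k: [] for k in ("epoch", "lr", "d_loss", "g_adv", "l1", "lcorr", "g_total")
    }
    n = len(data)
    for epoch in range(start_epoch, cfg.epochs_total):
        lr = lr_schedule(epoch, cfg)
        rng = np.random.default_rng(cfg.seed * 100003 + epoch)
        order = rng.permutation(n)
        if iterations_per_epoch is not None:
            reps = int(np.ceil(iterations_per_epoch * cfg.batch_size / n))
            order = np.concatenate([rng.permutation(n) for _ in range(max(reps, 1))])
            order = order[: iterations_per_epoch * cfg.batch_size]
        sums = dict.fromkeys(("d_loss", "g_adv", "l1", "lcorr", "g_total"), 0.0)
        n_batches = 0
        for b0 in range(0, len(order), cfg.batch_size):
            idx = order[b0 : b0 + cfg.batch_size]
            if len(idx) == 0:
                continue
            xb = _as_batch([data[i][0] for i in idx])
            yb = _as_batch([data[i][1] for i in idx])
            masks = [data[i][2] for i in idx]
            mb = None if any(m is None for m in masks) else np.stack(masks)
            lapb = np.stack([lap[i] for i in idx])[:, None]

            # --- discriminator update (fake detached) ---
            edge = model.correction(xb)
            fake = model.generate(xb, edge)
            optD.zero_grad()
            real_logits = model.discriminate(xb, yb)
            loss_r, grad_r = _bce_with_logits(real_logits, 1.0)
            model.discriminate_backward(grad_r)
            fake_logits = model.discriminate(xb, fake)
            loss_f, grad_f = _bce_with_logits(fake_logits, 0.0)
            model.discriminate_backward(grad_f)
            d_loss = loss_r + loss_f
            _check_finite("d_loss", d_loss)
            optD.step(lr)

            # --- generator + correction update ---
            optG.zero_grad()
            edge = model.correction(xb)
            fake = model.generate(xb, edge)
            adv_logits = model.discriminate(xb, fake)
            g_adv, grad_adv = _bce_with_logits(adv_logits, 1.0)
            _, dfake_adv = model.discriminate_backward(grad_adv)
            l1_val, dfake_l1 = _masked_l1_grad(yb, fake, mb)
            lcorr_val = float(((edge - lapb) ** 2).mean())
            for nm, v in (("g_adv", g_adv), ("l1", l1_val), ("lcorr", lcorr_val)):
                _check_finite(nm, v)
            dfake = dfake_adv + w.lambda1 * dfake_l1
            _, dedge = model.generate_backward(dfake)
            dedge_corr = 2.0 * (edge - lapb) / lapb.size
            model.correction_backward(dedge + w.lambda2 * dedge_corr)
            optG.step(lr)

            sums["d_loss"] += d_loss
            sums["g_adv"] += g_adv
            sums["l1"] += l1_val
            sums["lcorr"] += lcorr_val
            sums["g_total"] += total_loss((g_adv, l1_val, lcorr_val), w)
            n_batches += 1

        history["epoch"].append(epoch)
        history["lr"].append(lr)
        for k in sums:
            history[k].append(sums[k] / max(n_batches, 1))
        if checkpoint_path is not None:
            _save_checkpoint(checkpoint_path, model, optG, optD, epoch + 1)
    return history


def _save_checkpoint(path, model, optG, optD, next_epoch: int) -> None:
    path = Path(path)
    model.save(path)
    extra = {"next_epoch": np.array(next_epoch)}
    for tag, opt in (("G", optG), ("D", optD)):
        st = opt.state_dict()
        extra[f"{tag}/t"] = np.array(st["t"])
        for i, m in enumerate(st["m"]):
            extra[f"{tag}/m{i}"] = m
        for i, v in enumerate(st["v"]):
            extra[f"{tag}/v{i}"] = v
    np.savez(path.with_suffix(".opt.npz"), **extra)


def _load_checkpoint(path, model, optG, optD) -> int:
    path = Path(path)
    loaded = TranslationModel.load(path)
    for net_name in ("F", "G1", "G2E", "G2D", "D"):
        for (_, dst, _), (_, src, _) in zip(
            getattr(model, net_name).params(), getattr(loaded, net_name).params()
        ):
            dst[...] = src
    data = np.load(path.with_suffix(".opt.npz"))
    for tag, opt in (("G", optG), ("D", optD)):
        st = {
            "t": int(data[f"{tag}/t"]),
            "m": [data[f"{tag}/m{i}"] for i in range(len(opt.m))],
            "v": [data[f"{tag}/v{i}"] for i in range(len(opt.v))],
        }
        opt.load_state_dict(st)
    return int(data["next_epoch"])


# ----------------------------------------------------------------------------
# ablation harness


def run_ablation(
    phantom_pairs,
    cfg: TrainConfig,
    model_config: ModelConfig | None = None,
    w: LossWeights = LossWeights(),
) -> list[dict]:
    """2x2 ablation: {registration on/off} x {correction branch on/off}.

    Registration-on cells train on the scaled UFI warped into the CFI frame
    under the pair's ground-truth homography (ideal registration, with the
    footprint mask applied to the L1 term); registration-off cells train on
    the misaligned scaled UFI directly. Correction-off cells feed a zero
    edge map and drop the correction loss. Each cell trains its own model
    from the same seed and reports MSE / PSNR / SSIM / MS-SSIM of generated
    vs target over the pairs.
    """
    side = cfg.input_side
    model_config = model_config or ModelConfig.desk(input_side=side)
    datasets: dict[bool, list] = {}
    eval_masks: list[np.ndarray] = []
    for reg_on in (True, False):
        items = []
        for p in phantom_pairs:
            scaled = od_scale_adjust(p.ufi, p.od_box_ufi, side)
            if p.cfi.width != side:
                cfi = od_scale_adjust(p.cfi, _full_box(), side).image
                H = _rescale_h(p.H_true, p.cfi.width, side)
            else:
                cfi, H = p.cfi, Homography(p.H_true)
            warped, mask = warp_and_mask(scaled.image, _as_h(H), (side, side))
            if reg_on:
                items.append((warped.pixels, cfi.pixels, mask.astype(float)))
            else:
                items.append((scaled.image.pixels, cfi.pixels, None))
                eval_masks.append(mask)
        datasets[reg_on] = items

    rows = []
    for reg_on in (False, True):
        for corr_on in (False, True):
            model = TranslationModel(model_config, seed=cfg.seed)
            weights = w if corr_on else LossWeights(w.lambda1, 0.0)
            data = datasets[reg_on]
            if not corr_on:

                def zero_correction(x, _m=model):
                    return np.zeros((x.shape[0], 1, x.shape[2], x.shape[3]))

                model.correction = zero_correction  # type: ignore[assignment]
                model.correction_backward = lambda g: g  # type: ignore[assignment]
            train(data, model, cfg, weights)
            # evaluate every cell on the same valid-overlap region so cells
            # are compared on identical pixels
            reports = []
            for (x, y, _m), em in zip(data, eval_masks):
                edge = model.correction(_as_batch([x]))
                gen = model.generate(_as_batch([x]), edge)[0].transpose(1, 2, 0)
                reports.append(compute_metrics(y, np.clip(gen, 0, 1), mask=em))
            rows.append(
                {
                    "registration": reg_on,
                    "correction": corr_on,
                    "mse": float(np.mean([r.mse for r in reports])),
                    "psnr": float(np.mean([r.psnr for r in reports])),
                    "ssim": float(np.mean([r.ssim for r in reports])),
                    "ms_ssim": float(np.mean([r.ms_ssim for r in reports])),
                }
            )
    return rows


def _as_h(H) -> Homography:
    return H if isinstance(H, Homography) else Homography(H)


def _full_box():
    from .odscale import ODInfo

    # a box whose 6x window covers the whole image: w = h = 1/6 centered
    return ODInfo(cx=0.5, cy=0.5, w=1.0 / 6.0, h=1.0 / 6.0)


def _rescale_h(H: np.ndarray, side_from: int, side_to: int) -> Homography:
    s = side_to / side_from
    S = np.diag([s, s, 1.0])
    return Homography(S @ H @ np.linalg.inv(S))
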