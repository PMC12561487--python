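"""UFI-to-CFI translation networks.

Three components, mirroring an edge-guided conditional GAN:

* **Correction branch F** - a shallow stack of convolutional blocks that
  predicts a vessel edge map from the registered UFI. During training it is
  supervised by the Laplacian-filtered target CFI, injecting vessel-aware
  structure where the UFI is blurred or distorted.
* **Generator** - a global-local pair. G1 consumes the 2x-downsampled
  concatenation of the UFI and the edge map and extracts global context;
  G2's encoder (G2E) consumes the full-resolution concatenation and encodes
  local detail at half resolution. The two half-resolution feature maps are
  fused by element-wise addition and decoded by G2D into the synthetic CFI.
* **Discriminator** - a patch-based conditional critic: it scores the
  channel-wise concatenation of condition (UFI) and candidate (CFI) through
  three strided convolutions and a 1-channel head, yielding a spatial grid
  of real/fake logits whose cells correspond to image patches.

Images cross this module's public surface as ``FundusImage``s or NCHW
float arrays in [0, 1]; edge maps are single-channel rasters in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._nn import (
    Adam,
    AvgPool2x,
    Conv2d,
    InstanceNorm2d,
    LeakyReLU,
    ReLU,
    ResBlock,
    Sequential,
    Sigmoid,
    Upsample2x,
)
from .image import FundusImage

__all__ = [
    "ModelConfig",
    "TranslationModel",
    "correction_forward",
    "generator_forward",
    "discriminator_forward",
    "n_parameters",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The reference configuration uses 64 base filters with nine global and
    three local residual blocks and a 3-layer patch discriminator; the desk
    default is a narrow variant of the same shape.
    """

    base_filters: int = 64
    res_blocks_global: int = 9
    res_blocks_local: int = 3
    correction_blocks: int = 4
    disc_layers: int = 3
    input_side: int = 512

    def __post_init__(self) -> None:
        for name in (
            "base_filters",
            "res_blocks_global",
            "res_blocks_local",
            "correction_blocks",
            "disc_layers",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.input_side % 4 != 0:
            raise ValueError("input_side must be divisible by 4")

    @classmethod
    def desk(cls, input_side: int = 64, base_filters: int = 16) -> "ModelConfig":
        """Small configuration for CPU-scale experiments."""
        return cls(
            base_filters=base_filters,
            res_blocks_global=2,
            res_blocks_local=1,
            input_side=input_side,
        )


def _build_correction(cfg: ModelConfig, rng) -> Sequential:
    c = cfg.base_filters
    layers = [Conv2d(3, c, 3, rng=rng), InstanceNorm2d(), ReLU()]
    for _ in range(cfg.correction_blocks - 1):
        layers += [Conv2d(c, c, 3, rng=rng), InstanceNorm2d(), ReLU()]
    layers += [Conv2d(c, 1, 3, rng=rng), Sigmoid()]
    return Sequential(*layers)


def _build_g1(cfg: ModelConfig, rng) -> Sequential:
    c = cfg.base_filters
    layers = [AvgPool2x(), Conv2d(4, c, 3, rng=rng), InstanceNorm2d(), ReLU()]
    layers += [ResBlock(c, rng) for _ in range(cfg.res_blocks_global)]
    return Sequential(*layers)


def _build_g2e(cfg: ModelConfig, rng) -> Sequential:
    c = cfg.base_filters
    layers = [
        Conv2d(4, c, 3, rng=rng),
        InstanceNorm2d(),
        ReLU(),
        Conv2d(c, c, 4, stride=2, pad=1, rng=rng),
        InstanceNorm2d(),
        ReLU(),
    ]
    layers += [ResBlock(c, rng) for _ in range(cfg.res_blocks_local)]
    return Sequential(*layers)


def _build_g2d(cfg: ModelConfig, rng) -> Sequential:
    c = cfg.base_filters
    return Sequential(
        Upsample2x(),
        Conv2d(c, c, 3, rng=rng),
        InstanceNorm2d(),
        ReLU(),
        Conv2d(c, 3, 3, rng=rng),
        Sigmoid(),
    )


def _build_discriminator(cfg: ModelConfig, rng) -> Sequential:
    c = cfg.base_filters
    layers = [Conv2d(6, c, 4, stride=2, pad=1, rng=rng), LeakyReLU(0.2)]
    cin = c
    for i in range(1, cfg.disc_layers):
        cout = min(c * 2**i, c * 8)
        layers += [
            Conv2d(cin, cout, 4, stride=2, pad=1, rng=rng),
            InstanceNorm2d(),
            LeakyReLU(0.2),
        ]
        cin = cout
    layers += [Conv2d(cin, 1, 3, rng=rng)]
    return Sequential(*layers)


class TranslationModel:
    """Correction branch F, generator (G1, G2E, G2D) and discriminator D."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.F = _build_correction(config, rng)
        self.G1 = _build_g1(config, rng)
        self.G2E = _build_g2e(config, rng)
        self.G2D = _build_g2d(config, rng)
        self.D = _build_discriminator(config, rng)

    # -- batch-level forward/backward used by training ----------------------

    def correction(self, x: np.ndarray) -> np.ndarray:
        """F(x): (N,3,H,W) -> (N,1,H,W) edge map in [0,1]."""
        self._check_side(x)
        return self.F.forward(x)

    def correction_backward(self, grad: np.ndarray) -> np.ndarray:
        return self.F.backward(grad)

    def generate(self, x: np.ndarray, edge: np.ndarray) -> np.ndarray:
        """Fused generator forward: y_hat = G2D(G2E(x,x') + G1(Down(x,x')))."""
        self._check_side(x)
        cat = np.concatenate([x, edge], axis=1)
        f_global = self.G1.forward(cat)
        f_local = self.G2E.forward(cat)
        return self.G2D.forward(f_global + f_local)

    def generate_backward(self, grad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Backprop through the fusion; returns (dx, dedge)."""
        dfsum = self.G2D.backward(grad)
        dcat = self.G1.backward(dfsum) + self.G2E.backward(dfsum)
        return dcat[:, :3], dcat[:, 3:]

    def discriminate(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """D(x, y): patch logit grid for condition x and candidate y."""
        if x.shape != y.shape:
            raise ValueError(f"condition/candidate shape mismatch: {x.shape} vs {y.shape}")
        return self.D.forward(np.concatenate([x, y], axis=1))

    def discriminate_backward(self, grad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (dx, dy) gradients w.r.t. condition and candidate."""
        dcat = self.D.backward(grad)
        return dcat[:, :3], dcat[:, 3:]

    def generator_layers(self) -> list:
        return [self.F, self.G1, self.G2E, self.G2D]

    def zero_grad(self) -> None:
        for net in (self.F, self.G1, self.G2E, self.G2D, self.D):
            net.zero_grad()

    def _check_side(self, x: np.ndarray) -> None:
        if x.shape[-1] != self.config.input_side or x.shape[-2] != self.config.input_side:
            raise ValueError(
                f"input side {x.shape[-2:]}, model expects {self.config.input_side}"
            )

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write weights (.npz) plus a JSON sidecar with the configuration."""
        path = Path(path)
        arrays = {}
        for net_name in ("F", "G1", "G2E", "G2D", "D"):
            net = getattr(self, net_name)
            for pname, val, _ in net.params():
                arrays[f"{net_name}/{pname}"] = val
        np.savez(path.with_suffix(".npz"), **arrays)
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(asdict(self.config), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "TranslationModel":
        path = Path(path)
        with open(path.with_suffix(".json")) as fh:
            config = ModelConfig(**json.load(fh))
        model = cls(config, seed=0)
        data = np.load(path.with_suffix(".npz"))
        for net_name in ("F", "G1", "G2E", "G2D", "D"):
            net = getattr(model, net_name)
            for pname, val, _ in net.params():
                val[...] = data[f"{net_name}/{pname}"]
        return model


# ----------------------------------------------------------------------------
# single-image operation wrappers


def _to_nchw(img: FundusImage | np.ndarray) -> np.ndarray:
    px = img.pixels if isinstance(img, FundusImage) else np.asarray(img, float)
    return px.transpose(2, 0, 1)[None]


def correction_forward(model: TranslationModel, x: FundusImage | np.ndarray) -> np.ndarray:
    """Predict the vessel edge map of one image; returns an (H, W) raster."""
    return model.correction(_to_nchw(x))[0, 0]


def generator_forward(
    model: TranslationModel,
    x: FundusImage | np.ndarray,
    x_edge: np.ndarray,
) -> FundusImage:
    """Synthesize the CFI for one image given its predicted edge map."""
    edge = np.asarray(x_edge, float)[None, None]
    out = model.generate(_to_nchw(x), edge)[0]
    return FundusImage(np.clip(out.transpose(1, 2, 0), 0.0, 1.0))


def discriminator_forward(
    model: TranslationModel,
    x: FundusImage | np.ndarray,
    y: FundusImage | np.ndarray,
) -> np.ndarray:
    """Patch logit grid for one (condition, candidate) pair."""
    return model.discriminate(_to_nchw(x), _to_nchw(y))[0, 0]


def n_parameters(model: TranslationModel) -> int:
    total = 0
    for net in (model.F, model.G1, model.G2E, model.G2D, model.D):
        total += sum(v.size for _, v, _ in net.params())
    return total
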