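"""Translation networks: contracts, determinism, capacity scaling."""

import numpy as np
import pytest

from fundus2cfi._nn import Adam
from fundus2cfi.image import FundusImage
from fundus2cfi.training import laplacian_target
from fundus2cfi.translator import (
    ModelConfig,
    TranslationModel,
    correction_forward,
    discriminator_forward,
    generator_forward,
    n_parameters,
)


@pytest.fixture(scope="module")
def tiny_model():
    return TranslationModel(ModelConfig.desk(64, 8), seed=0)


@pytest.fixture(scope="module")
def tiny_image():
    return FundusImage(np.random.default_rng(5).uniform(0, 1, (64, 64, 3)))


class TestCorrectionBranch:
    def test_output_shape_and_range(self, tiny_model, tiny_image):
        edge = correction_forward(tiny_model, tiny_image)
        assert edge.shape == (64, 64)
        assert edge.min() >= 0.0 and edge.max() <= 1.0

    def test_wrong_side_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.correction(np.zeros((1, 3, 32, 32)))

    def test_overfit_reduces_gap_to_laplacian_target(self, tiny_image):
        """50 supervised steps halve the edge-prediction MSE."""
        model = TranslationModel(ModelConfig.desk(64, 8), seed=1)
        x = tiny_image.pixels.transpose(2, 0, 1)[None]
        target = laplacian_target(tiny_image)[None, None]
        opt = Adam([model.F], lr=2e-3)
        first = None
        for _ in range(50):
            pred = model.correction(x)
            gap = float(((pred - target) ** 2).mean())
            first = gap if first is None else first
            opt.zero_grad()
            model.correction_backward(2 * (pred - target) / target.size)
            opt.step()
        assert gap <= 0.5 * first


class TestGenerator:
    def test_output_shape_matches_input(self, tiny_model, tiny_image):
        edge = correction_forward(tiny_model, tiny_image)
        out = generator_forward(tiny_model, tiny_image, edge)
        assert out.shape == (64, 64)

    def test_eval_determinism(self, tiny_model, tiny_image):
        edge = correction_forward(tiny_model, tiny_image)
        a = generator_forward(tiny_model, tiny_image, edge)
        b = generator_forward(tiny_model, tiny_image, edge)
        assert np.array_equal(a.pixels, b.pixels)

    def test_global_path_contributes(self, tiny_model, tiny_image):
        """Zeroing the G1 addition path changes the output."""
        edge = correction_forward(tiny_model, tiny_image)
        full = generator_forward(tiny_model, tiny_image, edge)
        orig_forward = tiny_model.G1.forward
        tiny_model.G1.forward = lambda x: np.zeros_like(orig_forward(x))
        try:
            ablated = generator_forward(tiny_model, tiny_image, edge)
        finally:
            tiny_model.G1.forward = orig_forward
        assert np.abs(full.pixels - ablated.pixels).sum() > 0

    def test_zero_edge_map_is_valid_input(self, tiny_model, tiny_image):
        out = generator_forward(tiny_model, tiny_image, np.zeros((64, 64)))
        assert np.isfinite(out.pixels).all()


class TestDiscriminator:
    def test_patch_grid_shape(self, tiny_image):
        model = TranslationModel(ModelConfig.desk(128, 8), seed=0)
        big = FundusImage(np.random.default_rng(1).uniform(0, 1, (128, 128, 3)))
        grid = discriminator_forward(model, big, big)
        assert grid.shape == (16, 16)  # three stride-2 layers: 128 / 8
        assert min(grid.shape) >= 7

    def test_candidate_affects_scores(self, tiny_model, tiny_image):
        other = FundusImage(np.random.default_rng(9).uniform(0, 1, (64, 64, 3)))
        a = discriminator_forward(tiny_model, tiny_image, tiny_image)
        b = discriminator_forward(tiny_model, tiny_image, other)
        assert not np.allclose(a, b)

    def test_shape_mismatch(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.discriminate(np.zeros((1, 3, 64, 64)), np.zeros((1, 3, 32, 32)))


class TestModel:
    def test_parameter_count_scales_quadratically(self):
        n16 = n_parameters(TranslationModel(ModelConfig.desk(64, 16), seed=0))
        n32 = n_parameters(TranslationModel(ModelConfig.desk(64, 32), seed=0))
        assert 3.0 < n32 / n16 < 4.5

    @pytest.mark.parametrize("seed", range(5))
    def test_forwards_are_finite_at_init(self, seed):
        model = TranslationModel(ModelConfig.desk(64, 8), seed=seed)
        r = np.random.default_rng(seed)
        x = r.uniform(0, 1, (2, 3, 64, 64))
        y = r.uniform(0, 1, (2, 3, 64, 64))
        edge = model.correction(x)
        fake = model.generate(x, edge)
        scores = model.discriminate(x, y)
        for arr in (edge, fake, scores):
            assert np.isfinite(arr).all()

    def test_save_load_round_trip(self, tmp_path, tiny_model, tiny_image):
        tiny_model.save(tmp_path / "ckpt")
        loaded = TranslationModel.load(tmp_path / "ckpt")
        e0 = correction_forward(tiny_model, tiny_image)
        e1 = correction_forward(loaded, tiny_image)
        assert np.array_equal(e0, e1)
        a = generator_forward(tiny_model, tiny_image, e0)
        b = generator_forward(loaded, tiny_image, e1)
        assert np.array_equal(a.pixels, b.pixels)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            ModelConfig(input_side=63)
        with pytest.raises(ValueError):
            ModelConfig(base_filters=0)
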