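"""Losses, schedule, Laplacian target, training loop mechanics."""

import numpy as np
import pytest

from fundus2cfi.registration import to_grayscale
from fundus2cfi.training import (
    LossWeights,
    TrainConfig,
    cgan_loss,
    correction_loss,
    l1_loss,
    laplacian_target,
    lr_schedule,
    total_loss,
    train,
)
from fundus2cfi.translator import ModelConfig, TranslationModel

KERNEL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def laplacian_oracle(gray):
    """Explicit double-loop convolution with reflect padding."""
    h, w = gray.shape
    out = np.zeros_like(gray)
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ii = min(max(i + di, 0), h - 1) if not (0 <= i + di < h) else i + di
                    jj = min(max(j + dj, 0), w - 1) if not (0 <= j + dj < w) else j + dj
                    acc += KERNEL[di + 1, dj + 1] * gray[ii, jj]
            out[i, j] = acc
    return np.clip(np.abs(out) / 4.0, 0.0, 1.0)


class TestLaplacianTarget:
    def test_constant_image_is_zero(self):
        assert laplacian_target(np.full((16, 16, 3), 0.7)).max() == 0.0

    def test_unit_impulse(self):
        img = np.zeros((17, 17, 3))
        img[8, 8] = 1.0
        t = laplacian_target(img)
        assert t[8, 8] == pytest.approx(1.0)
        for n in ((8, 7), (8, 9), (7, 8), (9, 8)):
            assert t[n] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_convolution(self, seed):
        img = np.random.default_rng(seed).uniform(0, 1, (16, 16, 3))
        assert np.allclose(
            laplacian_target(img), laplacian_oracle(to_grayscale(img)), atol=1e-9
        )


class TestLossTerms:
    def test_l1_identities(self, rng):
        y = rng.uniform(0, 1, (16, 16, 3))
        assert l1_loss(y, y) == 0.0
        assert l1_loss(y, y + 0.1) == pytest.approx(0.1, abs=1e-12)

    def test_l1_matches_brute_force(self, rng):
        a = rng.uniform(0, 1, (8, 8, 3))
        b = rng.uniform(0, 1, (8, 8, 3))
        brute = sum(
            abs(a[i, j, c] - b[i, j, c])
            for i in range(8)
            for j in range(8)
            for c in range(3)
        ) / (8 * 8 * 3)
        assert l1_loss(a, b) == pytest.approx(brute, abs=1e-12)

    def test_correction_loss_identities(self, rng):
        y = rng.uniform(0, 1, (16, 16, 3))
        t = laplacian_target(y)
        assert correction_loss(y, t) == 0.0
        shifted = np.clip(t + 0.2, 0, None)  # stays in range when t <= 0.8
        assert correction_loss(y, t + 0.2) == pytest.approx(0.04, abs=1e-12)

    def test_correction_loss_matches_brute_force(self, rng):
        y = rng.uniform(0, 1, (8, 8, 3))
        pred = rng.uniform(0, 1, (8, 8))
        t = laplacian_target(y)
        brute = sum(
            (t[i, j] - pred[i, j]) ** 2 for i in range(8) for j in range(8)
        ) / 64
        assert correction_loss(y, pred) == pytest.approx(brute, abs=1e-12)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            l1_loss(np.zeros((8, 8, 3)), np.zeros((4, 4, 3)))
        with pytest.raises(ValueError):
            correction_loss(np.zeros((8, 8, 3)), np.zeros((4, 4)))


class TestCGANLoss:
    def test_saturated_discriminator_loss_vanishes(self):
        big = np.full((4, 4), 30.0)
        assert cgan_loss(big, -big, "discriminator") < 1e-10

    def test_uninformative_logits(self):
        z = np.zeros((5, 5))
        assert cgan_loss(z, z, "discriminator") == pytest.approx(2 * np.log(2))

    def test_generator_loss_monotone_in_fake_logits(self):
        losses = [cgan_loss(None, np.full((3, 3), v), "generator") for v in (-2, 0, 2, 5)]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            cgan_loss(np.array([[np.nan]]), np.zeros((1, 1)), "discriminator")


class TestTotalLossAndSchedule:
    def test_zero_weights_reduce_to_adversarial(self):
        assert total_loss((0.8, 0.5, 0.3), LossWeights(0, 0)) == 0.8

    def test_reference_arithmetic(self):
        assert total_loss((1.0, 0.5, 0.25), LossWeights(100, 10)) == 53.5

    def test_linearity(self):
        w = LossWeights(100, 10)
        a = total_loss((1.0, 0.2, 0.1), w)
        assert total_loss((2.0, 0.4, 0.2), w) == pytest.approx(2 * a)

    def test_schedule_phases(self):
        cfg = TrainConfig(epochs_total=200, epochs_constant_lr=100)
        assert all(lr_schedule(e, cfg) == 2e-4 for e in (0, 50, 99))
        assert lr_schedule(150, cfg) == pytest.approx(1e-4)
        assert lr_schedule(199, cfg) == pytest.approx(2e-6)
        # continuity at the boundary and monotone decay
        assert lr_schedule(100, cfg) == pytest.approx(2e-4)
        rates = [lr_schedule(e, cfg) for e in range(200)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_schedule_out_of_range(self):
        cfg = TrainConfig(epochs_total=10, epochs_constant_lr=5)
        with pytest.raises(ValueError):
            lr_schedule(10, cfg)
        with pytest.raises(ValueError):
            lr_schedule(-1, cfg)


def _toy_pairs(n=2, side=32, seed=0):
    r = np.random.default_rng(seed)
    return [
        (r.uniform(0, 1, (side, side, 3)), r.uniform(0, 1, (side, side, 3)))
        for _ in range(n)
    ]


class TestTrainLoop:
    def test_pure_adversarial_configuration_runs(self):
        model = TranslationModel(ModelConfig.desk(32, 8), seed=0)
        cfg = TrainConfig(epochs_total=1, epochs_constant_lr=1, batch_size=2,
                          input_side=32, seed=0)
        h = train(_toy_pairs(), model, cfg, LossWeights(0.0, 0.0))
        assert len(h["d_loss"]) == 1 and np.isfinite(h["d_loss"][0])

    def test_correction_branch_receives_gradients(self):
        model = TranslationModel(ModelConfig.desk(32, 8), seed=0)
        before = [v.copy() for _, v, _ in model.F.params()]
        cfg = TrainConfig(epochs_total=1, epochs_constant_lr=1, batch_size=2,
                          input_side=32, seed=0)
        train(_toy_pairs(), model, cfg, LossWeights(100.0, 10.0))
        after = [v for _, v, _ in model.F.params()]
        assert any(not np.array_equal(a, b) for a, b in zip(before, after))

    def test_checkpoint_resume_matches_uninterrupted_run(self, tmp_path):
        pairs = _toy_pairs(n=2, side=32, seed=1)
        cfg = TrainConfig(epochs_total=3, epochs_constant_lr=2, batch_size=2,
                          input_side=32, seed=4)

        full = TranslationModel(ModelConfig.desk(32, 8), seed=7)
        h_full = train(pairs, full, cfg)

        part = TranslationModel(ModelConfig.desk(32, 8), seed=7)
        cfg2 = TrainConfig(epochs_total=2, epochs_constant_lr=2, batch_size=2,
                           input_side=32, seed=4)
        train(pairs, part, cfg2, checkpoint_path=tmp_path / "ck")
        resumed = TranslationModel(ModelConfig.desk(32, 8), seed=7)
        h_res = train(pairs, resumed, cfg, resume_from=tmp_path / "ck")

        assert h_res["epoch"] == [2]
        assert h_res["g_total"][0] == pytest.approx(h_full["g_total"][2], abs=1e-5)

    def test_empty_dataset_rejected(self):
        model = TranslationModel(ModelConfig.desk(32, 8), seed=0)
        cfg = TrainConfig(input_side=32)
        with pytest.raises(ValueError):
            train([], model, cfg)
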