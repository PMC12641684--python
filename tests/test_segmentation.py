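"""Network geometry, losses, Dice and training behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from latentrad.segmentation import (MultiscaleNetConfig, SegTrainState,
                                    bce_loss, build_multiscale_unet,
                                    combined_loss, dice_coefficient,
                                    load_checkpoint, predict_mask,
                                    save_checkpoint, soft_dice_loss,
                                    train_segmentation)
from latentrad.nn import Tensor
from latentrad.volume import LesionMask


class TestConfig:
    def test_reference_scale_bottlenecks(self):
        cfg = MultiscaleNetConfig(full_res_shape=(128,) * 3, base_channels=32,
                                  depth=4, bottleneck_channels=512,
                                  deep_supervision_levels=2)
        assert cfg.bottleneck_shape_full == (512, 8, 8, 8)
        assert cfg.bottleneck_shape_half == (512, 4, 4, 4)

    def test_desk_scale_bottlenecks(self):
        cfg = MultiscaleNetConfig(full_res_shape=(32,) * 3, base_channels=8,
                                  depth=3, bottleneck_channels=64,
                                  deep_supervision_levels=1)
        assert cfg.bottleneck_shape_full == (64, 4, 4, 4)
        assert cfg.bottleneck_shape_half == (64, 2, 2, 2)

    def test_indivisible_extent_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            MultiscaleNetConfig(full_res_shape=(20,) * 3, depth=3)

    def test_half_shape_must_be_half(self):
        with pytest.raises(ValueError, match="half"):
            MultiscaleNetConfig(full_res_shape=(32,) * 3, half_res_shape=(32,) * 3,
                                depth=2)


class TestBuild:
    def test_forward_shapes_multiscale(self):
        cfg = MultiscaleNetConfig(full_res_shape=(16,) * 3, base_channels=4,
                                  depth=2, bottleneck_channels=16,
                                  deep_supervision_levels=1)
        model = build_multiscale_unet(cfg, seed=0)
        out = model.forward(np.zeros((1, 1, 16, 16, 16), np.float32))
        assert out["bottleneck_full"].data.shape == (1, 16, 4, 4, 4)
        assert out["bottleneck_half"].data.shape == (1, 16, 2, 2, 2)
        assert out["logits"][0].data.shape == (1, 1, 16, 16, 16)

    def test_single_scale_has_one_encoder(self):
        cfg = MultiscaleNetConfig(full_res_shape=(16,) * 3, base_channels=4,
                                  depth=2, bottleneck_channels=16,
                                  deep_supervision_levels=1, single_scale=True)
        model = build_multiscale_unet(cfg, seed=0)
        assert model.encoder_half is None
        out = model.forward(np.zeros((1, 1, 16, 16, 16), np.float32))
        assert out["bottleneck_half"] is None

    def test_deep_supervision_output_count(self):
        cfg = MultiscaleNetConfig(full_res_shape=(32,) * 3, base_channels=4,
                                  depth=3, bottleneck_channels=16,
                                  deep_supervision_levels=2)
        model = build_multiscale_unet(cfg, seed=0)
        out = model.forward(np.zeros((1, 1, 32, 32, 32), np.float32))
        assert len(out["logits"]) == 3  # full + 2 coarser


class TestLosses:
    def test_perfect_prediction_zero_dice_loss(self):
        target = np.zeros((1, 1, 4, 4, 4), np.float32)
        target[0, 0, 1:3, 1:3, 1:3] = 1.0
        logits = Tensor(np.where(target > 0, 30.0, -30.0).astype(np.float32))
        assert float(soft_dice_loss(logits, target).data) == pytest.approx(0.0, abs=1e-4)

    def test_combined_loss_nonnegative(self, rng):
        logits = [Tensor(rng.normal(size=(1, 1, 4, 4, 4)).astype(np.float32))]
        target = (rng.random((1, 1, 4, 4, 4)) > 0.5).astype(np.float32)
        loss = combined_loss(logits, target, 1.0, 1.0)
        assert float(loss.data) >= 0.0

    def test_bce_matches_reference(self, rng):
        z = rng.normal(size=(2, 1, 3, 3, 3)).astype(np.float32)
        t = (rng.random((2, 1, 3, 3, 3)) > 0.5).astype(np.float32)
        p = 1 / (1 + np.exp(-z))
        ref = -(t * np.log(p) + (1 - t) * np.log(1 - p)).mean()
        assert float(bce_loss(Tensor(z), t).data) == pytest.approx(ref, rel=1e-5)


class TestDice:
    def test_identical_masks(self):
        m = LesionMask(np.ones((3, 3, 3), dtype=bool), (1.0,) * 3)
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert dice_coefficient(LesionMask(a, (1,) * 3), LesionMask(b, (1,) * 3)) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, :4] = True
        b[0, 0, 2:4] = True
        b[0, 1, :2] = True
        assert dice_coefficient(LesionMask(a, (1,) * 3), LesionMask(b, (1,) * 3)) == 0.5

    def test_both_empty_is_one(self):
        e = LesionMask(np.zeros((2, 2, 2), dtype=bool), (1.0,) * 3)
        assert dice_coefficient(e, e) == 1.0

    def test_shape_mismatch_rejected(self):
        a = LesionMask(np.zeros((2, 2, 2), dtype=bool), (1.0,) * 3)
        b = LesionMask(np.zeros((3, 3, 3), dtype=bool), (1.0,) * 3)
        with pytest.raises(ValueError):
            dice_coefficient(a, b)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(hnp.arrays(bool, (4, 4, 4)), hnp.arrays(bool, (4, 4, 4)))
    def test_symmetric_and_bounded(self, a, b):
        d1 = dice_coefficient(LesionMask(a, (1,) * 3), LesionMask(b, (1,) * 3))
        d2 = dice_coefficient(LesionMask(b, (1,) * 3), LesionMask(a, (1,) * 3))
        assert d1 == d2
        assert 0.0 <= d1 <= 1.0


@pytest.fixture(scope="module")
def tiny_net_and_training(small_cohort_module):
    cfg = MultiscaleNetConfig(full_res_shape=(16,) * 3, base_channels=4,
                              depth=2, bottleneck_channels=16,
                              deep_supervision_levels=1)
    model = build_multiscale_unet(cfg, seed=3)
    state = train_segmentation(model, small_cohort_module[:6], epochs=4,
                               seed=5, lr=3e-3)
    return cfg, model, state


@pytest.fixture(scope="module")
def small_cohort_module():
    from latentrad.synthetic import LabelModel, PhantomConfig, generate_cohort

    cfg = PhantomConfig(grid_shape=(16,) * 3, spacing_mm=(4.0,) * 3,
                        lesion_volume_range_ml=(5.0, 30.0), irregularity=0.1,
                        background_noise_sd=2.0, rim_noise_sd_range=(0.5, 2.0))
    return generate_cohort(cfg, 8, LabelModel(), seed=11)


class TestTraining:
    def test_history_recorded_and_deterministic(self, small_cohort_module):
        cfg = MultiscaleNetConfig(full_res_shape=(16,) * 3, base_channels=2,
                                  depth=2, bottleneck_channels=8,
                                  deep_supervision_levels=1)
        hists = []
        for _ in range(2):
            model = build_multiscale_unet(cfg, seed=3)
            state = train_segmentation(model, small_cohort_module[:4], epochs=2, seed=5)
            hists.append(state.loss_history)
        assert hists[0] == hists[1]
        assert len(hists[0]) == 2

    def test_loss_decreases_with_training(self, tiny_net_and_training):
        _, _, state = tiny_net_and_training
        assert state.loss_history[-1] <= state.loss_history[0]

    def test_weights_validation(self, small_cohort_module):
        cfg = MultiscaleNetConfig(full_res_shape=(16,) * 3, base_channels=2,
                                  depth=2, bottleneck_channels=8,
                                  deep_supervision_levels=1)
        model = build_multiscale_unet(cfg, seed=0)
        with pytest.raises(ValueError, match="weights"):
            train_segmentation(model, small_cohort_module[:4], loss_weights=(0, 0))

    def test_all_empty_masks_rejected(self):
        from latentrad.synthetic import PhantomConfig, generate_cohort

        cfg = PhantomConfig(grid_shape=(16,) * 3, spacing_mm=(2.0,) * 3,
                            lesion_volume_range_ml=(0.0, 0.0))
        empties = generate_cohort(cfg, 2, seed=0)
        net_cfg = MultiscaleNetConfig(full_res_shape=(16,) * 3, base_channels=2,
                                      depth=2, bottleneck_channels=8,
                                      deep_supervision_levels=1)
        model = build_multiscale_unet(net_cfg, seed=0)
        with pytest.raises(ValueError, match="degenerate"):
            train_segmentation(model, empties)


class TestPredict:
    def test_untrained_model_rejected(self, small_cohort_module):
        cfg = MultiscaleNetConfig(full_res_shape=(16,) * 3, base_channels=2,
                                  depth=2, bottleneck_channels=8,
                                  deep_supervision_levels=1)
        model = build_multiscale_unet(cfg, seed=0)
        with pytest.raises(RuntimeError, match="train"):
            predict_mask(model, small_cohort_module[0].image)

    def test_inference_deterministic(self, tiny_net_and_training, small_cohort_module):
        _, model, _ = tiny_net_and_training
        a = predict_mask(model, small_cohort_module[6].image)
        b = predict_mask(model, small_cohort_module[6].image)
        np.testing.assert_array_equal(a.data, b.data)

    def test_threshold_validation(self, tiny_net_and_training, small_cohort_module):
        _, model, _ = tiny_net_and_training
        with pytest.raises(ValueError):
            predict_mask(model, small_cohort_module[0].image, threshold=1.5)

    def test_checkpoint_roundtrip(self, tiny_net_and_training, small_cohort_module,
                                  tmp_path):
        _, model, _ = tiny_net_and_training
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        a = predict_mask(model, small_cohort_module[7].image)
        b = predict_mask(back, small_cohort_module[7].image)
        np.testing.assert_array_equal(a.data, b.data)


class TestSegTrainState:
    def test_history_length_must_match(self):
        with pytest.raises(ValueError):
            SegTrainState(epoch=3, loss_history=[1.0], val_dice_history=[], seed=0)
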