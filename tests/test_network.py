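"""U-Net construction, training contracts, prediction determinism."""

import numpy as np
import pytest

from pavision.network import (PRESETS, TrainConfig, UNetSpec, build_unet,
                              load_model, predict, pretrain_finetune,
                              save_model, train)
from pavision.phantoms import PairedDataset


def toy_dataset(rng, n=6, size=16, splits=None):
    x = rng.standard_normal((n, size, size)).astype(np.float32)
    y = rng.random((n, size, size)).astype(np.float32)
    if splits is None:
        splits = {"train": np.arange(n)}
    return PairedDataset(x, y, splits, 40.0, np.arange(n))


class TestBuildUnet:
    def test_output_shape_matches_input(self, rng):
        model = build_unet(UNetSpec(depth=2, base_filters=4))
        x = rng.standard_normal((2, 1, 32, 32)).astype(np.float32)
        assert model.net.forward(x).shape == (2, 1, 32, 32)

    def test_indivisible_input_rejected(self, rng):
        model = build_unet(UNetSpec(depth=3, base_filters=4))
        with pytest.raises(ValueError, match="divisible"):
            model.net.forward(rng.standard_normal((1, 1, 20, 20)).astype(np.float32))

    def test_full_preset_parameter_count_near_30M(self):
        n = build_unet(PRESETS["full"]).n_parameters()
        assert abs(n - 3.0e7) / 3.0e7 < 0.10

    def test_reduced_preset_is_an_order_of_magnitude_smaller(self):
        n_full = build_unet(PRESETS["full"]).n_parameters()
        n_red = build_unet(PRESETS["reduced"]).n_parameters()
        assert n_red < n_full / 10

    def test_parameter_count_matches_layer_closed_form(self):
        # conv(cin->cout,k): k*k*cin*cout + cout; BN: 2c; convT(2x2): 4*cin*cout + cout
        def conv(ci, co, k=3):
            return k * k * ci * co + co

        def double(ci, co):
            return conv(ci, co) + conv(co, co) + 2 * co + 2 * co

        def up(ci, co):
            return 4 * ci * co + co

        b, d = 16, 4
        total = double(1, b)
        for i in range(1, d):
            total += double(b * 2 ** (i - 1), b * 2 ** i)
        total += double(b * 2 ** (d - 1), b * 2 ** d)
        for i in reversed(range(d)):
            total += up(b * 2 ** (i + 1), b * 2 ** i) + double(b * 2 ** (i + 1), b * 2 ** i)
        total += conv(b, 1, 1)
        assert build_unet(PRESETS["reduced"]).n_parameters() == total

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError, match="out_channels"):
            UNetSpec(out_channels=2)
        with pytest.raises(ValueError, match="activation"):
            UNetSpec(final_activation="sigmoid")


class TestTraining:
    def test_overfits_single_pair(self, rng):
        # a network with enough capacity must drive the MSE of one pair down
        ds = toy_dataset(rng, n=1, size=16)
        model = build_unet(UNetSpec(depth=2, base_filters=8, dropout_rate=0.0),
                           seed=0)
        x, y = ds.subset("train")
        init_mse = float(np.mean((model.net.forward(x)[:, 0] - y) ** 2))
        model = train(model, ds, TrainConfig(lr=2e-3, batch_size=1,
                                             max_epochs=500, seed=0), val_split=None)
        final_mse = model.history["train_loss"][-1]
        assert final_mse < 1e-3 * init_mse

    def test_zero_epoch_budget_leaves_weights_unchanged(self, rng):
        ds = toy_dataset(rng)
        model = build_unet(UNetSpec(depth=2, base_filters=4), seed=1)
        before = [p.value.copy() for p in model.net.params()]
        model = train(model, ds, TrainConfig(max_epochs=0))
        for b, p in zip(before, model.net.params()):
            np.testing.assert_array_equal(b, p.value)

    def test_restored_weights_hit_min_val_loss(self, rng):
        ds = toy_dataset(rng, n=8, splits={"train": np.arange(6),
                                           "val": np.arange(6, 8)})
        model = build_unet(UNetSpec(depth=2, base_filters=4, dropout_rate=0.3),
                           seed=2)
        model = train(model, ds, TrainConfig(max_epochs=15,
                                             early_stopping_patience=15, seed=0))
        x_va, y_va = ds.subset("val")
        restored = float(np.mean((model.net.forward(x_va)[:, 0] - y_va) ** 2))
        assert restored == pytest.approx(min(model.history["val_loss"]), rel=1e-5)

    def test_training_reproducible_for_fixed_seed(self, rng):
        ds = toy_dataset(rng)
        outs = []
        for _ in range(2):
            m = build_unet(UNetSpec(depth=2, base_filters=4, dropout_rate=0.2),
                           seed=3)
            m = train(m, ds, TrainConfig(max_epochs=3, seed=11), val_split=None)
            outs.append(m.net.forward(ds.inputs[:1]))
        np.testing.assert_array_equal(outs[0], outs[1])


class TestPredict:
    def test_prediction_deterministic_with_dropout_off(self, rng):
        model = build_unet(UNetSpec(depth=2, base_filters=4, dropout_rate=0.5))
        x = rng.standard_normal((16, 16)).astype(np.float32)
        np.testing.assert_array_equal(predict(model, x), predict(model, x))

    def test_batched_equals_per_image(self, rng):
        model = build_unet(UNetSpec(depth=2, base_filters=4))
        xs = rng.standard_normal((3, 16, 16)).astype(np.float32)
        batched = predict(model, xs)
        single = np.stack([predict(model, x) for x in xs])
        np.testing.assert_allclose(batched, single, atol=1e-6)

    def test_input_scale_invariance_from_normalization(self, rng):
        # inputs are max-|value|-normalized, so a global rescale cannot change
        # the prediction
        model = build_unet(UNetSpec(depth=2, base_filters=4))
        x = rng.standard_normal((16, 16)).astype(np.float32)
        # float32 normalization rounding (x/m vs 7.5x/(7.5m)) leaves ~1e-5
        np.testing.assert_allclose(predict(model, x), predict(model, 7.5 * x),
                                   atol=1e-4)


class TestCheckpointAndTransfer:
    def test_save_load_roundtrip(self, rng, tmp_path):
        ds = toy_dataset(rng)
        model = build_unet(UNetSpec(depth=2, base_filters=4), seed=4)
        model = train(model, ds, TrainConfig(max_epochs=2, seed=0), val_split=None)
        path = str(tmp_path / "model")
        save_model(model, path)
        back = load_model(path)
        x = ds.inputs[:2]
        np.testing.assert_allclose(predict(model, x), predict(back, x), atol=1e-7)

    def test_empty_finetune_returns_pretrained(self, rng):
        sim = toy_dataset(rng)
        exp = toy_dataset(rng, n=2, splits={"test": np.arange(2)})
        model = build_unet(UNetSpec(depth=2, base_filters=4), seed=5)
        model = pretrain_finetune(model, sim, exp,
                                  TrainConfig(max_epochs=2, seed=0))
        w_pre = [p.value.copy() for p in model.net.params()]
        assert model.provenance["pretrain_history"]["train_loss"]
        # second call fine-tuning on nothing must leave weights alone
        model2 = pretrain_finetune(model, sim, exp, TrainConfig(max_epochs=0))
        for a, p in zip(w_pre, model2.net.params()):
            np.testing.assert_array_equal(a, p.value)

    def test_zero_lr_finetune_keeps_pretrained_weights(self, rng):
        sim = toy_dataset(rng)
        exp = toy_dataset(rng, n=4)
        model = build_unet(UNetSpec(depth=2, base_filters=4), seed=6)
        model = train(model, sim, TrainConfig(max_epochs=2, seed=0), val_split=None)
        before = [p.value.copy() for p in model.net.params()]
        model = pretrain_finetune(build_unet(UNetSpec(depth=2, base_filters=4), seed=6),
                                  sim, exp, TrainConfig(max_epochs=2, seed=0),
                                  finetune_cfg=TrainConfig(lr=0.0, max_epochs=2))
        for b, p in zip(before, model.net.params()):
            np.testing.assert_array_equal(b, p.value)
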