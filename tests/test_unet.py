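"""Network architecture, loss, thresholding, stopping rule, and training."""

import numpy as np
import pytest

from vesselseg import unet as U
from vesselseg.phantom import PhantomSpec, generate_dataset, generate_phantom


def closed_form_parameter_count(base_width: int, depth: int, n_out: int) -> int:
    """Independent per-layer arithmetic: sum of filters x (kernel_area x
    in_channels + 1) over the whole architecture."""
    total = 0
    widths = [base_width * 2 ** i for i in range(depth)]
    c_in = 1
    for w in widths:
        total += w * (9 * c_in + 1) + w * (9 * w + 1)
        c_in = w
    for w in reversed(widths[:-1]):
        total += w * (4 * c_in + 1)            # 2x2 up-convolution
        total += w * (9 * 2 * w + 1)           # after skip concatenation
        total += w * (9 * w + 1)
        c_in = w
    total += 2 * (9 * c_in + 1)                # penultimate 3x3 to 2 channels
    total += n_out * (2 + 1)                   # 1x1 head
    return total


class TestArchitecture:
    def test_full_scale_binary_parameter_count(self):
        _, count = U.build_model(U.full_scale_config(n_out=1))
        assert count == 31_031_685

    def test_full_scale_multiclass_parameter_count(self):
        _, count = U.build_model(U.full_scale_config(n_out=3))
        assert count == 31_031_691

    @pytest.mark.parametrize("base,n_out", [(8, 1), (8, 3), (16, 1)])
    def test_count_matches_per_layer_arithmetic(self, base, n_out):
        cfg = U.UNetConfig(input_shape=(128, 128), base_width=base, n_out=n_out)
        _, count = U.build_model(cfg)
        assert count == closed_form_parameter_count(base, 5, n_out)

    def test_eighteen_hidden_layers(self):
        model, _ = U.build_model(U.test_scale_config())
        assert model.hidden_layer_count == 18

    def test_indivisible_input_rejected_with_padding_hint(self):
        with pytest.raises(ValueError, match="pad"):
            U.UNetConfig(input_shape=(100, 100))

    def test_multiclass_probabilities_sum_to_one(self):
        model, _ = U.build_model(U.UNetConfig(input_shape=(32, 32), depth=3,
                                              base_width=4, n_out=3), seed=0)
        x = np.random.default_rng(0).standard_normal((2, 32, 32, 1)).astype(np.float32)
        p = model.forward(x)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-5)
        assert p.min() >= 0.0 and p.max() <= 1.0


class TestDiceLoss:
    def test_perfect_and_inverted_predictions(self):
        t = (np.random.default_rng(0).random((8, 8)) < 0.5).astype(float)
        assert U.dice_loss(t, t) == pytest.approx(0.0, abs=1e-5)
        assert U.dice_loss(1 - t, t) == pytest.approx(1.0, abs=1e-5)

    def test_four_pixel_toy_hand_value(self):
        p = np.full(4, 0.5)
        t = np.array([1.0, 1.0, 0.0, 0.0])
        eps = U.DICE_EPS
        expected = 1 - (2 * 1.0 + eps) / (2.0 + 2.0 + eps)
        assert U.dice_loss(p, t) == pytest.approx(expected, abs=1e-12)
        assert U.dice_loss(p, t) == pytest.approx(0.5, abs=1e-5)

    def test_gradient_matches_finite_differences(self):
        """End-to-end backprop check on a tiny float64 network."""
        rng = np.random.default_rng(0)
        cfg = U.UNetConfig(input_shape=(16, 16), depth=3, base_width=2, n_out=1)
        model, _ = U.build_model(cfg, seed=1)
        for layer in model.layers():
            layer.W = layer.W.astype(np.float64)
            layer.b = layer.b.astype(np.float64)
            layer.dW = np.zeros_like(layer.W)
            layer.db = np.zeros_like(layer.b)
        x = rng.standard_normal((2, 16, 16, 1))
        t = (rng.random((2, 16, 16, 1)) < 0.3).astype(np.float64)
        model.zero_grad()
        p = model.forward(x, train=True)
        model.backward(U._dice_loss_grad(p, t))
        for layer in model.layers():
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in layer.W.shape)
                h, orig = 1e-6, layer.W[idx]
                layer.W[idx] = orig + h
                lp = U.dice_loss(model.forward(x), t)
                layer.W[idx] = orig - h
                lm = U.dice_loss(model.forward(x), t)
                layer.W[idx] = orig
                num = (lp - lm) / (2 * h)
                ana = layer.dW[idx]
                assert ana == pytest.approx(num, rel=1e-3, abs=1e-9)


class TestThreshold:
    def test_paper_boundary_semantics(self):
        assert U.threshold(np.array([0.5]))[0] == 1    # exactly 0.5 -> 1
        assert U.threshold(np.array([0.4999]))[0] == 0
        assert U.threshold(np.full((3, 3), 0.49)).sum() == 0

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = rng.random((16, 16))
        once = U.threshold(m)
        np.testing.assert_array_equal(U.threshold(once.astype(float)), once)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        m = rng.random((32, 32))
        oracle = np.array([[0 if v < 0.5 else 1 for v in row] for row in m])
        np.testing.assert_array_equal(U.threshold(m), oracle)

    def test_multiclass_argmax_masks(self):
        p = np.zeros((2, 2, 3))
        p[..., 0] = 0.2
        p[0, :, 1] = 0.7
        p[1, :, 2] = 0.7
        masks = U.multiclass_masks(p)
        assert masks["lumen"][0].all() and not masks["lumen"][1].any()
        assert masks["spine"][1].all() and not masks["spine"][0].any()


class TestStoppingRule:
    def test_reference_history_stops_after_sixth_epoch(self):
        hist = [0.50, 0.70, 0.800, 0.8005, 0.8003, 0.8004]
        assert U.should_stop(hist, window=3, tol=1e-3)
        assert not U.should_stop(hist[:5], window=3, tol=1e-3)

    def test_needs_window_plus_one_epochs(self):
        assert not U.should_stop([0.5, 0.5001, 0.5002], window=3, tol=1e-3)

    def test_large_changes_keep_training(self):
        assert not U.should_stop([0.1, 0.3, 0.5, 0.7, 0.9], window=3, tol=1e-3)


class TestTraining:
    @staticmethod
    def _tiny_dataset(n=10, seed=0):
        rng = np.random.default_rng(seed)
        pairs = []
        for _ in range(n):
            img = rng.standard_normal((32, 32)).astype(np.float32)
            mask = np.zeros((32, 32), dtype=np.uint8)
            r, c = rng.integers(8, 24, 2)
            mask[r - 4:r + 4, c - 4:c + 4] = 1
            img += mask * 2.0
            pairs.append((img, mask))
        return pairs

    def test_same_seed_reproduces_history_and_weights(self):
        cfg = U.UNetConfig(input_shape=(32, 32), depth=3, base_width=4)
        tcfg = U.TrainingConfig(learning_rate=1e-3, max_epochs=2, seed=3)
        runs = []
        for _ in range(2):
            m, _ = U.build_model(cfg, seed=3)
            runs.append(U.train(m, self._tiny_dataset(), tcfg))
        assert runs[0].history == runs[1].history
        for la, lb in zip(runs[0].model.layers(), runs[1].model.layers()):
            np.testing.assert_array_equal(la.W, lb.W)

    def test_empty_dataset_rejected(self):
        m, _ = U.build_model(U.UNetConfig(input_shape=(32, 32), depth=3, base_width=4))
        with pytest.raises(ValueError):
            U.train(m, [], U.TrainingConfig())

    def test_desk_scale_training_reaches_heldout_dice(self, model_factory):
        """Bootstrap training on expert-labelled phantom slices reaches a
        held-out monitored Dice of at least 0.8 at desk scale."""
        result = model_factory(0)["lumen"][1]
        assert max(result.history) >= 0.8
        assert result.stop_reason in ("max_epochs", "dice-stagnation")

    def test_checkpoint_round_trip(self, tmp_path):
        cfg = U.UNetConfig(input_shape=(32, 32), depth=3, base_width=4)
        m, _ = U.build_model(cfg, seed=7)
        p = U.save_model(m, tmp_path / "m.npz")
        back = U.load_model(p)
        assert back.cfg == m.cfg
        x = np.random.default_rng(0).standard_normal((1, 32, 32, 1)).astype(np.float32)
        np.testing.assert_allclose(back.forward(x), m.forward(x), atol=1e-6)


class TestBinaryVsMulticlass:
    def test_two_binary_models_beat_multiclass_on_average(self):
        """Architecture comparison at small scale: over >=3 seeds, the mean
        held-out Dice of two binary (lumen, spine) models is at least the
        multi-class model's mean."""
        spec = PhantomSpec(slice_shape=(64, 64), spacing=(1.6, 1.6, 2.0),
                           n_slices=16)
        train_ds = generate_dataset(2, spec, {"lumen_radius_mm": (7.0, 9.0)}, seed=31)
        test_vol, test_masks = generate_phantom(
            PhantomSpec(slice_shape=(64, 64), spacing=(1.6, 1.6, 2.0),
                        n_slices=16, seed=77))

        def pairs(target):
            out = []
            for _, vol, masks in train_ds:
                norm = U.normalize_volume(vol.voxels)
                for z in range(vol.n_slices):
                    if target == "multiclass":
                        lab = (masks["lumen"].voxels[z].astype(np.int64)
                               + 2 * masks["spine"].voxels[z].astype(np.int64))
                        out.append((norm[z], lab))
                    else:
                        out.append((norm[z], masks[target].voxels[z]))
            return out

        x_test = U.normalize_volume(test_vol.voxels)
        binary_scores, multi_scores = [], []
        for seed in range(3):
            tcfg = U.test_scale_training_config(max_epochs=4, seed=seed)
            per_class = {}
            for target in ("lumen", "spine"):
                m, _ = U.build_model(U.test_scale_config(
                    n_out=1, input_shape=(64, 64)), seed=seed)
                U.train(m, pairs(target), tcfg)
                pred = np.stack([U.threshold(U.predict(m, s)) for s in x_test])
                from vesselseg.metrics import evaluate
                per_class[target] = evaluate(pred, test_masks[target].voxels).dice
            binary_scores.append(np.mean(list(per_class.values())))

            m3, _ = U.build_model(U.test_scale_config(
                n_out=3, input_shape=(64, 64)), seed=seed)
            U.train(m3, pairs("multiclass"), tcfg)
            from vesselseg.metrics import evaluate
            scores = []
            for z_target, name in ((1, "lumen"), (2, "spine")):
                pred = np.stack([(U.predict(m3, s).argmax(-1) == z_target).astype(np.uint8)
                                 for s in x_test])
                scores.append(evaluate(pred, test_masks[name].voxels).dice)
            multi_scores.append(np.mean(scores))
        assert np.mean(binary_scores) >= np.mean(multi_scores)
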