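"""Network construction, losses, training behavior and inference contracts."""

import numpy as np
import pytest
from dataclasses import replace

from carieseg import (
    CariesMask,
    ModelConfig,
    Radiograph,
    TrainConfig,
    ValidationError,
    build_model,
    generate_phantom,
    load_model,
    penalty_loss,
    predict,
    resize_to_input,
    save_model,
    train,
)
from carieseg.nn import UNet, softmax, softmax_ce_loss
from carieseg.segnet import TrainedModel

TINY = ModelConfig(n_classes=2, input_size=(32, 32), depth=3, base_width=4, seed=0)


class TestBuildModel:
    def test_output_shape_and_softmax_rows(self):
        net = build_model(TINY)
        x = np.random.default_rng(0).random((1, 1, 32, 32)).astype(np.float32)
        prob = softmax(net.forward(x))
        assert prob.shape == (1, 2, 32, 32)
        np.testing.assert_allclose(prob.sum(axis=1), 1.0, atol=1e-5)

    def test_same_seed_same_init(self):
        a, b = build_model(TINY), build_model(TINY)
        for x, y in zip(a.state_arrays(), b.state_arrays()):
            assert np.array_equal(x, y)

    def test_incompatible_input_size_rejected(self):
        with pytest.raises(ValidationError):
            build_model(ModelConfig(n_classes=2, input_size=(30, 30), depth=3))

    def test_gradients_match_numeric(self):
        """Analytic backprop against central differences on a tiny net."""
        net = UNet(n_classes=2, depth=2, base_width=3, seed=1)
        x = np.random.default_rng(2).random((1, 1, 8, 8)).astype(np.float32)
        t = (np.random.default_rng(3).random((1, 8, 8)) > 0.6).astype(np.int64)
        _, dlog = softmax_ce_loss(net.forward(x), t)
        net.backward(dlog)
        for pi in (0, 3, -1):
            name, layer = net.params()[pi]
            arr, grad = getattr(layer, name), getattr(layer, "d" + name)
            flat = arr.ravel()
            j = flat.size // 2
            eps = 1e-3
            old = flat[j]
            flat[j] = old + eps
            l1, _ = softmax_ce_loss(net.forward(x), t)
            flat[j] = old - eps
            l2, _ = softmax_ce_loss(net.forward(x), t)
            flat[j] = old
            num = (l1 - l2) / (2 * eps)
            assert abs(num - grad.ravel()[j]) <= 2e-2 * max(1.0, abs(num))


class TestResizeToInput:
    def test_constant_full_scale_maps_to_one(self):
        rad = Radiograph(pixels=np.full((64, 64), 4095, dtype=np.uint16))
        out = resize_to_input(rad, TINY)
        np.testing.assert_allclose(out, 1.0, atol=1e-6)
        assert out.shape == (32, 32)

    def test_native_size_only_rescales(self):
        pix = np.random.default_rng(0).integers(0, 4096, (32, 32)).astype(np.uint16)
        out = resize_to_input(Radiograph(pixels=pix), TINY)
        np.testing.assert_allclose(out, pix / 4095.0, atol=1e-6)

    def test_downscale_preserves_plateaus(self):
        """Brute-force bilinear oracle: a half-bright/half-dark image keeps its
        two plateau values away from the boundary."""
        pix = np.zeros((64, 64), dtype=np.uint16)
        pix[:, 32:] = 4000
        out = resize_to_input(Radiograph(pixels=pix), TINY)
        np.testing.assert_allclose(out[:, :12], 0.0, atol=1e-6)
        np.testing.assert_allclose(out[:, 20:], 4000 / 4095, atol=1e-6)


class TestPenaltyLoss:
    def _uniform_prob(self, p_caries, shape=(8, 8)):
        prob = np.empty((2,) + shape)
        prob[1] = p_caries
        prob[0] = 1 - p_caries
        return prob

    def test_empty_target_zero_prediction_no_penalty(self):
        prob = self._uniform_prob(0.0)
        target = np.zeros((8, 8), dtype=np.uint8)
        base = penalty_loss(prob, target, fp_penalty=0.0)
        assert penalty_loss(prob, target, fp_penalty=5.0) == pytest.approx(base)

    def test_lambda_zero_is_cross_entropy(self):
        rng = np.random.default_rng(0)
        p = rng.random((8, 8)) * 0.8 + 0.1
        prob = np.stack([1 - p, p])
        target = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        expected = -np.where(target == 1, np.log(p), np.log(1 - p)).mean()
        assert penalty_loss(prob, target, fp_penalty=0.0) == pytest.approx(expected)

    def test_uniform_half_adds_half(self):
        prob = self._uniform_prob(0.5)
        target = np.zeros((8, 8), dtype=np.uint8)
        l0 = penalty_loss(prob, target, fp_penalty=0.0)
        l1 = penalty_loss(prob, target, fp_penalty=1.0)
        assert l1 - l0 == pytest.approx(0.5)

    def test_monotone_in_lambda_on_caries_free_input(self):
        rng = np.random.default_rng(1)
        p = rng.random((8, 8)) * 0.5
        prob = np.stack([1 - p, p])
        target = np.zeros((8, 8), dtype=np.uint8)
        losses = [penalty_loss(prob, target, fp_penalty=lam) for lam in (0, 0.5, 1, 2)]
        assert losses == sorted(losses)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            penalty_loss(np.zeros((2, 8, 8)), np.zeros((4, 4), dtype=np.uint8))


class TestTrain:
    def _tiny_pairs(self, small_spec, n, offset=0):
        spec = replace(small_spec, image_size=(32, 32), n_teeth=1, lesion_count=(1, 1))
        out = []
        for s in range(offset, offset + n):
            rad, _, caries, _ = generate_phantom(spec, s)
            out.append((rad, caries.mask))
        return out

    def test_loss_descends_and_best_epoch_is_argmin(self, small_spec):
        pairs = self._tiny_pairs(small_spec, 10)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=6, fp_penalty=0.0,
                          batch_size=4, rng_seed=0)
        trained = train(build_model(TINY), pairs[:8], pairs[8:], cfg, TINY)
        losses = [e["train_loss"] for e in trained.log]
        assert losses[-1] < losses[0]
        errs = [e["val_error"] for e in trained.log]
        assert trained.optimal_epoch == int(np.argmin(errs)) + 1

    def test_empty_sets_rejected(self, small_spec):
        pairs = self._tiny_pairs(small_spec, 2)
        cfg = TrainConfig(learning_rate=1e-3, max_epochs=1)
        with pytest.raises(ValidationError):
            train(build_model(TINY), [], pairs, cfg, TINY)
        with pytest.raises(ValidationError):
            train(build_model(TINY), pairs, [], cfg, TINY)

    def test_memorization_capacity(self, small_spec):
        """A width-reduced net drives training loss near zero on 2 phantoms."""
        pairs = self._tiny_pairs(small_spec, 2)
        cfg = TrainConfig(learning_rate=3e-3, max_epochs=80, fp_penalty=0.0,
                          batch_size=2, rng_seed=0)
        trained = train(build_model(TINY), pairs, pairs, cfg, TINY)
        assert min(e["train_loss"] for e in trained.log) < 0.03


class TestPredictAndCheckpoint:
    def test_predict_normalized_and_deterministic(self, small_spec):
        spec = replace(small_spec, image_size=(48, 48), n_teeth=1)
        rad, _, _, _ = generate_phantom(spec, 0)
        net = build_model(TINY)
        tm = TrainedModel(config=TINY, state=net.get_state(), optimal_epoch=0)
        p1 = predict(tm, rad)
        p2 = predict(tm, rad)
        assert p1.shape == (2, 48, 48)
        np.testing.assert_allclose(p1.sum(axis=0), 1.0, atol=1e-5)
        assert np.array_equal(p1, p2)

    def test_checkpoint_round_trip(self, tmp_path, small_spec):
        net = build_model(TINY)
        tm = TrainedModel(config=TINY, state=net.get_state(), optimal_epoch=3,
                          log=[{"epoch": 1, "train_loss": 0.5, "val_error": 0.1}])
        path = str(tmp_path / "m.ckpt.npz")
        save_model(tm, path)
        back = load_model(path)
        assert back.config == TINY
        assert back.optimal_epoch == 3
        for a, b in zip(tm.state, back.state):
            assert np.array_equal(a, b)
        spec = replace(small_spec, image_size=(32, 32), n_teeth=1)
        rad, _, _, _ = generate_phantom(spec, 1)
        assert np.array_equal(predict(tm, rad), predict(back, rad))
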