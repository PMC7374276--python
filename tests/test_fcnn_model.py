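"""The counting network: architecture contracts, gradients, training."""

import numpy as np
import pytest

from cellcount.count_targets import CountMapSpec, pad_image
from cellcount.fcnn_model import (
    ConfigurationError,
    FCNN,
    ModelSpec,
    TrainConfig,
    build_model,
    default_large_kernels,
    load_checkpoint,
    predict_count_map,
    save_checkpoint,
    train,
)
from cellcount._nn import l2_loss_grad
from cellcount.image_io import RasterImage, luma_grayscale
from cellcount.synthetic_data import SyntheticConfig, generate_scene
from cellcount.tiling import quadrant_pairs

TINY = ModelSpec(
    kernel_size=13, n_inception_blocks=1, stem_kernel=3, stem_channels=4,
    inception_channels=2, chokepoint_channels=2,
    large_kernels=(5, 5), large_channels=(3, 3),
)
TINY_FFT = ModelSpec(  # same receptive field budget, exercises the FFT conv path
    kernel_size=13, n_inception_blocks=1, stem_kernel=3, stem_channels=4,
    inception_channels=2, chokepoint_channels=2,
    large_kernels=(7, 7), large_channels=(3, 3),
)


def _tiny_pairs(n_scenes=2, seed=0):
    pairs = []
    for i in range(n_scenes):
        scene = generate_scene(
            SyntheticConfig(height=48, width=48, n_cells=6, seed=seed + i)
        )
        pairs.extend(quadrant_pairs(luma_grayscale(scene.image), scene.annotations))
    return pairs


class TestArchitecture:
    def test_reference_receptive_field_is_analytic_sum(self):
        spec = ModelSpec.reference(65)
        # stem 3 + five inception blocks (+2 each) + two 27x27 convs (+26 each)
        assert spec.receptive_field == 3 + 5 * 2 + 26 + 26 == 65

    def test_compact_receptive_field_covers_kernel(self):
        assert ModelSpec.compact(33).receptive_field == 33

    def test_default_report_lists_five_inception_blocks(self):
        report = ModelSpec.reference().describe()
        assert report.count("inception block") == 5
        assert "chokepoint 2" in report

    @pytest.mark.parametrize("k", list(range(13, 83, 2)))
    def test_derived_large_kernels_always_reach_k(self, k):
        l1, l2 = default_large_kernels(k)
        assert l1 % 2 == 1 and l2 % 2 == 1
        spec = ModelSpec(kernel_size=k, large_kernels=(l1, l2))
        assert spec.receptive_field >= k

    def test_insufficient_receptive_field_is_configuration_error(self):
        bad = ModelSpec(kernel_size=65, large_kernels=(3, 3))
        with pytest.raises(ConfigurationError):
            build_model(bad)

    def test_output_preserves_spatial_shape(self):
        model = build_model(TINY, seed=0)
        out = model.forward(np.zeros((1, 30, 41), dtype=np.float32), train=False)
        assert out.shape == (1, 30, 41)


@pytest.mark.parametrize("spec", [TINY, TINY_FFT], ids=["im2col", "fft"])
def test_analytic_gradient_matches_directional_derivative(spec):
    """Backprop through the whole network agrees with a central-difference
    directional derivative along the gradient (robust to float32 noise on
    individual tiny components)."""
    model = build_model(spec, seed=5)
    rng = np.random.default_rng(1)
    x = rng.uniform(0.1, 0.9, (1, 14, 14)).astype(np.float32)
    t = rng.uniform(0, 2, (1, 14, 14)).astype(np.float32)

    pred = model.forward(x, train=True)
    _, d_pred = l2_loss_grad(pred, t)
    model.backward(d_pred)

    grads = [g.copy() for _, g in model.parameters()]
    norm = np.sqrt(sum(float((g**2).sum()) for g in grads))
    assert norm > 0
    direction = [g / norm for g in grads]

    eps = 1e-3
    def loss_at(shift: float) -> float:
        for (p, _), d in zip(model.parameters(), direction):
            p += shift * d
        val, _ = l2_loss_grad(model.forward(x, train=True), t)
        for (p, _), d in zip(model.parameters(), direction):
            p -= shift * d
        return val

    numeric = (loss_at(eps) - loss_at(-eps)) / (2 * eps)
    # the directional derivative along g/|g| is exactly |g|
    assert numeric == pytest.approx(norm, rel=0.02)


class TestLayerGradients:
    """Finite-difference checks of each layer type in isolation."""

    def test_batchnorm_input_gradient(self):
        from cellcount._nn import BatchNorm

        rng = np.random.default_rng(0)
        bn = BatchNorm(2)
        bn.gamma[...] = rng.uniform(0.5, 1.5, 2)
        x = rng.uniform(-1, 1, (2, 5, 5)).astype(np.float32)
        a = rng.uniform(-1, 1, (2, 5, 5)).astype(np.float32)
        bn.forward(x, train=True)
        dx = bn.backward(a)
        eps = 1e-3
        for i in [(0, 1, 2), (1, 4, 4), (0, 0, 0)]:
            orig = x[i]
            x[i] = orig + eps
            up = float((a * bn.forward(x, True)).sum())
            x[i] = orig - eps
            dn = float((a * bn.forward(x, True)).sum())
            x[i] = orig
            assert (up - dn) / (2 * eps) == pytest.approx(float(dx[i]), abs=3e-3)

    @pytest.mark.parametrize("k", [1, 3, 7], ids=["matmul", "im2col", "fft"])
    def test_conv_weight_and_input_gradients(self, k):
        from cellcount._nn import Conv2d

        rng = np.random.default_rng(3)
        conv = Conv2d(2, 3, k, rng)
        x = rng.uniform(-1, 1, (2, 8, 8)).astype(np.float32)
        a = rng.uniform(-1, 1, (3, 8, 8)).astype(np.float32)
        conv.forward(x, train=True)
        dx = conv.backward(a)
        g = conv.d_weight.copy()
        eps = 1e-3
        for i in [np.unravel_index(j, conv.weight.shape) for j in (0, 1)]:
            orig = conv.weight[i]
            conv.weight[i] = orig + eps
            up = float((a * conv.forward(x, True)).sum())
            conv.weight[i] = orig - eps
            dn = float((a * conv.forward(x, True)).sum())
            conv.weight[i] = orig
            assert (up - dn) / (2 * eps) == pytest.approx(float(g[i]), abs=3e-3)
        for i in [(0, 3, 3), (1, 0, 7)]:
            orig = x[i]
            x[i] = orig + eps
            up = float((a * conv.forward(x, True)).sum())
            x[i] = orig - eps
            dn = float((a * conv.forward(x, True)).sum())
            x[i] = orig
            assert (up - dn) / (2 * eps) == pytest.approx(float(dx[i]), abs=3e-3)


def test_gradient_support_within_theoretical_receptive_field():
    """Perturbing one input pixel only moves outputs inside the RF box."""
    model = build_model(TINY, seed=2)
    x = np.random.default_rng(0).uniform(0.2, 0.8, (1, 40, 40)).astype(np.float32)
    base = model.forward(x, train=False)
    r = c = 20
    x2 = x.copy()
    x2[0, r, c] += 0.5
    diff = np.abs(model.forward(x2, train=False) - base)[0]
    moved = np.argwhere(diff > 1e-7)
    assert moved.size > 0  # the perturbation is visible at all
    half = TINY.receptive_field // 2
    assert (np.abs(moved - [r, c]) <= half).all()


class TestClippedLoss:
    """The calibration loss trains the zero-clipped output."""

    def test_zero_target_below_zero_is_silent(self):
        from cellcount._nn import clipped_l2_loss_grad

        pred = np.array([[-0.5, -0.01]], dtype=np.float32)
        target = np.zeros_like(pred)
        loss, grad = clipped_l2_loss_grad(pred, target)
        assert loss == 0.0
        assert np.all(grad == 0.0)  # raw output may rest below zero freely

    def test_positive_target_leaks_gradient_through_clip(self):
        from cellcount._nn import clipped_l2_loss_grad

        pred = np.array([[-1.0]], dtype=np.float32)
        target = np.array([[2.0]], dtype=np.float32)
        loss, grad = clipped_l2_loss_grad(pred, target, leak=0.1)
        assert loss == 4.0  # (clip(-1) - 2)^2
        assert grad[0, 0] == pytest.approx(2 * (0.0 - 2.0) * 0.1)  # upward push

    def test_positive_side_matches_plain_mse(self):
        from cellcount._nn import clipped_l2_loss_grad, l2_loss_grad

        rng = np.random.default_rng(0)
        pred = rng.uniform(0.1, 3.0, (4, 5)).astype(np.float32)
        target = rng.uniform(0.0, 3.0, (4, 5)).astype(np.float32)
        l_c, g_c = clipped_l2_loss_grad(pred, target)
        l_p, g_p = l2_loss_grad(pred, target)
        assert l_c == pytest.approx(l_p)
        assert np.allclose(g_c, g_p)


class TestTrain:
    def test_zero_epochs_is_noop(self):
        model = build_model(TINY, seed=0)
        before = model.get_state()
        res = train(model, _tiny_pairs(), TrainConfig(epochs=0, seed=0), CountMapSpec(13))
        assert res.train_losses == [] and res.val_losses == []
        assert res.best_epoch == 0
        for a, b in zip(model.get_state(), before):
            assert np.array_equal(a, b)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train(build_model(TINY), [], TrainConfig(epochs=1), CountMapSpec(13))

    def test_fixed_seed_reproducible_loss_curves(self):
        pairs = _tiny_pairs()
        curves = []
        for _ in range(2):
            model = build_model(TINY, seed=3)
            res = train(
                model, pairs, TrainConfig(epochs=2, seed=3, augment=False),
                CountMapSpec(13),
            )
            curves.append((res.train_losses, res.val_losses))
        assert curves[0] == curves[1]

    def test_loss_decreases_and_best_epoch_is_argmin(self):
        model = build_model(TINY, seed=4)
        res = train(
            model, _tiny_pairs(4, seed=10),
            TrainConfig(epochs=12, seed=4, augment=False, loss="mse"),
            CountMapSpec(13),
        )
        assert len(res.val_losses) == 12
        assert res.val_losses[-1] < res.val_losses[0]
        assert res.best_epoch == int(np.argmin(res.val_losses)) + 1

    def test_augmentation_quadruples_samples_seen(self):
        # with rotations on, one epoch performs 4x as many updates; verify
        # through the optimizer step counter
        from cellcount._nn import Adam

        pairs = _tiny_pairs(1)
        cfg_plain = TrainConfig(epochs=1, seed=0, augment=False, validation_fraction=0.0)
        cfg_aug = TrainConfig(epochs=1, seed=0, augment=True, validation_fraction=0.0)
        losses = {}
        for name, cfg in (("plain", cfg_plain), ("aug", cfg_aug)):
            model = build_model(TINY, seed=0)
            res = train(model, pairs, cfg, CountMapSpec(13))
            losses[name] = res.train_losses
        # both ran one epoch; the augmented run saw 16 samples vs 4
        assert len(losses["plain"]) == len(losses["aug"]) == 1
        assert losses["plain"] != losses["aug"]


class TestPrediction:
    def test_prediction_map_matches_padded_input_shape(self):
        model = build_model(TINY, seed=0)
        spec = CountMapSpec(13)
        img = RasterImage(pixels=np.zeros((30, 20), dtype=np.uint8))
        padded = pad_image(img, spec.pad)
        cm = predict_count_map(model, padded, spec)
        assert cm.values.shape == (42, 32)
        assert cm.kind == "prediction"

    def test_negative_outputs_clipped(self):
        model = build_model(TINY, seed=1)
        spec = CountMapSpec(13)
        img = RasterImage(
            pixels=np.random.default_rng(0).integers(0, 256, (40, 40), dtype=np.uint8)
        )
        raw = model.predict_map(img)
        cm = predict_count_map(model, img, spec)
        assert raw.min() < 0  # untrained nets do emit negatives
        assert cm.values.min() >= 0

    def test_kernel_mismatch_rejected(self):
        model = build_model(TINY, seed=0)
        img = RasterImage(pixels=np.zeros((20, 20), dtype=np.uint8))
        with pytest.raises(ValueError, match="does not match the model"):
            predict_count_map(model, img, CountMapSpec(65))

    def test_rgb_input_rejected(self):
        model = build_model(TINY, seed=0)
        img = RasterImage(pixels=np.zeros((20, 20, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="single-channel"):
            model.predict_map(img)


def test_checkpoint_round_trip(tmp_path):
    model = build_model(TINY_FFT, seed=6)
    spec = CountMapSpec(13)
    # dirty the batch-norm running stats so state is nontrivial
    train(model, _tiny_pairs(), TrainConfig(epochs=1, seed=6, augment=False), spec)
    path = tmp_path / "model.npz"
    save_checkpoint(model, spec, path, model_id="tiny")
    back, back_spec, model_id = load_checkpoint(path)
    assert model_id == "tiny"
    assert back_spec.kernel_size == 13
    assert back.spec == model.spec
    x = RasterImage(
        pixels=np.random.default_rng(2).integers(0, 256, (36, 36), dtype=np.uint8)
    )
    assert np.array_equal(back.predict_map(x), model.predict_map(x))
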