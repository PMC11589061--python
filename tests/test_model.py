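"""Window preprocessing, residual U-Net contracts, inference, composition."""

import numpy as np
import pytest

import kernelfuse as kf
from kernelfuse.model import (ModelConfig, WindowSetting, build_model,
                              compose_output, default_windows, infer,
                              load_checkpoint, preprocess, save_checkpoint,
                              window_normalize)


class TestWindowing:
    @pytest.mark.parametrize("name,level,width,hu,expected", [
        ("brain", 40, 80, 40.0, 0.0),
        ("brain", 40, 80, 80.0, 0.5),
        ("bone", 600, 2800, 600.0, 0.0),
        ("soft-tissue", 40, 400, 240.0, 0.5),
    ])
    def test_normalization_formula(self, name, level, width, hu, expected):
        w = WindowSetting(name, level=level, width=width)
        assert window_normalize(np.array([[hu]]), w)[0, 0] == pytest.approx(expected)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            WindowSetting("brain", 40, 0.0)

    def test_preprocess_builds_six_stable_channels(self, rng):
        s = rng.normal(40, 10, (16, 16))
        q = rng.normal(40, 50, (16, 16))
        a = preprocess(s, q)
        b = preprocess(s, q)
        assert a.shape == (1, 16, 16, 6)
        assert np.array_equal(a, b)

    def test_constant_level_input_zeroes_the_brain_channel(self):
        s = np.full((8, 8), 40.0)
        x = preprocess(s, s)
        assert np.all(x[0, :, :, 1] == 0.0)   # smooth input, brain window
        assert np.all(x[0, :, :, 4] == 0.0)   # sharp input, brain window


class TestNetworkContracts:
    def test_residual_identity_at_initialization(self, rng):
        # zero-initialized head -> the untrained model reproduces its anchor
        net = build_model(seed=0)      # default anchor: smooth-LD
        s = rng.normal(30, 10, (64, 64))
        q = rng.normal(30, 40, (64, 64))
        assert np.allclose(net.forward(s, q), s, atol=1e-3)

    def test_anchor_selection(self, rng):
        s = rng.normal(30, 10, (64, 64))
        q = rng.normal(30, 40, (64, 64))
        net = build_model(ModelConfig(anchor="sharp"), seed=0)
        assert np.allclose(net.forward(s, q), q, atol=1e-3)
        net = build_model(ModelConfig(anchor="mean"), seed=0)
        assert np.allclose(net.forward(s, q), 0.5 * (s + q), atol=1e-3)

    def test_same_seed_gives_identical_initial_weights(self):
        a = build_model(seed=9)
        b = build_model(seed=9)
        assert all(np.array_equal(p, q) for (p, _), (q, _) in
                   zip(a.parameters(), b.parameters()))
        c = build_model(seed=10)
        assert any(not np.array_equal(p, q) for (p, _), (q, _) in
                   zip(a.parameters(), c.parameters()))

    @pytest.mark.parametrize("size", [64, 128])
    def test_fully_convolutional_output_shape(self, rng, size):
        net = build_model(ModelConfig(filters=(4, 8, 16)), seed=1)
        s = rng.normal(30, 10, (size, size))
        assert net.forward(s, s).shape == (size, size)

    def test_patch_and_full_image_inference_agree_in_the_interior(self, rng):
        net = _perturbed_net(rng)
        s = rng.normal(30, 10, (128, 128)).astype(np.float32)
        q = rng.normal(30, 40, (128, 128)).astype(np.float32)
        full = net.forward(s, q)
        patch = net.forward(s[32:96, 32:96], q[32:96, 32:96])   # stride-aligned crop
        assert np.allclose(full[56:72, 56:72], patch[24:40, 24:40], atol=1e-3)

    def test_translation_covariance_for_stride_multiples(self, rng):
        net = _perturbed_net(rng)
        s = rng.normal(30, 10, (96, 96)).astype(np.float32)
        q = rng.normal(30, 40, (96, 96)).astype(np.float32)
        z = net.forward(s, q)
        zs = net.forward(np.roll(s, 4, axis=1), np.roll(q, 4, axis=1))
        inner = (slice(24, 72), slice(24, 72))
        assert np.allclose(np.roll(z, 4, axis=1)[inner], zs[inner], atol=1e-3)


def _perturbed_net(rng, filters=(4, 8, 16)):
    """Model with a non-trivial head so the output differs from the anchor."""
    net = build_model(ModelConfig(filters=filters), seed=2)
    w, _ = net.head.parameters()[0]
    w += rng.normal(0, 0.05, w.shape).astype(np.float32)
    return net


class TestInference:
    def test_zero_residual_model_returns_anchor_image(self, phantom):
        sm = kf.simulate_series(phantom, kf.smooth_kernel(), 0.25, seed=1)
        sh = kf.simulate_series(phantom, kf.sharp_kernel(), 0.25, seed=2)
        for anchor, ref in (("smooth", sm), ("sharp", sh)):
            net = build_model(ModelConfig(anchor=anchor), seed=0)
            z = infer(net, sm, sh)
            assert np.allclose(z.pixels, ref.pixels, atol=1e-2)
            assert z.provenance == "model-output"

    def test_inference_is_deterministic(self, rng):
        net = _perturbed_net(rng)
        s = kf.CTImage(rng.normal(30, 10, (64, 64)), spacing=0.5)
        q = kf.CTImage(rng.normal(30, 40, (64, 64)), spacing=0.5)
        assert np.array_equal(infer(net, s, q).pixels, infer(net, s, q).pixels)

    def test_misaligned_inputs_rejected(self, rng):
        net = build_model(seed=0)
        s = kf.CTImage(np.zeros((64, 64)), spacing=0.5)
        q = kf.CTImage(np.zeros((128, 128)), spacing=0.5)
        with pytest.raises(ValueError):
            infer(net, s, q)


class TestComposition:
    def test_blend_limits_and_average(self, rng):
        z = kf.CTImage(rng.normal(30, 5, (16, 16)), spacing=0.5)
        sharp = kf.CTImage(rng.normal(30, 40, (16, 16)), spacing=0.5)
        for val in (0.0, 0.5, 1.0):
            d_sharp = np.full((16, 16), val)
            mask = kf.WeightMask(distance=np.zeros((16, 16)), d_trunc=d_sharp,
                                 d_sharp=d_sharp, d_smooth=1.0 - d_sharp)
            out = compose_output(z, sharp, mask)
            expected = val * sharp.pixels + (1 - val) * z.pixels
            assert np.allclose(out.pixels, expected)


class TestCheckpoint:
    def test_round_trip_preserves_weights_and_config(self, tmp_path, rng):
        net = _perturbed_net(rng, filters=(3, 6, 12))
        path = tmp_path / "ckpt.npz"
        save_checkpoint(net, path)
        other = load_checkpoint(path)
        assert other.cfg.filters == (3, 6, 12)
        s = rng.normal(30, 10, (32, 32))
        assert np.array_equal(net.forward(s, s), other.forward(s, s))
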