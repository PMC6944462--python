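"""U-net architecture contracts, gradients, training behavior."""

import numpy as np
import pytest

from tctrecon.geometry import ConfigurationError
from tctrecon.projector import ImageGrid
from tctrecon.simulate import DatasetPair
from tctrecon.unet import TrainConfig, UNetConfig, build_unet, train


def _pairs(rng, count, size, noise=0.3):
    out = []
    for _ in range(count):
        y = rng.random((size, size))
        x = y + noise * rng.standard_normal((size, size))
        out.append(DatasetPair(ImageGrid(x, 1.0), ImageGrid(y, 1.0)))
    return out


@pytest.mark.parametrize("size", [32, 64])
def test_output_is_single_channel_same_size(size):
    model = build_unet(UNetConfig(depth=2, base_channels=4), seed=0)
    x = np.random.default_rng(0).random((size, size))
    out = model.apply(ImageGrid(x, 1.0))
    assert out.values.shape == (size, size)


def test_indivisible_input_size_rejected():
    model = build_unet(UNetConfig(depth=3, base_channels=4), seed=0)
    with pytest.raises(ConfigurationError):
        model.apply(ImageGrid(np.zeros((36, 36)), 1.0))


def test_zero_weights_with_residual_skip_is_identity():
    model = build_unet(UNetConfig(depth=2, base_channels=4), seed=1)
    model.zero_weights()
    x = np.random.default_rng(2).random((32, 32))
    out = model.apply(ImageGrid(x, 1.0))
    np.testing.assert_array_equal(out.values, x)


def test_untrained_network_is_identity_by_construction():
    """The output convolution is zero-initialized, so a freshly built model
    with the residual skip already acts as the identity."""
    model = build_unet(UNetConfig(depth=2, base_channels=4), seed=3)
    x = np.random.default_rng(4).random((32, 32))
    np.testing.assert_allclose(model.apply(ImageGrid(x, 1.0)).values, x, atol=1e-12)


def test_parameter_count_matches_layer_arithmetic():
    """Closed-form count for depth 2, base 8, single-channel input/output."""
    cfg = UNetConfig(depth=2, base_channels=8)
    model = build_unet(cfg, seed=0)

    def conv(ci, co, k):
        return co * ci * k * k + co

    expected = 0
    # encoder: (1->8, 8->8), (8->16, 16->16)
    expected += conv(1, 8, 3) + conv(8, 8, 3)
    expected += conv(8, 16, 3) + conv(16, 16, 3)
    # bottleneck: 16->32, 32->32
    expected += conv(16, 32, 3) + conv(32, 32, 3)
    # decoder stage 1: up 32->16 (2x2), conv 32->16, conv 16->16, 2 batchnorms
    expected += conv(32, 16, 2) + conv(32, 16, 3) + conv(16, 16, 3) + 2 * 2 * 16
    # decoder stage 0: up 16->8, conv 16->8, conv 8->8, 2 batchnorms
    expected += conv(16, 8, 2) + conv(16, 8, 3) + conv(8, 8, 3) + 2 * 2 * 8
    # final 1x1: 8->1
    expected += conv(8, 1, 1)
    assert model.n_parameters() == expected


def test_intermediate_shapes_follow_config():
    """Spatial size halves per encoder stage, channels double, and the
    decoder mirrors it back to the input size."""
    cfg = UNetConfig(depth=3, base_channels=4)
    model = build_unet(cfg, seed=0)
    trace = []
    model.net.forward(np.zeros((1, 64, 64)), train=False, trace=trace)
    enc = trace[: cfg.depth]
    assert [t[1] for t in enc] == [32, 16, 8]
    assert [t[0] for t in enc] == [4, 8, 16]
    assert trace[cfg.depth] == (32, 8, 8)  # bottleneck
    dec = trace[cfg.depth + 1 :]
    assert [t[1] for t in dec] == [16, 32, 64]
    assert [t[0] for t in dec] == [16, 8, 4]


def test_gradients_match_finite_differences():
    """Backprop equals central finite differences except at ReLU/pool kinks
    (a small fraction of coordinates may straddle one)."""
    model = build_unet(UNetConfig(depth=1, base_channels=2), seed=3)
    rng = np.random.default_rng(0)
    x = rng.random((8, 8))
    y = rng.random((8, 8))
    layers = model.net.layers()

    def loss():
        pred = model.net.forward(x[None], train=False)[0]
        return float(np.mean((pred - y) ** 2))

    pred = model.net.forward(x[None], train=False)[0]
    for l in layers:
        l.zero_grads()
    model.net.backward((2.0 * (pred - y) / pred.size)[None])

    errs = []
    for l in layers:
        for k, v in l.params.items():
            for _ in range(5):
                idx = tuple(rng.integers(0, s) for s in v.shape)
                eps = 1e-6
                old = v[idx]
                v[idx] = old + eps
                lp = loss()
                v[idx] = old - eps
                lm = loss()
                v[idx] = old
                num = (lp - lm) / (2 * eps)
                errs.append(abs(num - l.grads[k][idx]) / max(1e-6, abs(num) + abs(l.grads[k][idx])))
    errs = np.sort(errs)
    assert errs[int(0.9 * len(errs))] < 1e-5  # bulk agreement
    assert errs[-1] < 1e-2  # kink-straddling outliers stay small


def test_zero_epochs_returns_identical_weights():
    model = build_unet(UNetConfig(depth=2, base_channels=4), seed=0)
    before = [p.copy() for p in model.parameters()]
    pairs = _pairs(np.random.default_rng(0), 2, 32)
    out = train(model, pairs, pairs, TrainConfig(epochs=0, patch_size=32))
    for a, b in zip(before, out.parameters()):
        np.testing.assert_array_equal(a, b)


def test_overfit_four_pairs():
    """200 optimization steps on 4 pairs with a shared structured artifact
    (the learnable analog of limited-angle streaks) cut the training MSE at
    least 10x."""
    rng = np.random.default_rng(5)
    n = 64
    yy, xx = np.mgrid[0:n, 0:n]
    artifact = 0.3 * np.sin(xx / 4.0) * np.cos(yy / 7.0) + 0.1
    pairs = []
    for _ in range(4):
        y = rng.random((n, n))
        x = y + artifact + 0.02 * rng.standard_normal((n, n))
        pairs.append(DatasetPair(ImageGrid(x, 1.0), ImageGrid(y, 1.0)))
    model = build_unet(UNetConfig(depth=3, base_channels=8), seed=0)
    cfg = TrainConfig(epochs=50, patch_size=64, grad_clip=None, momentum=0.9,
                      lr_start=0.2, lr_end=0.1, seed=0)
    model = train(model, pairs, pairs[:1], cfg)
    hist = model.loss_history["train"]
    assert hist[-1] < 0.1 * hist[0]


def test_training_is_deterministic():
    rng = np.random.default_rng(9)
    pairs = _pairs(rng, 3, 32)
    cfg = TrainConfig(epochs=3, patch_size=32, seed=4)
    m1 = train(build_unet(UNetConfig(depth=2, base_channels=4), seed=2), pairs, pairs, cfg)
    m2 = train(build_unet(UNetConfig(depth=2, base_channels=4), seed=2), pairs, pairs, cfg)
    assert m1.loss_history == m2.loss_history
    for a, b in zip(m1.parameters(), m2.parameters()):
        np.testing.assert_array_equal(a, b)


def test_patch_cropping_when_input_exceeds_patch_size():
    rng = np.random.default_rng(10)
    pairs = _pairs(rng, 2, 64)
    model = build_unet(UNetConfig(depth=2, base_channels=4), seed=0)
    out = train(model, pairs, pairs, TrainConfig(epochs=1, patch_size=32, seed=0))
    assert len(out.loss_history["train"]) == 1


def test_checkpoint_roundtrip(tmp_path):
    rng = np.random.default_rng(11)
    pairs = _pairs(rng, 2, 32)
    model = train(
        build_unet(UNetConfig(depth=2, base_channels=4), seed=0),
        pairs, pairs, TrainConfig(epochs=2, patch_size=32, seed=0),
    )
    path = tmp_path / "model.npz"
    model.save(path)
    from tctrecon.unet import TrainedDenoiser

    loaded = TrainedDenoiser.load(path)
    assert loaded.epochs_trained == 2
    x = ImageGrid(rng.random((32, 32)), 1.0)
    np.testing.assert_array_equal(model.apply(x).values, loaded.apply(x).values)
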