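"""U-net artifact suppressor for limited-angle SART reconstructions.

The network maps a single-channel SART image to a single-channel corrected
image of the same size: an encoder of repeated [3x3 zero-padded conv, ReLU] x2
blocks with 2x2 max pooling (feature channels doubling per stage), a
bottleneck, and a decoder of 2x2 up-convolutions with skip concatenations,
batch-normalized convolutions and ReLUs, closed by a 1x1 convolution down to
one channel.  A residual connection from the network input to the output
makes the convolutional path learn the artifact/noise component only.

The implementation is pure numpy with explicit forward and backward passes
for every layer, and a momentum-SGD training loop (batch size 1, MSE loss,
log-spaced learning-rate decay, global gradient-norm clipping).  All
randomness (weight init, data order) flows from explicit seeds, so training
is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .geometry import ConfigurationError
from .projector import ImageGrid, Sinogram
from .recon import SARTConfig, sart_reconstruct

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "TrainedDenoiser",
    "build_unet",
    "train",
    "sartconvnet_reconstruct",
]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture: ``depth`` pooling stages, ``base_channels`` at stage 0,
    3x3 zero-padded convolutions, 2x2 max pooling, 2x2 up-convolutions,
    batch normalization on the decoder path, single output channel."""

    depth: int = 4
    base_channels: int = 64
    residual_input_skip: bool = True
    output_channels: int = 1

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_channels < 1:
            raise ConfigurationError("depth and base_channels must be >= 1")
        if self.output_channels != 1:
            raise ConfigurationError("only single-channel output is supported")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults are the production setting: batch size 1, patch size 256 (the
    full image at 256 x 256, so no cropping), momentum 0.99, 151 epochs,
    gradient clipping at 1e-2, learning rate log-spaced from 0.01 to 0.001,
    mean-squared-error loss.
    """

    lr_start: float = 0.01
    lr_end: float = 0.001
    batch_size: int = 1
    patch_size: int = 256
    momentum: float = 0.99
    epochs: int = 151
    grad_clip: Optional[float] = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lr_start >= self.lr_end > 0):
            raise ConfigurationError("require lr_start >= lr_end > 0")
        if self.epochs < 0:
            raise ConfigurationError("epochs must be >= 0")
        if self.batch_size != 1:
            raise ConfigurationError("only batch size 1 is supported")


# ---------------------------------------------------------------------------
# Layers.  Data layout: a single sample (C, H, W); batch size is fixed at 1.
# ---------------------------------------------------------------------------


class _Layer:
    params: dict
    grads: dict

    def zero_grads(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Conv2D(_Layer):
    """k x k zero-padded convolution (stride 1, 'same' output size)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.params = {"w": w, "b": np.zeros(c_out)}
        self.k = k
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        c, h, w = x.shape
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # (c, h, w, k, k) -> (c*k*k, h*w)
        cols = win.transpose(0, 3, 4, 1, 2).reshape(c * k * k, h * w)
        wm = self.params["w"].reshape(-1, c * k * k)
        out = (wm @ cols).reshape(-1, h, w) + self.params["b"][:, None, None]
        self._cache = (cols, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        c, h, w = xshape
        k = self.k
        p = k // 2
        dflat = dout.reshape(dout.shape[0], -1)
        self.grads["w"] += (dflat @ cols.T).reshape(self.params["w"].shape)
        self.grads["b"] += dflat.sum(axis=1)
        wm = self.params["w"].reshape(dout.shape[0], -1)
        dcols = (wm.T @ dflat).reshape(c, k, k, h, w)
        dxp = np.zeros((c, h + 2 * p, w + 2 * p))
        for a in range(k):
            for bcol in range(k):
                dxp[:, a : a + h, bcol : bcol + w] += dcols[:, a, bcol]
        return dxp[:, p : p + h, p : p + w] if p else dxp


class ReLU(_Layer):
    def __init__(self):
        self.params = {}
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MaxPool2(_Layer):
    def __init__(self):
        self.params = {}
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        c, h, w = x.shape
        xr = x.reshape(c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(2, 4))
        # break ties deterministically: keep only the first max per window
        windows = xr.transpose(0, 1, 3, 2, 4).reshape(c, h // 2, w // 2, 4)
        first = np.argmax(windows, axis=-1)
        m = np.zeros_like(windows)
        np.put_along_axis(m, first[..., None], 1.0, axis=-1)
        self._mask = m.reshape(c, h // 2, w // 2, 2, 2).transpose(0, 1, 3, 2, 4)
        self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c, h, w = self._shape
        d = self._mask * dout[:, :, None, :, None]
        return d.reshape(c, h, w)


class UpConv2(_Layer):
    """2x2 up-convolution (transposed convolution, stride 2)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_out, c_in, 2, 2))
        self.params = {"w": w, "b": np.zeros(c_out)}
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        out = np.einsum("oiab,ihw->ohawb", self.params["w"], x)
        c_out = out.shape[0]
        h, w = x.shape[1] * 2, x.shape[2] * 2
        return out.reshape(c_out, h, w) + self.params["b"][:, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        c_out = dout.shape[0]
        h2, w2 = dout.shape[1] // 2, dout.shape[2] // 2
        dr = dout.reshape(c_out, h2, 2, w2, 2)
        self.grads["w"] += np.einsum("ohawb,ihw->oiab", dr, self._x)
        self.grads["b"] += dout.sum(axis=(1, 2))
        return np.einsum("oiab,ohawb->ihw", self.params["w"], dr)


class BatchNorm(_Layer):
    """Per-channel normalization over the spatial dimensions (batch size 1)."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.params = {"gamma": np.ones(c), "beta": np.zeros(c)}
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.eps = eps
        self.momentum = momentum
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(1, 2))
            var = x.var(axis=(1, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv[:, None, None]
        self._cache = (xhat, inv, train)
        return self.params["gamma"][:, None, None] * xhat + self.params["beta"][:, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, trained = self._cache
        self.grads["gamma"] += (dout * xhat).sum(axis=(1, 2))
        self.grads["beta"] += dout.sum(axis=(1, 2))
        g = self.params["gamma"][:, None, None]
        if not trained:
            return dout * g * inv[:, None, None]
        m = xhat.shape[1] * xhat.shape[2]
        dxhat = dout * g
        return (
            inv[:, None, None]
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=(1, 2), keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=(1, 2), keepdims=True)
            )
        )


# ---------------------------------------------------------------------------
# The U-net.
# ---------------------------------------------------------------------------


class _UNet:
    def __init__(self, cfg: UNetConfig, rng: np.random.Generator):
        self.cfg = cfg
        B, D = cfg.base_channels, cfg.depth
        self.enc: list[tuple[Conv2D, ReLU, Conv2D, ReLU, MaxPool2]] = []
        c_in = 1
        for d in range(D):
            ch = B * 2**d
            self.enc.append(
                (Conv2D(c_in, ch, 3, rng), ReLU(), Conv2D(ch, ch, 3, rng), ReLU(), MaxPool2())
            )
            c_in = ch
        chb = B * 2**D
        self.bott = (Conv2D(c_in, chb, 3, rng), ReLU(), Conv2D(chb, chb, 3, rng), ReLU())
        self.dec: list[tuple[UpConv2, Conv2D, BatchNorm, ReLU, Conv2D, BatchNorm, ReLU]] = []
        c_in = chb
        for d in reversed(range(D)):
            ch = B * 2**d
            self.dec.append(
                (
                    UpConv2(c_in, ch, rng),
                    Conv2D(2 * ch, ch, 3, rng),
                    BatchNorm(ch),
                    ReLU(),
                    Conv2D(ch, ch, 3, rng),
                    BatchNorm(ch),
                    ReLU(),
                )
            )
            c_in = ch
        self.final = Conv2D(c_in, 1, 1, rng)
        # Zero-init the output convolution: with the residual input skip the
        # untrained network is then exactly the identity, so training can only
        # improve on its SART input rather than first un-learning init noise.
        self.final.params["w"][...] = 0.0

    def layers(self) -> list[_Layer]:
        out: list[_Layer] = []
        for block in self.enc:
            out.extend(block)
        out.extend(self.bott)
        for block in self.dec:
            out.extend(block)
        out.append(self.final)
        return out

    def forward(self, x: np.ndarray, train: bool = False, trace: Optional[list] = None) -> np.ndarray:
        cfg = self.cfg
        if x.ndim == 2:
            x = x[None]
        h = x.shape[1]
        if h % (2**cfg.depth) != 0 or x.shape[2] != h:
            raise ConfigurationError(
                f"input size {x.shape[1:]} must be square and divisible by 2^{cfg.depth}"
            )
        inp = x
        skips = []
        for c1, r1, c2, r2, pool in self.enc:
            x = r1.forward(c1.forward(x, train), train)
            x = r2.forward(c2.forward(x, train), train)
            skips.append(x)
            x = pool.forward(x, train)
            if trace is not None:
                trace.append(x.shape)
        c1, r1, c2, r2 = self.bott
        x = r1.forward(c1.forward(x, train), train)
        x = r2.forward(c2.forward(x, train), train)
        if trace is not None:
            trace.append(x.shape)
        for (up, c1, b1, r1, c2, b2, r2), skip in zip(self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=0)
            x = r1.forward(b1.forward(c1.forward(x, train), train), train)
            x = r2.forward(b2.forward(c2.forward(x, train), train), train)
            if trace is not None:
                trace.append(x.shape)
        x = self.final.forward(x, train)
        if cfg.residual_input_skip:
            x = x + inp
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.final.backward(dout)
        dskips = []
        for up, c1, b1, r1, c2, b2, r2 in reversed(self.dec):
            d = c2.backward(b2.backward(r2.backward(d)))
            d = c1.backward(b1.backward(r1.backward(d)))
            ch = d.shape[0] // 2
            dskips.append(d[:ch])
            d = up.backward(d[ch:])
        c1, r1, c2, r2 = self.bott
        d = c1.backward(r1.backward(c2.backward(r2.backward(d))))
        for (c1, r1, c2, r2, pool), dskip in zip(reversed(self.enc), reversed(dskips)):
            d = pool.backward(d)
            d = d + dskip
            d = c1.backward(r1.backward(c2.backward(r2.backward(d))))
        if self.cfg.residual_input_skip:
            d = d + dout
        return d


@dataclass
class TrainedDenoiser:
    """A U-net with its configuration, weights and input normalization."""

    config: UNetConfig
    net: _UNet = field(repr=False)
    normalization: float = 1.0
    loss_history: dict = field(default_factory=lambda: {"train": [], "test": []})
    epochs_trained: int = 0

    def apply(self, image: ImageGrid) -> ImageGrid:
        """Denoise one image; output has the label intensity scale."""
        x = image.values / self.normalization
        y = self.net.forward(x[None], train=False)[0]
        return ImageGrid(y * self.normalization, image.pixel_size)

    # -- parameter bookkeeping -------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.net.layers():
            out.extend(layer.params.values())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_weights(self) -> None:
        """Zero every convolution weight/bias (batch-norm affine terms kept);
        with the residual input skip on, the network is then exactly the
        identity map."""
        for layer in self.net.layers():
            if isinstance(layer, (Conv2D, UpConv2)):
                for v in layer.params.values():
                    v[...] = 0.0

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.net.layers()):
            for k, v in layer.params.items():
                state[f"layer{i:03d}.{k}"] = v
            if isinstance(layer, BatchNorm):
                state[f"layer{i:03d}.running_mean"] = layer.running_mean
                state[f"layer{i:03d}.running_var"] = layer.running_var
        return state

    def save(self, path: str) -> None:
        np.savez(
            path,
            normalization=self.normalization,
            epochs_trained=self.epochs_trained,
            **{f"cfg_{k}": v for k, v in asdict(self.config).items()},
            **self.state_arrays(),
        )

    @classmethod
    def load(cls, path: str) -> "TrainedDenoiser":
        data = np.load(path)
        cfg = UNetConfig(
            depth=int(data["cfg_depth"]),
            base_channels=int(data["cfg_base_channels"]),
            residual_input_skip=bool(data["cfg_residual_input_skip"]),
        )
        model = build_unet(cfg)
        model.normalization = float(data["normalization"])
        model.epochs_trained = int(data["epochs_trained"])
        for i, layer in enumerate(model.net.layers()):
            for k in layer.params:
                layer.params[k][...] = data[f"layer{i:03d}.{k}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = data[f"layer{i:03d}.running_mean"]
                layer.running_var[...] = data[f"layer{i:03d}.running_var"]
        return model


def build_unet(cfg: UNetConfig | None = None, seed: int = 0) -> TrainedDenoiser:
    """Construct an untrained U-net with seeded He-normal initialization."""
    cfg = cfg or UNetConfig()
    rng = np.random.default_rng(seed)
    return TrainedDenoiser(config=cfg, net=_UNet(cfg, rng))


# ---------------------------------------------------------------------------
# Training.
# ---------------------------------------------------------------------------


def _prepare(pairs, normalization: float, patch: int, rng: Optional[np.random.Generator]):
    """Normalized (input, label) arrays; random crops when larger than patch."""
    out = []
    for p in pairs:
        x = p.input_image.values / normalization
        y = p.label_image.values / normalization
        if x.shape[0] > patch and rng is not None:
            i = rng.integers(0, x.shape[0] - patch + 1)
            j = rng.integers(0, x.shape[1] - patch + 1)
            x = x[i : i + patch, j : j + patch]
            y = y[i : i + patch, j : j + patch]
        out.append((x, y))
    return out


def train(model: TrainedDenoiser, train_pairs, test_pairs, cfg: TrainConfig | None = None) -> TrainedDenoiser:
    """Momentum-SGD training of the denoiser on (SART image, label) pairs.

    MSE loss, batch size 1, learning rate log-spaced from ``lr_start`` to
    ``lr_end`` over epochs, optional clipping of the global gradient norm.
    Train/test losses are recorded every epoch in ``model.loss_history``;
    ``epochs == 0`` returns the model unchanged.
    """
    cfg = cfg or TrainConfig()
    if not train_pairs or not test_pairs:
        raise ValueError("train_pairs and test_pairs must be nonempty")
    if cfg.epochs == 0:
        return model

    # Single normalization constant: max over the training labels.
    scale = max(float(p.label_image.values.max()) for p in train_pairs)
    model.normalization = scale if scale > 0 else 1.0

    rng = np.random.default_rng(cfg.seed)
    lrs = np.logspace(np.log10(cfg.lr_start), np.log10(cfg.lr_end), cfg.epochs)
    layers = model.net.layers()
    velocity = [
        {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in layers
    ]
    test_data = _prepare(test_pairs, model.normalization, cfg.patch_size, None)

    for epoch in range(cfg.epochs):
        lr = lrs[epoch]
        data = _prepare(train_pairs, model.normalization, cfg.patch_size, rng)
        order = rng.permutation(len(data))
        epoch_loss = 0.0
        for idx in order:
            x, y = data[idx]
            pred = model.net.forward(x[None], train=True)[0]
            err = pred - y
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; reduce the "
                    "learning rate or check the input scaling"
                )
            epoch_loss += loss
            for layer in layers:
                layer.zero_grads()
            model.net.backward((2.0 * err / err.size)[None])
            if cfg.grad_clip is not None:
                gnorm = np.sqrt(
                    sum(float((g**2).sum()) for l in layers for g in l.grads.values())
                )
                if gnorm > cfg.grad_clip:
                    factor = cfg.grad_clip / gnorm
                    for l in layers:
                        for g in l.grads.values():
                            g *= factor
            for l, vel in zip(layers, velocity):
                for k in l.params:
                    vel[k] = cfg.momentum * vel[k] - lr * l.grads[k]
                    l.params[k] += vel[k]
        model.loss_history["train"].append(epoch_loss / len(data))
        test_loss = 0.0
        for x, y in test_data:
            pred = model.net.forward(x[None], train=False)[0]
            test_loss += float(np.mean((pred - y) ** 2))
        model.loss_history["test"].append(test_loss / len(test_data))
        model.epochs_trained += 1
    return model


def sartconvnet_reconstruct(
    sino: Sinogram,
    geom,
    sart_cfg: SARTConfig,
    model: TrainedDenoiser,
) -> ImageGrid:
    """Full pipeline: SART reconstruction first, then the trained U-net."""
    sart_image = sart_reconstruct(sino, geom, sart_cfg)
    return model.apply(sart_image)
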