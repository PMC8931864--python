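"""Residual U-Net architecture for phase-map translation.

Layout: four encoder stages (16, 32, 64, 128 channels), a 256-channel
bottleneck, and a mirrored decoder with skip concatenations.  Every stage is
two (3x3 conv -> batch norm -> ReLU) operations with a 1x1-convolution
residual shortcut summed after the pair; encoder stages are followed by 2x2
max pooling and the decoder upsamples with 2x2 transposed convolutions.
Dropout is applied at three sites: after encoder stages 3 and 4 and after
the bottleneck.  A final 1x1 convolution with linear output maps back to one
channel.  All convolutions are "same"-padded, so the network is fully
convolutional: output shape equals input shape for any side divisible by
16, and other sizes are handled by reflect padding plus crop-back.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .layers import BatchNorm2d, Conv2d, ConvTranspose2, Dropout, MaxPool2, ReLU


@dataclass(frozen=True)
class NetConfig:
    encoder_channels: tuple[int, ...] = (16, 32, 64, 128)
    bottleneck_channels: int = 256
    conv_kernel: int = 3
    residual_kernel: int = 1
    downsample_factor: int = 2
    dropout_rate: float = 0.25
    dropout_sites: int = 3
    activation: str = "relu"
    upsample_mode: str = "transposed_conv"
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if len(self.encoder_channels) != 4:
            raise ValueError("exactly 4 encoder stages are required")
        if self.conv_kernel != 3 or self.residual_kernel != 1:
            raise ValueError("kernel sizes are fixed at 3 (conv) and 1 (residual shortcut)")
        if self.downsample_factor != 2:
            raise ValueError("downsample factor is fixed at 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.activation != "relu" or self.upsample_mode != "transposed_conv":
            raise ValueError("supported configuration: relu activation, transposed-conv upsampling")


class ResidualBlock:
    """Two 3x3 conv+BN+ReLU with a 1x1-conv shortcut summed after the pair."""

    def __init__(self, name: str, c_in: int, c_out: int, k: int, use_bn: bool, rng):
        self.name = name
        self.conv1 = Conv2d(f"{name}/conv1", c_in, c_out, k, rng=rng)
        self.bn1 = BatchNorm2d(f"{name}/bn1", c_out) if use_bn else None
        self.relu1 = ReLU()
        self.conv2 = Conv2d(f"{name}/conv2", c_out, c_out, k, rng=rng)
        self.bn2 = BatchNorm2d(f"{name}/bn2", c_out) if use_bn else None
        self.shortcut = Conv2d(f"{name}/shortcut", c_in, c_out, 1, rng=rng)
        self.relu2 = ReLU()

    def layers(self):
        out = [self.conv1, self.conv2, self.shortcut]
        if self.bn1 is not None:
            out += [self.bn1, self.bn2]
        return out

    def forward(self, x, training=False):
        h = self.conv1.forward(x, training)
        if self.bn1 is not None:
            h = self.bn1.forward(h, training)
        h = self.relu1.forward(h, training)
        h = self.conv2.forward(h, training)
        if self.bn2 is not None:
            h = self.bn2.forward(h, training)
        s = self.shortcut.forward(x, training)
        return self.relu2.forward(h + s, training)

    def backward(self, grad):
        g = self.relu2.backward(grad)
        gs = self.shortcut.backward(g)
        gh = g
        if self.bn2 is not None:
            gh = self.bn2.backward(gh)
        gh = self.conv2.backward(gh)
        gh = self.relu1.backward(gh)
        if self.bn1 is not None:
            gh = self.bn1.backward(gh)
        gh = self.conv1.backward(gh)
        return gh + gs


class ResUNet:
    """The full encoder/bottleneck/decoder graph with explicit backprop."""

    def __init__(self, cfg: NetConfig = NetConfig(), seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = cfg.encoder_channels
        k = cfg.conv_kernel
        bn = cfg.batch_norm

        self.enc = []
        c_prev = 1
        for i, c in enumerate(ch, start=1):
            self.enc.append(ResidualBlock(f"enc{i}", c_prev, c, k, bn, rng))
            c_prev = c
        self.pools = [MaxPool2(f"pool{i}") for i in range(1, 5)]
        # dropout sites: encoder stages 3, 4 and the bottleneck
        self.drops = {
            "enc3": Dropout("drop_enc3", cfg.dropout_rate),
            "enc4": Dropout("drop_enc4", cfg.dropout_rate),
            "bottleneck": Dropout("drop_bottleneck", cfg.dropout_rate),
        }
        self.bottleneck = ResidualBlock("bottleneck", ch[-1], cfg.bottleneck_channels, k, bn, rng)

        self.ups = []
        self.dec = []
        c_prev = cfg.bottleneck_channels
        for i, c in enumerate(reversed(ch), start=1):
            stage = 5 - i  # 4, 3, 2, 1
            self.ups.append(ConvTranspose2(f"up{stage}", c_prev, c, rng=rng))
            self.dec.append(ResidualBlock(f"dec{stage}", 2 * c, c, k, bn, rng))
            c_prev = c
        self.head = Conv2d("head", ch[0], 1, 1, rng=rng)
        # start at the mid-range constant prediction: keeps the initial loss at
        # the variance of the target rather than the (large) variance of the
        # randomly-initialized feature stack, which wastes optimization steps
        self.head.params["kernel"][:] = 0.0
        self.head.params["bias"][:] = 0.5

    # -- parameter plumbing ------------------------------------------------
    def blocks(self):
        return self.enc + [self.bottleneck] + self.dec

    def layers(self):
        out = []
        for b in self.blocks():
            out.extend(b.layers())
        out.extend(self.ups)
        out.append(self.head)
        return out

    def parameters(self) -> dict[str, np.ndarray]:
        """Flat name -> array view of every trainable tensor."""
        out = {}
        for layer in self.layers():
            for pname, arr in layer.params.items():
                out[f"{layer.name}/{pname}"] = arr
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self.layers():
            for pname, arr in layer.grads.items():
                out[f"{layer.name}/{pname}"] = arr
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for layer in self.layers():
            for bname, arr in layer.buffers.items():
                out[f"{layer.name}/{bname}"] = arr
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in {**self.parameters(), **self.buffers()}.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for layer in self.layers():
            for store in (layer.params, layer.buffers):
                for pname in store:
                    key = f"{layer.name}/{pname}"
                    if key not in state:
                        raise KeyError(f"missing tensor {key}")
                    arr = np.asarray(state[key], dtype=np.float64)
                    if arr.shape != store[pname].shape:
                        raise ValueError(
                            f"shape mismatch for layer {layer.name!r} tensor {pname!r}: "
                            f"expected {store[pname].shape}, got {arr.shape}")
                    store[pname] = arr.copy()

    def copy(self) -> "ResUNet":
        return copy.deepcopy(self)

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """(N, 1, H, W) -> (N, 1, H, W); H, W must be divisible by 16 here
        (use :meth:`predict_image` for arbitrary sizes)."""
        skips = []
        h = x
        for i, (block, pool) in enumerate(zip(self.enc, self.pools), start=1):
            h = block.forward(h, training)
            if i == 3:
                h = self.drops["enc3"].forward(h, training, rng=rng)
            elif i == 4:
                h = self.drops["enc4"].forward(h, training, rng=rng)
            skips.append(h)
            h = pool.forward(h, training)
        h = self.bottleneck.forward(h, training)
        h = self.drops["bottleneck"].forward(h, training, rng=rng)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h, training)
            h = np.concatenate([skip, h], axis=1)
            h = dec.forward(h, training)
        return self.head.forward(h, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.head.backward(grad)
        skip_grads = []
        for up, dec in zip(reversed(self.ups), reversed(self.dec)):
            gd = dec.backward(g)
            c = up.c_out
            skip_grads.append(gd[:, :c])
            g = up.backward(gd[:, c:])
        g = self.drops["bottleneck"].backward(g)
        g = self.bottleneck.backward(g)
        # backward visited dec1 first, so skip_grads is already ordered enc1..enc4
        for i in range(3, -1, -1):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            if i == 3:
                g = self.drops["enc4"].backward(g)
            elif i == 2:
                g = self.drops["enc3"].backward(g)
            g = self.enc[i].backward(g)
        return g

    def predict_image(self, img: np.ndarray) -> np.ndarray:
        """Inference on a single 2-D image of any size (reflect pad to /16)."""
        img = np.asarray(img, dtype=np.float64)
        h, w = img.shape
        ph = (-h) % 16
        pw = (-w) % 16
        x = np.pad(img, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else img
        y = self.forward(x[None, None], training=False)[0, 0]
        return y[:h, :w]


def build_model(cfg: NetConfig = NetConfig(), seed: int = 0) -> ResUNet:
    """Construct the residual U-Net; enforces the 3.3M trainable-parameter budget."""
    model = ResUNet(cfg, seed=seed)
    n = count_parameters(model)
    if n > 3_300_000:
        raise ValueError(f"model has {n} trainable parameters, above the 3.3e6 budget")
    return model


def count_parameters(m) -> int:
    """Number of trainable scalars (conv kernels/biases, batch-norm scale/offset)."""
    if isinstance(m, ResUNet):
        return int(sum(arr.size for arr in m.parameters().values()))
    # single layer
    return int(sum(arr.size for arr in m.params.values()))
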