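"""Training and inference for the DPM-to-SLIM translator.

The public surface follows a model/results split: a
:class:`DpmToSlimTranslator` is built from registered image pairs and the
architecture/optimization configurations; :meth:`DpmToSlimTranslator.fit`
runs the optimization and returns a :class:`TranslationResults` carrying the
selected weights (validation-loss argmin checkpoint), the full per-epoch
loss history, and prediction/serialization methods.

Training follows the image-to-image regression recipe: per epoch one random
square crop per training image, mean-squared-error loss on [0, 1]-scaled
data, Adam with decay rates (0.9, 0.999).  The published full-scale recipe
is learning rate 6e-5, batch size 4, 400-pixel crops over 1000 epochs; all
of it is configurable for desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..types import PhaseMap
from .data import random_crop_pair, scale_to_unit, split_pairs, unit_to_phase
from .unet import NetConfig, ResUNet, build_model, count_parameters


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 6e-5
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 4
    epochs: int = 1000
    crop: int = 400
    loss: str = "mse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss != "mse":
            raise ValueError("only mean-squared-error loss is supported")


class Adam:
    def __init__(self, model: ResUNet, lr: float, beta1: float, beta2: float, eps: float = 1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in model.parameters().items()}
        self.v = {k: np.zeros_like(v) for k, v in model.parameters().items()}

    def step(self) -> None:
        self.t += 1
        grads = self.model.gradients()
        for layer in self.model.layers():
            for pname in layer.params:
                key = f"{layer.name}/{pname}"
                g = grads[key]
                self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
                self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
                mhat = self.m[key] / (1 - self.b1**self.t)
                vhat = self.v[key] / (1 - self.b2**self.t)
                layer.params[pname] = layer.params[pname] - self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _to_array(img) -> np.ndarray:
    return img.phase if isinstance(img, PhaseMap) else np.asarray(img, dtype=np.float64)


def _center_crop_div16(img: np.ndarray, max_side: int | None = None) -> np.ndarray:
    h, w = img.shape
    side = min(h, w)
    if max_side is not None:
        side = min(side, max_side)
    side -= side % 16
    top = (h - side) // 2
    left = (w - side) // 2
    return img[top:top + side, left:left + side]


@dataclass
class TranslationResults:
    """Fitted translator: selected weights, training history, diagnostics."""

    model: ResUNet
    net_config: NetConfig
    train_config: TrainConfig
    history: pd.DataFrame          # columns: epoch, train_loss, val_loss
    best_epoch: int
    split: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.model)

    def predict(self, dpm_phase: PhaseMap | np.ndarray) -> PhaseMap:
        """Translate a DPM phase map to a SLIM-quality (CIM) phase map."""
        arr = _to_array(dpm_phase)
        out_unit = self.model.predict_image(scale_to_unit(arr))
        phase = unit_to_phase(out_unit)
        wl = dpm_phase.wavelength if isinstance(dpm_phase, PhaseMap) else 0.623
        px = dpm_phase.pixel_size if isinstance(dpm_phase, PhaseMap) else None
        return PhaseMap(phase, modality="CIM", wavelength=wl, pixel_size=px,
                        meta={"best_epoch": self.best_epoch})

    def summary(self) -> str:
        h = self.history
        lines = [
            "DPM -> SLIM translation (residual U-Net)",
            "=" * 44,
            f"trainable parameters : {self.n_parameters:,}",
            f"encoder channels     : {self.net_config.encoder_channels}",
            f"bottleneck channels  : {self.net_config.bottleneck_channels}",
            f"epochs run           : {len(h)}",
            f"best epoch (val argmin): {self.best_epoch}",
            f"train loss (first/last): {h.train_loss.iloc[0]:.3e} / {h.train_loss.iloc[-1]:.3e}",
            f"val loss   (best)      : {h.val_loss.min():.3e}",
            f"optimizer            : Adam(lr={self.train_config.lr:g}, "
            f"betas=({self.train_config.adam_beta1}, {self.train_config.adam_beta2}))",
            f"batch size / crop    : {self.train_config.batch_size} / {self.train_config.crop}",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Train/validation MSE per epoch (the convergence diagnostic plot)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history.epoch, self.history.train_loss, label="train")
        ax.plot(self.history.epoch, self.history.val_loss, label="validation")
        ax.axvline(self.best_epoch, color="k", ls=":", lw=1, label="selected checkpoint")
        ax.set_xlabel("epoch")
        ax.set_ylabel("MSE loss")
        ax.set_yscale("log")
        ax.legend()
        return ax

    def save(self, path) -> None:
        from .hdf5io import export_weights

        export_weights(self, path)

    @classmethod
    def load(cls, path) -> "TranslationResults":
        from .hdf5io import import_weights

        return import_weights(path)


class DpmToSlimTranslator:
    """Image-to-image regression model from registered (DPM, SLIM) phase pairs.

    Parameters
    ----------
    pairs : sequence of (dpm, slim)
        Registered phase-map pairs (``PhaseMap`` or 2-D arrays, radians).
    net_config, train_config : configurations (defaults are the published recipe).
    split : dict, optional
        ``{"train": idx, "val": idx, "test": idx}`` disjoint by field of
        view; defaults to a seeded 80/10/10 split.
    val_crop : int, optional
        Side of the centre crop used for the per-epoch validation loss
        (full image when None); keeps checkpoint selection cheap on CPU.
    """

    def __init__(self, pairs, net_config: NetConfig | None = None,
                 train_config: TrainConfig | None = None,
                 split: dict | None = None, val_crop: int | None = None):
        self.pairs = [(_to_array(d), _to_array(s)) for d, s in pairs]
        if len(self.pairs) < 2:
            raise ValueError("need at least 2 pairs")
        shapes = {p[0].shape for p in self.pairs} | {p[1].shape for p in self.pairs}
        if len(shapes) != 1:
            raise ValueError("all pairs must share one image shape")
        self.net_config = net_config or NetConfig()
        self.train_config = train_config or TrainConfig()
        side = min(self.pairs[0][0].shape)
        if self.train_config.crop > side:
            raise ValueError("crop exceeds image side")
        self.split = split or split_pairs(len(self.pairs), seed=self.train_config.seed)
        for part in ("train", "val", "test"):
            if part not in self.split or len(self.split[part]) == 0:
                raise ValueError(f"empty split partition: {part}")
        self.val_crop = val_crop

    def fit(self, verbose: bool = False) -> TranslationResults:
        tc = self.train_config
        rng = np.random.default_rng(tc.seed)
        model = build_model(self.net_config, seed=tc.seed)
        opt = Adam(model, tc.lr, tc.adam_beta1, tc.adam_beta2)

        train_idx = np.asarray(self.split["train"])
        val_pairs = [self.pairs[i] for i in self.split["val"]]
        scaled = [(scale_to_unit(d), scale_to_unit(s)) for d, s in self.pairs]
        val_scaled = [(scale_to_unit(d), scale_to_unit(s)) for d, s in val_pairs]
        if self.val_crop is not None:
            val_scaled = [(_center_crop_div16(d, self.val_crop), _center_crop_div16(s, self.val_crop))
                          for d, s in val_scaled]
        else:
            val_scaled = [(_center_crop_div16(d), _center_crop_div16(s)) for d, s in val_scaled]

        crop = tc.crop - tc.crop % 16 if tc.crop % 16 else tc.crop
        history = []
        best_loss = np.inf
        best_state = None
        best_epoch = -1
        for epoch in range(tc.epochs):
            # one random crop per training image per epoch
            crops = []
            for i in rng.permutation(train_idx):
                d, s = scaled[i]
                crops.append(random_crop_pair(d, s, crop, rng=rng))
            losses = []
            for start in range(0, len(crops), tc.batch_size):
                batch = crops[start:start + tc.batch_size]
                x = np.stack([b[0] for b in batch])[:, None]
                y = np.stack([b[1] for b in batch])[:, None]
                pred = model.forward(x, training=True, rng=rng)
                resid = pred - y
                losses.append(float(np.mean(resid**2)))
                model.backward(2.0 * resid / resid.size)
                opt.step()
            train_loss = float(np.mean(losses))

            val_losses = [float(np.mean((model.forward(d[None, None], training=False)[0, 0] - s) ** 2))
                          for d, s in val_scaled]
            val_loss = float(np.mean(val_losses))
            history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
            if val_loss < best_loss:
                best_loss = val_loss
                best_state = model.state_dict()
                best_epoch = epoch
            if verbose:
                print(f"epoch {epoch:4d}  train {train_loss:.4e}  val {val_loss:.4e}")

        model.load_state_dict(best_state)
        return TranslationResults(model=model, net_config=self.net_config,
                                  train_config=tc, history=pd.DataFrame(history),
                                  best_epoch=best_epoch, split=self.split)


def train(pairs, net: NetConfig | None = None, tc: TrainConfig | None = None,
          split: dict | None = None, val_crop: int | None = None) -> TranslationResults:
    """Functional wrapper: fit a translator on registered pairs."""
    return DpmToSlimTranslator(pairs, net, tc, split=split, val_crop=val_crop).fit()


def infer(results: TranslationResults, dpm_phase: PhaseMap | np.ndarray) -> PhaseMap:
    """Functional wrapper around :meth:`TranslationResults.predict`."""
    return results.predict(dpm_phase)
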