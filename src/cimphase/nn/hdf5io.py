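"""HDF5 weight interchange.

All trained tensors — convolution kernels and batch-normalization parameters
(scale, offset, running mean/variance) — are stored in a single HDF5 file
under ``/layers/<layer name>/{kernel,bias,bn_gamma,bn_beta,bn_mean,bn_var}``,
with the architecture configuration serialized as a YAML string at
``/config`` and the training history/metadata alongside.  The round trip is
bit-exact, so an exported-then-imported model produces identical inference
output.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .unet import NetConfig, ResUNet

WEIGHT_KEYS = ("kernel", "bias", "bn_gamma", "bn_beta", "bn_mean", "bn_var")


def export_weights(results, path: str | Path) -> Path:
    """Write a fitted translator (weights + config + history) to one HDF5 file."""
    from .train import TrainConfig, TranslationResults  # local: avoid import cycle

    if not isinstance(results, TranslationResults):
        raise TypeError("export_weights expects a TranslationResults")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    model = results.model
    with h5py.File(path, "w") as f:
        layers_grp = f.create_group("layers")
        for layer in model.layers():
            grp = layers_grp.create_group(layer.name)
            for pname, arr in {**layer.params, **layer.buffers}.items():
                assert pname in WEIGHT_KEYS
                grp.create_dataset(pname, data=np.asarray(arr, dtype=np.float64))
        f.create_dataset("config", data=yaml.safe_dump({
            "net_config": asdict(results.net_config),
            "train_config": asdict(results.train_config),
            "best_epoch": int(results.best_epoch),
        }))
        hist = f.create_group("history")
        for col in results.history.columns:
            hist.create_dataset(col, data=results.history[col].to_numpy())
    return path


def import_weights(path: str | Path):
    """Rebuild a :class:`TranslationResults` from an exported HDF5 file.

    Raises a shape-mismatch error naming the offending layer if the file was
    tampered with.
    """
    from .train import TrainConfig, TranslationResults

    with h5py.File(path, "r") as f:
        cfg = yaml.safe_load(f["config"][()].decode() if isinstance(f["config"][()], bytes)
                             else str(f["config"][()]))
        net_cfg = NetConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in cfg["net_config"].items()})
        train_cfg = TrainConfig(**cfg["train_config"])
        state = {}

        def collect(path, obj):
            if isinstance(obj, h5py.Dataset):
                lname, _, pname = path.rpartition("/")
                if pname not in WEIGHT_KEYS:
                    raise ValueError(f"unexpected tensor {pname!r} in layer {lname!r}")
                state[path] = obj[()]

        f["layers"].visititems(collect)
        history = pd.DataFrame({col: ds[()] for col, ds in f["history"].items()})
    model = ResUNet(net_cfg, seed=0)
    model.load_state_dict(state)
    cols = [c for c in ("epoch", "train_loss", "val_loss") if c in history.columns]
    return TranslationResults(model=model, net_config=net_cfg, train_config=train_cfg,
                              history=history[cols], best_epoch=int(cfg["best_epoch"]))
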