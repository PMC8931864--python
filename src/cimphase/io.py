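"""TIFF + YAML-sidecar file interchange.

All images are stored as single-channel 32-bit float TIFF (lossless and
universally readable by microscopy software); every image carries a YAML
sidecar ``<name>.yml`` with its acquisition metadata (pixel size, wavelength,
seed, carrier, phase shifts, ...).  Multi-frame stacks are stored as
multi-page TIFF with page order equal to acquisition order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml


def sidecar_path(image_path: str | Path) -> Path:
    p = Path(image_path)
    return p.with_suffix(p.suffix + ".yml")


def write_image(path: str | Path, data: np.ndarray, meta: dict | None = None) -> Path:
    """Write a float32 TIFF (2-D image or 3-D stack) plus optional YAML sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32))
    if meta is not None:
        write_yaml(sidecar_path(path), meta)
    return path


def read_image(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a TIFF and its sidecar metadata (empty dict if no sidecar)."""
    data = tifffile.imread(path).astype(np.float64)
    sc = sidecar_path(path)
    meta = read_yaml(sc) if sc.exists() else {}
    return data, meta


def write_yaml(path: str | Path, obj: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(obj), fh, sort_keys=False)
    return path


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _plain(obj):
    """Recursively convert numpy scalars/arrays to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
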