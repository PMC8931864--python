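"""Data plumbing for training: scaling, cropping, splitting.

Network inputs and targets are phase maps in radians; they are mapped
affinely from [-pi, pi] to [0, 1] before entering the network and back
afterwards.  Out-of-range phase values are clipped and counted (a nonzero
count signals scenes exceeding the representable dynamic range).
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)


def scale_to_unit(phase: np.ndarray, return_clip_count: bool = False):
    """Affine map radians [-pi, pi] -> [0, 1]; out-of-range values are clipped.

    With ``return_clip_count=True`` also returns the number of clipped pixels
    (it is logged either way).
    """
    phase = np.asarray(phase, dtype=np.float64)
    n_clipped = int(np.count_nonzero((phase < -np.pi) | (phase > np.pi)))
    if n_clipped:
        logger.warning("scale_to_unit clipped %d out-of-range pixels", n_clipped)
    scaled = (np.clip(phase, -np.pi, np.pi) + np.pi) / (2.0 * np.pi)
    return (scaled, n_clipped) if return_clip_count else scaled


def unit_to_phase(unit: np.ndarray) -> np.ndarray:
    """Inverse of :func:`scale_to_unit` (no clipping: network output may overshoot)."""
    return np.asarray(unit, dtype=np.float64) * (2.0 * np.pi) - np.pi


def random_crop_pair(
    dpm_img: np.ndarray,
    slim_img: np.ndarray,
    size: int = 400,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One identical random square window cut from a registered image pair.

    The offset is uniform over all valid positions; ``size`` equal to the
    image side yields the identity crop.
    """
    dpm_img = np.asarray(dpm_img)
    slim_img = np.asarray(slim_img)
    if dpm_img.shape != slim_img.shape:
        raise ValueError("pair images must share a shape")
    h, w = dpm_img.shape
    if size > min(h, w):
        raise ValueError("crop larger than image")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    top = int(rng.integers(0, h - size + 1))
    left = int(rng.integers(0, w - size + 1))
    return (dpm_img[top:top + size, left:left + size],
            slim_img[top:top + size, left:left + size])


def split_pairs(
    n: int,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Disjoint train/validation/test indices by field of view (80/10/10 default)."""
    if n < 2:
        raise ValueError("need at least 2 pairs to split")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(fractions[1] * n)))
    n_test = max(1, int(round(fractions[2] * n)))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError("split leaves no training pairs")
    split = {
        "train": np.sort(order[:n_train]),
        "val": np.sort(order[n_train:n_train + n_val]),
        "test": np.sort(order[n_train + n_val:]),
    }
    assert all(len(v) > 0 for v in split.values())
    return split
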