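"""Image-quality evaluation: PSNR, Pearson correlation, and SSIM.

The three metrics compare a predicted phase map against the ground truth on
images scaled to [0, 1].  SSIM is evaluated per local window,

    SSIM(x, y) = (2*mu_x*mu_y + C1) * (2*sigma_xy + C2)
                 / ((mu_x^2 + mu_y^2 + C1) * (sigma_x^2 + sigma_y^2 + C2)),

and averaged over the image; an optional global mode evaluates the same
formula once with whole-image statistics.  The stability constants default
to C1 = (0.01*L)^2, C2 = (0.03*L)^2 with data range L = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

DATA_RANGE = 1.0
C1_DEFAULT = (0.01 * DATA_RANGE) ** 2
C2_DEFAULT = (0.03 * DATA_RANGE) ** 2


@dataclass
class MetricsReport:
    """Mean metric values over a set of image pairs plus the conventions used."""

    psnr: float
    pearson: float
    ssim: float
    ssim_c1: float = C1_DEFAULT
    ssim_c2: float = C2_DEFAULT
    data_range: float = DATA_RANGE
    n_pairs: int = 1
    per_pair: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"psnr": self.psnr, "pearson": self.pearson, "ssim": self.ssim,
                              "n_pairs": self.n_pairs}])


def _check_shapes(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    C1: float = C1_DEFAULT,
    C2: float = C2_DEFAULT,
    window: str = "gaussian",
    sigma: float = 1.5,
    truncate: float = 3.5,
) -> float:
    """Structural similarity index.

    ``window='gaussian'`` (default) uses 11x11 Gaussian-weighted local
    statistics (sigma = 1.5) mean-pooled over the image — the standard local
    form.  ``window='global'`` evaluates the formula once on whole-image
    means/variances/covariance.
    """
    x, y = _check_shapes(x, y)
    if window == "global":
        mu_x, mu_y = x.mean(), y.mean()
        var_x, var_y = x.var(), y.var()
        cov = ((x - mu_x) * (y - mu_y)).mean()
        return float((2 * mu_x * mu_y + C1) * (2 * cov + C2)
                     / ((mu_x**2 + mu_y**2 + C1) * (var_x + var_y + C2)))
    if window != "gaussian":
        raise ValueError("window must be 'gaussian' or 'global'")

    def filt(a):
        return ndimage.gaussian_filter(a, sigma, truncate=truncate, mode="reflect")

    mu_x, mu_y = filt(x), filt(y)
    var_x = filt(x * x) - mu_x**2
    var_y = filt(y * y) - mu_y**2
    cov = filt(x * y) - mu_x * mu_y
    smap = ((2 * mu_x * mu_y + C1) * (2 * cov + C2)
            / ((mu_x**2 + mu_y**2 + C1) * (var_x + var_y + C2)))
    # discard the border where window statistics are edge-contaminated
    pad = int(truncate * sigma + 0.5)
    if min(smap.shape) > 2 * pad:
        smap = smap[pad:-pad, pad:-pad]
    return float(smap.mean())


def psnr(x: np.ndarray, y: np.ndarray, peak: float = DATA_RANGE) -> float:
    """Peak signal-to-noise ratio, ``10*log10(peak^2 / MSE)`` in dB.

    Identical images have zero MSE; the infinity sentinel ``np.inf`` is
    returned in that case.
    """
    x, y = _check_shapes(x, y)
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return np.inf
    return float(10.0 * np.log10(peak**2 / mse))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation over flattened pixels; errors on constant input."""
    x, y = _check_shapes(x, y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson correlation undefined for a constant image")
    return float(np.corrcoef(x.ravel(), y.ravel())[0, 1])


def evaluate_pairs(
    predictions,
    truths,
    peak: float = DATA_RANGE,
    C1: float = C1_DEFAULT,
    C2: float = C2_DEFAULT,
    split: str | list[str] | None = None,
) -> MetricsReport:
    """Per-pair PSNR/Pearson/SSIM plus set means.

    ``predictions`` and ``truths`` are equal-length aligned sequences of 2-D
    arrays on the [0, 1] scale.  The per-pair table (one row per pair with a
    ``split`` column when given) is attached to the returned report.
    """
    preds = list(predictions)
    refs = list(truths)
    if len(preds) != len(refs):
        raise ValueError("predictions and truths must have equal length")
    if len(preds) == 0:
        raise ValueError("empty evaluation set")
    if isinstance(split, str) or split is None:
        split = [split or "all"] * len(preds)
    rows = []
    for i, (p, t) in enumerate(zip(preds, refs)):
        rows.append({"pair": i, "split": split[i],
                     "psnr": psnr(p, t, peak=peak),
                     "pearson": pearson(p, t),
                     "ssim": ssim(p, t, C1=C1, C2=C2)})
    df = pd.DataFrame(rows)
    return MetricsReport(psnr=float(df["psnr"].mean()), pearson=float(df["pearson"].mean()),
                         ssim=float(df["ssim"].mean()), ssim_c1=C1, ssim_c2=C2,
                         data_range=peak, n_pairs=len(df), per_pair=df)
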