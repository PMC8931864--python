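"""Ground-truth phase scene generation.

Synthetic scenes play the role of the physical sample: a 2-D map of optical
path-length expressed as phase delay (radians) at a stated wavelength.  Three
generators are provided:

* :func:`make_bead_scene` — a projected sphere (polystyrene calibration bead
  immersed in index oil) whose peak phase has the closed form
  ``phi = 2*pi*d*(n - n0)/lambda``, used to validate both reconstruction
  pipelines against an analytic value;
* :func:`make_cell_scene` — a field of smooth compact blobs emulating a
  blood-smear field of view (optionally with a central dimple approximating
  the erythrocyte torus shape);
* :func:`make_dynamic_sequence` — temporal perturbations of a base scene with
  a prescribed RMS, emulating membrane fluctuations between snapshots.

All generators are pure functions of their parameters and an integer seed.
Scenes are phase-only (samples treated as transparent): amplitude is unity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import read_image, write_image

DEFAULT_PIXEL_SIZE = 0.1  # micrometres / pixel, object space
DEFAULT_GRID = 512


@dataclass(frozen=True)
class OpticalConstants:
    """Bead/medium optical parameters for the analytic phase-shift formula.

    Defaults are the calibration standard: a 1 um polystyrene bead
    (n = 1.588) in immersion oil (n0 = 1.518) under 623 nm red illumination.
    """

    d: float = 1.0       # bead diameter, micrometres
    n: float = 1.588     # bead refractive index
    n0: float = 1.518    # medium refractive index
    lam: float = 0.623   # wavelength, micrometres

    def __post_init__(self) -> None:
        for name in ("d", "n", "n0", "lam"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass
class PhaseScene:
    """Ground-truth optical path-length map; source of truth for both simulators."""

    phase: np.ndarray          # radians
    pixel_size: float          # micrometres / pixel
    wavelength: float          # micrometres
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.phase.ndim != 2 or self.phase.shape[0] != self.phase.shape[1]:
            raise ValueError("scene must be a square 2-D array")
        if self.phase.shape[0] % 2 != 0:
            raise ValueError("scene side must be even (clean FFT grids)")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("scene contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape


def peak_phase(c: OpticalConstants) -> float:
    """Expected peak phase shift of a bead: ``2*pi*d*(n - n0)/lambda`` (radians).

    For the default constants this evaluates to 0.71 rad (2 d.p.).
    """
    if c.lam <= 0:
        raise ValueError("wavelength must be positive")
    return 2.0 * np.pi * c.d * (c.n - c.n0) / c.lam


def make_bead_scene(
    c: OpticalConstants = OpticalConstants(),
    center: tuple[float, float] | None = None,
    grid: int = DEFAULT_GRID,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> PhaseScene:
    """Phase map of a projected sphere on an otherwise empty field.

    The projected thickness of a sphere of diameter ``d`` at radial distance
    ``r`` from its centre is ``2*sqrt((d/2)**2 - r**2)``, so the phase is
    ``(2*pi/lam) * (n - n0) * thickness``, with maximum equal to
    :func:`peak_phase` at the centre.

    ``center`` is in pixel coordinates (row, col); defaults to the grid
    centre pixel so that the analytic maximum is sampled exactly.
    """
    radius_um = c.d / 2.0
    radius_px = radius_um / pixel_size
    if radius_px < 1.0:
        raise ValueError("pixel_size too coarse: bead diameter must span >= 2 pixels")
    if center is None:
        center = (grid // 2, grid // 2)
    cy, cx = center
    if not (radius_px <= cy <= grid - 1 - radius_px and radius_px <= cx <= grid - 1 - radius_px):
        raise ValueError("bead does not fit inside the grid")

    yy, xx = np.mgrid[0:grid, 0:grid].astype(np.float64)
    r_um = np.hypot(yy - cy, xx - cx) * pixel_size
    thickness = np.zeros((grid, grid))
    inside = r_um <= radius_um
    thickness[inside] = 2.0 * np.sqrt(np.maximum(radius_um**2 - r_um[inside] ** 2, 0.0))
    phase = (2.0 * np.pi / c.lam) * (c.n - c.n0) * thickness
    meta = {
        "kind": "bead",
        "center": [float(cy), float(cx)],
        "optical_constants": {"d": c.d, "n": c.n, "n0": c.n0, "lam": c.lam},
    }
    return PhaseScene(phase, pixel_size, c.lam, meta)


def make_cell_scene(
    n_cells: int = 120,
    phase_range: tuple[float, float] = (0.5, 2.5),
    grid: int = DEFAULT_GRID,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    wavelength: float = 0.623,
    cell_radius_um: tuple[float, float] = (2.0, 4.5),
    dimple_fraction: float = 0.7,
    seed: int = 0,
) -> PhaseScene:
    """Field of smooth compact cell-like blobs (blood-smear emulation).

    Each cell is an elliptical super-Gaussian profile with randomized centre,
    radius, eccentricity, orientation and peak amplitude drawn from
    ``phase_range``; a fraction of cells gets a central Gaussian dimple
    (difference of two Gaussians) as a visual stand-in for the erythrocyte
    torus.  Cells are summed; the total is clipped at the upper bound of
    ``phase_range`` so the scene respects the stated dynamic range even where
    cells overlap.  Deterministic given ``seed``.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    rng = np.random.default_rng(seed)
    phase = np.zeros((grid, grid))
    yy, xx = np.mgrid[0:grid, 0:grid].astype(np.float64)
    centers = []
    lo, hi = phase_range
    for _ in range(n_cells):
        cy = rng.uniform(0, grid - 1)
        cx = rng.uniform(0, grid - 1)
        r_px = rng.uniform(*cell_radius_um) / pixel_size
        ecc = rng.uniform(0.7, 1.0)          # minor/major axis ratio
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(lo, hi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        rho2 = (u / r_px) ** 2 + (v / (r_px * ecc)) ** 2
        cell = amp * np.exp(-(rho2**2))       # super-Gaussian: flat top, compact support
        if rng.random() < dimple_fraction:
            depth = rng.uniform(0.3, 0.6)
            cell -= amp * depth * np.exp(-rho2 / 0.15)
            cell = np.maximum(cell, 0.0)
        phase += cell
        centers.append([float(cy), float(cx)])
    np.clip(phase, 0.0, hi, out=phase)
    meta = {
        "kind": "cells",
        "seed": seed,
        "n_cells": n_cells,
        "centers": centers,
        "phase_range": [float(lo), float(hi)],
    }
    return PhaseScene(phase, pixel_size, wavelength, meta)


def make_dynamic_sequence(
    base: PhaseScene,
    n_frames: int,
    fluctuation_rms: float,
    interval_ms: float = 100.0,
    correlation_px: float = 5.0,
    seed: int = 0,
) -> list[PhaseScene]:
    """Temporal sequence of scenes with membrane-fluctuation-like perturbations.

    Each frame adds an independent smooth random field, confined to the
    object support (pixels where the base phase is above 2% of its maximum),
    normalized so its RMS over the support equals ``fluctuation_rms`` radians.
    Frame metadata records the frame index and the inter-frame interval.
    With ``fluctuation_rms=0`` every frame equals the base scene.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if fluctuation_rms < 0:
        raise ValueError("fluctuation_rms must be >= 0")
    rng = np.random.default_rng(seed)
    support = base.phase > 0.02 * base.phase.max() if base.phase.max() > 0 else np.zeros(base.shape, bool)
    frames = []
    for i in range(n_frames):
        if fluctuation_rms > 0 and support.any():
            noise = ndimage.gaussian_filter(rng.standard_normal(base.shape), correlation_px)
            noise *= support
            rms = np.sqrt(np.mean(noise[support] ** 2))
            pert = noise * (fluctuation_rms / rms)
        else:
            pert = 0.0
        meta = dict(base.meta)
        meta.update({"frame": i, "interval_ms": float(interval_ms), "fluctuation_rms": float(fluctuation_rms), "seed": seed})
        frames.append(PhaseScene(base.phase + pert, base.pixel_size, base.wavelength, meta))
    return frames


def save_scene(path, scene: PhaseScene):
    """Write a scene as float32 TIFF + YAML sidecar (pixel size, wavelength, meta)."""
    meta = {"pixel_size": scene.pixel_size, "wavelength": scene.wavelength, **scene.meta}
    return write_image(path, scene.phase, meta)


def load_scene(path) -> PhaseScene:
    data, meta = read_image(path)
    pixel_size = meta.pop("pixel_size", DEFAULT_PIXEL_SIZE)
    wavelength = meta.pop("wavelength", 0.623)
    return PhaseScene(data, pixel_size, wavelength, meta)
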