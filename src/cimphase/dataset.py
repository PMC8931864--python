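"""Paired-dataset assembly: one scene -> SLIM ground truth + registered DPM.

Each pair is produced the way the combined two-port instrument produces it:

1. a cell-field scene (the sample) is generated;
2. the SLIM arm records four phase-stepped frames at 623 nm and the
   four-frame reconstruction yields the clean ground-truth phase map;
3. the DPM arm sees the same sample through an extra 2.5x 4-f relay
   (rendered as a magnified central view), records a single noisy off-axis
   interferogram at 532 nm, and the sideband reconstruction plus 532/623
   wavelength normalization yields the noisy single-shot phase map;
4. the similarity transform between the two views is estimated once from
   the first pair (the optical bench is fixed) and used to resample the
   SLIM truth onto the DPM grid, giving pixel-registered pairs.

Pairs therefore live on the DPM (magnified) grid — the grid on which the
network operates.  :func:`simulate_pairs` keeps everything in memory;
:func:`build_dataset` additionally writes TIFF/YAML artifacts plus a
manifest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import dpm as dpm_mod
from . import slim as slim_mod
from .io import write_image, write_yaml
from .registration import SimilarityTransform, register_views, resample
from .scene import make_cell_scene
from .types import PhaseMap

RELAY_MAGNIFICATION = 2.5  # extra 4-f relay magnification of the DPM arm


@dataclass(frozen=True)
class DatasetConfig:
    """Study conditions for one synthetic paired acquisition run."""

    grid: int = 256
    pixel_size: float = 0.1
    # thin-smear regime: sparse coverage and sub-radian peaks keep the
    # unscattered component dominant (|U1| < |U0|), the regime in which the
    # four-frame SLIM inversion is exact and can serve as ground truth
    n_cells: int = 12                 # scaled with the field of view (see docs)
    phase_range: tuple = (0.3, 0.9)
    cell_radius_um: tuple = (1.0, 2.5)
    magnification: float = RELAY_MAGNIFICATION
    dpm_noise: dpm_mod.DpmNoise = dpm_mod.DpmNoise(
        speckle_contrast=0.25, speckle_correlation_px=6.0,
        background_phase_amp=0.6, shot_sigma=0.01)
    slim_noise_sigma: float = 0.0
    register_each: bool = False       # fixed bench: register the first pair only


def _magnified_view(phase: np.ndarray, magnification: float) -> np.ndarray:
    """Render the central portion of a scene magnified onto the same grid."""
    t = SimilarityTransform(scale=1.0 / magnification)
    return resample(phase, t)


def simulate_pair(cfg: DatasetConfig, seed: int):
    """One (scene, slim_truth, dpm_phase) triple; dpm is on the magnified grid."""
    scene = make_cell_scene(n_cells=cfg.n_cells, phase_range=cfg.phase_range,
                            grid=cfg.grid, pixel_size=cfg.pixel_size,
                            cell_radius_um=cfg.cell_radius_um, seed=seed)
    frames = slim_mod.synthesize_slim_frames(scene, noise_sigma=cfg.slim_noise_sigma, seed=seed)
    slim_truth = slim_mod.reconstruct_slim(frames)

    dpm_scene = type(scene)(
        _magnified_view(scene.phase, cfg.magnification),
        scene.pixel_size / cfg.magnification, scene.wavelength,
        {**scene.meta, "view": f"{cfg.magnification}x relay"})
    noise = dpm_mod.DpmNoise(**{**cfg.dpm_noise.__dict__, "seed": seed})
    ig = dpm_mod.synthesize_interferogram(dpm_scene, noise=noise)
    dpm_phase = dpm_mod.reconstruct_dpm(ig)
    dpm_phase = dpm_mod.wavelength_normalize(dpm_phase, slim_truth.wavelength)
    return scene, slim_truth, dpm_phase


def calibrate_transform(
    cfg: DatasetConfig = DatasetConfig(),
    seed: int = 999_001,
    scale_bounds: tuple[float, float] = (1.0, 4.0),
) -> SimilarityTransform:
    """Estimate the DPM-onto-SLIM transform from a calibration acquisition.

    A dense field of sub-micron beads (a registration target, as used on the
    bench) is imaged through both simulated arms — including the configured
    DPM noise — and the two reconstructions are registered.  The transform
    is a property of the fixed optics, so one calibration serves a whole
    acquisition run.
    """
    n_beads = max(16, int(round(80 * (cfg.grid / 256) ** 2)))  # constant areal density
    target = make_cell_scene(n_cells=n_beads, phase_range=(0.3, 0.8), grid=cfg.grid,
                             pixel_size=cfg.pixel_size, cell_radius_um=(0.4, 1.0),
                             dimple_fraction=0.0, seed=seed)
    frames = slim_mod.synthesize_slim_frames(target, noise_sigma=cfg.slim_noise_sigma, seed=seed)
    slim_pm = slim_mod.reconstruct_slim(frames)
    dpm_scene = type(target)(
        _magnified_view(target.phase, cfg.magnification),
        target.pixel_size / cfg.magnification, target.wavelength,
        {**target.meta, "view": f"{cfg.magnification}x relay"})
    noise = dpm_mod.DpmNoise(**{**cfg.dpm_noise.__dict__, "seed": seed})
    ig = dpm_mod.synthesize_interferogram(dpm_scene, noise=noise)
    dpm_pm = dpm_mod.wavelength_normalize(dpm_mod.reconstruct_dpm(ig), slim_pm.wavelength)
    return register_views(dpm_pm, slim_pm, scale_bounds=scale_bounds)


def simulate_pairs(
    n_pairs: int,
    cfg: DatasetConfig = DatasetConfig(),
    seed: int = 0,
    scale_bounds: tuple[float, float] = (1.0, 4.0),
):
    """Registered (dpm, slim) pairs on the DPM grid, plus the transform used.

    Returns ``(pairs, transform)`` where ``pairs`` is a list of
    ``(dpm PhaseMap, slim PhaseMap)`` and ``transform`` the similarity
    transform (scale ~ the relay magnification) estimated from a
    bead-target calibration acquisition (per-pair re-registration when
    ``cfg.register_each``).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    pairs = []
    transform = calibrate_transform(cfg, seed=999_001 + seed, scale_bounds=scale_bounds)
    for i in range(n_pairs):
        _, slim_truth, dpm_phase = simulate_pair(cfg, seed=seed + i)
        if cfg.register_each:
            transform = register_views(dpm_phase, slim_truth, scale_bounds=scale_bounds)
        slim_on_dpm = resample(slim_truth, transform.inverse(), out_shape=dpm_phase.shape)
        pairs.append((dpm_phase, slim_on_dpm))
    return pairs, transform


def build_dataset(
    n_pairs: int,
    out_dir: str | Path,
    cfg: DatasetConfig = DatasetConfig(),
    seed: int = 0,
) -> Path:
    """Write a paired dataset to disk and return the manifest path.

    Layout: ``pair_<i>_dpm.tif`` / ``pair_<i>_slim.tif`` (+ YAML sidecars),
    one ``transform.yml``, and ``manifest.yml`` listing every triple.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs, transform = simulate_pairs(n_pairs, cfg=cfg, seed=seed)
    transform_path = out_dir / "transform.yml"
    transform.to_yaml(transform_path)
    entries = []
    for i, (d, s) in enumerate(pairs):
        dpath = out_dir / f"pair_{i:04d}_dpm.tif"
        spath = out_dir / f"pair_{i:04d}_slim.tif"
        write_image(dpath, d.phase, {"modality": d.modality, "wavelength": d.wavelength,
                                     "pixel_size": d.pixel_size, "seed": seed + i})
        write_image(spath, s.phase, {"modality": s.modality, "wavelength": s.wavelength,
                                     "pixel_size": s.pixel_size, "seed": seed + i})
        entries.append({"dpm_tiff": dpath.name, "slim_tiff": spath.name,
                        "transform_yaml": transform_path.name})
    manifest_path = out_dir / "manifest.yml"
    write_yaml(manifest_path, {
        "seed": seed,
        "n_pairs": n_pairs,
        "grid": cfg.grid,
        "magnification": cfg.magnification,
        "dpm_noise": cfg.dpm_noise.__dict__,
        "slim_noise_sigma": cfg.slim_noise_sigma,
        "pairs": entries,
    })
    return manifest_path


def load_dataset(manifest_path: str | Path):
    """Read a dataset written by :func:`build_dataset` back into PhaseMap pairs."""
    from .io import read_image, read_yaml

    manifest_path = Path(manifest_path)
    manifest = read_yaml(manifest_path)
    root = manifest_path.parent
    pairs = []
    for entry in manifest["pairs"]:
        d_arr, d_meta = read_image(root / entry["dpm_tiff"])
        s_arr, s_meta = read_image(root / entry["slim_tiff"])
        pairs.append((
            PhaseMap(d_arr, d_meta.get("modality", "DPM"), d_meta.get("wavelength", 0.623),
                     d_meta.get("pixel_size")),
            PhaseMap(s_arr, s_meta.get("modality", "SLIM"), s_meta.get("wavelength", 0.623),
                     s_meta.get("pixel_size")),
        ))
    return pairs, manifest
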