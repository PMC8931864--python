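"""Shared container types for phase maps.

A reconstructed phase image is always tagged with the modality that produced
it (``DPM`` single-shot off-axis, ``SLIM`` four-frame phase shifting, or
``CIM`` network inference) and the illumination wavelength, because phase in
radians is only comparable across modalities after wavelength normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODALITIES = ("DPM", "SLIM", "CIM")


@dataclass
class PhaseMap:
    """A 2-D quantitative phase image in radians.

    Parameters
    ----------
    phase : ndarray
        2-D array of phase values, radians.
    modality : str
        One of ``DPM``, ``SLIM``, ``CIM``.
    wavelength : float
        Illumination wavelength in micrometres.
    pixel_size : float, optional
        Object-space sampling in micrometres/pixel.
    meta : dict
        Free-form provenance (seed, source files, transforms applied).
    """

    phase: np.ndarray
    modality: str
    wavelength: float
    pixel_size: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.phase.ndim != 2:
            raise ValueError("phase must be a 2-D array")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase map contains non-finite values")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.phase.shape
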