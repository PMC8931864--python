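"""SLIM: four-frame phase-shifting synthesis and reconstruction.

Spatial light interference microscopy steps the phase of the unscattered
(DC) component of the image field in increments of pi/2 with a spatial light
modulator at the pupil plane, recording four intensity frames.  Writing the
image field as ``U = U0 + U1`` — ``U0`` the unscattered component (here the
spatial mean of the field, the ideal-DC-filter approximation of the ring
aperture) and ``U1 = U - U0`` the scattered component — the frame at shift
``delta`` is

    I_delta = | U0 * exp(i*delta) + U1 |^2 .

The reconstruction solves this system pointwise for the phase difference
``dphi = arg(U1) - arg(U0)`` and the amplitude ratio ``beta = |U1| / |U0|``
(weak-scattering root, |U1| <= |U0|), and assembles the object phase

    phi = arg(U / U0) = atan2(beta*sin(dphi), 1 + beta*cos(dphi)),

which inverts the forward model exactly for noiseless scenes up to the
(unobservable) global phase of U0; the background level is pinned to the
image median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dpm import unwrap_phase
from .scene import PhaseScene
from .types import PhaseMap

SLIM_WAVELENGTH = 0.623  # um, red LED (20 nm bandwidth, not spectrally modeled)
SLIM_SHIFTS = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)


@dataclass
class FrameStack:
    """Four phase-stepped SLIM intensity frames (shift order 0, pi/2, pi, 3pi/2)."""

    frames: np.ndarray                       # (4, H, W), nonnegative
    shifts: tuple = SLIM_SHIFTS
    wavelength: float = SLIM_WAVELENGTH
    pixel_size: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] != 4:
            raise ValueError("FrameStack requires exactly 4 frames of identical shape")
        if not np.allclose(self.shifts, SLIM_SHIFTS):
            raise ValueError("shifts must be (0, pi/2, pi, 3pi/2)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be nonnegative")


def synthesize_slim_frames(
    scene: PhaseScene,
    noise_sigma: float = 0.0,
    seed: int = 0,
    wavelength: float = SLIM_WAVELENGTH,
) -> FrameStack:
    """Simulate the four phase-stepped frames for a (transparent) scene.

    ``noise_sigma`` is the additive Gaussian shot-noise std as a fraction of
    the mean frame intensity; SLIM's broadband low-noise character is
    emulated by keeping it at or near zero.
    """
    phi = scene.phase * (scene.wavelength / wavelength)
    U = np.exp(1j * phi)
    U0 = U.mean()
    U1 = U - U0
    rng = np.random.default_rng(seed)
    frames = np.empty((4,) + phi.shape)
    for k, delta in enumerate(SLIM_SHIFTS):
        I = np.abs(U0 * np.exp(1j * delta) + U1) ** 2
        if noise_sigma > 0:
            I = I + rng.normal(0.0, noise_sigma * I.mean(), size=I.shape)
            np.clip(I, 0.0, None, out=I)
        frames[k] = I
    return FrameStack(frames, wavelength=wavelength, pixel_size=scene.pixel_size,
                      meta={"seed": seed, "noise_sigma": noise_sigma})


def reconstruct_slim(fs: FrameStack, discriminant_tol: float = 1e-6) -> PhaseMap:
    """Four-frame phase retrieval with amplitude-ratio (beta) correction.

    Pointwise identities of the forward model:

    * ``I_0 - I_pi = 4*|U0|*|U1|*cos(dphi)``
    * ``I_{pi/2} - I_{3pi/2} = 4*|U0|*|U1|*sin(dphi)``
    * ``sum_delta I_delta = 4*(|U0|^2 + |U1|^2)``

    from which ``dphi``, the product ``|U0||U1|`` and the sum of squares are
    read off; the quadratic for the pair (|U0|, |U1|) is solved taking the
    weak-scattering root ``|U1| <= |U0|``.  Negative discriminants (possible
    under noise) are clamped to zero; a warning is emitted when the clamped
    mass exceeds ``discriminant_tol`` of the total.
    """
    I0, I1, I2, I3 = fs.frames
    num = I1 - I3
    den = I0 - I2
    dphi = np.arctan2(num, den)
    prod = 0.25 * np.hypot(num, den)              # |U0| * |U1|
    ssum = 0.25 * (I0 + I1 + I2 + I3)             # |U0|^2 + |U1|^2
    disc = ssum**2 - 4.0 * prod**2
    neg_mass = float(np.sum(np.clip(-disc, 0, None)))
    if neg_mass > discriminant_tol * max(float(np.sum(ssum**2)), 1e-300):
        warnings.warn("inconsistent SLIM frames: negative discriminant clamped", stacklevel=2)
    disc = np.clip(disc, 0.0, None)
    u0_sq = 0.5 * (ssum + np.sqrt(disc))
    u0 = np.sqrt(np.clip(u0_sq, 1e-300, None))
    beta = prod / u0_sq                            # |U1|/|U0| = (|U0||U1|)/|U0|^2
    wrapped = np.arctan2(beta * np.sin(dphi), 1.0 + beta * np.cos(dphi))
    phase = unwrap_phase(wrapped)
    phase = phase - np.median(phase)
    return PhaseMap(phase, modality="SLIM", wavelength=fs.wavelength,
                    pixel_size=fs.pixel_size, meta=dict(fs.meta))
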