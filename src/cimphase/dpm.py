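"""Off-axis DPM: interferogram synthesis and Fourier-sideband phase retrieval.

Diffraction phase microscopy records, in a single shot, the interference of
the image field with a low-pass-filtered copy of itself travelling at a tilt.
The tilt puts the object information on a spatial carrier; demodulating the
first-order spectral sideband (the Hilbert-transform method) recovers the
complex field, whose argument is the wrapped phase.

The forward model here is

    I(x, y) = | s(x, y) * exp(i*phi_total(x, y)) + r * exp(2*pi*i*(fx*x + fy*y)) |^2

with ``phi_total`` the scene phase plus a low-order background polynomial,
and ``s`` a partially developed speckle field (coherent laser artifact):
``s = (1 - c) + c * h`` where ``h`` is a unit-power correlated circular
Gaussian field and ``c`` the speckle contrast.  Shot noise is additive
Gaussian scaled to the mean intensity.  The reconstruction deliberately knows
nothing about the noise model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.restoration import unwrap_phase as _unwrap_reliability

from .scene import PhaseScene
from .types import PhaseMap

DPM_WAVELENGTH = 0.532   # um, green fiber laser
DPM_EXPOSURE_MS = 2.0


class NoCarrierError(ValueError):
    """Raised when no off-DC spectral peak rises above the noise floor."""


@dataclass(frozen=True)
class CarrierSpec:
    """Spatial carrier introduced by the off-axis geometry.

    Frequencies are in cycles/pixel; the default diagonal carrier maximizes
    the separation between the DC term and the first-order sideband.
    """

    fx: float = 0.25
    fy: float = 0.25
    reference_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.magnitude < 0.5:
            raise ValueError("carrier magnitude must lie strictly between 0 and the Nyquist limit 0.5 cycles/px")
        if self.reference_amplitude <= 0:
            raise ValueError("reference_amplitude must be positive")

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.fx, self.fy))


@dataclass(frozen=True)
class DpmNoise:
    """Laser-DPM noise model: speckle, background non-uniformity, shot noise."""

    speckle_contrast: float = 0.0        # [0, 1]; fraction of diffuse field
    speckle_correlation_px: float = 8.0  # speckle grain size, pixels
    background_phase_amp: float = 0.0    # radians, max of the order-2 background polynomial
    shot_sigma: float = 0.0              # additive noise std, fraction of mean intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.speckle_contrast <= 1.0:
            raise ValueError("speckle_contrast must be in [0, 1]")
        if self.speckle_correlation_px < 0 or self.background_phase_amp < 0 or self.shot_sigma < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class Interferogram:
    """Single off-axis intensity frame with carrier metadata."""

    intensity: np.ndarray
    carrier: CarrierSpec | None
    wavelength: float = DPM_WAVELENGTH
    exposure_ms: float = DPM_EXPOSURE_MS
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise ValueError("interferogram must be 2-D")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("interferogram contains non-finite values")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be nonnegative")


def _speckle_field(shape, contrast: float, correlation_px: float, rng) -> np.ndarray:
    """Partially developed speckle: (1-c) specular + c times correlated circular Gaussian."""
    if contrast == 0.0:
        return np.ones(shape)
    h = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    if correlation_px > 0:
        h = ndimage.gaussian_filter(h.real, correlation_px) + 1j * ndimage.gaussian_filter(h.imag, correlation_px)
    h /= np.sqrt(np.mean(np.abs(h) ** 2))
    return (1.0 - contrast) + contrast * h


def _background_polynomial(shape, amplitude: float, rng) -> np.ndarray:
    """Random order-2 polynomial phase, scaled to the stated max amplitude (radians)."""
    if amplitude == 0.0:
        return np.zeros(shape)
    ny, nx = shape
    y = np.linspace(-1, 1, ny)[:, None]
    x = np.linspace(-1, 1, nx)[None, :]
    coeffs = rng.uniform(-1, 1, size=6)
    poly = (coeffs[0] + coeffs[1] * x + coeffs[2] * y
            + coeffs[3] * x * y + coeffs[4] * x**2 + coeffs[5] * y**2)
    peak = np.max(np.abs(poly))
    return poly * (amplitude / peak) if peak > 0 else np.zeros(shape)


def synthesize_interferogram(
    scene: PhaseScene,
    carrier: CarrierSpec = CarrierSpec(),
    noise: DpmNoise = DpmNoise(),
    wavelength: float = DPM_WAVELENGTH,
    object_amplitude: float = 1.0,
) -> Interferogram:
    """Simulate the camera frame of the off-axis interferometer.

    ``scene.phase`` is interpreted as the phase delay at ``scene.wavelength``;
    when the DPM illumination wavelength differs, the delay is rescaled by
    ``scene.wavelength / wavelength`` (phase is inversely proportional to
    wavelength for a fixed optical path-length difference).
    """
    phi = scene.phase * (scene.wavelength / wavelength)
    rng = np.random.default_rng(noise.seed)
    ny, nx = phi.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)

    phi_total = phi + _background_polynomial(phi.shape, noise.background_phase_amp, rng)
    obj = object_amplitude * _speckle_field(phi.shape, noise.speckle_contrast, noise.speckle_correlation_px, rng) \
        * np.exp(1j * phi_total)
    ref = carrier.reference_amplitude * np.exp(2j * np.pi * (carrier.fx * xx + carrier.fy * yy))
    intensity = np.abs(obj + ref) ** 2
    if noise.shot_sigma > 0:
        intensity = intensity + rng.normal(0.0, noise.shot_sigma * intensity.mean(), size=intensity.shape)
        np.clip(intensity, 0.0, None, out=intensity)
    return Interferogram(intensity, carrier, wavelength=wavelength, pixel_size=scene.pixel_size)


def estimate_carrier(ig: Interferogram, min_peak_ratio: float = 5.0) -> CarrierSpec:
    """Locate the carrier as the strongest non-DC spectral peak in one half-plane.

    Real-valued interferograms have Hermitian spectra, so only the half-plane
    ``fy > 0`` (and ``fy = 0, fx > 0``) is searched; the estimate is accurate
    to one frequency bin.  Raises :class:`NoCarrierError` when the best peak
    does not rise ``min_peak_ratio`` times above the median spectral
    magnitude (e.g. on a constant image).
    """
    img = ig.intensity - ig.intensity.mean()
    mag = np.abs(np.fft.fft2(img))
    ny, nx = mag.shape
    fy = np.fft.fftfreq(ny)[:, None] * np.ones((1, nx))
    fx = np.ones((ny, 1)) * np.fft.fftfreq(nx)[None, :]
    half = (fy > 0) | ((fy == 0) & (fx > 0))
    # exclude the immediate DC neighbourhood (residual mean / background)
    dc_guard = np.hypot(fx, fy) < 3.0 / max(ny, nx)
    valid = half & ~dc_guard
    idx = np.argmax(np.where(valid, mag, -np.inf))
    iy, ix = np.unravel_index(idx, mag.shape)
    peak = mag[iy, ix]
    # noise floor: median off-DC magnitude (zero for a pure fringe pattern)
    floor = max(float(np.median(mag[valid])), 1e-12 * float(mag.max()))
    if peak <= 0 or peak < min_peak_ratio * floor:
        raise NoCarrierError("no off-DC spectral peak above the noise floor")
    return CarrierSpec(float(fx[iy, ix]), float(fy[iy, ix]), reference_amplitude=ig.carrier.reference_amplitude if ig.carrier else 1.0)


def unwrap_phase(wrapped: np.ndarray) -> np.ndarray:
    """2-D phase unwrapping (reliability-sorted); congruent to the input mod 2*pi."""
    wrapped = np.asarray(wrapped, dtype=np.float64)
    # enforce the (-pi, pi] contract before unwrapping
    principal = np.angle(np.exp(1j * wrapped))
    return np.asarray(_unwrap_reliability(principal), dtype=np.float64)


def _fit_background_poly(phase: np.ndarray, order: int = 2, n_iter: int = 4,
                         clip_sigma: float = 2.0) -> np.ndarray:
    """Robust low-order polynomial background fit.

    Object pixels (the sample's own phase) must not be absorbed into the
    background model, so the least-squares fit is iterated with sigma
    clipping: pixels whose residual exceeds ``clip_sigma`` standard
    deviations are dropped and the fit repeated, converging onto the empty
    background for scenes that are not wall-to-wall sample.
    """
    ny, nx = phase.shape
    y = np.linspace(-1, 1, ny)[:, None] * np.ones((1, nx))
    x = np.ones((ny, 1)) * np.linspace(-1, 1, nx)[None, :]
    cols = [np.ones_like(x)]
    if order >= 1:
        cols += [x, y]
    if order >= 2:
        cols += [x * y, x**2, y**2]
    A = np.stack([c.ravel() for c in cols], axis=1)
    b = phase.ravel()
    keep = np.ones(b.size, dtype=bool)
    for _ in range(n_iter):
        coef, *_ = np.linalg.lstsq(A[keep], b[keep], rcond=None)
        resid = b - A @ coef
        sigma = resid[keep].std()
        if sigma == 0:
            break
        new_keep = np.abs(resid) < clip_sigma * sigma
        if new_keep.sum() < A.shape[1] or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return (A @ coef).reshape(phase.shape)


def reconstruct_dpm(
    ig: Interferogram,
    carrier: CarrierSpec | None = None,
    background: Interferogram | None = None,
    filter_radius_frac: float = 0.5,
    background_poly_order: int | None = 2,
) -> PhaseMap:
    """Hilbert-transform (Fourier sideband) phase retrieval.

    Steps: demodulate the intensity against the carrier, low-pass with a hard
    circular mask of radius ``filter_radius_frac * |carrier|`` (isolating the
    shifted first-order sideband at baseband), inverse transform, take the
    argument, unwrap, and remove the background phase — from a no-sample
    reference interferogram when provided, otherwise by subtracting a fitted
    low-order polynomial.  The median of the result is pinned to zero (the
    empty background level).
    """
    if carrier is None:
        carrier = ig.carrier if ig.carrier is not None else estimate_carrier(ig)
    radius = filter_radius_frac * carrier.magnitude
    if radius >= 0.75 * carrier.magnitude:
        warnings.warn("sideband filter approaches the DC term; reconstruction may mix orders", stacklevel=2)

    wrapped = _demodulate(ig.intensity, carrier, radius)
    phase = unwrap_phase(wrapped)

    if background is not None:
        bg_wrapped = _demodulate(background.intensity, carrier, radius)
        phase = phase - unwrap_phase(bg_wrapped)
    elif background_poly_order is not None:
        phase = phase - _fit_background_poly(phase, background_poly_order)
    phase = phase - np.median(phase)
    return PhaseMap(phase, modality="DPM", wavelength=ig.wavelength, pixel_size=ig.pixel_size,
                    meta={"carrier": {"fx": carrier.fx, "fy": carrier.fy}, "filter_radius": radius})


def _demodulate(intensity: np.ndarray, carrier: CarrierSpec, radius: float) -> np.ndarray:
    ny, nx = intensity.shape
    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    shifted = intensity * np.exp(-2j * np.pi * (carrier.fx * xx + carrier.fy * yy))
    F = np.fft.fft2(shifted)
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    mask = (fx**2 + fy**2) <= radius**2
    analytic = np.fft.ifft2(F * mask)
    # the baseband term is a*r*exp(-i*phi): negate the argument to recover phi
    return -np.angle(analytic)


def wavelength_normalize(pm: PhaseMap, target_wavelength: float) -> PhaseMap:
    """Rescale a phase map to the phase it would show at ``target_wavelength``.

    Phase is inversely proportional to wavelength for a fixed optical path
    difference, so the map is multiplied by ``pm.wavelength / target_wavelength``
    (e.g. a 532 nm DPM map is multiplied by 532/623 to compare with 623 nm
    SLIM).
    """
    scaled = pm.phase * (pm.wavelength / target_wavelength)
    meta = dict(pm.meta)
    meta["wavelength_normalized_from"] = pm.wavelength
    return PhaseMap(scaled, modality=pm.modality, wavelength=target_wavelength,
                    pixel_size=pm.pixel_size, meta=meta)
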