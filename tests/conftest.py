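import numpy as np
import pytest

from cimphase.scene import OpticalConstants, PhaseScene


@pytest.fixture(scope="session")
def bead() -> OpticalConstants:
    """Calibration bead: 1 um polystyrene (n=1.588) in oil (n0=1.518) at 623 nm."""
    return OpticalConstants(d=1.0, n=1.588, n0=1.518, lam=0.623)


@pytest.fixture(scope="session")
def smooth_scene_factory():
    """Band-limited random scenes (object bandwidth well below the sideband
    filter), suitable for exact round-trip reconstruction checks."""
    from scipy import ndimage

    def make(seed: int, grid: int = 128, max_phase: float = 1.2,
             correlation_px: float = 10.0, wavelength: float = 0.623) -> PhaseScene:
        rng = np.random.default_rng(seed)
        # periodic smoothing: band-limited on the FFT torus, so the sideband
        # filter passes the scene exactly (no spurious edge bandwidth)
        field = ndimage.gaussian_filter(rng.standard_normal((grid, grid)), correlation_px,
                                        mode="wrap")
        field -= field.min()
        field *= max_phase / field.max()
        return PhaseScene(field, pixel_size=0.1, wavelength=wavelength, meta={"seed": seed})

    return make
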