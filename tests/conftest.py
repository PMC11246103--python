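import numpy as np
import pytest

from pcof import (
    BeadPhantomSpec,
    GridSpec,
    make_bead_phantom,
    render_hologram,
)

#: tabletop optics: 525 nm LED illumination, 1.55 um detector pitch
WAVELENGTH = 525e-9
PITCH = 1.55e-6
Z_RECORD = 1e-3


@pytest.fixture(scope="session")
def small_grid():
    """Tiny grid for kernel-level tests."""
    return GridSpec(nx=32, ny=32, pitch=PITCH, wavelength=WAVELENGTH)


@pytest.fixture(scope="session")
def bead_grid():
    """Reduced field of view that still resolves a 30 um bead (~19 px)."""
    return GridSpec(nx=256, ny=256, pitch=PITCH, wavelength=WAVELENGTH)


@pytest.fixture(scope="session")
def single_bead(bead_grid):
    """One seeded spherical-cap bead (30 um, peak 2*pi) and its hologram."""
    obj = make_bead_phantom(BeadPhantomSpec(n_beads=1, seed=3), bead_grid)
    holo = render_hologram(obj, z=Z_RECORD)
    return obj, holo


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def band_limited_field(grid, rng, cutoff_fraction=0.25):
    """Random complex field with spectrum confined inside the Nyquist disc."""
    spectrum = rng.normal(size=grid.shape) + 1j * rng.normal(size=grid.shape)
    fx = np.fft.fftfreq(grid.nx)
    fy = np.fft.fftfreq(grid.ny)
    fx2, fy2 = np.meshgrid(fx, fy)
    spectrum[np.hypot(fx2, fy2) > cutoff_fraction] = 0.0
    return np.fft.ifft2(spectrum)
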