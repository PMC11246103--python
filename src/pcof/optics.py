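"""Scalar free-space propagation on uniform grids (angular spectrum method).

The angular spectrum method (ASM) propagates a monochromatic complex
wavefield ``U(x, y)`` over a distance ``z`` by multiplying its 2D Fourier
transform by the exact transfer function

    H(fx, fy) = exp(i * (2*pi/lambda) * z * sqrt(1 - (lambda*fx)^2 - (lambda*fy)^2))

on the propagating band ``(lambda*fx)^2 + (lambda*fy)^2 <= 1`` and zero on
the evanescent band.  ``H`` is a unitary diagonal operator on the
propagating band, so propagation conserves energy and is exactly invertible
by propagating over ``-z``.

Conventions (contractual for reproducibility):

* FFT pair: forward transform with negative exponent and no normalisation,
  inverse carries ``1/N`` (numpy's default).
* Frequency grids are FFT-ordered (DC at index ``(0, 0)``).
* Evanescent components are hard-zeroed; this prevents exponential
  amplification during backward propagation.
* No zero-padding by default.  ``pad_factor > 1`` embeds the field in a
  larger zero grid to guard against wrap-around for large ``z``; at the
  detector-plane geometry used here (z ~ 1 mm) the diffraction spread is a
  few pixels and padding is unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GridSpec",
    "FrequencyGrid",
    "ComplexField",
    "PropagationConfig",
    "make_frequency_grid",
    "angular_spectrum_tf",
    "propagate",
    "extract_phase",
]


@dataclass(frozen=True)
class GridSpec:
    """Uniform sampling grid of an optical field.

    Parameters
    ----------
    nx, ny : int
        Pixel counts along x (columns) and y (rows); at least 16.
    pitch : float
        Pixel size in meters (e.g. ``1.55e-6``).
    wavelength : float
        Illumination wavelength in meters (e.g. ``525e-9``).
    """

    nx: int
    ny: int
    pitch: float
    wavelength: float

    def __post_init__(self) -> None:
        if self.nx < 16 or self.ny < 16:
            raise ValueError(f"grid must be at least 16x16, got {self.nx}x{self.ny}")
        if not self.pitch > 0:
            raise ValueError(f"pitch must be positive, got {self.pitch}")
        if not self.wavelength > 0:
            raise ValueError(f"wavelength must be positive, got {self.wavelength}")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(ny, nx)``; pixel (0, 0) is the top-left sample."""
        return (self.ny, self.nx)


@dataclass(frozen=True)
class FrequencyGrid:
    """FFT-ordered spatial-frequency coordinates, cycles/meter."""

    fx: np.ndarray
    fy: np.ndarray
    grid: GridSpec


@dataclass
class ComplexField:
    """2D complex wavefield sampled on a :class:`GridSpec`.

    ``plane_z`` tracks the axial position of the sampling plane in meters.
    """

    values: np.ndarray
    grid: GridSpec
    plane_z: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return extract_phase(self)


@dataclass(frozen=True)
class PropagationConfig:
    """Signed propagation step.

    ``direction="forward"`` moves the field from the object plane toward the
    detector over ``+z``; ``direction="backward"`` applies the conjugate
    kernel (detector back to the object plane).
    """

    z: float
    direction: str = "forward"
    pad_factor: int = 1

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.pad_factor < 1:
            raise ValueError("pad_factor must be >= 1")

    @property
    def signed_z(self) -> float:
        return self.z if self.direction == "forward" else -self.z


def make_frequency_grid(grid: GridSpec, pad_factor: int = 1) -> FrequencyGrid:
    """FFT-ordered frequency samples ``k/(n*pitch)``; Nyquist ``1/(2*pitch)``."""
    if not grid.pitch > 0:
        raise ValueError("pitch must be positive")
    nx = grid.nx * pad_factor
    ny = grid.ny * pad_factor
    fx = np.fft.fftfreq(nx, d=grid.pitch)
    fy = np.fft.fftfreq(ny, d=grid.pitch)
    fx2d, fy2d = np.meshgrid(fx, fy)
    return FrequencyGrid(fx=fx2d, fy=fy2d, grid=grid)


def angular_spectrum_tf(
    freq: FrequencyGrid, cfg: PropagationConfig, wavelength: float | None = None
) -> np.ndarray:
    """Angular-spectrum transfer function on the frequency grid.

    Returns the complex kernel ``H(fx, fy)``; unit modulus on the
    propagating band, zero on the evanescent band.
    """
    lam = freq.grid.wavelength if wavelength is None else wavelength
    if not lam > 0:
        raise ValueError("wavelength must be positive")
    z = cfg.signed_z
    arg = 1.0 - (lam * freq.fx) ** 2 - (lam * freq.fy) ** 2
    propagating = arg > 0
    kz = np.zeros_like(arg)
    np.sqrt(arg, out=kz, where=propagating)
    h = np.exp(1j * (2.0 * np.pi / lam) * z * kz)
    h[~propagating] = 0.0
    return h


def propagate(fld: ComplexField, cfg: PropagationConfig) -> ComplexField:
    """Propagate a field by ``cfg`` using the angular spectrum kernel."""
    pad = cfg.pad_factor
    values = fld.values
    if pad > 1:
        ny, nx = values.shape
        padded = np.zeros((ny * pad, nx * pad), dtype=values.dtype)
        y0 = (ny * pad - ny) // 2
        x0 = (nx * pad - nx) // 2
        padded[y0 : y0 + ny, x0 : x0 + nx] = values
        values = padded
    freq = make_frequency_grid(fld.grid, pad_factor=pad)
    h = angular_spectrum_tf(freq, cfg)
    if h.shape != values.shape:
        raise RuntimeError(
            f"transfer function shape {h.shape} does not match field {values.shape}"
        )
    out = np.fft.ifft2(np.fft.fft2(values) * h)
    if pad > 1:
        out = out[y0 : y0 + fld.grid.ny, x0 : x0 + fld.grid.nx]
    return ComplexField(values=out, grid=fld.grid, plane_z=fld.plane_z + cfg.signed_z)


def extract_phase(fld: ComplexField | np.ndarray) -> np.ndarray:
    """Four-quadrant arctangent phase in ``(-pi, pi]``; 0 at zero-modulus pixels."""
    values = fld.values if isinstance(fld, ComplexField) else np.asarray(fld)
    phase = np.arctan2(values.imag, values.real)
    phase[values == 0] = 0.0
    return phase
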