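"""Simulated pure-phase specimens and in-line hologram rendering.

Emulates a lensless in-line digital holographic microscope: a unit-amplitude
plane wave illuminates a thin pure-phase object with transmission
``t(x, y) = exp(i * phi(x, y))``, the transmitted field propagates in free
space to the detector (angular spectrum method), and the detector records
the intensity ``I_H = |U|^2`` only.  Because the object and reference waves
share one axis, a single back-propagation of ``I_H`` superposes the focused
image with its defocused conjugate -- the twin image that the PCOF
reconstruction removes.

Built-in phantoms:

* microsphere beads (default 30 um diameter, peak phase 2*pi,
  spherical-cap profile) placed uniformly at random without overlap;
* an Archimedean-spiral ribbon of constant phase (non-centrosymmetric
  extended object);
* a binary "psi" glyph stencil.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import ComplexField, GridSpec, PropagationConfig, propagate

__all__ = [
    "PhaseObject",
    "BeadPhantomSpec",
    "Hologram",
    "make_bead_phantom",
    "make_spiral_phantom",
    "make_glyph_phantom",
    "render_hologram",
    "add_noise",
]


@dataclass
class PhaseObject:
    """Ground-truth 2D phase map (radians, >= 0) of a pure-phase specimen."""

    phase: np.ndarray
    grid: GridSpec
    ground_truth_max: float = 0.0

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.phase.shape != self.grid.shape:
            raise ValueError("phase shape does not match grid")
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase contains non-finite values")
        if self.ground_truth_max == 0.0:
            self.ground_truth_max = float(self.phase.max(initial=0.0))

    def transmission(self) -> ComplexField:
        """Thin-object transmission ``exp(i*phase)`` as a unit-illuminated field."""
        return ComplexField(np.exp(1j * self.phase), self.grid, plane_z=0.0)


@dataclass(frozen=True)
class BeadPhantomSpec:
    """Parameters of the random microsphere-bead phantom.

    ``diameter`` and ``min_separation`` (center-to-center) are in meters.
    ``profile`` is ``"spherical-cap"`` (phase follows the chord height of a
    sphere, reaching ``peak_phase`` at the bead center) or ``"top-hat"``
    (uniform ``peak_phase`` disc).  The spherical cap is the default: a
    uniform 2*pi step has transmission exp(2i*pi) = 1 and would leave no
    trace in the hologram, whereas a continuous profile through 2*pi does
    diffract and lets the peak be recovered after unwrapping.
    """

    n_beads: int = 150
    diameter: float = 30e-6
    peak_phase: float = 2.0 * np.pi
    profile: str = "spherical-cap"
    seed: int = 0
    min_separation: float | None = None  # defaults to one diameter

    def __post_init__(self) -> None:
        if self.n_beads < 0:
            raise ValueError("n_beads must be >= 0")
        if not self.diameter > 0:
            raise ValueError("diameter must be positive")
        if self.profile not in ("spherical-cap", "top-hat"):
            raise ValueError(f"unknown bead profile {self.profile!r}")


@dataclass
class Hologram:
    """Recorded intensity ``I_H >= 0`` at the detector plane."""

    intensity: np.ndarray
    grid: GridSpec
    z_record: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.shape != self.grid.shape:
            raise ValueError("intensity shape does not match grid")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")
        if self.intensity.min(initial=0.0) < 0:
            raise ValueError("intensity must be non-negative")


class PlacementError(RuntimeError):
    """Raised when non-overlapping bead placement fails after bounded retries."""


def _bead_profile(r2: np.ndarray, radius: float, peak: float, profile: str) -> np.ndarray:
    inside = r2 < radius**2
    if profile == "top-hat":
        return np.where(inside, peak, 0.0)
    cap = np.zeros_like(r2)
    np.sqrt(np.clip(1.0 - r2 / radius**2, 0.0, None), out=cap, where=inside)
    return peak * cap


def make_bead_phantom(
    spec: BeadPhantomSpec, grid: GridSpec, max_retries: int = 10_000
) -> PhaseObject:
    """Place ``n_beads`` non-overlapping beads uniformly at random (seeded).

    Bead centers stay one radius clear of the field-of-view edge.  Rejection
    sampling enforces a center-to-center distance of at least
    ``min_separation`` (default: one diameter, i.e. tangency excluded).
    """
    radius = spec.diameter / 2.0
    min_sep = spec.diameter if spec.min_separation is None else spec.min_separation
    # one-pixel guard: exactly tangent discs would merge once rasterized
    min_sep = min_sep + grid.pitch
    rng = np.random.default_rng(spec.seed)
    width = grid.nx * grid.pitch
    height = grid.ny * grid.pitch
    lo_x, hi_x = radius, width - radius
    lo_y, hi_y = radius, height - radius
    if spec.n_beads > 0 and (lo_x >= hi_x or lo_y >= hi_y):
        raise PlacementError("bead diameter exceeds the field of view")

    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < spec.n_beads:
        if tries >= max_retries:
            raise PlacementError(
                f"could not place {spec.n_beads} beads without overlap "
                f"after {max_retries} tries"
            )
        tries += 1
        cx = rng.uniform(lo_x, hi_x)
        cy = rng.uniform(lo_y, hi_y)
        if all((cx - px) ** 2 + (cy - py) ** 2 >= min_sep**2 for px, py in centers):
            centers.append((cx, cy))

    phase = np.zeros(grid.shape)
    x = (np.arange(grid.nx) + 0.5) * grid.pitch
    y = (np.arange(grid.ny) + 0.5) * grid.pitch
    # only rasterize a local patch per bead
    rpx = int(np.ceil(radius / grid.pitch)) + 2
    for cx, cy in centers:
        ix = int(cx / grid.pitch)
        iy = int(cy / grid.pitch)
        sx = slice(max(ix - rpx, 0), min(ix + rpx + 1, grid.nx))
        sy = slice(max(iy - rpx, 0), min(iy + rpx + 1, grid.ny))
        xx, yy = np.meshgrid(x[sx], y[sy])
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        patch = _bead_profile(r2, radius, spec.peak_phase, spec.profile)
        np.maximum(phase[sy, sx], patch, out=phase[sy, sx])

    gt_max = spec.peak_phase if spec.n_beads > 0 else 0.0
    return PhaseObject(phase=phase, grid=grid, ground_truth_max=gt_max)


def make_spiral_phantom(
    grid: GridSpec,
    peak_phase: float = np.pi,
    turns: float = 3.0,
    arm_width: float = 8.0,
) -> PhaseObject:
    """Archimedean-spiral ribbon of constant phase on a zero background.

    ``arm_width`` is the ribbon thickness in pixels (>= 2).  The spiral
    ``r = a*theta`` is non-centrosymmetric by construction, exercising
    reconstruction of extended, asymmetric objects.
    """
    if turns <= 0:
        raise ValueError("turns must be positive")
    if arm_width < 2:
        raise ValueError("arm_width must be at least 2 pixels")
    ny, nx = grid.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)  # (-pi, pi]
    r_max = 0.42 * min(nx, ny)
    total_angle = 2.0 * np.pi * turns
    a = r_max / total_angle
    # unwrapped angle candidates theta + 2*pi*k; ribbon where |r - a*angle| < w/2
    k = np.arange(int(np.ceil(turns)) + 2)
    angle = theta[..., None] + 2.0 * np.pi * k
    dist = np.abs(r[..., None] - a * angle)
    on_arm = (
        (dist < arm_width / 2.0) & (angle > 0) & (angle <= total_angle)
    ).any(axis=-1)
    phase = np.where(on_arm, peak_phase, 0.0)
    return PhaseObject(phase=phase, grid=grid, ground_truth_max=peak_phase)


def _psi_stencil(ny: int, nx: int) -> np.ndarray:
    """Rasterize a Greek-letter-psi (trident) stencil on a normalized frame."""
    yy, xx = np.mgrid[0:ny, 0:nx]
    s = min(nx, ny)
    x = (xx - (nx - 1) / 2.0) / (s / 2.0)
    y = ((ny - 1) / 2.0 - yy) / (s / 2.0)  # y up
    stem = (np.abs(x) < 0.07) & (y > -0.62) & (y < 0.58)
    base = (np.abs(x) < 0.24) & (y > -0.62) & (y < -0.50)
    rr = np.hypot(x, y - 0.12)
    bowl = (rr > 0.36) & (rr < 0.50) & (y <= 0.12)
    arms = (np.abs(np.abs(x) - 0.43) < 0.07) & (y >= 0.12) & (y < 0.58)
    return stem | base | bowl | arms


def make_glyph_phantom(
    grid: GridSpec, glyph: str = "psi", peak_phase: float = np.pi
) -> PhaseObject:
    """Binary glyph stencil times ``peak_phase`` (default: psi at a pi step)."""
    if glyph != "psi":
        raise ValueError(f"unknown glyph {glyph!r}; available: 'psi'")
    stencil = _psi_stencil(*grid.shape)
    return PhaseObject(
        phase=stencil * float(peak_phase), grid=grid, ground_truth_max=float(peak_phase)
    )


def render_hologram(obj: PhaseObject, z: float, pad_factor: int = 1) -> Hologram:
    """Render the in-line hologram of a pure-phase object at distance ``z``.

    Plane-wave illumination of unit amplitude; the transmitted field
    ``exp(i*phase)`` is propagated forward by ``z`` and the squared modulus
    is recorded.
    """
    if not z > 0:
        raise ValueError("recording distance z must be positive")
    cfg = PropagationConfig(z=z, direction="forward", pad_factor=pad_factor)
    at_detector = propagate(obj.transmission(), cfg)
    intensity = np.abs(at_detector.values) ** 2
    return Hologram(intensity=intensity, grid=obj.grid, z_record=z)


def add_noise(
    holo: Hologram, model: str = "gaussian", level: float = 0.01, seed: int = 0
) -> Hologram:
    """Add detector noise; output clipped at zero.

    ``model="gaussian"``: additive zero-mean noise of standard deviation
    ``level`` (intensity units).  ``model="poisson"``: shot noise with
    ``level`` photons per unit intensity (larger = cleaner); ``level`` is
    the full-well photon count at I = 1.
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    if model not in ("gaussian", "poisson"):
        raise ValueError(f"unknown noise model {model!r}")
    if level == 0:
        return Hologram(holo.intensity.copy(), holo.grid, holo.z_record)
    rng = np.random.default_rng(seed)
    if model == "gaussian":
        noisy = holo.intensity + rng.normal(0.0, level, holo.intensity.shape)
    else:
        noisy = rng.poisson(holo.intensity * level).astype(np.float64) / level
    return Hologram(np.clip(noisy, 0.0, None), holo.grid, holo.z_record)
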