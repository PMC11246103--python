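"""Hologram reconstruction: ASM baseline, PCOF pipeline, ItPR baseline.

Three reconstruction routes for a single in-line hologram:

* :func:`reconstruct_asm` -- one backward angular-spectrum propagation of
  the recorded intensity.  Fast, but the defocused conjugate (twin) image
  remains superposed on the object as "ringing".
* :func:`pcof_reconstruct` -- phase-support constraint on the phase-only
  function.  Single pass, no iteration:

  1. preprocess the hologram (linear rescale to unit mean) and
     back-propagate it to the object plane;
  2. segment the object support from a sliding-window variance map of the
     reconstructed phase (window 5x5 by default), threshold at a fraction
     of the map maximum, mask the phase and smooth with a Gaussian blur;
  3. form the unit-amplitude phase-only field exp(i*phi) and propagate it
     forward to the detector;
  4. divide the recorded hologram by the squared reference beam (DC
     suppression), attach the forward-propagated phase to it, and
     back-propagate once more.  The phase of that field, unwrapped, is the
     twin-free object phase.

* :func:`itpr_reconstruct` -- Gerchberg-Saxton-type alternating
  projections (detector-amplitude replacement, object-plane unit amplitude
  with non-negative phase), 30 iterations by default.

All reconstruction-side propagations use the carrier-removed kernel
(``exp(i*k*z*(sqrt(1 - (lambda*f)^2) - 1))``), i.e. phases are referenced
to the illuminating plane wave so a featureless hologram reconstructs to
zero phase rather than to the propagation piston ``k*z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict

import numpy as np
from scipy import ndimage
from skimage import restoration

from .optics import (
    ComplexField,
    GridSpec,
    PropagationConfig,
    extract_phase,
    make_frequency_grid,
    angular_spectrum_tf,
    propagate,
)
from .phantoms import Hologram

__all__ = [
    "PhaseMap",
    "VarianceMap",
    "SupportMask",
    "ReferenceBeam",
    "ReconstructionResult",
    "PCOFParams",
    "preprocess_hologram",
    "reconstruct_asm",
    "variance_map",
    "threshold_mask",
    "apply_support",
    "phase_only",
    "dc_filter",
    "estimate_reference",
    "recombine",
    "pcof_reconstruct",
    "itpr_reconstruct",
    "unwrap_phase",
]


@dataclass
class PhaseMap:
    """2D phase map in radians; ``wrapped`` maps lie in ``(-pi, pi]``."""

    values: np.ndarray
    wrapped: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.wrapped:
            v = self.values
            if v.size and (v.min() <= -np.pi - 1e-12 or v.max() > np.pi + 1e-12):
                raise ValueError("wrapped phase must lie in (-pi, pi]")


@dataclass
class VarianceMap:
    """Sliding-window variance statistic of a phase map (values >= 0)."""

    values: np.ndarray
    window: int
    mode: str = "as-printed"


@dataclass
class SupportMask:
    """Binary support mask ``phi_mask`` derived from variance thresholding."""

    values: np.ndarray
    threshold: float
    threshold_fraction: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("mask values must be exactly 0 or 1")
        self.values = v.astype(np.float64)


@dataclass
class ReferenceBeam:
    """Reference wave ``U_r``; modulus floored away from zero before division."""

    values: np.ndarray
    model: str = "plane"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if np.abs(self.values).min() <= 0:
            raise ValueError("reference modulus must be positive (apply a floor)")


@dataclass
class ReconstructionResult:
    """Output of one reconstruction run.

    ``phase`` is the unwrapped object phase; ``phase_wrapped`` the raw
    four-quadrant phase of ``field``.  ``params`` records every parameter
    needed to replay the run; ``diagnostics`` holds method-specific
    intermediates (support mask, variance map, ItPR residual history).
    """

    field: ComplexField
    phase: PhaseMap
    phase_wrapped: PhaseMap
    amplitude: np.ndarray
    method: str
    params: dict
    diagnostics: dict = dc_field(default_factory=dict)


@dataclass(frozen=True)
class PCOFParams:
    """Tunable parameters of the PCOF pipeline.

    window : odd sliding-window size in pixels (default 5).
    threshold_fraction : tau as a fraction of the reference maximum
        (default 0.5, i.e. 50%).
    threshold_mode : "variance-max" (tau = fraction * max of the variance
        map; the default, since the mask compares V > tau) or "phase-max"
        (fraction * max of the phase map).
    variance_mode : "as-printed" (squares ``phi^2 - mu``) or "standard"
        (textbook variance, squares ``phi - mu``).
    blur_sigma : Gaussian blur width in pixels applied to the masked phase.
    reference : "plane" (U_r = 1, appropriate for simulations) or
        "estimated" (Gaussian low-pass of sqrt(I), width ``ref_sigma``).
    """

    window: int = 5
    threshold_fraction: float = 0.5
    threshold_mode: str = "variance-max"
    variance_mode: str = "as-printed"
    blur_sigma: float = 1.0
    reference: str = "plane"
    ref_sigma: float = 20.0


def preprocess_hologram(holo: Hologram) -> Hologram:
    """Linear contrast normalisation: rescale the intensity to unit mean."""
    mean = holo.intensity.mean()
    if mean <= 0:
        raise ValueError("hologram has non-positive mean intensity")
    return Hologram(holo.intensity / mean, holo.grid, holo.z_record)


def _backward(values: np.ndarray, grid: GridSpec, z: float) -> ComplexField:
    fld = ComplexField(values, grid)
    out = propagate(fld, PropagationConfig(z=z, direction="backward"))
    # reference the phase to the illuminating plane wave (remove the kz piston)
    out.values *= np.exp(1j * 2.0 * np.pi * z / grid.wavelength)
    out.plane_z = 0.0
    return out


def _forward(fld: ComplexField, z: float) -> ComplexField:
    out = propagate(fld, PropagationConfig(z=z, direction="forward"))
    out.values *= np.exp(-1j * 2.0 * np.pi * z / fld.grid.wavelength)
    return out


def reconstruct_asm(holo: Hologram, grid: GridSpec, z: float) -> ReconstructionResult:
    """Conventional single back-propagation; the twin image is not suppressed."""
    if z < 0:
        raise ValueError("reconstruction distance must be >= 0")
    pre = preprocess_hologram(holo)
    u_s = _backward(pre.intensity, grid, z)
    wrapped = extract_phase(u_s)
    unwrapped = unwrap_phase(PhaseMap(wrapped, wrapped=True))
    return ReconstructionResult(
        field=u_s,
        phase=unwrapped,
        phase_wrapped=PhaseMap(wrapped, wrapped=True),
        amplitude=np.abs(u_s.values),
        method="asm",
        params={"z": z, "wavelength": grid.wavelength, "pitch": grid.pitch},
    )


def variance_map(phase: PhaseMap | np.ndarray, m: int = 5, mode: str = "as-printed") -> VarianceMap:
    """Sliding-window variance statistic over centered ``m x m`` blocks.

    ``mode="as-printed"`` computes ``V = mean[(phi^2 - mu)^2]`` with
    ``mu = mean(phi)`` over the window -- the difference between squared
    phase values and the local arithmetic mean.  Because ``phi^2`` differs
    from ``mu`` wherever the phase is large *or* varying, this statistic
    lights up the whole object support, not just its edges, which is what
    makes it usable as a support detector.  ``mode="standard"`` is the
    textbook local variance ``mean[(phi - mu)^2]`` (edge detector only).
    Edges of the image are handled by reflective padding.
    """
    phi = phase.values if isinstance(phase, PhaseMap) else np.asarray(phase, float)
    if m % 2 == 0 or m < 3:
        raise ValueError("window size must be odd and >= 3")
    if m > min(phi.shape):
        raise ValueError(f"window {m} exceeds image extent {phi.shape}")
    if mode not in ("as-printed", "standard"):
        raise ValueError(f"unknown variance mode {mode!r}")
    win = {"size": m, "mode": "reflect"}
    mu = ndimage.uniform_filter(phi, **win)
    if mode == "as-printed":
        m2 = ndimage.uniform_filter(phi**2, **win)
        m4 = ndimage.uniform_filter(phi**4, **win)
        v = m4 - 2.0 * mu * m2 + mu**2
    else:
        m2 = ndimage.uniform_filter(phi**2, **win)
        v = m2 - mu**2
    np.clip(v, 0.0, None, out=v)
    return VarianceMap(values=v, window=m, mode=mode)


def threshold_mask(
    vmap: VarianceMap,
    phase: PhaseMap | np.ndarray | None = None,
    fraction: float = 0.5,
    mode: str = "variance-max",
) -> SupportMask:
    """Binary mask: 1 where ``V > tau``, else 0 (strict inequality).

    ``tau = fraction * max(V)`` in mode ``"variance-max"`` (default), or
    ``fraction * max(phi)`` in mode ``"phase-max"``.  An all-zero variance
    map yields an all-zero mask.
    """
    if not 0 < fraction < 1:
        raise ValueError("threshold fraction must lie in (0, 1)")
    if mode == "variance-max":
        ref_max = float(vmap.values.max(initial=0.0))
    elif mode == "phase-max":
        if phase is None:
            raise ValueError("phase-max mode requires the phase map")
        phi = phase.values if isinstance(phase, PhaseMap) else np.asarray(phase)
        ref_max = float(phi.max(initial=0.0))
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    tau = fraction * ref_max
    mask = (vmap.values > tau).astype(np.float64)
    return SupportMask(values=mask, threshold=tau, threshold_fraction=fraction)


def apply_support(
    phase: PhaseMap, mask: SupportMask, blur_sigma: float = 1.0
) -> PhaseMap:
    """Pointwise product ``phi * phi_mask``, then a normalised Gaussian blur."""
    if phase.values.shape != mask.values.shape:
        raise ValueError("phase and mask shapes differ")
    out = phase.values * mask.values
    if blur_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=blur_sigma, mode="reflect")
    return PhaseMap(out, wrapped=False)


def phase_only(fld: ComplexField) -> ComplexField:
    """Unit-modulus field ``exp(i*arg(U))``; zero pixels map to ``1+0j``."""
    out = np.exp(1j * extract_phase(fld))
    return ComplexField(out, fld.grid, plane_z=fld.plane_z)


def estimate_reference(holo: Hologram, sigma: float = 20.0) -> ReferenceBeam:
    """Estimate ``U_r`` as a Gaussian low-pass of ``sqrt(I_H)``, floored.

    Appropriate for experimental holograms with a non-uniform illumination
    envelope; the floor (1e-6 of the maximum) keeps the subsequent division
    finite everywhere.
    """
    amp = ndimage.gaussian_filter(np.sqrt(holo.intensity), sigma=sigma, mode="reflect")
    floor = 1e-6 * amp.max(initial=0.0)
    if floor == 0:
        amp = np.ones_like(amp)
    else:
        amp = np.clip(amp, floor, None)
    return ReferenceBeam(values=amp.astype(np.complex128), model="estimated")


def dc_filter(holo: Hologram, ref: ReferenceBeam) -> Hologram:
    """Suppress the DC term: divide the hologram by ``|U_r|^2``."""
    denom = np.abs(ref.values) ** 2
    return Hologram(holo.intensity / denom, holo.grid, holo.z_record)


def recombine(filtered: Hologram, forward_field: ComplexField) -> ComplexField:
    """Attach the phase of the forward-propagated field to the filtered hologram.

    ``I_Hnew = I_H x exp(i * arg(U_o))``: amplitude from the measurement,
    phase from the support-constrained estimate.
    """
    if filtered.intensity.shape != forward_field.values.shape:
        raise ValueError("hologram and field shapes differ")
    values = filtered.intensity * np.exp(1j * extract_phase(forward_field))
    return ComplexField(values, forward_field.grid, plane_z=forward_field.plane_z)


def pcof_reconstruct(
    holo: Hologram, grid: GridSpec, z: float, params: PCOFParams | None = None
) -> ReconstructionResult:
    """Full single-pass PCOF reconstruction (see module docstring)."""
    if not z > 0:
        raise ValueError("reconstruction distance must be positive")
    p = params or PCOFParams()

    pre = preprocess_hologram(holo)
    u_s = _backward(pre.intensity, grid, z)
    phi_o = PhaseMap(extract_phase(u_s), wrapped=True)

    vmap = variance_map(phi_o, m=p.window, mode=p.variance_mode)
    mask = threshold_mask(vmap, phi_o, fraction=p.threshold_fraction, mode=p.threshold_mode)
    phi = apply_support(phi_o, mask, blur_sigma=p.blur_sigma)

    constrained = ComplexField(np.exp(1j * phi.values), grid)
    u_o = _forward(constrained, z)

    if p.reference == "plane":
        ref = ReferenceBeam(np.ones(grid.shape, dtype=np.complex128), model="plane")
    elif p.reference == "estimated":
        ref = estimate_reference(pre, sigma=p.ref_sigma)
    else:
        raise ValueError(f"unknown reference model {p.reference!r}")
    filtered = dc_filter(pre, ref)

    i_new = recombine(filtered, u_o)
    u_obj = _backward(i_new.values, grid, z)
    # i_new is complex; _backward built it from values directly
    wrapped = PhaseMap(extract_phase(u_obj), wrapped=True)
    unwrapped = unwrap_phase(wrapped)

    return ReconstructionResult(
        field=u_obj,
        phase=unwrapped,
        phase_wrapped=wrapped,
        amplitude=np.abs(u_obj.values),
        method="pcof",
        params={"z": z, "wavelength": grid.wavelength, "pitch": grid.pitch, **asdict(p)},
        diagnostics={"variance_map": vmap, "support_mask": mask, "masked_phase": phi},
    )


def itpr_reconstruct(
    holo: Hologram, grid: GridSpec, z: float, n_iter: int = 30
) -> ReconstructionResult:
    """Gerchberg-Saxton-type iterative phase retrieval baseline.

    Alternates between the detector plane, where the field amplitude is
    replaced by ``sqrt(I_H)``, and the object plane, where the estimate is
    projected onto unit-amplitude fields with non-negative phase.  Returns
    the object-plane estimate after ``n_iter`` iterations together with the
    per-iteration detector-amplitude residual (RMS); non-convergence is
    reported through the residual history, never raised.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    pre = preprocess_hologram(holo)
    meas_amp = np.sqrt(pre.intensity)
    theta = np.zeros(grid.shape)
    residuals: list[float] = []
    constrained = None
    for _ in range(n_iter):
        u_det = ComplexField(meas_amp * np.exp(1j * theta), grid, plane_z=z)
        u_obj = _backward(u_det.values, grid, z)
        # positivity is imposed on the unwrapped phase: clamping the wrapped
        # phase would shred any object whose phase exceeds pi
        phi_u = restoration.unwrap_phase(extract_phase(u_obj))
        phi = np.clip(phi_u, 0.0, None)  # non-negative phase, |U| = 1
        constrained = ComplexField(np.exp(1j * phi), grid)
        u_fwd = _forward(constrained, z)
        residuals.append(float(np.sqrt(np.mean((np.abs(u_fwd.values) - meas_amp) ** 2))))
        theta = extract_phase(u_fwd)
    wrapped = PhaseMap(extract_phase(constrained), wrapped=True)
    # phi is already the unwrapped, clamped object phase of the final iterate
    unwrapped = PhaseMap(phi, wrapped=False)
    return ReconstructionResult(
        field=constrained,
        phase=unwrapped,
        phase_wrapped=wrapped,
        amplitude=np.abs(constrained.values),
        method="itpr",
        params={
            "z": z,
            "wavelength": grid.wavelength,
            "pitch": grid.pitch,
            "n_iter": n_iter,
        },
        diagnostics={"residuals": residuals},
    )


def unwrap_phase(phase: PhaseMap) -> PhaseMap:
    """2D phase unwrapping (reliability-sorted); output - input is in 2*pi*Z."""
    unwrapped = restoration.unwrap_phase(phase.values)
    return PhaseMap(np.asarray(unwrapped, dtype=np.float64), wrapped=False)
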