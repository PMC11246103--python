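"""Image-quality metrics: MSE, PSNR, MSSIM, and phase-to-thickness.

All comparisons are made on an 8-bit-equivalent scale: both phase maps are
linearly mapped from ``[0, reference_max]`` radians to ``[0, 255]`` gray
levels (clipped outside) before computing metrics.  Under this convention
the pair (MSE, PSNR) satisfies ``PSNR = 10*log10(255^2 / MSE)`` exactly.

MSSIM is the mean of the local structural-similarity index computed with a
Gaussian-weighted window (default 11x11, sigma 1.5) and stability
constants ``C1 = (K1*L)^2``, ``C2 = (K2*L)^2`` with dynamic range
``L = 255``, ``K1 = 0.01``, ``K2 = 0.03``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
from skimage.metrics import structural_similarity

from .reconstruct import PhaseMap, ReconstructionResult

__all__ = [
    "MetricReport",
    "to_metric_scale",
    "mse",
    "psnr",
    "mssim",
    "phase_to_thickness",
    "evaluate",
]

#: PSNR sentinel for a perfect reconstruction (MSE = 0).
PSNR_INF = np.inf


@dataclass(frozen=True)
class MetricReport:
    """MSE / PSNR / MSSIM triple on a common intensity scale."""

    mse: float
    psnr: float
    mssim: float
    scale_max: float = 255.0
    window: int = 11
    sigma: float = 1.5
    c1: float = (0.01 * 255.0) ** 2
    c2: float = (0.03 * 255.0) ** 2

    def to_json(self) -> str:
        d = asdict(self)
        if np.isinf(d["psnr"]):
            d["psnr"] = "inf"
        return json.dumps(d, indent=2)


def to_metric_scale(
    phase_map: np.ndarray | PhaseMap, reference_max: float
) -> np.ndarray:
    """Linear map ``[0, reference_max] -> [0, 255]``; values outside clipped."""
    if not reference_max > 0:
        raise ValueError("reference_max must be positive")
    values = phase_map.values if isinstance(phase_map, PhaseMap) else np.asarray(phase_map)
    return np.clip(values / reference_max * 255.0, 0.0, 255.0)


def _as_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(a, b) -> float:
    """Mean squared error ``(1/MN) * sum (rho - rho_o)^2``."""
    a, b = _as_pair(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(a, b, scale_max: float = 255.0) -> float:
    """Peak signal-to-noise ratio ``10*log10(scale_max^2 / MSE)`` in dB."""
    err = mse(a, b)
    if err == 0:
        return PSNR_INF
    return float(10.0 * np.log10(scale_max**2 / err))


def mssim(
    a,
    b,
    window: int = 11,
    sigma: float = 1.5,
    k1: float = 0.01,
    k2: float = 0.03,
    scale_max: float = 255.0,
) -> float:
    """Mean structural similarity index over Gaussian-weighted local windows.

    1 means identical images; values can be negative for structurally
    inverted content.  ``window`` must be odd and no larger than the image.
    """
    a, b = _as_pair(a, b)
    if window % 2 == 0:
        raise ValueError("SSIM window must be odd")
    if window > min(a.shape):
        raise ValueError(f"image {a.shape} smaller than SSIM window {window}")
    value = structural_similarity(
        a,
        b,
        win_size=window,
        gaussian_weights=True,
        sigma=sigma,
        K1=k1,
        K2=k2,
        data_range=scale_max,
        use_sample_covariance=False,
    )
    return float(value)


def phase_to_thickness(
    unwrapped_phase: np.ndarray | PhaseMap,
    wavelength: float,
    n_obj: float,
    n_med: float,
) -> np.ndarray:
    """Convert an unwrapped phase map to physical thickness in meters.

    ``t = phi * lambda / (2*pi * (n_obj - n_med))`` for a specimen of
    refractive index ``n_obj`` immersed in a medium ``n_med``.
    """
    if n_obj == n_med:
        raise ValueError("refractive-index contrast is zero (n_obj == n_med)")
    phi = (
        unwrapped_phase.values
        if isinstance(unwrapped_phase, PhaseMap)
        else np.asarray(unwrapped_phase, dtype=np.float64)
    )
    return phi * wavelength / (2.0 * np.pi * (n_obj - n_med))


def evaluate(
    reconstruction: ReconstructionResult | np.ndarray | PhaseMap,
    ground_truth: np.ndarray | PhaseMap,
    window: int = 11,
    sigma: float = 1.5,
) -> MetricReport:
    """Score a reconstructed phase map against the ground truth.

    Both maps are scaled to [0, 255] using the ground-truth maximum as the
    common reference before computing MSE, PSNR and MSSIM.
    """
    if isinstance(reconstruction, ReconstructionResult):
        rec_values = reconstruction.phase.values
    elif isinstance(reconstruction, PhaseMap):
        rec_values = reconstruction.values
    else:
        rec_values = np.asarray(reconstruction, dtype=np.float64)
    gt_values = (
        ground_truth.values
        if isinstance(ground_truth, PhaseMap)
        else np.asarray(ground_truth, dtype=np.float64)
    )
    reference_max = float(gt_values.max(initial=0.0))
    if reference_max <= 0:
        raise ValueError("ground truth has no positive phase; metrics undefined")
    rec = to_metric_scale(rec_values, reference_max)
    gt = to_metric_scale(gt_values, reference_max)
    return MetricReport(
        mse=mse(rec, gt),
        psnr=psnr(rec, gt),
        mssim=mssim(rec, gt, window=window, sigma=sigma),
        window=window,
        sigma=sigma,
    )
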