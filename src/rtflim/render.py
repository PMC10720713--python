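"""Headless compositing of the lifetime image.

Pixels are colored by their estimated lifetime through a colormap (turbo by
default), scaled in brightness by their photon intensity, and blacked out
where the fit is invalid or fails the user's lifetime / chi-square
thresholds.  The output is a plain ``[rows, cols, 3]`` float RGB array in
[0, 1] that any display layer can show; nothing here mutates analysis
results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import matplotlib

import numpy as np

from .fitcore import RLDField
from .session import AnalysisSettings

__all__ = ["LifetimeImage", "InvalidRangeError", "threshold_mask", "compose"]


class InvalidRangeError(ValueError):
    """Display lifetime range has non-positive extent."""


@dataclass(frozen=True)
class LifetimeImage:
    """Composited RGB lifetime image plus the fields it was built from."""

    rgb: np.ndarray
    tau: np.ndarray
    mask: np.ndarray
    tau_range: tuple[float, float]


def threshold_mask(field: RLDField, settings: AnalysisSettings) -> np.ndarray:
    """Pixels passing validity plus the lifetime and chi-square thresholds.

    A pixel passes iff its RLD fit is valid, its lifetime lies within
    ``[tau_min, tau_max]`` and its *reduced* chi-square is at most
    ``chi2_max``; absent bounds always pass.
    """
    mask = field.valid.copy()
    with np.errstate(invalid="ignore"):
        if settings.tau_min is not None:
            mask &= field.tau >= settings.tau_min
        if settings.tau_max is not None:
            mask &= field.tau <= settings.tau_max
        if settings.chi2_max is not None:
            mask &= field.chi2_reduced <= settings.chi2_max
    return mask


def _auto_tau_range(tau: np.ndarray, mask: np.ndarray) -> tuple[float, float]:
    """Default display range: [1st, 99th] percentile of passing lifetimes."""
    passing = tau[mask]
    if passing.size == 0:
        return (0.0, 1.0)
    lo, hi = np.percentile(passing, [1.0, 99.0])
    if hi <= lo:  # uniform lifetime: pad so the colormap midpoint is used
        lo, hi = lo - 0.5, hi + 0.5
    return float(lo), float(hi)


def compose(
    tau: np.ndarray,
    intensity: np.ndarray,
    mask: np.ndarray,
    colormap: str = "turbo",
    display_tau_range: Optional[tuple[float, float]] = None,
    intensity_norm: Optional[float] = None,
) -> LifetimeImage:
    """Build the lifetime-colored, intensity-scaled RGB image.

    Hue encodes ``clip((tau - lo) / (hi - lo), 0, 1)`` through the colormap;
    brightness multiplies by ``clip(intensity / intensity_norm, 0, 1)`` where
    the normalization defaults to the 99th percentile of the intensity image
    (robust against hot pixels; pass ``intensity_norm`` to pin the scale
    across frames).  Masked-out or invalid pixels render black.  A pure
    function of its inputs: same arrays in, same image out.
    """
    tau = np.asarray(tau, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if tau.shape != intensity.shape or tau.shape != mask.shape:
        raise ValueError("tau, intensity and mask shapes must match")

    if display_tau_range is None:
        lo, hi = _auto_tau_range(tau, mask)
    else:
        lo, hi = float(display_tau_range[0]), float(display_tau_range[1])
        if hi <= lo:
            raise InvalidRangeError(f"display tau range [{lo}, {hi}] has no extent")

    with np.errstate(invalid="ignore"):
        norm = np.clip((tau - lo) / (hi - lo), 0.0, 1.0)
    norm = np.where(mask, norm, 0.0)
    cmap = matplotlib.colormaps[colormap]
    rgb = np.asarray(cmap(norm))[..., :3]

    if intensity_norm is None:
        intensity_norm = float(np.percentile(intensity, 99.0))
    if intensity_norm > 0:
        brightness = np.clip(intensity / intensity_norm, 0.0, 1.0)
    else:
        brightness = np.zeros_like(intensity)
    rgb = rgb * np.where(mask, brightness, 0.0)[..., None]
    return LifetimeImage(rgb=rgb, tau=tau, mask=mask, tau_range=(lo, hi))
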