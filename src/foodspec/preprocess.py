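"""Three-stage spectral preprocessing: zero correction, L2 normalization, smoothing.

Each stage acts on one spectrum at a time, so the chain can be applied to a
whole set up front without any train/test leakage (no statistic is pooled
across rows).

* **Zero correction** subtracts the spectrum's minimum, removing any constant
  offset such as a uniform ambient-light floor.
* **Two-norm normalization** scales the spectrum to unit Euclidean length.
  Measured intensity varies with the distance between sensor, light source
  and object; scaling to unit norm cancels that multiplicative factor.
* **Savitzky-Golay smoothing** replaces each point by the centre value of a
  least-squares polynomial fitted over a sliding window (default window 31
  points, polynomial order 3).  Within the first and last half-window the
  edge polynomial is evaluated directly, avoiding boundary discontinuities.

The window is specified in points, not nanometres: on a grid with different
spacing the physical bandwidth changes, and the config never rescales it
silently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraSet, Spectrum

__all__ = [
    "PreprocessConfig",
    "zero_correct",
    "l2_normalize",
    "savgol_smooth",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Stage toggles and smoothing parameters for the preprocessing chain."""

    do_zero: bool = True
    do_normalize: bool = True
    do_smooth: bool = True
    sg_window: int = 31
    sg_polyorder: int = 3

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError(f"sg_window must be odd, got {self.sg_window}")
        if self.sg_window <= self.sg_polyorder:
            raise ValueError(
                f"sg_window ({self.sg_window}) must exceed sg_polyorder ({self.sg_polyorder})"
            )


def zero_correct(x: Spectrum) -> Spectrum:
    """Subtract the spectrum's minimum so its floor is exactly zero."""
    v = x.intensities
    if v.size == 0:
        raise ValueError("cannot zero-correct an empty spectrum")
    return replace(x, intensities=v - v.min())


def l2_normalize(x: Spectrum) -> Spectrum:
    """Scale the spectrum to unit Euclidean norm."""
    v = x.intensities
    norm = float(np.linalg.norm(v))
    if norm == 0.0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return replace(x, intensities=v / norm)


def savgol_smooth(x: Spectrum, window: int = 31, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing with polynomial-fit edge handling.

    ``window`` must be odd and greater than ``polyorder``, and the spectrum
    must have at least ``window`` points.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError(f"window ({window}) must exceed polyorder ({polyorder})")
    v = x.intensities
    if v.size < window:
        raise ValueError(f"spectrum length {v.size} shorter than window {window}")
    smoothed = savgol_filter(v, window_length=window, polyorder=polyorder, mode="interp")
    return replace(x, intensities=smoothed)


def preprocess_pipeline(s: SpectraSet, cfg: PreprocessConfig = PreprocessConfig()) -> SpectraSet:
    """Apply the enabled stages, in order zero → normalize → smooth, per row.

    Metadata is unchanged; stage errors are re-raised annotated with the
    offending row index.
    """
    out = np.array(s.matrix, dtype=float, copy=True)
    for i in range(s.n_rows):
        spec = Spectrum(s.grid, out[i], s.metas[i])
        try:
            if cfg.do_zero:
                spec = zero_correct(spec)
            if cfg.do_normalize:
                spec = l2_normalize(spec)
            if cfg.do_smooth:
                spec = savgol_smooth(spec, cfg.sg_window, cfg.sg_polyorder)
        except ValueError as exc:
            raise ValueError(f"preprocessing failed at row {i}: {exc}") from exc
        out[i] = spec.intensities
    return SpectraSet(s.grid, out, list(s.metas))
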