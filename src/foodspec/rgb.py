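"""Camera spectral sensitivity functions and spectra → RGB conversion.

A camera integrates an incoming spectrum into three channel values; each
channel value is the sensitivity-weighted sum of the spectrum over
wavelength: ``channel_c = Σ_λ S_c(λ)·x(λ)``.  Distinct spectra can integrate
to identical RGB triples (metamerism), which is exactly the information loss
this module lets the pipeline quantify: convert a spectra set to a 3-feature
table, re-run the same classifier, and compare accuracies.

No gamma, white balance or exposure scaling is applied — the conversion is
the raw weighted sum, and the illuminant is treated as already folded into
the measured reflected-light spectrum.

Profiles are plain 4-column CSVs (``wavelength_nm,R,G,B``); a few synthetic
bell-curve profiles ship with the package so the comparison runs without
external downloads, and real measured profiles in the same format are
drop-in replacements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import SampleMeta, Spectrum, SpectraSet, WavelengthGrid

__all__ = [
    "CameraProfile",
    "RGBSet",
    "read_camera_profile",
    "bundled_camera_profiles",
    "resample_to",
    "spectrum_to_rgb",
    "convert_set",
]

CHANNELS = ("R", "G", "B")


@dataclass(frozen=True)
class CameraProfile:
    """Per-channel sensitivity functions on the profile's own wavelength grid."""

    name: str
    grid: WavelengthGrid
    sensitivities: np.ndarray  # 3 × len(grid), rows R, G, B

    def __post_init__(self) -> None:
        s = np.asarray(self.sensitivities, dtype=float)
        if s.shape != (3, len(self.grid)):
            raise ValueError(
                f"sensitivities must be 3×{len(self.grid)}, got {s.shape}"
            )
        if np.any(s < 0):
            raise ValueError("sensitivities must be non-negative")
        if np.any(s.max(axis=1) <= 0):
            raise ValueError("every channel needs at least one positive sensitivity")
        object.__setattr__(self, "sensitivities", s)

    def sensitivity_matrix(self, grid: WavelengthGrid) -> np.ndarray:
        """The 3×p channel weights resampled onto ``grid`` (zero outside range)."""
        out = np.zeros((3, len(grid)))
        for c in range(3):
            out[c] = np.interp(
                grid.wavelengths, self.grid.wavelengths, self.sensitivities[c],
                left=0.0, right=0.0,
            )
        return out


@dataclass
class RGBSet:
    """Three-channel responses with carried-through metadata.

    Exposes the same row/metadata surface as a spectra set, so the PLS-DA and
    validation machinery consumes it like a 3-wavelength dataset.
    """

    matrix: np.ndarray
    metas: list[SampleMeta]
    profile_name: str
    grid: None = None  # no wavelength axis: features are camera channels

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 3:
            raise ValueError(f"RGB matrix must be n×3, got {m.shape}")
        if len(self.metas) != m.shape[0]:
            raise ValueError(f"{m.shape[0]} rows but {len(self.metas)} metadata records")
        self.matrix = m

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def subset(self, indices: Sequence[int] | np.ndarray) -> "RGBSet":
        idx = np.asarray(indices, dtype=int)
        return RGBSet(self.matrix[idx], [self.metas[i] for i in idx], self.profile_name)

    def session_ids(self) -> set[str]:
        return {m.session_id for m in self.metas}


def read_camera_profile(path: str | Path) -> CameraProfile:
    """Read a ``wavelength_nm,R,G,B`` CSV into a validated profile."""
    df = pd.read_csv(path)
    if df.shape[1] != 4:
        raise ValueError(f"camera profile {path} must have 4 columns, got {df.shape[1]}")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    grid = WavelengthGrid(wl)  # enforces strictly increasing
    sens = df.iloc[:, 1:4].to_numpy(dtype=float).T
    return CameraProfile(name=Path(path).stem, grid=grid, sensitivities=sens)


def bundled_camera_profiles() -> list[CameraProfile]:
    """The synthetic bell-curve profiles shipped with the package."""
    pkg = resources.files("foodspec") / "data" / "cameras"
    profiles = []
    for entry in sorted(pkg.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".csv"):
            with resources.as_file(entry) as p:
                profiles.append(read_camera_profile(p))
    return profiles


def resample_to(x: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target``.

    Target points outside the source range are set to 0 and a
    ``RuntimeWarning`` reporting how many is emitted.
    """
    if len(target) == 0:
        raise ValueError("empty target grid")
    src = x.grid.wavelengths
    out_of_range = int(np.sum((target.wavelengths < src[0]) | (target.wavelengths > src[-1])))
    if out_of_range:
        warnings.warn(
            f"{out_of_range} target wavelengths outside source range "
            f"[{src[0]:g}, {src[-1]:g}] nm set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    vals = np.interp(target.wavelengths, src, x.intensities, left=0.0, right=0.0)
    return Spectrum(target, vals, x.meta)


def spectrum_to_rgb(x: Spectrum, cam: CameraProfile) -> np.ndarray:
    """Integrate a spectrum into (R, G, B) on the profile's grid."""
    resampled = resample_to(x, cam.grid)
    return cam.sensitivities @ resampled.intensities


def convert_set(s: SpectraSet, cam: CameraProfile) -> RGBSet:
    """Row-wise spectra → RGB conversion with metadata carried through."""
    # one resampling of the whole matrix instead of a per-row python loop
    sens_on_cam = cam.sensitivities
    resampled = np.empty((s.n_rows, len(cam.grid)))
    with warnings.catch_warnings():
        warnings.simplefilter("once", RuntimeWarning)
        for i in range(s.n_rows):
            resampled[i] = resample_to(s.row(i), cam.grid).intensities
    return RGBSet(resampled @ sens_on_cam.T, list(s.metas), cam.name)
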