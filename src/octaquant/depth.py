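"""Automatic depth-of-interest (DOI) selection and en face projection.

Oral mucosa lacks a sharp epithelium/lamina-propria boundary under OCT, and
vessels from different depths overlap in a single full-depth projection.  The
pipeline therefore splits each angiography volume into two depth bands purely
from its depth intensity profile (mean OCTA intensity per axial slice):

* the *end depth* is the deepest slice whose (smoothed) intensity still
  reaches the mean over all depths — below it only noise remains;
* the *separation depth* is the global intensity peak above the end depth,
  where the superficial vascular plexus is densest.

DOI 1 spans [0, separation), DOI 2 spans [separation, end); both half-open,
0-based.  Each band is collapsed to an en face image by maximum intensity
projection (MIP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from octaquant.volume_io import AngioVolume3D, EnFaceImage

#: Moving-average width (slices) applied before peak/crossing detection.
#: Per-slice means already average the whole lateral field, so a short
#: window suffices; a window wider than the superficial plexus band would
#: tie all windows containing it and bias the peak toward the surface.
DEFAULT_SMOOTH_WINDOW = 5
#: Fraction of the profile maximum used to skip pre-tissue air at the top.
SURFACE_SKIP_FRACTION = 0.1


@dataclass
class DepthProfile:
    """Mean OCTA intensity per axial slice, raw and smoothed."""

    intensity: np.ndarray
    smoothed: np.ndarray
    mean_all: float

    def __len__(self) -> int:
        return len(self.intensity)


@dataclass(frozen=True)
class DOISplit:
    """Depth band boundaries: DOI1 = [0, separation), DOI2 = [separation, end)."""

    separation_depth: int
    end_depth: int

    def __post_init__(self) -> None:
        if not (0 < self.separation_depth < self.end_depth):
            raise ValueError("need 0 < separation_depth < end_depth")


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(np.float64).copy()
    pad = window // 2
    padded = np.pad(x.astype(np.float64), pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")[: len(x)]


def depth_profile(vol: AngioVolume3D, smooth_window: int = DEFAULT_SMOOTH_WINDOW) -> DepthProfile:
    """Average the volume over both lateral axes to a Z-length profile."""
    data = np.asarray(vol.data, dtype=np.float64)
    if data.size == 0:
        raise ValueError("empty volume")
    intensity = data.mean(axis=(1, 2))
    return DepthProfile(
        intensity=intensity,
        smoothed=_moving_average(intensity, smooth_window),
        mean_all=float(intensity.mean()),
    )


def find_end_depth(profile: DepthProfile) -> int:
    """Deepest slice whose smoothed intensity still reaches the overall mean.

    Signal attenuates with depth; below the last down-crossing of the mean
    level only the noise floor remains.
    """
    smoothed = profile.smoothed
    if np.ptp(profile.intensity) == 0:
        raise ValueError("no attenuation structure: profile is constant")
    above = np.nonzero(smoothed >= profile.mean_all)[0]
    if above.size == 0:
        raise ValueError("no attenuation structure: profile never reaches its mean")
    return int(above[-1])


def find_separation_depth(profile: DepthProfile, z_min: int | None = None) -> int:
    """Location of the maximum smoothed-intensity peak, searched above the end depth.

    ``z_min`` excludes the topmost slices (surface reflection / air); by
    default it is the first slice where the smoothed profile exceeds 10% of
    its maximum.  Ties break toward smaller z.
    """
    end = find_end_depth(profile)
    smoothed = profile.smoothed
    if z_min is None:
        z_min = int(np.argmax(smoothed > SURFACE_SKIP_FRACTION * smoothed.max()))
    if not (0 <= z_min < end):
        raise ValueError(f"empty search range [{z_min}, {end})")
    return z_min + int(np.argmax(smoothed[z_min:end]))


def split_doi(
    vol: AngioVolume3D,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    z_min: int | None = None,
) -> tuple[AngioVolume3D, AngioVolume3D, DOISplit]:
    """Split a volume into superficial (DOI 1) and deep (DOI 2) bands."""
    profile = depth_profile(vol, smooth_window)
    end = find_end_depth(profile)
    sep = find_separation_depth(profile, z_min)
    if sep < 2 or sep > end - 2:
        raise ValueError(
            f"degenerate split: separation {sep} within 2 slices of top or end {end}"
        )
    split = DOISplit(separation_depth=sep, end_depth=end)
    doi1 = AngioVolume3D(vol.data[:sep].copy(), vol.pixel_geometry)
    doi2 = AngioVolume3D(vol.data[sep:end].copy(), vol.pixel_geometry)
    return doi1, doi2, split


def mip(vol: AngioVolume3D, z_range: tuple[int, int] | None = None) -> EnFaceImage:
    """Maximum intensity projection over a half-open slice range."""
    z0, z1 = (0, vol.data.shape[0]) if z_range is None else z_range
    if not (0 <= z0 < z1 <= vol.data.shape[0]):
        raise ValueError(f"empty or out-of-range z range [{z0}, {z1})")
    return EnFaceImage(vol.data[z0:z1].max(axis=0), vol.pixel_geometry)
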