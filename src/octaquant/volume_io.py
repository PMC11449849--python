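"""Reading and writing angiography volumes, en face images, and reports.

On-disk conventions
-------------------
Volumes are stored as multi-page TIFF (pages = axial slices) or raw binary,
always accompanied by a JSON sidecar ``<stem>.json`` declaring axis order,
extents, dtype, and pixel geometry.  Internally every volume is held in
canonical ``(Z, X, Y)`` or ``(Z, X, Y, N)`` order: Z axial, X/Y lateral,
N temporal repeats.  En face images and binary masks go to 8- or 16-bit
grayscale PNG/TIFF; metric reports to CSV or JSON.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

#: Micrometers per lateral pixel for a 5.25 mm field of view sampled at 400 px.
DEFAULT_LATERAL_PIXEL_UM = 5250.0 / 400.0  # 13.125
#: Micrometers per axial pixel; nominal axial sampling of the source system.
DEFAULT_AXIAL_PIXEL_UM = 7.5


@dataclass(frozen=True)
class PixelGeometry:
    """Physical pixel spacing of an acquisition, in micrometers per pixel."""

    lateral_pixel_um: float = DEFAULT_LATERAL_PIXEL_UM
    axial_pixel_um: float = DEFAULT_AXIAL_PIXEL_UM

    def __post_init__(self) -> None:
        if not (self.lateral_pixel_um > 0 and self.axial_pixel_um > 0):
            raise ValueError("pixel spacings must be positive")


def _validate_intensities(data: np.ndarray) -> None:
    if not np.all(np.isfinite(data)):
        raise ValueError("intensities must be finite")
    if np.any(data < 0):
        raise ValueError("intensities must be non-negative")


@dataclass
class AngioVolume4D:
    """Raw repeated-frame acquisition, canonical axes (Z, X, Y, N)."""

    data: np.ndarray
    pixel_geometry: PixelGeometry = field(default_factory=PixelGeometry)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4 axes (Z, X, Y, N), got {self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all extents must be >= 1")
        _validate_intensities(self.data)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class AngioVolume3D:
    """Reconstructed angiography volume, canonical axes (Z, X, Y)."""

    data: np.ndarray
    pixel_geometry: PixelGeometry = field(default_factory=PixelGeometry)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3 axes (Z, X, Y), got {self.data.ndim}")
        _validate_intensities(self.data)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class EnFaceImage:
    """2D en face projection, axes (X, Y)."""

    data: np.ndarray
    pixel_geometry: PixelGeometry = field(default_factory=PixelGeometry)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"expected 2 axes (X, Y), got {self.data.ndim}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


# ---------------------------------------------------------------------------
# Volume I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _canonical_axes(ndim: int) -> str:
    return "ZXYN"[:ndim] if ndim == 4 else "ZXY"


def canonicalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Permute ``data`` whose axes are labelled by ``axes`` into (Z, X, Y[, N])."""
    axes = axes.upper()
    target = _canonical_axes(data.ndim)
    if sorted(axes) != sorted(target):
        raise ValueError(f"axes {axes!r} do not describe a {target} volume")
    return np.transpose(data, [axes.index(a) for a in target])


def read_volume(path: str | Path, layout_spec: dict | None = None) -> AngioVolume4D | AngioVolume3D:
    """Read a volume from multi-page TIFF or raw binary.

    ``layout_spec`` overrides or replaces the JSON sidecar; it may declare
    ``axes`` (e.g. ``"ZXYN"``), ``extents`` (in that axis order), ``dtype``
    (required for raw binary), ``lateral_pixel_um`` and ``axial_pixel_um``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    if layout_spec:
        meta.update(layout_spec)

    if path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
    else:
        if "dtype" not in meta or "extents" not in meta:
            raise ValueError("raw binary volumes need a sidecar with dtype and extents")
        data = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
        n_expected = int(np.prod(meta["extents"]))
        if data.size != n_expected:
            raise ValueError(
                f"payload has {data.size} values, sidecar declares {n_expected}"
            )
        data = data.reshape(meta["extents"])

    if "extents" in meta and tuple(data.shape) != tuple(meta["extents"]):
        raise ValueError(
            f"file shape {data.shape} inconsistent with declared extents {tuple(meta['extents'])}"
        )
    axes = meta.get("axes", _canonical_axes(data.ndim))
    data = canonicalize_axes(data, axes)

    if "lateral_pixel_um" not in meta:
        warnings.warn(
            f"no lateral pixel size declared; assuming {DEFAULT_LATERAL_PIXEL_UM} um/px",
            stacklevel=2,
        )
    geometry = PixelGeometry(
        lateral_pixel_um=float(meta.get("lateral_pixel_um", DEFAULT_LATERAL_PIXEL_UM)),
        axial_pixel_um=float(meta.get("axial_pixel_um", DEFAULT_AXIAL_PIXEL_UM)),
    )
    cls = AngioVolume4D if data.ndim == 4 else AngioVolume3D
    return cls(data=data, pixel_geometry=geometry)


def write_volume(vol: AngioVolume4D | AngioVolume3D, path: str | Path) -> Path:
    """Write a volume as multi-page TIFF (pages = Z) with a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, vol.data, photometric="minisblack")
    meta = {
        "axes": _canonical_axes(vol.data.ndim),
        "extents": list(vol.data.shape),
        "dtype": str(vol.data.dtype),
        "lateral_pixel_um": vol.pixel_geometry.lateral_pixel_um,
        "axial_pixel_um": vol.pixel_geometry.axial_pixel_um,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


# ---------------------------------------------------------------------------
# En face image I/O


def write_enface(image: EnFaceImage | np.ndarray, path: str | Path, bit_depth: int = 16) -> Path:
    """Write a grayscale en face image, linearly rescaled to the full bit range.

    The rescale slope/intercept is recorded in a JSON sidecar so intensities
    can be mapped back to the original scale.
    """
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    data = np.asarray(image.data if isinstance(image, EnFaceImage) else image, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("image must be finite")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lo, hi = float(data.min()), float(data.max())
    vmax = 2**bit_depth - 1
    if hi == lo:
        warnings.warn("constant image has no defined rescale; writing zeros", stacklevel=2)
        scaled = np.zeros_like(data)
    else:
        scaled = (data - lo) / (hi - lo) * vmax
    out = np.rint(scaled).astype(np.uint8 if bit_depth == 8 else np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)
    _sidecar_path(path).write_text(
        json.dumps({"min": lo, "max": hi, "bit_depth": bit_depth}, indent=1)
    )
    return path


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary map as 0/255 8-bit grayscale."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = (np.asarray(mask) > 0).astype(np.uint8) * 255
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)
    return path


# ---------------------------------------------------------------------------
# Report I/O


def _report_to_dict(report) -> dict:
    if isinstance(report, dict):
        return dict(report)
    if hasattr(report, "to_dict"):
        return report.to_dict()
    if dataclasses.is_dataclass(report):
        return dataclasses.asdict(report)
    raise TypeError(f"cannot serialize report of type {type(report)!r}")


def write_report(report, path: str | Path, format: str | None = None) -> Path:
    """Serialize a metrics/repeatability/cohort report to CSV or JSON.

    Values survive a round trip at better than 6 significant digits.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "json"
    format = format.lower()
    if format not in {"csv", "json"}:
        raise ValueError("format must be 'csv' or 'json'")
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = _report_to_dict(report)
    if format == "json":
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    else:
        rows = [{"field": k, "value": v} for k, v in payload.items()]
        pd.DataFrame(rows, columns=["field", "value"]).to_csv(path, index=False)
    return path


def read_report(path: str | Path) -> dict:
    """Read back a report written by :func:`write_report`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())
    df = pd.read_csv(path)
    out: dict = {}
    for _, row in df.iterrows():
        val = row["value"]
        try:
            val = float(val)
        except (TypeError, ValueError):
            pass
        out[row["field"]] = val
    return out
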