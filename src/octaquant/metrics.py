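"""Quantitative vascular metrics, heatmaps, repeatability and cohort statistics.

The four metrics, computed per depth-of-interest from the intermediate maps:

    VAD = 100 * sum(BAM) / (X * Y)                    [%]
    VSD = 100 * sum(BVS) / (X * Y)                    [%]
    VDI = sum_skel(2 * disEu) / sum(BVS) * pixel_um   [micrometers]
    TI  = (SegmentLength / EuclideanDistance - 1) * 100   per segment
    WTI = sum_n VDI_n * (L_n / D_n - 1) / sum_n VDI_n * 100

where disEu is the distance from a skeleton pixel to the vessel edge and
VDI_n the mean diameter of segment n, which weights each segment's tortuosity
by its caliber.  Scan-rescan repeatability is summarized by the coefficient
of variation (population SD / mean) and cohorts by mean, sample SD, and a
Student-t 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from octaquant.mask import (
    BinaryAngioMask,
    BinaryVesselSkeleton,
    DiameterField,
    TISkeletonMap,
    VesselSegment,
    _as_binary,
)
from octaquant.volume_io import PixelGeometry

METRIC_NAMES = ("vad_percent", "vsd_percent", "vdi_um", "wti")


@dataclass
class MetricsReport:
    """The four metrics for one depth-of-interest."""

    vad_percent: float
    vsd_percent: float
    vdi_um: float
    wti: float
    mean_ti: float
    n_segments: int
    doi_label: str = ""

    def to_dict(self) -> dict:
        return {
            "doi_label": self.doi_label,
            "vad_percent": round(self.vad_percent, 2),
            "vsd_percent": round(self.vsd_percent, 2),
            "vdi_um": round(self.vdi_um, 2),
            "wti": round(self.wti, 2),
            "mean_ti": round(self.mean_ti, 2),
            "n_segments": self.n_segments,
        }


@dataclass
class RepeatabilityReport:
    """Between-scan coefficient of variation per metric, per DOI."""

    cv: dict[str, dict[str, float]]  # {doi_label: {metric: cv}}
    n_scans: int = 2

    def to_dict(self) -> dict:
        out: dict = {"n_scans": self.n_scans}
        for doi, metrics in self.cv.items():
            for name, value in metrics.items():
                out[f"cv_{name}_{doi}"] = round(value, 4)
        return out


@dataclass
class CohortSummary:
    """Mean, sample SD, and symmetric t confidence interval of one metric."""

    n: int
    mean: float
    sd: float
    ci_lower: float
    ci_upper: float
    confidence: float = 0.95

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": round(self.mean, 2),
            "sd": round(self.sd, 2),
            "ci_lower": round(self.ci_lower, 2),
            "ci_upper": round(self.ci_upper, 2),
            "confidence": self.confidence,
        }


# ---------------------------------------------------------------------------
# The four metrics


def vad(bam: BinaryAngioMask | np.ndarray) -> float:
    """Vessel area density: percent of the field of view covered by vessels."""
    mask = _as_binary(bam)
    if mask.size == 0:
        raise ValueError("empty mask")
    return 100.0 * float(mask.sum()) / mask.size


def vsd(bvs: BinaryVesselSkeleton | np.ndarray) -> float:
    """Vessel skeleton density: percent of the field covered by centerlines."""
    skel = _as_binary(bvs)
    if skel.size == 0:
        raise ValueError("empty skeleton array")
    return 100.0 * float(skel.sum()) / skel.size


def vdi(
    bam: BinaryAngioMask | np.ndarray,
    bvs: BinaryVesselSkeleton | np.ndarray,
    pixel_geometry: PixelGeometry | None = None,
) -> float:
    """Vessel diameter index: mean diameter over skeleton pixels, micrometers."""
    from octaquant.mask import diameter_field  # local to avoid cycle at import

    geometry = pixel_geometry or PixelGeometry()
    skel = _as_binary(bvs)
    n_skel = int(skel.sum())
    if n_skel == 0:
        raise ValueError("no vessels: skeleton is empty")
    dfield = diameter_field(bam, bvs)
    return float(dfield.values.sum()) / n_skel * geometry.lateral_pixel_um


def segment_ti(seg: VesselSegment) -> float:
    """Tortuosity index of one segment: (length / chord - 1) * 100."""
    return seg.ti


def wti(segments: list[VesselSegment]) -> float:
    """Diameter-weighted mean tortuosity index over all segments."""
    if not segments:
        raise ValueError("no segments")
    diameters = np.array([s.mean_diameter_px for s in segments], dtype=np.float64)
    if np.any(~np.isfinite(diameters)) or np.any(diameters <= 0):
        raise ValueError("all segments need a positive mean diameter")
    tis = np.array([s.ti for s in segments])
    return float((diameters * tis).sum() / diameters.sum())


def mean_ti(segments: list[VesselSegment]) -> float:
    """Unweighted mean tortuosity index."""
    if not segments:
        raise ValueError("no segments")
    return float(np.mean([s.ti for s in segments]))


# ---------------------------------------------------------------------------
# Repeatability and cohort statistics


def coefficient_of_variation(values) -> float:
    """Scan-rescan CV: population standard deviation divided by the mean."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    m = arr.mean()
    if m == 0:
        raise ValueError("zero mean")
    return float(arr.std(ddof=0) / m)


def cohort_summary(values=None, confidence: float = 0.95, *, stats_in=None) -> CohortSummary:
    """Mean, sample SD, and symmetric Student-t confidence interval.

    Either raw ``values`` or precomputed ``stats_in = (mean, sd, n)`` (as
    printed in a summary table) may be given.
    """
    if stats_in is not None:
        m, sd, n = float(stats_in[0]), float(stats_in[1]), int(stats_in[2])
    else:
        arr = np.asarray(values, dtype=np.float64)
        n = arr.size
        if n < 2:
            raise ValueError("need at least 2 values")
        m, sd = float(arr.mean()), float(arr.std(ddof=1))
    if n < 2:
        raise ValueError("need n >= 2")
    margin = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1) * sd / np.sqrt(n)
    return CohortSummary(
        n=n, mean=m, sd=sd, ci_lower=m - margin, ci_upper=m + margin, confidence=confidence
    )


# ---------------------------------------------------------------------------
# Local heatmaps


def local_heatmap(
    field: np.ndarray | BinaryAngioMask | TISkeletonMap | DiameterField,
    kernel_px: int = 51,
    mode: str = "density",
) -> np.ndarray:
    """Moving-kernel local statistic of a map.

    ``density``: mean of the binary mask in the window (local VAD / 100).
    ``diameter`` / ``ti``: mean of the *non-zero* skeleton-map values in the
    window, 0 where the window holds no skeleton pixel — background zeros
    would otherwise dilute the local statistic.  Borders are edge-replicated.
    """
    if kernel_px < 3 or kernel_px % 2 == 0:
        raise ValueError("kernel_px must be odd and >= 3")
    if isinstance(field, BinaryAngioMask):
        data = field.mask.astype(np.float64)
    elif isinstance(field, (TISkeletonMap, DiameterField)):
        data = np.asarray(field.values, dtype=np.float64)
    else:
        data = np.asarray(field, dtype=np.float64)
    if kernel_px > max(data.shape):
        raise ValueError("kernel larger than the image")
    if mode == "density":
        return ndimage.uniform_filter(data, size=kernel_px, mode="nearest")
    if mode in {"diameter", "ti"}:
        support = (data != 0).astype(np.float64)
        num = ndimage.uniform_filter(data, size=kernel_px, mode="nearest")
        den = ndimage.uniform_filter(support, size=kernel_px, mode="nearest")
        out = np.zeros_like(data)
        np.divide(num, den, out=out, where=den > 0)
        return out
    raise ValueError(f"unknown heatmap mode {mode!r}")
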