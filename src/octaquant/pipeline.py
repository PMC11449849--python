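"""End-to-end pipeline: acquisition -> reconstruction -> DOI split -> metrics.

``run_pipeline`` mirrors the processing flow the package implements: the
repeated-frame volume is clutter-filtered into an angiography volume, split
into a superficial and a deep depth-of-interest, and each DOI's en face
maximum-intensity projection is binarized, skeletonized, decomposed into
segments, and quantified.  Every run writes its intermediate maps, heatmaps,
metric reports, the resolved configuration, and a deterministic log into the
output directory.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

import octaquant
from octaquant import depth as depth_mod
from octaquant import mask as mask_mod
from octaquant import metrics as metrics_mod
from octaquant.mask import BamParams
from octaquant.reconstruct import ReconstructionParams, reconstruct
from octaquant.volume_io import (
    AngioVolume3D,
    AngioVolume4D,
    EnFaceImage,
    PixelGeometry,
    read_volume,
    write_enface,
    write_mask,
    write_report,
)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    input_path: str | None = None
    layout: dict = field(default_factory=dict)
    out_dir: str = "octaquant_out"
    seed: int = 0
    doi_mode: str = "both"  # {"1", "2", "both", "none"}
    lateral_pixel_um: float = 5250.0 / 400.0
    axial_pixel_um: float = 7.5
    smooth_window: int = 5
    z_min: int | None = None
    reconstruction: ReconstructionParams = field(default_factory=ReconstructionParams)
    bam: BamParams = field(default_factory=BamParams)
    prune_px: float = 5.0
    min_len_px: float = 5.0
    kernel_px: int = 51

    def __post_init__(self) -> None:
        if self.doi_mode not in {"1", "2", "both", "none"}:
            raise ConfigError(f"doi_mode must be 1/2/both/none, got {self.doi_mode!r}")
        if self.kernel_px < 3 or self.kernel_px % 2 == 0:
            raise ConfigError("kernel_px must be odd and >= 3")
        if self.lateral_pixel_um <= 0 or self.axial_pixel_um <= 0:
            raise ConfigError("pixel sizes must be positive")
        if self.smooth_window < 1:
            raise ConfigError("smooth_window must be >= 1")

    @property
    def pixel_geometry(self) -> PixelGeometry:
        return PixelGeometry(self.lateral_pixel_um, self.axial_pixel_um)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        try:
            recon = ReconstructionParams(**raw.pop("reconstruction", {}))
            bam = BamParams(
                **{
                    k: tuple(v) if k == "vesselness_scales" else v
                    for k, v in raw.pop("bam", {}).items()
                }
            )
            return cls(reconstruction=recon, bam=bam, **raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        out = asdict(self)
        out["bam"]["vesselness_scales"] = list(out["bam"]["vesselness_scales"])
        return out


def quantify_enface(
    image: EnFaceImage,
    config: PipelineConfig | None = None,
    doi_label: str = "",
) -> tuple[metrics_mod.MetricsReport, dict]:
    """Quantify one en face angiogram; returns the report and all maps."""
    config = config or PipelineConfig()
    bam = mask_mod.make_bam(image, config.bam)
    bvs = mask_mod.skeletonize(bam, prune_px=config.prune_px)
    dfield = mask_mod.diameter_field(bam, bvs)
    segments = mask_mod.decompose_segments(bvs, min_len_px=config.min_len_px)
    mask_mod.attach_diameters(segments, dfield)
    ti_map = mask_mod.ti_skeleton_map(segments, bvs.shape)
    geometry = config.pixel_geometry
    if bvs.skeleton.any():
        vdi_um = metrics_mod.vdi(bam, bvs, geometry)
    else:
        vdi_um = 0.0
    report = metrics_mod.MetricsReport(
        vad_percent=metrics_mod.vad(bam),
        vsd_percent=metrics_mod.vsd(bvs),
        vdi_um=vdi_um,
        wti=metrics_mod.wti(segments) if segments else 0.0,
        mean_ti=metrics_mod.mean_ti(segments) if segments else 0.0,
        n_segments=len(segments),
        doi_label=doi_label,
    )
    maps = {
        "enface": image,
        "bam": bam,
        "bvs": bvs,
        "diameter_field": dfield,
        "ti_map": ti_map,
        "segments": segments,
    }
    return report, maps


def _render_heatmap(data: np.ndarray, path: Path, label: str, pixel_um: float) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(data, cmap="inferno")
    fig.colorbar(im, ax=ax, label=label, shrink=0.8)
    # 500 um scale bar, drawn in the lower-left corner
    bar_px = 500.0 / pixel_um
    x0, y0 = data.shape[1] * 0.05, data.shape[0] * 0.95
    ax.plot([x0, x0 + bar_px], [y0, y0], color="white", lw=3)
    ax.text(x0, y0 - data.shape[0] * 0.02, "500 µm", color="white", fontsize=9)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def _write_doi_outputs(
    out: Path, label: str, report, maps, config: PipelineConfig, log: list[str]
) -> None:
    import tifffile

    write_enface(maps["enface"], out / f"{label}_enface.png", bit_depth=16)
    write_mask(maps["bam"].mask, out / f"{label}_bam.png")
    write_mask(maps["bvs"].skeleton, out / f"{label}_bvs.png")
    tifffile.imwrite(out / f"{label}_ti_map.tiff", maps["ti_map"].values.astype(np.float32))
    heat_density = metrics_mod.local_heatmap(maps["bam"], config.kernel_px, "density")
    dia_um = maps["diameter_field"].values * config.lateral_pixel_um
    heat_diameter = metrics_mod.local_heatmap(dia_um, config.kernel_px, "diameter")
    heat_ti = metrics_mod.local_heatmap(maps["ti_map"], config.kernel_px, "ti")
    for name, heat, unit in (
        ("density", heat_density, "vessel density"),
        ("diameter", heat_diameter, "vessel diameter [µm]"),
        ("ti", heat_ti, "tortuosity index"),
    ):
        tifffile.imwrite(out / f"{label}_heatmap_{name}.tiff", heat.astype(np.float32))
        _render_heatmap(heat, out / f"{label}_heatmap_{name}.png", unit, config.lateral_pixel_um)
    write_report(report, out / f"{label}_metrics.json")
    write_report(report, out / f"{label}_metrics.csv")
    log.append(
        f"{label}: VAD={report.vad_percent:.2f}% VSD={report.vsd_percent:.2f}% "
        f"VDI={report.vdi_um:.2f}um WTI={report.wti:.2f} n_segments={report.n_segments}"
    )


def run_pipeline(
    config: PipelineConfig,
    volume: AngioVolume4D | AngioVolume3D | EnFaceImage | None = None,
) -> dict[str, metrics_mod.MetricsReport]:
    """Run the full pipeline; returns per-DOI metric reports.

    ``volume`` may be passed in memory; otherwise ``config.input_path`` is
    read.  Output maps, reports, resolved config, and a log are written to
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [f"octaquant {octaquant.__version__}", f"seed={config.seed}"]
    if volume is None:
        if config.input_path is None:
            raise ConfigError("no input: provide input_path or an in-memory volume")
        layout = dict(config.layout)
        layout.setdefault("lateral_pixel_um", config.lateral_pixel_um)
        layout.setdefault("axial_pixel_um", config.axial_pixel_um)
        volume = read_volume(config.input_path, layout)
        log.append(f"stage=read input={config.input_path} shape={volume.data.shape}")

    if isinstance(volume, AngioVolume4D):
        log.append(
            f"stage=reconstruct method={config.reconstruction.method} (wED-like) "
            f"window=({config.reconstruction.window_z},{config.reconstruction.window_x}) "
            f"n_static={config.reconstruction.n_static}"
        )
        volume = reconstruct(volume, config.reconstruction)
        # residual energy -> amplitude: the display/quantification scale;
        # energy's dynamic range is the square of the signal's and breaks
        # histogram-based thresholding downstream
        volume = AngioVolume3D(np.sqrt(volume.data), volume.pixel_geometry)
        log.append("stage=amplitude scale=sqrt(energy)")

    reports: dict[str, metrics_mod.MetricsReport] = {}
    if isinstance(volume, EnFaceImage) or (
        isinstance(volume, np.ndarray) and volume.ndim == 2
    ):
        if config.doi_mode != "none":
            raise ConfigError("DOI requires a volume; got a 2D image")
        image = volume if isinstance(volume, EnFaceImage) else EnFaceImage(volume)
        image.pixel_geometry = config.pixel_geometry
        report, maps = quantify_enface(image, config, doi_label="full")
        _write_doi_outputs(out, "full", report, maps, config, log)
        reports["full"] = report
    else:
        assert isinstance(volume, AngioVolume3D)
        volume.pixel_geometry = config.pixel_geometry
        if config.doi_mode == "none":
            image = depth_mod.mip(volume)
            report, maps = quantify_enface(image, config, doi_label="full")
            _write_doi_outputs(out, "full", report, maps, config, log)
            reports["full"] = report
        else:
            doi1, doi2, split = depth_mod.split_doi(
                volume, smooth_window=config.smooth_window, z_min=config.z_min
            )
            log.append(
                f"stage=doi separation={split.separation_depth} end={split.end_depth}"
            )
            profile = depth_mod.depth_profile(volume, config.smooth_window)
            np.savetxt(
                out / "depth_profile.csv",
                np.column_stack([np.arange(len(profile)), profile.intensity, profile.smoothed]),
                delimiter=",",
                header="z,raw,smoothed",
                comments="",
                fmt="%.6g",
            )
            write_report(
                {"separation_depth": split.separation_depth, "end_depth": split.end_depth},
                out / "doi_split.json",
            )
            selected = {"1": [("doi1", doi1)], "2": [("doi2", doi2)]}.get(
                config.doi_mode, [("doi1", doi1), ("doi2", doi2)]
            )
            for label, band in selected:
                image = depth_mod.mip(band)
                report, maps = quantify_enface(image, config, doi_label=label)
                _write_doi_outputs(out, label, report, maps, config, log)
                reports[label] = report

    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    (out / "run.log").write_text("\n".join(log) + "\n")
    return reports


def repeatability_from_reports(
    per_scan: list[dict[str, metrics_mod.MetricsReport]],
) -> metrics_mod.RepeatabilityReport:
    """Between-scan CV for every metric and DOI present in all scans."""
    if len(per_scan) < 2:
        raise ValueError("need at least 2 scans")
    labels = set(per_scan[0])
    for scans in per_scan[1:]:
        labels &= set(scans)
    cv: dict[str, dict[str, float]] = {}
    for label in sorted(labels):
        cv[label] = {}
        for name in metrics_mod.METRIC_NAMES:
            values = [getattr(scans[label], name) for scans in per_scan]
            cv[label][name] = metrics_mod.coefficient_of_variation(values)
    return metrics_mod.RepeatabilityReport(cv=cv, n_scans=len(per_scan))


def run_repeatability(
    config: PipelineConfig,
    scan_paths: list[str | Path] | None = None,
    volumes: list | None = None,
) -> metrics_mod.RepeatabilityReport:
    """Run the pipeline on repeated scans and report per-metric CVs."""
    inputs: list = list(volumes) if volumes is not None else []
    if scan_paths:
        layout = dict(config.layout)
        inputs.extend(read_volume(p, layout) for p in scan_paths)
    if len(inputs) < 2:
        raise ConfigError("repeatability needs at least 2 scans")
    shapes = {tuple(np.asarray(v.data).shape) for v in inputs}
    if len(shapes) > 1:
        raise ValueError(f"scan extents differ: {sorted(shapes)}")
    per_scan = []
    base_out = Path(config.out_dir)
    for i, vol in enumerate(inputs, start=1):
        cfg = PipelineConfig.from_dict(
            {**config.to_dict(), "out_dir": str(base_out / f"scan{i}"), "input_path": None}
        )
        per_scan.append(run_pipeline(cfg, volume=vol))
    report = repeatability_from_reports(per_scan)
    write_report(report, base_out / "repeatability.json")
    return report
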