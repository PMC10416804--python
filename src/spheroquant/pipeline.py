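"""End-to-end orchestration: imaging → morphometrics → time series, and
counts → QC → clustering, driven by a serializable run configuration.

Every output table is accompanied by a JSON summary carrying the package
version and a hash of the configuration, so identical configs are
recognizably identical runs (and produce byte-identical outputs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, counts as counts_mod, invasion, morphometry, segmentation
from . import synthetic
from .volumes import VoxelVolume

__all__ = [
    "RunConfig",
    "run_imaging_pipeline",
    "run_counts_pipeline",
    "InputError",
    "ConfigError",
]

logger = logging.getLogger("spheroquant")


class InputError(RuntimeError):
    """Unreadable or inconsistent input data (CLI exit code 2)."""


class ConfigError(RuntimeError):
    """Invalid run configuration (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips through YAML.

    Imaging inputs are either TIFF stacks (``inputs``: list of
    ``{day, path}`` mappings) or a synthetic scenario (``simulate``: keyword
    arguments of :class:`~spheroquant.synthetic.ImagingScenario` plus
    optional ``days``/``growth_rate``/``escape_schedule``).  Count inputs are
    a CSV path or an MTX triplet directory.
    """

    # imaging
    inputs: list = field(default_factory=list)  # [{"day": d, "path": ...}]
    simulate: dict = field(default_factory=dict)
    spacing: list | None = None  # μm (z, y, x) override
    segmentation_method: str = "otsu"
    segmentation_threshold: float | None = None
    min_object_volume: float = segmentation.DEFAULT_MIN_VOLUME
    smoothing_scale: float = 10.0
    sphericity_threshold: float = invasion.DEFAULT_SPHERICITY_THRESHOLD
    # counts
    counts_path: str | None = None
    cells_in_rows: bool = False
    panel_path: str | None = None
    min_count: int = 10
    max_low_fraction: float = 0.30
    outlier_factor: float = 3.0
    n_clusters: int = 3
    # general
    seed: int = 0
    output_dir: str = "spheroquant_out"

    def __post_init__(self) -> None:
        if self.segmentation_method not in ("otsu", "fixed"):
            raise ConfigError(f"unknown segmentation method {self.segmentation_method!r}")
        if self.segmentation_method == "fixed" and self.segmentation_threshold is None:
            raise ConfigError("segmentation_method='fixed' requires segmentation_threshold")
        if self.smoothing_scale < 0:
            raise ConfigError("smoothing_scale must be non-negative")
        if not 0 < self.sphericity_threshold <= 1:
            raise ConfigError("sphericity_threshold must be in (0, 1]")
        if self.min_count < 0 or not 0 <= self.max_low_fraction <= 1:
            raise ConfigError("invalid QC thresholds")
        if self.min_object_volume < 0:
            raise ConfigError("min_object_volume must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_imaging_inputs(config: RunConfig) -> list[tuple[float, VoxelVolume]]:
    if bool(config.inputs) == bool(config.simulate):
        raise ConfigError("provide exactly one of 'inputs' and 'simulate'")
    if config.inputs:
        volumes = []
        for entry in config.inputs:
            try:
                vol = VoxelVolume.load(entry["path"], spacing=config.spacing)
            except (OSError, KeyError, ValueError) as exc:
                raise InputError(f"cannot load {entry.get('path')}: {exc}") from exc
            volumes.append((float(entry.get("day", 0)), vol))
        return sorted(volumes, key=lambda t: t[0])

    sim = dict(config.simulate)
    days = sim.pop("days", [0])
    growth_rate = sim.pop("growth_rate", 1.0)
    schedule = sim.pop("escape_schedule", {d: 0 for d in days})
    sim.setdefault("seed", config.seed)
    if "cells" in sim:
        sim["cells"] = [synthetic.CellSpec(**c) if isinstance(c, dict) else c
                        for c in sim["cells"]]
    try:
        scenario = synthetic.ImagingScenario(**sim)
        series = synthetic.generate_timeseries(scenario, days, growth_rate, schedule)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulate scenario: {exc}") from exc
    return [(day, vol) for day, vol, _ in series]


def analyze_volume(volume: VoxelVolume, config: RunConfig
                   ) -> tuple[morphometry.SpheroidGeometry, pd.DataFrame]:
    """Run one stack through segmentation and morphometry.

    Returns the spheroid geometry and the classified per-cell metrics table
    for all escaped/attached cells inside the cropped (hemispheroid) region.
    """
    mask = segmentation.segment_foreground(
        volume,
        method=config.segmentation_method,
        threshold=config.segmentation_threshold,
        min_volume=config.min_object_volume,
    )
    if mask.n_labels == 0:
        raise InputError("segmentation found no objects in the stack")
    cropped, z_depth = segmentation.crop_at_widest(mask)
    spheroid_mask, cells_mask = segmentation.split_spheroid_and_cells(cropped)
    reference = segmentation.smoothed_reference_surface(spheroid_mask, config.smoothing_scale)

    widest_slice = spheroid_mask.labels[-1] > 0
    a, b = morphometry.fit_periphery_ellipse(widest_slice, spheroid_mask.spacing[1:])
    if z_depth <= 0:
        raise InputError("spheroid widest plane is at the imaging face; cannot "
                         "estimate volume (z = 0)")
    geometry = morphometry.SpheroidGeometry.from_measurements(a, b, z_depth)

    cropped_channel = VoxelVolume(
        volume.intensities[: cropped.shape[0]].copy(), volume.spacing,
        volume.channel_name,
    )
    metrics = morphometry.measure_all_cells(cells_mask, reference, channel=cropped_channel)
    metrics = invasion.classify_cells(metrics, config.sphericity_threshold)
    return geometry, metrics


def run_imaging_pipeline(config: RunConfig) -> dict:
    """Imaging → morphometrics → invasion time series; writes tidy outputs.

    Writes ``cells.csv`` (one row per cell per day), ``timeseries.csv`` (one
    row per day), ``spheroid_geometry.csv`` and ``summary.json`` into
    ``config.output_dir``.  Deterministic for a fixed config and seed.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = _load_imaging_inputs(config)
    logger.info("imaging pipeline: %d timepoint(s), config %s",
                len(inputs), config.config_hash())

    per_day_geometry, per_day_cells, cell_rows, geom_rows = [], [], [], []
    for day, volume in inputs:
        geometry, metrics = analyze_volume(volume, config)
        per_day_geometry.append((day, geometry))
        per_day_cells.append((day, metrics))
        geom_rows.append({"day": day, **geometry.as_dict()})
        day_metrics = metrics.copy()
        day_metrics.insert(0, "day", day)
        cell_rows.append(day_metrics)

    cells = pd.concat(cell_rows, ignore_index=True) if cell_rows else pd.DataFrame()
    timeseries = invasion.build_timeseries(per_day_geometry, per_day_cells,
                                           config.sphericity_threshold)
    geometry_table = pd.DataFrame(geom_rows)

    cells.to_csv(out_dir / "cells.csv", index=False)
    timeseries.to_csv(out_dir / "timeseries.csv", index=False)
    geometry_table.to_csv(out_dir / "spheroid_geometry.csv", index=False)
    summary = {
        "tool": "spheroquant",
        "version": __version__,
        "config_hash": config.config_hash(),
        "n_timepoints": len(inputs),
        "n_cells_total": int(len(cells)),
        "outputs": ["cells.csv", "timeseries.csv", "spheroid_geometry.csv"],
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return {"cells": cells, "timeseries": timeseries, "geometry": geometry_table,
            "summary": summary}


def _load_counts(config: RunConfig) -> pd.DataFrame:
    if not config.counts_path:
        raise ConfigError("counts_path is required for the counts pipeline")
    path = Path(config.counts_path)
    try:
        if path.is_dir():
            return counts_mod.read_counts_mtx(path)
        return counts_mod.read_counts_csv(path, cells_in_rows=config.cells_in_rows)
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read counts from {path}: {exc}") from exc


def run_counts_pipeline(config: RunConfig, counts: pd.DataFrame | None = None) -> dict:
    """Counts → zero-gene removal → housekeeping QC → normalize → Ward tree.

    Writes ``qc_report.csv``, ``transformed.csv``, ``dendrogram.json``,
    ``dendrogram.nwk``, ``clusters.csv`` and ``summary.json``.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if counts is None:
        counts = _load_counts(config)
    if counts.empty:
        raise InputError("count matrix is empty")

    panel = (
        [g for g in Path(config.panel_path).read_text().splitlines()
         if g.strip() and not g.startswith("#")]
        if config.panel_path else counts_mod.default_housekeeping_panel()
    )
    logger.info("counts pipeline: %d genes × %d cells, panel of %d, config %s",
                *counts.shape, len(panel), config.config_hash())

    nonzero = counts_mod.drop_zero_genes(counts)
    try:
        report = counts_mod.housekeeping_qc(nonzero, panel, config.min_count,
                                            config.max_low_fraction)
    except KeyError as exc:
        raise InputError(str(exc)) from exc
    kept = counts_mod.apply_qc(nonzero, report)
    if kept.shape[1] < 2:
        raise InputError("fewer than 2 cells pass housekeeping QC; cannot cluster")
    transformed = counts_mod.normalize_for_clustering(kept)
    dendrogram = counts_mod.ward_cluster(transformed)
    outliers = counts_mod.flag_outliers(dendrogram, config.outlier_factor)
    clusters = dendrogram.cut(config.n_clusters)

    report.to_csv(out_dir / "qc_report.csv")
    transformed.to_csv(out_dir / "transformed.csv")
    dendrogram.to_json(out_dir / "dendrogram.json")
    (out_dir / "dendrogram.nwk").write_text(dendrogram.to_newick() + "\n")
    clusters.to_frame().assign(outlier=lambda df: df.index.isin(outliers)).to_csv(
        out_dir / "clusters.csv")
    summary = {
        "tool": "spheroquant",
        "version": __version__,
        "config_hash": config.config_hash(),
        "n_genes_input": int(counts.shape[0]),
        "n_genes_nonzero": int(nonzero.shape[0]),
        "n_cells_input": int(counts.shape[1]),
        "n_cells_excluded": int(report["excluded"].sum()),
        "excluded_cells": sorted(report.index[report["excluded"]].tolist()),
        "outlier_cells": outliers,
        "outputs": ["qc_report.csv", "transformed.csv", "dendrogram.json",
                    "dendrogram.nwk", "clusters.csv"],
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return {"qc_report": report, "transformed": transformed, "dendrogram": dendrogram,
            "clusters": clusters, "outliers": outliers, "summary": summary}


def plot_timeseries(timeseries: pd.DataFrame, path: str | Path) -> None:
    """Three-panel overview plot: relative volume, invasion density, sphericity."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    axes[0].plot(timeseries["day"], timeseries["relative_volume"], "o-")
    axes[0].set(xlabel="day", ylabel="relative spheroid volume")
    axes[1].plot(timeseries["day"], timeseries["invasion_density"], "o-")
    axes[1].set(xlabel="day", ylabel="cumulative escaped cells / μm²")
    axes[2].plot(timeseries["day"], timeseries["mean_escaped_sphericity"], "o-")
    axes[2].set(xlabel="day", ylabel="mean escaped-cell sphericity", ylim=(0, 1.05))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
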