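"""Run orchestration: simulate -> segment -> score -> trend statistics.

A run is driven by a :class:`RunConfig` (built in code, from a YAML
file, or from a scenario preset) and writes a self-contained run
directory::

    run_dir/
      images/ layout.csv truth_cells.csv truth_wells.csv   (synthetic runs)
      cells.csv      one row per segmented cell
      wells.csv      per-well metrics (HSI or YAP index)
      groups.csv     per-group summary with percent-of-control
      stats.csv      trend-test decisions per analysis
      stats.json     the same, structured
      manifest.json  config echo, seed, versions, timestamps

Stages communicate only through these CSV contracts, so an image
directory plus layout produced elsewhere can be analyzed identically to
a simulated plate.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

import sarcoscreen
from sarcoscreen.core import SARCOMERE_60X, ConfigurationError, FieldImage
from sarcoscreen.presets import (
    PRESET_NAMES,
    TrendAnalysisSpec,
    WASHOUT_SEVERITIES,
    get_preset,
    preset_sim_config,
)
from sarcoscreen.score import ScoringParams, relative_to_control, score_wells
from sarcoscreen.segment import SegmentationParams, analyze_field
from sarcoscreen.simulate import (
    SimConfig,
    config_from_dict,
    config_to_dict,
    generate_plate,
)
from sarcoscreen.trend import DoseSeries, run_trend

log = logging.getLogger("sarcoscreen")


@dataclass
class RunConfig:
    """Everything needed for one reproducible analysis run."""

    output_dir: str
    sim: SimConfig | None = None
    images_dir: str | None = None
    layout_csv: str | None = None
    mode: str = SARCOMERE_60X
    pixel_size_um: float | None = None
    scoring: ScoringParams = dc_field(default_factory=ScoringParams)
    segmentation: SegmentationParams = dc_field(default_factory=SegmentationParams)
    analyses: list = dc_field(default_factory=list)
    control_label: str = "DMSO"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.images_dir is None):
            raise ConfigurationError(
                "exactly one input source required: either a SimConfig or an "
                "image directory with a layout CSV"
            )
        if self.images_dir is not None and self.layout_csv is None:
            raise ConfigurationError("image-directory input needs a layout CSV")
        if self.sim is not None:
            self.mode = self.sim.mode
            self.pixel_size_um = self.sim.pixel_size_um


def config_from_yaml(path) -> RunConfig:
    """Load a RunConfig from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    sim = config_from_dict(raw["sim"]) if "sim" in raw else None
    scoring = ScoringParams(**raw.get("scoring", {}))
    segmentation = SegmentationParams(**raw.get("segmentation", {}))
    analyses = [TrendAnalysisSpec(**a) for a in raw.get("analyses", [])]
    kwargs = {k: raw[k] for k in (
        "output_dir", "images_dir", "layout_csv", "mode", "pixel_size_um",
        "control_label", "seed", "log_level",
    ) if k in raw}
    return RunConfig(sim=sim, scoring=scoring, segmentation=segmentation,
                     analyses=analyses, **kwargs)


def _load_layout(path) -> pd.DataFrame:
    layout = pd.read_csv(path)
    required = {"well", "group_label", "dose_uM", "is_control"}
    missing = required - set(layout.columns)
    if missing:
        raise ConfigurationError(f"layout CSV missing columns {sorted(missing)}")
    if layout.empty:
        raise ConfigurationError("layout CSV contains no wells")
    return layout


def _iter_field_images(images_dir: Path, layout: pd.DataFrame, mode: str,
                       pixel_size_um: float):
    wells = set(layout["well"])
    files = sorted(images_dir.glob("*.tif"))
    if not files:
        raise ConfigurationError(f"no TIFF fields found in {images_dir}")
    for path in files:
        stem_parts = path.stem.split("_", 2)
        well, field_id = stem_parts[0], int(stem_parts[1])
        if well not in wells:
            continue
        channels = tifffile.imread(path)
        yield FieldImage(well=well, field=field_id, channels=channels,
                         pixel_size_um=pixel_size_um, mode=mode)


def analyze_plate(images_dir, layout: pd.DataFrame, mode: str,
                  pixel_size_um: float,
                  params: SegmentationParams | None = None) -> pd.DataFrame:
    """Segment every field of a plate into the per-cell table."""
    params = params or SegmentationParams()
    frames = []
    for fimg in _iter_field_images(Path(images_dir), layout, mode, pixel_size_um):
        frames.append(analyze_field(fimg, params))
    if not frames:
        raise ConfigurationError("no fields matched the layout")
    return pd.concat(frames, ignore_index=True)


def run_statistics(wells: pd.DataFrame, metric: str, analyses: list,
                   seed: int) -> tuple[pd.DataFrame, list]:
    """Run each configured trend analysis on the per-well metric."""
    rows = []
    results = []
    for spec in analyses:
        control = wells.loc[wells["group_label"] == spec.control_label,
                            metric].dropna().to_numpy()
        dose_obs = [
            wells.loc[wells["group_label"] == lab, metric].dropna().to_numpy()
            for lab in spec.dose_labels
        ]
        series = DoseSeries(control=control, doses=dose_obs,
                            dose_labels=list(spec.dose_labels),
                            direction=spec.direction)
        result = run_trend(series, alpha=spec.alpha, seed=seed)
        results.append((spec, result))
        for dec in result.decisions:
            rows.append(dict(
                analysis=spec.name, test=result.test, alpha=spec.alpha,
                direction=spec.direction, control_label=spec.control_label,
                group_label=dec.label, statistic=dec.statistic,
                critical_value=dec.critical_value,
                significant=dec.significant, stars="*" * dec.stars,
                heterogeneity_p=result.heterogeneity_p,
            ))
    return pd.DataFrame(rows), results


def run(config: RunConfig) -> Path:
    """Execute all stages and return the run directory.

    Fails before any computation when the input images or layout are
    missing; outputs are fully determined by (config, seed) apart from
    manifest timestamps.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    if config.sim is not None:
        log.info("simulating synthetic plate (%d groups x %d wells)",
                 len(config.sim.groups), config.sim.wells_per_group)
        paths = generate_plate(config.sim, out)
        images_dir, layout_path = paths["images_dir"], paths["layout"]
    else:
        images_dir = Path(config.images_dir)
        layout_path = Path(config.layout_csv)
        if not images_dir.is_dir():
            raise ConfigurationError(f"image directory not found: {images_dir}")
        if not layout_path.is_file():
            raise ConfigurationError(f"layout CSV not found: {layout_path}")
    layout = _load_layout(layout_path)
    if config.control_label not in set(layout["group_label"]):
        raise ConfigurationError(
            f"control label {config.control_label!r} not present in layout"
        )

    log.info("segmenting fields from %s", images_dir)
    cells = analyze_plate(images_dir, layout, config.mode,
                          config.pixel_size_um, config.segmentation)
    cells.to_csv(out / "cells.csv", index=False)

    wells = score_wells(cells, layout, config.mode, config.scoring)
    wells.to_csv(out / "wells.csv", index=False)
    metric = "hsi" if config.mode == SARCOMERE_60X else "yap_index"
    groups = relative_to_control(wells, metric, config.control_label)
    groups.drop(columns=["well_values"]).to_csv(out / "groups.csv", index=False)

    analyses = config.analyses
    if not analyses:
        dose_order = (
            layout[layout["group_label"] != config.control_label]
            .groupby("group_label", sort=False)["dose_uM"].first()
            .sort_values()
        )
        analyses = [TrendAnalysisSpec(
            name=f"{metric}_vs_control", control_label=config.control_label,
            dose_labels=list(dose_order.index), direction="decreasing",
        )]
    stats_df, results = run_statistics(wells, metric, analyses, config.seed)
    stats_df.to_csv(out / "stats.csv", index=False)
    stats_json = [
        dict(analysis=spec.name, test=res.test, alpha=spec.alpha,
             direction=res.direction, heterogeneity_p=res.heterogeneity_p,
             decisions=[vars(d) for d in res.decisions])
        for spec, res in results
    ]
    (out / "stats.json").write_text(json.dumps(stats_json, indent=2))

    manifest = dict(
        package_version=sarcoscreen.__version__,
        numpy_version=np.__version__,
        seed=config.seed,
        mode=config.mode,
        control_label=config.control_label,
        metric=metric,
        sim=config_to_dict(config.sim) if config.sim is not None else None,
        images_dir=str(images_dir),
        elapsed_s=round(time.time() - t0, 2),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("run complete in %.1f s -> %s", time.time() - t0, out)
    return out


def run_scenario(name: str, seed: int, output_dir,
                 wells_per_group: int = 5, **sim_overrides) -> Path:
    """Run a named scenario preset end to end.

    ``washout_recovery`` emits one result set per timepoint in
    subdirectories ``t0h``, ``t72h``, ``t144h``; the other presets
    write a single run directory.
    """
    if name not in PRESET_NAMES:
        raise ConfigurationError(f"unknown preset {name!r}; expected {PRESET_NAMES}")
    out = Path(output_dir)
    if name == "washout_recovery":
        for tp in WASHOUT_SEVERITIES:
            preset = get_preset(name, timepoint=tp)
            sim = preset_sim_config(preset, seed, wells_per_group, **sim_overrides)
            cfg = RunConfig(output_dir=str(out / f"t{tp}"), sim=sim,
                            analyses=preset.analyses, seed=seed)
            run(cfg)
        return out
    preset = get_preset(name)
    sim = preset_sim_config(preset, seed, wells_per_group, **sim_overrides)
    cfg = RunConfig(output_dir=str(out), sim=sim,
                    analyses=preset.analyses, seed=seed)
    return run(cfg)
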