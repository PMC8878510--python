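"""End-to-end orchestration: load -> segment -> classify -> quantify -> summarize.

A run is driven by a strict YAML/dict configuration. Every numeric constant
of the imaging pipeline lives in one defaults table (``PIPELINE_DEFAULTS``)
so a run manifest can echo exactly which values were used; identical
configuration and inputs give byte-identical output CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classification import (
    classify_nuclei,
    compute_features,
    default_model,
    LinearClassifierModel,
)
from .quantification import (
    assign_cytoplasm,
    filter_elongated,
    measure_cell,
    positive_calls,
    prepare_marker_mask,
    summarize_slide,
)
from .scene import read_scene
from .segmentation import DAPI, ConfigurationError, ImageScene, SegmentationConfig, segment_nuclei

logger = logging.getLogger(__name__)

# the imaging constants, in one auditable place
PIPELINE_DEFAULTS: dict[str, float | int] = {
    "min_filter_size": 50,
    "sat_low_pct": 5.0,
    "sat_high_pct": 95.0,
    "nuc_threshold": 0.4,
    "min_area": 10,
    "split_area": 200,
    "connectivity": 8,
    "marker_min_distance": 3,
    "expansion_radius": 10,
    "min_overlap_px": 5,
    "elongation_min_area": 20,
    "elongation_min_ratio": 0.5,
}


class ConfigError(ValueError):
    """Configuration problem, reported with the offending key path."""


@dataclass
class RunConfig:
    """Normalized full-pipeline configuration."""

    image: str
    channel_map: dict[str, int]                  # channel name -> TIFF page
    out_dir: str = "camquant_out"
    model_path: str | None = None
    seed: int = 0
    log_level: str = "INFO"
    segmentation: dict = field(default_factory=dict)
    expansion_radius: float = PIPELINE_DEFAULTS["expansion_radius"]
    min_overlap_px: int = PIPELINE_DEFAULTS["min_overlap_px"]
    elongation_markers: list[str] = field(default_factory=list)
    double_positive_pairs: list[tuple[str, str]] = field(default_factory=list)

    def segmentation_config(self) -> SegmentationConfig:
        merged = {
            k: PIPELINE_DEFAULTS[k]
            for k in ("min_filter_size", "sat_low_pct", "sat_high_pct",
                      "nuc_threshold", "min_area", "split_area", "connectivity",
                      "marker_min_distance")
        }
        merged.update(self.segmentation)
        return SegmentationConfig(**merged)


_TOP_LEVEL_KEYS = {
    "image", "channel_map", "out_dir", "model_path", "seed", "log_level",
    "segmentation", "expansion_radius", "min_overlap_px",
    "elongation_markers", "double_positive_pairs",
}
_SEG_KEYS = {
    "min_filter_size", "sat_low_pct", "sat_high_pct", "nuc_threshold",
    "min_area", "split_area", "connectivity", "max_single_area",
    "marker_min_distance",
}


def validate_config(source: str | Path | dict) -> RunConfig:
    """Parse + validate a config file or dict; fill all defaults; strict schema.

    Every error is raised with the key path that caused it; no partially
    validated configuration escapes.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "image" not in raw:
        raise ConfigError("image: required")
    if "channel_map" not in raw or not isinstance(raw["channel_map"], dict):
        raise ConfigError("channel_map: required mapping of channel name -> page index")
    cmap = {str(k): int(v) for k, v in raw["channel_map"].items()}
    if DAPI not in cmap:
        raise ConfigError(f"channel_map: must include the {DAPI!r} channel")
    pages = list(cmap.values())
    if len(pages) != len(set(pages)):
        raise ConfigError("channel_map: duplicate page indices")
    if len(set(raw["channel_map"])) != len(raw["channel_map"]):
        raise ConfigError("channel_map: duplicate channel names")

    seg = raw.get("segmentation") or {}
    unknown_seg = set(seg) - _SEG_KEYS
    if unknown_seg:
        raise ConfigError(f"segmentation: unknown keys {sorted(unknown_seg)}")

    config = RunConfig(
        image=str(raw["image"]),
        channel_map=cmap,
        out_dir=str(raw.get("out_dir", "camquant_out")),
        model_path=raw.get("model_path"),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
        segmentation=dict(seg),
        expansion_radius=float(raw.get("expansion_radius",
                                       PIPELINE_DEFAULTS["expansion_radius"])),
        min_overlap_px=int(raw.get("min_overlap_px", PIPELINE_DEFAULTS["min_overlap_px"])),
        elongation_markers=[str(m) for m in raw.get("elongation_markers", [])],
        double_positive_pairs=[tuple(p) for p in raw.get("double_positive_pairs", [])],
    )
    for marker in config.elongation_markers:
        if marker not in cmap:
            raise ConfigError(f"elongation_markers: {marker!r} not in channel_map")
    for pair in config.double_positive_pairs:
        if len(pair) != 2 or any(m not in cmap for m in pair):
            raise ConfigError(f"double_positive_pairs: bad pair {pair!r}")
    try:
        config.segmentation_config()  # validate numeric constraints now
    except (ConfigurationError, TypeError) as exc:
        raise ConfigError(f"segmentation: {exc}") from exc
    if config.expansion_radius <= 0:
        raise ConfigError("expansion_radius: must be positive")
    return config


def _config_hash(config: RunConfig) -> str:
    doc = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write per-cell CSV, slide summary CSV and manifest.

    Returns a dict with the output paths and the slide summary. Any stage
    failure raises with the stage name attached.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "load"
    try:
        t0 = time.perf_counter()
        scene_raw, _ = read_scene(config.image)
        pages = list(scene_raw.channels.values())
        by_page = {name: pages[idx] for name, idx in config.channel_map.items()}
        scene = ImageScene(channels=by_page)
        timings[stage] = time.perf_counter() - t0

        stage = "segment"
        t0 = time.perf_counter()
        seg_config = config.segmentation_config()
        label_map = segment_nuclei(scene, seg_config)
        timings[stage] = time.perf_counter() - t0

        stage = "classify"
        t0 = time.perf_counter()
        features = compute_features(label_map)
        if config.model_path:
            model = LinearClassifierModel.load(config.model_path)
        else:
            model = default_model(seed=config.seed)
        classified = classify_nuclei(features, model) if not features.empty else features
        timings[stage] = time.perf_counter() - t0

        stage = "quantify"
        t0 = time.perf_counter()
        regions = assign_cytoplasm(label_map, config.expansion_radius)
        markers = [name for name in config.channel_map if name != DAPI]
        per_cell_frames = []
        for marker in markers:
            mask = prepare_marker_mask(
                scene.channels[marker], seg_config.min_filter_size, seg_config.nuc_threshold
            )
            if marker in config.elongation_markers:
                mask = filter_elongated(
                    mask,
                    PIPELINE_DEFAULTS["elongation_min_area"],
                    PIPELINE_DEFAULTS["elongation_min_ratio"],
                )
            mfi = measure_cell(scene, regions, marker)
            pos = positive_calls(regions, mask, config.min_overlap_px)
            frame = mfi.merge(pos, on="label")
            frame.insert(1, "marker", marker)
            per_cell_frames.append(frame)
        if per_cell_frames:
            per_cell = pd.concat(per_cell_frames, ignore_index=True)
            per_cell = per_cell.merge(
                classified[["label", "class"]], on="label", how="left"
            )
        else:
            per_cell = pd.DataFrame(
                columns=["label", "marker", "nuclear_mfi", "cytoplasmic_mfi",
                         "combined_mfi", "overlap_px", "positive", "class"]
            )
        timings[stage] = time.perf_counter() - t0

        stage = "summarize"
        t0 = time.perf_counter()
        summary = summarize_slide(per_cell, config.double_positive_pairs)
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed on {config.image}: {exc}") from exc

    stage = "write"
    per_cell_path = out_dir / "per_cell.csv"
    summary_path = out_dir / "slide_summary.csv"
    dp_path = out_dir / "double_positive.csv"
    nuclei_path = out_dir / "nuclei.csv"
    per_cell.to_csv(per_cell_path, index=False)
    summary.per_class.to_csv(summary_path, index=False)
    summary.double_positive.to_csv(dp_path, index=False)
    classified.to_csv(nuclei_path, index=False)
    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "defaults_used": PIPELINE_DEFAULTS,
        "config": asdict(config),
        "n_nuclei": int(label_map.n_labels),
        "stage_timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete: %d nuclei, outputs in %s", label_map.n_labels, out_dir)
    return {
        "per_cell": per_cell_path,
        "slide_summary": summary_path,
        "double_positive": dp_path,
        "nuclei": nuclei_path,
        "manifest": manifest_path,
        "summary": summary,
    }
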