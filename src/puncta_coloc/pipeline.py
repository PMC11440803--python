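"""Experiment-level orchestration: run the full analysis over a directory.

An experiment directory must contain at least one subfolder; each subfolder
holds only image files and its name is carried into the output as the
``group`` column (groups are organizational only and do not affect the
analysis).  For every image: load -> grouped max z-projection -> 8-bit RGB
-> optional preprocessing -> per-channel thresholding -> ROI restriction ->
puncta detection -> colocalization -> tables and feedback overlay.  The
resolved configuration and all threshold records are echoed into the output
directory, making the complete run reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import yaml

from puncta_coloc import image_io
from puncta_coloc.colocalize import ROISpec, apply_roi, coloc_circular, coloc_pixel
from puncta_coloc.image_io import ImageRecord, RGB8Image, load_image, to_rgb8, zproject_groups
from puncta_coloc.preprocess import PreprocessParams, preprocess_plane
from puncta_coloc.puncta_detect import DetectionParams, detect_puncta, size_filtered_mask
from puncta_coloc.reporting import (
    ImageResult,
    render_coloc_overlay,
    write_puncta_tables,
    write_summary,
    write_threshold_records,
)
from puncta_coloc.thresholding import (
    SynQuantParams,
    ThresholdRecord,
    apply_fixed_threshold,
    otsu_threshold,
    statistical_threshold,
    thresholds_from_file,
)

logger = logging.getLogger(__name__)

IMAGE_EXTENSIONS = (".tif", ".tiff", ".png", ".bmp")


@dataclass
class RunConfig:
    """Complete configuration of one analysis run."""

    experiment_dir: str
    output_dir: str
    channels_mode: str = "two"  # two | three | pick
    channel_map: dict[str, int] = field(default_factory=lambda: {"red": 0, "green": 1})
    zproj_group: int = 1
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    threshold_mode: str = "fixed"  # fixed | manual | file | otsu | statistical
    fixed_values: dict[str, int] = field(default_factory=lambda: {"red": 50, "green": 50})
    threshold_file: str | None = None
    synquant: SynQuantParams = field(default_factory=SynQuantParams)
    roi: ROISpec = field(default_factory=ROISpec)
    detection: dict[str, DetectionParams] = field(default_factory=dict)
    analysis_mode: str = "circular"  # circular | pixel
    coloc_min_size: int = 1
    rgb_conversion: str = "fixed"  # fixed floor(v/256) | minmax
    dot_radius: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channels_mode not in ("two", "three", "pick"):
            raise ValueError(f"unknown channels_mode {self.channels_mode!r}")
        if self.threshold_mode not in ("fixed", "manual", "file", "otsu", "statistical"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.analysis_mode not in ("circular", "pixel"):
            raise ValueError(f"unknown analysis_mode {self.analysis_mode!r}")
        if self.zproj_group < 1:
            raise ValueError("zproj_group must be >= 1")
        if self.channels_mode == "two":
            self.channel_map = {r: i for r, i in self.channel_map.items() if r in ("red", "green")}
        if self.channels_mode == "three" and "blue" not in self.channel_map:
            self.channel_map.setdefault("blue", 2)

    @property
    def analysis_channels(self) -> list[str]:
        return ["red", "green", "blue"] if self.channels_mode == "three" else ["red", "green"]

    @classmethod
    def from_yaml(cls, path: str, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(raw.get("preprocess"), Mapping):
            raw["preprocess"] = PreprocessParams(**raw["preprocess"])
        if isinstance(raw.get("synquant"), Mapping):
            raw["synquant"] = SynQuantParams(**raw["synquant"])
        if isinstance(raw.get("roi"), str):
            raw["roi"] = ROISpec.from_string(raw["roi"])
        elif isinstance(raw.get("roi"), Mapping):
            raw["roi"] = ROISpec(**raw["roi"])
        if isinstance(raw.get("detection"), Mapping):
            raw["detection"] = {
                ch: DetectionParams(**p) if isinstance(p, Mapping) else p
                for ch, p in raw["detection"].items()
            }
        return cls(**raw)

    def to_dict(self) -> dict:
        def encode(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    f.name: encode(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                    if not f.name.startswith("_")
                }
            if isinstance(obj, dict):
                return {k: encode(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        return encode(self)


def _list_experiment_images(experiment_dir: str) -> list[tuple[str, str]]:
    """(group, path) pairs for every image in the experiment subfolders."""
    if not os.path.isdir(experiment_dir):
        raise FileNotFoundError(f"experiment directory not found: {experiment_dir}")
    subfolders = sorted(
        d for d in os.listdir(experiment_dir) if os.path.isdir(os.path.join(experiment_dir, d))
    )
    if not subfolders:
        raise ValueError(
            f"experiment directory {experiment_dir} must include at least one subfolder"
        )
    images: list[tuple[str, str]] = []
    for sub in subfolders:
        entries = sorted(os.listdir(os.path.join(experiment_dir, sub)))
        found = [
            (sub, os.path.join(experiment_dir, sub, e))
            for e in entries
            if e.lower().endswith(IMAGE_EXTENSIONS)
        ]
        if not found:
            logger.warning("subfolder %s contains no image files", sub)
        images.extend(found)
    return images


def _threshold_channel(
    config: RunConfig,
    plane: np.ndarray,
    image_name: str,
    channel: str,
    file_thresholds: Mapping[tuple[str, str], int] | None,
) -> tuple[np.ndarray, ThresholdRecord]:
    mode = config.threshold_mode
    if mode in ("fixed", "manual"):
        cutoff = config.fixed_values.get(channel)
        if cutoff is None:
            raise ValueError(f"no {mode} threshold value configured for channel {channel!r}")
        return (
            apply_fixed_threshold(plane, int(cutoff)),
            ThresholdRecord(image_name, channel, mode, int(cutoff)),
        )
    if mode == "file":
        assert file_thresholds is not None
        key = (image_name, channel)
        if key not in file_thresholds:
            raise KeyError(f"threshold file has no record for image {image_name!r} channel {channel!r}")
        cutoff = file_thresholds[key]
        return (
            apply_fixed_threshold(plane, cutoff),
            ThresholdRecord(image_name, channel, "from_file", cutoff),
        )
    if mode == "otsu":
        cutoff = otsu_threshold(plane)
        return (
            apply_fixed_threshold(plane, cutoff),
            ThresholdRecord(image_name, channel, "otsu", cutoff),
        )
    mask, _ = statistical_threshold(plane, config.synquant)
    return mask, ThresholdRecord(image_name, channel, "statistical", None)


def analyze_projection(
    config: RunConfig,
    rgb: RGB8Image,
    image_name: str,
    projection_index: int,
    group: str = "",
    file_thresholds: Mapping[tuple[str, str], int] | None = None,
) -> ImageResult:
    """Run thresholding, ROI, detection and colocalization on one projection."""
    channels = config.analysis_channels
    masks: dict[str, np.ndarray] = {}
    records: list[ThresholdRecord] = []
    puncta: dict[str, list] = {}
    for channel in channels:
        plane = rgb.plane(channel)
        if config.preprocess.subtract_background or config.preprocess.normalize_brightness:
            plane = preprocess_plane(plane, config.preprocess)
        mask, record = _threshold_channel(config, plane, image_name, channel, file_thresholds)
        mask = apply_roi(mask, config.roi)
        masks[channel] = mask
        records.append(record)
        det = config.detection.get(channel, DetectionParams())
        puncta[channel] = detect_puncta(mask, det, channel)

    analysis_mode = config.analysis_mode
    if analysis_mode == "circular" and len(channels) > 2:
        logger.warning(
            "circular mode supports 2 channels only; 3-channel analysis routed to pixel mode"
        )
        analysis_mode = "pixel"
    if analysis_mode == "circular":
        colocs = coloc_circular(puncta["red"], puncta["green"])
    else:
        # Pixel mode counts overlap between size-filtered puncta, so each
        # channel mask is rebuilt from its surviving components.
        filtered = {
            channel: size_filtered_mask(masks[channel], config.detection.get(channel, DetectionParams()))
            for channel in channels
        }
        _, colocs = coloc_pixel(
            filtered["red"],
            filtered["green"],
            filtered.get("blue"),
            coloc_min_size=config.coloc_min_size,
        )

    det_red = config.detection.get("red", DetectionParams())
    det_green = config.detection.get("green", DetectionParams())
    return ImageResult(
        image_name=image_name,
        projection_index=projection_index,
        group=group,
        red_count=len(puncta.get("red", [])),
        green_count=len(puncta.get("green", [])),
        blue_count=len(puncta.get("blue", [])),
        coloc_count=len(colocs),
        thresholds=records,
        red_min_size=det_red.min_size,
        green_min_size=det_green.min_size,
        coloc_min_size=config.coloc_min_size,
        roi_area=config.roi.area(rgb.red.shape),
        mode=analysis_mode,
        puncta=puncta,
        colocalizations=colocs,
    )


def run_experiment(config: RunConfig) -> list[ImageResult]:
    """Analyze every image in the experiment directory and write all outputs.

    One unreadable image is skipped with a logged warning and never aborts
    the run.  Outputs: ``summary.csv`` and ``thresholds.csv`` at the top of
    the output directory, the resolved configuration as ``config.yaml``,
    and per-projection puncta/colocalization tables plus ``_colocs``
    feedback overlays under one subdirectory per group.
    """
    images = _list_experiment_images(config.experiment_dir)
    os.makedirs(config.output_dir, exist_ok=True)

    log_path = os.path.join(config.output_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("puncta_coloc")
    root.addHandler(handler)
    try:
        file_thresholds = (
            thresholds_from_file(config.threshold_file) if config.threshold_mode == "file" else None
        )
        logger.info("run configuration: %s", config.to_dict())
        results: list[ImageResult] = []
        for group, path in images:
            try:
                record = load_image(path, config.channel_map)
            except Exception as exc:  # noqa: BLE001 - skip-and-log contract
                logger.warning("skipping unreadable image %s: %s", path, exc)
                continue
            projections = zproject_groups(record, config.zproj_group)
            for proj_index, planes in enumerate(projections):
                rgb = to_rgb8(planes, bit_depth=record.bit_depth, mode=config.rgb_conversion)
                result = analyze_projection(
                    config, rgb, record.name, proj_index, group=group, file_thresholds=file_thresholds
                )
                group_dir = os.path.join(config.output_dir, group)
                write_puncta_tables(result, group_dir)
                overlay_path = os.path.join(
                    group_dir, f"{record.name}_p{proj_index}_colocs.png"
                )
                render_coloc_overlay(rgb, result.colocalizations, config.dot_radius, overlay_path)
                results.append(result)
        if not results:
            raise ValueError("no analyzable images found in the experiment directory")
        write_summary(results, os.path.join(config.output_dir, "summary.csv"))
        write_threshold_records(results, os.path.join(config.output_dir, "thresholds.csv"))
        with open(os.path.join(config.output_dir, "config.yaml"), "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
        return results
    finally:
        root.removeHandler(handler)
        handler.close()
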