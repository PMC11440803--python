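"""Result tables and the "_colocs" feedback overlay.

One summary row per analyzed projection, per-channel puncta tables and a
per-colocalization table, plus an overlay image with a white dot at every
counted colocalization for visual quality control.

All tables are plain CSV (header row, "." decimal separator); coordinates
are pixels, 0-based, ``x`` = column and ``y`` = row.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import imageio.v3 as iio

from puncta_coloc.colocalize import Colocalization
from puncta_coloc.image_io import RGB8Image
from puncta_coloc.puncta_detect import Punctum
from puncta_coloc.thresholding import ThresholdRecord

SUMMARY_COLUMNS = [
    "group",
    "image_name",
    "projection_index",
    "red_count",
    "green_count",
    "blue_count",
    "coloc_count",
    "red_threshold",
    "green_threshold",
    "blue_threshold",
    "red_min_size",
    "green_min_size",
    "coloc_min_size",
    "roi_area",
    "mode",
]


@dataclass
class ImageResult:
    """Everything recorded for one analyzed projection."""

    image_name: str
    projection_index: int
    group: str = ""
    red_count: int = 0
    green_count: int = 0
    blue_count: int = 0
    coloc_count: int = 0
    thresholds: list[ThresholdRecord] = field(default_factory=list)
    red_min_size: int = 0
    green_min_size: int = 0
    coloc_min_size: int = 1
    roi_area: int = 0
    mode: str = "pixel"
    puncta: dict[str, list[Punctum]] = field(default_factory=dict)
    colocalizations: list[Colocalization] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.red_count, self.green_count, self.blue_count, self.coloc_count) < 0:
            raise ValueError("counts must be >= 0")
        if self.mode not in ("circular", "pixel"):
            raise ValueError(f"unknown analysis mode {self.mode!r}")

    def threshold_value(self, channel: str) -> int | str:
        for rec in self.thresholds:
            if rec.channel == channel:
                return rec.value if rec.value is not None else rec.method
        return ""


def write_summary(results: Sequence[ImageResult], path: str) -> pd.DataFrame:
    """Write the per-projection summary CSV (one row per projection,
    input order preserved) and return it as a DataFrame."""
    if not results:
        raise ValueError("no results to summarize")
    rows = []
    for r in results:
        rows.append(
            {
                "group": r.group,
                "image_name": r.image_name,
                "projection_index": r.projection_index,
                "red_count": r.red_count,
                "green_count": r.green_count,
                "blue_count": r.blue_count,
                "coloc_count": r.coloc_count,
                "red_threshold": r.threshold_value("red"),
                "green_threshold": r.threshold_value("green"),
                "blue_threshold": r.threshold_value("blue"),
                "red_min_size": r.red_min_size,
                "green_min_size": r.green_min_size,
                "coloc_min_size": r.coloc_min_size,
                "roi_area": r.roi_area,
                "mode": r.mode,
            }
        )
    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    table.to_csv(path, index=False, lineterminator="\n")
    return table


def write_threshold_records(results: Sequence[ImageResult], path: str) -> pd.DataFrame:
    """Write the threshold-record table used by the threshold-from-file mode."""
    rows = [
        {
            "image_name": rec.image_name,
            "channel": rec.channel,
            "method": rec.method,
            "value": rec.value if rec.value is not None else "",
        }
        for r in results
        for rec in r.thresholds
    ]
    table = pd.DataFrame(rows, columns=["image_name", "channel", "method", "value"])
    table.to_csv(path, index=False, lineterminator="\n")
    return table


def _puncta_frame(puncta: Sequence[Punctum]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": p.id,
                "channel": p.channel,
                "x": p.centroid_x,
                "y": p.centroid_y,
                "area": p.area,
                "radius": p.radius,
                "circularity": p.circularity,
            }
            for p in puncta
        ],
        columns=["id", "channel", "x", "y", "area", "radius", "circularity"],
    )


def coloc_frame(colocs: Sequence[Colocalization]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "red_id": c.red_id,
                "green_id": c.green_id,
                "blue_id": c.blue_id if c.blue_id is not None else "",
                "x": c.centroid_x,
                "y": c.centroid_y,
                "area": c.overlap_area,
            }
            for c in colocs
        ],
        columns=["red_id", "green_id", "blue_id", "x", "y", "area"],
    )


def write_puncta_tables(result: ImageResult, out_dir: str) -> dict[str, str]:
    """Write one CSV per channel plus the colocalization table.

    Coordinates are pixels, 0-based (x = column, y = row).  Empty channels
    still produce a header-only table.  Returns a name -> path mapping.
    """
    os.makedirs(out_dir, exist_ok=True)
    stem = f"{result.image_name}_p{result.projection_index}"
    written: dict[str, str] = {}
    for channel in ("red", "green", "blue"):
        if channel == "blue" and channel not in result.puncta:
            continue
        path = os.path.join(out_dir, f"{stem}_{channel}_puncta.csv")
        _puncta_frame(result.puncta.get(channel, [])).to_csv(path, index=False, lineterminator="\n")
        written[channel] = path
    coloc_path = os.path.join(out_dir, f"{stem}_colocalizations.csv")
    coloc_frame(result.colocalizations).to_csv(coloc_path, index=False, lineterminator="\n")
    written["colocalizations"] = coloc_path
    return written


def render_coloc_overlay(
    rgb: RGB8Image,
    colocs: Sequence[Colocalization],
    dot_radius: int,
    path: str,
) -> str:
    """Write the feedback image: the RGB input with a filled white disk of
    ``dot_radius`` at each colocalization centroid.

    The output is named ``<image>_colocs.png`` (the caller passes the full
    path); pixels within ``dot_radius`` of a centroid are set to
    ``(255, 255, 255)``, the rest of the image is unchanged.
    """
    canvas = rgb.to_array().copy()
    h, w = canvas.shape[:2]
    offsets = [
        (dr, dc)
        for dr in range(-dot_radius, dot_radius + 1)
        for dc in range(-dot_radius, dot_radius + 1)
        if dr * dr + dc * dc <= dot_radius * dot_radius
    ]
    for c in colocs:
        r0, c0 = int(round(c.centroid_y)), int(round(c.centroid_x))
        for dr, dc in offsets:
            r, cc = r0 + dr, c0 + dc
            if 0 <= r < h and 0 <= cc < w:
                canvas[r, cc] = 255
    iio.imwrite(path, canvas)
    return path
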