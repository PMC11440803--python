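"""Colocalization counting between channels.

Two analysis modes are provided:

* **circular** — each punctum is approximated by a disk of its
  equivalent-disk radius centered at its centroid; a red/green pair is a
  colocalization when the distance between centers is strictly less than
  the sum of the radii, and the overlap area is the circle-circle lens
  area computed in closed form.  Valid for near-circular puncta only.
* **pixel** — the per-pixel logical AND of the channel masks; each
  connected overlap component of at least ``coloc_min_size`` pixels is one
  colocalization.  Supports a third (blue) channel.

Analysis can be restricted to a region of interest (whole image, circle,
or arbitrary mask).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import imageio.v3 as iio
from scipy import ndimage

from puncta_coloc.puncta_detect import DetectionParams, Punctum, detect_puncta


@dataclass
class ROISpec:
    """Region of interest: whole image, a circle, or an arbitrary mask.

    Circle coordinates follow the package convention (``center_x`` = column,
    ``center_y`` = row, 0-based); a pixel is inside when its distance from
    the center is <= ``radius``.  A mask ROI is a single-channel image file
    in which nonzero pixels mark the inside.
    """

    kind: str = "whole_image"
    center_x: float | None = None
    center_y: float | None = None
    radius: float | None = None
    mask_path: str | None = None
    _mask_cache: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("whole_image", "circle", "mask"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "circle":
            if self.center_x is None or self.center_y is None or self.radius is None:
                raise ValueError("circle ROI requires center_x, center_y and radius")
            if self.radius <= 0:
                raise ValueError("circle ROI radius must be > 0")
        if self.kind == "mask" and self.mask_path is None and self._mask_cache is None:
            raise ValueError("mask ROI requires mask_path")

    @classmethod
    def from_string(cls, text: str) -> "ROISpec":
        """Parse ``whole`` | ``circle:cx,cy,r`` | ``mask:PATH``."""
        if text in ("whole", "whole_image"):
            return cls(kind="whole_image")
        kind, _, rest = text.partition(":")
        if kind == "circle":
            try:
                cx, cy, r = (float(v) for v in rest.split(","))
            except ValueError as exc:
                raise ValueError(f"cannot parse circle ROI {text!r}; expected circle:cx,cy,r") from exc
            return cls(kind="circle", center_x=cx, center_y=cy, radius=r)
        if kind == "mask":
            return cls(kind="mask", mask_path=rest)
        raise ValueError(f"unknown ROI specification {text!r}")

    def inside_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean inside-ROI mask for an image of the given (h, w) shape."""
        if self.kind == "whole_image":
            return np.ones(shape, dtype=bool)
        if self.kind == "circle":
            rows, cols = np.ogrid[: shape[0], : shape[1]]
            return (rows - self.center_y) ** 2 + (cols - self.center_x) ** 2 <= self.radius**2
        if self._mask_cache is None:
            arr = np.asarray(iio.imread(self.mask_path))
            if arr.ndim == 3:
                arr = arr[..., 0]
            self._mask_cache = arr > 0
        if self._mask_cache.shape != shape:
            raise ValueError(
                f"ROI mask shape {self._mask_cache.shape} does not match image shape {shape}"
            )
        return self._mask_cache

    def area(self, shape: tuple[int, int]) -> int:
        """Number of pixels inside the ROI (recorded in the summary)."""
        return int(np.count_nonzero(self.inside_mask(shape)))


@dataclass(frozen=True)
class Colocalization:
    """One counted synapse: a red/green (optionally +blue) overlap.

    In circular mode ``red_id``/``green_id`` are the punctum ids and
    ``overlap_area`` the real-valued lens area; in pixel mode they both
    carry the overlap-component id and ``overlap_area`` is the component
    pixel count.
    """

    red_id: int
    green_id: int
    overlap_area: float
    centroid_x: float
    centroid_y: float
    blue_id: int | None = None

    def __post_init__(self) -> None:
        if self.overlap_area <= 0:
            raise ValueError("overlap_area must be > 0")


def circles_overlap(p1: Punctum, p2: Punctum) -> bool:
    """True iff the equivalent disks intersect with positive area.

    The test is strict: tangent circles (distance exactly equal to the sum
    of radii) do not count as a colocalization.
    """
    d = math.hypot(p1.centroid_x - p2.centroid_x, p1.centroid_y - p2.centroid_y)
    return d < p1.radius + p2.radius


def circle_overlap_area(p1: Punctum, p2: Punctum) -> float:
    """Closed-form area of the intersection lens of two overlapping disks.

    For center distance ``d`` and radii ``r1, r2`` the chord line sits at
    ``d1 = (d^2 + r1^2 - r2^2) / (2 d)`` from center 1 and ``d2 = d - d1``
    from center 2, with half-chord ``h = sqrt(r1^2 - d1^2)``; the lens is
    the sum of the two circular sectors minus the two triangles outside the
    overlap:

        area = r1^2 acos(d1/r1) + r2^2 acos(d2/r2) - d h

    When one disk contains the other (``d <= |r1 - r2|``, where the sector
    construction is undefined) the full area of the smaller disk is
    returned.
    """
    r1, r2 = p1.radius, p2.radius
    d = math.hypot(p1.centroid_x - p2.centroid_x, p1.centroid_y - p2.centroid_y)
    if d >= r1 + r2:
        raise ValueError(f"circles do not overlap (d={d}, r1+r2={r1 + r2})")
    if d <= abs(r1 - r2):
        return math.pi * min(r1, r2) ** 2
    d1 = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    d2 = d - d1
    h = math.sqrt(max(r1 * r1 - d1 * d1, 0.0))
    return (
        r1 * r1 * math.acos(max(-1.0, min(1.0, d1 / r1)))
        + r2 * r2 * math.acos(max(-1.0, min(1.0, d2 / r2)))
        - d * h
    )


def _lens_centroid(p1: Punctum, p2: Punctum) -> tuple[float, float]:
    """Midpoint of the chord line: at distance d1 from center 1 along the
    center line (the centers' common point when d = 0 or under containment)."""
    d = math.hypot(p1.centroid_x - p2.centroid_x, p1.centroid_y - p2.centroid_y)
    if d == 0:
        return p1.centroid_x, p1.centroid_y
    if d <= abs(p1.radius - p2.radius):
        small = p1 if p1.radius <= p2.radius else p2
        return small.centroid_x, small.centroid_y
    d1 = (d * d + p1.radius**2 - p2.radius**2) / (2 * d)
    t = d1 / d
    return (
        p1.centroid_x + t * (p2.centroid_x - p1.centroid_x),
        p1.centroid_y + t * (p2.centroid_y - p1.centroid_y),
    )


def coloc_circular(red: Sequence[Punctum], green: Sequence[Punctum]) -> list[Colocalization]:
    """All red/green punctum pairs whose equivalent disks overlap.

    Counting is pairwise: one red punctum overlapping two distinct green
    puncta contributes two colocalizations.  Restricted to two channels.
    """
    colocs: list[Colocalization] = []
    for p_red in red:
        for p_green in green:
            if not circles_overlap(p_red, p_green):
                continue
            cx, cy = _lens_centroid(p_red, p_green)
            colocs.append(
                Colocalization(
                    red_id=p_red.id,
                    green_id=p_green.id,
                    overlap_area=circle_overlap_area(p_red, p_green),
                    centroid_x=cx,
                    centroid_y=cy,
                )
            )
    return colocs


def coloc_pixel(
    red_mask: np.ndarray,
    green_mask: np.ndarray,
    blue_mask: np.ndarray | None = None,
    coloc_min_size: int = 1,
    connectivity: int = 8,
) -> tuple[np.ndarray, list[Colocalization]]:
    """Pixel-overlap colocalization: logical AND of the channel masks.

    Connected components of the overlap mask with area >= ``coloc_min_size``
    become colocalization records (area = pixel count, centroid = component
    centroid).  With a blue mask the AND runs over all three channels.
    Returns the overlap mask and the records.
    """
    red_mask = np.asarray(red_mask, dtype=bool)
    green_mask = np.asarray(green_mask, dtype=bool)
    if red_mask.shape != green_mask.shape:
        raise ValueError(f"mask shapes differ: {red_mask.shape} vs {green_mask.shape}")
    overlap = red_mask & green_mask
    if blue_mask is not None:
        blue_mask = np.asarray(blue_mask, dtype=bool)
        if blue_mask.shape != red_mask.shape:
            raise ValueError(f"blue mask shape {blue_mask.shape} differs from {red_mask.shape}")
        overlap = overlap & blue_mask
    components = detect_puncta(
        overlap,
        DetectionParams(min_size=max(coloc_min_size, 1), max_size=None, connectivity=connectivity),
        channel="overlap",
    )
    colocs = [
        Colocalization(
            red_id=c.id,
            green_id=c.id,
            overlap_area=float(c.area),
            centroid_x=c.centroid_x,
            centroid_y=c.centroid_y,
            blue_id=c.id if blue_mask is not None else None,
        )
        for c in components
    ]
    return overlap, colocs


def apply_roi(mask: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Clear mask pixels outside the ROI (identity for whole-image ROI)."""
    mask = np.asarray(mask, dtype=bool)
    if roi.kind == "whole_image":
        return mask
    return mask & roi.inside_mask(mask.shape)
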