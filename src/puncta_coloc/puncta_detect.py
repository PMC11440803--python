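"""Punctum extraction from binary masks (particle analysis).

A punctum is one connected foreground component that survives the
per-channel size filter; for each we record location, area, equivalent-disk
radius, bounding box and circularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class DetectionParams:
    """Size filter and connectivity for particle analysis.

    ``connectivity`` 8 treats diagonal neighbors as connected (the particle
    analyzer convention); 4 uses edge neighbors only.  ``max_size=None``
    leaves the upper bound open.
    """

    min_size: int = 4
    max_size: int | None = None
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.min_size < 0:
            raise ValueError("min_size must be >= 0")
        if self.max_size is not None and self.min_size > self.max_size:
            raise ValueError("min_size must be <= max_size")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class Punctum:
    """One detected object.

    ``centroid_x`` is the column coordinate and ``centroid_y`` the row
    coordinate (0-based, origin top-left).  ``radius`` is the equivalent-disk
    radius ``sqrt(area / pi)``.  ``bbox`` is ``(row0, col0, height, width)``.
    """

    id: int
    channel: str
    centroid_x: float
    centroid_y: float
    area: int
    radius: float
    bbox: tuple[int, int, int, int]
    circularity: float

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("punctum area must be >= 1")


def equivalent_radius(area: float) -> float:
    """Radius of the disk with the given area: ``sqrt(area / pi)``."""
    if area < 1:
        raise ValueError(f"area must be >= 1 pixel, got {area}")
    return math.sqrt(area / math.pi)


def _perimeter_edge_count(mask: np.ndarray) -> int:
    """Perimeter as the number of pixel faces exposed to background."""
    padded = np.pad(mask, 1)
    exposed = 0
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neighbor = np.roll(padded, shift, axis=(0, 1))
        exposed += int(np.count_nonzero(padded & ~neighbor))
    return exposed


def size_filtered_mask(mask: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Mask retaining only the connected components the size filter keeps."""
    mask = np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(2, 2 if params.connectivity == 8 else 1)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1)).astype(int)
    max_size = params.max_size if params.max_size is not None else np.iinfo(np.int64).max
    keep = np.flatnonzero((areas >= params.min_size) & (areas <= max_size)) + 1
    return np.isin(labels, keep)


def detect_puncta(mask: np.ndarray, params: DetectionParams, channel: str) -> list[Punctum]:
    """Extract size-filtered connected components from a binary mask.

    Components are found under ``params.connectivity``; those with area
    outside ``[min_size, max_size]`` are discarded.  Centroid is the mean of
    member pixel coordinates; circularity is ``4*pi*area / perimeter**2``
    with the perimeter estimated by boundary-pixel edge counting, clipped
    to 1.0.  Puncta ids are assigned in label order (top-left first).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if mask.dtype != bool:
        unique = np.unique(mask)
        if not np.all(np.isin(unique, (0, 1))):
            raise ValueError("mask must be binary")
        mask = mask.astype(bool)
    structure = ndimage.generate_binary_structure(2, 2 if params.connectivity == 8 else 1)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return []
    index = np.arange(1, n + 1)
    areas = ndimage.sum_labels(mask, labels, index=index).astype(int)
    centroids = ndimage.center_of_mass(mask, labels, index=index)
    slices = ndimage.find_objects(labels)

    puncta: list[Punctum] = []
    next_id = 0
    max_size = params.max_size if params.max_size is not None else np.inf
    for i, (area, (cy, cx), sl) in enumerate(zip(areas, centroids, slices)):
        if area < params.min_size or area > max_size:
            continue
        local = labels[sl] == (i + 1)
        perimeter = _perimeter_edge_count(local)
        circularity = min(1.0, 4.0 * math.pi * area / perimeter**2) if perimeter else 1.0
        puncta.append(
            Punctum(
                id=next_id,
                channel=channel,
                centroid_x=float(cx),
                centroid_y=float(cy),
                area=int(area),
                radius=equivalent_radius(int(area)),
                bbox=(sl[0].start, sl[1].start, sl[0].stop - sl[0].start, sl[1].stop - sl[1].start),
                circularity=circularity,
            )
        )
        next_id += 1
    return puncta
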