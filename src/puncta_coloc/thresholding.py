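"""Foreground segmentation: fixed/manual cutoffs, recorded thresholds,
Otsu's method, and a statistical z-score object detector.

The statistical detector is an original implementation of component-tree
style spot detection driven by a z-score contrast statistic, following the
parameter semantics used for synapse detection (z-score threshold, object
size bounds, bounding-box fill, width-to-height ratio, estimated noise
standard deviation).  It is not a port of any existing detector and makes
no claim of numerical parity with one.

Convention: a pixel is foreground when its intensity is >= the cutoff, so
cutoff 0 marks every pixel (lower-bound thresholding).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

_RING_STRUCT = ndimage.generate_binary_structure(2, 2)  # 8-connected dilation step


@dataclass(frozen=True)
class ThresholdRecord:
    """One thresholding decision, for reproduction via threshold-from-file."""

    image_name: str
    channel: str
    method: str  # fixed | manual | from_file | otsu | statistical
    value: int | None  # present iff the method yields a single cutoff
    params_digest: str = ""

    def __post_init__(self) -> None:
        if self.method not in ("fixed", "manual", "from_file", "otsu", "statistical"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.value is not None and not (0 <= self.value <= 255):
            raise ValueError(f"threshold value {self.value} out of [0, 255]")


@dataclass(frozen=True)
class SynQuantParams:
    """Parameters of the statistical object detector.

    ``z_score_threshold`` is the minimum contrast z-score for acceptance;
    ``min_object_size``/``max_object_size`` bound object area in pixels;
    ``min_object_fill`` is the minimum area / bounding-box-area ratio;
    ``max_width_height_ratio`` bounds bounding-box elongation;
    ``noise_std`` is the estimated noise standard deviation in intensity
    units, or ``"auto"`` for a robust MAD-based estimate.
    ``z_axis_multiplier`` is carried for configuration parity but unused
    in 2-D analysis.
    """

    z_score_threshold: float = 10.0
    min_object_size: int = 10
    max_object_size: int = 100
    min_object_fill: float = 0.5
    max_width_height_ratio: float = 4.0
    noise_std: float | str = 12.0
    z_axis_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.z_score_threshold <= 0:
            raise ValueError("z_score_threshold must be > 0")
        if self.min_object_size > self.max_object_size:
            raise ValueError("min_object_size must be <= max_object_size")
        if not (0 < self.min_object_fill <= 1):
            raise ValueError("min_object_fill must be in (0, 1]")
        if self.max_width_height_ratio < 1:
            raise ValueError("max_width_height_ratio must be >= 1")
        if isinstance(self.noise_std, str):
            if self.noise_std != "auto":
                raise ValueError("noise_std must be a positive number or 'auto'")
        elif self.noise_std <= 0:
            raise ValueError("noise_std must be > 0")


def apply_fixed_threshold(plane: np.ndarray, cutoff: int) -> np.ndarray:
    """Binary mask of pixels with intensity >= ``cutoff`` (0-255)."""
    plane = np.asarray(plane)
    if not (0 <= cutoff <= 255):
        raise ValueError(f"cutoff {cutoff} out of [0, 255]")
    return plane >= cutoff


def thresholds_from_file(path: str) -> dict[tuple[str, str], int]:
    """Load recorded cutoffs as a ``(image_name, channel) -> value`` mapping.

    Re-running a fixed or manual analysis with this mapping reproduces the
    original masks bit-exactly.
    """
    table = pd.read_csv(path, dtype={"image_name": str, "channel": str})
    required = {"image_name", "channel", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"threshold file {path} missing column(s): {sorted(missing)}")
    keys = list(zip(table["image_name"], table["channel"]))
    dupes = table.loc[pd.Series(keys).duplicated(), ["image_name", "channel"]]
    if len(dupes):
        raise ValueError(f"duplicate (image, channel) rows in {path}: {dupes.values.tolist()}")
    mapping: dict[tuple[str, str], int] = {}
    for (name, channel), value in zip(keys, table["value"]):
        if pd.isna(value):
            continue  # statistical-mode rows carry no single cutoff
        value = int(value)
        if not (0 <= value <= 255):
            raise ValueError(f"threshold {value} for ({name!r}, {channel!r}) out of [0, 255]")
        mapping[(name, channel)] = value
    return mapping


def otsu_threshold(plane: np.ndarray) -> int:
    """Cutoff maximizing between-class variance on the 256-bin histogram.

    Classes are split as ``< cutoff`` vs ``>= cutoff``; the returned value is
    directly usable with :func:`apply_fixed_threshold`.
    """
    plane = np.asarray(plane)
    hist = np.bincount(np.clip(plane, 0, 255).astype(np.intp).ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: plane is constant")
    # For every cutoff t in 1..255 the background class is bins [0, t).
    w0 = np.cumsum(hist)[:-1]              # weight below cutoff t = index + 1
    w1 = total - w0
    levels = np.arange(256, dtype=np.float64)
    cum_mean = np.cumsum(hist * levels)[:-1]
    mu0 = np.divide(cum_mean, w0, out=np.zeros_like(w0), where=w0 > 0)
    mu1 = np.divide(cum_mean[-1] + hist[255] * 255 - cum_mean, w1, out=np.zeros_like(w1), where=w1 > 0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    between[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(between)) + 1


def estimate_noise_std(plane: np.ndarray) -> float:
    """Robust noise scale: 1.4826 x median absolute deviation from the median."""
    plane = np.asarray(plane, dtype=np.float64)
    mad = float(np.median(np.abs(plane - np.median(plane))))
    return 1.4826 * mad


@dataclass
class _Candidate:
    zscore: float
    area: int
    bbox: tuple[int, int, int, int]  # row0, col0, height, width
    local_mask: np.ndarray


def _score_candidate(
    plane_f: np.ndarray, local_mask: np.ndarray, bbox: tuple[int, int, int, int], noise_std: float
) -> float:
    """Contrast z-score of one candidate against its 2-px dilation ring."""
    r0, c0, h, w = bbox
    H, W = plane_f.shape
    pad = 2
    rr0, cc0 = max(r0 - pad, 0), max(c0 - pad, 0)
    rr1, cc1 = min(r0 + h + pad, H), min(c0 + w + pad, W)
    region = np.zeros((rr1 - rr0, cc1 - cc0), dtype=bool)
    region[r0 - rr0 : r0 - rr0 + h, c0 - cc0 : c0 - cc0 + w] = local_mask
    ring = ndimage.binary_dilation(region, structure=_RING_STRUCT, iterations=pad) & ~region
    crop = plane_f[rr0:rr1, cc0:cc1]
    n_in = int(region.sum())
    n_ring = int(ring.sum())
    if n_ring == 0:
        return 0.0
    mean_in = float(crop[region].mean())
    mean_ring = float(crop[ring].mean())
    se = noise_std * np.sqrt(1.0 / n_in + 1.0 / n_ring)
    return (mean_in - mean_ring) / se


def statistical_threshold(
    plane: np.ndarray, params: SynQuantParams
) -> tuple[np.ndarray, list[dict]]:
    """Detect spot objects by statistical contrast against local background.

    Candidate objects are generated by sweeping intensity cutoffs from high
    to low and tracking the connected components of each super-level set
    (component-tree style).  Every candidate that satisfies the geometric
    filters (area within ``[min_object_size, max_object_size]``, bounding-box
    fill >= ``min_object_fill``, bounding-box elongation <=
    ``max_width_height_ratio``) is scored with

        z = (mean_inside - mean_ring) / (noise_std * sqrt(1/n_in + 1/n_ring))

    where the ring is the 2-pixel dilation shell around the candidate.
    Among nested/overlapping candidates the best-scoring one is kept
    (ties broken toward smaller area); accepted objects must reach
    ``z >= z_score_threshold`` and are pairwise disjoint.

    Returns
    -------
    mask, objects
        ``mask`` is the union of accepted objects; ``objects`` is a list of
        dicts with keys ``zscore``, ``area``, ``bbox`` (row0, col0, h, w) and
        ``mask`` (local boolean patch), sorted by descending z-score.
    """
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ValueError("expected a 2-D plane")
    noise_std = (
        estimate_noise_std(plane) if isinstance(params.noise_std, str) else float(params.noise_std)
    )
    if noise_std <= 0:
        noise_std = 1.0  # blank plane; any contrast is infinite otherwise
    plane_f = plane.astype(np.float64)
    plane_u8 = np.clip(plane, 0, 255).astype(np.uint8)

    candidates: list[_Candidate] = []
    seen: set[tuple] = set()
    # Sweep all 256 levels descending; levels above the maximum are empty.
    top = int(plane_u8.max())
    for level in range(top, 0, -1):
        mask = plane_u8 >= level
        labels, n = ndimage.label(mask, structure=_RING_STRUCT)
        if n == 0:
            continue
        areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(
            (areas >= params.min_object_size) & (areas <= params.max_object_size)
        )
        if keep.size == 0:
            continue
        objects = ndimage.find_objects(labels)
        for i in keep:
            sl = objects[i]
            h = sl[0].stop - sl[0].start
            w = sl[1].stop - sl[1].start
            area = int(areas[i])
            if area / (h * w) < params.min_object_fill:
                continue
            if max(h, w) / min(h, w) > params.max_width_height_ratio:
                continue
            local = labels[sl] == (i + 1)
            key = (sl[0].start, sl[1].start, h, w, area, local.tobytes())
            if key in seen:
                continue
            seen.add(key)
            z = _score_candidate(plane_f, local, (sl[0].start, sl[1].start, h, w), noise_std)
            if z >= params.z_score_threshold:
                candidates.append(
                    _Candidate(zscore=z, area=area, bbox=(sl[0].start, sl[1].start, h, w), local_mask=local)
                )

    # Greedy selection by descending z (tie -> smaller area, then position):
    # among nested candidates this keeps exactly the best-scoring one.
    candidates.sort(key=lambda c: (-c.zscore, c.area, c.bbox))
    out_mask = np.zeros(plane.shape, dtype=bool)
    accepted: list[dict] = []
    for cand in candidates:
        r0, c0, h, w = cand.bbox
        window = out_mask[r0 : r0 + h, c0 : c0 + w]
        if np.any(window & cand.local_mask):
            continue  # overlaps an already-accepted (better-scoring) object
        window |= cand.local_mask
        accepted.append(
            {"zscore": cand.zscore, "area": cand.area, "bbox": cand.bbox, "mask": cand.local_mask}
        )
    return out_mask, accepted
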