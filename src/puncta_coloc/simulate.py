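"""Simulated-synapse benchmark generator.

Red/green image pairs are built by pasting small puncta templates at known
anchor positions onto a Gaussian-noise background whose mean and standard
deviation scale with a *noise multiplier*.  Anchors carry one of three
labels: red-only, green-only, or double-labeled ("both" — a red and a green
punctum pasted at the same anchor, emulating a structural synapse).  The
default split is 334 red-only / 333 green-only / 333 both over 1000 anchors,
i.e. 667 red-bearing and 666 green-bearing positions; the default dataset is
20 images at each multiplier in {0.00, 0.25, 0.50, 0.75, 1.00}, 100 pairs in
total.

Because both-labeled anchors share a single top-left anchor point, the
actual red/green overlap of a pasted pair depends on the template shapes
(and amplitude jitter), producing the partial overlaps that keep benchmark
recall and precision realistically below the ceiling.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

DEFAULT_MULTIPLIERS = (0.00, 0.25, 0.50, 0.75, 1.00)


@dataclass(frozen=True)
class SimLayout:
    """Ground-truth anchor positions and labels for one simulated image.

    Anchors are the top-left corners of the pasted template bounding boxes,
    0-based (row, col).  Labels are ``red_only``, ``green_only`` or ``both``.
    """

    positions: tuple[tuple[int, int], ...]
    labels: tuple[str, ...]
    image_shape: tuple[int, int]
    seed: int

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.labels):
            raise ValueError("positions and labels must align")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("anchor positions must be distinct")

    @property
    def counts(self) -> tuple[int, int, int]:
        """(n_red_only, n_green_only, n_both)."""
        return (
            sum(1 for l in self.labels if l == "red_only"),
            sum(1 for l in self.labels if l == "green_only"),
            sum(1 for l in self.labels if l == "both"),
        )

    def anchors_with(self, channel: str) -> list[tuple[int, int]]:
        """Anchors bearing a punctum in the given channel ('red'/'green')."""
        wanted = {"red": ("red_only", "both"), "green": ("green_only", "both")}[channel]
        return [p for p, l in zip(self.positions, self.labels) if l in wanted]


def gaussian_template(amplitude: float = 180.0, sigma: float = 1.5, support: int = 9) -> np.ndarray:
    """Isotropic Gaussian spot template on a square support, peak at center."""
    half = (support - 1) / 2.0
    r = np.arange(support) - half
    g = np.exp(-(r[:, None] ** 2 + r[None, :] ** 2) / (2.0 * sigma**2))
    return amplitude * g


@dataclass
class SimParams:
    """Benchmark generation settings.

    ``base_mean``/``base_std`` are the background Gaussian parameters before
    multiplication by the noise multiplier; the pasted spot is a parametric
    isotropic Gaussian (``template_amplitude`` at peak, ``template_sigma``
    px, square ``template_support``) with per-paste amplitude jitter of
    ``amplitude_jitter`` (fractional, both channels independently), or a
    user-supplied template bank for parity with template-from-image
    workflows.
    """

    noise_multipliers: tuple[float, ...] = DEFAULT_MULTIPLIERS
    images_per_level: int = 20
    base_mean: float = 30.0
    base_std: float = 12.0
    image_shape: tuple[int, int] = (512, 512)
    n_red_only: int = 334
    n_green_only: int = 333
    n_both: int = 333
    template_amplitude: float = 180.0
    template_sigma: float = 1.5
    template_support: int = 9
    amplitude_jitter: float = 0.2
    template_bank: list[np.ndarray] | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.noise_multipliers):
            raise ValueError("noise multipliers must be >= 0")
        if self.images_per_level < 1:
            raise ValueError("images_per_level must be >= 1")
        if self.template_bank is not None and not self.template_bank:
            raise ValueError("template_bank must be non-empty when given")

    def template_shape(self) -> tuple[int, int]:
        if self.template_bank is not None:
            h = max(t.shape[0] for t in self.template_bank)
            w = max(t.shape[1] for t in self.template_bank)
            return (h, w)
        return (self.template_support, self.template_support)


@dataclass
class SimImage:
    """One rendered simulated pair with its ground truth."""

    red: np.ndarray
    green: np.ndarray
    layout: SimLayout
    multiplier: float

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row": [p[0] for p in self.layout.positions],
                "col": [p[1] for p in self.layout.positions],
                "label": list(self.layout.labels),
            }
        )


def make_layout(
    n_red_only: int,
    n_green_only: int,
    n_both: int,
    image_shape: tuple[int, int],
    seed: int,
    template_shape: tuple[int, int] = (9, 9),
    max_tries_factor: int = 200,
) -> SimLayout:
    """Draw distinct non-colliding anchors and assign labels by shuffling.

    Anchors are sampled uniformly over positions that keep the template
    inside the image; a candidate is rejected when its bounding box would
    overlap an already-placed box.  Label assignment shuffles the anchor
    list, so label classes are spatially interchangeable.  Deterministic in
    ``seed``.
    """
    if min(n_red_only, n_green_only, n_both) < 0:
        raise ValueError("counts must be >= 0")
    total = n_red_only + n_green_only + n_both
    th, tw = template_shape
    h, w = image_shape
    if th > h or tw > w:
        raise ValueError("template larger than image")
    rng = np.random.default_rng(seed)
    max_row, max_col = h - th, w - tw

    # Coarse grid bucketing: boxes overlap iff |dr| < th and |dc| < tw.
    buckets: dict[tuple[int, int], list[tuple[int, int]]] = {}
    placed: list[tuple[int, int]] = []
    tries = 0
    max_tries = max_tries_factor * max(total, 1)
    while len(placed) < total:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {total} non-colliding {th}x{tw} boxes on a "
                f"{h}x{w} image after {max_tries} tries"
            )
        tries += 1
        r = int(rng.integers(0, max_row + 1))
        c = int(rng.integers(0, max_col + 1))
        cell = (r // th, c // tw)
        collides = False
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                for (pr, pc) in buckets.get((cell[0] + dr, cell[1] + dc), ()):
                    if abs(pr - r) < th and abs(pc - c) < tw:
                        collides = True
                        break
                if collides:
                    break
            if collides:
                break
        if collides:
            continue
        placed.append((r, c))
        buckets.setdefault(cell, []).append((r, c))

    labels = ["red_only"] * n_red_only + ["green_only"] * n_green_only + ["both"] * n_both
    order = rng.permutation(total)
    labels = [labels[i] for i in order]
    return SimLayout(
        positions=tuple(placed), labels=tuple(labels), image_shape=(h, w), seed=seed
    )


def _paste(plane: np.ndarray, template: np.ndarray, anchor: tuple[int, int]) -> None:
    r, c = anchor
    th, tw = template.shape
    window = plane[r : r + th, c : c + tw]
    np.maximum(window, template, out=window)


def render_sim_pair(
    layout: SimLayout, params: SimParams, multiplier: float, rng: np.random.Generator
) -> SimImage:
    """Render one red/green image pair for the given noise multiplier.

    Background pixels are drawn from Normal(base_mean * m, base_std * m),
    rounded half-to-even and clipped to [0, 255]; at m = 0 every
    non-punctum pixel is exactly 0.  Templates are combined with the
    background by per-pixel maximum so spots are never dimmed by noise.
    """
    if multiplier < 0:
        raise ValueError("multiplier must be >= 0")
    h, w = layout.image_shape
    th, tw = params.template_shape()
    if th > h or tw > w:
        raise ValueError("template larger than image")

    planes: dict[str, np.ndarray] = {}
    for channel in ("red", "green"):
        if multiplier == 0:
            plane = np.zeros((h, w), dtype=np.float64)
        else:
            noise = rng.normal(params.base_mean * multiplier, params.base_std * multiplier, (h, w))
            plane = np.clip(np.rint(noise), 0, 255)
        for anchor in layout.anchors_with(channel):
            if params.template_bank is not None:
                template = params.template_bank[int(rng.integers(len(params.template_bank)))]
            else:
                jitter = 1.0 + params.amplitude_jitter * float(rng.uniform(-1.0, 1.0))
                template = gaussian_template(
                    params.template_amplitude * jitter, params.template_sigma, params.template_support
                )
            _paste(plane, np.clip(np.rint(template), 0, 255), anchor)
        planes[channel] = plane.astype(np.uint8)
    return SimImage(red=planes["red"], green=planes["green"], layout=layout, multiplier=multiplier)


def generate_dataset(params: SimParams, out_dir: str) -> pd.DataFrame:
    """Write the full benchmark dataset and return its manifest.

    Emits ``images_per_level`` pairs per multiplier (default 20 x 5 = 100),
    each as a 2-channel TIFF (page 0 = red, page 1 = green) plus a
    ground-truth CSV, with per-image seeds derived from ``master_seed``.
    The manifest records file names, multipliers, seeds and the fraction of
    double-labeled anchors (overlap pressure) per image.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    counter = 0
    for multiplier in params.noise_multipliers:
        for i in range(params.images_per_level):
            seed = int((params.master_seed + 1) * 100_000 + counter) % (2**31)
            layout = make_layout(
                params.n_red_only,
                params.n_green_only,
                params.n_both,
                params.image_shape,
                seed=seed,
                template_shape=params.template_shape(),
            )
            rng = np.random.default_rng(seed + 1)
            sim = render_sim_pair(layout, params, multiplier, rng)
            stem = f"sim_m{multiplier:.2f}_{i:03d}"
            image_path = os.path.join(out_dir, f"{stem}.tif")
            tifffile.imwrite(image_path, np.stack([sim.red, sim.green]), photometric="minisblack")
            truth_path = os.path.join(out_dir, f"{stem}_truth.csv")
            sim.truth_frame().to_csv(truth_path, index=False, lineterminator="\n")
            n_both = sim.layout.counts[2]
            rows.append(
                {
                    "image": f"{stem}.tif",
                    "truth": f"{stem}_truth.csv",
                    "multiplier": multiplier,
                    "seed": seed,
                    "n_anchors": len(layout.positions),
                    "frac_double_labeled": n_both / len(layout.positions) if layout.positions else 0.0,
                }
            )
            counter += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False, lineterminator="\n")
    return manifest
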