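"""End-to-end benchmark: simulate, analyze, and score in one call.

Renders the parametric simulated-synapse dataset in memory, tunes one fixed
per-channel threshold on a zero-noise image (Otsu on the 256-bin
histogram), analyzes every image with that fixed threshold, and scores the
detected colocalizations against the known double-labeled positions.
"""

from __future__ import annotations

import numpy as np

from puncta_coloc.colocalize import coloc_pixel
from puncta_coloc.evaluate import (
    EvalResult,
    compute_metrics,
    default_tolerance,
    evaluate_dataset,
    match_detections,
)
from puncta_coloc.puncta_detect import DetectionParams, size_filtered_mask
from puncta_coloc.simulate import SimLayout, SimParams, make_layout, render_sim_pair
from puncta_coloc.thresholding import apply_fixed_threshold, otsu_threshold


def _image_seed(master_seed: int, index: int) -> int:
    return int((master_seed + 1) * 100_000 + index) % (2**31)


def tune_fixed_thresholds(params: SimParams) -> dict[str, int]:
    """Per-channel Otsu cutoffs from one zero-noise rendered image."""
    seed = _image_seed(params.master_seed, 0)
    layout = make_layout(
        params.n_red_only, params.n_green_only, params.n_both,
        params.image_shape, seed=seed, template_shape=params.template_shape(),
    )
    sim = render_sim_pair(layout, params, 0.0, np.random.default_rng(seed + 1))
    return {"red": otsu_threshold(sim.red), "green": otsu_threshold(sim.green)}


def analyze_sim_image(
    red: np.ndarray,
    green: np.ndarray,
    layout: SimLayout,
    multiplier: float,
    cutoffs: dict[str, int],
    params: SimParams,
    detection: DetectionParams | None = None,
    image_name: str = "",
) -> EvalResult:
    """Fixed-threshold pixel-mode analysis of one simulated pair, scored
    against the double-labeled ground truth."""
    detection = detection or DetectionParams()
    masks = {
        "red": size_filtered_mask(apply_fixed_threshold(red, cutoffs["red"]), detection),
        "green": size_filtered_mask(apply_fixed_threshold(green, cutoffs["green"]), detection),
    }
    _, colocs = coloc_pixel(masks["red"], masks["green"])
    detected = [(c.centroid_x, c.centroid_y) for c in colocs]
    th, tw = params.template_shape()
    half_r, half_c = (th - 1) / 2.0, (tw - 1) / 2.0
    truth = [
        (c + half_c, r + half_r)
        for (r, c), label in zip(layout.positions, layout.labels)
        if label == "both"
    ]
    tolerance = default_tolerance(params.template_shape())
    tp, fp, fn = match_detections(detected, truth, tolerance)
    return compute_metrics(tp, fp, fn, multiplier=multiplier, image_name=image_name,
                           match_tolerance=tolerance)


def run_benchmark(params: SimParams | None = None):
    """Simulate, analyze and score the full parametric dataset in memory.

    Returns ``(per_image_table, per_level_table, cutoffs)`` where the level
    table carries mean and standard error of recall and precision at each
    noise multiplier.
    """
    params = params or SimParams()
    cutoffs = tune_fixed_thresholds(params)
    results = []
    index = 0
    for multiplier in params.noise_multipliers:
        for i in range(params.images_per_level):
            seed = _image_seed(params.master_seed, index)
            layout = make_layout(
                params.n_red_only, params.n_green_only, params.n_both,
                params.image_shape, seed=seed, template_shape=params.template_shape(),
            )
            sim = render_sim_pair(layout, params, multiplier, np.random.default_rng(seed + 1))
            results.append(
                analyze_sim_image(sim.red, sim.green, layout, multiplier, cutoffs, params,
                                  image_name=f"sim_m{multiplier:.2f}_{i:03d}")
            )
            index += 1
    per_image, per_level = evaluate_dataset(results)
    return per_image, per_level, cutoffs
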