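"""Recall/precision scoring of detected colocalizations against ground truth.

A detected colocalization is a true positive when it can be matched
one-to-one to a double-labeled ("both") truth position within a distance
tolerance; unmatched detections are false positives and unmatched truths
false negatives.  Recall = TP/(TP+FN), precision = TP/(TP+FP) — the natural
metrics here because true negatives (every empty location) are not well
defined for spot detection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalResult:
    """TP/FP/FN counts with recall and precision for one image."""

    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    multiplier: float = float("nan")
    image_name: str = ""
    match_tolerance: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be >= 0")


def match_detections(
    detected: Sequence[tuple[float, float]],
    truth: Sequence[tuple[float, float]],
    tolerance: float,
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detections to truth centers.

    Candidate pairs within ``tolerance`` are matched in ascending distance
    order (ties broken by detection index, then truth index); a detection
    matches at most one truth and vice versa.  Matched pairs are TP,
    unmatched detections FP, unmatched truths FN.

    ``detected`` and ``truth`` are sequences of (x, y) centers in pixels.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    if not detected or not truth:
        return 0, len(detected), len(truth)
    det = np.asarray(detected, dtype=np.float64)
    tru = np.asarray(truth, dtype=np.float64)
    dists = np.hypot(det[:, None, 0] - tru[None, :, 0], det[:, None, 1] - tru[None, :, 1])
    pairs = [
        (dists[i, j], i, j)
        for i in range(det.shape[0])
        for j in range(tru.shape[0])
        if dists[i, j] <= tolerance
    ]
    pairs.sort()
    used_det: set[int] = set()
    used_tru: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_det or j in used_tru:
            continue
        used_det.add(i)
        used_tru.add(j)
        tp += 1
    return tp, det.shape[0] - tp, tru.shape[0] - tp


def compute_metrics(
    tp: int,
    fp: int,
    fn: int,
    multiplier: float = float("nan"),
    image_name: str = "",
    match_tolerance: float = float("nan"),
) -> EvalResult:
    """Recall and precision from counts; 0 when a denominator is 0 (logged)."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be >= 0")
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall = 0.0
        logger.warning("no truth positives for %s; recall defined as 0", image_name or "<image>")
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision = 0.0
        logger.warning("no detections for %s; precision defined as 0", image_name or "<image>")
    return EvalResult(
        tp=tp, fp=fp, fn=fn, recall=recall, precision=precision,
        multiplier=multiplier, image_name=image_name, match_tolerance=match_tolerance,
    )


def default_tolerance(template_shape: tuple[int, int] = (9, 9)) -> float:
    """Template half-diagonal: any detection inside the pasted footprint
    counts as a hit (about 6.4 px for the default 9x9 template)."""
    return math.hypot(template_shape[0], template_shape[1]) / 2.0


def truth_centers(
    truth: pd.DataFrame, template_shape: tuple[int, int] = (9, 9)
) -> list[tuple[float, float]]:
    """Centers of double-labeled truth positions as (x, y).

    Truth tables store top-left anchors; the center is the anchor plus the
    template half-extent.
    """
    both = truth[truth["label"] == "both"]
    half_r = (template_shape[0] - 1) / 2.0
    half_c = (template_shape[1] - 1) / 2.0
    return [(float(c) + half_c, float(r) + half_r) for r, c in zip(both["row"], both["col"])]


def evaluate_dataset(
    per_image: Sequence[EvalResult],
    plot_path: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-image results into per-image and per-multiplier tables.

    Returns ``(per_image_table, per_level_table)``; the per-level table
    carries mean and standard error of recall and precision over the images
    at each noise multiplier.  When ``plot_path`` is given, a
    recall/precision-vs-multiplier figure is written there.
    """
    if not per_image:
        raise ValueError("no evaluation results")
    table = pd.DataFrame(
        [
            {
                "image": r.image_name,
                "multiplier": r.multiplier,
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
                "recall": r.recall,
                "precision": r.precision,
            }
            for r in per_image
        ]
    )

    def sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0

    levels = (
        table.groupby("multiplier", sort=True)
        .agg(
            n_images=("image", "size"),
            recall_mean=("recall", "mean"),
            recall_sem=("recall", sem),
            precision_mean=("precision", "mean"),
            precision_sem=("precision", sem),
        )
        .reset_index()
    )
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.errorbar(levels["multiplier"], levels["recall_mean"], yerr=levels["recall_sem"],
                    marker="o", label="recall")
        ax.errorbar(levels["multiplier"], levels["precision_mean"], yerr=levels["precision_sem"],
                    marker="s", label="precision")
        ax.set_xlabel("noise multiplier")
        ax.set_ylabel("metric")
        ax.set_ylim(0, 1.05)
        ax.legend()
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return table, levels
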