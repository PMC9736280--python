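"""Evaluation metrics for segmentation overlap and frame-level detection.

Segmentation quality is measured by the Dice score between two binary masks
X = (x_ij) and Y = (y_ij),

    Dice(X, Y) = 2 Σ x_ij y_ij / (Σ x_ij + Σ y_ij),

and the Jaccard score |X∩Y| / |X∪Y| (related by J = D / (2 − D)).

Frame-level aspiration detection uses a confusion matrix over frames: a
frame counts as a true positive whenever aspiration was segmented and its
Dice overlap with the reference is greater than 0.  Precision, recall and
F1 = 2TP / (2TP + FP + FN) summarize the counts.  A Spearman rank
correlation between reference bolus size (pixels) and Dice score probes
whether larger boluses are detected more easily.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "FrameOutcome",
    "ConfusionCounts",
    "DetectionMetrics",
    "CorrelationResult",
    "dice",
    "jaccard",
    "classify_frame",
    "confusion_matrix",
    "detection_metrics",
    "fp_glottis_frame_rate",
    "spearman_size_dice",
]


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    return x, y


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Dice overlap of two binary masks; both-empty is scored 1.0.

    An empty structure that is correctly predicted empty is a perfect
    segmentation; frame-level emptiness is judged separately by
    :func:`classify_frame` and :func:`fp_glottis_frame_rate`.
    """
    x, y = _check_pair(x, y)
    total = int(x.sum()) + int(y.sum())
    if total == 0:
        return 1.0
    return 2.0 * int(np.logical_and(x, y).sum()) / total


def jaccard(x: np.ndarray, y: np.ndarray) -> float:
    """Jaccard (intersection over union) of two binary masks; both-empty → 1.0."""
    x, y = _check_pair(x, y)
    union = int(np.logical_or(x, y).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(x, y).sum()) / union


class FrameOutcome(enum.Enum):
    """Frame-level aspiration-detection outcome.

    ``MISMATCH`` covers a prediction and a reference that are both nonempty
    but do not overlap at all: the detector missed the true bolus *and*
    raised a spurious one, so it tallies as one FP and one FN.
    """

    TP = "TP"
    FP = "FP"
    FN = "FN"
    TN = "TN"
    MISMATCH = "FP+FN"


def classify_frame(
    pred_aspiration: np.ndarray,
    ref_aspiration: np.ndarray | None,
) -> FrameOutcome:
    """Classify one frame's aspiration detection.

    ``ref_aspiration is None`` (or an empty mask) means the frame is
    annotated aspiration-free.  A frame is a true positive whenever
    aspiration was segmented and the Dice overlap with the reference is
    greater than 0.
    """
    pred = np.asarray(pred_aspiration, dtype=bool)
    ref_present = ref_aspiration is not None and bool(np.asarray(ref_aspiration).any())
    pred_present = bool(pred.any())
    if ref_present:
        if not pred_present:
            return FrameOutcome.FN
        if dice(pred, np.asarray(ref_aspiration, dtype=bool)) > 0:
            return FrameOutcome.TP
        return FrameOutcome.MISMATCH
    return FrameOutcome.FP if pred_present else FrameOutcome.TN


@dataclass
class ConfusionCounts:
    """Frame-level TP/FP/FN/TN counts for aspiration detection.

    ``mismatches`` audits frames counted as both FP and FN (nonempty
    prediction with zero reference overlap), so
    ``tp + fp + fn + tn == n_frames + mismatches``.
    """

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    mismatches: int = 0
    n_frames: int = 0

    def as_matrix(self) -> np.ndarray:
        """2×2 matrix [[TN, FP], [FN, TP]] (true label × predicted label)."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


def confusion_matrix(outcomes: Iterable[FrameOutcome]) -> ConfusionCounts:
    """Tally frame outcomes; order-independent."""
    c = ConfusionCounts()
    for o in outcomes:
        c.n_frames += 1
        if o is FrameOutcome.TP:
            c.tp += 1
        elif o is FrameOutcome.FP:
            c.fp += 1
        elif o is FrameOutcome.FN:
            c.fn += 1
        elif o is FrameOutcome.TN:
            c.tn += 1
        else:
            c.fp += 1
            c.fn += 1
            c.mismatches += 1
    return c


@dataclass
class DetectionMetrics:
    """Precision, recall and F1; ``None`` flags an undefined ratio (0/0)."""

    precision: float | None
    recall: float | None
    f1: float | None


def detection_metrics(c: ConfusionCounts) -> DetectionMetrics:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN)."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    denom = 2 * c.tp + c.fp + c.fn
    f1 = 2 * c.tp / denom if denom > 0 else None
    return DetectionMetrics(precision=precision, recall=recall, f1=f1)


def fp_glottis_frame_rate(
    glottis_masks: Sequence[np.ndarray],
    glottis_visible: Sequence[bool] | None = None,
    min_pixels: int = 1,
) -> float:
    """Fraction of glottis-absent frames with a falsely segmented glottis.

    Every input frame must be labeled as not containing the glottis; a frame
    counts as false-positive when its final glottis mask has at least
    ``min_pixels`` pixels (the strictest reading, any-pixel, is the default).
    """
    masks = list(glottis_masks)
    if glottis_visible is not None:
        for vis in glottis_visible:
            if vis:
                raise ValueError(
                    "fp_glottis_frame_rate expects only frames labeled glottis-absent"
                )
    if not masks:
        raise ValueError("no frames given")
    n_fp = sum(1 for m in masks if int(np.asarray(m, dtype=bool).sum()) >= min_pixels)
    return n_fp / len(masks)


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def spearman_size_dice(pairs: Sequence[tuple[float, float]]) -> CorrelationResult:
    """Spearman rank correlation of reference bolus size vs Dice score.

    Average-rank tie handling, two-sided p-value; requires at least 3 pairs.
    """
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(pairs)}")
    sizes, dices = zip(*pairs)
    res = stats.spearmanr(sizes, dices)
    return CorrelationResult(rho=float(res.statistic), p_value=float(res.pvalue), n=len(pairs))


# ---------------------------------------------------------------------------
# Report export


def export_report(
    per_frame: "pd.DataFrame",
    counts: ConfusionCounts,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the per-frame metrics table (CSV) and summary (JSON) to a directory."""
    import pandas as pd  # local: keep the metric functions importable without pandas

    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    csv_path = d / "per_frame_metrics.csv"
    pd.DataFrame(per_frame).to_csv(csv_path, index=False)
    m = detection_metrics(counts)
    summary = {
        "confusion": {k: getattr(counts, k) for k in ("tp", "fp", "fn", "tn", "mismatches", "n_frames")},
        "precision": m.precision,
        "recall": m.recall,
        "f1": m.f1,
    }
    json_path = d / "detection_summary.json"
    json_path.write_text(json.dumps(summary, indent=2))
    return {"csv": csv_path, "json": json_path}


def plot_confusion_heatmap(counts: ConfusionCounts, path: str | Path) -> Path:
    """Render the 2×2 frame-level confusion matrix as a heat map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = counts.as_matrix()
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(mat, cmap="Blues")
    for (i, j), v in np.ndenumerate(mat):
        ax.text(j, i, str(v), ha="center", va="center",
                color="white" if v > mat.max() / 2 else "black")
    ax.set_xticks([0, 1], ["0", "1"])
    ax.set_yticks([0, 1], ["0", "1"])
    ax.set_xlabel("predicted label")
    ax.set_ylabel("true label")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return p


def plot_dice_boxplot(scores_by_class: dict[str, Sequence[float]], path: str | Path) -> Path:
    """Boxplot of per-frame Dice scores per structure class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    labels = list(scores_by_class)
    ax.boxplot([list(scores_by_class[k]) for k in labels], tick_labels=labels)
    ax.set_ylabel("Dice score")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return p


def plot_size_dice_scatter(pairs: Sequence[tuple[float, float]], path: str | Path) -> Path:
    """Scatter of reference bolus size (pixels) against Dice score."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sizes, dices = zip(*pairs) if pairs else ((), ())
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(sizes, dices, s=12, alpha=0.7)
    ax.set_xlabel("reference aspiration size (pixels)")
    ax.set_ylabel("Dice score")
    fig.tight_layout()
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(p, dpi=120)
    plt.close(fig)
    return p
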