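"""Published summary statistics of the original FEES study corpus.

The clinical corpus itself (92 patient videos) is private; what is public is
its summary arithmetic: how the videos were split, how annotated frames were
distributed over the splits, and the frame-level aspiration-detection
confusion counts per split.  These numbers serve as worked-example inputs
for the metrics module and as consistency checks for the splitting logic.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "N_VIDEOS",
    "SPLIT_FRACTIONS",
    "SPLIT_VIDEO_COUNTS",
    "BOLUS_TYPE_VIDEO_COUNTS",
    "frame_distribution",
    "detection_counts",
]

#: Total number of patient videos in the study corpus.
N_VIDEOS = 92

#: Realized split fractions (train, validation, test) of the 92 videos.
SPLIT_FRACTIONS = (0.772, 0.065, 0.163)

#: Realized video counts per split.
SPLIT_VIDEO_COUNTS = {"train": 71, "validation": 6, "test": 15}

#: Among the 50 aspiration videos: bolus-type distribution.
BOLUS_TYPE_VIDEO_COUNTS = {"slurry": 21, "saliva": 18, "liquid": 11}

#: Annotated-frame distribution per split: fully segmented frames, the subset
#: of those showing aspiration, and frames carrying only the frame-level
#: "glottis not visible" label.
_FRAME_DISTRIBUTION = {
    "train": {"segmented": 1029, "with_aspiration": 424, "not_showing_glottis": 2220},
    "validation": {"segmented": 103, "with_aspiration": 17, "not_showing_glottis": 186},
    "test": {"segmented": 199, "with_aspiration": 63, "not_showing_glottis": 489},
}

#: Frame-level aspiration-detection confusion counts per split.  These integer
#: counts reproduce the published precision/recall/F1 of each split to three
#: decimals (TP+FN equals the split's frames-with-aspiration for validation
#: and test); the raw training counts were not published, so the training
#: triple is the smallest one consistent with all three printed metrics.
_DETECTION_COUNTS = {
    "train": {"tp": 211, "fp": 10, "fn": 24},
    "validation": {"tp": 10, "fp": 10, "fn": 7},
    "test": {"tp": 36, "fp": 15, "fn": 27},
}


def frame_distribution() -> pd.DataFrame:
    """Annotated-frame counts per split as a DataFrame (rows: splits)."""
    return pd.DataFrame(_FRAME_DISTRIBUTION).T


def detection_counts(split: str) -> dict[str, int]:
    """Aspiration-detection TP/FP/FN frame counts for one split."""
    return dict(_DETECTION_COUNTS[split])
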