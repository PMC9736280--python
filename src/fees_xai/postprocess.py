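"""Post-processing of soft segmentation maps into final binary masks.

The pipeline is: threshold each class map, keep only the largest connected
component of the glottis ROI, then restrict the vocal-cord and aspiration
masks to that component — the anatomical prior that both structures only
exist relative to the glottis suppresses isolated false positives elsewhere
in the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SegmentationResult",
    "binarize",
    "largest_connected_component",
    "restrict_to_roi",
    "postprocess_frame",
]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class SegmentationResult:
    """Final per-frame masks after post-processing, with pixel counts."""

    glottis_roi: np.ndarray
    vocal_cords: np.ndarray
    aspiration: np.ndarray
    pixel_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pixel_counts:
            self.pixel_counts = {
                "glottis_roi": int(np.asarray(self.glottis_roi, dtype=bool).sum()),
                "vocal_cords": int(np.asarray(self.vocal_cords, dtype=bool).sum()),
                "aspiration": int(np.asarray(self.aspiration, dtype=bool).sum()),
            }


def binarize(maps: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold soft maps (pixel ≥ threshold → 1), preserving the class axis."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return np.asarray(maps) >= threshold


def largest_connected_component(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Keep only the largest connected component of a binary mask.

    Empty input stays empty.  Ties between equal-size components are broken
    deterministically: the component containing the first foreground pixel
    in row-major scan order wins.
    """
    mask = np.asarray(mask, dtype=bool)
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    if not mask.any():
        return np.zeros_like(mask)
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 1:
        return mask.copy()
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        flat = labels.ravel()
        first_idx = {lab: np.flatnonzero(flat == lab)[0] for lab in candidates}
        keep = min(candidates, key=lambda lab: first_idx[lab])
    return labels == keep


def restrict_to_roi(roi_mask: np.ndarray, class_mask: np.ndarray) -> np.ndarray:
    """Pixelwise AND of a class mask with the ROI mask."""
    roi = np.asarray(roi_mask, dtype=bool)
    cls = np.asarray(class_mask, dtype=bool)
    if roi.shape != cls.shape:
        raise ValueError(f"mask shapes differ: {roi.shape} vs {cls.shape}")
    return np.logical_and(roi, cls)


def postprocess_frame(
    maps: np.ndarray,
    threshold: float = 0.5,
    connectivity: int = 8,
) -> SegmentationResult:
    """Binarize 3×H×W class maps and apply the ROI-constrained cleanup.

    Class order is (glottis ROI, vocal cords, aspiration).  The restriction
    uses the glottis mask *after* largest-component selection, so the final
    vocal-cord and aspiration masks are subsets of a single glottis blob.
    """
    maps = np.asarray(maps)
    if maps.ndim != 3 or maps.shape[0] != 3:
        raise ValueError(f"expected 3×H×W probability maps, got shape {maps.shape}")
    hard = binarize(maps, threshold)
    glottis = largest_connected_component(hard[0], connectivity)
    cords = restrict_to_roi(glottis, hard[1])
    aspiration = restrict_to_roi(glottis, hard[2])
    return SegmentationResult(glottis_roi=glottis, vocal_cords=cords, aspiration=aspiration)
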