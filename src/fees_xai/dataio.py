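"""Data model and I/O for endoscopic swallowing-video datasets.

The unit of ground truth is a video frame together with a
:class:`ReferenceAnnotation`: one binary mask per annotated structure
(glottis region of interest, vocal cords, aspirated bolus), a frame-level
"glottis visible" label, the glottis state, and the bolus type.  Masks are
stored as one PNG per class (classes overlap — the aspiration always lies
inside the glottis ROI — so a single label map cannot represent them),
videos as lossless multipage TIFF stacks or directories of PNG frames, and
dataset indices as JSON lines.

Coordinates are row-major and 0-based: pixel ``(i, j)`` is (row, column).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "GLOTTIS_STATES",
    "BOLUS_TYPES",
    "SPLITS",
    "FrameImage",
    "ReferenceAnnotation",
    "IndexRecord",
    "DatasetIndex",
    "ValidationError",
    "read_video",
    "write_video",
    "read_mask",
    "write_mask",
    "read_annotation",
    "write_annotation",
    "split_dataset",
]

GLOTTIS_STATES = ("open", "closed", "obscured", "unknown")
BOLUS_TYPES = ("slurry", "saliva", "liquid", "none")
SPLITS = ("train", "validation", "test")

MASK_NAMES = ("glottis_roi", "vocal_cords", "aspiration")


class ValidationError(ValueError):
    """An annotation or index violates a structural invariant."""


@dataclass
class FrameImage:
    """One video frame: an H×W×3 raster of 8-bit intensities."""

    pixels: np.ndarray
    video_id: str = ""
    frame_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = np.stack([px] * 3, axis=-1)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(f"frame pixels must be H×W×3, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("frame must have positive height and width")
        if self.frame_index < 0:
            raise ValidationError("frame_index must be non-negative")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _as_bool_mask(mask: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1, 255))):
            raise ValidationError(
                f"{name} mask is not binary (values {vals[:8].tolist()}...)"
                if len(vals) > 8
                else f"{name} mask is not binary (values {vals.tolist()})"
            )
        m = m > 0
    return m


@dataclass
class ReferenceAnnotation:
    """Ground truth for one frame: per-class masks plus frame-level labels.

    ``glottis_visible=False`` means the glottis does not appear in the frame
    at all, in which case every structural mask must be empty (the vocal
    cords and any aspiration are only annotated relative to the glottis ROI).
    """

    glottis_roi: np.ndarray
    vocal_cords: np.ndarray
    aspiration: np.ndarray
    glottis_visible: bool = True
    glottis_state: str = "unknown"
    bolus_type: str = "none"

    def __post_init__(self) -> None:
        self.glottis_roi = _as_bool_mask(self.glottis_roi, "glottis_roi")
        self.vocal_cords = _as_bool_mask(self.vocal_cords, "vocal_cords")
        self.aspiration = _as_bool_mask(self.aspiration, "aspiration")
        shapes = {m.shape for m in (self.glottis_roi, self.vocal_cords, self.aspiration)}
        if len(shapes) != 1:
            raise ValidationError(f"mask shapes differ across classes: {shapes}")
        if self.glottis_state not in GLOTTIS_STATES:
            raise ValidationError(f"glottis_state must be one of {GLOTTIS_STATES}")
        if self.bolus_type not in BOLUS_TYPES:
            raise ValidationError(f"bolus_type must be one of {BOLUS_TYPES}")
        if not self.glottis_visible and self.glottis_roi.any():
            raise ValidationError("glottis_visible=False but glottis_roi mask is nonempty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.glottis_roi.shape

    def masks(self) -> dict[str, np.ndarray]:
        return {
            "glottis_roi": self.glottis_roi,
            "vocal_cords": self.vocal_cords,
            "aspiration": self.aspiration,
        }

    def stacked(self) -> np.ndarray:
        """Masks as a 3×H×W float array in class order (ROI, cords, aspiration)."""
        return np.stack([self.glottis_roi, self.vocal_cords, self.aspiration]).astype(np.float32)


@dataclass
class IndexRecord:
    video_id: str
    frame_index: int
    annotation_path: str | None = None  # None ⇒ frame-label-only record
    glottis_visible: bool = True
    bolus_type: str = "none"
    split: str = "train"

    def __post_init__(self) -> None:
        if self.split not in SPLITS:
            raise ValidationError(f"split must be one of {SPLITS}")


@dataclass
class DatasetIndex:
    """Flat index of annotated frames with a per-video split assignment.

    Splitting is by ``video_id``: frames of one video are correlated, so a
    video never contributes frames to two splits.
    """

    records: list[IndexRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.check_disjoint()

    def check_disjoint(self) -> None:
        seen: dict[str, str] = {}
        for r in self.records:
            prev = seen.setdefault(r.video_id, r.split)
            if prev != r.split:
                raise ValidationError(
                    f"video {r.video_id!r} assigned to both {prev!r} and {r.split!r}"
                )

    def subset(self, split: str) -> list[IndexRecord]:
        return [r for r in self.records if r.split == split]

    def video_ids(self, split: str | None = None) -> list[str]:
        recs = self.records if split is None else self.subset(split)
        out: list[str] = []
        for r in recs:
            if r.video_id not in out:
                out.append(r.video_id)
        return out

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps(vars(r)) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "DatasetIndex":
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(IndexRecord(**json.loads(line)))
        return cls(records)


# ---------------------------------------------------------------------------
# Video I/O


def _is_frame_dir(path: Path) -> bool:
    return path.is_dir() or path.suffix == ""


def read_video(path: str | Path) -> list[FrameImage]:
    """Read a video as a list of frames in temporal order (0-based indices).

    Accepts a multipage TIFF stack or a directory of per-frame PNGs named
    ``frame_<index>.png``.
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"video not found: {p}")
    if _is_frame_dir(p):
        files = sorted(p.glob("frame_*.png"))
        if not files:
            raise IOError(f"no frames found in directory {p}")
        stack = [iio.imread(f) for f in files]
    else:
        try:
            arr = tifffile.imread(p)
        except Exception as exc:  # noqa: BLE001 - normalize to IOError per contract
            raise IOError(f"unreadable video file {p}: {exc}") from exc
        if arr.ndim == 3 and arr.shape[-1] == 3:
            arr = arr[None]
        if arr.ndim != 4 or arr.shape[0] == 0:
            raise IOError(f"video file {p} contains no frames")
        stack = list(arr)
    vid = p.stem if p.suffix else p.name
    return [FrameImage(pixels=fr, video_id=vid, frame_index=i) for i, fr in enumerate(stack)]


def write_video(frames: Sequence[FrameImage | np.ndarray], path: str | Path) -> Path:
    """Write frames losslessly: ``.tif``/``.tiff`` → multipage TIFF, else PNG dir."""
    p = Path(path)
    arrs = [f.pixels if isinstance(f, FrameImage) else np.asarray(f, dtype=np.uint8) for f in frames]
    if not arrs:
        raise IOError("cannot write a zero-frame video")
    if p.suffix.lower() in (".tif", ".tiff"):
        p.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(p, np.stack(arrs))
    else:
        p.mkdir(parents=True, exist_ok=True)
        for i, a in enumerate(arrs):
            iio.imwrite(p / f"frame_{i:05d}.png", a)
    return p


# ---------------------------------------------------------------------------
# Mask / annotation I/O


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(p, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    return p


def read_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 255))):
        raise ValidationError(f"mask {path} is not binary 0/255 (values {vals.tolist()[:8]})")
    return arr > 0


def write_annotation(ann: ReferenceAnnotation, directory: str | Path) -> dict[str, Path]:
    """Serialize an annotation as one PNG per class plus a JSON label sidecar."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, mask in ann.masks().items():
        paths[name] = write_mask(mask, d / f"{name}.png")
    meta = {
        "glottis_visible": bool(ann.glottis_visible),
        "glottis_state": ann.glottis_state,
        "bolus_type": ann.bolus_type,
    }
    meta_path = d / "labels.json"
    meta_path.write_text(json.dumps(meta))
    paths["labels"] = meta_path
    return paths


def read_annotation(directory: str | Path) -> ReferenceAnnotation:
    d = Path(directory)
    masks = {name: read_mask(d / f"{name}.png") for name in MASK_NAMES}
    meta = json.loads((d / "labels.json").read_text())
    return ReferenceAnnotation(**masks, **meta)


# ---------------------------------------------------------------------------
# Dataset splitting


def split_dataset(
    video_ids: Sequence[str],
    fractions: tuple[float, float, float],
    seed: int,
) -> dict[str, str]:
    """Partition videos into disjoint train/validation/test sets.

    Counts are ``round(fraction * n)`` for validation and test, with the
    remainder going to training; assignment is a seeded shuffle, so the
    partition is deterministic per seed.  Returns ``{video_id: split}``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    ids = list(video_ids)
    n = len(ids)
    if len(set(ids)) != n:
        raise ValueError("video_ids contains duplicates")
    n_val = round(fractions[1] * n)
    n_test = round(fractions[2] * n)
    n_train = n - n_val - n_test
    n_nonzero = sum(1 for f in fractions if f > 0)
    if n < n_nonzero:
        raise ValueError(f"{n} videos cannot fill {n_nonzero} nonempty splits")
    if n_train < 0:
        raise ValueError("rounding left no videos for training; adjust fractions")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment: dict[str, str] = {}
    for pos, idx in enumerate(order):
        if pos < n_train:
            split = "train"
        elif pos < n_train + n_val:
            split = "validation"
        else:
            split = "test"
        assignment[ids[idx]] = split
    return assignment
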