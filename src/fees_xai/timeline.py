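"""Timeline-based explainability: pixel-count curves, meaningful frames, overlays.

Applying the segmentation network to an entire video yields per-frame pixel
counts for each structure.  Plotted as a timeline, these counts give the
examiner the whole video at one glance; stretches where aspiration is
detected on several consecutive frames — the "meaningful frames" — are the
places worth scrolling to for human verification of the model's output.
An overlay video draws the predicted (and optionally reference) contours
into every frame so a detection can be judged in situ.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .dataio import FrameImage, ReferenceAnnotation, write_video
from .postprocess import SegmentationResult, postprocess_frame
from .preprocess import downscale_frame
from .unet import UNet, predict_frame

__all__ = [
    "TimelineRecord",
    "EventRun",
    "compute_timeline",
    "detect_event_runs",
    "render_overlay_video",
    "export_timeline",
    "OVERLAY_PALETTE",
]

#: Contour colors per class: yellow glottis ROI, cyan vocal cords, magenta aspiration.
OVERLAY_PALETTE = {
    "glottis_roi": (255, 255, 0),
    "vocal_cords": (0, 255, 255),
    "aspiration": (255, 0, 255),
}


@dataclass
class TimelineRecord:
    frame_index: int
    glottis_pixels: int
    vocal_cord_pixels: int
    aspiration_pixels: int


@dataclass
class EventRun:
    """A maximal run of consecutive frames with detected aspiration."""

    start_frame: int
    end_frame: int  # inclusive
    peak_frame: int  # earliest argmax of aspiration pixels within the run
    peak_pixels: int
    total_pixels: int


def compute_timeline(
    frames: Sequence[FrameImage],
    model: UNet,
    threshold: float = 0.5,
    connectivity: int = 8,
    downscale: bool = True,
    keep_results: bool = False,
) -> list[TimelineRecord] | tuple[list[TimelineRecord], list[SegmentationResult]]:
    """Run the model over a whole video and count post-processed pixels per frame."""
    records: list[TimelineRecord] = []
    results: list[SegmentationResult] = []
    for frame in frames:
        f = downscale_frame(frame) if downscale else frame
        maps = predict_frame(model, f)
        result = postprocess_frame(maps, threshold=threshold, connectivity=connectivity)
        records.append(
            TimelineRecord(
                frame_index=frame.frame_index,
                glottis_pixels=result.pixel_counts["glottis_roi"],
                vocal_cord_pixels=result.pixel_counts["vocal_cords"],
                aspiration_pixels=result.pixel_counts["aspiration"],
            )
        )
        if keep_results:
            results.append(result)
    return (records, results) if keep_results else records


def detect_event_runs(
    timeline: Sequence[TimelineRecord],
    min_consecutive: int = 3,
    min_pixels: int = 1,
) -> list[EventRun]:
    """Extract maximal consecutive-frame aspiration runs (the meaningful frames).

    A run is a maximal block of consecutive frames whose aspiration pixel
    count is at least ``min_pixels``; only runs spanning at least
    ``min_consecutive`` frames are reported.  ``peak_frame`` is the earliest
    frame attaining the run's maximum count.
    """
    if min_consecutive < 1:
        raise ValueError("min_consecutive must be ≥ 1")
    if min_pixels < 1:
        raise ValueError("min_pixels must be ≥ 1")
    runs: list[EventRun] = []
    block: list[TimelineRecord] = []

    def flush() -> None:
        if len(block) >= min_consecutive:
            counts = [r.aspiration_pixels for r in block]
            peak_pos = int(np.argmax(counts))
            runs.append(
                EventRun(
                    start_frame=block[0].frame_index,
                    end_frame=block[-1].frame_index,
                    peak_frame=block[peak_pos].frame_index,
                    peak_pixels=counts[peak_pos],
                    total_pixels=int(sum(counts)),
                )
            )

    prev_index: int | None = None
    for rec in timeline:
        hit = rec.aspiration_pixels >= min_pixels
        contiguous = prev_index is not None and rec.frame_index == prev_index + 1
        if hit and block and contiguous:
            block.append(rec)
        elif hit:
            flush()
            block = [rec]
        else:
            flush()
            block = []
        prev_index = rec.frame_index
    flush()
    return runs


def _contour(mask: np.ndarray) -> np.ndarray:
    """One-pixel contour band of a binary mask (mask minus its erosion)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask
    return mask & ~ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))


def _dotted(contour: np.ndarray) -> np.ndarray:
    """Thin a contour to a dotted line by keeping alternating pixel diagonals."""
    ii, jj = np.mgrid[0 : contour.shape[0], 0 : contour.shape[1]]
    return contour & (((ii + jj) // 2) % 2 == 0)


def render_overlay_video(
    frames: Sequence[FrameImage],
    results: Sequence[SegmentationResult],
    path: str | Path,
    palette: dict[str, tuple[int, int, int]] | None = None,
    references: Sequence[ReferenceAnnotation] | None = None,
    filled: bool = False,
) -> Path:
    """Draw per-class contours into every frame and write the overlay video.

    Predictions are solid contours in the palette colors; references, when
    given, are drawn dotted.  With ``filled=True`` predicted regions are
    alpha-blended instead of outlined.  Frames outside any overlay are
    written unmodified.
    """
    if len(frames) != len(results):
        raise ValueError(f"frame/result count mismatch: {len(frames)} vs {len(results)}")
    if references is not None and len(references) != len(frames):
        raise ValueError("reference count must match frame count")
    palette = palette or OVERLAY_PALETTE
    out_frames: list[np.ndarray] = []
    for i, (frame, result) in enumerate(zip(frames, results)):
        img = frame.pixels.copy()
        masks = {
            "glottis_roi": result.glottis_roi,
            "vocal_cords": result.vocal_cords,
            "aspiration": result.aspiration,
        }
        for name, mask in masks.items():
            color = np.array(palette[name], dtype=np.uint8)
            if filled:
                region = np.asarray(mask, dtype=bool)
                img[region] = (0.6 * img[region] + 0.4 * color).astype(np.uint8)
            else:
                img[_contour(mask)] = color
        if references is not None:
            ref = references[i]
            for name, mask in ref.masks().items():
                img[_dotted(_contour(mask))] = palette[name]
        out_frames.append(img)
    return write_video(out_frames, path)


def export_timeline(
    timeline: Sequence[TimelineRecord],
    events: Sequence[EventRun],
    out_dir: str | Path,
    zoom_halfwidth: int = 15,
) -> dict[str, Path]:
    """Write timeline CSV, sorted event-run JSON, and the timeline plot.

    The plot shows per-class pixel-count curves with detected runs shaded,
    plus a zoom panel centered on the highest-peak run.
    """
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame([asdict(r) for r in timeline])
    csv_path = d / "timeline.csv"
    df.to_csv(csv_path, index=False)

    events_sorted = sorted(events, key=lambda e: e.start_frame)
    json_path = d / "events.json"
    json_path.write_text(json.dumps([asdict(e) for e in events_sorted], indent=2))

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(8, 5.5), height_ratios=[2, 1])
    for ax in axes:
        if len(df):
            ax.plot(df.frame_index, df.glottis_pixels, color="gold", label="glottis ROI")
            ax.plot(df.frame_index, df.vocal_cord_pixels, color="c", label="vocal cords")
            ax.plot(df.frame_index, df.aspiration_pixels, color="m", label="aspiration")
        for ev in events_sorted:
            ax.axvspan(ev.start_frame, ev.end_frame, color="m", alpha=0.15)
        ax.set_ylabel("pixels")
    axes[0].legend(fontsize=8)
    axes[0].set_title("segmentation pixel counts per frame")
    if events_sorted:
        top = max(events_sorted, key=lambda e: e.peak_pixels)
        axes[1].set_xlim(top.peak_frame - zoom_halfwidth, top.peak_frame + zoom_halfwidth)
        axes[1].axvline(top.peak_frame, color="k", linewidth=0.8)
        axes[1].set_title(f"zoom around peak frame {top.peak_frame}", fontsize=9)
    axes[1].set_xlabel("frame index")
    fig.tight_layout()
    png_path = d / "timeline.png"
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return {"csv": csv_path, "events": json_path, "plot": png_path}


def load_timeline_csv(path: str | Path) -> list[TimelineRecord]:
    df = pd.read_csv(path)
    return [
        TimelineRecord(
            frame_index=int(r.frame_index),
            glottis_pixels=int(r.glottis_pixels),
            vocal_cord_pixels=int(r.vocal_cord_pixels),
            aspiration_pixels=int(r.aspiration_pixels),
        )
        for r in df.itertuples()
    ]
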