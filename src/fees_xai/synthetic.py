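"""Synthetic endoscopy-like videos with exact ground-truth annotations.

The clinical videos behind this pipeline are private, so every downstream
stage (sampler, network, post-processing, metrics, timeline) is exercised
on generated scenes that reproduce the *structure* of the data: a dark
elliptical/wedge glottis whose opening oscillates and which is
intermittently absent or clipped at the image edge, two brighter vocal-cord
bands flanking it, occasional bolus blobs that enter the glottis region
(three appearance types: slurry, saliva, liquid), specular reflections, and
frame-to-frame brightness/sharpness variability.  Masks are rendered from
the same geometry as the image, so the annotations are exact by
construction.  Synthetic realism is a stand-in for testing, not an
emulation claim about clinical appearance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
from scipy import ndimage

from .dataio import DatasetIndex, FrameImage, IndexRecord, ReferenceAnnotation, write_annotation, write_video

__all__ = [
    "SceneConfig",
    "BolusEvent",
    "SyntheticDataset",
    "ConfigurationError",
    "schedule_events",
    "generate_video",
    "corrupt_frame",
    "save_dataset",
]


class ConfigurationError(ValueError):
    """A SceneConfig field violates its constraint; the message names the field."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one generated video.

    Sizes are in pixels at the raw (pre-downscale) resolution.
    ``glottis_size_range`` bounds the major-axis length of the glottis
    ellipse; ``bolus_size_range`` bounds the target bolus area;
    ``bolus_event_rate`` is events per 100 frames; ``visibility_schedule``
    is the per-frame probability that the glottis is in view at all.
    """

    image_size: tuple[int, int] = (192, 192)
    n_frames: int = 200
    glottis_size_range: tuple[float, float] = (48.0, 88.0)
    open_close_period: int = 40
    visibility_schedule: float = 0.9
    partial_visibility_rate: float = 0.1
    bolus_event_rate: float = 5.0
    bolus_size_range: tuple[float, float] = (150.0, 700.0)
    bolus_type: str = "slurry"
    reflection_rate: float = 0.05
    brightness_jitter: float = 0.1
    blur_sigma_range: tuple[float, float] = (0.0, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ConfigurationError(f"image_size must be at least 64×64, got {self.image_size}")
        if self.n_frames < 1:
            raise ConfigurationError(f"n_frames must be positive, got {self.n_frames}")
        for name in ("glottis_size_range", "bolus_size_range", "blur_sigma_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ConfigurationError(f"{name} must be a non-negative (lo, hi) range, got {(lo, hi)}")
        for name in ("visibility_schedule", "partial_visibility_rate", "reflection_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be a probability in [0, 1], got {p}")
        if self.bolus_event_rate < 0:
            raise ConfigurationError(f"bolus_event_rate must be non-negative, got {self.bolus_event_rate}")
        if self.brightness_jitter < 0:
            raise ConfigurationError(f"brightness_jitter must be non-negative, got {self.brightness_jitter}")
        if self.open_close_period < 2:
            raise ConfigurationError(f"open_close_period must be at least 2, got {self.open_close_period}")
        if self.bolus_type not in ("slurry", "saliva", "liquid"):
            raise ConfigurationError(f"bolus_type must be slurry|saliva|liquid, got {self.bolus_type!r}")


@dataclass
class BolusEvent:
    """One logged aspiration interval (frames inclusive) with per-frame sizes."""

    start_frame: int
    end_frame: int
    bolus_type: str
    sizes: list[int] = field(default_factory=list)  # rendered aspiration pixels per frame


@dataclass
class SyntheticDataset:
    frames: list[FrameImage]
    annotations: list[ReferenceAnnotation]
    event_log: list[BolusEvent]

    def __post_init__(self) -> None:
        assert len(self.frames) == len(self.annotations)


# RNG streams are derived from the config seed with fixed stream tags so that
# the event schedule, visibility draws and rendering noise are independent and
# each re-derivable on its own.
_STREAM_GEOMETRY, _STREAM_EVENTS, _STREAM_VISIBILITY, _STREAM_NOISE = 0, 1, 2, 3


def _stream(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([seed, tag])


def schedule_events(config: SceneConfig) -> list[tuple[int, int]]:
    """Draw the aspiration-event intervals for a config (pure in the seed).

    The nominal event count is ``round(rate × n_frames / 100)``; start frames
    are uniform draws, durations uniform in [3, 10] frames, and overlapping
    or adjacent intervals are merged.  This is the exact placement step used
    by :func:`generate_video`, exposed so the schedule can be regenerated
    independently of rendering.
    """
    rng = _stream(config.seed, _STREAM_EVENTS)
    n_nominal = int(round(config.bolus_event_rate * config.n_frames / 100.0))
    if n_nominal == 0:
        return []
    starts = np.sort(rng.integers(0, config.n_frames, size=n_nominal))
    durations = rng.integers(3, 11, size=n_nominal)
    intervals: list[tuple[int, int]] = []
    for s, d in zip(starts, durations):
        e = min(int(s + d - 1), config.n_frames - 1)
        if intervals and s <= intervals[-1][1] + 1:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], e))
        else:
            intervals.append((int(s), e))
    return intervals


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    h, w = shape
    ii, jj = np.mgrid[0:h, 0:w]
    ci, cj = center
    a, b = semi_axes
    c, s = np.cos(angle), np.sin(angle)
    u = (ii - ci) * c + (jj - cj) * s
    v = -(ii - ci) * s + (jj - cj) * c
    return (u / max(a, 1e-6)) ** 2 + (v / max(b, 1e-6)) ** 2 <= 1.0


def _smooth_noise(shape: tuple[int, int], rng: np.random.Generator, sigma: float, amp: float) -> np.ndarray:
    field_ = rng.standard_normal(shape)
    field_ = ndimage.gaussian_filter(field_, sigma)
    m = np.abs(field_).max()
    return amp * field_ / m if m > 0 else field_


# per-type bolus appearance: (base RGB, opacity, texture amplitude)
_BOLUS_APPEARANCE = {
    "slurry": (np.array([205.0, 190.0, 150.0]), 0.85, 35.0),  # textured mid-intensity
    "saliva": (np.array([235.0, 232.0, 225.0]), 0.9, 8.0),    # small bright
    "liquid": (np.array([170.0, 140.0, 130.0]), 0.4, 5.0),    # low-contrast translucent
}


def generate_video(config: SceneConfig) -> SyntheticDataset:
    """Render one synthetic video with exact annotations and an event log.

    Deterministic given ``config.seed``.  Frames where the glottis is not
    visible contain no structural mask pixels and carry
    ``glottis_visible=False``; bolus blobs are rendered only inside the
    glottis ROI, so the aspiration mask is always a subset of it.
    """
    h, w = config.image_size
    geo = _stream(config.seed, _STREAM_GEOMETRY)
    vis_rng = _stream(config.seed, _STREAM_VISIBILITY)
    noise_rng = _stream(config.seed, _STREAM_NOISE)

    # Per-video geometry: glottis pose and size, vocal-cord offsets.
    major = geo.uniform(*config.glottis_size_range) / 2.0  # semi-axis
    angle = geo.uniform(-0.35, 0.35)
    center = (
        h / 2.0 + geo.uniform(-h * 0.08, h * 0.08),
        w / 2.0 + geo.uniform(-w * 0.08, w * 0.08),
    )
    base_tissue = np.array([168.0, 105.0, 98.0]) + geo.uniform(-12, 12, size=3)
    texture = _smooth_noise((h, w), geo, sigma=9.0, amp=18.0)
    ii, jj = np.mgrid[0:h, 0:w]
    vignette = 1.0 - 0.35 * (((ii - h / 2) / (h / 2)) ** 2 + ((jj - w / 2) / (w / 2)) ** 2) / 2.0

    events = schedule_events(config)
    event_objs = [BolusEvent(s, e, config.bolus_type, sizes=[0] * (e - s + 1)) for s, e in events]
    frame_event: dict[int, BolusEvent] = {}
    for ev in event_objs:
        for t in range(ev.start_frame, ev.end_frame + 1):
            frame_event[t] = ev

    visible = vis_rng.random(config.n_frames) < config.visibility_schedule
    partial = vis_rng.random(config.n_frames) < config.partial_visibility_rate

    frames: list[FrameImage] = []
    annotations: list[ReferenceAnnotation] = []
    video_id = f"synthetic-{config.seed:06d}"

    for t in range(config.n_frames):
        img = base_tissue[None, None, :] * vignette[..., None] + texture[..., None]
        glottis = np.zeros((h, w), dtype=bool)
        cords = np.zeros((h, w), dtype=bool)
        aspiration = np.zeros((h, w), dtype=bool)
        state = "unknown"
        bolus_type = "none"

        if visible[t]:
            # Open/close cycle: the minor axis oscillates with the configured period.
            openness = 0.10 + 0.45 * (1 + np.sin(2 * np.pi * t / config.open_close_period)) / 2.0
            minor = major * openness
            c_t = center
            if partial[t]:
                # Clip the glottis at the nearest image edge (partial visibility).
                shift = noise_rng.uniform(0.75, 1.0) * (h / 2.0)
                c_t = (center[0] - shift, center[1])
            glottis = _ellipse_mask((h, w), c_t, (minor, major), angle)
            if not glottis.any():
                # Clipping pushed the glottis fully off-image: the frame is
                # effectively a glottis-absent frame and is labeled as such.
                visible[t] = False
            state = "open" if openness > 0.28 else "closed"

        if visible[t]:
            # Vocal cords: two bright bands flanking the glottis along its minor axis.
            off = minor + major * 0.28
            di, dj = np.cos(angle) * off, np.sin(angle) * off
            for sign in (-1.0, 1.0):
                cc = (c_t[0] + sign * di, c_t[1] + sign * dj)
                band = _ellipse_mask((h, w), cc, (major * 0.30, major * 0.95), angle)
                band &= ~glottis
                cords |= band
                img[band] = 0.65 * img[band] + 0.35 * np.array([225.0, 205.0, 195.0])

            img[glottis] = np.array([34.0, 18.0, 20.0]) + texture[glottis, None] * 0.3

            ev = frame_event.get(t)
            if ev is not None and glottis.any():
                bolus_type = ev.bolus_type
                # Bolus grows toward mid-event then shrinks; rendered inside the ROI.
                span = ev.end_frame - ev.start_frame
                phase = (t - ev.start_frame) / max(span, 1)
                scale = 0.5 + 0.5 * np.sin(np.pi * min(max(phase, 0.0), 1.0)) if span > 0 else 1.0
                lo, hi = config.bolus_size_range
                area = (lo + (hi - lo) * noise_rng.uniform(0.3, 1.0)) * scale
                if ev.bolus_type == "saliva":
                    area *= 0.5  # saliva boluses are small
                radius = max(np.sqrt(area / np.pi), 1.5)
                rows, cols = np.nonzero(glottis)
                pick = noise_rng.integers(0, len(rows))
                blob = np.zeros((h, w), dtype=bool)
                for _ in range(3):
                    jit = noise_rng.uniform(-radius * 0.5, radius * 0.5, size=2)
                    blob |= _ellipse_mask(
                        (h, w),
                        (rows[pick] + jit[0], cols[pick] + jit[1]),
                        (radius * noise_rng.uniform(0.7, 1.1), radius * noise_rng.uniform(0.7, 1.1)),
                        noise_rng.uniform(0, np.pi),
                    )
                aspiration = blob & glottis
                color, opacity, tex_amp = _BOLUS_APPEARANCE[ev.bolus_type]
                tex = _smooth_noise((h, w), noise_rng, sigma=2.0, amp=tex_amp)
                img[aspiration] = (
                    (1 - opacity) * img[aspiration]
                    + opacity * (color[None, :] + tex[aspiration, None])
                )
                ev.sizes[t - ev.start_frame] = int(aspiration.sum())

        frame = FrameImage(
            pixels=np.clip(img, 0, 255).astype(np.uint8),
            video_id=video_id,
            frame_index=t,
        )
        blur_sigma = noise_rng.uniform(*config.blur_sigma_range)
        frame = corrupt_frame(
            frame,
            reflection_rate=config.reflection_rate,
            blur_sigma=blur_sigma,
            brightness_jitter=config.brightness_jitter,
            rng=noise_rng,
        )
        frames.append(frame)
        annotations.append(
            ReferenceAnnotation(
                glottis_roi=glottis,
                vocal_cords=cords,
                aspiration=aspiration,
                glottis_visible=bool(visible[t]),
                glottis_state=state if visible[t] else "unknown",
                bolus_type=bolus_type,
            )
        )

    return SyntheticDataset(frames=frames, annotations=annotations, event_log=event_objs)


def corrupt_frame(
    frame: FrameImage,
    reflection_rate: float = 0.0,
    blur_sigma: float = 0.0,
    brightness_jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> FrameImage:
    """Apply acquisition-style degradations: brightness shift, blur, reflections.

    With all parameters zero the frame is returned unchanged.  The
    brightness factor is drawn uniformly within ±``brightness_jitter`` of 1,
    so the output frame mean stays within that fraction of the input mean.
    A specular reflection is a compact saturated patch, emulating a common
    source of false bolus detections.  Out-of-range parameters are clamped
    with a warning.
    """
    if reflection_rate < 0 or reflection_rate > 1:
        warnings.warn(f"reflection_rate {reflection_rate} clamped to [0, 1]", stacklevel=2)
        reflection_rate = min(max(reflection_rate, 0.0), 1.0)
    if blur_sigma < 0:
        warnings.warn(f"blur_sigma {blur_sigma} clamped to 0", stacklevel=2)
        blur_sigma = 0.0
    if brightness_jitter < 0:
        warnings.warn(f"brightness_jitter {brightness_jitter} clamped to 0", stacklevel=2)
        brightness_jitter = 0.0
    if reflection_rate == 0 and blur_sigma == 0 and brightness_jitter == 0:
        return frame
    rng = rng if rng is not None else np.random.default_rng()
    img = frame.pixels.astype(np.float32)
    h, w = img.shape[:2]
    if brightness_jitter > 0:
        img *= 1.0 + rng.uniform(-brightness_jitter, brightness_jitter)
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, (blur_sigma, blur_sigma, 0))
    if reflection_rate > 0 and rng.random() < reflection_rate:
        for _ in range(int(rng.integers(1, 3))):
            ci, cj = rng.uniform(0, h), rng.uniform(0, w)
            r = rng.uniform(2.0, 6.0)
            spot = _ellipse_mask((h, w), (ci, cj), (r, r), 0.0)
            img[spot] = 255.0
    return FrameImage(
        pixels=np.clip(img, 0, 255).astype(np.uint8),
        video_id=frame.video_id,
        frame_index=frame.frame_index,
    )


def save_dataset(ds: SyntheticDataset, out_dir: str | Path, split: str = "train") -> Path:
    """Write a generated dataset: video stack, per-frame mask PNGs, JSONL index."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    video_id = ds.frames[0].video_id if ds.frames else "synthetic"
    write_video(ds.frames, d / f"{video_id}.tif")
    records = []
    for frame, ann in zip(ds.frames, ds.annotations):
        ann_dir = d / "annotations" / f"{video_id}_{frame.frame_index:05d}"
        write_annotation(ann, ann_dir)
        records.append(
            IndexRecord(
                video_id=video_id,
                frame_index=frame.frame_index,
                annotation_path=str(ann_dir),
                glottis_visible=ann.glottis_visible,
                bolus_type=ann.bolus_type,
                split=split,
            )
        )
    index = DatasetIndex(records)
    index.save(d / "index.jsonl")
    import json

    (d / "events.json").write_text(
        json.dumps(
            [
                {
                    "start_frame": ev.start_frame,
                    "end_frame": ev.end_frame,
                    "bolus_type": ev.bolus_type,
                    "sizes": ev.sizes,
                }
                for ev in ds.event_log
            ],
            indent=2,
        )
    )
    return d
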