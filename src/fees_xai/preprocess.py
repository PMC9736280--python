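"""Frame preprocessing, training-time augmentation, and patch sampling.

Frames are downscaled by a factor of two (2×2 block averaging) to remove
comb artifacts from interlaced recording; masks follow with 2×2 max-pooling
so every annotated pixel survives.  Training patches are sampled with a
stratified scheme that counteracts class imbalance: 80% of patches contain
the glottis ROI and 25% of those show aspiration, while the remainder come
from frames labeled as not containing the ROI (the negative stratum, which
teaches the network to stay silent on glottis-free frames).

Augmentation is applied online, per draw: rotation, zoom up to ×1.5,
left-right mirroring, contrast change, and brightness shifts of up to ±25%
of the patch mean, with one shared geometric transform for image and masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import transform as sktransform

from .dataio import FrameImage, ReferenceAnnotation

__all__ = [
    "PatchSample",
    "SamplerConfig",
    "AugmentParams",
    "AugmentRanges",
    "downscale_frame",
    "downscale_mask",
    "downscale_annotation",
    "augment",
    "augment_with_params",
    "PatchSampler",
    "sample_patch",
    "STRATA",
]

STRATA = ("roi_with_aspiration", "roi_without_aspiration", "negative")


@dataclass
class PatchSample:
    """One training sample: an image patch with its 3-channel target masks."""

    image: np.ndarray  # (H, W, 3) uint8
    targets: np.ndarray  # (3, H, W) bool, class order (ROI, cords, aspiration)
    stratum: str

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValueError(f"stratum must be one of {STRATA}")
        self.targets = np.asarray(self.targets, dtype=bool)
        if self.stratum == "negative" and self.targets.any():
            raise ValueError("negative stratum requires empty target masks")
        if self.stratum != "negative" and not self.targets[0].any():
            raise ValueError("roi stratum requires a nonempty glottis target")


@dataclass(frozen=True)
class SamplerConfig:
    """Stratified sampling design: P(ROI patch) and P(aspiration | ROI)."""

    p_roi: float = 0.8
    p_aspiration_given_roi: float = 0.25
    batch_size: int = 16
    patch_size: tuple[int, int] = (288, 352)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_roi", "p_aspiration_given_roi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")

    @property
    def stratum_probabilities(self) -> tuple[float, float, float]:
        p_asp = self.p_roi * self.p_aspiration_given_roi
        return (p_asp, self.p_roi - p_asp, 1.0 - self.p_roi)


# ---------------------------------------------------------------------------
# Downscaling


def _pad_even(arr: np.ndarray) -> np.ndarray:
    h, w = arr.shape[:2]
    ph, pw = h % 2, w % 2
    if ph == 0 and pw == 0:
        return arr
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (arr.ndim - 2)
    return np.pad(arr, pad, mode="edge")


def downscale_frame(frame: FrameImage) -> FrameImage:
    """Downscale ×2 by 2×2 block averaging (edge-replicated if odd-sized)."""
    px = _pad_even(frame.pixels).astype(np.float32)
    h, w = px.shape[:2]
    small = px.reshape(h // 2, 2, w // 2, 2, 3).mean(axis=(1, 3))
    return FrameImage(
        pixels=np.clip(np.rint(small), 0, 255).astype(np.uint8),
        video_id=frame.video_id,
        frame_index=frame.frame_index,
    )


def downscale_mask(mask: np.ndarray) -> np.ndarray:
    """Downscale a binary mask ×2 by 2×2 max-pooling (any annotated pixel survives)."""
    m = _pad_even(np.asarray(mask, dtype=bool))
    h, w = m.shape
    return m.reshape(h // 2, 2, w // 2, 2).any(axis=(1, 3))


def downscale_annotation(ann: ReferenceAnnotation) -> ReferenceAnnotation:
    return ReferenceAnnotation(
        glottis_roi=downscale_mask(ann.glottis_roi),
        vocal_cords=downscale_mask(ann.vocal_cords),
        aspiration=downscale_mask(ann.aspiration),
        glottis_visible=ann.glottis_visible,
        glottis_state=ann.glottis_state,
        bolus_type=ann.bolus_type,
    )


# ---------------------------------------------------------------------------
# Augmentation


@dataclass(frozen=True)
class AugmentRanges:
    """Sampling ranges for the augmentation parameters.

    Rotation and contrast ranges are package defaults (conservative,
    config-exposed); zoom is in-only, up to ×1.5, and brightness shifts are
    bounded by ±25% of the patch mean.
    """

    max_rotation_deg: float = 30.0
    zoom_range: tuple[float, float] = (1.0, 1.5)
    contrast_range: tuple[float, float] = (0.75, 1.25)
    max_brightness_frac: float = 0.25
    p_mirror: float = 0.5


@dataclass(frozen=True)
class AugmentParams:
    rotation_deg: float = 0.0
    zoom: float = 1.0
    mirror: bool = False
    contrast: float = 1.0
    brightness_frac: float = 0.0  # shift as a fraction of the patch mean

    @classmethod
    def draw(cls, rng: np.random.Generator, ranges: AugmentRanges | None = None) -> "AugmentParams":
        r = ranges or AugmentRanges()
        return cls(
            rotation_deg=float(rng.uniform(-r.max_rotation_deg, r.max_rotation_deg)),
            zoom=float(rng.uniform(*r.zoom_range)),
            mirror=bool(rng.random() < r.p_mirror),
            contrast=float(rng.uniform(*r.contrast_range)),
            brightness_frac=float(rng.uniform(-r.max_brightness_frac, r.max_brightness_frac)),
        )


def _geometric_transform(shape: tuple[int, int], params: AugmentParams) -> sktransform.AffineTransform:
    h, w = shape
    # skimage transforms act on (x, y) = (col, row) coordinates.
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    t_center = sktransform.AffineTransform(translation=-center)
    mirror = sktransform.AffineTransform(matrix=np.diag([-1.0, 1.0, 1.0])) if params.mirror else sktransform.AffineTransform()
    core = sktransform.AffineTransform(scale=params.zoom, rotation=np.deg2rad(params.rotation_deg))
    t_back = sktransform.AffineTransform(translation=center)
    return t_center + mirror + core + t_back


def augment_with_params(patch: PatchSample, params: AugmentParams) -> PatchSample:
    """Apply one augmentation with explicit parameters.

    The identical geometric transform is applied to the image (bilinear)
    and to every mask (nearest neighbor); identity parameters return the
    patch bit-for-bit.
    """
    image = patch.image
    targets = patch.targets
    geometric = params.rotation_deg != 0.0 or params.zoom != 1.0 or params.mirror
    if geometric:
        tform = _geometric_transform(image.shape[:2], params)
        inv = tform.inverse
        warped = sktransform.warp(
            image.astype(np.float32), inv, order=1, mode="reflect", preserve_range=True
        )
        image = np.clip(np.rint(warped), 0, 255).astype(np.uint8)
        targets = np.stack(
            [
                sktransform.warp(t.astype(np.float32), inv, order=0, mode="constant", cval=0.0, preserve_range=True) > 0.5
                for t in targets
            ]
        )
    if params.contrast != 1.0 or params.brightness_frac != 0.0:
        img = image.astype(np.float32)
        mean = img.mean()
        img = params.contrast * (img - mean) + mean + params.brightness_frac * mean
        image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    # Geometric warps can empty a small glottis target; demote to negative if so.
    stratum = patch.stratum
    if stratum != "negative" and not targets[0].any():
        targets = np.zeros_like(targets)
        stratum = "negative"
    return PatchSample(image=image, targets=targets, stratum=stratum)


def augment(
    patch: PatchSample,
    rng: np.random.Generator,
    ranges: AugmentRanges | None = None,
) -> PatchSample:
    """Apply one randomly drawn augmentation (see :class:`AugmentRanges`)."""
    return augment_with_params(patch, AugmentParams.draw(rng, ranges))


# ---------------------------------------------------------------------------
# Stratified patch sampling


def _reflect_pad_to(arr: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    h, w = arr.shape[:2]
    ph, pw = max(size[0] - h, 0), max(size[1] - w, 0)
    if ph == 0 and pw == 0:
        return arr
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (arr.ndim - 2)
    return np.pad(arr, pad, mode="reflect")


class PatchSampler:
    """Stratified sampler over downscaled (frame, annotation) pairs.

    Strata: frames with the glottis ROI and aspiration, frames with the ROI
    only, and glottis-absent frames (negative).  The stratum is drawn with
    probabilities (p_roi·p_asp, p_roi·(1−p_asp), 1−p_roi); within a stratum
    the frame is chosen uniformly.  ROI patches are centered on a uniformly
    chosen ROI pixel (clamped to image bounds) so the stratum contract is
    guaranteed; negative patches are positioned uniformly.
    """

    def __init__(
        self,
        pairs: Sequence[tuple[FrameImage, ReferenceAnnotation]],
        config: SamplerConfig,
        downscale: bool = True,
        augment_ranges: AugmentRanges | None = None,
    ) -> None:
        self.config = config
        self.augment_ranges = augment_ranges
        if downscale:
            pairs = [(downscale_frame(f), downscale_annotation(a)) for f, a in pairs]
        self.pairs = list(pairs)
        self._strata: dict[str, list[int]] = {s: [] for s in STRATA}
        for i, (_, ann) in enumerate(self.pairs):
            if not ann.glottis_visible:
                self._strata["negative"].append(i)
            elif ann.aspiration.any():
                self._strata["roi_with_aspiration"].append(i)
            else:
                self._strata["roi_without_aspiration"].append(i)

    def stratum_sizes(self) -> dict[str, int]:
        return {s: len(v) for s, v in self._strata.items()}

    def sample(self, rng: np.random.Generator, augment_patch: bool = False) -> PatchSample:
        p_asp, p_roi_only, _ = self.config.stratum_probabilities
        u = rng.random()
        if u < p_asp:
            stratum = "roi_with_aspiration"
        elif u < p_asp + p_roi_only:
            stratum = "roi_without_aspiration"
        else:
            stratum = "negative"
        pool = self._strata[stratum]
        if not pool:
            raise ValueError(f"no frames available in stratum {stratum!r}")
        frame, ann = self.pairs[pool[rng.integers(len(pool))]]
        patch = self._extract(frame, ann, stratum, rng)
        if augment_patch:
            patch = augment(patch, rng, self.augment_ranges)
        return patch

    def batch(
        self, rng: np.random.Generator, augment_patch: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """One training batch: images (N,H,W,3) float32 in [0,1], targets (N,H,W,3)."""
        samples = [self.sample(rng, augment_patch) for _ in range(self.config.batch_size)]
        images = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
        targets = np.stack([s.targets.transpose(1, 2, 0) for s in samples]).astype(np.float32)
        return images, targets

    def _extract(
        self,
        frame: FrameImage,
        ann: ReferenceAnnotation,
        stratum: str,
        rng: np.random.Generator,
    ) -> PatchSample:
        ph, pw = self.config.patch_size
        img = _reflect_pad_to(frame.pixels, (ph, pw))
        masks = np.stack([_reflect_pad_to(m, (ph, pw)) for m in ann.stacked().astype(bool)])
        h, w = img.shape[:2]
        if stratum == "negative":
            i0 = int(rng.integers(h - ph + 1))
            j0 = int(rng.integers(w - pw + 1))
        else:
            rows, cols = np.nonzero(masks[0])
            k = int(rng.integers(len(rows)))
            i0 = int(np.clip(rows[k] - ph // 2, 0, h - ph))
            j0 = int(np.clip(cols[k] - pw // 2, 0, w - pw))
        image = img[i0 : i0 + ph, j0 : j0 + pw]
        targets = masks[:, i0 : i0 + ph, j0 : j0 + pw]
        if stratum == "negative":
            targets = np.zeros_like(targets)
        elif not targets[0].any():  # pragma: no cover - centering guarantees nonempty
            raise RuntimeError("ROI patch lost its glottis pixels")
        return PatchSample(image=image, targets=targets, stratum=stratum)


def sample_patch(
    pairs: Sequence[tuple[FrameImage, ReferenceAnnotation]],
    config: SamplerConfig,
    rng: np.random.Generator,
    downscale: bool = True,
) -> PatchSample:
    """Convenience one-shot draw; for repeated draws build a :class:`PatchSampler`."""
    return PatchSampler(pairs, config, downscale=downscale).sample(rng)
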