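"""Downscaling, augmentation geometry, and the stratified patch sampler."""

import numpy as np
import pytest

from fees_xai.dataio import FrameImage, ReferenceAnnotation
from fees_xai.preprocess import (
    AugmentParams,
    PatchSampler,
    PatchSample,
    SamplerConfig,
    augment_with_params,
    downscale_annotation,
    downscale_frame,
    downscale_mask,
)


class TestDownscale:
    def test_halves_interlaced_resolution(self):
        frame = FrameImage(np.zeros((576, 704, 3), dtype=np.uint8))
        small = downscale_frame(frame)
        assert small.shape == (288, 352)

    def test_constant_frame_stays_constant(self):
        frame = FrameImage(np.full((64, 64, 3), 97, dtype=np.uint8))
        small = downscale_frame(frame)
        assert np.all(small.pixels == 97)

    def test_block_average_oracle(self):
        px = np.zeros((4, 4, 3), dtype=np.uint8)
        px[0, 0] = 100  # one bright pixel in the top-left 2×2 block
        small = downscale_frame(FrameImage(px))
        assert small.pixels[0, 0, 0] == 25  # mean of (100, 0, 0, 0)
        assert np.all(small.pixels[1:, :, :] == 0)

    def test_single_mask_pixel_survives_max_pool(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[3, 1] = True
        small = downscale_mask(mask)
        assert small.sum() == 1
        assert small[1, 0]

    def test_odd_sizes_padded_by_edge_replication(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[4, 4] = True
        small = downscale_mask(mask)
        assert small.shape == (3, 3)
        assert small[2, 2]


def _patch(rng, with_aspiration=True):
    img = rng.integers(20, 230, size=(64, 64, 3)).astype(np.uint8)
    targets = np.zeros((3, 64, 64), dtype=bool)
    targets[0, 20:40, 24:44] = True
    targets[1, 14:18, 24:44] = True
    if with_aspiration:
        targets[2, 25:30, 28:34] = True
    return PatchSample(image=img, targets=targets, stratum="roi_with_aspiration" if with_aspiration else "roi_without_aspiration")


class TestAugment:
    def test_identity_parameters_return_input_bitwise(self, rng):
        patch = _patch(rng)
        out = augment_with_params(patch, AugmentParams())
        assert np.array_equal(out.image, patch.image)
        assert np.array_equal(out.targets, patch.targets)

    def test_mirror_is_an_involution(self, rng):
        patch = _patch(rng)
        mirrored = augment_with_params(patch, AugmentParams(mirror=True))
        back = augment_with_params(mirrored, AugmentParams(mirror=True))
        assert np.array_equal(back.image, patch.image)
        assert np.array_equal(back.targets, patch.targets)

    @pytest.mark.parametrize("angle", [-25.0, 10.0, 30.0])
    def test_rotation_moves_mask_centroid_as_predicted(self, angle):
        """A one-pixel mask rotates about the patch center per the closed form."""
        img = np.zeros((65, 65, 3), dtype=np.uint8)
        targets = np.zeros((3, 65, 65), dtype=bool)
        targets[0, 19:22, 39:42] = True  # 3×3 block, centroid at (20, 40)
        patch = PatchSample(image=img, targets=targets, stratum="roi_without_aspiration")
        out = augment_with_params(patch, AugmentParams(rotation_deg=angle))
        c = 32.0
        # forward mapping of output coords uses the inverse rotation; the mask
        # pixel lands where the forward transform sends (row, col)
        theta = np.deg2rad(angle)
        drow, dcol = 20 - c, 40 - c
        # skimage rotates in (x, y) = (col, row); derive expected (row, col)
        exp_col = c + dcol * np.cos(theta) - drow * np.sin(theta)
        exp_row = c + dcol * np.sin(theta) + drow * np.cos(theta)
        rows, cols = np.nonzero(out.targets[0])
        assert len(rows) >= 1
        centroid = (rows.mean(), cols.mean())
        assert abs(centroid[0] - exp_row) <= 1.0
        assert abs(centroid[1] - exp_col) <= 1.0

    def test_geometric_transform_shared_between_image_and_masks(self, rng):
        """Transforming a coordinate-grid image matches the mask transform."""
        grid = np.zeros((64, 64, 3), dtype=np.uint8)
        grid[30:34, 30:34] = 255
        targets = np.zeros((3, 64, 64), dtype=bool)
        targets[0, 30:34, 30:34] = True
        patch = PatchSample(image=grid, targets=targets, stratum="roi_without_aspiration")
        params = AugmentParams(rotation_deg=17.0, zoom=1.2)
        out = augment_with_params(patch, params)
        bright = out.image[..., 0] > 200
        if out.stratum != "negative":
            overlap = (bright & out.targets[0]).sum()
            assert overlap / out.targets[0].sum() > 0.6

    def test_brightness_shift_bounded_by_quarter_of_mean(self, rng):
        patch = _patch(rng)
        out = augment_with_params(patch, AugmentParams(brightness_frac=0.25))
        mean_in = patch.image.mean()
        assert out.image.mean() <= mean_in * 1.26 + 1

    def test_zoom_is_in_only(self):
        from fees_xai.preprocess import AugmentRanges

        r = AugmentRanges()
        assert r.zoom_range[0] >= 1.0
        draws = [AugmentParams.draw(np.random.default_rng(s)).zoom for s in range(50)]
        assert all(1.0 <= z <= 1.5 for z in draws)


def _pairs_from(dataset):
    return list(zip(dataset.frames, dataset.annotations))


@pytest.fixture(scope="module")
def sampler(small_dataset):
    cfg = SamplerConfig(patch_size=(64, 64), seed=0)
    return PatchSampler(_pairs_from(small_dataset), cfg)


class TestPatchSampler:
    def test_stratum_frequencies_match_design(self, sampler):
        """10,000 draws hit the 20/60/20 stratified design within 3σ."""
        rng = np.random.default_rng(2024)
        n = 10_000
        counts = {s: 0 for s in ("roi_with_aspiration", "roi_without_aspiration", "negative")}
        for _ in range(n):
            counts[sampler.sample(rng).stratum] += 1
        for stratum, p in zip(counts, (0.20, 0.60, 0.20)):
            bound = 3 * np.sqrt(p * (1 - p) / n)
            assert abs(counts[stratum] / n - p) < bound, (stratum, counts)

    def test_roi_only_design_yields_glottis_without_aspiration(self, small_dataset):
        cfg = SamplerConfig(p_roi=1.0, p_aspiration_given_roi=0.0, patch_size=(64, 64))
        sampler = PatchSampler(_pairs_from(small_dataset), cfg)
        rng = np.random.default_rng(5)
        for _ in range(20):
            s = sampler.sample(rng)
            assert s.targets[0].any()
            assert not s.targets[2].any()

    def test_negative_stratum_has_empty_targets(self, small_dataset):
        cfg = SamplerConfig(p_roi=0.0, patch_size=(64, 64))
        sampler = PatchSampler(_pairs_from(small_dataset), cfg)
        rng = np.random.default_rng(6)
        s = sampler.sample(rng)
        assert s.stratum == "negative"
        assert not s.targets.any()

    def test_empty_stratum_raises_naming_it(self, small_dataset):
        pairs = [
            (f, a) for f, a in _pairs_from(small_dataset) if a.glottis_visible
        ]
        cfg = SamplerConfig(p_roi=0.0, patch_size=(64, 64))
        sampler = PatchSampler(pairs, cfg)
        with pytest.raises(ValueError, match="negative"):
            sampler.sample(np.random.default_rng(0))

    def test_batch_shapes_and_range(self, sampler):
        rng = np.random.default_rng(9)
        images, targets = sampler.batch(rng)
        assert images.shape == (16, 64, 64, 3)
        assert targets.shape == (16, 64, 64, 3)
        assert images.min() >= 0.0 and images.max() <= 1.0

    def test_small_frames_reflect_padded_to_patch_size(self, rng):
        img = FrameImage(rng.integers(0, 255, size=(40, 40, 3)).astype(np.uint8))
        glottis = np.zeros((40, 40), dtype=bool)
        glottis[10:20, 10:20] = True
        ann = ReferenceAnnotation(
            glottis_roi=glottis,
            vocal_cords=np.zeros((40, 40), dtype=bool),
            aspiration=np.zeros((40, 40), dtype=bool),
        )
        cfg = SamplerConfig(p_roi=1.0, p_aspiration_given_roi=0.0, patch_size=(64, 64))
        sampler = PatchSampler([(img, ann)], cfg, downscale=False)
        s = sampler.sample(np.random.default_rng(1))
        assert s.image.shape == (64, 64, 3)
        assert s.targets[0].any()
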