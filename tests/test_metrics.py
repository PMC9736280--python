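"""Overlap scores, frame-level detection tallies, and the size–Dice correlation."""

import numpy as np
import pytest

from fees_xai import corpus
from fees_xai.metrics import (
    ConfusionCounts,
    FrameOutcome,
    classify_frame,
    confusion_matrix,
    detection_metrics,
    dice,
    fp_glottis_frame_rate,
    jaccard,
    spearman_size_dice,
)


from helpers import pixel_count_dice, pixel_count_jaccard


class TestOverlapScores:
    def test_identical_masks_score_one(self, rng):
        m = rng.random((8, 8)) > 0.5
        m[0, 0] = True
        assert dice(m, m) == 1.0
        assert jaccard(m, m) == 1.0

    def test_disjoint_masks_score_zero(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0] = True
        b[3, 3] = True
        assert dice(a, b) == 0.0
        assert jaccard(a, b) == 0.0

    def test_hand_worked_example(self):
        """|X|=1, |Y|=2, one overlapping pixel → Dice 2/3, Jaccard 1/2."""
        x = np.zeros((2, 2), dtype=bool)
        y = np.zeros((2, 2), dtype=bool)
        x[0, 0] = True
        y[0, 0] = y[0, 1] = True
        assert dice(x, y) == pytest.approx(2 / 3)
        assert jaccard(x, y) == pytest.approx(0.5)

    def test_both_empty_convention(self):
        e = np.zeros((3, 3), dtype=bool)
        assert dice(e, e) == 1.0
        assert jaccard(e, e) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2), dtype=bool), np.zeros((3, 2), dtype=bool))

    def test_agree_with_pixel_count_oracles_and_identity(self):
        """dice/jaccard match counting oracles; J = D/(2−D) to 1e−12."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            x = rng.random((8, 8)) < rng.uniform(0.2, 0.8)
            y = rng.random((8, 8)) < rng.uniform(0.2, 0.8)
            d = dice(x, y)
            j = jaccard(x, y)
            assert d == pytest.approx(pixel_count_dice(x, y), abs=1e-12)
            assert j == pytest.approx(pixel_count_jaccard(x, y), abs=1e-12)
            assert abs(j - d / (2 - d)) < 1e-12


class TestClassifyFrame:
    def _mask(self, *pixels, shape=(6, 6)):
        m = np.zeros(shape, dtype=bool)
        for i, j in pixels:
            m[i, j] = True
        return m

    def test_single_pixel_overlap_is_true_positive(self):
        pred = self._mask((2, 2), (2, 3))
        ref = self._mask((2, 2), (4, 4))
        assert classify_frame(pred, ref) is FrameOutcome.TP

    def test_both_absent_is_true_negative(self):
        assert classify_frame(self._mask(), None) is FrameOutcome.TN
        assert classify_frame(self._mask(), self._mask()) is FrameOutcome.TN

    def test_zero_overlap_counts_as_fp_and_fn(self):
        pred = self._mask((0, 0))
        ref = self._mask((5, 5))
        assert classify_frame(pred, ref) is FrameOutcome.MISMATCH

    def test_missed_reference_is_false_negative(self):
        assert classify_frame(self._mask(), self._mask((1, 1))) is FrameOutcome.FN

    def test_spurious_prediction_is_false_positive(self):
        assert classify_frame(self._mask((1, 1)), None) is FrameOutcome.FP


class TestConfusionMatrix:
    def test_all_true_negative(self):
        c = confusion_matrix([FrameOutcome.TN] * 10)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 10)

    def test_scripted_frames_match_hand_tally(self):
        outcomes = [
            FrameOutcome.TP,
            FrameOutcome.TP,
            FrameOutcome.FP,
            FrameOutcome.FN,
            FrameOutcome.TN,
            FrameOutcome.TN,
            FrameOutcome.MISMATCH,  # one FP and one FN
            FrameOutcome.TP,
        ]
        c = confusion_matrix(outcomes)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 2, 2, 2)
        assert c.mismatches == 1
        assert c.n_frames == 8
        assert c.tp + c.fp + c.fn + c.tn == c.n_frames + c.mismatches

    def test_permutation_invariant(self, rng):
        outcomes = [FrameOutcome.TP] * 3 + [FrameOutcome.FP] * 2 + [FrameOutcome.TN] * 5
        shuffled = list(outcomes)
        rng.shuffle(shuffled)
        a, b = confusion_matrix(outcomes), confusion_matrix(shuffled)
        assert (a.tp, a.fp, a.fn, a.tn) == (b.tp, b.fp, b.fn, b.tn)


class TestDetectionMetrics:
    @pytest.mark.parametrize(
        "split, expected",
        [
            ("train", (0.955, 0.898, 0.925)),
            ("validation", (0.500, 0.588, 0.541)),
            ("test", (0.706, 0.571, 0.632)),
        ],
    )
    def test_reproduces_study_precision_recall_f1(self, split, expected):
        """The published per-split detection metrics follow from the counts."""
        counts = corpus.detection_counts(split)
        m = detection_metrics(ConfusionCounts(tp=counts["tp"], fp=counts["fp"], fn=counts["fn"]))
        assert round(m.precision, 3) == expected[0]
        assert round(m.recall, 3) == expected[1]
        assert round(m.f1, 3) == expected[2]

    def test_degenerate_counts_flagged_undefined(self):
        m = detection_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=5))
        assert m.precision is None
        assert m.recall is None
        assert m.f1 is None

    def test_f1_equals_harmonic_mean_form(self):
        c = ConfusionCounts(tp=7, fp=3, fn=2)
        m = detection_metrics(c)
        harmonic = 2 / (1 / m.recall + 1 / m.precision)
        assert m.f1 == pytest.approx(harmonic)


class TestFpFrameRate:
    def test_all_empty_predictions(self):
        masks = [np.zeros((4, 4), dtype=bool)] * 5
        assert fp_glottis_frame_rate(masks) == 0.0

    def test_one_in_twenty(self):
        masks = [np.zeros((4, 4), dtype=bool) for _ in range(20)]
        masks[3][1, 1] = True
        assert fp_glottis_frame_rate(masks) == pytest.approx(0.05)

    def test_rate_ignores_false_region_size(self):
        small = np.zeros((32, 32), dtype=bool)
        small[0, 0] = True
        big = np.ones((32, 32), dtype=bool)
        assert fp_glottis_frame_rate([small]) == fp_glottis_frame_rate([big]) == 1.0

    def test_visible_frame_in_input_rejected(self):
        with pytest.raises(ValueError):
            fp_glottis_frame_rate([np.zeros((2, 2), dtype=bool)], glottis_visible=[True])


class TestSpearman:
    def test_monotone_pairs(self):
        pairs = [(10, 0.1), (20, 0.2), (30, 0.5), (40, 0.9)]
        assert spearman_size_dice(pairs).rho == pytest.approx(1.0)
        rev = [(s, 1 - d) for s, d in pairs]
        assert spearman_size_dice(rev).rho == pytest.approx(-1.0)

    def test_tie_handling_matches_manual_rank_computation(self):
        # sizes have one tie (20, 20): average ranks 1, 2.5, 2.5, 4, 5, 6
        pairs = [(10, 0.3), (20, 0.1), (20, 0.4), (30, 0.2), (40, 0.6), (50, 0.5)]
        size_ranks = np.array([1, 2.5, 2.5, 4, 5, 6])
        dice_ranks = np.array([3, 1, 4, 2, 6, 5])
        manual_rho = np.corrcoef(size_ranks, dice_ranks)[0, 1]
        assert spearman_size_dice(pairs).rho == pytest.approx(manual_rho, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_size_dice([(1, 0.5), (2, 0.6)])


class TestReportExports:
    def test_plots_and_report_written(self, tmp_path, rng):
        from fees_xai.metrics import (
            export_report,
            plot_confusion_heatmap,
            plot_dice_boxplot,
            plot_size_dice_scatter,
        )

        counts = ConfusionCounts(tp=3, fp=1, fn=2, tn=4, n_frames=10)
        import pandas as pd

        frame_table = pd.DataFrame({"frame_index": [0, 1], "dice_glottis_roi": [0.9, 0.8]})
        paths = export_report(frame_table, counts, tmp_path)
        assert paths["csv"].exists() and paths["json"].exists()
        assert plot_confusion_heatmap(counts, tmp_path / "cm.png").exists()
        assert plot_dice_boxplot({"glottis_roi": [0.9, 0.95], "aspiration": [0.2]}, tmp_path / "box.png").exists()
        pairs = [(int(s), float(d)) for s, d in zip(rng.integers(1, 500, 10), rng.random(10))]
        assert plot_size_dice_scatter(pairs, tmp_path / "scatter.png").exists()


class TestCorpusArithmetic:
    def test_frames_not_showing_glottis_total(self):
        df = corpus.frame_distribution()
        assert int(df["not_showing_glottis"].sum()) == 2895

    def test_split_fractions_match_video_counts(self):
        counts = corpus.SPLIT_VIDEO_COUNTS
        assert sum(counts.values()) == corpus.N_VIDEOS
        assert round(100 * counts["train"] / corpus.N_VIDEOS, 1) == 77.2
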