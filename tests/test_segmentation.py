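"""Histogram thresholding, morphological lung extraction, ROI splitting."""

import numpy as np
import pytest

import lungcad as lc
from lungcad.segmentation import HUHistogram


def dice(a: np.ndarray, b: np.ndarray) -> float:
    return 2.0 * np.sum(a & b) / (a.sum() + b.sum())


def synthetic_histogram(peaks_hu: dict[float, int], bin_width: float = 10.0) -> HUHistogram:
    """Hand-built histogram: a few HU positions with given counts, low floor."""
    lo = min(peaks_hu) - 200
    hi = max(peaks_hu) + 200
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts = np.full(len(edges) - 1, 2, dtype=np.int64)
    centers = (edges[:-1] + edges[1:]) / 2
    for hu, count in peaks_hu.items():
        counts[np.argmin(np.abs(centers - hu))] = count
    return HUHistogram(bin_edges=edges, counts=counts, bin_width=bin_width)


class TestComputeHistogram:
    def test_counts_conserve_pixels(self):
        image = lc.CTImage(np.array([[-3024.0, -3024.0], [-700.0, -50.0]]))
        hist = lc.compute_histogram(image, bin_width=10)
        assert hist.counts.sum() == 4

    def test_constant_image_single_bin(self):
        hist = lc.compute_histogram(lc.CTImage(np.full((8, 8), -500.0)))
        assert np.count_nonzero(hist.counts) == 1

    def test_phantom_modes_near_spec_levels(self, filtered_phantom, phantom):
        hist = lc.compute_histogram(filtered_phantom)
        peaks = lc.find_peaks(hist)
        spec = phantom.spec
        assert abs(peaks.lung_peak_hu - spec.hu_lung) <= hist.bin_width
        assert abs(peaks.background_spike_hu - spec.hu_background) <= hist.bin_width
        assert any(abs(f - spec.hu_fat_muscle) <= hist.bin_width for f in peaks.fat_muscle_peaks_hu)

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError):
            lc.compute_histogram(lc.CTImage(np.zeros((4, 4))), bin_width=0)


class TestFindPeaks:
    def test_two_fat_peaks_detected(self):
        hist = synthetic_histogram({-3024: 5000, -700: 800, -60: 900, -40: 950})
        peaks = lc.find_peaks(hist)
        assert peaks.fat_muscle_peaks_hu == pytest.approx([-60, -40], abs=6)
        assert peaks.lung_peak_hu == pytest.approx(-700, abs=6)

    def test_no_lung_band_peak_is_error(self):
        rng = np.random.default_rng(0)
        image = lc.CTImage(rng.uniform(0, 100, size=(64, 64)))
        with pytest.raises(lc.SegmentationError):
            lc.find_peaks(lc.compute_histogram(image))

    def test_peak_ordering_invariant(self, segmented_phantom):
        p = segmented_phantom["peaks"]
        assert p.background_spike_hu < p.lung_peak_hu < min(p.fat_muscle_peaks_hu)


class TestComputeThreshold:
    @pytest.mark.parametrize("lung,fat,expected", [
        (-900, [-100], -500.0),
        (-700, [-60, -40], -375.0),
    ])
    def test_midpoint_formula(self, lung, fat, expected):
        peaks = lc.HistogramPeaks(
            lung_peak_hu=lung, fat_muscle_peaks_hu=fat, background_spike_hu=-3024
        )
        assert lc.compute_threshold(peaks) == pytest.approx(expected)

    def test_threshold_strictly_between_peaks(self, segmented_phantom):
        p = segmented_phantom["peaks"]
        t = segmented_phantom["threshold"]
        assert p.lung_peak_hu < t < float(np.mean(p.fat_muscle_peaks_hu))

    def test_degenerate_coincident_peaks_warns(self, caplog):
        peaks = lc.HistogramPeaks(
            lung_peak_hu=-100, fat_muscle_peaks_hu=[-100], background_spike_hu=-3024
        )
        with caplog.at_level("WARNING", logger="lungcad"):
            assert lc.compute_threshold(peaks) == -100
        assert any("degenerate" in r.message for r in caplog.records)

    def test_no_fat_peaks_is_error(self):
        peaks = lc.HistogramPeaks(
            lung_peak_hu=-700, fat_muscle_peaks_hu=[], background_spike_hu=-3024
        )
        with pytest.raises(lc.SegmentationError):
            lc.compute_threshold(peaks)


class TestSegmentThorax:
    def test_phantom_thorax_dice(self, filtered_phantom, segmented_phantom, phantom):
        expected = phantom.thorax_mask.as_bool() & ~phantom.lung_mask.as_bool()
        got = segmented_phantom["thorax"].as_bool()
        assert dice(got, expected) >= 0.95

    def test_all_background_is_error(self):
        image = lc.CTImage(np.full((32, 32), -3024.0))
        with pytest.raises(lc.SegmentationError):
            lc.segment_thorax(image, -375.0)

    def test_largest_component_kept(self):
        pixels = np.full((40, 40), -3024.0)
        pixels[2:4, 2:4] = 0.0       # small blob (scanner table)
        pixels[10:30, 10:30] = 0.0   # 100x larger blob (body)
        mask = lc.segment_thorax(lc.CTImage(pixels), -375.0).as_bool()
        assert mask[15, 15] and not mask[2, 2]


class TestSegmentLungs:
    def test_annulus_yields_central_disc(self):
        rr, cc = np.ogrid[:64, :64]
        r = np.hypot(rr - 32, cc - 32)
        annulus = lc.BinaryMask((r < 28) & (r > 14))
        lungs = lc.segment_lungs(annulus, min_area_frac=0.001).as_bool()
        assert lungs[32, 32]
        assert not lungs[1, 1]

    def test_solid_disc_is_error(self):
        rr, cc = np.ogrid[:64, :64]
        disc = lc.BinaryMask(np.hypot(rr - 32, cc - 32) < 20)
        with pytest.raises(lc.SegmentationError):
            lc.segment_lungs(disc)

    def test_phantom_lungs_dice(self, segmented_phantom, phantom):
        assert dice(segmented_phantom["lungs"].as_bool(), phantom.lung_mask.as_bool()) >= 0.95

    def test_small_specks_removed(self):
        rr, cc = np.ogrid[:128, :128]
        thorax = ((np.hypot(rr - 64, cc - 40) < 30) | (np.hypot(rr - 64, cc - 90) < 30)).astype(bool)
        thorax &= ~(np.hypot(rr - 64, cc - 40) < 15)  # real cavity
        thorax[60:62, 88:90] = False  # 4-pixel speck
        lungs = lc.segment_lungs(lc.BinaryMask(thorax), min_area_frac=0.005)
        labels_n = __import__("scipy.ndimage", fromlist=["label"]).label(lungs.as_bool())[1]
        assert labels_n == 1


class TestSplitLungs:
    def test_phantom_rois_partition_lungs(self, segmented_phantom, phantom):
        left, right = segmented_phantom["left"], segmented_phantom["right"]
        total = left.mask.count() + right.mask.count()
        assert total == segmented_phantom["lungs"].count()
        # side convention: patient-left lung sits at larger columns
        assert left.bbox[2] > right.bbox[2]
        # each ROI overwhelmingly overlaps its own truth side
        lt = phantom.left_mask.as_bool()
        r0, r1, c0, c1 = left.bbox
        assert dice(left.mask.as_bool(), lt[r0:r1, c0:c1]) >= 0.95

    def test_mirror_symmetric_phantom_mirror_bboxes(self):
        size = 256
        spec = lc.PhantomSpec(
            image_size=size,
            thorax_ellipse=lc.Ellipse(center=(128, 127.5), axes=(80, 100)),
            lung_ellipses={
                "right": lc.Ellipse(center=(128, 77.5), axes=(48, 32)),
                "left": lc.Ellipse(center=(128, 177.5), axes=(48, 32)),
            },
            lung_texture_sd=0.0,
            noise_sd=0.0,
            seed=0,
        )
        truth = lc.make_phantom(spec)
        seg = lc.segment_slice(truth.image)
        l, r = seg["left"], seg["right"]
        assert (l.bbox[0], l.bbox[1]) == (r.bbox[0], r.bbox[1])
        assert l.bbox[2] == size - r.bbox[3]
        assert l.bbox[3] == size - r.bbox[2]

    def test_merged_component_split_at_midline(self, caplog):
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[20:40, 10:54] = 1  # single bar spanning the midline
        mask[20:40, 30:34] = 1
        image = lc.CTImage(np.zeros((64, 64)))
        with caplog.at_level("WARNING", logger="lungcad"):
            left, right = lc.split_lungs(lc.BinaryMask(mask), image)
        assert left.mask.count() > 0 and right.mask.count() > 0
        assert any("merged" in r.message for r in caplog.records)

    def test_empty_mask_is_error(self):
        with pytest.raises(lc.SegmentationError):
            lc.split_lungs(lc.BinaryMask(np.zeros((32, 32), dtype=np.uint8)),
                           lc.CTImage(np.zeros((32, 32))))


def test_pipeline_determinism(filtered_phantom):
    a = lc.segment_slice(filtered_phantom)
    b = lc.segment_slice(filtered_phantom)
    assert np.array_equal(a["lungs"].values, b["lungs"].values)
    assert a["threshold"] == b["threshold"]
    assert a["left"].bbox == b["left"].bbox
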