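"""Histogram-threshold lung segmentation and left/right ROI extraction.

A chest CT histogram has a background spike near -3024 HU (scanner
padding), a lung-parenchyma peak (roughly -910..-500 HU), and one or two
fat/muscle/mediastinum peaks above -500 HU.  The threshold

    T = (I_FM - I_L) / 2 + I_L

(midpoint between the lung peak I_L and the mean fat/muscle peak I_FM)
binarizes the slice; the largest connected component above T is the thorax,
hole-filling minus the thorax recovers the lung cavities, and each cavity
becomes one rectangular ROI.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage, signal

from .io import BinaryMask, CTImage, SegmentationError

logger = logging.getLogger("lungcad")

# Peak-assignment bands (HU). The lung band upper edge sits above the
# -500 HU tissue bound with margin; the background band catches the
# scanner-padding spike.
BACKGROUND_MAX_HU = -2000.0
LUNG_BAND_HU = (-1000.0, -400.0)
FAT_SPLIT_HU = -400.0

PEAK_SMOOTH_BINS = 5
PEAK_PROMINENCE_FRAC = 0.01
MIN_AREA_FRAC = 0.005
ROI_MARGIN = 5


@dataclasses.dataclass
class HUHistogram:
    """Counts of HU values over uniform bins."""

    bin_edges: np.ndarray
    counts: np.ndarray
    bin_width: float

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclasses.dataclass
class HistogramPeaks:
    """Detected histogram modes: lung peak, fat/muscle peaks, background spike."""

    lung_peak_hu: float
    fat_muscle_peaks_hu: list[float]
    background_spike_hu: float

    def __post_init__(self) -> None:
        # equality tolerated for the degenerate coincident-peak case,
        # which compute_threshold flags with a warning
        if self.fat_muscle_peaks_hu and not (
            self.background_spike_hu < self.lung_peak_hu <= min(self.fat_muscle_peaks_hu)
        ):
            raise SegmentationError(
                "peak ordering violated: background < lung < fat/muscle required"
            )


@dataclasses.dataclass
class LungROI:
    """One lung as a rectangular crop of the parent slice.

    ``bbox`` is (row_start, row_stop, col_start, col_stop), 0-based and
    half-open, in parent coordinates.  ``side`` follows radiological
    display: the patient's left lung appears at larger column indices.
    ``label`` is 0 (normal), 1 (cancer), or None when unknown.
    """

    image: CTImage
    mask: BinaryMask
    side: str
    bbox: tuple[int, int, int, int]
    label: int | None = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.image.shape != self.mask.shape:
            raise ValueError("ROI image and mask shapes differ")
        if self.mask.count() == 0:
            raise ValueError("ROI mask is empty")


def compute_histogram(image: CTImage, bin_width: float = 10.0) -> HUHistogram:
    """Histogram of HU values with uniform bins of ``bin_width`` HU."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pixels = image.pixels.ravel()
    lo = np.floor(pixels.min() / bin_width) * bin_width
    hi = np.ceil(pixels.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(pixels, bins=edges)
    return HUHistogram(bin_edges=edges, counts=counts, bin_width=bin_width)


def find_peaks(hist: HUHistogram) -> HistogramPeaks:
    """Locate background spike, lung peak, and fat/muscle peaks.

    Counts are smoothed with a short moving average, then local maxima with
    prominence >= 1% of the largest non-background count are kept.  The
    background spike is the tallest bin below -2000 HU; the lung peak is
    the tallest detected maximum inside the lung band; fat/muscle peaks are
    the (up to) two tallest maxima above -400 HU.
    """
    centers = hist.centers
    counts = hist.counts.astype(float)

    bg_bins = centers < BACKGROUND_MAX_HU
    if not np.any(bg_bins & (hist.counts > 0)):
        raise SegmentationError("no background spike below -2000 HU")
    bg_idx = np.flatnonzero(bg_bins)[np.argmax(counts[bg_bins])]
    background_hu = float(centers[bg_idx])

    kernel = np.ones(PEAK_SMOOTH_BINS) / PEAK_SMOOTH_BINS
    smoothed = np.convolve(counts, kernel, mode="same")
    nonbg = centers >= BACKGROUND_MAX_HU
    if not np.any(nonbg):
        raise SegmentationError("histogram contains only background")
    prominence = PEAK_PROMINENCE_FRAC * smoothed[nonbg].max()
    # zero-pad so modes sitting in the first or last bin are detectable
    peak_idx, _ = signal.find_peaks(
        np.pad(smoothed, 1), prominence=max(prominence, 1e-12)
    )
    peak_idx -= 1
    # snap each smoothed-curve maximum to the raw-count argmax nearby, so
    # reported peak positions are not biased by asymmetric neighborhoods
    half = PEAK_SMOOTH_BINS // 2
    snapped = [
        max(0, i - half) + int(np.argmax(counts[max(0, i - half) : i + half + 1]))
        for i in peak_idx
    ]
    # modes closer together than the smoothing width merge on the smoothed
    # curve; recover them from the raw counts, at a stricter prominence bar
    # so count noise cannot sneak in
    raw_prom = max(prominence, 0.05 * counts[nonbg].max())
    raw_idx, _ = signal.find_peaks(np.pad(counts, 1), prominence=raw_prom)
    raw_idx -= 1
    peak_idx = np.unique(np.concatenate([snapped, raw_idx]).astype(int))

    lung_lo, lung_hi = LUNG_BAND_HU
    lung_candidates = [i for i in peak_idx if lung_lo <= centers[i] <= lung_hi]
    if not lung_candidates:
        raise SegmentationError(
            f"no histogram peak in the lung band [{lung_lo}, {lung_hi}] HU"
        )
    lung_idx = max(lung_candidates, key=lambda i: smoothed[i])
    lung_hu = float(centers[lung_idx])

    fat_candidates = [i for i in peak_idx if centers[i] > FAT_SPLIT_HU]
    fat_candidates = sorted(fat_candidates, key=lambda i: smoothed[i], reverse=True)[:2]
    fat_hu = sorted(float(centers[i]) for i in fat_candidates)

    return HistogramPeaks(
        lung_peak_hu=lung_hu,
        fat_muscle_peaks_hu=fat_hu,
        background_spike_hu=background_hu,
    )


def compute_threshold(peaks: HistogramPeaks) -> float:
    """Midpoint threshold T = (I_FM - I_L)/2 + I_L.

    I_FM is the average of the fat/muscle peak intensities.  T lies
    strictly between I_L and I_FM whenever the peaks are distinct.
    """
    if not peaks.fat_muscle_peaks_hu:
        raise SegmentationError("no fat/muscle peaks: cannot compute threshold")
    i_l = peaks.lung_peak_hu
    i_fm = float(np.mean(peaks.fat_muscle_peaks_hu))
    if i_fm == i_l:
        logger.warning("degenerate histogram: lung and fat/muscle peaks coincide at %g HU", i_l)
    return (i_fm - i_l) / 2.0 + i_l


def segment_thorax(image: CTImage, threshold: float) -> BinaryMask:
    """Binarize at ``threshold`` and keep the largest connected component.

    Pixels above T are body (fat/muscle/mediastinum); the largest component
    is the thorax, discarding the scanner table and other bright artifacts.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    binary = image.pixels > threshold
    if not binary.any():
        raise SegmentationError("no pixels above threshold: empty thorax mask")
    labels, n = ndimage.label(binary)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = 1 + int(np.argmax(sizes))
    return BinaryMask(labels == largest)


def segment_lungs(thorax: BinaryMask, min_area_frac: float = MIN_AREA_FRAC) -> BinaryMask:
    """Recover lung cavities: fill_holes(thorax) minus thorax, cleaned.

    Components smaller than ``min_area_frac`` of the image area (airways,
    noise specks) are dropped.  Exactly one or two components must survive.
    """
    thorax_bool = thorax.as_bool()
    filled = ndimage.binary_fill_holes(thorax_bool)
    cavities = filled & ~thorax_bool
    min_area = int(min_area_frac * cavities.size)
    labels, n = ndimage.label(cavities)
    if n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_area) + 1
        cavities = np.isin(labels, keep)
        n = len(keep)
    if n == 0:
        raise SegmentationError("no lung cavities found inside the thorax")
    if n > 2:
        raise SegmentationError(f"{n} cavities survived cleanup, expected at most 2")
    return BinaryMask(cavities)


def _merged_split_column(mask: np.ndarray) -> int:
    """Column of minimum mask thickness near the image midline."""
    n_cols = mask.shape[1]
    mid = n_cols // 2
    band = max(1, n_cols // 10)
    cols = np.arange(max(0, mid - band), min(n_cols, mid + band))
    thickness = mask[:, cols].sum(axis=0)
    return int(cols[np.argmin(thickness)])


def split_lungs(lungs: BinaryMask, image: CTImage, margin: int = ROI_MARGIN) -> tuple[LungROI, LungROI]:
    """Split the lung mask into left and right ROIs.

    With two components each becomes an ROI.  A single component spanning
    the midline is split at the column of minimum thickness near the
    midline (merged-anterior-junction fallback, logged).  Side follows
    radiological display: larger centroid column = patient-left lung.
    Returns ``(left_roi, right_roi)``.
    """
    mask = lungs.as_bool()
    if lungs.shape != image.shape:
        raise ValueError("lung mask and image shapes differ")
    labels, n = ndimage.label(mask)
    if n == 0:
        raise SegmentationError("empty lung mask: nothing to split")
    if n == 1:
        cols = np.flatnonzero(mask.any(axis=0))
        mid = mask.shape[1] // 2
        if cols.min() >= mid or cols.max() < mid:
            raise SegmentationError("single lung component does not span the midline")
        split_col = _merged_split_column(mask)
        logger.warning("merged lung component: splitting at column %d", split_col)
        labels = labels.copy()
        labels[:, split_col:][labels[:, split_col:] == 1] = 2
        if not (labels == 1).any() or not (labels == 2).any():
            raise SegmentationError("midline split produced an empty lung half")
        n = 2
    if n > 2:
        raise SegmentationError(f"expected at most 2 lung components, got {n}")

    rois = []
    for lab in (1, 2):
        comp = labels == lab
        rows = np.flatnonzero(comp.any(axis=1))
        cols = np.flatnonzero(comp.any(axis=0))
        r0 = max(0, rows.min() - margin)
        r1 = min(comp.shape[0], rows.max() + 1 + margin)
        c0 = max(0, cols.min() - margin)
        c1 = min(comp.shape[1], cols.max() + 1 + margin)
        roi = LungROI(
            image=CTImage(image.pixels[r0:r1, c0:c1], source_id=image.source_id),
            mask=BinaryMask(comp[r0:r1, c0:c1]),
            side="right",  # reassigned below
            bbox=(int(r0), int(r1), int(c0), int(c1)),
        )
        centroid_col = float(np.nonzero(comp)[1].mean())
        rois.append((centroid_col, roi))

    rois.sort(key=lambda t: t[0])
    right_roi, left_roi = rois[0][1], rois[1][1]
    right_roi.side = "right"
    left_roi.side = "left"
    return left_roi, right_roi


def segment_slice(
    image: CTImage,
    bin_width: float = 10.0,
    min_area_frac: float = MIN_AREA_FRAC,
    margin: int = ROI_MARGIN,
) -> dict:
    """Full segmentation of one (already filtered) slice.

    Returns a dict with the histogram, peaks, threshold, thorax and lung
    masks, and the (left, right) ROI pair.
    """
    hist = compute_histogram(image, bin_width=bin_width)
    peaks = find_peaks(hist)
    threshold = compute_threshold(peaks)
    thorax = segment_thorax(image, threshold)
    lungs = segment_lungs(thorax, min_area_frac=min_area_frac)
    left, right = split_lungs(lungs, image, margin=margin)
    return {
        "histogram": hist,
        "peaks": peaks,
        "threshold": threshold,
        "thorax": thorax,
        "lungs": lungs,
        "left": left,
        "right": right,
    }
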