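"""Histogram feature vectors from AM-FM estimates.

Per scale combination, the masked-pixel distributions of IA, |IF|, and IP
are summarized as three 32-bin histograms (96 values), each normalized to
unit mass.  IA bins span [0, masked max] (adaptive, contrast-invariant in
shape); |IF| bins span [0, pi] rad/pixel; IP bins span (-pi, pi] and are
circularly rotated so the modal bin sits at the center index.  The 11
combinations concatenate to the 1056-value per-image feature row.
"""

from __future__ import annotations

import numpy as np

from .amfm import (
    SCALE_COMBINATIONS,
    AMFMEstimates,
    Filterbank,
    ScaleCombination,
    build_filterbank,
    demodulate_all,
    dominant_component,
)
from .io import BinaryMask, FeatureMatrix
from .segmentation import LungROI

N_BINS = 32
N_BLOCKS = 3  # IA, |IF|, IP
VECTOR_LENGTH = N_BINS * N_BLOCKS  # 96
ROW_LENGTH = VECTOR_LENGTH * len(SCALE_COMBINATIONS)  # 1056
IP_CENTER_BIN = N_BINS // 2


def _normalized_hist(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    counts, _ = np.histogram(values, bins=N_BINS, range=(lo, hi))
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def histogram_features(
    est: AMFMEstimates, mask: BinaryMask, combo_id: int
) -> np.ndarray:
    """96-value feature vector (32 IA + 32 |IF| + 32 IP bins) for one combination."""
    if est.ia.shape != mask.shape:
        raise ValueError("estimates and mask shapes differ")
    m = mask.as_bool()
    if not m.any():
        raise ValueError("mask selects no pixels")
    if not 1 <= combo_id <= len(SCALE_COMBINATIONS):
        raise ValueError(f"combo_id must be 1..{len(SCALE_COMBINATIONS)}")

    ia = est.ia[m]
    if_mag = np.clip(est.if_mag[m], 0.0, np.pi)
    ip = est.ip[m]

    ia_hi = float(ia.max())
    ia_block = _normalized_hist(ia, 0.0, ia_hi if ia_hi > 0 else 1.0)
    if_block = _normalized_hist(if_mag, 0.0, np.pi)
    ip_counts, _ = np.histogram(ip, bins=N_BINS, range=(-np.pi, np.pi))
    # rotate so the modal bin lands at the center index
    ip_counts = np.roll(ip_counts, IP_CENTER_BIN - int(np.argmax(ip_counts)))
    total = ip_counts.sum()
    ip_block = ip_counts / total if total else ip_counts.astype(float)

    return np.concatenate([ia_block, if_block, ip_block])


def image_features(
    roi: LungROI,
    filterbank: Filterbank | None = None,
    combos: tuple[ScaleCombination, ...] = SCALE_COMBINATIONS,
) -> np.ndarray:
    """1056-value feature row for one lung ROI.

    The 25 channels are demodulated once on the ROI rectangle; per
    combination, dominant component analysis composes the competing
    channels and the masked-pixel histograms are concatenated in
    combination-id order.
    """
    if filterbank is None:
        filterbank = build_filterbank(roi.image.shape)
    elif filterbank.shape != roi.image.shape:
        raise ValueError("filterbank shape does not match ROI shape")
    channels = demodulate_all(roi.image.pixels, filterbank)
    blocks = []
    for combo in combos:
        dom = dominant_component(channels, filterbank, combo)
        blocks.append(histogram_features(dom, roi.mask, combo.id))
    return np.concatenate(blocks)


def feature_names(combos: tuple[ScaleCombination, ...] = SCALE_COMBINATIONS) -> list[str]:
    """Column names in the fixed combination-then-bin order of the CSV layout."""
    names = []
    for combo in combos:
        for block in ("ia", "ifmag", "ip"):
            names.extend(f"c{combo.id:02d}_{block}_{b:02d}" for b in range(N_BINS))
    return names


def extract_feature_matrix(rois: list[LungROI]) -> FeatureMatrix:
    """Stack per-ROI feature rows into a labelled FeatureMatrix.

    Every ROI must carry a 0/1 label; ids are ``<source_id>_<side>``.
    """
    if not rois:
        raise ValueError("no ROIs given")
    rows, labels, ids = [], [], []
    for roi in rois:
        if roi.label is None:
            raise ValueError(f"ROI {roi.image.source_id}/{roi.side} has no label")
        rows.append(image_features(roi))
        labels.append(roi.label)
        ids.append(f"{roi.image.source_id}_{roi.side}")
    return FeatureMatrix(
        values=np.vstack(rows),
        labels=np.asarray(labels),
        ids=ids,
        column_names=feature_names(),
    )
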