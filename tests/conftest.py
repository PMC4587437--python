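"""Shared fixtures: in-memory phantoms, segmentations, and DICOM writers."""

from __future__ import annotations

import numpy as np
import pydicom
import pytest
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

import lungcad as lc


def write_test_dicom(
    path,
    pixels: np.ndarray,
    slope: float | None = 1.0,
    intercept: float | None = 0.0,
    n_frames: int | None = None,
) -> None:
    """Write a minimal single-frame CT DICOM for fixture use."""
    pixels = np.asarray(pixels, dtype=np.int16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = pixels.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    if slope is not None:
        ds.RescaleSlope = slope
    if intercept is not None:
        ds.RescaleIntercept = intercept
    if n_frames is not None:
        ds.NumberOfFrames = n_frames
    ds.PixelData = pixels.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


@pytest.fixture(scope="session")
def phantom() -> lc.PhantomTruth:
    return lc.make_phantom(lc.PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def filtered_phantom(phantom) -> lc.CTImage:
    return lc.wiener_filter(phantom.image)


@pytest.fixture(scope="session")
def segmented_phantom(filtered_phantom) -> dict:
    return lc.segment_slice(filtered_phantom)


@pytest.fixture(scope="session")
def small_roi(segmented_phantom) -> lc.LungROI:
    """A 64x64 crop of a segmented lung, for fast feature-geometry checks."""
    roi = segmented_phantom["left"]
    mask = roi.mask.values[:64, :64]
    if mask.sum() == 0:  # pragma: no cover - geometry guard
        mask = roi.mask.values[-64:, -64:]
    return lc.LungROI(
        image=lc.CTImage(roi.image.pixels[:64, :64], source_id="crop64"),
        mask=lc.BinaryMask(mask),
        side=roi.side,
        bbox=(0, 64, 0, 64),
        label=0,
    )


@pytest.fixture(scope="session")
def phantom_features() -> lc.FeatureMatrix:
    """Feature matrix of the 20-per-class jittered phantom suite (n=40 ROIs)."""
    from lungcad.pipeline import PipelineConfig, extract_rois

    phantoms = lc.make_dataset(20, seed=7)
    rois = extract_rois([(p.image, p.labels) for p in phantoms], PipelineConfig(seed=7))
    return lc.extract_feature_matrix(rois)
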