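"""Core data containers and file I/O.

Hounsfield-unit CT slices come in as single-frame DICOM; binary masks go
out as 8-bit grayscale PNG (0 = background, 255 = foreground); feature
matrices round-trip through CSV; evaluation reports are JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pydicom
from pydicom.errors import InvalidDicomError
from PIL import Image

logger = logging.getLogger("lungcad")


class LungCADError(Exception):
    """Base class for pipeline errors."""


class FormatError(LungCADError):
    """Malformed or unsupported input file."""


class SegmentationError(LungCADError):
    """Lung segmentation could not produce a valid result."""


@dataclasses.dataclass
class CTImage:
    """A 2D CT slice in Hounsfield units.

    Parameters
    ----------
    pixels
        2D array of finite HU values.
    source_id
        Identifier of the originating file or phantom.
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"CTImage requires a 2D array, got ndim={self.pixels.ndim}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("CTImage pixels must be finite")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclasses.dataclass
class BinaryMask:
    """A {0,1} mask with the same shape as its parent image."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("BinaryMask requires a 2D array")
        if values.dtype == bool:
            values = values.astype(np.uint8)
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("BinaryMask values must be 0 or 1")
        self.values = values.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def as_bool(self) -> np.ndarray:
        return self.values.astype(bool)

    def count(self) -> int:
        return int(self.values.sum())


@dataclasses.dataclass
class FeatureMatrix:
    """Per-image feature rows with aligned labels and identifiers.

    The full pipeline produces 1056 columns per row (11 scale combinations
    x 96 histogram bins), but the container itself is size-agnostic so that
    reduced matrices and small fixtures use the same type.
    """

    values: np.ndarray
    labels: np.ndarray
    ids: list[str]
    column_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.size == 0:
            self.values = self.values.reshape(0, self.values.shape[-1] if self.values.ndim == 2 else 0)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.ids = [str(i) for i in self.ids]
        n = self.values.shape[0]
        if len(self.labels) != n or len(self.ids) != n:
            raise ValueError("labels and ids must align with feature rows")
        if n and not np.all(np.isin(self.labels, [0, 1])):
            raise ValueError("labels must be 0 (normal) or 1 (cancer)")
        if self.column_names is not None and len(self.column_names) != self.values.shape[1]:
            raise ValueError("column_names must match the number of feature columns")

    @property
    def n_images(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def read_ct_dicom(path: str | Path) -> CTImage:
    """Read a single-frame DICOM CT slice and rescale stored values to HU.

    HU = stored_value * RescaleSlope + RescaleIntercept.  Missing rescale
    tags default to slope 1 / intercept 0 with a logged warning so that
    hand-built fixtures load.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        ds = pydicom.dcmread(path)
    except (InvalidDicomError, ValueError) as exc:
        raise FormatError(f"{path} is not a readable DICOM file: {exc}") from exc
    if int(getattr(ds, "NumberOfFrames", 1) or 1) > 1:
        raise FormatError(f"{path}: multi-frame DICOM is not supported")
    if "PixelData" not in ds:
        raise FormatError(f"{path}: DICOM file has no pixel data")
    try:
        stored = ds.pixel_array
    except Exception as exc:  # undecodable pixel data
        raise FormatError(f"{path}: cannot decode pixel data: {exc}") from exc
    if stored.ndim != 2:
        raise FormatError(f"{path}: expected a single 2D frame, got shape {stored.shape}")
    slope = getattr(ds, "RescaleSlope", None)
    intercept = getattr(ds, "RescaleIntercept", None)
    if slope is None or intercept is None:
        logger.warning("%s: missing RescaleSlope/Intercept, defaulting to 1/0", path.name)
        slope = 1.0 if slope is None else slope
        intercept = 0.0 if intercept is None else intercept
    declared = (int(getattr(ds, "Rows", stored.shape[0])), int(getattr(ds, "Columns", stored.shape[1])))
    if stored.shape != declared:
        raise FormatError(f"{path}: pixel array shape {stored.shape} != declared {declared}")
    hu = stored.astype(np.float64) * float(slope) + float(intercept)
    return CTImage(pixels=hu, source_id=path.stem)


# ---------------------------------------------------------------------------
# Mask PNG
# ---------------------------------------------------------------------------

def write_mask_png(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as 8-bit grayscale PNG (0 background, 255 foreground)."""
    img = Image.fromarray((mask.values * 255).astype(np.uint8), mode="L")
    img.save(Path(path), format="PNG")


def read_mask_png(path: str | Path) -> BinaryMask:
    """Read a grayscale PNG as a binary mask, thresholding at 128."""
    with Image.open(Path(path)) as img:
        arr = np.asarray(img.convert("L"))
    return BinaryMask((arr >= 128).astype(np.uint8))


# ---------------------------------------------------------------------------
# Feature CSV
# ---------------------------------------------------------------------------

_ID_COL = "image_id"
_LABEL_COL = "label"


def write_feature_csv(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as CSV: image_id, label, then feature columns."""
    names = matrix.column_names or [f"f{i:04d}" for i in range(matrix.n_features)]
    df = pd.DataFrame(matrix.values, columns=names)
    df.insert(0, _LABEL_COL, matrix.labels)
    df.insert(0, _ID_COL, matrix.ids)
    df.to_csv(Path(path), index=False, float_format="%.17g")


def read_feature_csv(path: str | Path) -> FeatureMatrix:
    """Read a feature CSV written by :func:`write_feature_csv`."""
    try:
        df = pd.read_csv(Path(path))
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed CSV: {exc}") from exc
    if list(df.columns[:2]) != [_ID_COL, _LABEL_COL]:
        raise FormatError(f"{path}: first columns must be '{_ID_COL}', '{_LABEL_COL}'")
    feat = df.iloc[:, 2:]
    if len(df) and (df[_LABEL_COL].isna().any() or feat.isna().any().any()):
        raise FormatError(f"{path}: missing values (short row?)")
    labels = df[_LABEL_COL].to_numpy(dtype=np.int64) if len(df) else np.empty(0, dtype=np.int64)
    values = feat.to_numpy(dtype=np.float64) if len(df) else np.empty((0, feat.shape[1]))
    return FeatureMatrix(
        values=values,
        labels=labels,
        ids=df[_ID_COL].astype(str).tolist(),
        column_names=list(feat.columns),
    )


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_json_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
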