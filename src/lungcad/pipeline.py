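"""End-to-end orchestration: preprocess -> segment -> split -> AM-FM
features -> PLSR -> classify, with config, logging, and reproducible seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import __version__
from .classify import CLASSIFIER_KINDS, EvalReport, leave_m_out_cv
from .features import extract_feature_matrix, feature_names
from .io import (
    CTImage,
    FeatureMatrix,
    FormatError,
    LungCADError,
    read_ct_dicom,
    write_feature_csv,
    write_json_report,
    write_mask_png,
)
from .preprocess import WienerConfig, wiener_filter
from .segmentation import MIN_AREA_FRAC, ROI_MARGIN, segment_slice
from .synthetic import PhantomSpec, PhantomTruth, make_dataset

logger = logging.getLogger("lungcad")

# uint16 PNG fixture dialect: stored = HU - PNG_HU_INTERCEPT
PNG_HU_INTERCEPT = -4096.0


@dataclasses.dataclass
class PipelineConfig:
    """Every stage's tunables under one flat, namespaced key scheme."""

    wiener_window: tuple[int, int] = (3, 3)
    wiener_noise_variance: float | str = "estimate"
    hist_bin_width: float = 10.0
    min_area_frac: float = MIN_AREA_FRAC
    roi_margin: int = ROI_MARGIN
    plsr_threshold: float = 0.90
    plsr_max_factors: int | None = 20
    knn_k: int = 5
    svm_c: float = 1.0
    cv_test_fraction: float = 0.4
    cv_m: int | None = None
    cv_repeats: int = 50
    seed: int = 0
    version: str = "1"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "wiener_window" in data:
            data["wiener_window"] = tuple(data["wiener_window"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["wiener_window"] = list(self.wiener_window)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def classifier_params(self) -> dict:
        return {"knn": {"k": self.knn_k}, "svm": {"C": self.svm_c}}


# ---------------------------------------------------------------------------
# Input loading
# ---------------------------------------------------------------------------

def _read_png_hu(path: Path) -> CTImage:
    """Read a uint16 PNG written by the synth fixture writer.

    The JSON sidecar ``<stem>.json`` supplies the affine rescale back to HU
    (mirroring DICOM slope/intercept); 8-bit PNG cannot carry HU directly.
    """
    sidecar = path.with_suffix(".json")
    slope, intercept = 1.0, PNG_HU_INTERCEPT
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        slope = float(meta.get("rescale_slope", 1.0))
        intercept = float(meta.get("rescale_intercept", PNG_HU_INTERCEPT))
    else:
        logger.warning("%s: no JSON sidecar, assuming default rescale", path.name)
    with Image.open(path) as img:
        arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel image")
    return CTImage(arr * slope + intercept, source_id=path.stem)


def _load_labels(path: Path) -> dict[str, int] | None:
    meta_path = path.with_suffix(".json")
    if not meta_path.exists():
        return None
    meta = json.loads(meta_path.read_text())
    if "label_left" in meta and "label_right" in meta:
        return {"left": int(meta["label_left"]), "right": int(meta["label_right"])}
    return None


def load_input_images(input_dir: str | Path) -> list[tuple[CTImage, dict[str, int] | None]]:
    """Load every DICOM/PNG slice in a directory with optional side labels."""
    input_dir = Path(input_dir)
    pairs = []
    for path in sorted(input_dir.iterdir()):
        if path.suffix.lower() in (".dcm", ".dicom"):
            pairs.append((read_ct_dicom(path), _load_labels(path)))
        elif path.suffix.lower() == ".png" and not path.stem.endswith("_mask"):
            pairs.append((_read_png_hu(path), _load_labels(path)))
    if not pairs:
        raise FormatError(f"no DICOM or PNG images found in {input_dir}")
    return pairs


# ---------------------------------------------------------------------------
# Fixture writing (synth subcommand)
# ---------------------------------------------------------------------------

def write_phantom_fixture(truth: PhantomTruth, out_dir: str | Path) -> None:
    """Write one phantom as uint16 PNG + JSON truth + mask PNGs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = truth.image.source_id
    stored = np.clip(truth.image.pixels - PNG_HU_INTERCEPT, 0, 65535)
    Image.fromarray(stored.astype(np.uint16)).save(out_dir / f"{stem}.png")
    meta = {
        "rescale_slope": 1.0,
        "rescale_intercept": PNG_HU_INTERCEPT,
        "label_left": truth.labels["left"],
        "label_right": truth.labels["right"],
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(meta, indent=2) + "\n")
    for name in ("thorax_mask", "lung_mask", "left_mask", "right_mask"):
        write_mask_png(getattr(truth, name), out_dir / f"{stem}_{name}.png")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _process_slice(image: CTImage, labels: dict[str, int] | None, config: PipelineConfig):
    """Filter and segment one slice; returns (left ROI, right ROI, seg dict)."""
    t0 = time.perf_counter()
    filtered = wiener_filter(
        image, WienerConfig(config.wiener_window, config.wiener_noise_variance)
    )
    seg = segment_slice(
        filtered,
        bin_width=config.hist_bin_width,
        min_area_frac=config.min_area_frac,
        margin=config.roi_margin,
    )
    left, right = seg["left"], seg["right"]
    if labels is not None:
        left.label = labels["left"]
        right.label = labels["right"]
    logger.info(
        "segment id=%s T=%.1f HU elapsed=%.2fs",
        image.source_id,
        seg["threshold"],
        time.perf_counter() - t0,
    )
    return left, right, seg


def extract_rois(
    images: list[tuple[CTImage, dict[str, int] | None]],
    config: PipelineConfig,
    out_dir: Path | None = None,
) -> list:
    """Segment every slice into labelled lung ROIs (stage errors name the image)."""
    rois = []
    for image, labels in images:
        try:
            left, right, seg = _process_slice(image, labels, config)
        except LungCADError as exc:
            raise LungCADError(f"segmentation failed for {image.source_id}: {exc}") from exc
        if out_dir is not None:
            write_mask_png(seg["lungs"], out_dir / f"{image.source_id}_lungs.png")
        rois.extend([left, right])
    return rois


def run_pipeline(
    inputs: str | Path | list,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    evaluate: bool = True,
) -> tuple[EvalReport | None, FeatureMatrix]:
    """Run the five-stage CAD pipeline.

    ``inputs`` is a directory of DICOM/PNG slices (JSON sidecars carry the
    per-side labels) or a pre-loaded list of (CTImage, labels) pairs.
    With ``evaluate=True`` the reduced features go through leave-M-out CV
    over the four classifiers; feature-only mode stops after the CSV.
    Intermediates (masks, feature CSV, report JSON, manifest) land in
    ``out_dir`` when given.
    """
    config = config or PipelineConfig()
    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)

    images = load_input_images(inputs) if isinstance(inputs, (str, Path)) else inputs
    rois = extract_rois(images, config, out_path)
    logger.info("extracted %d lung ROIs from %d slices", len(rois), len(images))

    labelled = all(r.label is not None for r in rois)
    if evaluate and not labelled:
        raise ValueError("evaluation mode requires labels for every input image")
    if not labelled:
        for r in rois:
            r.label = 0  # placeholder for feature-only mode
    t0 = time.perf_counter()
    matrix = extract_feature_matrix(rois)
    if not labelled:
        matrix.labels[:] = 0
    logger.info(
        "features: %d rows x %d cols elapsed=%.1fs",
        matrix.n_images,
        matrix.n_features,
        time.perf_counter() - t0,
    )
    if out_path is not None:
        write_feature_csv(matrix, out_path / "features.csv")

    report = None
    if evaluate:
        n = matrix.n_images
        m = config.cv_m if config.cv_m is not None else max(1, round(config.cv_test_fraction * n))
        report = leave_m_out_cv(
            matrix.values,
            matrix.labels,
            m=m,
            n_repeats=config.cv_repeats,
            seed=config.seed,
            kinds=CLASSIFIER_KINDS,
            plsr_threshold=config.plsr_threshold,
            max_factors=config.plsr_max_factors,
            classifier_params=config.classifier_params(),
        )
        logger.info(
            "evaluation M=%d: linear acc %.1f%%",
            m,
            report.per_classifier["linear"].accuracy_mean,
        )
    if out_path is not None:
        manifest = {
            "config": config.to_dict(),
            "config_hash": config.digest(),
            "seed": config.seed,
            "n_images": len(images),
            "n_rois": len(rois),
            "lungcad_version": __version__,
        }
        write_json_report(manifest, out_path / "manifest.json")
        if report is not None:
            write_json_report(report.to_dict(), out_path / "report.json")
    return report, matrix


def demo_synthetic(
    n_per_class: int,
    seed: int = 0,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    base_spec: PhantomSpec | None = None,
) -> tuple[EvalReport, FeatureMatrix]:
    """Self-contained end-to-end run on generated phantoms.

    Generates ``n_per_class`` nodule-bearing phantoms (one cancer and one
    normal lung each) and pushes them through the full pipeline, including
    leave-M-out evaluation at the configured test fraction.
    """
    if n_per_class < 5:
        raise ValueError("n_per_class must be >= 5 for a meaningful evaluation")
    config = config or PipelineConfig()
    config = dataclasses.replace(config, seed=seed)
    phantoms = make_dataset(n_per_class, base_spec=base_spec, seed=seed)
    images = [(p.image, p.labels) for p in phantoms]
    report, matrix = run_pipeline(images, config=config, out_dir=out_dir, evaluate=True)
    return report, matrix
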