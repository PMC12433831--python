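"""Readers, writers, pipeline configuration and the end-to-end pipeline.

Formats: single-channel 8/16-bit TIFF images (pixel size from ImageJ-style
metadata, overridable from the config), GeoJSON FeatureCollections for
annotations and ROIs (property ``classification``), CSV readout tables
mirroring the per-animal supplementary-table schema, and a YAML pipeline
config that round-trips losslessly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import mapping, shape

from .groupstats import run_study_analysis
from .lesionquant import (
    CONDITIONS,
    GENOTYPES,
    QuantConfig,
    RegionOfInterest,
    SampleReadout,
    build_roi_mask,
    extract_lesions,
    quantify_sample,
)
from .pixelclass import (
    DEFAULT_SCALES_PX,
    AnnotationSet,
    FluorescenceImage,
    Hyperparameters,
    classify_pixels,
    compute_feature_stack,
    load_classifier,
)

logger = logging.getLogger("xirplesion")

#: CSV column order mirroring the supplementary per-animal table
READOUT_COLUMNS = (
    "sample_id",
    "genotype",
    "condition",
    "roi_area_um2",
    "lesion_count",
    "lesion_density_per_mm2",
    "mean_lesion_size_um2",
    "macro_count",
    "macro_fraction_pct",
    "macro_density_per_mm2",
)


class PipelineStageError(RuntimeError):
    """Failure in a named pipeline stage (maps to a nonzero exit status)."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def write_image(path: str | Path, image: FluorescenceImage) -> None:
    res = 1.0 / image.pixel_size_um
    tifffile.imwrite(
        path,
        np.asarray(image.pixels),
        imagej=True,
        resolution=(res, res),
        metadata={"unit": "um"},
    )


def _metadata_pixel_size(tf: tifffile.TiffFile) -> float | None:
    meta = tf.imagej_metadata or {}
    if meta.get("unit") not in ("um", "micron", "µm"):
        return None
    tags = tf.pages[0].tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    return den / num


def read_image(
    path: str | Path,
    pixel_size_um: float | None = None,
    channel: int | None = None,
    sample_id: str | None = None,
) -> FluorescenceImage:
    """Load a single-channel image; config pixel size overrides metadata."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta_ps = _metadata_pixel_size(tf)
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path.name}: multichannel image requires a channel selector"
            )
        axis = int(np.argmin(arr.shape))
        arr = np.take(arr, channel, axis=axis)
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2D image, got shape {arr.shape}")

    if pixel_size_um is not None and meta_ps is not None:
        if not math.isclose(pixel_size_um, meta_ps, rel_tol=1e-6):
            warnings.warn(
                f"{path.name}: config pixel size {pixel_size_um} overrides "
                f"metadata value {meta_ps:.6g}",
                UserWarning,
                stacklevel=2,
            )
        ps = pixel_size_um
    elif pixel_size_um is not None:
        ps = pixel_size_um
    elif meta_ps is not None:
        ps = meta_ps
    else:
        raise ValueError(
            f"{path.name}: pixel size missing from both metadata and config"
        )
    return FluorescenceImage(arr, ps, sample_id=sample_id or path.stem)


# ---------------------------------------------------------------------------
# GeoJSON annotations / ROI
# ---------------------------------------------------------------------------

def _features(path: str | Path) -> list[dict]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    return doc["features"]


def read_annotations(path: str | Path) -> AnnotationSet:
    annots = []
    for feat in _features(path):
        cls = (feat.get("properties") or {}).get("classification")
        if cls not in ("lesion", "ignore"):
            raise ValueError(f"annotation classification must be lesion/ignore, got {cls!r}")
        annots.append((shape(feat["geometry"]), cls))
    return AnnotationSet(annots)


def write_annotations(annots: AnnotationSet, path: str | Path) -> None:
    feats = [
        {"type": "Feature", "geometry": mapping(p), "properties": {"classification": c}}
        for p, c in annots.annotations
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_roi(path: str | Path) -> RegionOfInterest:
    include, exclude = [], []
    for feat in _features(path):
        cls = (feat.get("properties") or {}).get("classification")
        geom = shape(feat["geometry"])
        if cls == "roi":
            include.append(geom)
        elif cls == "exclude":
            exclude.append(geom)
        else:
            raise ValueError(f"ROI classification must be roi/exclude, got {cls!r}")
    return RegionOfInterest(include_polygons=include, exclude_polygons=exclude)


def write_roi(roi: RegionOfInterest, path: str | Path) -> None:
    feats = [
        {"type": "Feature", "geometry": mapping(p), "properties": {"classification": "roi"}}
        for p in roi.include_polygons
    ] + [
        {"type": "Feature", "geometry": mapping(p), "properties": {"classification": "exclude"}}
        for p in roi.exclude_polygons
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


# ---------------------------------------------------------------------------
# readout tables
# ---------------------------------------------------------------------------

def readouts_to_frame(readouts: Sequence[SampleReadout]) -> pd.DataFrame:
    rows = [asdict(r) for r in readouts]
    df = pd.DataFrame(rows)
    return df[list(READOUT_COLUMNS)]


def write_readouts(readouts: Sequence[SampleReadout] | pd.DataFrame, path: str | Path) -> None:
    df = readouts if isinstance(readouts, pd.DataFrame) else readouts_to_frame(readouts)
    df = df[list(READOUT_COLUMNS)]
    df.to_csv(path, index=False)  # NaN -> empty field


def read_readouts(path: str | Path) -> pd.DataFrame:
    """Readout table with validated labels; errors name the offending line."""
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    missing = set(READOUT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if pd.notna(row["genotype"]) and row["genotype"] not in GENOTYPES:
            raise ValueError(f"{path}, line {line}: unknown genotype {row['genotype']!r}")
        if pd.notna(row["condition"]) and row["condition"] not in CONDITIONS:
            raise ValueError(f"{path}, line {line}: unknown condition {row['condition']!r}")
    return df[list(READOUT_COLUMNS)]


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class SampleEntry:
    sample_id: str
    image: str
    roi: str
    genotype: str | None = None
    condition: str | None = None


@dataclass
class PipelineConfig:
    pixel_size_um: float = 0.13
    scales_px: list[float] = field(default_factory=lambda: list(DEFAULT_SCALES_PX))
    hidden_units: int = 32
    epochs: int = 200
    learning_rate: float = 0.05
    seed: int = 0
    min_detection_um2: float = 0.01
    macro_threshold_um2: float = 10.0
    connectivity: int = 8
    alpha: float = 0.05
    classifier_path: str = ""
    samples: list[SampleEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        # delegate numeric validation to the owning modules' types
        Hyperparameters(self.hidden_units, self.epochs, self.learning_rate)
        QuantConfig(self.min_detection_um2, self.macro_threshold_um2, self.connectivity)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.samples = [
            SampleEntry(**s) if isinstance(s, dict) else s for s in self.samples
        ]

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @property
    def quant_config(self) -> QuantConfig:
        return QuantConfig(
            self.min_detection_um2, self.macro_threshold_um2, self.connectivity
        )


# ---------------------------------------------------------------------------
# end-to-end pipeline: classify -> quantify -> stats
# ---------------------------------------------------------------------------

def quantify_one_sample(
    image: FluorescenceImage,
    clf,
    roi: RegionOfInterest,
    cfg: QuantConfig,
    scales_px: Sequence[float] = DEFAULT_SCALES_PX,
    sample_id: str = "",
    genotype: str | None = None,
    condition: str | None = None,
) -> SampleReadout:
    stack = compute_feature_stack(image, scales_px)
    lesion_raster = classify_pixels(clf, stack)
    mask, roi_area_um2 = build_roi_mask(roi, image)
    lesions = extract_lesions(lesion_raster, mask, image.pixel_size_um, cfg)
    return quantify_sample(lesions, roi_area_um2, sample_id=sample_id,
                           genotype=genotype, condition=condition)


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Classify and quantify every configured sample, then run the statistics.

    Writes ``readouts.csv``, ``stats_report.csv`` (when all six groups are
    present), and ``audit.json``. Refuses to overwrite outputs produced
    under a different config hash.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    audit_path = out / "audit.json"
    if audit_path.exists():
        prev = json.loads(audit_path.read_text())
        if prev.get("config_hash") not in (None, cfg_hash):
            raise PipelineStageError(
                "setup",
                f"output dir {out} holds results from config {prev['config_hash']}; "
                f"refusing to overwrite with {cfg_hash}",
            )

    try:
        clf = load_classifier(cfg.classifier_path)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("load-classifier", str(exc)) from exc

    readouts = []
    for entry in cfg.samples:
        try:
            image = read_image(entry.image, pixel_size_um=cfg.pixel_size_um,
                               sample_id=entry.sample_id)
            roi = read_roi(entry.roi)
            readout = quantify_one_sample(
                image, clf, roi, cfg.quant_config, cfg.scales_px,
                sample_id=entry.sample_id, genotype=entry.genotype,
                condition=entry.condition,
            )
            readouts.append(readout)
            logger.info("quantified %s: %d lesions", entry.sample_id, readout.lesion_count)
        except PipelineStageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("quantify", f"{entry.sample_id}: {exc}") from exc

    try:
        readouts_path = out / "readouts.csv"
        write_readouts(readouts, readouts_path)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("write-readouts", str(exc)) from exc

    artifacts = {"readouts": readouts_path, "audit": audit_path}

    df = readouts_to_frame(readouts)
    have_all_groups = all(
        ((df["genotype"] == g) & (df["condition"] == c)).sum() >= 3
        for g in GENOTYPES
        for c in CONDITIONS
    )
    if have_all_groups:
        try:
            report = run_study_analysis(df, alpha=cfg.alpha)
            report_path = out / "stats_report.csv"
            report.to_frame().to_csv(report_path, index=False)
            artifacts["stats_report"] = report_path
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("stats", str(exc)) from exc
    else:
        logger.info("statistics stage skipped: not all six groups present with n >= 3")

    import scipy
    from . import __version__

    audit = {
        "config": cfg.to_dict(),
        "config_hash": cfg_hash,
        "versions": {
            "xirplesion": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "n_samples": len(readouts),
    }
    audit_path.write_text(json.dumps(audit, indent=2))
    return artifacts
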