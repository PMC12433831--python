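"""Lesion morphometry inside a manually set region of interest.

Connected components of the classified lesion raster are measured in
calibrated units (area = pixel count x pixel size squared), filtered by a
minimum detection size (>= 0.01 um^2 by default) and split into micro- and
macrolesions at a strict 10 um^2 area threshold. Seven per-section readout
parameters summarize each sample: ROI area, lesion count, mean lesion size,
macrolesion count, lesion density, macrolesion fraction and macrolesion
density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
from shapely.geometry import Polygon

from ._geometry import check_in_bounds, polygon_mask, validate_polygon
from .pixelclass import FluorescenceImage

GENOTYPES = ("WT", "HET", "HOM")
CONDITIONS = ("no_run", "run")

UM2_PER_MM2 = 1.0e6


@dataclass(frozen=True)
class QuantConfig:
    min_detection_um2: float = 0.01
    macro_threshold_um2: float = 10.0
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not (0 < self.min_detection_um2 < self.macro_threshold_um2):
            raise ValueError("need 0 < min_detection_um2 < macro_threshold_um2")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class RegionOfInterest:
    include_polygons: list[Polygon]
    exclude_polygons: list[Polygon] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.include_polygons:
            raise ValueError("ROI needs at least one include polygon")
        for p in [*self.include_polygons, *self.exclude_polygons]:
            validate_polygon(p)


@dataclass(frozen=True)
class LesionDetection:
    pixel_count: int
    area_um2: float
    centroid: tuple[float, float]  # (row, col)
    is_macro: bool


@dataclass(frozen=True)
class SampleReadout:
    """The seven readout parameters of one muscle section, plus identifiers.

    ``mean_lesion_size_um2`` and ``macro_fraction_pct`` are NaN (missing,
    never zero) when the section contains no lesions.
    """

    sample_id: str
    roi_area_um2: float
    lesion_count: int
    mean_lesion_size_um2: float
    macro_count: int
    lesion_density_per_mm2: float
    macro_fraction_pct: float
    macro_density_per_mm2: float
    genotype: str | None = None
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.genotype is not None and self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")
        if self.condition is not None and self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.macro_count > self.lesion_count:
            raise ValueError("macro_count cannot exceed lesion_count")


def build_roi_mask(
    roi: RegionOfInterest, image: FluorescenceImage
) -> tuple[np.ndarray, float]:
    """Binary mask = union(includes) minus union(excludes), with area in um^2."""
    shape = image.shape
    for p in [*roi.include_polygons, *roi.exclude_polygons]:
        check_in_bounds(p, shape)
    mask = polygon_mask(roi.include_polygons, shape)
    if roi.exclude_polygons:
        mask &= ~polygon_mask(roi.exclude_polygons, shape)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("ROI mask is empty after exclusions")
    return mask, n * image.pixel_size_um**2


def _structure(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def extract_lesions(
    lesion_raster: np.ndarray,
    mask: np.ndarray,
    pixel_size_um: float,
    cfg: QuantConfig = QuantConfig(),
) -> list[LesionDetection]:
    """Connected components of the lesion raster clipped to the ROI.

    Components are labeled under ``cfg.connectivity``, discarded when their
    calibrated area falls below the minimum detection size, flagged macro by
    strict comparison against the macrolesion threshold, and returned sorted
    by centroid (row, col).
    """
    lesion_raster = np.asarray(lesion_raster)
    mask = np.asarray(mask)
    if lesion_raster.shape != mask.shape:
        raise ValueError("lesion raster and ROI mask shapes differ")
    binary = (lesion_raster > 0) & (mask > 0)
    labeled, n = ndi.label(binary, structure=_structure(cfg.connectivity))
    if n == 0:
        return []
    counts = np.bincount(labeled.ravel())[1:]
    centroids = ndi.center_of_mass(binary, labeled, index=np.arange(1, n + 1))
    px_area = pixel_size_um**2
    out = []
    for count, (cr, cc) in zip(counts, centroids):
        area = float(count) * px_area
        if area < cfg.min_detection_um2:
            continue
        out.append(
            LesionDetection(
                pixel_count=int(count),
                area_um2=area,
                centroid=(float(cr), float(cc)),
                is_macro=area > cfg.macro_threshold_um2,
            )
        )
    out.sort(key=lambda d: d.centroid)
    return out


def quantify_sample(
    lesions: Sequence[LesionDetection],
    roi_area_um2: float,
    sample_id: str = "",
    genotype: str | None = None,
    condition: str | None = None,
) -> SampleReadout:
    """Seven-parameter summary; mean size and macro fraction are NaN when empty."""
    if not (roi_area_um2 > 0):
        raise ValueError("roi_area_um2 must be positive")
    n = len(lesions)
    areas = np.array([d.area_um2 for d in lesions], dtype=float)
    n_macro = int(sum(d.is_macro for d in lesions))
    roi_mm2 = roi_area_um2 / UM2_PER_MM2
    return SampleReadout(
        sample_id=sample_id,
        roi_area_um2=float(roi_area_um2),
        lesion_count=n,
        mean_lesion_size_um2=float(areas.mean()) if n else math.nan,
        macro_count=n_macro,
        lesion_density_per_mm2=n / roi_mm2,
        macro_fraction_pct=100.0 * n_macro / n if n else math.nan,
        macro_density_per_mm2=n_macro / roi_mm2,
        genotype=genotype,
        condition=condition,
    )


def detections_from_areas(
    areas_um2: Sequence[float],
    pixel_size_um: float,
    cfg: QuantConfig = QuantConfig(),
) -> list[LesionDetection]:
    """Detections from a ledger of calibrated areas (no raster available).

    Applies the same minimum-size filter and macro rule as ``extract_lesions``
    so ledger-derived ground truth shares one definition with the pixel path.
    """
    px_area = pixel_size_um**2
    out = []
    for a in areas_um2:
        a = float(a)
        if a < cfg.min_detection_um2:
            continue
        out.append(
            LesionDetection(
                pixel_count=max(1, round(a / px_area)),
                area_um2=a,
                centroid=(math.nan, math.nan),
                is_macro=a > cfg.macro_threshold_um2,
            )
        )
    return out
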