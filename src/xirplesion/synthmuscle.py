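"""Synthetic muscle cross-section images and cohorts with known ground truth.

The generator emulates what the quantification pipeline actually sees in a
stained soleus cross-section: a textured autofluorescent fiber mosaic
(Voronoi cells with per-fiber level jitter plus smooth texture), bright
punctate-to-patchy lesions placed by a homogeneous spatial Poisson process
inside a soleus-like region of interest, a right-skewed two-component
lognormal lesion-size law spanning the micro/macro boundary at 10 um^2,
optics blur and shot/read noise. Every placement is recorded in a ledger so
classifier and quantifier outputs can be scored against exact ground truth.

Cohort generation reuses the group means of the R349P desmin knock-in
treadmill study (three genotypes x sedentary/exercised) as regime
parameters, with a lognormal between-animal variability multiplier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.stats as sps
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .lesionquant import (
    QuantConfig,
    RegionOfInterest,
    SampleReadout,
    build_roi_mask,
    detections_from_areas,
    quantify_sample,
)
from .pixelclass import FluorescenceImage

UM2_PER_MM2 = 1.0e6
_MAX_EXPECTED_LESIONS = 1_000_000


@dataclass(frozen=True)
class TissueSpec:
    """Parameters of one simulated muscle section."""

    field_size_px: tuple[int, int] = (768, 768)
    pixel_size_um: float = 0.13
    lesion_density_per_mm2: float = 2000.0
    #: two-component lognormal lesion-area law (um^2)
    micro_mean_um2: float = 0.9
    micro_sigma_log: float = 0.6
    macro_mean_um2: float = 20.0
    macro_sigma_log: float = 0.4
    macro_weight: float = 0.01
    #: intensities (arbitrary counts) and optics/noise
    lesion_peak: float = 400.0
    background_level: float = 80.0
    texture_amplitude: float = 8.0
    fiber_level_cv: float = 0.08
    psf_sigma_px: float = 0.8
    read_noise_sd: float = 4.0
    shot_noise: bool = True
    #: ROI geometry
    roi_fraction: float = 0.5
    n_artefacts: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        r, c = self.field_size_px
        if r <= 0 or c <= 0:
            raise ValueError("field_size_px must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.lesion_density_per_mm2 < 0 or self.lesion_peak < 0:
            raise ValueError("density and peak must be non-negative")
        if not (0 <= self.macro_weight < 1):
            raise ValueError("macro_weight must be in [0, 1)")
        if not (0.25 <= self.roi_fraction <= 0.75):
            raise ValueError("roi_fraction must lie in [0.25, 0.75]")

    @property
    def field_area_mm2(self) -> float:
        r, c = self.field_size_px
        return r * c * self.pixel_size_um**2 / UM2_PER_MM2


@dataclass
class GroundTruth:
    """Ledger of placed lesions, reconciled with the merged pre-blur mask."""

    lesion_mask: np.ndarray  # bool, clipped to the ROI
    areas_um2: np.ndarray  # per merged component, ROI-clipped
    placed_count: int  # before overlap merging / ROI clipping


def sample_lesion_areas(rng: np.random.Generator, n: int, spec: TissueSpec) -> np.ndarray:
    """Right-skewed areas from the micro/macro lognormal mixture (um^2)."""
    is_macro = rng.random(n) < spec.macro_weight
    mu_micro = math.log(spec.micro_mean_um2) - spec.micro_sigma_log**2 / 2
    mu_macro = math.log(spec.macro_mean_um2) - spec.macro_sigma_log**2 / 2
    areas = np.where(
        is_macro,
        rng.lognormal(mu_macro, spec.macro_sigma_log, n),
        rng.lognormal(mu_micro, spec.micro_sigma_log, n),
    )
    return areas


def macro_draw_probability(spec: TissueSpec, threshold_um2: float = 10.0) -> float:
    """P(a drawn area exceeds the macro threshold) under the mixture."""
    mu_mi = math.log(spec.micro_mean_um2) - spec.micro_sigma_log**2 / 2
    mu_ma = math.log(spec.macro_mean_um2) - spec.macro_sigma_log**2 / 2
    lt = math.log(threshold_um2)
    p_mi = sps.norm.sf((lt - mu_mi) / spec.micro_sigma_log)
    p_ma = sps.norm.sf((lt - mu_ma) / spec.macro_sigma_log)
    return float((1 - spec.macro_weight) * p_mi + spec.macro_weight * p_ma)


def _roi_polygon(rng: np.random.Generator, shape: tuple[int, int], fraction: float) -> Polygon:
    """Soleus-like smooth blob covering roughly ``fraction`` of the field."""
    rows, cols = shape
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    base = math.sqrt(fraction * rows * cols / math.pi)
    theta = np.linspace(0, 2 * math.pi, 72, endpoint=False)
    r = np.full_like(theta, base)
    for k in range(2, 6):
        amp = rng.normal(0, 0.05)
        phase = rng.uniform(0, 2 * math.pi)
        r = r * (1 + amp * np.cos(k * theta + phase))
    r = np.clip(r, 0.2 * base, 0.49 * min(rows, cols))
    xs = cx + r * np.cos(theta)
    ys = cy + r * np.sin(theta)
    xs = np.clip(xs, -0.49, cols - 0.51)
    ys = np.clip(ys, -0.49, rows - 0.51)
    return Polygon(zip(xs, ys))


def _artefact_polygons(
    rng: np.random.Generator, roi_mask: np.ndarray, n: int, shape: tuple[int, int]
) -> list[Polygon]:
    rows, cols = shape
    radius = 0.03 * min(rows, cols)
    inside = np.argwhere(roi_mask)
    out = []
    for _ in range(n):
        r0, c0 = inside[rng.integers(len(inside))]
        theta = np.linspace(0, 2 * math.pi, 24, endpoint=False)
        xs = np.clip(c0 + radius * np.cos(theta), -0.49, cols - 0.51)
        ys = np.clip(r0 + radius * np.sin(theta), -0.49, rows - 0.51)
        out.append(Polygon(zip(xs, ys)))
    return out


def _ellipse_footprint(
    rng: np.random.Generator, center: tuple[float, float], area_px: float,
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices of a random-orientation ellipse of the requested area."""
    q = rng.uniform(1.0, 3.0)  # axis ratio
    ang = rng.uniform(0, math.pi)
    a = math.sqrt(area_px * q / math.pi)
    b = a / q
    r0, c0 = center
    rad = int(math.ceil(a)) + 1
    rr = np.arange(max(0, int(r0) - rad), min(shape[0], int(r0) + rad + 1))
    cc = np.arange(max(0, int(c0) - rad), min(shape[1], int(c0) + rad + 1))
    if rr.size == 0 or cc.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    R, C = np.meshgrid(rr, cc, indexing="ij")
    dy, dx = R - r0, C - c0
    u = dx * math.cos(ang) + dy * math.sin(ang)
    v = -dx * math.sin(ang) + dy * math.cos(ang)
    hit = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    ri, ci = R[hit], C[hit]
    if ri.size == 0:  # sub-pixel lesion: keep the nearest pixel
        ri = np.array([int(round(r0))]).clip(0, shape[0] - 1)
        ci = np.array([int(round(c0))]).clip(0, shape[1] - 1)
    return ri, ci


def _background(rng: np.random.Generator, spec: TissueSpec) -> np.ndarray:
    rows, cols = spec.field_size_px
    fiber_px = 40.0 / spec.pixel_size_um / 8.0  # coarse mosaic cell scale
    n_seeds = max(6, int(rows * cols / fiber_px**2 / 40))
    seeds = rng.uniform([0, 0], [rows, cols], size=(n_seeds, 2))
    tree = cKDTree(seeds)
    R, C = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    _, idx = tree.query(np.column_stack([R.ravel(), C.ravel()]))
    levels = spec.background_level * (1 + rng.normal(0, spec.fiber_level_cv, n_seeds))
    bg = levels[idx].reshape(rows, cols)
    texture = ndi.gaussian_filter(rng.normal(0, 1, (rows, cols)), 3.0, mode="reflect")
    sd = texture.std()
    if sd > 0:
        bg = bg + spec.texture_amplitude * texture / sd
    return np.clip(bg, 0, None)


def generate_tissue_image(
    spec: TissueSpec,
) -> tuple[FluorescenceImage, GroundTruth, RegionOfInterest]:
    """Render one section: background mosaic + Poisson-placed lesions + noise."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.field_size_px
    px_area = spec.pixel_size_um**2

    roi_poly = _roi_polygon(rng, shape, spec.roi_fraction)
    roi = RegionOfInterest(include_polygons=[roi_poly])
    probe = FluorescenceImage(np.zeros(shape), spec.pixel_size_um)
    roi_mask, roi_area_um2 = build_roi_mask(roi, probe)
    if spec.n_artefacts:
        roi = RegionOfInterest(
            include_polygons=[roi_poly],
            exclude_polygons=_artefact_polygons(rng, roi_mask, spec.n_artefacts, shape),
        )
        roi_mask, roi_area_um2 = build_roi_mask(roi, probe)

    expected = spec.lesion_density_per_mm2 * roi_area_um2 / UM2_PER_MM2
    if expected > _MAX_EXPECTED_LESIONS:
        raise ValueError(f"expected lesion count {expected:.0f} exceeds guard")
    n = int(rng.poisson(expected))

    inside = np.argwhere(roi_mask)
    mask = np.zeros(shape, dtype=bool)
    lesion_layer = np.zeros(shape, dtype=np.float64)
    areas = sample_lesion_areas(rng, n, spec)
    for area_um2 in areas:
        r0, c0 = inside[rng.integers(len(inside))] + rng.uniform(-0.5, 0.5, 2)
        ri, ci = _ellipse_footprint(rng, (r0, c0), max(area_um2 / px_area, 1.0), shape)
        mask[ri, ci] = True
        peak = spec.lesion_peak * rng.uniform(0.8, 1.25)
        np.maximum.at(lesion_layer, (ri, ci), peak)

    # canonical ground truth: merged footprints clipped to the ROI
    mask &= roi_mask
    labeled, n_comp = ndi.label(mask, structure=ndi.generate_binary_structure(2, 2))
    comp_areas = (
        np.bincount(labeled.ravel())[1:].astype(float) * px_area
        if n_comp
        else np.array([], dtype=float)
    )
    gt = GroundTruth(lesion_mask=mask, areas_um2=comp_areas, placed_count=n)

    img = _background(rng, spec) + lesion_layer
    if spec.psf_sigma_px > 0:
        img = ndi.gaussian_filter(img, spec.psf_sigma_px, mode="reflect")
    if spec.shot_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    if spec.read_noise_sd > 0:
        img = img + rng.normal(0, spec.read_noise_sd, shape)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    return FluorescenceImage(img, spec.pixel_size_um, sample_id=f"synthetic_{spec.seed}"), gt, roi


def ground_truth_readout(
    gt: GroundTruth,
    roi_area_um2: float,
    cfg: QuantConfig = QuantConfig(),
    pixel_size_um: float = 0.13,
    sample_id: str = "",
    genotype: str | None = None,
    condition: str | None = None,
) -> SampleReadout:
    """Seven-parameter readout computed from the placed-lesion ledger."""
    dets = detections_from_areas(gt.areas_um2, pixel_size_um, cfg)
    return quantify_sample(dets, roi_area_um2, sample_id=sample_id,
                           genotype=genotype, condition=condition)


def dot_annotations_from_ground_truth(
    gt: GroundTruth,
    seed: int,
    n_per_class: int = 400,
    margin_px: int = 2,
):
    """Brush-dot style annotations sampled from a ground-truth mask.

    Emulates sparse manual supervision: single-pixel 'dots' (tiny square
    polygons around pixel centers) on lesion pixels for the lesion class and
    on pixels at least ``margin_px`` away from any lesion for the ignore
    class — annotators avoid the ambiguous blurred rim.
    """
    from shapely.geometry import box

    from .pixelclass import AnnotationSet

    rng = np.random.default_rng(seed)
    lesion_px = np.argwhere(gt.lesion_mask)
    far = ~ndi.binary_dilation(gt.lesion_mask, iterations=margin_px)
    bg_px = np.argwhere(far)
    if len(lesion_px) == 0 or len(bg_px) == 0:
        raise ValueError("ground truth lacks pixels for one of the classes")
    n = min(n_per_class, len(lesion_px), len(bg_px))
    annots = []
    for r, c in lesion_px[rng.choice(len(lesion_px), n, replace=False)]:
        annots.append((box(c - 0.3, r - 0.3, c + 0.3, r + 0.3), "lesion"))
    for r, c in bg_px[rng.choice(len(bg_px), n, replace=False)]:
        annots.append((box(c - 0.3, r - 0.3, c + 0.3, r + 0.3), "ignore"))
    return AnnotationSet(annots)


def classifier_benchmark_spec(seed: int = 0, **overrides) -> TissueSpec:
    """Benchmark section for classifier training/validation.

    320x320 px at 0.13 um/px with a dense lesion regime (plenty of labeled
    objects per image), ~3 um^2 mean lesion size and peak:background 5 —
    the annotated-lesion scale of a training section at this resolution.
    """
    params = dict(
        field_size_px=(320, 320),
        lesion_density_per_mm2=25000.0,
        micro_mean_um2=3.0,
        micro_sigma_log=0.5,
        macro_weight=0.03,
        lesion_peak=400.0,
        background_level=80.0,
        roi_fraction=0.6,
        seed=seed,
    )
    params.update(overrides)
    return TissueSpec(**params)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: group means of the R349P desmin knock-in treadmill study, used as
#: simulation regime parameters (lesion density /mm^2, mean lesion size um^2,
#: macrolesion density /mm^2)
DESMIN_COHORT_PARAMS: dict[tuple[str, str], dict[str, float]] = {
    ("WT", "no_run"): dict(density=1874.0, mean_size=0.7, macro_density=16.0),
    ("HET", "no_run"): dict(density=3473.0, mean_size=0.9, macro_density=39.0),
    ("HOM", "no_run"): dict(density=16924.0, mean_size=1.4, macro_density=341.0),
    ("WT", "run"): dict(density=5232.0, mean_size=0.8, macro_density=49.0),
    ("HET", "run"): dict(density=5468.0, mean_size=1.0, macro_density=62.0),
    ("HOM", "run"): dict(density=18149.0, mean_size=1.4, macro_density=337.0),
}

#: group sizes of the six-group study
DESMIN_GROUP_N: dict[tuple[str, str], int] = {
    ("WT", "no_run"): 8,
    ("WT", "run"): 9,
    ("HET", "no_run"): 9,
    ("HET", "run"): 9,
    ("HOM", "no_run"): 10,
    ("HOM", "run"): 12,
}


def tissue_spec_for_group(
    genotype: str,
    condition: str,
    base: TissueSpec = TissueSpec(),
    params: Mapping[tuple[str, str], Mapping[str, float]] = DESMIN_COHORT_PARAMS,
) -> TissueSpec:
    """Tissue spec whose density/size mixture hits a group's target means.

    The macro-component weight is solved so the expected fraction of drawn
    areas above 10 um^2 equals the group's macrolesion fraction, then the
    micro-mode mean is solved so the overall mean size hits the target.
    """
    p = params[(genotype, condition)]
    target_frac = p["macro_density"] / p["density"]
    mu_ma = math.log(base.macro_mean_um2) - base.macro_sigma_log**2 / 2
    p_macro_gt10 = float(sps.norm.sf((math.log(10.0) - mu_ma) / base.macro_sigma_log))
    w = target_frac / p_macro_gt10
    micro_mean = (p["mean_size"] - w * base.macro_mean_um2) / (1 - w)
    if micro_mean <= 0:
        raise ValueError("size-mixture targets are infeasible")
    return replace(
        base,
        lesion_density_per_mm2=p["density"],
        macro_weight=w,
        micro_mean_um2=micro_mean,
    )


@dataclass(frozen=True)
class CohortSpec:
    base_spec: TissueSpec = TissueSpec()
    group_params: Mapping[tuple[str, str], Mapping[str, float]] = field(
        default_factory=lambda: dict(DESMIN_COHORT_PARAMS)
    )
    n_per_group: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DESMIN_GROUP_N)
    )
    #: between-animal lognormal multiplier on lesion density (CV)
    animal_cv: float = 0.3
    #: ROI area used in ledger-only (non-rendered) simulation, mm^2
    roi_area_mm2: float = 0.2
    base_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 6:
            raise ValueError("cohort needs exactly six groups")
        for key, n in self.n_per_group.items():
            if key not in self.group_params:
                raise ValueError(f"invalid group label {key}")
            if n < 2:
                raise ValueError(f"group {key} needs n >= 2")


@dataclass
class CohortResult:
    table: pd.DataFrame
    samples: dict[str, tuple[FluorescenceImage, GroundTruth, RegionOfInterest]]


def generate_cohort(
    cs: CohortSpec, render: bool = False, cfg: QuantConfig = QuantConfig()
) -> CohortResult:
    """Simulate a six-group cohort of per-animal ground-truth readouts.

    With ``render=False`` (default) only the placement ledgers are sampled:
    per animal, a lognormal density multiplier (CV ``animal_cv``), a Poisson
    lesion count over ``roi_area_mm2`` and areas from the group's size
    mixture. With ``render=True`` full images are generated and readouts come
    from each rendered ground-truth mask and drawn ROI.
    """
    rng = np.random.default_rng(cs.base_seed)
    sigma = math.sqrt(math.log(1 + cs.animal_cv**2))
    rows: list[SampleReadout] = []
    samples: dict[str, tuple] = {}

    for (genotype, condition), n_animals in cs.n_per_group.items():
        group_spec = tissue_spec_for_group(
            genotype, condition, base=cs.base_spec, params=cs.group_params
        )
        for i in range(n_animals):
            sample_id = f"{genotype}_{condition}_{i:02d}"
            mult = float(rng.lognormal(-sigma**2 / 2, sigma))
            density_i = group_spec.lesion_density_per_mm2 * mult
            seed_i = int(rng.integers(0, 2**31 - 1))
            if render:
                spec_i = replace(group_spec, lesion_density_per_mm2=density_i, seed=seed_i)
                img, gt, roi = generate_tissue_image(spec_i)
                probe = FluorescenceImage(np.zeros(spec_i.field_size_px), spec_i.pixel_size_um)
                _, roi_area_um2 = build_roi_mask(roi, probe)
                rows.append(
                    ground_truth_readout(
                        gt, roi_area_um2, cfg, spec_i.pixel_size_um,
                        sample_id=sample_id, genotype=genotype, condition=condition,
                    )
                )
                samples[sample_id] = (img, gt, roi)
            else:
                sub = np.random.default_rng(seed_i)
                n_lesions = int(sub.poisson(density_i * cs.roi_area_mm2))
                areas = sample_lesion_areas(sub, n_lesions, group_spec)
                dets = detections_from_areas(areas, group_spec.pixel_size_um, cfg)
                rows.append(
                    quantify_sample(
                        dets, cs.roi_area_mm2 * UM2_PER_MM2,
                        sample_id=sample_id, genotype=genotype, condition=condition,
                    )
                )

    from .io import readouts_to_frame

    return CohortResult(table=readouts_to_frame(rows), samples=samples)
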