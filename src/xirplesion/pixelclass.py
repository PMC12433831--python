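"""Trainable binary pixel classification for lesion detection.

Each pixel of a single-channel fluorescence image is described by a
multiscale texture vector (Gaussian smoothing, gradient magnitude,
Laplacian of Gaussian and the two structure-tensor eigenvalues, at several
smoothing scales) and labeled lesion / not-lesion by a small neural
network trained from sparse polygon annotations. The classifier keeps one
checkpoint per training image so that the deployed iteration can be picked
by validation performance — the usual workflow when a pixel classifier is
grown interactively over a handful of annotated sections.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
from shapely.geometry import Polygon
from skimage.feature import structure_tensor, structure_tensor_eigenvalues

from . import _mlp
from ._geometry import check_in_bounds, polygon_mask, polygons_overlap, validate_polygon

# label raster codes
UNLABELED = 0
LESION = 1
IGNORE = 2

ANNOTATION_CLASSES = ("lesion", "ignore")

#: default smoothing scales (pixels) and per-scale base features
DEFAULT_SCALES_PX: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0)
BASE_FEATURES: tuple[str, ...] = (
    "gaussian",
    "gradient_magnitude",
    "laplacian_of_gaussian",
    "structure_tensor_eig_max",
    "structure_tensor_eig_min",
)

#: annotation-count guideline for a trustworthy training set
MIN_OBJECTS_PER_CLASS = 100


@dataclass(frozen=True)
class FluorescenceImage:
    """Single-channel intensity raster with physical pixel calibration."""

    pixels: np.ndarray
    pixel_size_um: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("image raster must be 2D and non-empty")
        if not np.all(np.isfinite(px)):
            raise ValueError("image intensities must be finite")
        if px.min() < 0:
            raise ValueError("image intensities must be non-negative")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class FeatureStack:
    """Per-pixel feature vectors, spatial shape preserved (H, W, C)."""

    features: np.ndarray
    scales_px: tuple[float, ...]
    feature_names: tuple[str, ...]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.features.shape[:2]  # type: ignore[return-value]

    @property
    def n_features(self) -> int:
        return self.features.shape[2]


@dataclass
class AnnotationSet:
    """Sparse polygon supervision in two classes ('lesion', 'ignore')."""

    annotations: list[tuple[Polygon, str]]

    def __post_init__(self) -> None:
        for poly, cls in self.annotations:
            validate_polygon(poly)
            if cls not in ANNOTATION_CLASSES:
                raise ValueError(f"annotation class must be one of {ANNOTATION_CLASSES}, got {cls!r}")

    def count(self, cls: str) -> int:
        return sum(1 for _, c in self.annotations if c == cls)

    def polygons(self, cls: str) -> list[Polygon]:
        return [p for p, c in self.annotations if c == cls]


@dataclass(frozen=True)
class Hyperparameters:
    hidden_units: int = 32
    epochs: int = 200
    learning_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.hidden_units < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("invalid hyperparameters")


@dataclass
class Checkpoint:
    """Model state after a given number of training images."""

    theta: np.ndarray
    feature_mean: np.ndarray
    feature_std: np.ndarray
    loss_history: np.ndarray
    n_training_images: int


@dataclass
class PixelClassifier:
    checkpoints: list[Checkpoint]
    selected_iteration: int  # 1-based index into checkpoints
    training_seed: int
    hyperparameters: Hyperparameters
    feature_names: tuple[str, ...]
    scales_px: tuple[float, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.selected_iteration <= len(self.checkpoints):
            raise ValueError("selected_iteration out of range")

    @property
    def selected(self) -> Checkpoint:
        return self.checkpoints[self.selected_iteration - 1]


def compute_feature_stack(
    image: FluorescenceImage,
    scales_px: Sequence[float] = DEFAULT_SCALES_PX,
) -> FeatureStack:
    """Multiscale per-pixel features with reflect border padding.

    At each scale sigma: Gaussian-smoothed intensity, Gaussian gradient
    magnitude, Laplacian of Gaussian, and the max/min eigenvalues of the
    sigma-windowed structure tensor.
    """
    scales = tuple(float(s) for s in scales_px)
    if len(scales) == 0:
        raise ValueError("scales_px must be non-empty")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    if any(b >= a for a, b in zip(scales[1:], scales[:-1])):
        raise ValueError("scales must be strictly increasing")

    img = image.pixels.astype(np.float64)
    planes: list[np.ndarray] = []
    names: list[str] = []
    for s in scales:
        smoothed = ndi.gaussian_filter(img, s, mode="reflect")
        planes.append(smoothed)
        planes.append(ndi.gaussian_gradient_magnitude(img, s, mode="reflect"))
        # the truncated sampled second-derivative kernel is not exactly
        # zero-sum at small sigma; subtract its DC response so constants map
        # to zero (zero-sum discrete LoG operator)
        dc = float(ndi.gaussian_laplace(np.ones((1, 1)), s, mode="reflect")[0, 0])
        planes.append(ndi.gaussian_laplace(img, s, mode="reflect") - dc * smoothed)
        tens = structure_tensor(img, sigma=s, mode="reflect", order="rc")
        eig_max, eig_min = structure_tensor_eigenvalues(tens)
        planes.append(eig_max)
        planes.append(eig_min)
        names.extend(f"{base}_s{s:g}" for base in BASE_FEATURES)
    stack = np.stack(planes, axis=-1).astype(np.float32)
    if not np.all(np.isfinite(stack)):
        raise ValueError("non-finite feature values computed")
    return FeatureStack(features=stack, scales_px=scales, feature_names=tuple(names))


def rasterize_annotations(annots: AnnotationSet, image: FluorescenceImage) -> np.ndarray:
    """Label raster with values {UNLABELED, LESION, IGNORE} (pixel-center rule)."""
    shape = image.shape
    for poly, _ in annots.annotations:
        check_in_bounds(poly, shape)
    lesion_polys = annots.polygons("lesion")
    ignore_polys = annots.polygons("ignore")
    if polygons_overlap(lesion_polys, ignore_polys):
        raise ValueError("lesion and ignore annotations overlap: ambiguous supervision")

    n_lesion, n_ignore = len(lesion_polys), len(ignore_polys)
    if min(n_lesion, n_ignore) < MIN_OBJECTS_PER_CLASS:
        warnings.warn(
            f"training-set guideline: at least {MIN_OBJECTS_PER_CLASS} annotated objects "
            f"per class are recommended (got lesion={n_lesion}, ignore={n_ignore})",
            UserWarning,
            stacklevel=2,
        )
    if n_lesion != n_ignore:
        warnings.warn(
            f"unequal annotation counts between classes (lesion={n_lesion}, ignore={n_ignore}); "
            "a balanced object count is recommended",
            UserWarning,
            stacklevel=2,
        )

    labels = np.full(shape, UNLABELED, dtype=np.uint8)
    labels[polygon_mask(ignore_polys, shape)] = IGNORE
    labels[polygon_mask(lesion_polys, shape)] = LESION
    return labels


def _gather_training_pixels(
    stacks: Sequence[FeatureStack], labels: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for stack, lab in zip(stacks, labels):
        if lab.shape != stack.spatial_shape:
            raise ValueError("shape mismatch between feature stack and label raster")
        sel = lab != UNLABELED
        xs.append(stack.features[sel].astype(np.float64))
        ys.append((lab[sel] == LESION).astype(np.float64))
    return np.concatenate(xs), np.concatenate(ys)


def train_classifier(
    stacks: Sequence[FeatureStack],
    labels: Sequence[np.ndarray],
    hp: Hyperparameters = Hyperparameters(),
    seed: int = 0,
) -> PixelClassifier:
    """Train with one saved checkpoint per training image.

    Checkpoint k is fitted (from the same seeded initialization) on the
    labeled pixels of images 1..k; IGNORE pixels are negative examples,
    UNLABELED pixels are excluded. Pixel-level class imbalance is handled
    with inverse-frequency sample weights.
    """
    if len(stacks) == 0 or len(stacks) != len(labels):
        raise ValueError("need equally many feature stacks and label rasters (>= 1)")
    names = stacks[0].feature_names
    for s in stacks:
        if s.feature_names != names:
            raise ValueError("feature stacks have inconsistent feature sets")

    X_all, y_all = _gather_training_pixels(stacks, labels)
    if y_all.sum() == 0 or y_all.sum() == y_all.size:
        raise ValueError("training set must contain labeled pixels of both classes")

    checkpoints: list[Checkpoint] = []
    for k in range(1, len(stacks) + 1):
        X, y = _gather_training_pixels(stacks[:k], labels[:k])
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        Xs = (X - mean) / std
        n_pos = y.sum()
        n_neg = y.size - n_pos
        w = np.where(y == 1.0, y.size / max(2 * n_pos, 1), y.size / max(2 * n_neg, 1))
        theta, hist = _mlp.train(
            Xs, y, w,
            n_hidden=hp.hidden_units,
            epochs=hp.epochs,
            learning_rate=hp.learning_rate,
            seed=seed,
        )
        checkpoints.append(
            Checkpoint(theta=theta, feature_mean=mean, feature_std=std,
                       loss_history=hist, n_training_images=k)
        )
    return PixelClassifier(
        checkpoints=checkpoints,
        selected_iteration=len(checkpoints),
        training_seed=seed,
        hyperparameters=hp,
        feature_names=names,
        scales_px=stacks[0].scales_px,
    )


def _classify_with_checkpoint(
    ckpt: Checkpoint, stack: FeatureStack, hidden_units: int
) -> np.ndarray:
    X = stack.features.reshape(-1, stack.n_features).astype(np.float64)
    Xs = (X - ckpt.feature_mean) / ckpt.feature_std
    proba = _mlp.predict_proba(ckpt.theta, Xs, hidden_units)
    return (proba > 0.5).astype(np.uint8).reshape(stack.spatial_shape)


def pixel_f1(pred: np.ndarray, truth: np.ndarray) -> float:
    """F1 of the lesion class; 0 when no lesion is predicted or present."""
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def select_classifier(
    clf: PixelClassifier,
    val_stacks: Sequence[FeatureStack],
    val_truth: Sequence[np.ndarray],
) -> PixelClassifier:
    """Pick the checkpoint maximizing pooled pixel-level F1 on validation data.

    This operationalizes "best compromise between detection sensitivity and
    false positives"; ties go to the earliest checkpoint.
    """
    if len(val_stacks) == 0 or len(val_stacks) != len(val_truth):
        raise ValueError("validation set must be non-empty and consistent")
    pooled = np.concatenate([np.asarray(t).ravel() for t in val_truth])
    if pooled.min() == pooled.max():
        raise ValueError("validation truth contains only one class")

    best_f1, best_iter = -1.0, 1
    for i, ckpt in enumerate(clf.checkpoints, start=1):
        preds = [
            _classify_with_checkpoint(ckpt, s, clf.hyperparameters.hidden_units).ravel()
            for s in val_stacks
        ]
        f1 = pixel_f1(np.concatenate(preds), pooled.astype(np.uint8))
        if f1 > best_f1:  # strict: earliest checkpoint wins ties
            best_f1, best_iter = f1, i
    return dataclasses.replace(clf, selected_iteration=best_iter)


def classify_pixels(clf: PixelClassifier, stack: FeatureStack) -> np.ndarray:
    """Binary lesion raster from the selected checkpoint (deterministic)."""
    if stack.feature_names != clf.feature_names:
        raise ValueError(
            "feature manifest mismatch between classifier and stack; refusing to classify"
        )
    return _classify_with_checkpoint(clf.selected, stack, clf.hyperparameters.hidden_units)


# ---------------------------------------------------------------------------
# persistence: JSON manifest + npz weights
# ---------------------------------------------------------------------------

def save_classifier(clf: PixelClassifier, json_path: str | Path) -> None:
    json_path = Path(json_path)
    weights_path = json_path.with_suffix(".weights.npz")
    arrays: dict[str, np.ndarray] = {}
    for i, ck in enumerate(clf.checkpoints):
        arrays[f"theta_{i}"] = ck.theta
        arrays[f"mean_{i}"] = ck.feature_mean
        arrays[f"std_{i}"] = ck.feature_std
        arrays[f"loss_{i}"] = ck.loss_history
    np.savez(weights_path, **arrays)
    manifest = {
        "format": "xirplesion-pixel-classifier",
        "version": 1,
        "feature_names": list(clf.feature_names),
        "scales_px": list(clf.scales_px),
        "hyperparameters": dataclasses.asdict(clf.hyperparameters),
        "training_seed": clf.training_seed,
        "selected_iteration": clf.selected_iteration,
        "n_checkpoints": len(clf.checkpoints),
        "weights_file": weights_path.name,
    }
    json_path.write_text(json.dumps(manifest, indent=2))


def load_classifier(json_path: str | Path) -> PixelClassifier:
    json_path = Path(json_path)
    manifest = json.loads(json_path.read_text())
    if manifest.get("format") != "xirplesion-pixel-classifier":
        raise ValueError(f"{json_path} is not a pixel-classifier manifest")
    data = np.load(json_path.parent / manifest["weights_file"])
    checkpoints = [
        Checkpoint(
            theta=data[f"theta_{i}"],
            feature_mean=data[f"mean_{i}"],
            feature_std=data[f"std_{i}"],
            loss_history=data[f"loss_{i}"],
            n_training_images=i + 1,
        )
        for i in range(manifest["n_checkpoints"])
    ]
    return PixelClassifier(
        checkpoints=checkpoints,
        selected_iteration=manifest["selected_iteration"],
        training_seed=manifest["training_seed"],
        hyperparameters=Hyperparameters(**manifest["hyperparameters"]),
        feature_names=tuple(manifest["feature_names"]),
        scales_px=tuple(manifest["scales_px"]),
    )
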