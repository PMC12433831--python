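"""Shared fixtures: benchmark synthetic sections and a trained classifier.

The classifier fixture follows the documented workflow — four annotated
training sections, checkpoint per section, selection by pooled validation
F1 — and is session-scoped because several tests (and the acceptance
checks) reuse it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from xirplesion.lesionquant import build_roi_mask
from xirplesion.pixelclass import (
    compute_feature_stack,
    rasterize_annotations,
    select_classifier,
    train_classifier,
)
from xirplesion.synthmuscle import (
    classifier_benchmark_spec,
    dot_annotations_from_ground_truth,
    generate_tissue_image,
)

TRAIN_SEEDS = (100, 101, 102, 103)
VAL_SEEDS = (300, 301)
HELDOUT_SEEDS = (400, 401, 402)


@pytest.fixture(scope="session")
def training_material():
    """Four annotated benchmark sections: (stacks, label rasters, images, gts)."""
    stacks, labels, images, gts = [], [], [], []
    for s in TRAIN_SEEDS:
        img, gt, roi = generate_tissue_image(classifier_benchmark_spec(seed=s))
        ann = dot_annotations_from_ground_truth(gt, seed=s + 1000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            lab = rasterize_annotations(ann, img)
        stacks.append(compute_feature_stack(img))
        labels.append(lab)
        images.append(img)
        gts.append(gt)
    return stacks, labels, images, gts


@pytest.fixture(scope="session")
def validation_material():
    stacks, truths = [], []
    for s in VAL_SEEDS:
        img, gt, _roi = generate_tissue_image(classifier_benchmark_spec(seed=s))
        stacks.append(compute_feature_stack(img))
        truths.append(gt.lesion_mask.astype(np.uint8))
    return stacks, truths


@pytest.fixture(scope="session")
def trained_classifier(training_material, validation_material):
    stacks, labels, _images, _gts = training_material
    clf = train_classifier(stacks, labels, seed=42)
    return select_classifier(clf, *validation_material)


@pytest.fixture(scope="session")
def heldout_sections():
    """Held-out benchmark sections with ROI masks for pixel-level scoring."""
    out = []
    for s in HELDOUT_SEEDS:
        img, gt, roi = generate_tissue_image(classifier_benchmark_spec(seed=s))
        mask, area_um2 = build_roi_mask(roi, img)
        out.append((img, gt, roi, mask, area_um2))
    return out
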