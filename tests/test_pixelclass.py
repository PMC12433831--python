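"""Feature extraction, annotation rasterization, training and selection."""

import dataclasses
import warnings

import numpy as np
import pytest
from shapely.geometry import Polygon, box

from xirplesion.pixelclass import (
    IGNORE,
    LESION,
    UNLABELED,
    AnnotationSet,
    FluorescenceImage,
    Hyperparameters,
    classify_pixels,
    compute_feature_stack,
    load_classifier,
    pixel_f1,
    rasterize_annotations,
    save_classifier,
    select_classifier,
    train_classifier,
)

from oracles import direct_gaussian_response_at_peak

SCALES = (0.5, 1.0, 2.0, 4.0, 8.0)


def _img(arr, ps=0.13):
    return FluorescenceImage(np.asarray(arr, dtype=float), ps)


class TestFeatureStack:
    def test_constant_image_only_gaussian_channels_respond(self):
        fs = compute_feature_stack(_img(np.full((24, 24), 7.0)), SCALES)
        for i, name in enumerate(fs.feature_names):
            plane = fs.features[:, :, i]
            if name.startswith("gaussian"):
                assert np.allclose(plane, 7.0, atol=1e-5)
            else:
                assert np.allclose(plane, 0.0, atol=1e-5), name

    def test_channel_count_is_scales_times_base_features(self):
        fs = compute_feature_stack(_img(np.ones((8, 8))), SCALES)
        assert fs.n_features == 5 * 5 == len(fs.feature_names)
        assert fs.spatial_shape == (8, 8)

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 2.0])
    def test_single_bright_pixel_matches_direct_convolution(self, sigma):
        raster = np.zeros((41, 41))
        raster[20, 20] = 250.0
        fs = compute_feature_stack(_img(raster), [sigma])
        expected = direct_gaussian_response_at_peak(250.0, sigma)
        got = float(fs.features[20, 20, 0])
        assert abs(got - expected) / expected <= 1e-6

    def test_translation_equivariance_on_interior(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0, 100, (48, 48))
        shifted = np.roll(base, (3, 5), axis=(0, 1))
        f0 = compute_feature_stack(_img(base), (1.0, 2.0)).features
        f1 = compute_feature_stack(_img(shifted), (1.0, 2.0)).features
        inner = (slice(16, 32), slice(16, 32))
        assert np.allclose(np.roll(f0, (3, 5), axis=(0, 1))[inner], f1[inner], atol=1e-4)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            FluorescenceImage(np.zeros((0, 4)), 0.13)
        with pytest.raises(ValueError):
            FluorescenceImage(np.full((4, 4), -1.0), 0.13)
        with pytest.raises(ValueError):
            compute_feature_stack(_img(np.ones((4, 4))), [])
        with pytest.raises(ValueError):
            compute_feature_stack(_img(np.ones((4, 4))), [-1.0])
        with pytest.raises(ValueError):
            compute_feature_stack(_img(np.ones((4, 4))), [2.0, 1.0])


class TestRasterizeAnnotations:
    def test_rectangle_covering_ten_pixel_centers(self):
        # box over x in (0.25, 5.75), y in (0.25, 2.75): centers x=1..5, y=1..2
        annots = AnnotationSet([(box(0.25, 0.25, 5.75, 2.75), "lesion")])
        img = _img(np.zeros((8, 8)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            lab = rasterize_annotations(annots, img)
        assert (lab == LESION).sum() == 10
        assert (lab == UNLABELED).sum() == 64 - 10
        assert lab[1, 1] == LESION and lab[0, 0] == UNLABELED

    def test_few_objects_warns_about_training_guideline(self):
        annots = AnnotationSet(
            [(box(0.2, 0.2, 1.8, 1.8), "lesion"), (box(4.2, 4.2, 5.8, 5.8), "ignore")]
        )
        with pytest.warns(UserWarning, match="100"):
            rasterize_annotations(annots, _img(np.zeros((8, 8))))

    def test_unequal_counts_warn_not_error(self):
        annots = AnnotationSet(
            [
                (box(0.2, 0.2, 1.8, 1.8), "lesion"),
                (box(4.2, 4.2, 5.8, 5.8), "ignore"),
                (box(4.2, 0.2, 5.8, 1.8), "ignore"),
            ]
        )
        with pytest.warns(UserWarning, match="unequal"):
            rasterize_annotations(annots, _img(np.zeros((8, 8))))

    def test_cross_class_overlap_is_an_error(self):
        annots = AnnotationSet(
            [(box(0.2, 0.2, 3.8, 3.8), "lesion"), (box(2.2, 2.2, 5.8, 5.8), "ignore")]
        )
        with pytest.raises(ValueError, match="ambiguous"):
            rasterize_annotations(annots, _img(np.zeros((8, 8))))

    def test_out_of_bounds_polygon_is_an_error(self):
        annots = AnnotationSet([(box(5.0, 5.0, 12.0, 12.0), "lesion")])
        with pytest.raises(ValueError, match="outside"):
            rasterize_annotations(annots, _img(np.zeros((8, 8))))

    def test_self_intersecting_polygon_rejected(self):
        bowtie = Polygon([(0, 0), (4, 4), (4, 0), (0, 4)])
        with pytest.raises(ValueError):
            AnnotationSet([(bowtie, "lesion")])


def _separable_stacks(seed=0, n_images=2, n=300):
    """Feature stacks carrying two well-separated Gaussian clouds."""
    rng = np.random.default_rng(seed)
    stacks, labels = [], []
    from xirplesion.pixelclass import FeatureStack

    for _ in range(n_images):
        side = int(np.ceil(np.sqrt(2 * n)))
        feats = rng.normal(0, 0.5, (side, side, 3))
        lab = np.full((side, side), UNLABELED, dtype=np.uint8)
        coords = [(r, c) for r in range(side) for c in range(side)][: 2 * n]
        for i, (r, c) in enumerate(coords):
            if i % 2 == 0:
                feats[r, c] += 4.0
                lab[r, c] = LESION
            else:
                feats[r, c] -= 4.0
                lab[r, c] = IGNORE
        stacks.append(
            FeatureStack(feats.astype(np.float32), (1.0,), ("f0", "f1", "f2"))
        )
        labels.append(lab)
    return stacks, labels


class TestTraining:
    def test_one_checkpoint_per_training_image(self):
        stacks, labels = _separable_stacks(n_images=4)
        clf = train_classifier(stacks, labels, seed=1)
        assert len(clf.checkpoints) == 4
        assert [c.n_training_images for c in clf.checkpoints] == [1, 2, 3, 4]

    def test_separable_clouds_reach_high_accuracy(self):
        stacks, labels = _separable_stacks(seed=3)
        clf = train_classifier(stacks, labels, seed=1)
        probe, probe_labels = _separable_stacks(seed=99, n_images=1)
        pred = classify_pixels(clf, probe[0])
        labeled = probe_labels[0] != UNLABELED
        truth = (probe_labels[0] == LESION).astype(np.uint8)
        acc = (pred[labeled] == truth[labeled]).mean()
        assert acc >= 0.99

    def test_training_is_deterministic_given_seed(self):
        stacks, labels = _separable_stacks()
        clf1 = train_classifier(stacks, labels, seed=5)
        clf2 = train_classifier(stacks, labels, seed=5)
        probe, _ = _separable_stacks(seed=50, n_images=1)
        assert np.array_equal(classify_pixels(clf1, probe[0]), classify_pixels(clf2, probe[0]))

    def test_training_loss_non_increasing(self):
        stacks, labels = _separable_stacks()
        clf = train_classifier(stacks, labels, seed=2)
        for ck in clf.checkpoints:
            assert np.all(np.diff(ck.loss_history) <= 1e-15)

    def test_single_class_training_set_rejected(self):
        stacks, labels = _separable_stacks(n_images=1)
        only_lesion = np.where(labels[0] == IGNORE, UNLABELED, labels[0]).astype(np.uint8)
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(stacks, [only_lesion], seed=0)

    def test_shape_mismatch_rejected(self):
        stacks, labels = _separable_stacks()
        with pytest.raises(ValueError, match="mismatch"):
            train_classifier(stacks, [labels[0][:-1, :], labels[1]], seed=0)


class TestSelection:
    def test_selected_checkpoint_maximizes_f1(self, trained_classifier, validation_material):
        from xirplesion.pixelclass import _classify_with_checkpoint

        stacks, truths = validation_material
        pooled = np.concatenate([t.ravel() for t in truths])
        f1s = []
        for ck in trained_classifier.checkpoints:
            preds = np.concatenate(
                [_classify_with_checkpoint(ck, s, 32).ravel() for s in stacks]
            )
            f1s.append(pixel_f1(preds, pooled))
        sel = trained_classifier.selected_iteration
        assert f1s[sel - 1] == max(f1s)

    def test_tie_breaks_to_earliest_and_argmax_semantics(self):
        # synthetic F1 sequence via identical checkpoints: tie -> earliest
        stacks, labels = _separable_stacks(n_images=2)
        clf = train_classifier(stacks, labels, seed=1)
        clf.checkpoints[1] = clf.checkpoints[0]  # force a tie
        truths = [(labels[0] == LESION).astype(np.uint8)]
        sel = select_classifier(clf, [stacks[0]], truths)
        assert sel.selected_iteration == 1

    def test_single_class_validation_rejected(self, trained_classifier):
        stacks, _ = _separable_stacks(n_images=1)
        with pytest.raises(ValueError, match="one class"):
            select_classifier(
                trained_classifier, stacks, [np.zeros(stacks[0].spatial_shape, dtype=np.uint8)]
            )


class TestClassify:
    def test_classification_deterministic_and_binary(self, trained_classifier, heldout_sections):
        img, *_ = heldout_sections[0]
        stack = compute_feature_stack(img)
        p1 = classify_pixels(trained_classifier, stack)
        p2 = classify_pixels(trained_classifier, stack)
        assert np.array_equal(p1, p2)
        assert set(np.unique(p1)) <= {0, 1}

    def test_raster_equals_per_pixel_classification(self, trained_classifier, heldout_sections):
        """No hidden spatial coupling: tiling the stack changes nothing."""
        img, *_ = heldout_sections[0]
        stack = compute_feature_stack(img)
        full = classify_pixels(trained_classifier, stack)
        import dataclasses as dc

        top = dc.replace(stack, features=stack.features[:100])
        bottom = dc.replace(stack, features=stack.features[100:])
        stitched = np.vstack(
            [classify_pixels(trained_classifier, top), classify_pixels(trained_classifier, bottom)]
        )
        assert np.array_equal(full, stitched)

    def test_feature_manifest_mismatch_refused(self, trained_classifier):
        stacks, _ = _separable_stacks(n_images=1)
        with pytest.raises(ValueError, match="manifest"):
            classify_pixels(trained_classifier, stacks[0])

    def test_all_background_section_has_low_false_positive_fraction(self, trained_classifier):
        from xirplesion.synthmuscle import classifier_benchmark_spec, generate_tissue_image

        spec = classifier_benchmark_spec(seed=900, lesion_density_per_mm2=0.0)
        img, gt, _roi = generate_tissue_image(spec)
        assert len(gt.areas_um2) == 0
        pred = classify_pixels(trained_classifier, compute_feature_stack(img))
        assert pred.mean() <= 0.01


class TestPersistence:
    def test_roundtrip_preserves_decisions(self, trained_classifier, heldout_sections, tmp_path):
        path = tmp_path / "clf.json"
        save_classifier(trained_classifier, path)
        loaded = load_classifier(path)
        assert loaded.selected_iteration == trained_classifier.selected_iteration
        assert loaded.feature_names == trained_classifier.feature_names
        img, *_ = heldout_sections[0]
        stack = compute_feature_stack(img)
        assert np.array_equal(
            classify_pixels(loaded, stack), classify_pixels(trained_classifier, stack)
        )

    def test_foreign_manifest_refused(self, tmp_path):
        bad = tmp_path / "not_clf.json"
        bad.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="manifest"):
            load_classifier(bad)
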