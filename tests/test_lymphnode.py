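"""Lymph-node pipeline: features, classifiers, segmentation, VCI."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ablaquant import lymphnode as ln, synth
from ablaquant.errors import FeatureError, ParameterError, TrainingError, \
    InvalidAnnotationError


class TestPixelFeatures:
    def test_constant_image(self):
        stack = ln.compute_pixel_features(np.full((64, 64), 3.5))
        cfg = ln.PixelFeatureConfig()
        assert stack.shape == (64, 64, cfg.n_planes)
        # plane order: (gaussian, det, eig_max, eig_min) per scale
        assert np.allclose(stack[..., 0], 3.5)
        assert np.allclose(stack[..., 1:4], 0.0, atol=1e-10)

    def test_isotropic_blob_equal_eigenvalues_at_center(self):
        yy, xx = np.mgrid[0:65, 0:65]
        img = np.exp(-(((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 6.0 ** 2)))
        stack = ln.compute_pixel_features(img)
        eig_max, eig_min = stack[32, 32, 2], stack[32, 32, 3]
        assert eig_max == pytest.approx(eig_min, rel=1e-6)

    def test_quadratic_ramp_hessian_determinant(self):
        a, b = 0.02, 0.05
        yy, xx = np.mgrid[0:96, 0:96].astype(float)
        img = a * (xx - 48) ** 2 + b * (yy - 48) ** 2
        stack = ln.compute_pixel_features(
            img, ln.PixelFeatureConfig(scales_px=(2.0,)))
        det_center = stack[48, 48, 1]
        assert det_center == pytest.approx(4 * a * b, rel=0.05)

    def test_too_small_image(self):
        with pytest.raises(ParameterError):
            ln.compute_pixel_features(np.zeros((8, 8)))


class TestPixelClassifier:
    @staticmethod
    def toy_scene(seed=0, shape=(192, 192)):
        spec = synth.LymphNodeSpec(seed=seed, shape=shape, n_lymphatic=2,
                                   n_blood=3, n_debris=0, noise_sd=2.0)
        scene = synth.gen_if_lymphnode(spec)
        labels = scene.channels["cd31"] > 100.0
        feats = ln.compute_pixel_features(scene.channels["cd31"])
        return feats, labels, scene

    def test_separable_training_accuracy(self):
        feats, labels, _ = self.toy_scene()
        clf = ln.train_pixel_classifier(feats, labels, seed=0)
        prob = clf.predict_proba(feats)
        acc = np.mean((prob > 0.5) == labels)
        assert acc >= 0.99
        losses = clf.training_loss_curve
        assert losses[-1] < losses[0]

    def test_seed_determinism(self):
        feats, labels, _ = self.toy_scene()
        c1 = ln.train_pixel_classifier(feats, labels, seed=7)
        c2 = ln.train_pixel_classifier(feats, labels, seed=7)
        for w1, w2 in zip(c1.model.coefs_, c2.model.coefs_):
            assert np.array_equal(w1, w2)

    def test_single_class_rejected(self):
        feats, labels, _ = self.toy_scene()
        with pytest.raises(TrainingError):
            ln.train_pixel_classifier(feats, np.zeros_like(labels), seed=0)

    def test_held_out_tile_accuracy(self):
        feats, labels, _ = self.toy_scene(seed=1)
        clf = ln.train_pixel_classifier(feats, labels, seed=1)
        feats2, labels2, _ = self.toy_scene(seed=2)
        acc = np.mean((clf.predict_proba(feats2) > 0.5) == labels2)
        assert acc >= 0.95


def disk_prob(shape, cy, cx, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return ((yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2).astype(float)


class TestSegmentation:
    def test_single_disk_geometry(self):
        # radius 10 um at 1 um/px
        prob = disk_prob((64, 64), 32, 32, 10.0)
        objs = ln.segment_vessels(prob, 0.5, pixel_size_um=1.0)
        assert len(objs) == 1
        o = objs[0]
        assert o.area_um2 == pytest.approx(math.pi * 100.0, rel=0.02)
        assert o.perimeter_um == pytest.approx(2 * math.pi * 10.0, rel=0.02)
        assert o.circularity == pytest.approx(1.0, abs=0.05)

    def test_two_disjoint_disks(self):
        prob = np.maximum(disk_prob((64, 128), 32, 32, 9),
                          disk_prob((64, 128), 32, 96, 9))
        assert len(ln.segment_vessels(prob, 0.5, 1.0)) == 2

    def test_notched_disk_solidity(self):
        prob = disk_prob((64, 64), 32, 32, 14)
        prob[28:36, 32:48] = 0.0  # notch
        objs = ln.segment_vessels(prob, 0.5, 1.0)
        assert len(objs) == 1
        assert objs[0].solidity < 0.95

    def test_digitized_circle_perimeter_convergence(self):
        """Sub-pixel contours keep a digitized circle near its ideal VCI."""
        for r in (10.0, 16.0, 25.0):
            n = int(4 * r + 16)
            prob = disk_prob((n, n), n // 2, n // 2, r)
            o = ln.segment_vessels(prob, 0.5, 1.0)[0]
            vci = ln.vascular_complexity_index([o])
            assert abs(vci - 1.0) < 0.02


class TestObjectClassification:
    @staticmethod
    def scene_objects(seed=4):
        spec = synth.LymphNodeSpec(seed=seed, shape=(384, 384))
        scene = synth.gen_if_lymphnode(spec)
        prob = np.clip((scene.channels["cd31"] - 60.0) / 80.0, 0, 1)
        objs = ln.segment_vessels(prob, 0.5, spec.pixel_size_um,
                                  cd31=scene.channels["cd31"],
                                  lyve1=scene.channels["lyve1"])
        return scene, objs, spec

    def test_fallback_rule_blood_vs_lymphatic(self):
        base = dict(polygon_um=((0, 0), (1, 0), (1, 1), (0, 1)),
                    area_um2=1.0, perimeter_um=4.0, circularity=0.8,
                    solidity=1.0, cd31_mean=100.0, cd31_median=100.0,
                    cd31_sd=5.0, lyve1_sd=2.0)
        at_bg = ln.VesselObject(id=0, lyve1_mean=20.0, **base)
        bright = ln.VesselObject(id=1, lyve1_mean=150.0, **base)
        out = ln.classify_objects([at_bg, bright],
                                  lyve1_background=(20.0, 4.0))
        assert out[0].vessel_class == "blood"
        assert out[1].vessel_class == "lymphatic"

    def test_generator_cohort_accuracy(self):
        scene, objs, spec = self.scene_objects()
        objs = ln.filter_by_area(objs, 15.0)
        out = ln.classify_objects(objs, lyve1_background=(
            spec.background, spec.noise_sd))
        truth = scene.truth[scene.truth["class"] != "debris"]
        # match objects to truth by centroid proximity
        correct = 0
        for o in out:
            xs = [p[0] for p in o.polygon_um]
            ys = [p[1] for p in o.polygon_um]
            cx, cy = np.mean(xs) / spec.pixel_size_um, \
                np.mean(ys) / spec.pixel_size_um
            d = np.hypot(truth.cx_px - cx, truth.cy_px - cy)
            if o.vessel_class == truth.iloc[int(np.argmin(d))]["class"]:
                correct += 1
        assert correct / len(out) >= 0.95

    def test_trained_ensemble_accuracy(self):
        scene, objs, spec = self.scene_objects(seed=5)
        objs = ln.filter_by_area(objs, 15.0)
        truth = scene.truth[scene.truth["class"] != "debris"]

        def truth_class(o):
            xs = [p[0] for p in o.polygon_um]
            ys = [p[1] for p in o.polygon_um]
            d = np.hypot(truth.cx_px - np.mean(xs) / spec.pixel_size_um,
                         truth.cy_px - np.mean(ys) / spec.pixel_size_um)
            return truth.iloc[int(np.argmin(d))]["class"]

        labels = [truth_class(o) for o in objs]
        clf = ln.ObjectClassifier.train(objs, labels, seed=0)
        scene2, objs2, spec2 = self.scene_objects(seed=6)
        objs2 = ln.filter_by_area(objs2, 15.0)
        truth = scene2.truth[scene2.truth["class"] != "debris"]
        out = ln.classify_objects(objs2, classifier=clf)
        acc = np.mean([o.vessel_class == truth_class(o) for o in out])
        assert acc >= 0.95

    def test_missing_features_rejected(self):
        o = ln.VesselObject(0, ((0, 0), (1, 0), (0, 1)), 1.0, 4.0, 0.8, 1.0)
        with pytest.raises(FeatureError):
            ln.classify_objects([o], lyve1_background=(10, 2))


class TestAreaFilter:
    @staticmethod
    def obj(area):
        return ln.VesselObject(0, ((0, 0), (1, 0), (0, 1)), area,
                               4.0, 0.8, 1.0)

    def test_boundary_kept(self):
        objs = [self.obj(a) for a in (10.0, 15.0, 20.0)]
        kept = ln.filter_by_area(objs, 15.0)
        assert [o.area_um2 for o in kept] == [15.0, 20.0]

    def test_zero_min_keeps_all(self):
        objs = [self.obj(a) for a in (1.0, 2.0)]
        assert len(ln.filter_by_area(objs, 0.0)) == 2

    def test_idempotent(self):
        objs = [self.obj(a) for a in (5.0, 15.0, 40.0)]
        once = ln.filter_by_area(objs, 15.0)
        assert ln.filter_by_area(once, 15.0) == once

    def test_negative_min_rejected(self):
        with pytest.raises(ParameterError):
            ln.filter_by_area([], -1.0)

    def test_debris_spiked_scene_recovers_truth(self):
        spec = synth.LymphNodeSpec(seed=9, shape=(384, 384), n_debris=8)
        scene = synth.gen_if_lymphnode(spec)
        prob = np.clip((scene.channels["cd31"] - 60.0) / 80.0, 0, 1)
        objs = ln.segment_vessels(prob, 0.5, spec.pixel_size_um)
        kept = ln.filter_by_area(objs, 15.0)
        n_true = int((scene.truth["class"] != "debris").sum())
        assert len(kept) == n_true


class TestVCI:
    def test_single_circle_is_one(self):
        r = 7.3
        assert ln.vascular_complexity_index(
            perimeters=[2 * math.pi * r], areas=[math.pi * r ** 2]) == \
            pytest.approx(1.0)

    def test_square(self):
        s = 2.0
        assert ln.vascular_complexity_index(
            perimeters=[4 * s], areas=[s * s]) == pytest.approx(4 / math.pi)

    @pytest.mark.parametrize("n", [1, 3, 10])
    def test_n_identical_circles(self, n):
        r = 5.0
        assert ln.vascular_complexity_index(
            perimeters=[2 * math.pi * r] * n,
            areas=[math.pi * r ** 2] * n) == pytest.approx(n)

    @given(st.floats(0.1, 100.0), st.floats(0.1, 50.0))
    def test_scale_invariance(self, r, k):
        v1 = ln.vascular_complexity_index(
            perimeters=[2 * math.pi * r], areas=[math.pi * r ** 2])
        v2 = ln.vascular_complexity_index(
            perimeters=[2 * math.pi * r * k], areas=[math.pi * (r * k) ** 2])
        assert v1 == pytest.approx(v2)

    def test_convex_object_at_least_one(self, rng):
        # isoperimetric inequality on random rectangles
        for _ in range(20):
            w, h = rng.uniform(0.5, 20, 2)
            assert ln.vascular_complexity_index(
                perimeters=[2 * (w + h)], areas=[w * h]) >= 1.0

    def test_empty_set_nan_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert math.isnan(ln.vascular_complexity_index(
                perimeters=[], areas=[]))


class TestNodeSummary:
    @staticmethod
    def circle(cx, cy, r, n=64):
        t = np.linspace(0, 2 * math.pi, n, endpoint=False)
        return tuple((cx + r * math.cos(a), cy + r * math.sin(a)) for a in t)

    def test_no_vessels(self):
        rec = ln.summarize_node(self.circle(500, 500, 400), (), [])
        assert rec.summaries["lymphatic"].count == 0
        assert rec.summaries["blood"].area_percent == 0.0

    def test_single_vessel_area_percent(self):
        node = ((0, 0), (1000.0, 0), (1000.0, 1000.0), (0, 1000.0))
        o = ln.VesselObject(0, self.circle(500, 500, 50), math.pi * 50 ** 2,
                            2 * math.pi * 50, 1.0, 1.0,
                            vessel_class="lymphatic")
        rec = ln.summarize_node(node, (), [o])
        assert rec.summaries["lymphatic"].area_percent == pytest.approx(
            100 * math.pi * 50 ** 2 / 1e6)
        assert rec.summaries["lymphatic"].vci == pytest.approx(1.0)

    def test_artifact_subtraction_and_validation(self):
        node = ((0, 0), (100.0, 0), (100.0, 100.0), (0, 100.0))
        half = ((0, 0), (100.0, 0), (100.0, 50.0), (0, 50.0))
        rec = ln.summarize_node(node, (half,), [])
        assert rec.net_area_mm2 == pytest.approx(5000.0 / 1e6)
        with pytest.raises(InvalidAnnotationError):
            ln.summarize_node(node, (node,), [])

    def test_record_serializes(self):
        rec = ln.summarize_node(self.circle(100, 100, 80), (), [])
        assert "net_area_mm2" in rec.to_json()


class TestPipelineDeterminism:
    def test_object_tables_identical_across_runs(self):
        def run():
            spec = synth.LymphNodeSpec(seed=21, shape=(256, 256))
            scene = synth.gen_if_lymphnode(spec)
            prob = np.clip((scene.channels["cd31"] - 60.0) / 80.0, 0, 1)
            objs = ln.segment_vessels(prob, 0.5, spec.pixel_size_um,
                                      cd31=scene.channels["cd31"],
                                      lyve1=scene.channels["lyve1"])
            objs = ln.filter_by_area(objs, 15.0)
            objs = ln.classify_objects(objs, lyve1_background=(
                spec.background, spec.noise_sd))
            return ln.objects_to_dataframe(objs).to_csv(index=False)

        assert run() == run()
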