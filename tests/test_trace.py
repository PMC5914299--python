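import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from nervemosaic.io_formats import DEFAULT_MICRONS_PER_PIXEL, Tracing, TracingSource
from nervemosaic.mosaic import Mosaic
from nervemosaic.synth import polyline_length
from nervemosaic.trace import (
    CandidateSegment,
    FilterBankConfig,
    Label,
    Region,
    ThresholdConfig,
    TraceConfig,
    auto_trace,
    classify_segments,
    compute_density,
    compute_whorl_density,
    enhance_nerves,
    extract_candidates,
    label_candidates_by_truth,
    train_classifier,
)


def _line_image(size=256, width_sigma=1.2, angle="h"):
    img = np.zeros((size, size))
    if angle == "h":
        img[size // 2] = 1.0
    else:
        img[:, size // 2] = 1.0
    return gaussian_filter(img, width_sigma) * 10 + 0.1


def _full_mosaic(pixels, scale=DEFAULT_MICRONS_PER_PIXEL):
    pixels = np.asarray(pixels, dtype=float)
    return Mosaic(pixels=pixels, weight_map=np.ones_like(pixels),
                  coverage_mask=np.ones(pixels.shape, bool),
                  microns_per_pixel=scale, contributing_frames=[1])


class TestEnhance:
    def test_constant_image_no_response(self):
        resp = enhance_nerves(np.full((128, 128), 0.5))
        assert np.abs(resp).max() < 1e-9

    def test_bright_line_gives_ridge(self):
        img = _line_image()
        resp = enhance_nerves(img)
        mid = resp[128, 40:216]
        off = resp[100, 40:216]
        assert mid.mean() > 5 * off.mean()

    def test_rotation_covariance_90deg(self):
        img = _line_image(angle="h")
        r_h = enhance_nerves(img)
        r_v = enhance_nerves(np.rot90(img))
        np.testing.assert_allclose(np.rot90(r_h), r_v, atol=1e-6)

    def test_degenerate_bank_errors(self):
        with pytest.raises(ValueError):
            FilterBankConfig(n_orientations=0)


class TestCandidates:
    def test_zero_response_empty(self):
        assert extract_candidates(np.zeros((64, 64))) == []

    def test_straight_line_single_candidate(self):
        img = _line_image(size=350)
        resp = enhance_nerves(img)
        cands = extract_candidates(resp, ThresholdConfig(min_length_px=50),
                                   intensity=img)
        assert len(cands) == 1
        assert polyline_length(cands[0].polyline) == pytest.approx(349, abs=8)
        assert np.isfinite(cands[0].features).all()

    def test_cross_decomposes_at_junction(self):
        size = 256
        img = np.zeros((size, size))
        img[size // 2] = 1.0
        img[:, size // 2] = 1.0
        img = gaussian_filter(img, 1.2) * 10 + 0.1
        resp = enhance_nerves(img)
        cands = extract_candidates(resp, ThresholdConfig(min_length_px=40),
                                   intensity=img)
        # two crossing lines split into 4 branchless arms at the junction
        assert len(cands) == 4


class TestClassifier:
    def _toy_candidates(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        cands = []
        for k in range(n):
            label = Label.NERVE if k % 2 == 0 else Label.OTHER
            center = 3.0 if label is Label.NERVE else -3.0
            feats = rng.normal(center, 0.5, 8)
            poly = np.array([[0.0, 0.0], [10.0, float(k)]])
            cands.append(CandidateSegment(polyline=poly, mean_response=1.0,
                                          features=feats, label=label))
        return cands

    def test_separable_toy_perfect_training_accuracy(self):
        cands = self._toy_candidates()
        model = train_classifier(cands, seed=0)
        out = classify_segments(cands, model)
        assert all(o.label == c.label for o, c in zip(out, cands))

    def test_single_class_errors(self):
        cands = [c for c in self._toy_candidates() if c.label is Label.NERVE]
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(cands)

    def test_empty_candidate_list(self, nerve_classifier):
        assert classify_segments([], nerve_classifier) == []

    def test_untrained_model_errors(self):
        with pytest.raises(ValueError):
            classify_segments(self._toy_candidates(4), None)

    def test_duplicate_candidates_identical_labels(self, nerve_classifier):
        c = self._toy_candidates(2)[0]
        out = classify_segments([c, c], nerve_classifier)
        assert out[0].label == out[1].label

    def test_retrain_same_seed_identical_decisions(self):
        train = self._toy_candidates(40, seed=1)
        test = self._toy_candidates(20, seed=2)
        m1 = train_classifier(train, seed=7)
        m2 = train_classifier(train, seed=7)
        l1 = [c.label for c in classify_segments(test, m1)]
        l2 = [c.label for c in classify_segments(test, m2)]
        assert l1 == l2

    def test_phantom_train_test_generalization(self, small_scene, nerve_classifier):
        # candidates from a scene never seen in training; labels from truth
        spec, scene, truth = small_scene
        resp = enhance_nerves(scene)
        cands = extract_candidates(resp, intensity=scene)
        truth_px = [np.asarray(p) / spec.microns_per_pixel
                    for p in truth.nerve_polylines]
        labeled = label_candidates_by_truth(cands, truth_px)
        pred = classify_segments(cands, nerve_classifier)
        agree = np.mean([p.label == t.label for p, t in zip(pred, labeled)])
        assert agree >= 0.9


class TestAutoTrace:
    def test_blank_mosaic_empty_tracing(self):
        m = _full_mosaic(np.full((256, 256), 0.2))
        t = auto_trace(m)
        assert t.polylines == []
        assert t.source is TracingSource.AUTO

    def test_scene_length_recovery(self, small_scene):
        spec, scene, truth = small_scene
        t = auto_trace(_full_mosaic(scene))
        err = abs(t.total_length_mm() - truth.total_length_mm) / truth.total_length_mm
        assert err < 0.15

    def test_tiled_matches_untiled(self, small_scene):
        spec, scene, truth = small_scene
        full = auto_trace(_full_mosaic(scene))
        tiled = auto_trace(_full_mosaic(scene),
                           config=TraceConfig(tile_size=512, tile_overlap=96))
        assert abs(tiled.total_length_mm() - full.total_length_mm()) \
            / full.total_length_mm() < 0.02


class TestDensity:
    def test_exact_quotient(self):
        t = Tracing(polylines=[np.array([[0.0, 0.0], [3000.0 * 384 / 400, 0.0]])])
        # 3000 px-equivalents scaled: compute via total_length_mm directly
        res = compute_density(t, area_mm2=1.5)
        assert res.density_mm_per_mm2 == pytest.approx(res.total_length_mm / 1.5)
        assert res.region is Region.WHOLE_MOSAIC

    def test_empty_like_tracing_zero_density(self):
        t = Tracing(polylines=[np.array([[0.0, 0.0], [0.0, 1e-9]])])
        assert compute_density(t, 2.0).density_mm_per_mm2 == pytest.approx(0.0, abs=1e-9)

    def test_nonpositive_area_errors(self):
        t = Tracing(polylines=[np.array([[0.0, 0.0], [1.0, 0.0]])])
        with pytest.raises(ValueError):
            compute_density(t, 0.0)

    def test_scale_consistency(self):
        poly = np.array([[0.0, 0.0], [100.0, 0.0]])
        t1 = Tracing(polylines=[poly], microns_per_pixel=1.0)
        t2 = Tracing(polylines=[poly], microns_per_pixel=2.0)
        # doubling the scale doubles length; with area quadrupled the
        # density halves
        d1 = compute_density(t1, 1.0).density_mm_per_mm2
        d2 = compute_density(t2, 4.0).density_mm_per_mm2
        assert d2 == pytest.approx(d1 / 2.0)


class TestWhorl:
    scale = DEFAULT_MICRONS_PER_PIXEL
    radius_px = 400.0 / scale  # 800 um diameter

    def _mosaic(self, size=900):
        return _full_mosaic(np.full((size, size), 0.3))

    def test_chord_through_center(self):
        m = self._mosaic()
        c = (450.0, 450.0)
        t = Tracing(polylines=[np.array([[0.0, 450.0], [899.0, 450.0]])],
                    microns_per_pixel=self.scale)
        res = compute_whorl_density(t, m, c)
        assert res.total_length_mm == pytest.approx(0.8, rel=1e-3)
        assert res.region is Region.WHORL

    def test_fully_covered_disc_area(self):
        res = compute_whorl_density(
            Tracing(polylines=[np.array([[0.0, 450.0], [899.0, 450.0]])],
                    microns_per_pixel=self.scale),
            self._mosaic(), (450.0, 450.0))
        assert res.area_mm2 == pytest.approx(np.pi * 0.4 ** 2, rel=2e-3)

    def test_nerve_outside_disc_zero_length(self):
        t = Tracing(polylines=[np.array([[0.0, 10.0], [899.0, 10.0]])],
                    microns_per_pixel=self.scale)
        res = compute_whorl_density(t, self._mosaic(), (450.0, 450.0))
        assert res.total_length_mm == 0.0

    def test_partial_coverage_counts_covered_pixels_only(self):
        m = self._mosaic()
        m.coverage_mask[:, 450:] = False
        res = compute_whorl_density(
            Tracing(polylines=[np.array([[0.0, 450.0], [899.0, 450.0]])],
                    microns_per_pixel=self.scale), m, (449.0, 450.0))
        assert res.area_mm2 == pytest.approx(np.pi * 0.4 ** 2 / 2, rel=2e-2)

    def test_center_outside_coverage_errors(self):
        m = self._mosaic()
        m.coverage_mask[:] = False
        with pytest.raises(ValueError):
            compute_whorl_density(
                Tracing(polylines=[np.array([[0.0, 0.0], [1.0, 0.0]])]),
                m, (450.0, 450.0))

    def test_clipped_length_bounded_by_total(self, small_scene):
        spec, scene, truth = small_scene
        m = _full_mosaic(scene)
        t = Tracing(polylines=[np.asarray(p) / spec.microns_per_pixel
                               for p in truth.nerve_polylines],
                    microns_per_pixel=spec.microns_per_pixel)
        h, w = scene.shape
        res = compute_whorl_density(t, m, (w / 2, h / 2))
        assert res.total_length_mm <= t.total_length_mm() + 1e-9
        assert res.area_mm2 <= np.pi * 0.4 ** 2 + 1e-9
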