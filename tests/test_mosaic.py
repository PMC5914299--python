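import numpy as np
import pytest

from nervemosaic.io_formats import Frame
from nervemosaic.mosaic import (
    MosaicConfig,
    MotionCurve,
    StripeMatch,
    blend,
    build_mosaics,
    decompose_into_stripes,
    fit_motion_curves,
    frame_offsets_from_positions,
    local_ncc_shift,
    mosaic_area_mm2,
    phase_correlate,
    register_pair,
    select_pairs,
    solve_positions,
    warp_frame,
)


def _frame(pixels, index=1):
    return Frame(pixels=pixels, index=index)


class TestStripes:
    def test_twelve_equal_stripes(self, rng):
        f = _frame(rng.random((384, 384)))
        stripes = decompose_into_stripes(f)
        assert len(stripes) == 12
        assert all(s.pixel_rows.shape == (32, 384) for s in stripes)
        assert [s.stripe_index for s in stripes] == list(range(1, 13))

    def test_reassembly_is_identity(self, rng):
        f = _frame(rng.random((384, 384)))
        stripes = decompose_into_stripes(f)
        np.testing.assert_array_equal(
            np.vstack([s.pixel_rows for s in stripes]), f.pixels)

    def test_constant_frame_constant_stripes(self):
        stripes = decompose_into_stripes(_frame(np.full((384, 384), 7.0)))
        assert all((s.pixel_rows == 7.0).all() for s in stripes)

    def test_indivisible_height_errors(self):
        with pytest.raises(ValueError):
            decompose_into_stripes(_frame(np.zeros((100, 384))))


class TestPhaseCorrelate:
    def test_identity_shift(self, rng):
        a = rng.random((64, 128))
        u, peak = phase_correlate(a, a)
        np.testing.assert_allclose(u, [0, 0], atol=1e-6)
        assert peak > 0.99

    def test_circular_shift_recovered(self, rng):
        a = rng.random((64, 128))
        b = np.roll(a, (-3, 5), axis=(0, 1))  # content moves by (dx=5, dy=-3)
        u, _ = phase_correlate(a, b)
        np.testing.assert_allclose(u, [5, -3], atol=0.5)

    def test_antisymmetry(self, rng):
        a = rng.random((64, 128))
        b = np.roll(a, (4, -7), axis=(0, 1))
        u_ab, _ = phase_correlate(a, b)
        u_ba, _ = phase_correlate(b, a)
        np.testing.assert_allclose(u_ab, -u_ba, atol=0.1)

    def test_independent_noise_rejected(self, rng):
        a = rng.random((32, 384))
        b = rng.random((32, 384))
        _, peak = phase_correlate(a, b)
        assert peak < MosaicConfig().peak_threshold

    def test_all_zero_stripe_flagged(self):
        u, peak = phase_correlate(np.zeros((32, 384)), np.zeros((32, 384)))
        assert peak == 0.0
        assert np.isnan(u).all()

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            phase_correlate(np.zeros((32, 32)), np.zeros((16, 32)))


class TestLocalNcc:
    def test_known_small_shift(self, rng):
        base = rng.random((40, 300))
        a = base[4:36, 10:290]
        b = base[6:38, 7:287]  # content of a appears in b at (+3, -2)
        u, score = local_ncc_shift(a, b)
        np.testing.assert_allclose(u, [3, -2], atol=0.3)
        assert score > 0.9


class TestSelectPairs:
    @pytest.mark.parametrize("n,expected", [(1, 0), (2, 1), (20, 190), (50, 1225)])
    def test_all_pairs_count(self, n, expected):
        pairs = select_pairs(n)
        assert len(pairs) == expected
        assert all(i < j for i, j in pairs)


class TestSolver:
    def test_single_frame_vertical_line(self):
        pos = solve_positions([], n_frames=1)
        p = np.array([pos.p[(1, m)] for m in range(1, 13)])
        np.testing.assert_allclose(p[:, 0], 0.0, atol=1e-9)
        np.testing.assert_allclose(p[:, 1], 32 * np.arange(12), atol=1e-9)

    def test_chain_of_exact_matches(self):
        # 3 frames offset by exactly (128, 0); same-index stripe matches
        matches = []
        for i in (1, 2):
            for m in range(1, 13):
                matches.append(StripeMatch(a=(i, m), b=(i + 1, m),
                                           u=np.array([128.0, 0.0]), peak=1.0))
        pos = solve_positions(matches, 3)
        offs = frame_offsets_from_positions(pos)
        np.testing.assert_allclose(offs[2] - offs[1], [128, 0], atol=1e-6)
        np.testing.assert_allclose(offs[3] - offs[2], [128, 0], atol=1e-6)

    def test_noisy_matches_recovered_within_1px(self, rng):
        # 2x3 grid of frames, noisy measurements sigma=0.3 px
        truth = {i: np.array([(i - 1) % 3 * 230.0, (i - 1) // 3 * 230.0])
                 for i in range(1, 7)}
        matches = []
        for i in range(1, 7):
            for j in range(i + 1, 7):
                if np.abs(truth[j] - truth[i]).max() > 250:
                    continue
                for m in range(1, 13):
                    u = truth[j] - truth[i] + rng.normal(0, 0.3, 2)
                    matches.append(StripeMatch(a=(i, m), b=(j, m),
                                               u=u, peak=1.0))
        pos = solve_positions(matches, 6)
        offs = frame_offsets_from_positions(pos)
        sol = np.array([offs[i] for i in range(1, 7)])
        tru = np.array([truth[i] for i in range(1, 7)])
        err = sol - tru - (sol - tru).mean(axis=0)
        assert np.sqrt((err ** 2).sum(axis=1).mean()) < 1.0

    def test_disconnected_graph_splits_components(self):
        matches = [StripeMatch(a=(1, m), b=(2, m), u=np.array([100.0, 0.0]),
                               peak=1.0) for m in range(1, 13)]
        pos = solve_positions(matches, 4)  # frames 3,4 unmatched
        assert pos.component_of[1] == pos.component_of[2]
        assert len({pos.component_of[i] for i in range(1, 5)}) == 3


class TestMotionCurves:
    def _positions_from_anchor_fn(self, fn):
        from nervemosaic.mosaic import StripePositions
        p = {}
        for m in range(1, 13):
            row = 32 * (m - 1) + 15.5
            p[(1, m)] = np.array([fn(row), 32.0 * (m - 1)])
        return StripePositions(p=p, component_of={1: 0}, residual_rms=0.0)

    def test_linear_anchors_reproduced(self):
        pos = self._positions_from_anchor_fn(lambda r: 0.5 * r + 3.0)
        curve = fit_motion_curves(pos)[1]
        rows = np.arange(384)
        np.testing.assert_allclose(curve.row_positions[:, 0],
                                   0.5 * rows + 3.0, atol=1e-9)
        # y follows the rows exactly for rigid vertical stacking
        np.testing.assert_allclose(np.diff(curve.row_positions[:, 1]), 1.0,
                                   atol=1e-9)

    def test_quadratic_anchors_interpolated(self):
        pos = self._positions_from_anchor_fn(lambda r: 1e-3 * r ** 2)
        curve = fit_motion_curves(pos)[1]
        anchor_rows = 32 * np.arange(12) + 15.5
        np.testing.assert_allclose(
            curve.row_positions[np.round(anchor_rows - 0.5).astype(int) + 0, 0],
            1e-3 * np.round(anchor_rows - 0.5) ** 2, atol=2e-2)
        # interior rows close to the quadratic (splines reproduce smooth data)
        interior = np.arange(16, 368)
        np.testing.assert_allclose(curve.row_positions[interior, 0],
                                   1e-3 * interior ** 2, atol=1e-3)


class TestWarpBlend:
    def _identity_curve(self, index=1):
        rows = np.arange(384, dtype=float)
        rp = np.column_stack([np.zeros(384), rows])
        return MotionCurve(frame_index=index, row_positions=rp)

    def test_identity_warp_reproduces_frame(self, rng):
        img = rng.random((384, 384))
        wf = warp_frame(_frame(img), self._identity_curve(),
                        origin=np.array([0.0, 0.0]), out_shape=(384, 384))
        np.testing.assert_allclose(wf.image[wf.valid],
                                   img[wf.valid], atol=1e-9)

    def test_pure_translation(self, rng):
        img = rng.random((384, 384))
        rp = self._identity_curve().row_positions + np.array([10.0, 0.0])
        wf = warp_frame(_frame(img), MotionCurve(1, rp),
                        origin=np.array([0.0, 0.0]), out_shape=(384, 400))
        np.testing.assert_allclose(wf.image[:, 10:394][wf.valid[:, 10:394]],
                                   img[wf.valid[:, 10:394]], atol=1e-9)

    def test_blend_of_identical_frames_is_identity(self, rng):
        img = rng.random((384, 384))
        wfs = [warp_frame(_frame(img, i), self._identity_curve(i),
                          origin=np.array([0.0, 0.0]), out_shape=(384, 384))
               for i in (1, 2)]
        m = blend(wfs, microns_per_pixel=400 / 384)
        np.testing.assert_allclose(m.pixels[m.coverage_mask],
                                   img[m.coverage_mask], atol=1e-9)

    def test_blend_weighted_mean_of_constants(self):
        a = warp_frame(_frame(np.full((384, 384), 10.0), 1),
                       self._identity_curve(1), origin=np.zeros(2),
                       out_shape=(384, 384))
        b = warp_frame(_frame(np.full((384, 384), 30.0), 2),
                       self._identity_curve(2), origin=np.zeros(2),
                       out_shape=(384, 384))
        m = blend([a, b], microns_per_pixel=400 / 384)
        np.testing.assert_allclose(m.pixels[m.coverage_mask], 20.0, atol=1e-9)

    def test_blend_empty_errors(self):
        with pytest.raises(ValueError):
            blend([], microns_per_pixel=1.0)


class TestArea:
    def _mosaic_one_frame(self):
        img = np.ones((384, 384))
        wf = warp_frame(_frame(img), TestWarpBlend()._identity_curve(),
                        origin=np.zeros(2), out_shape=(384, 384))
        return blend([wf], microns_per_pixel=400 / 384)

    def test_single_field_area(self):
        m = self._mosaic_one_frame()
        assert mosaic_area_mm2(m) == pytest.approx(0.16, abs=1e-12)

    def test_exclusion_halves_area(self):
        m = self._mosaic_one_frame()
        excl = np.zeros_like(m.coverage_mask)
        excl[:192] = True
        assert mosaic_area_mm2(m, excl) == pytest.approx(0.08, abs=1e-12)

    def test_exclusion_shape_mismatch_errors(self):
        m = self._mosaic_one_frame()
        with pytest.raises(ValueError):
            mosaic_area_mm2(m, np.zeros((10, 10), bool))


class TestRegistration:
    def test_two_identical_frames(self, rng):
        img = rng.random((384, 384))
        ms = register_pair(_frame(img, 1), _frame(img, 2), MosaicConfig())
        assert len(ms) >= 12
        for mt in ms:
            np.testing.assert_allclose(
                mt.u, [0, 32 * (mt.b[1] - mt.a[1])], atol=0.3)

    def test_known_offset_recovered(self, small_scene):
        _spec, scene, _truth = small_scene
        a = _frame(scene[:384, :384], 1)
        b = _frame(scene[:384, 100:484], 2)  # frame b sits 100 px to the right
        ms = register_pair(a, b, MosaicConfig())
        assert len(ms) >= 3
        mean_u = np.mean([mt.u - [0, 32 * (mt.b[1] - mt.a[1])] for mt in ms],
                         axis=0)
        np.testing.assert_allclose(mean_u, [100, 0], atol=0.5)

    def test_independent_noise_no_matches(self, rng):
        a = _frame(rng.random((384, 384)), 1)
        b = _frame(rng.random((384, 384)), 2)
        assert register_pair(a, b, MosaicConfig()) == []


class TestBuildMosaics:
    def test_empty_frame_list_errors(self):
        with pytest.raises(ValueError):
            build_mosaics([])

    def test_single_frame_mosaic(self, rng):
        ms = build_mosaics([_frame(rng.random((384, 384)))])
        assert len(ms) == 1
        assert ms[0].coverage_area_mm2 == pytest.approx(0.16, abs=1e-6)

    def test_small_phantom_one_component(self, small_sequence):
        _spec, frames, truth, _scene = small_sequence
        ms = build_mosaics(frames)
        assert len(ms) == 1
        assert sorted(ms[0].contributing_frames) == [1, 2, 3, 4]
        # coverage close to the union of truth footprints
        tp = truth.frame_positions_px
        lo = tp.min(axis=0)
        hi = tp.max(axis=0) + 384
        union_px = np.zeros((int(hi[1] - lo[1]) + 1, int(hi[0] - lo[0]) + 1), bool)
        for x, y in tp:
            xi, yi = int(x - lo[0]), int(y - lo[1])
            union_px[yi:yi + 384, xi:xi + 384] = True
        assert ms[0].coverage_mask.sum() == pytest.approx(union_px.sum(), rel=0.05)
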