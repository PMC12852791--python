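import numpy as np
import pytest
from dataclasses import replace

from optoloop import vision
from optoloop.microscope import (Frame, LexyGeometry, Optics,
                                 render_lexy_frame, render_migration_frame)
from optoloop.plants import LexyPlant, MigratingCell
from optoloop.vision import (CalibrationError, CompartmentCalibration,
                             SegmentationParams, TemporalFilter, Tracker,
                             calibrate_range, ctcf, measure_compartments,
                             segment_frame)


def _cell(x, y, expression=30000.0):
    return MigratingCell(position=np.array([x, y]), polarity=(1.0, 0.0),
                         expression=expression)


class TestSegmentation:
    def test_single_cell_centroid_accuracy(self, optics):
        c = _cell(30.4, 33.7)
        f = render_migration_frame([c], optics, rng=None)
        seg = segment_frame(f, "whole-cell")
        assert seg.labels == [1]
        cx, cy = seg.centroids[1]
        assert cx == pytest.approx(30.4, abs=0.2)
        assert cy == pytest.approx(33.7, abs=0.2)

    def test_blank_frame_empty_result(self, optics):
        f = Frame(np.full(optics.shape, optics.background), 1.0)
        seg = segment_frame(f)
        assert seg.labels == []

    def test_two_symmetric_cells_equal_areas(self):
        optics = Optics(shape=(64, 128))
        f = render_migration_frame([_cell(32, 32), _cell(96, 32)], optics,
                                   rng=None)
        seg = segment_frame(f)
        assert len(seg.labels) == 2
        a1, a2 = (seg.areas[l] for l in seg.labels)
        assert abs(a1 - a2) / max(a1, a2) < 0.05

    def test_nucleus_cytosol_roundtrip_ratio_grid(self, optics, lexy_geometry):
        """Segment-then-measure recovers N/C within 2% across a state grid."""
        cal = CompartmentCalibration((0.0, 1.0), (0.0, 1.0))
        for N, C in [(0.8, 0.2), (0.6, 0.3), (0.9, 0.45), (0.3, 0.6)]:
            p = LexyPlant(N=N, C=C)
            marker = render_lexy_frame([p], [lexy_geometry], optics,
                                       rng=None, channel="marker")
            reporter = render_lexy_frame([p], [lexy_geometry], optics,
                                         rng=None, channel="reporter")
            seg = segment_frame(marker, "nucleus+cytosol")
            assert seg.labels == [1]
            seg_r = replace(seg, background=vision._background(
                reporter.pixels, seg.label_mask > 0)[0])
            m = measure_compartments(reporter, seg_r, 1, cal)
            assert m.valid
            assert m.nucleus_mean / m.cytosol_mean == pytest.approx(
                N / C, rel=0.02)


class TestTracker:
    def test_persistent_single_track(self, optics):
        tracker = Tracker(max_step=10.0, max_gap=2)
        ids = set()
        for k in range(10):
            f = render_migration_frame([_cell(20.0 + 2 * k, 32.0)], optics,
                                       rng=None)
            seg = segment_frame(f)
            ids |= set(tracker.update(seg, k))
        assert ids == {1}

    def test_gap_closure_spawns_new_id(self, optics):
        tracker = Tracker(max_step=10.0, max_gap=1)
        f = render_migration_frame([_cell(32, 32)], optics, rng=None)
        seg = segment_frame(f)
        empty = segment_frame(Frame(np.full(optics.shape, 100.0), 1.0))
        assert tracker.update(seg, 0) == {1: 1}
        tracker.update(empty, 1)
        tracker.update(empty, 2)
        assert tracker.update(seg, 3) == {2: 1}   # old track closed

    def test_no_assignment_beyond_gate(self):
        """Detections farther than max_step from every track terminate the
        old tracks (after the gap) and spawn fresh ids — identities are never
        stretched across impossible jumps."""
        tracker = Tracker(max_step=8.0, max_gap=0)

        def fake_seg(p1, p2):
            lm = np.zeros((4, 4), np.int32)
            return vision.SegmentationResult(
                lm, {1: p1, 2: p2}, {1: 10, 2: 10}, {1: 1.0, 2: 1.0})

        a0 = tracker.update(fake_seg((0.0, 0.0), (30.0, 0.0)), 0)
        a1 = tracker.update(fake_seg((10.0, 40.0), (10.0, -40.0)), 1)
        assert set(a1).isdisjoint(set(a0))
        assert set(tracker.tracks) == set(a1)   # old tracks closed

    def test_identity_preserved_long_run(self, optics):
        """Well-separated cells keep their ids over hundreds of frames."""
        rng = np.random.default_rng(8)
        tracker = Tracker(max_step=12.0, max_gap=2)
        optics2 = Optics(shape=(64, 128))
        pos = np.array([[32.0, 32.0], [96.0, 32.0]])
        first = None
        for k in range(300):
            pos += rng.normal(0, 1.0, pos.shape)
            pos = np.clip(pos, 16, [112, 48])
            pos[1, 0] = max(pos[1, 0], pos[0, 0] + 50)  # keep 4+ radii apart
            cells = [_cell(*p) for p in pos]
            seg = segment_frame(render_migration_frame(cells, optics2,
                                                       rng=None))
            assign = tracker.update(seg, k)
            by_x = sorted(assign, key=lambda t: seg.centroids[assign[t]][0])
            if first is None:
                first = by_x
            assert by_x == first


class TestCompartments:
    def test_normalisation_and_contrast(self):
        cal = CompartmentCalibration((20.0, 100.0), (5.0, 60.0))
        lm = np.zeros((20, 20), np.int32)
        lm[2:18, 2:18] = 1
        nm = np.zeros_like(lm)
        nm[6:14, 6:14] = 1
        img = np.full((20, 20), 10.0)
        img[lm == 1] = 30.0      # cytosol
        img[nm == 1] = 100.0     # nucleus
        seg = vision.SegmentationResult(lm, {1: (10.0, 10.0)}, {1: 256},
                                        {1: 50.0}, background=10.0,
                                        nucleus_mask=nm)
        m = measure_compartments(Frame(img, 1.0), seg, 1, cal, erosion=1)
        assert m.normalised_nucleus == pytest.approx((90 - 20) / 80.0)
        assert m.contrast_ok

    def test_equal_means_low_contrast(self):
        cal = CompartmentCalibration((0.0, 100.0), (0.0, 100.0))
        lm = np.zeros((20, 20), np.int32)
        lm[2:18, 2:18] = 1
        nm = np.zeros_like(lm)
        nm[6:14, 6:14] = 1
        img = np.full((20, 20), 50.0)
        seg = vision.SegmentationResult(lm, {1: (10.0, 10.0)}, {1: 256},
                                        {1: 50.0}, background=0.0,
                                        nucleus_mask=nm)
        m = measure_compartments(Frame(img, 1.0), seg, 1, cal)
        assert not m.contrast_ok

    def test_missing_nucleus_invalid(self):
        cal = CompartmentCalibration((0.0, 1.0), (0.0, 1.0))
        lm = np.zeros((10, 10), np.int32)
        lm[2:8, 2:8] = 1
        seg = vision.SegmentationResult(lm, {1: (5.0, 5.0)}, {1: 36},
                                        {1: 1.0}, nucleus_mask=np.zeros_like(lm))
        m = measure_compartments(Frame(np.ones((10, 10)), 1.0), seg, 1, cal)
        assert not m.valid


class TestTemporalFilter:
    def test_all_valid_identity(self):
        tf = TemporalFilter()
        out = [tf.update(v, True) for v in (0.1, 0.2, 0.3)]
        assert out == [0.1, 0.2, 0.3]

    def test_invalid_frame_held(self):
        tf = TemporalFilter()
        tf.update(0.4, True)
        assert tf.update(99.0, False) == 0.4

    def test_alternating_piecewise_constant(self):
        tf = TemporalFilter()
        out = []
        for k, v in enumerate([0.1, 9.0, 0.3, 9.0, 0.5]):
            out.append(tf.update(v, k % 2 == 0))
        assert out == [0.1, 0.1, 0.3, 0.3, 0.5]

    def test_never_valid_defers(self):
        tf = TemporalFilter()
        assert tf.update(1.0, False) is None

    def test_median_mode_within_convex_hull(self):
        """Filter output never leaves the hull of valid window values."""
        rng = np.random.default_rng(4)
        tf = TemporalFilter("median", window=5)
        valid_vals = []
        for _ in range(100):
            v = rng.uniform(0, 1)
            ok = rng.random() > 0.4
            out = tf.update(v, ok)
            if ok:
                valid_vals.append(v)
                valid_vals = valid_vals[-5:]
            if out is not None and valid_vals:
                assert min(valid_vals) - 1e-12 <= out <= max(valid_vals) + 1e-12


class TestCalibration:
    def test_ranges_oriented_by_state(self):
        cal = calibrate_range([(100.0, 5.0)], [(20.0, 60.0)])
        assert cal.nucleus_range == (20.0, 100.0)
        assert cal.cytosol_range == (5.0, 60.0)

    def test_indistinguishable_states_fail(self):
        with pytest.raises(CalibrationError):
            calibrate_range([(50.0, 50.0)], [(50.0, 50.0)])

    def test_rendered_calibration_brackets_run(self, optics, lexy_geometry):
        """Dark/saturated calibration brackets any intermediate state."""
        from optoloop.plants import lexy_step

        def measure(p):
            marker = render_lexy_frame([p], [lexy_geometry], optics,
                                       rng=None, channel="marker")
            reporter = render_lexy_frame([p], [lexy_geometry], optics,
                                         rng=None)
            seg = segment_frame(marker, "nucleus+cytosol")
            seg = replace(seg, background=vision._background(
                reporter.pixels, seg.label_mask > 0)[0])
            return vision._compartment_means(reporter, seg, 1)

        dark = LexyPlant()
        lit = lexy_step(LexyPlant(), 10.4, 3600.0)
        cal = calibrate_range([measure(dark)], [measure(lit)])
        mid = lexy_step(LexyPlant(), 1.0, 600.0)
        nuc, cyto = measure(mid)
        assert cal.nucleus_range[0] <= nuc <= cal.nucleus_range[1]
        assert cal.cytosol_range[0] <= cyto <= cal.cytosol_range[1]


class TestCTCF:
    def test_direct_formula(self):
        img = np.zeros((10, 10))
        cell = np.zeros((10, 10), bool)
        cell[0, :10] = True
        img[0, :10] = 100.0
        bg = np.zeros((10, 10), bool)
        bg[5:, :] = True
        img[bg] = 5.0
        assert ctcf(img, cell, bg) == pytest.approx(1000.0 - 10 * 5.0)

    def test_uniform_image_zero(self):
        img = np.full((10, 10), 7.0)
        cell = np.zeros((10, 10), bool)
        cell[:3, :3] = True
        bg = ~cell
        assert ctcf(img, cell, bg) == pytest.approx(0.0)

    def test_recovers_rendered_signal(self, optics):
        c = _cell(32, 32, expression=25000.0)
        f = render_migration_frame([c], optics, rng=None)
        seg = segment_frame(f)
        cell = seg.label_mask == 1
        from scipy import ndimage
        bg = ~ndimage.binary_dilation(cell, iterations=6)
        got = ctcf(f.pixels, ndimage.binary_dilation(cell, iterations=4), bg)
        assert got == pytest.approx(25000.0, rel=0.02)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            ctcf(np.ones((5, 5)), np.ones((5, 5), bool),
                 np.zeros((5, 5), bool))
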