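"""Circle-annulus measurement, traces, ensembles and tethering metrics."""

import dataclasses
import math

import numpy as np
import pytest

from fusionmode import (ImagingParams, KineticParams, ReporterModel, RoiGeometry)
from fusionmode.config import DetectionParams, QuantifyParams
from fusionmode.kinetics import event_brightness, simulate_event_kinetics
from fusionmode.quantify import (EnsembleError, FusionEvent, GeometryError,
                                 NormalizationError, Trace,
                                 circle_annulus_intensity, detect_fusion_events,
                                 ensemble_average, excise_ministack,
                                 extract_trace, normalize_marker_trace,
                                 normalize_reporter_trace, tethering_metrics)
from fusionmode.render import ChannelSpec, default_channels, render_movie


def roi_oracle(frame, center, geometry, pixel_size):
    """Exhaustive pixel-by-pixel evaluation of the circle-annulus measure."""
    r_c = geometry.circle_diameter / 2
    r_in = geometry.annulus_inner / 2
    r_out = geometry.annulus_outer / 2
    circ_sum = circ_n = ann_sum = ann_n = 0.0
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            d = pixel_size * math.hypot(i - center[0], j - center[1])
            if d <= r_c:
                circ_sum += frame[i, j]
                circ_n += 1
            elif r_in < d <= r_out:
                ann_sum += frame[i, j]
                ann_n += 1
    return circ_sum / circ_n - ann_sum / ann_n


class TestCircleAnnulus:
    def test_matches_enumeration_oracle_on_random_frames(self, geometry, rng):
        for _ in range(25):
            px = rng.uniform(0.08, 0.4)
            n = rng.integers(21, 41)
            frame = rng.uniform(0, 4000, size=(n, n))
            center = (n / 2 + rng.uniform(-1, 1), n / 2 + rng.uniform(-1, 1))
            got = circle_annulus_intensity(frame, center, geometry, px)
            want = roi_oracle(frame, center, geometry, px)
            assert got == pytest.approx(want, abs=1e-9)

    def test_uniform_frame_gives_zero(self, geometry):
        frame = np.full((25, 25), 1234.5)
        assert circle_annulus_intensity(frame, (12, 12), geometry, 0.18) == 0.0

    def test_single_hot_pixel_scales_with_circle_count(self, geometry):
        px = 0.18
        frame = np.zeros((25, 25))
        frame[12, 12] = 1000.0
        n_circle = sum(
            1 for i in range(25) for j in range(25)
            if px * math.hypot(i - 12, j - 12) <= geometry.circle_diameter / 2)
        got = circle_annulus_intensity(frame, (12, 12), geometry, px)
        assert got == pytest.approx(1000.0 / n_circle, rel=1e-12)

    def test_invariant_to_constant_offset(self, geometry, rng):
        frame = rng.uniform(0, 100, size=(25, 25))
        a = circle_annulus_intensity(frame, (12.3, 11.7), geometry, 0.18)
        b = circle_annulus_intensity(frame + 500.0, (12.3, 11.7), geometry, 0.18)
        assert b == pytest.approx(a, abs=1e-9)

    def test_coarse_pixels_raise_geometry_error(self, geometry):
        with pytest.raises(GeometryError):
            circle_annulus_intensity(np.ones((5, 5)), (2, 2), geometry, 5.0)


class TestMinistack:
    def _movie(self, px=0.18, shape=(6, 64, 64)):
        from fusionmode.movie import MovieStack
        return MovieStack(np.zeros(shape, dtype=np.uint16), px, 0.5, "reporter")

    def test_crop_side_forced_odd(self, geometry):
        # 4 um / 0.18 um = 22.2 -> round 22 -> odd 23
        assert geometry.square_side_px(0.18) == 23
        # 4 / 0.2 = 20 -> odd 21
        assert geometry.square_side_px(0.2) == 21
        ev = FusionEvent(0, 0, (32, 32), 2)
        mini = excise_ministack(self._movie(), ev, geometry)
        assert mini.shape == (6, 23, 23)

    def test_temporal_extent_preserved(self, geometry):
        mini = excise_ministack(self._movie(shape=(480, 64, 64)),
                                FusionEvent(0, 0, (32, 32), 100), geometry)
        assert mini.n_frames == 480

    def test_edge_event_flagged_not_cropped(self, geometry):
        ev = FusionEvent(0, 0, (2, 32), 1)
        assert excise_ministack(self._movie(), ev, geometry) is None
        assert "edge" in ev.qc


class TestTraceExtraction:
    def test_noise_free_ks_trace_tracks_ground_truth(self, kinetics, geometry):
        imaging = ImagingParams(field_size=(64, 64), n_frames=120, seed=0)
        c = 32.5 * imaging.pixel_size
        ev = simulate_event_kinetics(kinetics, "KS", 60.0,
                                     np.random.default_rng(2),
                                     fusion_time=20.0, xy_um=(c, c))
        stacks, _ = render_movie([ev], default_channels(), imaging, kinetics,
                                 noise=False)
        onset = ev.onset_frame(imaging.frame_interval)
        mini = excise_ministack(stacks["reporter"], FusionEvent(0, 0, (32, 32), onset),
                                geometry)
        trace = extract_trace(mini, onset, geometry)
        truth = event_brightness(ev, ReporterModel(),
                                 penetration_depth=imaging.penetration_depth)
        assert len(trace.values) == imaging.n_frames
        assert np.corrcoef(trace.values, truth)[0, 1] > 0.999

    def test_constant_movie_gives_zero_trace(self, geometry):
        from fusionmode.movie import MovieStack
        movie = MovieStack(np.full((5, 23, 23), 777, dtype=np.uint16), 0.18, 0.5)
        trace = extract_trace(movie, 2, geometry)
        np.testing.assert_allclose(trace.values, 0.0, atol=1e-9)
        assert trace.time[2] == 0.0


class TestNormalization:
    def _trace(self, values, dt=0.5, onset_idx=40):
        t = (np.arange(len(values)) - onset_idx) * dt
        return Trace(np.asarray(values, float), t, "reporter")

    def test_reporter_affine_map(self):
        v = np.full(80, 200.0)
        v[40:] = 1200.0
        norm = normalize_reporter_trace(self._trace(v))
        assert norm.values[:40] == pytest.approx(0.0)
        assert norm.values[40:].max() == pytest.approx(1.0)

    def test_reporter_affine_invariance(self, rng):
        v = rng.uniform(100, 200, size=80)
        v[40:50] += 800
        a = normalize_reporter_trace(self._trace(v)).values
        b = normalize_reporter_trace(self._trace(3.7 * v + 55.0)).values
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_constant_trace_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_reporter_trace(self._trace(np.full(80, 5.0)))

    def test_short_baseline_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_reporter_trace(self._trace(np.arange(20.0), onset_idx=5))

    def test_marker_step_normalised_to_unit(self):
        v = np.zeros(120)
        v[30:60] = 500.0       # tether step from -30 s to 0 s
        norm = normalize_marker_trace(self._trace(v, onset_idx=60))
        assert norm.values.max() == pytest.approx(1.0)
        assert set(np.round(np.unique(norm.values), 12)) == {0.0, 1.0}

    def test_marker_zero_trace_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_marker_trace(self._trace(np.zeros(80)))


class TestEnsemble:
    def _event(self, values, onset, cell=0, eid=0, dt=0.5):
        t = (np.arange(len(values)) - onset) * dt
        ev = FusionEvent(eid, cell, (32, 32), onset)
        ev.traces["reporter"] = Trace(np.asarray(values, float), t, "reporter")
        return ev

    def test_early_event_excluded_then_empty_error(self):
        ev = self._event(np.ones(480), onset=30)
        with pytest.raises(EnsembleError):
            ensemble_average([ev], "reporter", 480)
        assert "excluded_early" in ev.qc

    def test_late_event_excluded(self):
        ev = self._event(np.ones(480), onset=400)
        with pytest.raises(EnsembleError):
            ensemble_average([ev], "reporter", 480)
        assert "excluded_late" in ev.qc

    def test_two_identical_traces_sem_zero(self):
        evs = [self._event(np.sin(np.arange(480) / 30), 100, eid=i, cell=i)
               for i in range(2)]
        ens = ensemble_average(evs, "reporter", 480)
        ok = np.isfinite(ens.mean)
        np.testing.assert_allclose(ens.mean[ok],
                                   evs[0].traces["reporter"].values[ok])
        np.testing.assert_allclose(ens.sem[ok], 0.0, atol=1e-12)

    def test_per_cell_vs_pooled_weighting(self):
        # cell 0 has two events (values 1, 3), cell 1 has one event (value 7):
        # per-cell mean = ((1+3)/2 + 7)/2 = 4.5; pooled = (1+3+7)/3
        evs = [self._event(np.full(480, 1.0), 100, cell=0, eid=0),
               self._event(np.full(480, 3.0), 100, cell=0, eid=1),
               self._event(np.full(480, 7.0), 100, cell=1, eid=2)]
        per_cell = ensemble_average(evs, "reporter", 480, level="per-cell")
        pooled = ensemble_average(evs, "reporter", 480, level="pooled")
        ok = np.isfinite(per_cell.mean)
        assert per_cell.mean[ok] == pytest.approx(4.5)
        assert pooled.mean[np.isfinite(pooled.mean)] == pytest.approx(11 / 3)
        assert per_cell.n_cells == 2 and pooled.n_events == 3


class TestTetheringMetrics:
    def _trace(self, values, dt=0.5, onset_idx=120):
        t = (np.arange(len(values)) - onset_idx) * dt
        return Trace(np.asarray(values, float), t, "tether")

    def test_ceiling_trace_integrates_to_window(self):
        m = tethering_metrics(self._trace(np.ones(160)))
        assert m["integral"] == pytest.approx(50.0)

    def test_unit_step_at_minus_25s(self):
        v = np.zeros(160)
        t = (np.arange(160) - 120) * 0.5
        v[t >= -25] = 1.0
        m = tethering_metrics(self._trace(v))
        assert m["integral"] == pytest.approx(25.0, abs=0.5)
        assert m["half_rise_time"] == pytest.approx(25.0, abs=0.5)

    def test_half_rise_linear_interpolation(self):
        t = (np.arange(160) - 120) * 0.5
        v = np.clip((t + 40) / 40, 0, 1)     # ramps 0 -> 1 over [-40, 0]
        m = tethering_metrics(Trace(v, t))
        assert m["half_rise_time"] == pytest.approx(20.0, abs=0.51)

    def test_insufficient_coverage_raises(self):
        with pytest.raises(ValueError):
            tethering_metrics(self._trace(np.ones(100), onset_idx=60))

    def test_longer_dwell_gives_larger_integral(self, rng):
        def mean_integral(tau):
            params = KineticParams(dwell_mean_per_mode=(tau, tau, tau))
            vals = []
            local = np.random.default_rng(11)
            for _ in range(120):
                ev = simulate_event_kinetics(params, "FF", 121.0, local,
                                             frame_interval=0.5, fusion_time=60.0)
                tr = Trace(ev.tethered.astype(float), ev.times - 60.0)
                vals.append(tethering_metrics(tr)["integral"])
            return np.mean(vals)

        assert mean_integral(15.0) > mean_integral(5.0)


class TestDetection:
    def test_threshold_monotonicity(self, mixture_dataset):
        movie = mixture_dataset[0].movies["reporter"]
        n5 = len(detect_fusion_events(movie, DetectionParams(k_sd=5.0)))
        n1 = len(detect_fusion_events(movie, DetectionParams(k_sd=1.0)))
        assert n1 >= n5

    def test_movie_shorter_than_baseline_raises(self):
        from fusionmode.movie import MovieStack
        movie = MovieStack(np.zeros((10, 32, 32), dtype=np.uint16), 0.18, 0.5)
        with pytest.raises(ValueError):
            detect_fusion_events(movie)
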