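import numpy as np
import pytest

from vesiscope.core import GroundTruthEvent, TimelapseMovie
from vesiscope.detection import (CandidateEvent, DetectionConfig,
                                 brute_force_detect, detect_events,
                                 find_candidates, measure_amplitude,
                                 measure_duration, validate_event)
from vesiscope.preprocess import compute_dff_avg, preprocess_movie
from vesiscope.synthetic import (SceneConfig, make_geometry, render_movie,
                                 simulate_events, simulate_profile)

from conftest import (build_scene, count_matches, flat_movie, match_event_sets,
                      small_scene_config)


def make_trace_candidate(trace, peak_frame):
    """Wrap a 1D trace as a single-pixel candidate for rule-boundary tests."""
    trace = np.asarray(trace, dtype=float)
    return CandidateEvent(seed=(peak_frame, 0, 0), peak_dff=1.0,
                          roi=np.array([[0, 0]]), roi_trace=trace,
                          seed_trace=trace)


def baseline10(f0=100.0, sd=1.0):
    """Ten baseline frames with mean exactly f0 and SD exactly sd."""
    return [f0 - sd, f0 + sd] * 5


class TestValidationRuleBoundaries:
    """Constructed fixtures for the acceptance rule boundaries."""

    def test_four_frames_at_6sd_accepted(self):
        trace = baseline10() + [106.0] * 4 + [100.0] * 6
        cand = make_trace_candidate(trace, peak_frame=10)
        val = validate_event(cand, DetectionConfig())
        assert val.accepted
        assert val.start_frame == 10
        assert val.f0 == pytest.approx(100.0)
        assert val.sd0 == pytest.approx(1.0)

    def test_three_frames_above_rejected(self):
        trace = baseline10() + [106.0] * 3 + [100.0] * 7
        val = validate_event(make_trace_candidate(trace, 10), DetectionConfig())
        assert not val.accepted
        assert val.reason == "too_short"

    def test_peak_at_4sd_rejected(self):
        trace = baseline10() + [104.0] * 6 + [100.0] * 4
        val = validate_event(make_trace_candidate(trace, 10), DetectionConfig())
        assert not val.accepted
        assert val.reason == "below_threshold"

    def test_peak_just_above_5sd_accepted(self):
        trace = baseline10() + [105.1] * 4 + [100.0] * 6
        val = validate_event(make_trace_candidate(trace, 10), DetectionConfig())
        assert val.accepted

    def test_no_baseline_at_movie_start(self):
        trace = [100.0, 100.0] + [106.0] * 5 + [100.0] * 5
        val = validate_event(make_trace_candidate(trace, 3), DetectionConfig())
        assert not val.accepted
        assert val.reason == "no_baseline"

    def test_short_baseline_accepted_with_flag(self):
        trace = [99.0, 101.0, 99.0, 101.0] + [110.0] * 5 + [100.0] * 6
        val = validate_event(make_trace_candidate(trace, 5), DetectionConfig())
        assert val.accepted
        assert val.baseline_short


class TestMeasureAmplitude:
    def test_arithmetic(self):
        trace = baseline10() + [150.0, 160.0, 150.0, 150.0] + [100.0] * 6
        cand = make_trace_candidate(trace, 10)
        val = validate_event(cand, DetectionConfig())
        assert measure_amplitude(cand, val) == pytest.approx(0.6)

    def test_peak_window_limits_amplitude(self):
        # a larger excursion after the 10-frame peak period does not count
        trace = baseline10() + [160.0] * 10 + [180.0] + [100.0] * 4
        cand = make_trace_candidate(trace, 10)
        val = validate_event(cand, DetectionConfig())
        assert measure_amplitude(cand, val) == pytest.approx(0.6)


class TestMeasureDuration:
    def test_return_after_8_frames(self):
        trace = baseline10() + [160.0] * 8 + [100.0] * 10
        cand = make_trace_candidate(trace, 10)
        val = validate_event(cand, DetectionConfig())
        dur, censored = measure_duration(cand, val, frame_interval=1.0)
        assert dur == pytest.approx(8.0)
        assert not censored

    def test_never_returning_censored(self):
        trace = baseline10() + [160.0] * 10
        cand = make_trace_candidate(trace, 10)
        val = validate_event(cand, DetectionConfig())
        dur, censored = measure_duration(cand, val, frame_interval=1.0)
        assert censored
        assert dur == pytest.approx(len(trace) - 1 - 10)


class TestFindCandidates:
    def test_flat_movie_no_candidates(self):
        assert find_candidates(flat_movie()) == []

    def test_single_spot_single_event(self):
        cfg = SceneConfig(field_length=40.0, n_frames=60, n_gaps=0, n_collaterals=0)
        prof = simulate_profile(cfg)
        ev = GroundTruthEvent(20.0, "axon", 25, 2.0, 6.0)
        movie, _ = render_movie(cfg, prof, [ev])
        events = detect_events(movie, DetectionConfig(), geometry=make_geometry(cfg))
        assert len(events) == 1
        assert events[0].arc_position == pytest.approx(20.0, abs=0.5)
        assert events[0].start_frame == 25

    def test_two_close_spots_merged(self):
        cfg = SceneConfig(field_length=40.0, n_frames=60, n_gaps=0, n_collaterals=0)
        prof = simulate_profile(cfg)
        evs = [GroundTruthEvent(20.0, "axon", 25, 2.0, 6.0),
               GroundTruthEvent(20.5, "axon", 25, 1.5, 6.0)]
        movie, _ = render_movie(cfg, prof, evs)
        events = detect_events(movie, DetectionConfig(merge_radius=1.0),
                               geometry=make_geometry(cfg))
        assert len(events) == 1

    def test_two_separated_spots_kept(self):
        cfg = SceneConfig(field_length=40.0, n_frames=60, n_gaps=0, n_collaterals=0)
        prof = simulate_profile(cfg)
        evs = [GroundTruthEvent(12.0, "axon", 25, 2.0, 6.0),
               GroundTruthEvent(28.0, "axon", 25, 2.0, 6.0)]
        movie, _ = render_movie(cfg, prof, evs)
        events = detect_events(movie, DetectionConfig(), geometry=make_geometry(cfg))
        assert len(events) == 2


class TestDisplacement:
    def _scene_with_event(self, ev, n_frames=80):
        cfg = SceneConfig(field_length=40.0, n_frames=n_frames, n_gaps=0,
                          n_collaterals=0)
        prof = simulate_profile(cfg)
        movie, _ = render_movie(cfg, prof, [ev])
        events = detect_events(movie, DetectionConfig(), geometry=make_geometry(cfg))
        return events

    def test_stationary_spot_static(self):
        ev = GroundTruthEvent(20.0, "axon", 20, 2.0, 8.0)
        (det,) = self._scene_with_event(ev)
        assert det.motion_class == "static"
        assert det.cumulative_displacement < 1.0
        assert det.direction_class == "none"

    def test_12um_drift_excluded(self):
        # 0.3 um/s for 50 s: > 10 um cumulative displacement, slow enough to
        # dwell in the frozen validation ROI for the required frames
        ev = GroundTruthEvent(10.0, "axon", 20, 3.0, 50.0, mobile=True,
                              velocity=0.3)
        dets = self._scene_with_event(ev, n_frames=100)
        assert any(d.motion_class == "excluded_mobile"
                   and d.cumulative_displacement > 10.0 for d in dets)
        assert all(d.motion_class == "excluded_mobile" for d in dets)

    def test_step_then_dwell_limited_displacement(self):
        # manual render: spot moves 4 um over 4 frames then dwells 10 frames
        cfg = SceneConfig(field_length=40.0, n_frames=60, n_gaps=0, n_collaterals=0)
        prof = simulate_profile(cfg)
        movie, _ = render_movie(cfg, prof, [])
        frames = movie.frames.copy()
        geo = make_geometry(cfg)
        row = int(geo.axon_path[0][0])
        from vesiscope.synthetic import _add_spot
        start = 20
        sig_px = cfg.spot_sigma / cfg.pixel_size
        for k in range(24):
            # 8 moving frames of 0.375 um each (3 um), then a 16-frame dwell
            arc = 10.0 + min(k, 8) * 0.375
            col = cfg.border_px + arc / cfg.pixel_size
            _add_spot(frames[start + k], row, col, 2.0 * cfg.axon_baseline, sig_px)
        movie2 = TimelapseMovie(frames, cfg.pixel_size, cfg.frame_interval)
        events = detect_events(movie2, DetectionConfig(), geometry=geo)
        assert len(events) >= 1
        ev = max(events, key=lambda e: e.cumulative_displacement)
        assert ev.motion_class == "limited_displacement"
        assert 2.0 <= ev.cumulative_displacement <= 10.0
        assert ev.direction_class == "unidirectional"

    def test_net_bounded_by_cumulative(self):
        scene = build_scene(small_scene_config(13, mobile_fraction=0.3))
        movie, dff = preprocess_movie(scene["movie"], register=False)[0], None
        events = detect_events(movie, DetectionConfig(), geometry=scene["geometry"])
        for e in events:
            assert abs(e.net_displacement) <= e.cumulative_displacement + 1e-9


class TestBruteForceOracle:
    def test_guard(self):
        big = flat_movie(shape=(200, 200, 200))
        with pytest.raises(ValueError):
            brute_force_detect(big)

    def test_empty_movie(self):
        assert brute_force_detect(flat_movie(shape=(30, 20, 40))) == []

    def test_sub_and_suprathreshold_events(self):
        cfg = SceneConfig(field_length=40.0, n_frames=80, n_gaps=0,
                          n_collaterals=0, photon_scale=1.0, read_sd=2.0)
        prof = simulate_profile(cfg)
        evs = [GroundTruthEvent(10.0, "axon", 20, 0.2, 6.0),   # ~2 x SD: sub
               GroundTruthEvent(30.0, "axon", 40, 2.0, 6.0)]  # supra
        movie, _ = render_movie(cfg, prof, evs, rng=cfg.rng())
        pre, _ = preprocess_movie(movie, register=False)
        found = brute_force_detect(pre, DetectionConfig(),
                                   geometry=make_geometry(cfg))
        assert len(found) == 1
        assert found[0].arc_position == pytest.approx(30.0, abs=1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_equivalence_small_scenes(self, seed):
        scene = build_scene(small_scene_config(seed))
        movie, _ = preprocess_movie(scene["movie"], register=False)
        dff = compute_dff_avg(movie)
        cfg = DetectionConfig()
        fast = detect_events(movie, cfg, geometry=scene["geometry"], dff=dff)
        brute = brute_force_detect(movie, cfg, geometry=scene["geometry"], dff=dff)
        assert match_event_sets(fast, brute)


class TestInvariants:
    def test_global_scale_invariance(self):
        scene = build_scene(small_scene_config(17))
        movie, _ = preprocess_movie(scene["movie"], register=False)
        scaled = movie.with_frames(movie.frames * 5.0)
        cfg = DetectionConfig()
        a = detect_events(movie, cfg, geometry=scene["geometry"])
        b = detect_events(scaled, cfg, geometry=scene["geometry"])
        assert match_event_sets(a, b, tol_um=1e-9, tol_frames=0)
        for x, y in zip(sorted(a, key=lambda e: e.start_frame),
                        sorted(b, key=lambda e: e.start_frame)):
            assert y.amplitude == pytest.approx(x.amplitude, rel=1e-9)

    def test_amplitude_monotonicity(self):
        """Raising injected amplitudes never decreases the accepted count."""
        cfg = small_scene_config(19, photon_scale=1.0, read_sd=2.0)
        rng = cfg.rng()
        prof = simulate_profile(cfg, rng)
        base_events = simulate_events(cfg, prof, 0.05, rng)
        counts = []
        for scale in (0.4, 1.0, 2.0):
            evs = [GroundTruthEvent(e.arc_position, e.compartment, e.start_frame,
                                    e.amplitude * scale, e.duration,
                                    collateral_index=e.collateral_index)
                   for e in base_events]
            movie, _ = render_movie(cfg, prof, evs, rng=cfg.rng())
            pre, _ = preprocess_movie(movie, register=False)
            counts.append(len(detect_events(pre, DetectionConfig(),
                                            geometry=make_geometry(cfg))))
        assert counts[0] <= counts[1] <= counts[2]

    def test_recall_precision_small_scene(self):
        scene = build_scene(small_scene_config(23, event_start_margin_frames=15))
        movie, _ = preprocess_movie(scene["movie"], register=False)
        det = detect_events(movie, DetectionConfig(), geometry=scene["geometry"])
        true = scene["events"]
        tp = count_matches(true, det)
        assert tp / max(len(true), 1) >= 0.8
        assert tp / max(len(det), 1) >= 0.8
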