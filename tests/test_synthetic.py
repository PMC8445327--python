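import numpy as np
import pytest
from scipy import stats

from vesiscope.synthetic import (SceneConfig, make_geometry, noise_sigma,
                                 render_movie, render_red_channel,
                                 simulate_events, simulate_profile,
                                 simulate_sheath_timecourse)

from conftest import small_scene_config


def rates(**kw):
    base = {"nonmyelinated": 0.0, "myelinated": 0.0, "collateral": 0.0,
            "heminodal_factor": 1.0}
    base.update(kw)
    return base


class TestSimulateProfile:
    def test_zero_coverage(self):
        cfg = SceneConfig(field_length=100.0, n_gaps=0)
        prof = simulate_profile(cfg)
        assert prof.gaps() == []
        assert prof.percent_myelination == 0.0
        assert prof.axon_class == "not_yet_myelinated"

    def test_requested_coverage_arithmetic(self):
        cfg = SceneConfig(field_length=100.0, gap_lengths=(20.0, 10.0))
        prof = simulate_profile(cfg)
        assert prof.percent_myelination == pytest.approx(30.0, abs=0.5)

    def test_determinism(self):
        cfg = SceneConfig(field_length=100.0, n_gaps=2, rng_seed=42)
        p1 = simulate_profile(cfg)
        p2 = simulate_profile(cfg)
        assert p1.segments == p2.segments

    def test_infeasible_placement_raises(self):
        cfg = SceneConfig(field_length=30.0, gap_lengths=(20.0, 20.0))
        with pytest.raises(ValueError):
            simulate_profile(cfg)

    def test_gaps_complete_and_separated(self):
        for seed in range(5):
            cfg = SceneConfig(field_length=100.0, n_gaps=3, rng_seed=seed)
            prof = simulate_profile(cfg)
            gaps = prof.gaps()
            assert all(flag for flag in prof.gap_complete_flags)
            for (s0, e0), (s1, e1) in zip(gaps, gaps[1:]):
                assert s1 - e0 >= cfg.min_gap_separation - cfg.pixel_size


class TestSimulateEvents:
    def test_all_rates_zero(self):
        cfg = SceneConfig(field_length=100.0, n_gaps=0, event_rates=rates())
        prof = simulate_profile(cfg)
        assert simulate_events(cfg, prof, 1.0) == []

    def test_poisson_mean_and_variance(self):
        # 2 events per 10 um per h = 0.2 /um/h on a 100 um unmyelinated axon
        cfg = SceneConfig(field_length=100.0, n_gaps=0, n_collaterals=0,
                          event_rates=rates(nonmyelinated=0.2))
        prof = simulate_profile(cfg)
        rng = np.random.default_rng(123)
        counts = np.array([len(simulate_events(cfg, prof, 1.0, rng))
                           for _ in range(200)])
        expected = 20.0
        se_mean = np.sqrt(expected / 200)
        assert abs(counts.mean() - expected) < 3 * se_mean
        # Poisson variance ~= mean; SE(var) ~ sqrt(2/n)*var for Gaussian-ish
        assert abs(counts.var() - expected) < 3 * expected * np.sqrt(2 / 200)

    def test_uniform_density_when_factor_one(self):
        cfg = SceneConfig(field_length=100.0, n_gaps=0, n_collaterals=0,
                          event_rates=rates(nonmyelinated=5.0, heminodal_factor=1.0))
        prof = simulate_profile(cfg)
        rng = np.random.default_rng(7)
        positions = []
        for _ in range(20):
            positions.extend(e.arc_position for e in simulate_events(cfg, prof, 1.0, rng))
        _d, p = stats.kstest(np.array(positions) / 100.0, "uniform")
        assert p > 0.01

    def test_mobile_fraction(self):
        cfg = SceneConfig(field_length=100.0, n_gaps=0, n_collaterals=0,
                          mobile_fraction=1.0,
                          event_rates=rates(nonmyelinated=1.0))
        prof = simulate_profile(cfg)
        events = simulate_events(cfg, prof, 0.5)
        assert events and all(e.mobile and e.velocity != 0 for e in events)

    def test_determinism(self):
        cfg = small_scene_config(3)
        prof = simulate_profile(cfg, cfg.rng())
        e1 = simulate_events(cfg, prof, 0.1, np.random.default_rng(5))
        e2 = simulate_events(cfg, prof, 0.1, np.random.default_rng(5))
        assert [(a.arc_position, a.start_frame) for a in e1] == \
               [(b.arc_position, b.start_frame) for b in e2]


class TestRenderMovie:
    def test_no_events_no_noise_frames_identical(self):
        cfg = SceneConfig(field_length=40.0, n_frames=20, n_gaps=1,
                          gap_length_range=(6, 10), n_collaterals=1)
        prof = simulate_profile(cfg)
        movie, _ = render_movie(cfg, prof, [])
        assert np.array_equal(movie.frames[0], movie.frames[-1])

    def test_peak_pixel_equals_amplitude_times_baseline(self):
        from vesiscope.core import GroundTruthEvent
        cfg = SceneConfig(field_length=40.0, n_frames=60, n_gaps=0, n_collaterals=0)
        prof = simulate_profile(cfg)
        ev = GroundTruthEvent(arc_position=20.0, compartment="axon",
                              start_frame=20, amplitude=2.0, duration=6.0)
        movie, _ = render_movie(cfg, prof, [ev])
        geo = make_geometry(cfg)
        row = int(geo.axon_path[0][0])
        col = cfg.border_px + int(round(20.0 / cfg.pixel_size))
        assert movie.frames[20, row, col] == pytest.approx(3 * cfg.axon_baseline, rel=1e-9)
        assert movie.frames[19, row, col] == pytest.approx(cfg.axon_baseline, rel=1e-9)

    def test_under_sheath_attenuation(self):
        cfg = SceneConfig(field_length=40.0, n_frames=5, gap_lengths=(10.0,),
                          n_collaterals=0, under_sheath_attenuation=0.4)
        prof = simulate_profile(cfg)
        movie, _ = render_movie(cfg, prof, [])
        geo = make_geometry(cfg)
        row = int(geo.axon_path[0][0])
        (s, e), = prof.gaps()
        col_gap = cfg.border_px + int(round((s + e) / 2 / cfg.pixel_size))
        col_pos = cfg.border_px + 2
        assert movie.frames[0, row, col_gap] == pytest.approx(0.4 * cfg.axon_baseline)
        assert movie.frames[0, row, col_pos] == pytest.approx(cfg.axon_baseline)

    def test_bleach_closed_form(self):
        cfg = SceneConfig(field_length=40.0, n_frames=101, n_gaps=0,
                          n_collaterals=0, bleach_tau=100.0)
        prof = simulate_profile(cfg)
        movie, _ = render_movie(cfg, prof, [])
        m0 = movie.frames[0].mean()
        mT = movie.frames[100].mean()  # t = tau
        assert mT == pytest.approx(m0 * np.exp(-1), rel=1e-9)

    def test_event_outside_frame_raises(self):
        from vesiscope.core import GroundTruthEvent
        cfg = SceneConfig(field_length=40.0, n_frames=10, n_gaps=0, n_collaterals=1)
        prof = simulate_profile(cfg)
        ev = GroundTruthEvent(arc_position=20.0, compartment="collateral",
                              start_frame=2, amplitude=2.0, duration=5.0,
                              collateral_index=0)
        with pytest.raises((ValueError, IndexError)):
            render_movie(cfg, prof, [ev])

    def test_full_determinism_bytes(self):
        cfg = small_scene_config(9)
        rng1, rng2 = cfg.rng(), cfg.rng()
        prof = simulate_profile(cfg, rng1)
        ev = simulate_events(cfg, prof, 0.05, rng1)
        m1, _ = render_movie(cfg, prof, ev, rng=rng1)

        prof2 = simulate_profile(cfg, rng2)
        ev2 = simulate_events(cfg, prof2, 0.05, rng2)
        m2, _ = render_movie(cfg, prof2, ev2, rng=rng2)
        assert m1.frames.tobytes() == m2.frames.tobytes()

    def test_noise_sigma_model(self):
        cfg = SceneConfig(photon_scale=1.0, read_sd=2.0)
        assert noise_sigma(cfg, 100.0) == pytest.approx(np.sqrt(104.0))
        assert noise_sigma(SceneConfig(), 100.0) == 0.0


class TestRedChannel:
    def test_gaps_dark_positive_bright(self):
        cfg = SceneConfig(field_length=40.0, gap_lengths=(10.0,), n_collaterals=0)
        prof = simulate_profile(cfg)
        red = render_red_channel(cfg, prof)
        geo = make_geometry(cfg)
        row = int(geo.axon_path[0][0])
        (s, e), = prof.gaps()
        col_gap = cfg.border_px + int(round((s + e) / 2 / cfg.pixel_size))
        assert red.frames[0, row, col_gap] == cfg.background_intensity
        assert red.frames[0, row, cfg.border_px + 2] == cfg.red_baseline
        assert red.channel_role == "static_red"


class TestSheathTimecourse:
    def test_constant_growth_when_uncoupled(self):
        cfg = SceneConfig(field_length=100.0, n_gaps=3, gap_length_range=(3, 10),
                          growth_b0_nascent=0.5, growth_b0_mature=0.5,
                          growth_b1=0.0, growth_noise_sd=0.0)
        prof = simulate_profile(cfg)
        tcs = simulate_sheath_timecourse(cfg, prof, [])
        assert tcs
        for tc in tcs:
            assert tc.growth_rate == pytest.approx(0.5)
            assert tc.fate == "grow"

    def test_full_retraction_fate(self):
        cfg = SceneConfig(field_length=100.0, gap_lengths=(3.0,),
                          growth_b0_nascent=-5.0, growth_b1=0.0,
                          growth_noise_sd=0.0, session_interval_h=4.0)
        prof = simulate_profile(cfg)
        (tc,) = simulate_sheath_timecourse(cfg, prof, [])
        assert tc.fate == "full_retraction"
        assert tc.lengths[-1] == 0.0

    def test_positive_coupling_recovered(self):
        rng = np.random.default_rng(11)
        rates_cfg = rates(nonmyelinated=1.0, heminodal_factor=3.0)
        all_tcs = []
        for seed in range(40):
            cfg = SceneConfig(field_length=100.0, n_gaps=3, gap_length_range=(3, 10),
                              event_rates=rates_cfg, rng_seed=seed,
                              growth_b1=0.2, growth_noise_sd=0.3)
            prof = simulate_profile(cfg, rng)
            events = simulate_events(cfg, prof, cfg.event_window_h, rng)
            all_tcs.extend(simulate_sheath_timecourse(cfg, prof, events, rng))
        nascent = [tc for tc in all_tcs if tc.initial_length < 6.0]
        r = np.corrcoef([tc.heminodal_frequency for tc in nascent],
                        [tc.growth_rate for tc in nascent])[0, 1]
        assert len(nascent) >= 20
        assert r > 0.3

    def test_no_mature_sheath_fully_retracts(self):
        # generator contract mirroring the nascent-only retraction regime
        rng = np.random.default_rng(2)
        count = 0
        tcs_all = []
        while count < 500:
            cfg = SceneConfig(field_length=120.0, n_gaps=3, gap_length_range=(3, 18),
                              rng_seed=count)
            prof = simulate_profile(cfg, rng)
            events = simulate_events(cfg, prof, cfg.event_window_h, rng)
            tcs = simulate_sheath_timecourse(cfg, prof, events, rng)
            tcs_all.extend(tcs)
            count += len(tcs)
        mature = [tc for tc in tcs_all if tc.initial_length >= 6.0]
        assert mature
        assert all(tc.fate != "full_retraction" for tc in mature)


class TestConfigIO:
    def test_json_round_trip(self, tmp_path):
        cfg = small_scene_config(5, bleach_tau=200.0)
        path = tmp_path / "cfg.json"
        cfg.save(path)
        back = SceneConfig.load(path)
        assert back == cfg

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        cfg = small_scene_config(5)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_json_dict()))
        back = SceneConfig.load(path)
        assert back == cfg

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(event_rates={"nonmyelinated": -1.0})

    def test_bad_attenuation_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(under_sheath_attenuation=0.0)


class TestIntervalSubtractionProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.tuples(st.floats(0, 90), st.floats(1, 10)),
                    min_size=0, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_subtraction_never_grows_and_stays_disjoint(self, raw):
        from vesiscope.synthetic import _subtract_intervals
        base = [(0.0, 100.0)]
        remove = [(s, s + w) for s, w in raw]
        out = _subtract_intervals(base, remove)
        total = sum(e - s for s, e in out)
        assert total <= 100.0 + 1e-9
        for (s, e) in out:
            assert e > s
            for (rs, re) in remove:
                assert e <= rs + 1e-9 or s >= re - 1e-9
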