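import numpy as np
import pytest

from vesiscope.core import TimelapseMovie
from vesiscope.detection import DetectionConfig
from vesiscope.preprocess import compute_dff_avg, preprocess_movie
from vesiscope.synthetic import (SceneConfig, make_geometry, render_movie,
                                 simulate_events, simulate_profile)


def small_scene_config(seed: int, **overrides) -> SceneConfig:
    """A compact scene that fits under the brute-force oracle guard."""
    defaults = dict(
        n_frames=100, field_length=40.0, n_collaterals=1, collateral_length=5.0,
        n_gaps=2, gap_length_range=(5.0, 9.0), photon_scale=1.0, read_sd=2.0,
        event_rates={"nonmyelinated": 2.0, "myelinated": 0.6,
                     "collateral": 2.0, "heminodal_factor": 3.0},
        amplitude_dist={"kind": "lognormal", "mu": 0.5, "sigma": 0.3, "min": 0.9},
        duration_dist={"kind": "uniform", "low": 5.0, "high": 8.0},
        rng_seed=seed,
    )
    defaults.update(overrides)
    return SceneConfig(**defaults)


def build_scene(config: SceneConfig, duration_h: float = 0.04):
    """Simulate profile + events and render; returns a dict of artifacts."""
    rng = config.rng()
    profile = simulate_profile(config, rng)
    events = simulate_events(config, profile, duration_h, rng)
    movie, truth = render_movie(config, profile, events, rng=rng)
    geometry = make_geometry(config)
    return {"config": config, "profile": profile, "events": events,
            "movie": movie, "truth": truth, "geometry": geometry}


def preprocessed(scene: dict):
    movie, _model = preprocess_movie(scene["movie"], register=False)
    dff = compute_dff_avg(movie)
    return movie, dff


def match_event_sets(events_a, events_b, tol_um=1.0, tol_frames=2) -> bool:
    """Greedy bipartite equality of two event sets within tolerances."""
    if len(events_a) != len(events_b):
        return False
    used = set()
    for a in events_a:
        hit = False
        for j, b in enumerate(events_b):
            if j in used:
                continue
            if (a.compartment_raw == b.compartment_raw
                    and abs(a.arc_position - b.arc_position) <= tol_um
                    and abs(a.start_frame - b.start_frame) <= tol_frames):
                used.add(j)
                hit = True
                break
        if not hit:
            return False
    return True


def count_matches(true_events, detected, tol_um=1.0, tol_frames=2) -> int:
    used = set()
    tp = 0
    for t in true_events:
        for j, d in enumerate(detected):
            if j in used:
                continue
            if (d.compartment_raw == t.compartment
                    and abs(d.arc_position - t.arc_position) <= tol_um
                    and abs(d.start_frame - t.start_frame) <= tol_frames):
                used.add(j)
                tp += 1
                break
    return tp


@pytest.fixture(scope="session")
def default_detection_config() -> DetectionConfig:
    return DetectionConfig()


def flat_movie(value=100.0, shape=(30, 20, 40), pixel_size=0.25, frame_interval=1.0):
    return TimelapseMovie(np.full(shape, value), pixel_size, frame_interval)
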