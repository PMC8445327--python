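"""End-to-end orchestration: simulate -> preprocess -> detect -> profile ->
hotspots -> sheaths, with all intermediates written to disk."""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import write_event_table, write_movie
from .detection import DetectionConfig, detect_events
from .myelin import ProfileConfig, sample_axon_intensity, segment_profile
from .preprocess import compute_dff_avg, preprocess_movie
from .spatial import assign_compartments, frequency_report, heminodal_enrichment
from .synthetic import (SceneConfig, make_geometry, render_movie,
                        render_red_channel, simulate_events, simulate_profile,
                        simulate_sheath_timecourse)
from .sheaths import GrowthAnalysisConfig, nascent_fate_table

__all__ = ["run_pipeline"]


def run_pipeline(scene: SceneConfig, outdir, seed: int | None = None,
                 detection: DetectionConfig | None = None,
                 register: bool = False) -> dict:
    """Run the full synthetic pipeline and write every intermediate.

    Returns a summary dict (also written as ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        scene.rng_seed = seed
    rng = scene.rng()
    detection = detection or DetectionConfig()

    duration_h = scene.n_frames * scene.frame_interval / 3600.0
    geometry = make_geometry(scene)
    profile = simulate_profile(scene, rng)
    true_events = simulate_events(scene, profile, duration_h, rng)
    movie, truth = render_movie(scene, profile, true_events, geometry, rng)
    red = render_red_channel(scene, profile, geometry)

    write_movie(movie, outdir / "movie.tif")
    write_movie(red, outdir / "red.tif")
    truth.save(outdir / "ground_truth.json")
    scene.save(outdir / "scene_config.json")
    (outdir / "geometry.json").write_text(json.dumps(geometry.to_json_dict(), indent=1))

    pre, model = preprocess_movie(movie, register=register)
    model.save(outdir / "preprocess_model.json")
    dff = compute_dff_avg(pre)

    events = detect_events(pre, detection, geometry=geometry, dff=dff)
    write_event_table(events, outdir / "events.csv")

    red_profile_intensity = sample_axon_intensity(red, geometry)
    seg_profile = segment_profile(red_profile_intensity, scene.pixel_size, ProfileConfig())
    seg_profile.to_dataframe().to_csv(outdir / "profile.csv", index=False)

    labelled = assign_compartments(events, geometry, seg_profile)
    freq = frequency_report(labelled, seg_profile, geometry, duration_h)
    hotspot = None
    if seg_profile.heminodes:
        hs = heminodal_enrichment(labelled, seg_profile, duration_h)
        hotspot = {"observed": hs.observed_heminodal, "predicted": hs.predicted_uniform,
                   "ratio": hs.ratio, "n_heminodes": hs.n_heminodes}

    timecourses = simulate_sheath_timecourse(scene, profile, true_events, rng, geometry)
    tc_rows = [{
        "sheath_id": tc.sheath_id, "length_t0": tc.lengths[0],
        "length_t1": tc.lengths[-1], "t0_h": tc.session_times[0],
        "t1_h": tc.session_times[-1], "growth_rate": tc.growth_rate,
        "fate": tc.fate, "free_to_grow": tc.free_to_grow,
        "heminodal_frequency": tc.heminodal_frequency,
        "under_sheath_frequency": tc.under_sheath_frequency,
    } for tc in timecourses]
    pd.DataFrame(tc_rows).to_csv(outdir / "sheaths.csv", index=False)
    fate = nascent_fate_table(timecourses, GrowthAnalysisConfig()) if timecourses else None

    summary = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": scene.rng_seed,
        "n_true_events": len(true_events),
        "n_detected_events": len(events),
        "percent_myelination": seg_profile.percent_myelination,
        "axon_class": seg_profile.axon_class,
        "frequencies_per_um_h": {
            "axonal": freq.axonal_freq, "collateral": freq.collateral_freq,
            "positive": freq.positive_region_freq, "gap": freq.gap_region_freq,
            "heminodal": freq.heminodal_freq,
        },
        "hotspot": hotspot,
        "n_sheaths": len(timecourses),
        "fate_table": fate["table"] if fate else None,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary
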