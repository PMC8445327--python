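"""Compartment assignment, frequency normalization and the heminodal
observed-vs-predicted enrichment statistic."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import AxonGeometry, MyelinProfile, SypHyEvent

__all__ = [
    "EventFrequencyReport",
    "HotspotStats",
    "assign_compartments",
    "frequency_report",
    "heminodal_enrichment",
    "paired_enrichment_test",
    "colocalization_overlap",
]

COMPARTMENT_LABELS = ("collateral", "gap_region", "heminodal", "positive_other")


@dataclass
class EventFrequencyReport:
    """Per-axon event frequencies in events/um/h (also exposed per 10 um.h)."""

    axonal_freq: float
    collateral_freq: float
    positive_region_freq: float
    gap_region_freq: float
    heminodal_freq: float
    imaging_duration_h: float
    axon_length: float
    collateral_length: float
    positive_length: float
    gap_length: float
    counts: dict = field(default_factory=dict)

    def per_10um_h(self) -> dict:
        out = {}
        for name in ("axonal_freq", "collateral_freq", "positive_region_freq",
                     "gap_region_freq", "heminodal_freq"):
            v = getattr(self, name)
            out[name] = v * 10.0 if np.isfinite(v) else v
        return out


@dataclass
class HotspotStats:
    """Observed vs predicted heminodal frequency, in events/(3 um)/h."""

    observed_heminodal: float
    predicted_uniform: float
    n_heminodes: int
    heminode_window: float = 3.0

    @property
    def ratio(self) -> float:
        if self.predicted_uniform > 0:
            return self.observed_heminodal / self.predicted_uniform
        return float("nan")


def _in_any(x: float, intervals) -> bool:
    return any(s <= x < e for s, e in intervals)


def assign_compartments(events, geometry: AxonGeometry,
                        profile: MyelinProfile) -> list:
    """Attach exactly one compartment label to each event.

    Labels: ``collateral``; along the axon, ``gap_region`` inside a gap,
    ``heminodal`` within a heminode interval (the first 3 um of positive axon
    bordering a gap), else ``positive_other``. Intervals are half-open with
    the lower bound inclusive; the event's peak arc position decides.
    """
    out = []
    for ev in events:
        if ev.compartment_raw == "collateral":
            label = "collateral"
        else:
            x = ev.arc_position
            if not (0.0 <= x <= profile.field_length):
                raise ValueError(f"event at {x} um lies outside the field")
            if _in_any(x, profile.gaps()):
                label = "gap_region"
            elif _in_any(x, profile.heminodes):
                label = "heminodal"
            else:
                label = "positive_other"
        out.append((ev, label))
    return out


def _included(ev: SypHyEvent) -> bool:
    return ev.motion_class != "excluded_mobile"


def frequency_report(labelled_events, profile: MyelinProfile,
                     geometry: AxonGeometry, duration_h: float) -> EventFrequencyReport:
    """Counts normalized to compartment length and imaging duration.

    Mobile-excluded events are not counted. Compartments with zero length are
    reported as NaN (undefined), not zero.
    """
    if duration_h <= 0:
        raise ValueError("imaging duration must be positive")
    counts = {label: 0 for label in COMPARTMENT_LABELS}
    for ev, label in labelled_events:
        if _included(ev):
            counts[label] += 1

    axon_len = profile.field_length
    col_len = float(sum(geometry.collateral_lengths())) if geometry else 0.0
    pos_len = profile.positive_length()
    gap_len = profile.gap_length()
    axonal_count = counts["gap_region"] + counts["heminodal"] + counts["positive_other"]
    positive_count = counts["heminodal"] + counts["positive_other"]

    def freq(count, length):
        return count / length / duration_h if length > 0 else float("nan")

    hemi_len = float(sum(e - s for s, e in profile.heminodes))
    return EventFrequencyReport(
        axonal_freq=freq(axonal_count, axon_len),
        collateral_freq=freq(counts["collateral"], col_len),
        positive_region_freq=freq(positive_count, pos_len),
        gap_region_freq=freq(counts["gap_region"], gap_len),
        heminodal_freq=freq(counts["heminodal"], hemi_len),
        imaging_duration_h=duration_h, axon_length=axon_len,
        collateral_length=col_len, positive_length=pos_len, gap_length=gap_len,
        counts=dict(counts),
    )


def heminodal_enrichment(labelled_events, profile: MyelinProfile,
                         duration_h: float, window: float = 3.0) -> HotspotStats:
    """Observed per-heminode frequency vs the uniform prediction.

    Predicted = (positive-region count / positive length / duration) scaled to
    one ``window``-um interval; observed = heminodal count divided by the
    number of heminodes and the duration.
    """
    n_hemi = len(profile.heminodes)
    if n_hemi < 1:
        raise ValueError("enrichment undefined without heminodes")
    pos_len = profile.positive_length()
    if pos_len <= 0:
        raise ValueError("enrichment undefined without positive axon length")
    pos_count = sum(1 for ev, label in labelled_events
                    if _included(ev) and label in ("heminodal", "positive_other"))
    hemi_count = sum(1 for ev, label in labelled_events
                     if _included(ev) and label == "heminodal")
    predicted = pos_count / pos_len / duration_h * window
    observed = hemi_count / n_hemi / duration_h
    return HotspotStats(observed_heminodal=observed, predicted_uniform=predicted,
                        n_heminodes=n_hemi, heminode_window=window)


def paired_enrichment_test(per_axon_stats) -> dict:
    """Wilcoxon matched-pairs signed-rank test on (observed, predicted)."""
    pairs = [(s.observed_heminodal, s.predicted_uniform) for s in per_axon_stats
             if np.isfinite(s.observed_heminodal) and np.isfinite(s.predicted_uniform)]
    if len(pairs) < 6:
        raise ValueError("need at least 6 axons with defined pairs")
    obs = np.array([p[0] for p in pairs])
    pred = np.array([p[1] for p in pairs])
    diffs = obs - pred
    if np.allclose(diffs, 0):
        p = 1.0
    else:
        _stat, p = stats.wilcoxon(obs, pred)
    direction = "observed_higher" if np.median(diffs) > 0 else (
        "observed_lower" if np.median(diffs) < 0 else "none")
    return {"p_value": float(p), "n": len(pairs),
            "median_difference": float(np.median(diffs)), "direction": direction}


def colocalization_overlap(event_positions, puncta_positions, tolerance: float) -> dict:
    """Counts of events within ``tolerance`` um of any punctum (and vice
    versa), in shared arc coordinates."""
    ev = np.asarray(event_positions, dtype=float)
    pu = np.asarray(puncta_positions, dtype=float)
    if ev.size == 0 or pu.size == 0:
        return {"events_near_puncta": 0, "puncta_near_events": 0,
                "n_events": int(ev.size), "n_puncta": int(pu.size)}
    d = np.abs(ev[:, None] - pu[None, :])
    return {
        "events_near_puncta": int((d.min(axis=1) <= tolerance).sum()),
        "puncta_near_events": int((d.min(axis=0) <= tolerance).sum()),
        "n_events": int(ev.size), "n_puncta": int(pu.size),
    }
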