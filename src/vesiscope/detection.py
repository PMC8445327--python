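"""Detection, measurement and classification of vesicle-fusion events.

Two routes produce accepted events:

* :func:`find_candidates` + :func:`validate_event` — spatiotemporal local
  maxima of dF/F_avg above a threshold, ROI growth from the peak pixel, then
  the acceptance criteria (excursion beyond ``sd_multiple`` baseline SDs
  sustained for ``min_frames`` frames);
* :func:`brute_force_detect` — an exhaustive oracle that tests every pixel and
  frame against the identical criteria and deduplicates the result.

Photometry conventions: the acceptance criterion is evaluated on the ROI-mean
trace; amplitude and duration are measured on the peak-pixel trace, whose
rendered peak equals ``amplitude x local baseline`` in the forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import AxonGeometry, SypHyEvent, TimelapseMovie
from .preprocess import compute_dff_avg

__all__ = [
    "DetectionConfig",
    "CandidateEvent",
    "ValidationResult",
    "find_candidates",
    "validate_event",
    "measure_amplitude",
    "measure_duration",
    "track_displacement",
    "detect_events",
    "brute_force_detect",
]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class DetectionConfig:
    sd_multiple: float = 5.0
    min_frames: int = 4
    baseline_frames: int = 10
    min_baseline_frames: int = 3
    peak_window_frames: int = 10
    candidate_dff_threshold: float = 0.5
    merge_radius: float = 1.0  # um
    roi_fraction: float = 1.0 / 3.0
    displacement_substantial: float = 2.0  # um
    displacement_exclusion: float = 10.0  # um
    search_radius: float = 1.5  # um, per-frame re-localization window
    duration_floor_fraction: float = 0.01  # SD floor as fraction of f0
    unidirectional_fraction: float = 0.9
    brute_force_guard: int = 1_000_000  # max pixel-frames for the oracle

    def __post_init__(self) -> None:
        for name in ("sd_multiple", "min_frames", "baseline_frames",
                     "peak_window_frames", "merge_radius", "search_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CandidateEvent:
    seed: tuple  # (t, row, col)
    peak_dff: float
    roi: np.ndarray  # (n, 2) array of (row, col)
    roi_trace: np.ndarray
    seed_trace: np.ndarray

    def __post_init__(self) -> None:
        t, r, c = self.seed
        if not any((r == rr and c == cc) for rr, cc in self.roi):
            raise ValueError("seed pixel must belong to its ROI")


@dataclass
class ValidationResult:
    accepted: bool
    reason: str = ""
    start_frame: int = -1
    f0: float = np.nan
    sd0: float = np.nan
    f0_seed: float = np.nan
    sd0_seed: float = np.nan
    baseline_short: bool = False
    n_above: int = 0


# ---------------------------------------------------------------------------
# ROI growth and candidate extraction
# ---------------------------------------------------------------------------

def _grow_roi(change_frame: np.ndarray, row: int, col: int, fraction: float) -> np.ndarray:
    """4-connected region containing (row, col) above ``fraction`` of its
    value. Returns an (n, 2) array of pixel coordinates."""
    peak = change_frame[row, col]
    mask = change_frame >= fraction * peak
    labels, _ = ndimage.label(mask, structure=_FOUR_CONN)
    roi = np.argwhere(labels == labels[row, col])
    return roi


def _hill_climb(img: np.ndarray, r: int, c: int) -> tuple:
    """Ascend to the 8-neighbourhood local maximum of ``img`` from (r, c)."""
    H, W = img.shape
    for _ in range(10_000):
        r_lo, r_hi = max(0, r - 1), min(H, r + 2)
        c_lo, c_hi = max(0, c - 1), min(W, c + 2)
        win = img[r_lo:r_hi, c_lo:c_hi]
        k = np.unravel_index(np.argmax(win), win.shape)
        nr, nc = r_lo + int(k[0]), c_lo + int(k[1])
        if img[nr, nc] <= img[r, c]:
            return r, c
        r, c = nr, nc
    return r, c


def _extract_candidate(movie: TimelapseMovie, dff: np.ndarray, avg: np.ndarray,
                       seed: tuple, config: DetectionConfig) -> CandidateEvent:
    """Build a candidate from a seed voxel.

    The seed is re-centred on the local maximum of the background-subtracted
    change image (dF = dF/F_avg x time-average), which is unbiased across
    baseline steps such as sheath borders; the ROI is the 4-connected region
    above a third of that maximum change.
    """
    t, r0, c0 = seed
    change = dff[t] * avg
    r, c = _hill_climb(change, r0, c0)
    roi = _grow_roi(change, r, c, config.roi_fraction)
    roi_trace = movie.frames[:, roi[:, 0], roi[:, 1]].mean(axis=1)
    return CandidateEvent(seed=(t, r, c), peak_dff=float(change[r, c]), roi=roi,
                          roi_trace=roi_trace, seed_trace=movie.frames[:, r, c])


def find_candidates(movie: TimelapseMovie, config: DetectionConfig | None = None,
                    dff: np.ndarray | None = None) -> list:
    """Spatiotemporal local maxima of dF/F_avg above the candidate threshold."""
    config = config or DetectionConfig()
    if dff is None:
        dff = compute_dff_avg(movie)
    avg = movie.frames.mean(axis=0)
    m_px = max(1, int(round(config.merge_radius / movie.pixel_size)))
    # spatial-only suppression: every frame of an event may seed a candidate,
    # duplicates collapse in the shared deduplication step
    size = (1, 2 * m_px + 1, 2 * m_px + 1)
    mx = ndimage.maximum_filter(dff, size=size)
    peaks = np.argwhere((dff >= mx) & (dff > config.candidate_dff_threshold))
    # strongest first so that deduplication is deterministic
    order = np.argsort(-dff[peaks[:, 0], peaks[:, 1], peaks[:, 2]], kind="stable")
    out = []
    seen = set()
    for t, r, c in peaks[order]:
        cand = _extract_candidate(movie, dff, avg, (int(t), int(r), int(c)), config)
        if cand.seed not in seen:
            seen.add(cand.seed)
            out.append(cand)
    return out


# ---------------------------------------------------------------------------
# validation and photometry
# ---------------------------------------------------------------------------

def _find_onset(trace: np.ndarray, peak_frame: int, config: DetectionConfig) -> int:
    """Walk back from the peak while the preceding frame is still elevated.

    A frame is "elevated" while it stays above the halfway level between the
    whole-trace median (a robust baseline, since events are temporally sparse)
    and the candidate's peak value. The acceptance criterion itself is
    evaluated afterwards with the plain mean/SD baseline over the frames
    preceding the returned onset.
    """
    med = float(np.median(trace))
    half = 0.5 * (float(trace[peak_frame]) + med)
    s = peak_frame
    while s > 0 and trace[s - 1] > half:
        s -= 1
    return s


def validate_event(candidate: CandidateEvent,
                   config: DetectionConfig | None = None) -> ValidationResult:
    """Apply the acceptance criteria to a candidate's ROI-mean trace.

    Accepted iff the trace exceeds ``f0 + sd_multiple * sd0`` in at least
    ``min_frames`` consecutive frames starting at the event onset, where the
    baseline is the mean of the ``baseline_frames`` frames preceding onset
    (at least ``min_baseline_frames``, flagged when short).
    """
    config = config or DetectionConfig()
    trace = candidate.roi_trace
    t_peak = candidate.seed[0]
    s = _find_onset(trace, t_peak, config)
    lo = max(0, s - config.baseline_frames)
    pre = trace[lo:s]
    if pre.size < config.min_baseline_frames:
        return ValidationResult(False, reason="no_baseline")
    f0, sd0 = float(pre.mean()), float(pre.std())
    thr = f0 + config.sd_multiple * sd0
    # start: first frame at/after onset above threshold (search up to the peak)
    start = -1
    for u in range(s, t_peak + 1):
        if trace[u] > thr:
            start = u
            break
    if start < 0:
        return ValidationResult(False, reason="below_threshold")
    n_above = 0
    for u in range(start, trace.size):
        if trace[u] > thr:
            n_above += 1
        else:
            break
    if n_above < config.min_frames:
        return ValidationResult(False, reason="too_short", start_frame=start,
                                f0=f0, sd0=sd0, n_above=n_above)
    seed_pre = candidate.seed_trace[lo:s]
    return ValidationResult(
        True, start_frame=start, f0=f0, sd0=sd0,
        f0_seed=float(seed_pre.mean()), sd0_seed=float(seed_pre.std()),
        baseline_short=pre.size < config.baseline_frames, n_above=n_above,
    )


def measure_amplitude(candidate: CandidateEvent, validation: ValidationResult,
                      config: DetectionConfig | None = None) -> float:
    """Peak dF/F0 of the peak-pixel trace within the peak period (the first
    ``peak_window_frames`` frames from the event start)."""
    config = config or DetectionConfig()
    s = validation.start_frame
    window = candidate.seed_trace[s: s + config.peak_window_frames]
    f0 = validation.f0_seed
    return float((window.max() - f0) / f0)


def measure_duration(candidate: CandidateEvent, validation: ValidationResult,
                     frame_interval: float,
                     config: DetectionConfig | None = None) -> tuple:
    """Seconds until the peak-pixel trace returns to within one baseline SD
    (floored at a small fraction of f0 for noise-free input).

    Returns ``(duration_s, censored)``; censored durations run to movie end.
    """
    config = config or DetectionConfig()
    s = validation.start_frame
    trace = candidate.seed_trace
    f0 = validation.f0_seed
    ret = f0 + max(validation.sd0_seed, config.duration_floor_fraction * f0)
    for u in range(s + 1, trace.size):
        if trace[u] <= ret:
            return (u - s) * frame_interval, False
    return (trace.size - 1 - s) * frame_interval, True


# ---------------------------------------------------------------------------
# displacement tracking
# ---------------------------------------------------------------------------

def track_displacement(candidate: CandidateEvent, validation: ValidationResult,
                       dff: np.ndarray, movie: TimelapseMovie,
                       config: DetectionConfig | None = None,
                       geometry: AxonGeometry | None = None,
                       compartment: str = "axon",
                       avg: np.ndarray | None = None) -> dict:
    """Re-localize the maximum-intensity pixel frame by frame for as long as
    the event's change signal persists, and classify its motion.

    A frame counts as "moving" when its step exceeds one pixel. Motion class:
    ``excluded_mobile`` for cumulative displacement beyond the exclusion
    threshold or motion in all but at most one tracked frame; ``static``
    below the substantial-displacement threshold; otherwise
    ``limited_displacement`` iff static frames outnumber moving frames.
    """
    config = config or DetectionConfig()
    if avg is None:
        avg = movie.frames.mean(axis=0)
    ps = movie.pixel_size
    T = dff.shape[0]
    s = validation.start_frame
    end = T - 1
    radius_px = config.search_radius / ps
    r_int = int(np.ceil(radius_px))

    positions = [(candidate.seed[1], candidate.seed[2])]
    lost = False
    floor = config.roi_fraction * candidate.peak_dff
    # once the seed-pixel trace has returned to baseline while the tracked
    # position is still at the seed, the event is over; without this stop a
    # later event at the same site would be chained onto this track
    f0s = validation.f0_seed
    ret = f0s + max(validation.sd0_seed, config.duration_floor_fraction * f0s)
    stop_radius_px = 0.5 * config.merge_radius / ps
    seed_r, seed_c = candidate.seed[1], candidate.seed[2]
    for u in range(s + 1, end + 1):
        pr, pc = positions[-1]
        if (candidate.seed_trace[u] <= ret
                and np.hypot(pr - seed_r, pc - seed_c) <= stop_radius_px):
            break
        r_lo, r_hi = max(0, pr - r_int), min(dff.shape[1], pr + r_int + 1)
        c_lo, c_hi = max(0, pc - r_int), min(dff.shape[2], pc + r_int + 1)
        win = dff[u, r_lo:r_hi, c_lo:c_hi] * avg[r_lo:r_hi, c_lo:c_hi]
        k = np.unravel_index(np.argmax(win), win.shape)
        nr, nc = r_lo + int(k[0]), c_lo + int(k[1])
        if np.hypot(nr - pr, nc - pc) > radius_px or win[k] < floor:
            lost = True
            break
        positions.append((nr, nc))

    steps = [np.hypot(b[0] - a[0], b[1] - a[1]) * ps
             for a, b in zip(positions, positions[1:])]
    cumulative = float(sum(steps))
    moving = sum(1 for d in steps if d > ps)
    static = len(steps) - moving
    n_frames_tracked = len(positions)

    if cumulative > config.displacement_exclusion:
        motion = "excluded_mobile"
    elif n_frames_tracked >= 3 and moving >= n_frames_tracked - 1:
        motion = "excluded_mobile"  # moving throughout
    elif cumulative < config.displacement_substantial:
        motion = "static"
    elif static > moving:
        motion = "limited_displacement"
    else:
        motion = "excluded_mobile"

    # signed steps along the structure's arc
    if geometry is not None:
        arcs = [geometry.locate(p)[1] for p in positions]
    else:
        arcs = [p[1] * ps for p in positions]  # fall back to the column axis
    net = float(arcs[-1] - arcs[0]) if arcs else 0.0
    net = float(np.clip(net, -cumulative, cumulative))

    direction = "none"
    if cumulative >= config.displacement_substantial and moving > 0:
        if compartment == "collateral":
            direction = "anterograde" if net > 0 else "retrograde"
        else:
            signed = [b - a for a, b in zip(arcs, arcs[1:])
                      if abs(b - a) > ps]
            if signed:
                pos_frac = sum(1 for d in signed if d > 0) / len(signed)
                frac = max(pos_frac, 1 - pos_frac)
                direction = ("unidirectional"
                             if frac >= config.unidirectional_fraction
                             else "bidirectional")

    return {
        "cumulative_displacement": cumulative,
        "net_displacement": net,
        "motion_class": motion,
        "direction_class": direction,
        "track_lost": lost,
        "positions": positions,
    }


# ---------------------------------------------------------------------------
# assembly and deduplication
# ---------------------------------------------------------------------------

def _dedupe(records: list, merge_radius_px: float, frame_window: int,
            track_radius_px: float | None = None) -> list:
    """Greedy non-maximum suppression of accepted records by position and
    onset frame; records must arrive sorted strongest-first.

    A weaker record is a duplicate when (a) its onset is within
    ``frame_window`` of a kept record and its seed lies within the merge
    radius of that record or its ROI intersects that record's ROI (low
    secondary maxima on an event's shoulder grow regions that engulf the
    primary event), or (b) its seed lies on the kept record's displacement
    track at its own onset frame (trailing re-detections of a moving event).
    """
    kept: list = []
    for rec in records:
        dup = False
        for k in kept:
            idx = rec["start"] - k["start"]
            track = k["disp"]["positions"]
            radius = merge_radius_px if track_radius_px is None else track_radius_px
            if 0 <= idx < len(track):
                tr, tc = track[idx]
                if np.hypot(rec["row"] - tr, rec["col"] - tc) <= radius:
                    dup = True
                    break
            if abs(rec["start"] - k["start"]) > frame_window:
                continue
            d = np.hypot(rec["row"] - k["row"], rec["col"] - k["col"])
            if d <= merge_radius_px or not k["roi_set"].isdisjoint(rec["roi_set"]):
                dup = True
                break
        if not dup:
            kept.append(rec)
    return kept


def _assemble(movie: TimelapseMovie, dff: np.ndarray, candidates: list,
              config: DetectionConfig, geometry: AxonGeometry | None):
    avg = movie.frames.mean(axis=0)
    accepted = []
    rejected = []
    for cand in candidates:
        val = validate_event(cand, config)
        if not val.accepted:
            rejected.append((cand, val))
            continue
        compartment, arc = "axon", cand.seed[2] * movie.pixel_size
        if geometry is not None:
            compartment, arc, _dist = geometry.locate((cand.seed[1], cand.seed[2]))
        accepted.append({
            "cand": cand, "val": val, "row": cand.seed[1], "col": cand.seed[2],
            "start": val.start_frame, "strength": cand.peak_dff,
            "roi_set": {(int(r), int(c)) for r, c in cand.roi},
            "compartment": compartment, "arc": arc,
        })
    accepted.sort(key=lambda r: (-r["strength"], r["start"], r["row"], r["col"]))
    # track every accepted record before deduplication so that trailing
    # re-detections of one moving event collapse onto the first detection
    for rec in accepted:
        rec["disp"] = track_displacement(rec["cand"], rec["val"], dff, movie,
                                         config, geometry=geometry,
                                         compartment=rec["compartment"], avg=avg)
    m_px = config.merge_radius / movie.pixel_size
    kept = _dedupe(accepted, m_px, config.min_frames,
                   track_radius_px=config.search_radius / movie.pixel_size)

    events = []
    for rec in kept:
        cand, val = rec["cand"], rec["val"]
        amplitude = measure_amplitude(cand, val, config)
        duration, censored = measure_duration(cand, val, movie.frame_interval, config)
        compartment, arc = rec["compartment"], rec["arc"]
        disp = rec["disp"]
        events.append(SypHyEvent(
            arc_position=arc, compartment_raw=compartment,
            start_frame=val.start_frame, amplitude=amplitude, duration=duration,
            cumulative_displacement=disp["cumulative_displacement"],
            net_displacement=disp["net_displacement"],
            motion_class=disp["motion_class"],
            direction_class=disp["direction_class"],
            duration_censored=censored, baseline_short=val.baseline_short,
            peak_row=rec["row"], peak_col=rec["col"], peak_frame=cand.seed[0],
        ))
    events.sort(key=lambda e: (e.start_frame, e.arc_position))
    return events, rejected


def detect_events(movie: TimelapseMovie, config: DetectionConfig | None = None,
                  geometry: AxonGeometry | None = None,
                  dff: np.ndarray | None = None,
                  return_rejected: bool = False):
    """Full detection pipeline on a preprocessed movie."""
    config = config or DetectionConfig()
    if dff is None:
        dff = compute_dff_avg(movie)
    candidates = find_candidates(movie, config, dff=dff)
    events, rejected = _assemble(movie, dff, candidates, config, geometry)
    if return_rejected:
        return events, rejected
    return events


def brute_force_detect(movie: TimelapseMovie, config: DetectionConfig | None = None,
                       geometry: AxonGeometry | None = None,
                       dff: np.ndarray | None = None) -> list:
    """Exhaustive oracle: test every pixel and frame against the validation
    criteria and deduplicate. Guarded to small movies."""
    config = config or DetectionConfig()
    T, H, W = movie.frames.shape
    if T * H * W > config.brute_force_guard:
        raise ValueError("movie exceeds the brute-force size guard")
    if dff is None:
        dff = compute_dff_avg(movie)

    avg = movie.frames.mean(axis=0)
    candidates = []
    seen = set()
    above = np.argwhere(dff > config.candidate_dff_threshold)
    for t, r, c in above:
        t, r, c = int(t), int(r), int(c)
        v = dff[t, r, c]
        # quick rejection: a strictly brighter 4-neighbour means this pixel
        # cannot be the maximum of its grown region
        brighter = False
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and dff[t, rr, cc] > v:
                brighter = True
                break
        if brighter:
            continue
        cand = _extract_candidate(movie, dff, avg, (t, r, c), config)
        if cand.seed not in seen:
            seen.add(cand.seed)
            candidates.append(cand)
    events, _rej = _assemble(movie, dff, candidates, config, geometry)
    return events
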