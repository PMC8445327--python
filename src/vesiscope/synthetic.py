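"""Synthetic time-lapse movies, myelin profiles and sheath time-courses with
known ground truth.

The forward model renders a straight horizontal axon with vertical collateral
branches on a dark background. Residual surface fluorescence along the axon is
attenuated under myelin gaps. Fusion events add an isotropic Gaussian spot
whose peak-pixel intensity is ``amplitude x local baseline``; the temporal
profile is a plateau followed by an exponential tail sized so that the spot
contribution crosses the measurement return level exactly at the drawn
duration. Photobleaching, rigid drift and Poisson + Gaussian noise are applied
afterwards, in detector order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import (
    AxonGeometry,
    GroundTruth,
    GroundTruthEvent,
    MyelinProfile,
    SheathTimecourse,
    TimelapseMovie,
)
from .myelin import ProfileConfig, profile_from_segments

__all__ = [
    "SceneConfig",
    "make_geometry",
    "simulate_profile",
    "simulate_events",
    "render_movie",
    "render_red_channel",
    "simulate_sheath_timecourse",
    "noise_sigma",
]


@dataclass
class SceneConfig:
    # geometry / sampling
    field_length: float = 120.0  # um of axon sampled
    pixel_size: float = 0.25  # um/px
    frame_interval: float = 1.0  # s
    n_frames: int = 600
    n_collaterals: int = 3
    collateral_length: float = 8.0  # um
    axon_width_px: int = 3
    border_px: int = 6

    # intensities
    axon_baseline: float = 100.0
    background_intensity: float = 5.0
    under_sheath_attenuation: float = 0.5  # multiplicative, in (0, 1]
    red_baseline: float = 100.0

    # degradation
    bleach_tau: float = float("inf")  # s
    photon_scale: float = 0.0  # photons per intensity unit; 0 disables shot noise
    read_sd: float = 0.0  # Gaussian read noise SD (intensity units)
    drift_per_frame: tuple = (0.0, 0.0)  # (drow, dcol) px per frame, cumulative

    # myelin profile
    n_gaps: int = 3
    gap_length_range: tuple = (4.0, 20.0)
    gap_lengths: tuple | None = None  # explicit lengths override the range
    min_gap_separation: float = 4.0  # um of positive axon between gaps
    gap_edge_margin: float = 3.0  # um, keeps simulated gaps complete

    # event statistics (rates in events/um/h)
    event_rates: dict = field(default_factory=lambda: {
        "nonmyelinated": 0.15,
        "myelinated": 0.03,
        "collateral": 0.25,
        "heminodal_factor": 3.0,
    })
    amplitude_dist: dict = field(default_factory=lambda: {
        "kind": "lognormal", "mu": 0.3, "sigma": 0.3, "min": 0.0})
    duration_dist: dict = field(default_factory=lambda: {
        "kind": "lognormal", "mu": 1.8, "sigma": 0.2, "min": 4.0})  # seconds
    mobile_fraction: float = 0.0
    mobile_speed: float = 0.3  # um/s
    event_start_margin_frames: int = 0  # keep event onsets away from movie edges

    # event rendering
    spot_sigma: float = 0.5  # um
    plateau_fraction: float = 0.7  # fraction of the duration spent at peak
    return_floor_fraction: float = 0.01  # return level floor, x local baseline

    # sheath growth model
    growth_b0_nascent: float = -0.35  # um/h
    growth_b0_mature: float = 0.5  # um/h
    growth_b1: float = 0.15  # um/h per (heminodal event/h)
    growth_noise_sd: float = 0.25  # um/h
    nascent_threshold: float = 6.0  # um
    session_interval_h: float = 4.0
    event_window_h: float = 0.25  # observation window for event frequencies

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.under_sheath_attenuation <= 1.0):
            raise ValueError("under_sheath_attenuation must be in (0, 1]")
        for k, v in self.event_rates.items():
            if v < 0:
                raise ValueError(f"event rate {k} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        if not np.isfinite(d["bleach_tau"]):
            d["bleach_tau"] = None
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if d.get("bleach_tau") is None:
            d["bleach_tau"] = float("inf")
        for key in ("drift_per_frame", "gap_length_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("gap_lengths") is not None:
            d["gap_lengths"] = tuple(d["gap_lengths"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "SceneConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml
            return cls.from_json_dict(yaml.safe_load(text))
        return cls.from_json_dict(json.loads(text))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def make_geometry(config: SceneConfig) -> AxonGeometry:
    """Straight horizontal axon with evenly spaced vertical collaterals."""
    ps = config.pixel_size
    n_ax = int(round(config.field_length / ps))
    col0 = config.border_px
    collat_px = int(round(config.collateral_length / ps))
    row_axon = config.border_px + collat_px + config.axon_width_px // 2
    path = [(row_axon, col0), (row_axon, col0 + n_ax)]
    collaterals = []
    for i in range(config.n_collaterals):
        arc = (i + 1) * config.field_length / (config.n_collaterals + 1)
        arc = round(arc / ps) * ps  # snap to pixel grid
        c = col0 + int(round(arc / ps))
        collaterals.append((arc, [(row_axon, c), (row_axon - collat_px, c)]))
    return AxonGeometry(axon_path=np.asarray(path, dtype=float), pixel_size=ps,
                        collaterals=collaterals)


def frame_shape(config: SceneConfig) -> tuple:
    ps = config.pixel_size
    n_ax = int(round(config.field_length / ps))
    collat_px = int(round(config.collateral_length / ps))
    H = 2 * config.border_px + collat_px + config.axon_width_px
    W = 2 * config.border_px + n_ax + 1
    return H, W


# ---------------------------------------------------------------------------
# profile simulation
# ---------------------------------------------------------------------------

def simulate_profile(config: SceneConfig, rng: np.random.Generator | None = None,
                     profile_config: ProfileConfig | None = None) -> MyelinProfile:
    """Place non-overlapping gaps of the requested lengths along the axon.

    Gap edges are snapped to the pixel grid so that coverage recovery from the
    rendered reporter channel is exact up to one pixel per gap edge.
    """
    rng = rng if rng is not None else config.rng()
    ps = config.pixel_size
    L = config.field_length
    if config.n_gaps == 0 and not config.gap_lengths:
        return profile_from_segments([(0.0, L, "positive")], L, profile_config)

    if config.gap_lengths is not None:
        lengths = [float(x) for x in config.gap_lengths]
    else:
        lo, hi = config.gap_length_range
        lengths = list(rng.uniform(lo, hi, size=config.n_gaps))
    lengths = [round(g / ps) * ps for g in lengths]
    if sum(lengths) > L:
        raise ValueError("requested total gap length exceeds the field length")

    sep = config.min_gap_separation
    margin = config.gap_edge_margin
    n = len(lengths)
    free = L - sum(lengths) - 2 * margin - (n - 1) * sep
    if free < 0:
        raise ValueError("gap placement infeasible: total gap length plus "
                         "separations exceeds the field")
    lengths = list(rng.permutation(lengths))
    slack = rng.dirichlet(np.ones(n + 1)) * free
    placed = []
    pos = margin + slack[0]
    for k, g in enumerate(lengths):
        s = round(pos / ps) * ps
        placed.append((s, s + g))
        pos = s + g + sep + slack[k + 1]
    segments = []
    cursor = 0.0
    for (s, e) in placed:
        if s > cursor:
            segments.append((cursor, s, "positive"))
        segments.append((s, e, "gap"))
        cursor = e
    if cursor < L:
        segments.append((cursor, L, "positive"))
    return profile_from_segments(segments, L, profile_config)


# ---------------------------------------------------------------------------
# event simulation
# ---------------------------------------------------------------------------

def _draw(dist: dict, rng: np.random.Generator, n: int) -> np.ndarray:
    kind = dist.get("kind", "lognormal")
    if kind == "fixed":
        out = np.full(n, float(dist["value"]))
    elif kind == "lognormal":
        out = rng.lognormal(mean=dist["mu"], sigma=dist["sigma"], size=n)
    elif kind == "uniform":
        out = rng.uniform(dist["low"], dist["high"], size=n)
    else:
        raise ValueError(f"unknown distribution kind {kind!r}")
    return np.maximum(out, float(dist.get("min", 0.0)))


def _subtract_intervals(base: list, remove: list) -> list:
    """Interval-list subtraction on half-open [s, e) intervals."""
    out = []
    for (s, e) in base:
        cuts = [(s, e)]
        for (rs, re) in remove:
            nxt = []
            for (cs, ce) in cuts:
                if re <= cs or rs >= ce:
                    nxt.append((cs, ce))
                    continue
                if rs > cs:
                    nxt.append((cs, rs))
                if re < ce:
                    nxt.append((re, ce))
            cuts = nxt
        out.extend(cuts)
    return [(s, e) for (s, e) in out if e - s > 1e-12]


def _uniform_in_intervals(intervals: list, rng: np.random.Generator, n: int) -> np.ndarray:
    lens = np.array([e - s for s, e in intervals])
    total = lens.sum()
    u = rng.uniform(0, total, size=n)
    edges = np.concatenate([[0.0], np.cumsum(lens)])
    idx = np.clip(np.searchsorted(edges, u, side="right") - 1, 0, len(intervals) - 1)
    return np.array([intervals[i][0] + (u[k] - edges[i]) for k, i in enumerate(idx)])


def simulate_events(config: SceneConfig, profile: MyelinProfile, duration_h: float,
                    rng: np.random.Generator | None = None) -> list:
    """Draw ground-truth events from independent Poisson processes.

    Compartment rates (events/um/h): non-myelinated positive axon at the base
    rate, heminodal windows at base rate x ``heminodal_factor``, gaps at the
    myelinated rate, and collaterals at the collateral rate.
    """
    rng = rng if rng is not None else config.rng()
    rates = config.event_rates
    base = rates.get("nonmyelinated", 0.0)
    factor = rates.get("heminodal_factor", 1.0)
    events: list = []

    heminodes = list(profile.heminodes)
    positive_rest = _subtract_intervals(profile.positive_segments(), heminodes)
    regions = [
        (positive_rest, base, "axon"),
        (heminodes, base * factor, "axon"),
        (profile.gaps(), rates.get("myelinated", 0.0), "axon"),
    ]
    for intervals, rate, compartment in regions:
        total_len = sum(e - s for s, e in intervals)
        if total_len <= 0 or rate <= 0:
            continue
        n = rng.poisson(rate * total_len * duration_h)
        if n == 0:
            continue
        arcs = _uniform_in_intervals(intervals, rng, n)
        events.extend(_make_events(config, rng, arcs, compartment, -1))

    crate = rates.get("collateral", 0.0)
    if crate > 0:
        for ci in range(config.n_collaterals):
            n = rng.poisson(crate * config.collateral_length * duration_h)
            if n == 0:
                continue
            arcs = rng.uniform(0.2, config.collateral_length, size=n)
            events.extend(_make_events(config, rng, arcs, "collateral", ci))

    events.sort(key=lambda e: (e.start_frame, e.arc_position))
    return events


def _make_events(config, rng, arcs, compartment, collateral_index):
    # event centres are snapped to the pixel grid so that rendered peak-pixel
    # photometry recovers the drawn amplitude without sub-pixel loss; flooring
    # (not rounding) keeps every event inside its drawn region because region
    # boundaries lie on the grid
    arcs = np.floor(np.asarray(arcs) / config.pixel_size) * config.pixel_size
    n = len(arcs)
    amps = _draw(config.amplitude_dist, rng, n)
    durs = _draw(config.duration_dist, rng, n)
    m = config.event_start_margin_frames
    lo, hi = min(m, config.n_frames - 1), max(config.n_frames - m, min(m, config.n_frames - 1) + 1)
    starts = rng.integers(lo, hi, size=n)
    mobile = rng.uniform(size=n) < config.mobile_fraction
    out = []
    for k in range(n):
        vel = 0.0
        if mobile[k]:
            vel = config.mobile_speed * (1 if rng.uniform() < 0.5 else -1)
        out.append(GroundTruthEvent(
            arc_position=float(arcs[k]), compartment=compartment,
            start_frame=int(starts[k]), amplitude=float(amps[k]),
            duration=float(durs[k]), mobile=bool(mobile[k]), velocity=vel,
            collateral_index=collateral_index,
        ))
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def noise_sigma(config: SceneConfig, intensity: float) -> float:
    """Expected measurement noise SD at a given intensity under the config's
    Poisson + Gaussian noise model."""
    var = config.read_sd ** 2
    if config.photon_scale > 0:
        var += intensity / config.photon_scale
    return float(np.sqrt(var))


def _baseline_image(config: SceneConfig, profile: MyelinProfile,
                    geometry: AxonGeometry) -> np.ndarray:
    H, W = frame_shape(config)
    img = np.full((H, W), config.background_intensity, dtype=np.float64)
    ps = config.pixel_size
    col0 = config.border_px
    row_axon = int(geometry.axon_path[0][0])
    n_ax = int(round(config.field_length / ps))
    half = config.axon_width_px // 2
    line = np.full(n_ax, config.axon_baseline)
    for (s, e) in profile.gaps():
        i0, i1 = int(round(s / ps)), int(round(e / ps))
        line[i0:i1] *= config.under_sheath_attenuation
    img[row_axon - half: row_axon + half + 1, col0: col0 + n_ax] = line
    for _arc, poly in geometry.collaterals:
        c = int(round(poly[0][1]))
        r_top = int(round(poly[-1][0]))
        img[r_top: row_axon - half, c] = config.axon_baseline
    return img


def _event_center_px(config: SceneConfig, geometry: AxonGeometry,
                     ev: GroundTruthEvent) -> tuple:
    ps = config.pixel_size
    col0 = config.border_px
    row_axon = geometry.axon_path[0][0]
    if ev.compartment == "axon":
        return (row_axon, col0 + ev.arc_position / ps)
    arc, poly = geometry.collaterals[ev.collateral_index]
    return (row_axon - ev.arc_position / ps, float(poly[0][1]))


def _local_baseline(config: SceneConfig, profile: MyelinProfile,
                    ev: GroundTruthEvent) -> float:
    b = config.axon_baseline
    if ev.compartment == "axon":
        for (s, e) in profile.gaps():
            if s <= ev.arc_position < e:
                return b * config.under_sheath_attenuation
    return b


def render_movie(config: SceneConfig, profile: MyelinProfile, events: list,
                 geometry: AxonGeometry | None = None,
                 rng: np.random.Generator | None = None) -> tuple:
    """Render the forward model. Returns ``(TimelapseMovie, GroundTruth)``."""
    rng = rng if rng is not None else config.rng()
    geometry = geometry or make_geometry(config)
    base = _baseline_image(config, profile, geometry)
    H, W = base.shape
    T = config.n_frames
    dt = config.frame_interval
    sig_px = config.spot_sigma / config.pixel_size

    frames = np.repeat(base[None], T, axis=0)

    for ev in events:
        b_local = _local_baseline(config, profile, ev)
        ret = max(noise_sigma(config, b_local), config.return_floor_fraction * b_local)
        peak = ev.amplitude * b_local
        if peak <= ret:
            continue  # unrenderable below the return level; stays in ground truth
        plateau = config.plateau_fraction * ev.duration
        tau_d = (ev.duration - plateau) / np.log(peak / ret)
        r0, c0 = _event_center_px(config, geometry, ev)
        for t in range(ev.start_frame, T):
            delta = (t - ev.start_frame) * dt
            amp = peak if delta <= plateau else peak * np.exp(-(delta - plateau) / tau_d)
            if amp < 1e-3 * b_local:
                break
            rr, cc = r0, c0
            if ev.mobile:
                step = ev.velocity * delta / config.pixel_size
                if ev.compartment == "axon":
                    cc = c0 + step
                else:
                    rr = r0 - step
            _add_spot(frames[t], rr, cc, amp, sig_px)

    # bleaching
    if np.isfinite(config.bleach_tau):
        decay = np.exp(-np.arange(T) * dt / config.bleach_tau)
        frames *= decay[:, None, None]

    # drift (cumulative, rounded to integer pixels)
    drift = []
    drow, dcol = config.drift_per_frame
    for t in range(T):
        sr, sc = int(round(drow * t)), int(round(dcol * t))
        drift.append((sr, sc))
        if sr or sc:
            frames[t] = ndimage.shift(frames[t], (sr, sc), order=0, mode="nearest")

    # noise, applied last
    if config.photon_scale > 0:
        frames = rng.poisson(frames * config.photon_scale) / config.photon_scale
    if config.read_sd > 0:
        frames = frames + rng.normal(0.0, config.read_sd, size=frames.shape)
    frames = np.maximum(frames, 0.0)

    movie = TimelapseMovie(frames, pixel_size=config.pixel_size,
                           frame_interval=dt, channel_role="pHluorin")
    truth = GroundTruth(
        true_events=list(events), true_profile=profile,
        noise_params={"photon_scale": config.photon_scale, "read_sd": config.read_sd},
        drift_per_frame=drift, bleach_tau=config.bleach_tau,
    )
    return movie, truth


def _add_spot(frame: np.ndarray, r0: float, c0: float, amp: float, sigma_px: float) -> None:
    H, W = frame.shape
    ext = int(np.ceil(3 * sigma_px))
    ri, ci = int(round(r0)), int(round(c0))
    if not (0 <= ri < H and 0 <= ci < W):
        raise ValueError("event spot placed outside the frame")
    r_lo, r_hi = max(0, ri - ext), min(H, ri + ext + 1)
    c_lo, c_hi = max(0, ci - ext), min(W, ci + ext + 1)
    rr = np.arange(r_lo, r_hi)[:, None] - r0
    cc = np.arange(c_lo, c_hi)[None, :] - c0
    frame[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(-(rr ** 2 + cc ** 2) / (2 * sigma_px ** 2))


def render_red_channel(config: SceneConfig, profile: MyelinProfile,
                       geometry: AxonGeometry | None = None,
                       rng: np.random.Generator | None = None) -> TimelapseMovie:
    """Single-frame static reporter channel: positive axon bright, gaps dark."""
    geometry = geometry or make_geometry(config)
    import dataclasses as _dc
    cfg_red = _dc.replace(config, axon_baseline=config.red_baseline,
                          under_sheath_attenuation=1.0)
    base = _baseline_image(cfg_red, profile, geometry)
    # gaps are reporter-negative: drop to background level
    ps = config.pixel_size
    col0 = config.border_px
    row_axon = int(geometry.axon_path[0][0])
    half = config.axon_width_px // 2
    for (s, e) in profile.gaps():
        i0, i1 = col0 + int(round(s / ps)), col0 + int(round(e / ps))
        base[row_axon - half: row_axon + half + 1, i0:i1] = config.background_intensity
    if rng is not None and config.read_sd > 0:
        base = np.maximum(base + rng.normal(0.0, config.read_sd, size=base.shape), 0.0)
    return TimelapseMovie(base[None], pixel_size=ps,
                          frame_interval=config.frame_interval, channel_role="static_red")


# ---------------------------------------------------------------------------
# sheath growth simulation
# ---------------------------------------------------------------------------

def simulate_sheath_timecourse(config: SceneConfig, profile: MyelinProfile,
                               events: list,
                               rng: np.random.Generator | None = None,
                               geometry: AxonGeometry | None = None) -> list:
    """Per-sheath length time-courses coupled to local event frequency.

    Nascent sheaths (initial length below ``nascent_threshold``) grow at
    ``b0_nascent + b1 x heminodal event frequency + noise``; sheaths past the
    threshold grow at ``b0_mature + noise`` independent of activity. A nascent
    sheath whose projected length reaches zero fully retracts.
    """
    rng = rng if rng is not None else config.rng()
    geometry = geometry or make_geometry(config)
    collat_arcs = [a for a, _ in geometry.collaterals]
    dt_h = config.session_interval_h
    window = config.event_window_h
    out = []
    node_set = [tuple(n) for n in profile.nodes]
    for sid, (s, e) in enumerate(profile.gaps(complete_only=True)):
        hemis = [h for h in profile.heminodes
                 if abs(h[1] - s) < 1e-9 or abs(h[0] - e) < 1e-9]
        n_hemi_events = sum(
            1 for ev in events if ev.compartment == "axon" and not ev.mobile
            and any(h[0] <= ev.arc_position < h[1] for h in hemis))
        hemi_freq = n_hemi_events / window
        n_under = sum(1 for ev in events if ev.compartment == "axon" and not ev.mobile
                      and s <= ev.arc_position < e)
        under_freq = n_under / (e - s) / window

        L0 = e - s
        if L0 < config.nascent_threshold:
            rate = (config.growth_b0_nascent + config.growth_b1 * hemi_freq
                    + rng.normal(0.0, config.growth_noise_sd))
        else:
            rate = config.growth_b0_mature + rng.normal(0.0, config.growth_noise_sd)
        L1 = L0 + rate * dt_h

        flank = []
        for edge in (s, e):
            label = "open"
            if any(abs(edge - n0) < 1e-9 or abs(edge - n1) < 1e-9 for n0, n1 in node_set):
                label = "node"
            elif any(abs(edge - a) <= 0.5 for a in collat_arcs):
                label = "collateral"
            flank.append(label)

        if L0 < config.nascent_threshold and L1 <= 0:
            fate, L1 = "full_retraction", 0.0
        else:
            L1 = max(L1, 0.05)
            fate = "grow" if L1 > L0 else ("shrink" if L1 < L0 else "stable")
        out.append(SheathTimecourse(
            sheath_id=sid, lengths=[L0, L1], session_times=[0.0, dt_h],
            fate=fate, free_to_grow=not all(f in ("node", "collateral") for f in flank),
            flanking=tuple(flank), heminodal_frequency=hemi_freq,
            under_sheath_frequency=under_freq,
        ))
    return out
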