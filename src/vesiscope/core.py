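"""Shared domain types, physical-calibration conventions and file I/O.

Conventions used throughout the package:

* movies are ``(T, H, W)`` arrays of non-negative fluorescence intensities;
* pixel indices are 0-based ``(row, col)`` pairs;
* arc positions are continuous micrometres measured from the anterior end of
  the sampled field (anterior = low arc position, a fixed convention of this
  package); intervals along the axon are half-open ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "TimelapseMovie",
    "AxonGeometry",
    "FluorescenceTrace",
    "SypHyEvent",
    "MyelinProfile",
    "SheathTimecourse",
    "GroundTruth",
    "GroundTruthEvent",
    "read_movie",
    "write_movie",
    "write_event_table",
    "read_event_table",
    "save_kymograph_png",
]

MOTION_CLASSES = ("static", "limited_displacement", "excluded_mobile")
DIRECTION_CLASSES = ("none", "unidirectional", "bidirectional", "anterograde", "retrograde")


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

@dataclass
class TimelapseMovie:
    """A 2D+T fluorescence stack with physical calibration.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity per time point, arbitrary fluorescence units.
    pixel_size : float
        Micrometres per pixel (isotropic).
    frame_interval : float
        Seconds per frame.
    channel_role : str
        ``"pHluorin"`` for the dynamic green channel, ``"static_red"`` for the
        single-frame myelin reporter channel.
    t0 : float
        Acquisition start time in seconds.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_role: str = "pHluorin"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("movie must contain at least one frame")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not (self.frame_interval > 0):
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("intensities must be finite")
        if self.frames.min() < 0:
            raise ValueError("intensities must be >= 0")
        if self.channel_role not in ("pHluorin", "static_red"):
            raise ValueError(f"unknown channel_role {self.channel_role!r}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds (relative to t0)."""
        return np.arange(self.n_frames) * self.frame_interval

    def with_frames(self, frames: np.ndarray) -> "TimelapseMovie":
        return TimelapseMovie(
            frames=frames,
            pixel_size=self.pixel_size,
            frame_interval=self.frame_interval,
            channel_role=self.channel_role,
            t0=self.t0,
        )


def read_movie(path, pixel_size: float, frame_interval: float,
               channel_role: str = "pHluorin") -> TimelapseMovie:
    """Read a multi-page TIFF stack into a :class:`TimelapseMovie`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2D+T stack in {path}, got shape {arr.shape}")
    return TimelapseMovie(arr, pixel_size=pixel_size, frame_interval=frame_interval,
                          channel_role=channel_role)


def write_movie(movie: TimelapseMovie, path) -> None:
    """Write the movie as a float64 multi-page TIFF (lossless round trip)."""
    tifffile.imwrite(str(path), movie.frames.astype(np.float64),
                     photometric="minisblack")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _polyline_arc(points: np.ndarray, pixel_size: float) -> np.ndarray:
    """Cumulative arc length (um) at each vertex of a pixel-space polyline."""
    d = np.sqrt(np.sum(np.diff(points, axis=0) ** 2, axis=1)) * pixel_size
    return np.concatenate([[0.0], np.cumsum(d)])


def _project_on_polyline(points: np.ndarray, arc: np.ndarray, p: np.ndarray):
    """Project pixel point ``p`` onto a polyline; return (arc_um, dist_px)."""
    best = (0.0, np.inf)
    for i in range(len(points) - 1):
        a, b = points[i], points[i + 1]
        ab = b - a
        denom = float(ab @ ab)
        t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
        q = a + t * ab
        dist = float(np.hypot(*(p - q)))
        if dist < best[1]:
            seg_len = arc[i + 1] - arc[i]
            best = (float(arc[i] + t * seg_len), dist)
    return best


@dataclass
class AxonGeometry:
    """Linearized axon geometry: main path plus collateral branches.

    ``axon_path`` is an ordered ``(N, 2)`` array of ``(row, col)`` pixel
    vertices; ``collaterals`` maps a branch-point arc position (um along the
    axon) to the branch polyline (first vertex at the branch point).
    """

    axon_path: np.ndarray
    pixel_size: float
    collaterals: list = field(default_factory=list)  # (branch_arc_um, polyline)

    def __post_init__(self) -> None:
        self.axon_path = np.asarray(self.axon_path, dtype=np.float64)
        if self.axon_path.ndim != 2 or self.axon_path.shape[1] != 2:
            raise ValueError("axon_path must be an (N, 2) array of (row, col)")
        self._arc = _polyline_arc(self.axon_path, self.pixel_size)
        if np.any(np.diff(self._arc) <= 0):
            raise ValueError("axon path arc positions must be strictly increasing")
        self.collaterals = [
            (float(a), np.asarray(p, dtype=np.float64)) for a, p in self.collaterals
        ]
        for a, _ in self.collaterals:
            if not (0.0 <= a <= self.field_length):
                raise ValueError(f"branch point {a} outside [0, {self.field_length}]")

    @property
    def field_length(self) -> float:
        """Total sampled axon length (um)."""
        return float(self._arc[-1])

    def collateral_lengths(self) -> list:
        return [float(_polyline_arc(p, self.pixel_size)[-1]) for _, p in self.collaterals]

    def locate(self, point_px) -> tuple:
        """Locate a pixel point on the structure.

        Returns ``(compartment, arc_um, dist_px)`` where compartment is
        ``"axon"`` or ``"collateral"``; for collaterals ``arc_um`` is measured
        along the branch from its branch point.
        """
        p = np.asarray(point_px, dtype=np.float64)
        arc, dist = _project_on_polyline(self.axon_path, self._arc, p)
        best = ("axon", arc, dist)
        for branch_arc, poly in self.collaterals:
            barc = _polyline_arc(poly, self.pixel_size)
            a, d = _project_on_polyline(poly, barc, p)
            # points at the branch point itself stay axonal
            if d < best[2] and a > 0:
                best = ("collateral", a, d)
        return best

    def to_json_dict(self) -> dict:
        return {
            "axon_path": self.axon_path.tolist(),
            "pixel_size": self.pixel_size,
            "collaterals": [
                {"branch_arc_um": a, "polyline": p.tolist()} for a, p in self.collaterals
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "AxonGeometry":
        return cls(
            axon_path=np.asarray(d["axon_path"]),
            pixel_size=float(d["pixel_size"]),
            collaterals=[(c["branch_arc_um"], np.asarray(c["polyline"]))
                         for c in d.get("collaterals", [])],
        )


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

@dataclass
class FluorescenceTrace:
    """ROI intensity trace with its pre-event baseline statistics."""

    values: np.ndarray
    f0: float
    sd0: float
    roi: tuple = ()  # tuple of (row, col) pixel pairs

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.sd0 < 0:
            raise ValueError("sd0 must be >= 0")


@dataclass
class SypHyEvent:
    """One accepted vesicle-fusion event."""

    arc_position: float
    compartment_raw: str  # "axon" | "collateral"
    start_frame: int
    amplitude: float  # peak dF/F0, dimensionless
    duration: float  # seconds
    cumulative_displacement: float = 0.0
    net_displacement: float = 0.0
    motion_class: str = "static"
    direction_class: str = "none"
    duration_censored: bool = False
    baseline_short: bool = False
    peak_row: int = -1
    peak_col: int = -1
    peak_frame: int = -1

    def __post_init__(self) -> None:
        if self.compartment_raw not in ("axon", "collateral"):
            raise ValueError(f"bad compartment {self.compartment_raw!r}")
        if self.motion_class not in MOTION_CLASSES:
            raise ValueError(f"bad motion_class {self.motion_class!r}")
        if self.direction_class not in DIRECTION_CLASSES:
            raise ValueError(f"bad direction_class {self.direction_class!r}")
        if abs(self.net_displacement) > self.cumulative_displacement + 1e-9:
            raise ValueError("|net_displacement| cannot exceed cumulative_displacement")


_EVENT_COLUMNS = [
    "arc_position", "compartment_raw", "start_frame", "amplitude", "duration",
    "cumulative_displacement", "net_displacement", "motion_class",
    "direction_class", "duration_censored", "baseline_short",
    "peak_row", "peak_col", "peak_frame",
]


def write_event_table(events: Sequence[SypHyEvent], path) -> None:
    """Write events to CSV, one row per event, stable column order."""
    rows = [{c: getattr(e, c) for c in _EVENT_COLUMNS} for e in events]
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    df.to_csv(path, index=False)


def read_event_table(path) -> list:
    df = pd.read_csv(path)
    events = []
    for _, r in df.iterrows():
        events.append(SypHyEvent(
            arc_position=float(r["arc_position"]),
            compartment_raw=str(r["compartment_raw"]),
            start_frame=int(r["start_frame"]),
            amplitude=float(r["amplitude"]),
            duration=float(r["duration"]),
            cumulative_displacement=float(r["cumulative_displacement"]),
            net_displacement=float(r["net_displacement"]),
            motion_class=str(r["motion_class"]),
            direction_class=str(r["direction_class"]),
            duration_censored=bool(r["duration_censored"]),
            baseline_short=bool(r["baseline_short"]),
            peak_row=int(r["peak_row"]),
            peak_col=int(r["peak_col"]),
            peak_frame=int(r["peak_frame"]),
        ))
    return events


# ---------------------------------------------------------------------------
# myelin profile
# ---------------------------------------------------------------------------

@dataclass
class MyelinProfile:
    """Partition of an axon's arc length into reporter-positive regions and
    reporter-negative gaps (putative myelin sheaths), with derived heminodes,
    nodes and summary statistics.

    ``segments`` is an ordered list of ``(start_um, end_um, label)`` with
    label in ``{"positive", "gap"}``; segments tile ``[0, field_length)``.
    """

    segments: list
    field_length: float
    gap_complete_flags: list = field(default_factory=list)
    heminodes: list = field(default_factory=list)  # (start_um, end_um)
    nodes: list = field(default_factory=list)  # (start_um, end_um)
    percent_myelination: float = 0.0
    axon_class: str = "not_yet_myelinated"
    boundary_flag: bool = False

    def __post_init__(self) -> None:
        pos = 0.0
        for (s, e, label) in self.segments:
            if abs(s - pos) > 1e-6:
                raise ValueError("segments must tile [0, field_length) without overlap")
            if e <= s:
                raise ValueError("empty or reversed segment")
            if label not in ("positive", "gap"):
                raise ValueError(f"bad segment label {label!r}")
            pos = e
        if self.segments and abs(pos - self.field_length) > 1e-6:
            raise ValueError("segments must cover the full field length")
        if not (0.0 <= self.percent_myelination <= 100.0):
            raise ValueError("percent_myelination must be within [0, 100]")

    def gaps(self, complete_only: bool = False) -> list:
        """Gap intervals ``(start, end)``; optionally only complete ones."""
        out = []
        gi = 0
        for (s, e, label) in self.segments:
            if label != "gap":
                continue
            complete = self.gap_complete_flags[gi] if gi < len(self.gap_complete_flags) else True
            gi += 1
            if complete_only and not complete:
                continue
            out.append((s, e))
        return out

    def positive_segments(self) -> list:
        return [(s, e) for (s, e, label) in self.segments if label == "positive"]

    def positive_length(self) -> float:
        return float(sum(e - s for s, e in self.positive_segments()))

    def gap_length(self) -> float:
        return float(sum(e - s for s, e in self.gaps()))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        gi = 0
        for (s, e, label) in self.segments:
            complete = True
            if label == "gap":
                if gi < len(self.gap_complete_flags):
                    complete = self.gap_complete_flags[gi]
                gi += 1
            rows.append({"start_um": s, "end_um": e, "label": label, "complete": complete})
        return pd.DataFrame(rows, columns=["start_um", "end_um", "label", "complete"])

    def to_json_dict(self) -> dict:
        return {
            "segments": [[s, e, label] for (s, e, label) in self.segments],
            "field_length": self.field_length,
            "gap_complete_flags": list(map(bool, self.gap_complete_flags)),
            "heminodes": [list(h) for h in self.heminodes],
            "nodes": [list(n) for n in self.nodes],
            "percent_myelination": self.percent_myelination,
            "axon_class": self.axon_class,
            "boundary_flag": self.boundary_flag,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "MyelinProfile":
        return cls(
            segments=[(float(s), float(e), str(label)) for s, e, label in d["segments"]],
            field_length=float(d["field_length"]),
            gap_complete_flags=[bool(x) for x in d.get("gap_complete_flags", [])],
            heminodes=[tuple(h) for h in d.get("heminodes", [])],
            nodes=[tuple(n) for n in d.get("nodes", [])],
            percent_myelination=float(d.get("percent_myelination", 0.0)),
            axon_class=str(d.get("axon_class", "not_yet_myelinated")),
            boundary_flag=bool(d.get("boundary_flag", False)),
        )


# ---------------------------------------------------------------------------
# sheath time-courses
# ---------------------------------------------------------------------------

@dataclass
class SheathTimecourse:
    """Matched sheath lengths across imaging sessions."""

    sheath_id: int
    lengths: list  # um per session
    session_times: list  # hours
    fate: str = "grow"  # grow | shrink | stable | full_retraction
    free_to_grow: bool = True
    flanking: tuple = ("open", "open")  # per side: node | collateral | open
    heminodal_frequency: float = 0.0  # events/h at the bordering heminodes
    under_sheath_frequency: float = 0.0  # events/um/h under the sheath

    def __post_init__(self) -> None:
        if len(self.lengths) != len(self.session_times):
            raise ValueError("lengths and session_times must align")
        if len(self.lengths) < 2:
            raise ValueError("a time-course needs at least two sessions")
        if self.fate == "full_retraction" and self.lengths[-1] != 0:
            raise ValueError("full_retraction requires final length 0")
        both_blocked = all(f in ("node", "collateral") for f in self.flanking)
        if not self.free_to_grow and not both_blocked:
            raise ValueError("free_to_grow may be False only when both sides are blocked")

    @property
    def growth_rate(self) -> float:
        """um/h between the first and last session."""
        dt = self.session_times[-1] - self.session_times[0]
        return (self.lengths[-1] - self.lengths[0]) / dt

    @property
    def initial_length(self) -> float:
        return float(self.lengths[0])


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthEvent:
    arc_position: float
    compartment: str  # "axon" | "collateral"
    start_frame: int
    amplitude: float
    duration: float  # seconds
    mobile: bool = False
    velocity: float = 0.0  # um/s along the structure (signed)
    collateral_index: int = -1

    def to_json_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruthEvent":
        return cls(**d)


@dataclass
class GroundTruth:
    """The synthetic scene against which recovery is scored."""

    true_events: list
    true_profile: Optional[MyelinProfile]
    noise_params: dict = field(default_factory=dict)
    drift_per_frame: list = field(default_factory=list)  # (drow, dcol) px per frame
    bleach_tau: float = float("inf")

    def to_json_dict(self) -> dict:
        return {
            "true_events": [e.to_json_dict() for e in self.true_events],
            "true_profile": self.true_profile.to_json_dict() if self.true_profile else None,
            "noise_params": self.noise_params,
            "drift_per_frame": [list(map(float, s)) for s in self.drift_per_frame],
            "bleach_tau": self.bleach_tau if np.isfinite(self.bleach_tau) else None,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        tau = d.get("bleach_tau")
        return cls(
            true_events=[GroundTruthEvent.from_json_dict(e) for e in d["true_events"]],
            true_profile=(MyelinProfile.from_json_dict(d["true_profile"])
                          if d.get("true_profile") else None),
            noise_params=d.get("noise_params", {}),
            drift_per_frame=[tuple(s) for s in d.get("drift_per_frame", [])],
            bleach_tau=float("inf") if tau is None else float(tau),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "GroundTruth":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# kymograph export
# ---------------------------------------------------------------------------

def kymograph(movie: TimelapseMovie, geometry: AxonGeometry, half_width_px: int = 1) -> np.ndarray:
    """Position x time matrix: transverse-mean intensity along the axon path.

    Only supports the package's straight horizontal axon convention for the
    transverse mean; general polylines fall back to nearest-pixel sampling.
    """
    T, H, W = movie.frames.shape
    # sample one position per axon pixel step
    n = max(2, int(round(geometry.field_length / movie.pixel_size)) + 1)
    ts = np.linspace(0, 1, n)
    pts = []
    path, arc = geometry.axon_path, geometry._arc
    total = arc[-1]
    for t in ts:
        target = t * total
        i = int(np.searchsorted(arc, target, side="right")) - 1
        i = min(max(i, 0), len(path) - 2)
        seg = (target - arc[i]) / (arc[i + 1] - arc[i])
        pts.append(path[i] + seg * (path[i + 1] - path[i]))
    pts = np.asarray(pts)
    rows = np.clip(np.round(pts[:, 0]).astype(int), 0, H - 1)
    cols = np.clip(np.round(pts[:, 1]).astype(int), 0, W - 1)
    out = np.zeros((n, T))
    for k in range(-half_width_px, half_width_px + 1):
        rr = np.clip(rows + k, 0, H - 1)
        out += movie.frames[:, rr, cols].T
    return out / (2 * half_width_px + 1)


def save_kymograph_png(movie: TimelapseMovie, geometry: AxonGeometry, path,
                       half_width_px: int = 1) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    km = kymograph(movie, geometry, half_width_px=half_width_px)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(km, aspect="auto", cmap="gray",
              extent=[0, movie.n_frames * movie.frame_interval, geometry.field_length, 0])
    ax.set_xlabel("time (s)")
    ax.set_ylabel("arc position (um)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
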