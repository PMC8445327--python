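"""Segmentation of the static axonal reporter profile into positive regions
and reporter-negative gaps (putative myelin sheaths), and derivation of
heminodes, nodes, percent myelination and axon class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AxonGeometry, MyelinProfile, TimelapseMovie

__all__ = [
    "ProfileConfig",
    "segment_profile",
    "percent_myelination",
    "classify_axon",
    "derive_heminodes_nodes",
    "build_profile",
    "profile_from_segments",
    "sample_axon_intensity",
]


@dataclass
class ProfileConfig:
    gap_threshold_fraction: float = 0.5
    min_gap_length: float = 1.0  # um
    heminode_window: float = 3.0  # um
    node_max_length: float = 1.0  # um
    not_yet_myelinated_max: float = 5.0  # percent
    min_heminodes_for_myelinating: int = 3
    threshold_iterations: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.gap_threshold_fraction < 1.0):
            raise ValueError("gap_threshold_fraction must be in (0, 1)")
        for name in ("min_gap_length", "heminode_window", "node_max_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def sample_axon_intensity(movie: TimelapseMovie, geometry: AxonGeometry,
                          half_width_px: int = 1) -> np.ndarray:
    """Transverse-mean reporter intensity along the axon path, one sample per
    axon pixel (time-averaged if the movie has several frames)."""
    from .core import kymograph

    km = kymograph(movie, geometry, half_width_px=half_width_px)
    return km.mean(axis=1)


def segment_profile(red_intensity: np.ndarray, pixel_size: float,
                    config: ProfileConfig | None = None) -> MyelinProfile:
    """Threshold a 1D reporter-intensity profile into positive/gap segments.

    The threshold is ``gap_threshold_fraction`` times a robust estimate of the
    positive-region intensity, refined iteratively: the initial estimate is
    the median over all positions, then the median over currently-positive
    positions.
    """
    config = config or ProfileConfig()
    v = np.asarray(red_intensity, dtype=np.float64)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("red_intensity must be a 1D profile with >= 2 samples")

    ref = float(np.median(v))
    if ref <= 0:
        raise ValueError("no reporter-positive signal found along the axon")
    positive = v >= config.gap_threshold_fraction * ref
    for _ in range(config.threshold_iterations):
        if not positive.any():
            break
        ref = float(np.median(v[positive]))
        positive = v >= config.gap_threshold_fraction * ref
    if not positive.any():
        raise ValueError("no reporter-positive signal found along the axon")

    field_length = float(v.size * pixel_size)

    # runs of constant label, in pixels
    labels = positive.astype(np.int8)
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [v.size]])

    # gaps shorter than min_gap_length are relabelled positive
    runs = []
    for s, e in zip(starts, ends):
        label = "positive" if labels[s] else "gap"
        if label == "gap" and (e - s) * pixel_size < config.min_gap_length:
            label = "positive"
        runs.append([s, e, label])
    # merge adjacent runs with identical labels after relabelling
    merged = [runs[0]]
    for s, e, label in runs[1:]:
        if label == merged[-1][2]:
            merged[-1][1] = e
        else:
            merged.append([s, e, label])

    segments = [(s * pixel_size, e * pixel_size, label) for s, e, label in merged]
    # normalize last boundary to field_length exactly
    if segments:
        s, e, label = segments[-1]
        segments[-1] = (s, field_length, label)

    gap_complete = []
    for (s, e, label) in segments:
        if label == "gap":
            gap_complete.append(s > 0.0 and e < field_length)

    profile = MyelinProfile(segments=segments, field_length=field_length,
                            gap_complete_flags=gap_complete)
    return build_profile(profile, config)


def profile_from_segments(segments, field_length: float,
                          config: ProfileConfig | None = None) -> MyelinProfile:
    """Build a full profile (heminodes, nodes, class) from exact segments."""
    config = config or ProfileConfig()
    gap_complete = [s > 0.0 and e < field_length
                    for (s, e, label) in segments if label == "gap"]
    profile = MyelinProfile(segments=list(segments), field_length=field_length,
                            gap_complete_flags=gap_complete)
    return build_profile(profile, config)


def percent_myelination(profile: MyelinProfile) -> float:
    """Percent of the sampled field covered by gaps, incomplete included."""
    return 100.0 * profile.gap_length() / profile.field_length


def derive_heminodes_nodes(profile: MyelinProfile,
                           config: ProfileConfig | None = None) -> tuple:
    """Heminode and node intervals from the segmented profile.

    For each gap border, the adjacent positive interval up to
    ``heminode_window`` (3 um) is a heminode. A positive segment shorter than
    ``node_max_length`` (1 um) flanked by gaps on both sides is a node and
    yields no heminodes. A positive segment of length ``L`` shared between two
    gaps with ``node_max_length <= L < 2 * heminode_window`` is split into two
    heminodes of ``L / 2`` each.
    """
    config = config or ProfileConfig()
    w = config.heminode_window
    heminodes: list = []
    nodes: list = []
    segs = profile.segments
    for i, (s, e, label) in enumerate(segs):
        if label != "positive":
            continue
        gap_left = i > 0 and segs[i - 1][2] == "gap"
        gap_right = i < len(segs) - 1 and segs[i + 1][2] == "gap"
        L = e - s
        if not (gap_left or gap_right):
            continue
        if gap_left and gap_right:
            if L < config.node_max_length:
                nodes.append((s, e))
            elif L < 2 * w:
                heminodes.append((s, s + L / 2))
                heminodes.append((s + L / 2, e))
            else:
                heminodes.append((s, s + w))
                heminodes.append((e - w, e))
        elif gap_left:
            heminodes.append((s, min(s + w, e)))
        else:  # gap_right
            heminodes.append((max(e - w, s), e))
    return heminodes, nodes


def classify_axon(profile: MyelinProfile, config: ProfileConfig | None = None) -> tuple:
    """Return ``(axon_class, boundary_flag)``.

    Myelinating iff percent myelination exceeds the threshold or there are
    more than ``min_heminodes_for_myelinating - 1`` heminodes. A coverage of
    exactly the threshold with few heminodes is assigned to
    ``not_yet_myelinated`` and flagged as a boundary case.
    """
    config = config or ProfileConfig()
    pct = profile.percent_myelination
    n_hemi = len(profile.heminodes)
    if pct > config.not_yet_myelinated_max or n_hemi >= config.min_heminodes_for_myelinating:
        return "myelinating", False
    boundary = pct == config.not_yet_myelinated_max
    return "not_yet_myelinated", boundary


def build_profile(profile: MyelinProfile, config: ProfileConfig | None = None) -> MyelinProfile:
    """Fill in heminodes, nodes, percent myelination and axon class."""
    config = config or ProfileConfig()
    profile.percent_myelination = percent_myelination(profile)
    profile.heminodes, profile.nodes = derive_heminodes_nodes(profile, config)
    profile.axon_class, profile.boundary_flag = classify_axon(profile, config)
    return profile
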