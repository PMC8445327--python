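"""Sheath matching across sessions, growth rates, the nascent-length fate
analysis and growth-vs-activity correlations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import AxonGeometry, MyelinProfile, SheathTimecourse

__all__ = [
    "GrowthAnalysisConfig",
    "match_sheaths",
    "growth_rate",
    "nascent_fate_table",
    "growth_vs_heminodal_activity",
    "fully_grown_classification",
    "frequency_fold_change",
]


@dataclass
class GrowthAnalysisConfig:
    nascent_threshold: float = 6.0  # um; boundary sheaths go to the >= class
    heminode_window: float = 3.0  # um
    matching_tolerance: float = 3.0  # um midpoint agreement after alignment
    flank_tolerance: float = 0.5  # um for node/collateral flanking

    def __post_init__(self) -> None:
        if self.nascent_threshold <= 0 or self.matching_tolerance <= 0:
            raise ValueError("thresholds must be positive")


def _landmark_interval(mid: float, landmarks: list) -> tuple:
    """Ordered pair of flanking landmark indices (None at open ends)."""
    lo = None
    hi = None
    for i, a in enumerate(landmarks):
        if a <= mid:
            lo = i
        elif hi is None:
            hi = i
    return (lo, hi)


def match_sheaths(profile_t1: MyelinProfile, profile_t2: MyelinProfile,
                  geometry: AxonGeometry,
                  config: GrowthAnalysisConfig | None = None) -> dict:
    """Match complete gaps between two sessions of the same axon.

    Sheaths match when they lie between the same ordered pair of collateral
    landmarks and their midpoints agree within the tolerance. Unmatched
    first-session sheaths are retractions; unmatched second-session sheaths
    are new.
    """
    config = config or GrowthAnalysisConfig()
    landmarks = sorted(a for a, _ in geometry.collaterals)
    g1 = profile_t1.gaps(complete_only=True)
    g2 = profile_t2.gaps(complete_only=True)
    used = set()
    pairs = []
    for i, (s1, e1) in enumerate(g1):
        m1 = 0.5 * (s1 + e1)
        k1 = _landmark_interval(m1, landmarks)
        best = None
        for j, (s2, e2) in enumerate(g2):
            if j in used:
                continue
            m2 = 0.5 * (s2 + e2)
            if _landmark_interval(m2, landmarks) != k1:
                continue
            d = abs(m2 - m1)
            if d <= config.matching_tolerance and (best is None or d < best[0]):
                best = (d, j)
        if best is not None:
            used.add(best[1])
            pairs.append((i, best[1]))
    retractions = [i for i in range(len(g1)) if i not in {p[0] for p in pairs}]
    new = [j for j in range(len(g2)) if j not in used]
    return {"pairs": pairs, "retractions": retractions, "new": new,
            "gaps_t1": g1, "gaps_t2": g2}


def growth_rate(length_t1: float, length_t2: float, time_t1: float,
                time_t2: float) -> tuple:
    """Rate in um/h between two sessions, with fate grow/shrink/stable."""
    dt = time_t2 - time_t1
    if dt <= 0:
        raise ValueError("session interval must be positive")
    rate = (length_t2 - length_t1) / dt
    fate = "grow" if rate > 0 else ("shrink" if rate < 0 else "stable")
    return rate, fate


def nascent_fate_table(timecourses, config: GrowthAnalysisConfig | None = None) -> dict:
    """Cross-tabulate initial length class x fate at the nascent threshold.

    Full retractions count as shrink (and are reported separately); sheaths at
    exactly the threshold length join the >= class. Fisher's exact test on the
    2x2 table is included.
    """
    config = config or GrowthAnalysisConfig()
    table = {"nascent": {"grow": 0, "shrink": 0, "stable": 0},
             "mature": {"grow": 0, "shrink": 0, "stable": 0}}
    full_retractions = 0
    for tc in timecourses:
        cls = "nascent" if tc.initial_length < config.nascent_threshold else "mature"
        fate = tc.fate
        if fate == "full_retraction":
            full_retractions += 1
            fate = "shrink"
        table[cls][fate] += 1
    contingency = np.array([
        [table["nascent"]["grow"], table["nascent"]["shrink"]],
        [table["mature"]["grow"], table["mature"]["shrink"]],
    ])
    if contingency.sum() > 0:
        _odds, p = stats.fisher_exact(contingency)
    else:
        p = float("nan")
    return {"table": table, "full_retractions": full_retractions,
            "fisher_p": float(p), "contingency": contingency.tolist()}


def growth_vs_heminodal_activity(timecourses,
                                 config: GrowthAnalysisConfig | None = None) -> dict:
    """Pearson correlations of growth rate with heminodal and under-sheath
    event frequency, for the nascent and mature subsets, plus the
    with/without-heminodal-activity group comparison.

    Time-courses must carry ``heminodal_frequency`` and
    ``under_sheath_frequency`` annotations. Only sheaths free to grow enter.
    """
    config = config or GrowthAnalysisConfig()
    free = [tc for tc in timecourses if tc.free_to_grow]
    out = {}
    for name, subset in (
        ("nascent", [tc for tc in free if tc.initial_length < config.nascent_threshold]),
        ("mature", [tc for tc in free if tc.initial_length >= config.nascent_threshold]),
    ):
        rates = np.array([tc.growth_rate for tc in subset])
        hemi = np.array([tc.heminodal_frequency for tc in subset])
        under = np.array([tc.under_sheath_frequency for tc in subset])
        entry = {"n": len(subset)}
        for key, x in (("heminodal", hemi), ("under_sheath", under)):
            if len(subset) < 3 or np.std(x) == 0 or np.std(rates) == 0:
                entry[f"r_{key}"] = float("nan")
                entry[f"p_{key}"] = float("nan")
            else:
                r, p = stats.pearsonr(x, rates)
                entry[f"r_{key}"] = float(r)
                entry[f"p_{key}"] = float(p)
        out[name] = entry

    nascent = [tc for tc in free if tc.initial_length < config.nascent_threshold]
    with_act = np.array([tc.growth_rate for tc in nascent if tc.heminodal_frequency > 0])
    without = np.array([tc.growth_rate for tc in nascent if tc.heminodal_frequency == 0])
    groups = {"n_with": int(with_act.size), "n_without": int(without.size)}
    if with_act.size >= 1 and without.size >= 1 and (with_act.size + without.size) >= 4:
        try:
            _u, p = stats.mannwhitneyu(with_act, without, alternative="two-sided")
            groups["mannwhitney_p"] = float(p)
        except ValueError:
            groups["mannwhitney_p"] = float("nan")
    else:
        groups["mannwhitney_p"] = float("nan")
    for key, sample in (("with", with_act), ("without", without)):
        if sample.size >= 5 and not np.allclose(sample, 0):
            _s, p = stats.wilcoxon(sample)
            groups[f"wilcoxon_vs_zero_{key}"] = float(p)
        else:
            groups[f"wilcoxon_vs_zero_{key}"] = float("nan")
        groups[f"median_rate_{key}"] = float(np.median(sample)) if sample.size else float("nan")
    out["activity_groups"] = groups
    return out


def fully_grown_classification(profile: MyelinProfile, geometry: AxonGeometry,
                               config: GrowthAnalysisConfig | None = None) -> list:
    """Per complete sheath: ``fully_grown`` iff both flanks are a node or a
    collateral branch point (within tolerance); else ``free``. Edge-incomplete
    sheaths are excluded."""
    config = config or GrowthAnalysisConfig()
    collat = [a for a, _ in geometry.collaterals]
    node_edges = [x for n0, n1 in profile.nodes for x in (n0, n1)]
    out = []
    for (s, e) in profile.gaps(complete_only=True):
        flanks = []
        for edge in (s, e):
            if any(abs(edge - x) <= config.flank_tolerance for x in node_edges):
                flanks.append("node")
            elif any(abs(edge - a) <= config.flank_tolerance for a in collat):
                flanks.append("collateral")
            else:
                flanks.append("open")
        label = "fully_grown" if all(f != "open" for f in flanks) else "free"
        out.append({"interval": (s, e), "flanking": tuple(flanks), "label": label})
    return out


def frequency_fold_change(count_pre: int, count_post: int, length: float,
                          duration_pre_h: float, duration_post_h: float,
                          pseudocount: float = 0.5) -> dict:
    """Post/pre frequency fold change for one compartment of one axon.

    A zero pre-count makes the plain ratio undefined; an additive-pseudocount
    alternative is always reported alongside.
    """
    if length <= 0:
        raise ValueError("compartment length must be positive")
    if duration_pre_h <= 0 or duration_post_h <= 0:
        raise ValueError("durations must be positive")
    pre = count_pre / length / duration_pre_h
    post = count_post / length / duration_post_h
    fold = post / pre if pre > 0 else float("nan")
    pre_ps = (count_pre + pseudocount) / length / duration_pre_h
    post_ps = (count_post + pseudocount) / length / duration_post_h
    return {"pre_freq": pre, "post_freq": post, "fold_change": fold,
            "fold_change_pseudocount": post_ps / pre_ps}
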