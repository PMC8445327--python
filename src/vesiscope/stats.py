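"""Cohort statistics: normality-based test selection and execution.

Routing: every group is checked with two normality tests (D'Agostino-Pearson
omnibus and Shapiro-Wilk); the parametric route is taken only when all groups
pass both at alpha = 0.05. Paired data never route to unpaired tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["StatPlanEntry", "select_test", "run_comparison"]

ALPHA = 0.05


@dataclass
class StatPlanEntry:
    chosen_test: str
    paired: bool
    k_groups: int
    normality: list = field(default_factory=list)  # per group dicts
    all_normal: bool = False
    flagged_small_n: bool = False
    alpha: float = ALPHA


def _normality_verdict(sample: np.ndarray) -> dict:
    """Both normality tests for one group; groups too small for the omnibus
    test are treated as failing (conservative, flagged by the caller)."""
    sample = np.asarray(sample, dtype=float)
    out = {"n": int(sample.size)}
    if sample.size < 8 or np.std(sample) == 0:
        out.update({"dagostino_p": float("nan"), "shapiro_p": float("nan"),
                    "normal": False})
        return out
    _k, p_dag = stats.normaltest(sample)
    _w, p_sh = stats.shapiro(sample)
    out.update({"dagostino_p": float(p_dag), "shapiro_p": float(p_sh),
                "normal": bool(p_dag > ALPHA and p_sh > ALPHA)})
    return out


def select_test(groups, paired: bool = False) -> StatPlanEntry:
    """Choose the comparison test for the given groups.

    Two normal groups route to the t test (paired or unpaired); more than two
    to one-way ANOVA with Bonferroni-corrected follow-ups. Non-normal data
    route to Mann-Whitney, Wilcoxon signed-rank (paired) or Kruskal-Wallis
    with Dunn's correction.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 1 or any(g.size == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    k = len(groups)
    small = any(g.size < 3 for g in groups)
    verdicts = [_normality_verdict(g) for g in groups]
    all_normal = (not small) and all(v["normal"] for v in verdicts)
    if k == 1:
        chosen = "one-sample t-test" if all_normal else "wilcoxon-signed-rank"
    elif k == 2:
        if paired:
            chosen = "paired t-test" if all_normal else "wilcoxon-signed-rank"
        else:
            chosen = "t-test" if all_normal else "mann-whitney"
    else:
        chosen = "anova+bonferroni" if all_normal else "kruskal-wallis+dunn"
    return StatPlanEntry(chosen_test=chosen, paired=paired, k_groups=k,
                         normality=verdicts, all_normal=all_normal,
                         flagged_small_n=small)


def run_comparison(groups, paired: bool = False) -> dict:
    """Select and execute the test; returns the plan plus a p-value."""
    plan = select_test(groups, paired=paired)
    gs = [np.asarray(g, dtype=float) for g in groups]
    name = plan.chosen_test
    if name == "one-sample t-test":
        p = float(stats.ttest_1samp(gs[0], 0.0).pvalue)
    elif name == "wilcoxon-signed-rank":
        if plan.k_groups == 2:
            p = float(stats.wilcoxon(gs[0], gs[1]).pvalue)
        else:
            p = float(stats.wilcoxon(gs[0]).pvalue)
    elif name == "paired t-test":
        p = float(stats.ttest_rel(gs[0], gs[1]).pvalue)
    elif name == "t-test":
        p = float(stats.ttest_ind(gs[0], gs[1]).pvalue)
    elif name == "mann-whitney":
        p = float(stats.mannwhitneyu(gs[0], gs[1], alternative="two-sided").pvalue)
    elif name == "anova+bonferroni":
        p = float(stats.f_oneway(*gs).pvalue)
    else:  # kruskal-wallis+dunn
        p = float(stats.kruskal(*gs).pvalue)
    return {"plan": plan, "p_value": p, "significant": p < plan.alpha}
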