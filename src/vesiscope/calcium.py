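"""Pre/post-treatment dF/F analysis of axonal calcium traces."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TreatmentTracePair", "baseline_activity", "treatment_response"]


@dataclass
class TreatmentTracePair:
    """Background-subtracted ROI traces bracketing a treatment."""

    pre_trace: np.ndarray
    post_trace: np.ndarray
    background_pre: float = 0.0
    background_post: float = 0.0

    def __post_init__(self) -> None:
        self.pre_trace = np.asarray(self.pre_trace, dtype=float) - self.background_pre
        self.post_trace = np.asarray(self.post_trace, dtype=float) - self.background_post

    @property
    def f0_pre(self) -> float:
        return float(self.pre_trace.mean())


def baseline_activity(pre_trace, background: float = 0.0) -> np.ndarray:
    """dF/F_avg of a background-subtracted trace: (F - mean) / mean."""
    trace = np.asarray(pre_trace, dtype=float) - background
    mean = trace.mean()
    if mean <= 0:
        raise ValueError("trace mean must be positive after background subtraction")
    return (trace - mean) / mean


def treatment_response(pair: TreatmentTracePair) -> dict:
    """Post-treatment dF/F0 using the pre-treatment average as F0."""
    f0 = pair.f0_pre
    if f0 <= 0:
        raise ValueError("pre-treatment mean must be positive")
    response = (pair.post_trace - f0) / f0
    return {"response": response,
            "mean_response": float(response.mean()),
            "peak_response": float(response.max())}
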