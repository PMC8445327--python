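"""Bleach correction, rigid registration and dF/F_avg computation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .core import TimelapseMovie

__all__ = [
    "PreprocessModel",
    "fit_bleach",
    "correct_bleach",
    "register_rigid",
    "compute_dff_avg",
    "preprocess_movie",
]


@dataclass
class PreprocessModel:
    """Fitted bleach model and per-frame rigid shifts.

    The bleach model is ``F_mean(t) = A * exp(-t / tau) + C`` fitted to the
    whole-field mean trace; the correction factor at t=0 is 1 by construction.
    """

    bleach_A: float = 0.0
    bleach_tau: float = float("inf")
    bleach_C: float = 0.0
    bleach_rms: float = 0.0
    bleach_fallback: bool = False
    shifts: list = field(default_factory=list)  # (drow, dcol) int px per frame
    reference_frame: int = -1
    registration_failed: bool = False
    registration_unreliable: bool = False

    def bleach_factor(self, t: np.ndarray) -> np.ndarray:
        """fit(t) / fit(0) — the multiplicative signal remaining at time t."""
        t = np.asarray(t, dtype=np.float64)
        if not np.isfinite(self.bleach_tau):
            return np.ones_like(t)
        f0 = self.bleach_A + self.bleach_C
        ft = self.bleach_A * np.exp(-t / self.bleach_tau) + self.bleach_C
        return ft / f0

    def to_json_dict(self) -> dict:
        return {
            "bleach_A": self.bleach_A,
            "bleach_tau": self.bleach_tau if np.isfinite(self.bleach_tau) else None,
            "bleach_C": self.bleach_C,
            "bleach_rms": self.bleach_rms,
            "bleach_fallback": self.bleach_fallback,
            "shifts": [list(map(int, s)) for s in self.shifts],
            "reference_frame": self.reference_frame,
            "registration_failed": self.registration_failed,
            "registration_unreliable": self.registration_unreliable,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))


def fit_bleach(movie: TimelapseMovie, model: PreprocessModel | None = None) -> PreprocessModel:
    """Least-squares fit of ``A*exp(-t/tau) + C`` to the whole-field mean."""
    if movie.n_frames < 10:
        raise ValueError("bleach fitting needs at least 10 frames")
    model = model or PreprocessModel()
    t = movie.times()
    y = movie.frames.mean(axis=(1, 2))

    span = float(y.max() - y.min())
    if span < 1e-9 * max(float(y.mean()), 1e-12):
        # constant movie: no bleaching, correction factors are all 1
        model.bleach_A, model.bleach_tau, model.bleach_C = 0.0, float("inf"), float(y.mean())
        model.bleach_rms = 0.0
        return model

    A0 = span
    C0 = float(y.min())
    tau0 = max(t[-1] / 2.0, movie.frame_interval)
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, A, tau, C: A * np.exp(-tt / tau) + C,
            t, y, p0=(A0, tau0, C0),
            bounds=([0.0, movie.frame_interval * 1e-3, 0.0],
                    [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        A, tau, C = map(float, popt)
        fitted = A * np.exp(-t / tau) + C
    except Exception:
        # fall back to a linear fit in log space with C = 0
        mask = y > 0
        slope, intercept = np.polyfit(t[mask], np.log(y[mask]), 1)
        tau = float("inf") if slope >= 0 else -1.0 / slope
        A, C = float(np.exp(intercept)), 0.0
        fitted = A * (np.exp(-t / tau) if np.isfinite(tau) else np.ones_like(t))
        model.bleach_fallback = True
    model.bleach_A, model.bleach_tau, model.bleach_C = A, tau, C
    model.bleach_rms = float(np.sqrt(np.mean((y - fitted) ** 2)))
    return model


def correct_bleach(movie: TimelapseMovie, model: PreprocessModel) -> TimelapseMovie:
    """Divide each frame by the fitted bleach factor (1 at t=0)."""
    factor = model.bleach_factor(movie.times())
    if np.any(factor <= 0):
        raise ValueError("bleach fit is non-positive within the movie's time range")
    return movie.with_frames(movie.frames / factor[:, None, None])


def register_rigid(movie: TimelapseMovie, reference: str = "median",
                   model: PreprocessModel | None = None) -> tuple:
    """Integer-pixel rigid registration against a reference image.

    Reference is the temporal median image (default) or the first frame.
    Returns ``(registered_movie, model)``; shifts exceeding 20% of the frame
    size flag the registration as failed, and a low correlation with the
    reference flags it as unreliable (e.g., pure-noise input).
    """
    model = model or PreprocessModel()
    frames = movie.frames
    T, H, W = frames.shape
    if reference == "median":
        ref = np.median(frames, axis=0)
        model.reference_frame = -1
    elif reference == "first":
        ref = frames[0]
        model.reference_frame = 0
    else:
        raise ValueError(f"unknown reference {reference!r}")
    if float(ref.std()) == 0.0:
        raise ValueError("reference image is constant; no features to register")

    out = np.empty_like(frames)
    shifts = []
    corrs = []
    max_shift = 0.2 * min(H, W)
    for t in range(T):
        shift, _err, _ph = phase_cross_correlation(ref, frames[t], upsample_factor=1)
        sr, sc = int(round(shift[0])), int(round(shift[1]))
        if max(abs(sr), abs(sc)) > max_shift:
            model.registration_failed = True
        shifts.append((sr, sc))
        out[t] = ndimage.shift(frames[t], (sr, sc), order=0, mode="nearest") \
            if (sr or sc) else frames[t]
        a, b = out[t].ravel(), ref.ravel()
        sa, sb = a.std(), b.std()
        corrs.append(0.0 if sa == 0 or sb == 0
                     else float(np.corrcoef(a, b)[0, 1]))
    model.shifts = shifts
    if float(np.median(corrs)) < 0.2:
        model.registration_unreliable = True
    return movie.with_frames(out), model


def compute_dff_avg(movie: TimelapseMovie, floor_percentile: float = 5.0,
                    relative_floor: float = 0.25) -> np.ndarray:
    """Per-pixel proportional change over the all-time average.

    Background pixels — time-average below the ``floor_percentile`` of the
    time-averaged image, or below ``relative_floor`` times its 99th
    percentile — are set to 0 to avoid divide-by-near-zero outside structures.
    """
    avg = movie.frames.mean(axis=0)
    floor = float(np.percentile(avg, floor_percentile))
    floor = max(floor, relative_floor * float(np.percentile(avg, 99.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (movie.frames - avg) / avg
    dff[:, avg <= floor] = 0.0
    return dff


def preprocess_movie(movie: TimelapseMovie, register: bool = True,
                     reference: str = "median") -> tuple:
    """Register (optional) then bleach-correct. Returns (movie, model)."""
    model = PreprocessModel()
    if register:
        movie, model = register_rigid(movie, reference=reference, model=model)
    model = fit_bleach(movie, model)
    movie = correct_bleach(movie, model)
    return movie, model
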