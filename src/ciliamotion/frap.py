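"""FRAP trace normalization and mobile-fraction estimation.

A fluorescence-recovery trace consists of an ROI intensity and a matching
background ROI measured next to the structure. The background-subtracted
signal is normalized by its pre-bleach mean, so the pre-bleach level is 1
by construction. The mobile fraction is read out as the recovered share of
the bleached signal at an evaluation time (default 120 s after bleach),
measured relative to the post-bleach floor. The raw normalized intensity
at the evaluation time is exported alongside, since the floor-relative
and raw readouts differ when the bleach is incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FrapTrace:
    """ROI and background intensities versus time, with the bleach time."""

    times: np.ndarray
    roi_intensity: np.ndarray
    background_intensity: np.ndarray
    bleach_time: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.roi_intensity = np.asarray(self.roi_intensity, dtype=float)
        self.background_intensity = np.asarray(
            self.background_intensity, dtype=float
        )
        if not (self.times.size == self.roi_intensity.size
                == self.background_intensity.size):
            raise ValueError("times, roi and background must share one length")
        if not self.times[0] < self.bleach_time <= self.times[-1]:
            raise ValueError("bleach_time must lie inside the time range")
        if not np.any(self.times < self.bleach_time):
            raise ValueError("pre-bleach interval is empty")


def normalize_frap(trace: FrapTrace) -> pd.DataFrame:
    """Background-subtract and normalize a FRAP trace.

    I_norm(t) = (roi(t) − bg(t)) / mean_prebleach(roi − bg). Raises if the
    pre-bleach background-subtracted mean is not positive.
    """
    signal = trace.roi_intensity - trace.background_intensity
    pre = signal[trace.times < trace.bleach_time]
    pre_mean = float(pre.mean())
    if pre_mean <= 0:
        raise ValueError("non-positive pre-bleach signal; cannot normalize")
    return pd.DataFrame({"t_s": trace.times, "i_norm": signal / pre_mean})


def recovery_fraction(
    curve: pd.DataFrame,
    bleach_time: float,
    t_eval: float = 120.0,
    eval_halfwidth: int = 2,
    floor_method: str = "early",
    floor_frames: int = 3,
) -> dict:
    """Mobile fraction from a normalized recovery curve.

    fraction = (I(t_eval) − I_floor) / (1 − I_floor), with I(t_eval)
    averaged over ``eval_halfwidth`` frames either side of the frame
    nearest ``t_eval`` (time measured from the bleach). The post-bleach
    floor I_floor is the mean of the first ``floor_frames`` post-bleach
    frames (``floor_method="early"``, default — unbiased under noise) or
    the post-bleach minimum (``floor_method="min"``); the two coincide for
    noiseless monotone recoveries. Returns the floor-relative fraction
    (default readout), the raw normalized intensity at t_eval, and the
    floor.
    """
    t = curve["t_s"].to_numpy()
    i = curve["i_norm"].to_numpy()
    t_abs = bleach_time + t_eval
    if not t[0] <= t_abs <= t[-1]:
        raise ValueError(f"t_eval={t_eval} s falls outside the trace")
    post = t >= bleach_time
    if floor_method == "min":
        floor = float(i[post].min())
    elif floor_method == "early":
        floor = float(i[post][:floor_frames].mean())
    else:
        raise ValueError("floor_method must be 'early' or 'min'")
    k = int(np.argmin(np.abs(t - t_abs)))
    lo, hi = max(k - eval_halfwidth, 0), min(k + eval_halfwidth + 1, t.size)
    i_eval = float(i[lo:hi].mean())
    denom = 1.0 - floor
    frac = (i_eval - floor) / denom if denom > 0 else 0.0
    return {
        "mobile_fraction": frac,
        "i_norm_at_eval": i_eval,
        "post_bleach_floor": floor,
        "t_eval_s": t_eval,
    }


def read_frap_csv(path, bleach_time: float) -> FrapTrace:
    """Load a trace from CSV with columns t_s, roi, background."""
    df = pd.read_csv(path)
    return FrapTrace(
        times=df["t_s"].to_numpy(),
        roi_intensity=df["roi"].to_numpy(),
        background_intensity=df["background"].to_numpy(),
        bleach_time=bleach_time,
    )


def linear_decay_correction(curve: pd.DataFrame,
                            bleach_time: float) -> pd.DataFrame:
    """Optional acquisition-photobleaching correction.

    Divides the post-bleach curve by a linear trend fit to the pre-bleach
    frames (slope per second, intercept 1). With a flat pre-bleach trace
    this is the identity; interpret corrected curves qualitatively.
    """
    t = curve["t_s"].to_numpy()
    i = curve["i_norm"].to_numpy().copy()
    pre = t < bleach_time
    if pre.sum() >= 2:
        slope, intercept = np.polyfit(t[pre], i[pre], 1)
        trend = slope * t + intercept
        i = i / np.clip(trend, 1e-12, None)
    return pd.DataFrame({"t_s": t, "i_norm": i})
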