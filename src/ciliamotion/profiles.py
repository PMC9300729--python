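"""Location-resolved apparent velocities and diffusion coefficients.

For window estimates classified as directed (α_// ≥ 1.4) the apparent
velocity is the per-frame parallel displacement over the frame time,
v_app = (x(t+dt) − x(t)) / dt, locally averaged over 10 displacements; a
positive sign is anterograde (base → tip). For windows classified as
diffusive (α ≤ 1.1 on the relevant axis) the apparent diffusion
coefficient is the squared per-frame displacement over the frame time,
D = (r(t+dt) − r(t))² / dt, locally averaged over 60 displacements.

The single-displacement D estimator as written has expectation 2·D for
Brownian motion in one dimension (the MSD convention MSD = 2·Γ·τ carries
the factor 2 explicitly). It is implemented as printed under the
"as-printed" convention; "msd-consistent" divides by 2 so that the
estimator's expectation equals the generator D. The discrepancy is kept
explicit rather than silently corrected.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .geometry import CiliaryTrack, SegmentTable

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 0.25
AS_PRINTED = "as-printed"
MSD_CONSISTENT = "msd-consistent"


def _center_frame_lookup(estimates: pd.DataFrame, track_id) -> pd.DataFrame:
    est = estimates[estimates["track_id"] == track_id]
    return est.set_index("center_frame")


def _rolling_mean(values: np.ndarray, n: int) -> np.ndarray:
    if values.size == 0:
        return values
    return (
        pd.Series(values)
        .rolling(window=n, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def apparent_velocities(
    track: CiliaryTrack,
    estimates: pd.DataFrame,
    threshold: float = 1.4,
    smooth_n: int = 10,
) -> pd.DataFrame:
    """Signed apparent velocities for directed stretches of one track.

    A displacement t → t+1 qualifies when the sliding-window estimate
    centred on frame t is valid and has α_// ≥ threshold. Qualifying
    displacements are split into runs of constant direction and locally
    averaged with a centred running mean over ``smooth_n`` displacements.
    Returns columns s_par, v_app, direction, segment.
    """
    est = _center_frame_lookup(estimates, track.track_id)
    dt = track.dt
    v = np.diff(track.s_par) / dt
    s_mid = 0.5 * (track.s_par[:-1] + track.s_par[1:])
    frames = np.arange(v.size)
    valid_col = "valid_par" if "valid_par" in est else "valid"
    ok = np.array(
        [
            f in est.index
            and bool(est.loc[f, valid_col])
            and est.loc[f, "alpha_par"] >= threshold
            for f in frames
        ]
    )
    if not ok.any():
        logger.info("track %s: no directed windows above alpha >= %.2f",
                    track.track_id, threshold)
        return pd.DataFrame(columns=["s_par", "v_app", "direction", "segment"])

    rows = []
    # runs of consecutive qualifying displacements with a constant sign
    idx = np.flatnonzero(ok)
    splits = np.flatnonzero(
        (np.diff(idx) != 1) | (np.sign(v[idx[1:]]) != np.sign(v[idx[:-1]]))
    )
    for run in np.split(idx, splits + 1):
        smoothed = _rolling_mean(v[run], smooth_n)
        direction = "anterograde" if v[run[0]] > 0 else "retrograde"
        for f, val in zip(run, smoothed):
            rows.append(
                {
                    "s_par": s_mid[f],
                    "v_app": val,
                    "direction": direction,
                    "segment": track.segment[f],
                }
            )
    return pd.DataFrame(rows)


def apparent_diffusion(
    track: CiliaryTrack,
    estimates: pd.DataFrame,
    alpha_max: float = 1.1,
    smooth_n: int = 60,
    perp_guard: float = 1.4,
    convention: str = AS_PRINTED,
) -> pd.DataFrame:
    """Apparent diffusion coefficients for diffusive stretches of one track.

    Parallel samples require α_// ≤ alpha_max in the window centred on the
    displacement; perpendicular samples require α_⊥ ≤ alpha_max and
    additionally α_// < perp_guard, so that the perpendicular estimate is
    never taken while the molecule is actively transported. Estimates are
    (Δr)²/dt per displacement ("as-printed"; divide by 2 for
    "msd-consistent"), locally averaged over ``smooth_n`` displacements.
    Returns columns s_par, d_est, axis, segment, convention.
    """
    if convention not in (AS_PRINTED, MSD_CONSISTENT):
        raise ValueError(f"unknown convention {convention!r}")
    est = _center_frame_lookup(estimates, track.track_id)
    dt = track.dt
    factor = 1.0 if convention == AS_PRINTED else 0.5
    out = []
    for axis, coord in (("par", track.s_par), ("perp", track.d_perp)):
        d2 = factor * np.diff(coord) ** 2 / dt
        s_mid = 0.5 * (track.s_par[:-1] + track.s_par[1:])
        frames = np.arange(d2.size)

        valid_col = f"valid_{axis}" if f"valid_{axis}" in est else "valid"

        def qualifies(f):
            if f not in est.index or not bool(est.loc[f, valid_col]):
                return False
            alpha = est.loc[f, "alpha_par" if axis == "par" else "alpha_perp"]
            if not alpha <= alpha_max:
                return False
            if axis == "perp" and not est.loc[f, "alpha_par"] < perp_guard:
                return False
            return True

        ok = np.array([qualifies(f) for f in frames])
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            continue
        smoothed = _rolling_mean(d2[idx], smooth_n)
        for f, val in zip(idx, smoothed):
            out.append(
                {
                    "s_par": s_mid[f],
                    "d_est": val,
                    "axis": axis,
                    "segment": track.segment[f],
                    "convention": convention,
                }
            )
    return pd.DataFrame(
        out, columns=["s_par", "d_est", "axis", "segment", "convention"]
    )


def bin_profile(
    samples: pd.DataFrame,
    value_column: str | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
    table: SegmentTable | None = None,
) -> pd.DataFrame:
    """Bin samples along the parallel axis into mean ± s.e.m. profiles.

    Bins are half-open lower-inclusive intervals of width ``bin_width``
    aligned to multiples of the width (a sample at exactly a boundary
    lands in the upper bin). Returns columns s_center, segment, mean, sem,
    n; empty input yields an empty profile.
    """
    table = table or SegmentTable()
    if len(samples) == 0:
        return pd.DataFrame(columns=["s_center", "segment", "mean", "sem", "n"])
    if value_column is None:
        value_column = "v_app" if "v_app" in samples else "d_est"
    s = samples["s_par"].to_numpy(dtype=float)
    v = samples[value_column].to_numpy(dtype=float)
    bins = np.floor(s / bin_width).astype(int)
    rows = []
    for b in np.unique(bins):
        mask = bins == b
        vals = v[mask]
        center = (b + 0.5) * bin_width
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        rows.append(
            {
                "s_center": center,
                "segment": table.assign(center),
                "mean": float(vals.mean()),
                "sem": sem,
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows).sort_values("s_center", ignore_index=True)
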