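"""Time-averaged MSD curves and sliding-window power-law estimation.

The anomalous-diffusion model is MSD(τ) = 2·Γ·τ^α, with Γ the generalized
transport coefficient and α the exponent: α = 1 is normal diffusion
(Γ = D), α = 2 is ballistic motion (v = √(2Γ)), α < 1 subdiffusion.
Instantaneous estimates come from a sliding window of 15 consecutive
localizations: within each window the time-averaged MSD is fit by ordinary
least squares in log-log space over the first six lags, independently for
the coordinates parallel and perpendicular to the cilium.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CiliaryTrack

WINDOW = 15
N_LAGS = 6


@dataclass(frozen=True)
class MsdCurve:
    """Time-averaged MSD: lags in s, msd in μm², pair counts per lag."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray


def ta_msd(positions, dt: float, max_lag: int = N_LAGS) -> MsdCurve:
    """Time-averaged MSD over overlapping pairs.

    msd(k·dt) = mean over all start frames t of (x(t + k·dt) − x(t))² for
    k = 1..max_lag.
    """
    x = np.asarray(positions, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if x.size < max_lag + 1:
        raise ValueError(
            f"series of length {x.size} too short for max_lag={max_lag}"
        )
    lags = np.arange(1, max_lag + 1)
    msd = np.array([np.mean((x[k:] - x[:-k]) ** 2) for k in lags])
    n_pairs = x.size - lags
    return MsdCurve(lags=lags * dt, msd=msd, n_pairs=n_pairs)


def fit_powerlaw(curve: MsdCurve, n_lags: int = N_LAGS):
    """Fit MSD = 2·Γ·τ^α by OLS of log₁₀(msd) on log₁₀(τ).

    Returns (alpha, gamma, r2, valid). A window containing zero or negative
    MSD values among the fitted lags is rejected (valid = False) rather
    than raising.
    """
    n_lags = min(n_lags, curve.lags.size)
    tau = curve.lags[:n_lags]
    msd = curve.msd[:n_lags]
    if np.any(msd <= 0) or n_lags < 2:
        return np.nan, np.nan, np.nan, False
    lx = np.log10(tau)
    ly = np.log10(msd)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = np.sum((ly - pred) ** 2)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    gamma = 10.0**intercept / 2.0
    return float(slope), float(gamma), float(r2), True


def sliding_window_estimates(
    track: CiliaryTrack, window: int = WINDOW, n_lags: int = N_LAGS
) -> pd.DataFrame:
    """Instantaneous (α, Γ) for every run of ``window`` localizations.

    A track of length N yields N − window + 1 estimates (stride 1), each
    anchored to the window's mean parallel position and central frame.
    Parallel and perpendicular coordinates are fit independently. Tracks
    shorter than the window return an empty table.
    """
    n = len(track)
    cols = [
        "track_id", "center_frame", "s_par_um", "segment",
        "alpha_par", "gamma_par", "alpha_perp", "gamma_perp",
        "fit_r2", "valid", "valid_par", "valid_perp",
    ]
    if n < window:
        return pd.DataFrame(columns=cols)
    dt = track.dt
    rows = []
    for start in range(n - window + 1):
        sl = slice(start, start + window)
        a_par, g_par, r2_par, ok_par = fit_powerlaw(
            ta_msd(track.s_par[sl], dt, n_lags), n_lags
        )
        a_perp, g_perp, _, ok_perp = fit_powerlaw(
            ta_msd(track.d_perp[sl], dt, n_lags), n_lags
        )
        center = start + window // 2
        s_mean = float(np.mean(track.s_par[sl]))
        rows.append(
            {
                "track_id": track.track_id,
                "center_frame": center,
                "s_par_um": s_mean,
                "segment": track.segment[center],
                "alpha_par": a_par,
                "gamma_par": g_par,
                "alpha_perp": a_perp,
                "gamma_perp": g_perp,
                "fit_r2": r2_par,
                # per-axis validity: a degenerate perpendicular window (e.g.
                # zero motion) must not discard a good parallel estimate
                "valid": bool(ok_par and ok_perp),
                "valid_par": bool(ok_par),
                "valid_perp": bool(ok_perp),
            }
        )
    return pd.DataFrame(rows, columns=cols)


def estimates_for_tracks(tracks, window: int = WINDOW,
                         n_lags: int = N_LAGS) -> pd.DataFrame:
    """Concatenate sliding-window estimates over an iterable of tracks."""
    parts = [sliding_window_estimates(t, window, n_lags) for t in tracks]
    parts = [p for p in parts if len(p)]
    if not parts:
        return pd.DataFrame(
            columns=[
                "track_id", "center_frame", "s_par_um", "segment",
                "alpha_par", "gamma_par", "alpha_perp", "gamma_perp",
                "fit_r2", "valid", "valid_par", "valid_perp",
            ]
        )
    return pd.concat(parts, ignore_index=True)
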