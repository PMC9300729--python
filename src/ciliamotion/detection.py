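"""Single-molecule spot localization, trajectory linking and reconstruction.

Spots are candidate local maxima refined by least-squares 2D Gaussian
fitting in a small ROI; detections are linked frame-to-frame by greedy
mutual-nearest-neighbour assignment with a maximum link distance and an
optional gap memory; fitted centres can be rendered into a super-resolved
reconstruction image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter
from scipy.optimize import least_squares


@dataclass
class Detection:
    """One fitted spot. Coordinates in pixels unless converted by caller."""

    frame: int
    x: float
    y: float
    amplitude: float
    background: float
    sigma: float
    fit_ok: bool = True


def _gauss2d(params, xx, yy):
    a, x0, y0, s, b = params
    return a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s**2)) + b


def localize_spots(
    frame: np.ndarray,
    candidate_threshold: float,
    roi_halfwidth: int = 4,
    min_sigma: float = 1e-3,
) -> list[Detection]:
    """Detect and fit spots in one image frame.

    Local maxima above ``candidate_threshold`` seed a least-squares 2D
    Gaussian fit (amplitude, centre, isotropic sigma, constant background)
    within a square ROI of half-width ``roi_halfwidth`` pixels. Fits that
    do not converge, run out of the ROI, or collapse to non-positive width
    are flagged ``fit_ok=False``. An empty or flat frame yields an empty
    list.
    """
    img = np.asarray(frame, dtype=float)
    if img.size == 0:
        return []
    if not np.all(np.isfinite(img)):
        raise ValueError("frame contains non-finite values")
    footprint = maximum_filter(img, size=2 * roi_halfwidth + 1, mode="nearest")
    peaks = np.argwhere((img == footprint) & (img > candidate_threshold))
    detections: list[Detection] = []
    h, w = img.shape
    for py, px in peaks:
        y0, y1 = max(py - roi_halfwidth, 0), min(py + roi_halfwidth + 1, h)
        x0, x1 = max(px - roi_halfwidth, 0), min(px + roi_halfwidth + 1, w)
        roi = img[y0:y1, x0:x1]
        yy, xx = np.mgrid[y0:y1, x0:x1]
        bg0 = float(roi.min())
        p0 = [float(img[py, px] - bg0), float(px), float(py), 1.3, bg0]
        try:
            res = least_squares(
                lambda p: (_gauss2d(p, xx, yy) - roi).ravel(), p0,
                bounds=([0, x0 - 1, y0 - 1, min_sigma, -np.inf],
                        [np.inf, x1, y1, max(h, w), np.inf]),
                max_nfev=400,
            )
            a, cx, cy, s, b = res.x
            ok = bool(res.success and s > min_sigma and a > 0
                      and x0 - 1 <= cx <= x1 and y0 - 1 <= cy <= y1)
        except Exception:
            a, cx, cy, s, b = p0
            ok = False
        detections.append(
            Detection(frame=0, x=float(cx), y=float(cy), amplitude=float(a),
                      background=float(b), sigma=float(s), fit_ok=ok)
        )
    return detections


def localize_stack(stack: np.ndarray, candidate_threshold: float,
                   roi_halfwidth: int = 4) -> pd.DataFrame:
    """Localize every frame of a stack; returns a tidy detection table."""
    rows = []
    for f, frame in enumerate(stack):
        for d in localize_spots(frame, candidate_threshold, roi_halfwidth):
            rows.append(
                {"frame": f, "x": d.x, "y": d.y, "amplitude": d.amplitude,
                 "background": d.background, "sigma": d.sigma,
                 "fit_ok": d.fit_ok}
            )
    return pd.DataFrame(
        rows, columns=["frame", "x", "y", "amplitude", "background",
                       "sigma", "fit_ok"]
    )


def link_detections(
    detections: pd.DataFrame,
    r_max: float = 5.0,
    memory: int = 1,
) -> pd.DataFrame:
    """Link detections into trajectories by greedy mutual nearest neighbours.

    Within each consecutive frame pair, a link is made when two detections
    are mutual nearest neighbours and closer than ``r_max``; ties are
    broken by smallest distance, then lowest detection index. A track that
    misses up to ``memory`` frames may resume; otherwise a new track id is
    opened. Every detection belongs to exactly one track (singleton tracks
    are kept, so nothing is silently dropped).

    Returns the detection table with a ``track_id`` column added.
    """
    if r_max <= 0:
        raise ValueError("r_max must be > 0")
    if memory < 0:
        raise ValueError("memory must be >= 0")
    det = detections.reset_index(drop=True).copy()
    det["track_id"] = -1
    next_id = 0
    # open tracks: list of dicts with id, last position, last frame
    open_tracks: list[dict] = []
    for frame in sorted(det["frame"].unique()):
        # a link across a gap of g missed frames needs g <= memory
        open_tracks = [t for t in open_tracks
                       if frame - t["frame"] <= memory + 1]
        rows = det.index[det["frame"] == frame].to_numpy()
        pos = det.loc[rows, ["x", "y"]].to_numpy(dtype=float)
        # candidate pairs (track, detection) within r_max
        assigned_rows = set()
        assigned_tracks = set()
        if open_tracks and rows.size:
            tpos = np.array([t["pos"] for t in open_tracks])
            dmat = np.linalg.norm(tpos[:, None, :] - pos[None, :, :], axis=2)
            # mutual nearest neighbours under r_max, greedy by distance
            pairs = [
                (dmat[i, j], i, j)
                for i in range(len(open_tracks))
                for j in range(rows.size)
                if dmat[i, j] <= r_max
                and j == np.argmin(dmat[i])
                and i == np.argmin(dmat[:, j])
            ]
            for d, i, j in sorted(pairs):
                if i in assigned_tracks or j in assigned_rows:
                    continue
                t = open_tracks[i]
                det.loc[rows[j], "track_id"] = t["id"]
                t["pos"] = pos[j]
                t["frame"] = frame
                assigned_tracks.add(i)
                assigned_rows.add(j)
        for j in range(rows.size):
            if j not in assigned_rows:
                det.loc[rows[j], "track_id"] = next_id
                open_tracks.append(
                    {"id": next_id, "pos": pos[j], "frame": frame}
                )
                next_id += 1
    return det


def render_superres(
    detections: pd.DataFrame,
    pixel_size: float,
    extent: tuple[float, float, float, float] | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Histogram the fitted centres into a super-resolved image.

    ``pixel_size`` is the super-resolved pixel edge in the detections'
    coordinate unit. Total rendered mass equals the number of detections.
    Returns (image, (x_origin, y_origin)); rows map y, columns x.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if len(detections) == 0:
        raise ValueError("no detections to render")
    x = detections["x"].to_numpy(dtype=float)
    y = detections["y"].to_numpy(dtype=float)
    if extent is None:
        extent = (x.min(), x.max(), y.min(), y.max())
    x0, x1, y0, y1 = extent
    nx = max(int(np.ceil((x1 - x0) / pixel_size)), 1) + 1
    ny = max(int(np.ceil((y1 - y0) / pixel_size)), 1) + 1
    img, _, _ = np.histogram2d(
        y, x, bins=[ny, nx],
        range=[[y0, y0 + ny * pixel_size], [x0, x0 + nx * pixel_size]],
    )
    return img, (x0, y0)
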