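"""Ciliary coordinate geometry.

A cilium is represented by a smooth spline drawn along its long axis.
Trajectories recorded in image coordinates are transposed onto this spline,
yielding an arclength ("parallel") coordinate and a signed perpendicular
offset. The parallel axis is partitioned into the anatomical segments of a
chemosensory cilium: dendrite, periciliary membrane compartment (PCMC),
transition zone (TZ), proximal segment (PS), distal segment (DS) and Tip.

Units are micrometres for lengths and seconds for time throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline


class InvalidGeometryError(ValueError):
    """Raised for degenerate splines or malformed segment tables."""


# Segment boundaries on the parallel axis (μm), lower-inclusive half-open
# intervals. x < -0.8 is dendrite; x >= 6.5 is Tip.
DEFAULT_SEGMENT_BOUNDARIES = (-0.8, 0.0, 0.8, 3.5, 6.5)
DEFAULT_SEGMENT_LABELS = ("dendrite", "PCMC", "TZ", "PS", "DS", "Tip")


@dataclass(frozen=True)
class SegmentTable:
    """Partition of the parallel axis into named ciliary segments.

    ``boundaries`` are strictly increasing breakpoints; ``labels`` has one
    more entry than ``boundaries``. Interval ``i`` is
    ``[boundaries[i-1], boundaries[i])``; values below the first breakpoint
    map to ``labels[0]``, values at or above the last to ``labels[-1]``.
    """

    boundaries: tuple[float, ...] = DEFAULT_SEGMENT_BOUNDARIES
    labels: tuple[str, ...] = DEFAULT_SEGMENT_LABELS

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.size == 0 or len(self.labels) != b.size + 1:
            raise InvalidGeometryError(
                "need len(labels) == len(boundaries) + 1 with >= 1 boundary"
            )
        if not np.all(np.diff(b) > 0):
            raise InvalidGeometryError("boundaries must be strictly increasing")

    def assign(self, s_par):
        """Vectorised segment lookup; scalar in, scalar out."""
        idx = np.searchsorted(self.boundaries, np.asarray(s_par, dtype=float),
                              side="right")
        labels = np.asarray(self.labels, dtype=object)[idx]
        if np.isscalar(s_par) or np.ndim(s_par) == 0:
            return str(labels)
        return labels.astype(str)

    def span(self, label: str) -> tuple[float, float]:
        """(lower, upper) interval of a segment; outermost are infinite."""
        i = self.labels.index(label)
        lo = -np.inf if i == 0 else self.boundaries[i - 1]
        hi = np.inf if i == len(self.boundaries) else self.boundaries[i]
        return lo, hi


def assign_segment(s_par, table: SegmentTable | None = None):
    """Map parallel coordinate(s) to segment label(s) (total function)."""
    return (table or SegmentTable()).assign(s_par)


@dataclass
class Spline:
    """Smooth curve through hand-drawn control points.

    ``samples`` is a dense polyline approximation used for nearest-point
    projection; ``arclength`` holds the cumulative arclength at each sample.
    """

    control_points: np.ndarray
    samples: np.ndarray
    arclength: np.ndarray

    @property
    def total_arclength(self) -> float:
        return float(self.arclength[-1])

    def tangents(self) -> np.ndarray:
        """Unit tangent at each polyline sample (direction of increasing s)."""
        d = np.gradient(self.samples, axis=0)
        return d / np.linalg.norm(d, axis=1, keepdims=True)


def fit_spline(control_points, sampling_step: float = 0.01) -> Spline:
    """Interpolate ordered 2D control points with a cubic spline.

    The curve is parameterised by chordal arclength, interpolated with a
    natural cubic spline per coordinate, and resampled at approximately
    ``sampling_step`` (default 10 nm) spacing.
    """
    pts = np.atleast_2d(np.asarray(control_points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise InvalidGeometryError("need >= 2 two-dimensional control points")
    if sampling_step <= 0:
        raise InvalidGeometryError("sampling_step must be > 0")
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(chord == 0):
        raise InvalidGeometryError("duplicate consecutive control points")
    u = np.concatenate([[0.0], np.cumsum(chord)])
    if pts.shape[0] == 2:
        # two points define a straight segment; cubic needs >= 3 knots
        n = max(int(np.ceil(u[-1] / sampling_step)), 1) + 1
        t = np.linspace(0.0, 1.0, n)
        samples = pts[0] + t[:, None] * (pts[1] - pts[0])
    else:
        cs = CubicSpline(u, pts, axis=0, bc_type="natural")
        n = max(int(np.ceil(u[-1] / sampling_step)) * 2, 4) + 1
        samples = cs(np.linspace(0.0, u[-1], n))
    seg = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(seg)])
    if arclength[-1] <= 0 or np.any(seg <= 0):
        raise InvalidGeometryError("degenerate spline: arclength not increasing")
    return Spline(control_points=pts, samples=samples, arclength=arclength)


@dataclass
class CiliaryTrack:
    """A trajectory transposed to ciliary (parallel, perpendicular) coordinates.

    ``s_par`` is arclength along the spline with the origin at the
    dendrite/TZ boundary convention chosen by the caller; ``d_perp`` is the
    signed distance to the spline, positive to the left of the direction of
    increasing arclength.
    """

    track_id: int | str
    times: np.ndarray
    s_par: np.ndarray
    d_perp: np.ndarray
    segment: np.ndarray
    outlier: np.ndarray = field(default=None)  # type: ignore[assignment]
    perp_flag: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.s_par = np.asarray(self.s_par, dtype=float)
        self.d_perp = np.asarray(self.d_perp, dtype=float)
        if self.outlier is None:
            self.outlier = np.zeros(self.times.size, dtype=bool)
        if self.perp_flag is None:
            self.perp_flag = np.zeros(self.times.size, dtype=bool)
        n = self.times.size
        if not (self.s_par.size == self.d_perp.size == n):
            raise ValueError("coordinate arrays must share one length")
        if n >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times))) if len(self) > 1 else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "track_id": self.track_id,
                "frame": np.arange(len(self)),
                "t_s": self.times,
                "s_par_um": self.s_par,
                "d_perp_um": self.d_perp,
                "segment": self.segment,
            }
        )


def to_ciliary_coords(
    trajectory,
    spline: Spline,
    origin_offset: float = 0.0,
    table: SegmentTable | None = None,
    max_distance: float = 2.0,
    sanity_radius: float = 0.5,
    track_id=0,
    times=None,
) -> CiliaryTrack:
    """Project an image-coordinate trajectory onto the ciliary spline.

    ``trajectory`` is an (n, 2) array of x, y positions or a DataFrame with
    ``x_um``/``y_um`` (and optionally ``t_s``, ``track_id``) columns.
    Each point maps to its nearest dense spline sample; ``s_par`` is that
    sample's arclength minus ``origin_offset`` and ``d_perp`` the signed
    offset (positive left of the local tangent). Points farther than
    ``max_distance`` from the spline are flagged as outliers, and
    ``|d_perp| > sanity_radius`` sets ``perp_flag``; neither is dropped.
    """
    if isinstance(trajectory, pd.DataFrame):
        if times is None and "t_s" in trajectory:
            times = trajectory["t_s"].to_numpy()
        if "track_id" in trajectory:
            ids = trajectory["track_id"].unique()
            if ids.size == 1:
                track_id = ids[0]
        xy = trajectory[["x_um", "y_um"]].to_numpy(dtype=float)
    else:
        xy = np.atleast_2d(np.asarray(trajectory, dtype=float))
    if xy.size == 0:
        raise ValueError("empty trajectory")
    if times is None:
        times = np.arange(xy.shape[0], dtype=float)

    diffs = xy[:, None, :] - spline.samples[None, :, :]
    dist2 = np.einsum("ijk,ijk->ij", diffs, diffs)
    nearest = np.argmin(dist2, axis=1)
    s_par = spline.arclength[nearest] - origin_offset
    tangent = spline.tangents()[nearest]
    offset = xy - spline.samples[nearest]
    dist = np.sqrt(dist2[np.arange(xy.shape[0]), nearest])
    # sign by z-component of tangent x offset: positive = left of tangent
    side = np.sign(tangent[:, 0] * offset[:, 1] - tangent[:, 1] * offset[:, 0])
    side[side == 0] = 1.0
    d_perp = np.where(dist == 0, 0.0, side * dist)

    table = table or SegmentTable()
    return CiliaryTrack(
        track_id=track_id,
        times=np.asarray(times, dtype=float),
        s_par=s_par,
        d_perp=d_perp,
        segment=table.assign(s_par),
        outlier=dist > max_distance,
        perp_flag=np.abs(d_perp) > sanity_radius,
    )


def read_spline_csv(path, sampling_step: float = 0.01) -> Spline:
    """Load control points from a CSV with ``x_um``/``y_um`` columns."""
    df = pd.read_csv(path)
    return fit_spline(df[["x_um", "y_um"]].to_numpy(), sampling_step)
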