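"""Stochastic steady-state simulation of membrane-protein transport in a cilium.

The cilium is modelled as a one-dimensional track (nominal cylinder
diameter 200 nm, metadata only) partitioned into dendrite, PCMC, TZ, PS,
DS and Tip. Each molecule, every ``mode_hold`` frames (15 frames = 1.5 s
at 10 Hz), draws a transport mode from the probabilities of the segment it
currently occupies: directed (IFT-bound) with probability ``p_ift``,
otherwise diffusive. Directed bouts are anterograde with probability 1/3
and retrograde with probability 2/3, reflecting the anterograde/retrograde
IFT-train frequency asymmetry; they step v·dt per frame with the local
segment speed. Diffusive frames take Gaussian steps of s.d. √(2·D·dt)
with the local D (Itô convention: the step uses the D at the current
position, with no spurious-drift correction, so density accumulates in
low-D regions — a deliberate feature of the model).

Boundary model: the dendrite is pure active transport — a molecule whose
drawn mode is diffusive is overridden to anterograde (import) while it is
in the dendrite, at the dendrite speed of 1.5 μm/s; a molecule leaving
through the dendrite end is removed and replaced by one injected at the
dendrite entry, so the molecule count is conserved exactly. The tip end
reflects. Seeding: 50 molecules at each micrometre from 0 to 7 μm
(inclusive, 400 molecules); 5000 steps of 0.1 s. Density profiles are
position histograms over 3-s windows in the steady-state regime
(180–390 s), plus their grand average.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .geometry import SegmentTable
from .synthetic import ConfigError

DIFFUSIVE, ANTERO, RETRO = 0, 1, 2
MODE_NAMES = {DIFFUSIVE: "diffusive", ANTERO: "directed-antero",
              RETRO: "directed-retro"}


@dataclass(frozen=True)
class SimSegment:
    """Per-segment transport parameters for the simulator."""

    p_ift: float
    v_antero: float
    v_retro: float
    D: float
    p_antero: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.p_ift <= 1 or not 0 <= self.p_antero <= 1:
            raise ConfigError("probabilities must be in [0, 1]")
        if self.D < 0 or self.v_antero < 0 or self.v_retro < 0:
            raise ConfigError("D and velocities must be >= 0")


def default_segments() -> dict[str, SimSegment]:
    """Illustrative per-segment parameter table.

    The dendrite values (100% active transport at 1.5 μm/s) and the
    anterograde/retrograde split (1/3 vs 2/3) are fixed model constants;
    the ciliary values are reconstructed from the location-resolved
    single-molecule profiles this model is meant to reproduce (directed
    fraction high in the TZ, low in PS, slightly higher in DS, zero at the
    tip; anterograde speed ~0.5 μm/s near the TZ rising beyond 1 μm/s
    distally; D_// ≈ 0.03 μm²/s along the cilium but ≈ 0.01 in the TZ, and
    the PCMC taking the D at x = 0). They are illustrative defaults, not
    measured constants.
    """
    return {
        "dendrite": SimSegment(p_ift=1.0, v_antero=1.5, v_retro=1.5, D=0.0,
                               p_antero=1.0),
        "PCMC": SimSegment(p_ift=0.5, v_antero=0.5, v_retro=0.5, D=0.01),
        "TZ": SimSegment(p_ift=0.7, v_antero=0.5, v_retro=0.5, D=0.01),
        "PS": SimSegment(p_ift=0.15, v_antero=0.8, v_retro=0.6, D=0.03),
        "DS": SimSegment(p_ift=0.25, v_antero=1.2, v_retro=0.8, D=0.03),
        "Tip": SimSegment(p_ift=0.0, v_antero=1.0, v_retro=1.0, D=0.03),
    }


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of the steady-state simulator."""

    segment_table: SegmentTable = field(default_factory=SegmentTable)
    segments: dict = field(default_factory=default_segments)
    dt: float = 0.1
    mode_hold: int = 15
    n_per_seed_point: int = 50
    seed_points: tuple = tuple(float(x) for x in range(0, 8))
    n_steps: int = 5000
    steady_state_start: float = 180.0
    analysis_end: float = 390.0
    profile_window: float = 3.0
    x_min: float = -1.5  # dendrite exit (removal/replacement boundary)
    x_max: float = 7.5   # tip end (reflecting)
    lower_boundary: str = "replace"  # or "reflect"
    diameter_nm: float = 200.0  # nominal cylinder diameter, metadata only

    def __post_init__(self) -> None:
        labels = set(self.segment_table.labels)
        missing = labels - set(self.segments)
        if missing:
            raise ConfigError(f"segments missing parameters: {sorted(missing)}")
        if self.n_steps < self.mode_hold:
            raise ConfigError("n_steps must be >= mode_hold")
        if not self.steady_state_start < self.analysis_end <= self.n_steps * self.dt:
            raise ConfigError(
                "need steady_state_start < analysis_end <= n_steps * dt"
            )
        if self.lower_boundary not in ("replace", "reflect"):
            raise ConfigError("lower_boundary must be 'replace' or 'reflect'")
        if self.x_min >= self.x_max:
            raise ConfigError("x_min must be < x_max")

    @property
    def n_molecules(self) -> int:
        return self.n_per_seed_point * len(self.seed_points)


@dataclass
class SimResult:
    """Positions and mode history of one simulation run.

    ``positions`` has shape (n_molecules, n_steps + 1); ``mode`` and
    ``drawn_mode`` (n_molecules, n_steps) hold the effective and the drawn
    mode code for each step; ``replaced`` marks steps where a molecule was
    removed at the dendrite exit and re-injected; ``redraw`` marks steps at
    which modes were (re)drawn.
    """

    config: SimConfig
    positions: np.ndarray
    mode: np.ndarray
    drawn_mode: np.ndarray
    replaced: np.ndarray
    redraw: np.ndarray
    seed: int


def ift_off(config: SimConfig) -> SimConfig:
    """Copy of ``config`` with IFT disabled (p_ift = 0 in every segment).

    Molecule import through the dendrite still works: the dendrite
    overrides diffusive molecules to anterograde transport, so entry flux
    persists while no directed bouts are ever drawn. Idempotent.
    """
    segs = {k: replace(v, p_ift=0.0) for k, v in config.segments.items()}
    return replace(config, segments=segs)


def _segment_arrays(config: SimConfig):
    labels = config.segment_table.labels
    p_ift = np.array([config.segments[s].p_ift for s in labels])
    p_ant = np.array([config.segments[s].p_antero for s in labels])
    v_a = np.array([config.segments[s].v_antero for s in labels])
    v_r = np.array([config.segments[s].v_retro for s in labels])
    D = np.array([config.segments[s].D for s in labels])
    return p_ift, p_ant, v_a, v_r, D


def run_simulation(config: SimConfig, seed: int = 0) -> SimResult:
    """Run the stochastic transport simulation (bit-reproducible per seed)."""
    rng = np.random.default_rng(seed)
    p_ift, p_ant, v_a, v_r, D = _segment_arrays(config)
    boundaries = np.asarray(config.segment_table.boundaries)
    n_mol = config.n_molecules
    n_steps = config.n_steps
    dt = config.dt

    x = np.repeat(np.asarray(config.seed_points, dtype=float),
                  config.n_per_seed_point).copy()
    drawn = np.zeros(n_mol, dtype=np.int8)
    positions = np.empty((n_mol, n_steps + 1))
    positions[:, 0] = x
    mode_hist = np.empty((n_mol, n_steps), dtype=np.int8)
    drawn_hist = np.empty((n_mol, n_steps), dtype=np.int8)
    replaced = np.zeros((n_mol, n_steps), dtype=bool)
    redraw = np.zeros(n_steps, dtype=bool)
    sqrt2dt = np.sqrt(2.0 * dt)

    for step in range(n_steps):
        seg = np.searchsorted(boundaries, x, side="right")
        if step % config.mode_hold == 0:
            redraw[step] = True
            directed = rng.random(n_mol) < p_ift[seg]
            antero = rng.random(n_mol) < p_ant[seg]
            drawn = np.where(
                directed, np.where(antero, ANTERO, RETRO), DIFFUSIVE
            ).astype(np.int8)
        # dendrite is pure active transport: diffusive molecules there are
        # carried anterograde (import); directed bouts keep their direction.
        # Only meaningful with the removal/replacement boundary model.
        eff = drawn.copy()
        if config.lower_boundary == "replace":
            in_dendrite = seg == 0
            eff[in_dendrite & (drawn == DIFFUSIVE)] = ANTERO

        noise = rng.standard_normal(n_mol)
        dx = np.where(
            eff == ANTERO,
            v_a[seg] * dt,
            np.where(eff == RETRO, -v_r[seg] * dt,
                     noise * np.sqrt(D[seg]) * sqrt2dt),
        )
        x = x + dx
        # tip reflects
        over = x > config.x_max
        x[over] = 2.0 * config.x_max - x[over]
        # dendrite end: removal + replacement (or reflection)
        out = x < config.x_min
        if config.lower_boundary == "replace":
            x[out] = config.x_min
            drawn[out] = DIFFUSIVE  # dendrite override carries them inward
            eff[out] = ANTERO
            replaced[out, step] = True
        else:
            x[out] = 2.0 * config.x_min - x[out]

        positions[:, step + 1] = x
        mode_hist[:, step] = eff
        drawn_hist[:, step] = drawn

    return SimResult(
        config=config,
        positions=positions,
        mode=mode_hist,
        drawn_mode=drawn_hist,
        replaced=replaced,
        redraw=redraw,
        seed=seed,
    )


def dendrite_speeds(result: SimResult) -> np.ndarray:
    """Per-frame apparent speeds |Δx|/dt for frames spent in the dendrite.

    Replacement steps (removal + re-injection jumps) are excluded, since
    they are bookkeeping events, not physical displacements.
    """
    cfg = result.config
    boundaries = np.asarray(cfg.segment_table.boundaries)
    seg = np.searchsorted(boundaries, result.positions[:, :-1], side="right")
    mask = (seg == 0) & ~result.replaced
    dx = np.diff(result.positions, axis=1)
    return np.abs(dx[mask]) / cfg.dt


def directed_draw_stats(result: SimResult, ciliary_only: bool = True):
    """(n_directed_draws, retro_share) over all mode redraw events."""
    cfg = result.config
    cols = np.flatnonzero(result.redraw)
    drawn = result.drawn_mode[:, cols]
    if ciliary_only:
        boundaries = np.asarray(cfg.segment_table.boundaries)
        seg = np.searchsorted(boundaries, result.positions[:, cols], side="right")
        drawn = drawn[seg > 0]
    directed = drawn[drawn != DIFFUSIVE]
    if directed.size == 0:
        return 0, np.nan
    return int(directed.size), float(np.mean(directed == RETRO))


def density_profiles(result: SimResult, bin_width: float = 0.25,
                     window: float | None = None) -> pd.DataFrame:
    """Position histograms over consecutive steady-state windows.

    Each window of ``window`` seconds (default from the config, 3 s)
    between ``steady_state_start`` and ``analysis_end`` yields one
    profile; counts are normalised by the number of frames in the window,
    so each profile sums to the (conserved) molecule count. Returns a
    long-format table (window_start_s, bin_center_um, count).
    """
    cfg = result.config
    window = cfg.profile_window if window is None else window
    if window > cfg.analysis_end - cfg.steady_state_start:
        raise ConfigError("profile window longer than the analysis interval")
    edges = np.arange(cfg.x_min, cfg.x_max + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    frames_per_window = int(round(window / cfg.dt))
    start_frame = int(round(cfg.steady_state_start / cfg.dt))
    end_frame = int(round(cfg.analysis_end / cfg.dt))
    rows = []
    for w0 in range(start_frame, end_frame - frames_per_window + 1,
                    frames_per_window):
        pos = result.positions[:, w0:w0 + frames_per_window]
        counts, _ = np.histogram(pos, bins=edges)
        rows.append(
            pd.DataFrame(
                {
                    "window_start_s": w0 * cfg.dt,
                    "bin_center_um": centers,
                    "count": counts / frames_per_window,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def grand_average_profile(profiles: pd.DataFrame) -> pd.DataFrame:
    """Average density over all steady-state windows."""
    return (
        profiles.groupby("bin_center_um", as_index=False)["count"]
        .mean()
        .sort_values("bin_center_um", ignore_index=True)
    )


# regions (μm) in which the experimental distribution shows local maxima
PEAK_REGIONS = {
    "PCMC": (-0.8, 0.0),
    "PS_start": (0.8, 2.5),
    "tip": (6.0, 7.5),
}


def peak_report(profile: pd.DataFrame,
                regions: dict | None = None,
                prominence_frac: float = 0.2,
                max_width_um: float = 2.0,
                smooth_bins: int = 3) -> dict:
    """Detect pronounced local maxima of a grand-average profile by region.

    A peak is a local maximum of the (lightly smoothed) profile whose
    prominence is at least ``prominence_frac`` times the mean density and
    whose width at half prominence is at most ``max_width_um``; the width
    cap distinguishes genuine accumulation peaks from broad monotone
    gradients ending at a boundary. The profile is padded with its minimum
    so maxima at the domain ends are eligible. Returns
    {region: {"peak": bool, "position_um": float | None}}.
    """
    regions = PEAK_REGIONS if regions is None else regions
    x = profile["bin_center_um"].to_numpy()
    y = profile["count"].to_numpy()
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        ypad = np.concatenate([y[:1].repeat(smooth_bins), y,
                               y[-1:].repeat(smooth_bins)])
        y = np.convolve(ypad, kernel, mode="same")[smooth_bins:-smooth_bins]
    bin_width = float(np.median(np.diff(x)))
    padded = np.concatenate([[y.min()], y, [y.min()]])
    idx, props = find_peaks(
        padded,
        prominence=prominence_frac * y.mean(),
        width=(None, max_width_um / bin_width),
        rel_height=0.5,
    )
    idx = np.clip(idx - 1, 0, y.size - 1)
    report = {}
    for name, (lo, hi) in regions.items():
        in_region = idx[(x[idx] >= lo) & (x[idx] < hi)]
        if in_region.size:
            best = in_region[np.argmax(y[in_region])]
            report[name] = {"peak": True, "position_um": float(x[best])}
        else:
            report[name] = {"peak": False, "position_um": None}
    return report
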