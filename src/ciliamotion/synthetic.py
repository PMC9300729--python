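"""Ground-truth synthetic data: trajectories, image stacks and FRAP traces.

The trajectory generator emulates the motion regimes of a membrane protein
in a chemosensory cilium: directed IFT runs (0.5–1.5 μm/s), normal membrane
diffusion (D ≈ 0.01–0.03 μm²/s) and subdiffusion (α ≈ 0.5, modelled as
fractional Brownian motion). The transport mode is held constant over a
window of ``mode_hold`` frames (default 15) and redrawn from the local
segment's probabilities, mirroring the analysis window of the
sliding-window MSD estimator. Localization noise is added per frame, and
track lengths are photobleaching-limited by a geometric survival draw.

Trajectories are emitted in a straightened-cilium image frame: x is the
coordinate along the ciliary axis, y the perpendicular offset (confined
diffusion inside a reflecting interval, emulating the ≤200 nm membrane
diameter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import SegmentTable


class ConfigError(ValueError):
    """Raised for physically invalid generator settings."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera/acquisition settings.

    dt: frame interval in s (10 Hz default); localization_sigma: per-axis
    Gaussian localization noise s.d. in μm; bleach_survival: per-frame
    probability that the fluorophore survives (1.0 = no bleaching).
    """

    dt: float = 0.1
    n_frames: int = 150
    localization_sigma: float = 0.02
    bleach_survival: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if not 0 < self.bleach_survival <= 1:
            raise ConfigError("bleach_survival must be in (0, 1]")
        if self.localization_sigma < 0:
            raise ConfigError("localization_sigma must be >= 0")


@dataclass(frozen=True)
class SegmentMotility:
    """Per-segment motion parameters.

    p_ift: probability that a mode window is directed (IFT-bound);
    p_antero: probability a directed window is anterograde; p_sub:
    probability a non-directed window is subdiffusive; alpha_sub: target
    anomalous exponent of subdiffusive windows.
    """

    p_ift: float = 0.0
    v_antero: float = 1.0
    v_retro: float = 1.0
    p_antero: float = 0.5
    D: float = 0.03
    alpha_sub: float = 0.5
    p_sub: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_ift", "p_antero", "p_sub"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.D < 0 or self.v_antero < 0 or self.v_retro < 0:
            raise ConfigError("D and velocities must be >= 0")
        if not 0 < self.alpha_sub <= 1:
            raise ConfigError("alpha_sub must be in (0, 1]")


@dataclass(frozen=True)
class MotilityParams:
    """Segment-keyed motility table with a ``default`` fallback entry."""

    segments: dict = field(default_factory=lambda: {"default": SegmentMotility()})
    mode_hold: int = 15
    perp_halfwidth: float = 0.1

    def __post_init__(self) -> None:
        if self.mode_hold < 1:
            raise ConfigError("mode_hold must be >= 1")
        if not self.segments:
            raise ConfigError("empty motility table")

    def local(self, label: str) -> SegmentMotility:
        return self.segments.get(label, self.segments.get("default"))


@dataclass
class GroundTruth:
    """Per-frame truth emitted alongside a noisy trajectory."""

    x_true: np.ndarray
    y_true: np.ndarray
    mode: np.ndarray  # directed-antero | directed-retro | diffusive | subdiffusive
    segment: np.ndarray


def fractional_gaussian_noise(n: int, hurst: float, dt: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Exact stationary increments of fractional Brownian motion.

    Returns n increments of unit-coefficient fBm (E[B(t)^2] = t^(2H))
    sampled at spacing dt, via Davies–Harte circulant embedding with a
    Cholesky fallback when the embedding is not nonnegative-definite.
    """
    if not 0 < hurst < 1:
        raise ConfigError("hurst must be in (0, 1)")
    if hurst == 0.5:
        return rng.standard_normal(n) * dt**0.5
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * dt ** (2 * hurst) * (
        (k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst)
    )
    # circulant first row: gamma(0..n), gamma(n-1..1); length m = 2n
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    m = row.size
    eig = np.fft.rfft(row).real
    if np.min(eig) >= -1e-10 * np.max(eig):
        eig = np.clip(eig, 0.0, None)
        a = np.empty(m // 2 + 1, dtype=complex)
        a[0] = np.sqrt(eig[0] / m) * rng.standard_normal()
        a[1:-1] = np.sqrt(eig[1:-1] / (2 * m)) * (
            rng.standard_normal(m // 2 - 1) + 1j * rng.standard_normal(m // 2 - 1)
        )
        a[-1] = np.sqrt(eig[-1] / m) * rng.standard_normal()
        return (m * np.fft.irfft(a, n=m))[:n]
    # rare fallback: exact Cholesky of the increment covariance
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    cov = gamma[idx]
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
    return L @ rng.standard_normal(n)


MODE_LABELS = ("directed-antero", "directed-retro", "diffusive", "subdiffusive")


def _draw_mode(p: SegmentMotility, rng: np.random.Generator) -> str:
    if rng.random() < p.p_ift:
        return "directed-antero" if rng.random() < p.p_antero else "directed-retro"
    return "subdiffusive" if rng.random() < p.p_sub else "diffusive"


def generate_trajectory(
    params: MotilityParams,
    acq: AcquisitionParams,
    start: tuple[float, float] = (0.0, 0.0),
    seed: int | np.random.Generator = 0,
    segment_table: SegmentTable | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one molecule and return (trajectory table, ground truth).

    The trajectory table has columns track_id, frame, t_s, x_um, y_um with
    localization noise applied; the ground truth carries noise-free
    positions and the per-frame mode and segment labels.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = segment_table or SegmentTable()

    # photobleaching-limited length: geometric number of surviving frames
    n = acq.n_frames
    if acq.bleach_survival < 1.0:
        n = min(n, 1 + int(rng.geometric(1.0 - acq.bleach_survival)) - 1)
        n = max(n, 2)

    x = np.empty(n)
    y = np.empty(n)
    modes = np.empty(n, dtype=object)
    segs = np.empty(n, dtype=object)
    x[0], y[0] = start
    modes[0] = "diffusive"
    segs[0] = table.assign(x[0])
    hw = params.perp_halfwidth

    mode = None
    sub_steps = None
    for i in range(1, n):
        seg = table.assign(x[i - 1])
        loc = params.local(seg)
        if mode is None or (i - 1) % params.mode_hold == 0:
            mode = _draw_mode(loc, rng)
            if mode == "subdiffusive":
                # one fBm realisation spanning the mode window
                inc = fractional_gaussian_noise(
                    params.mode_hold, loc.alpha_sub / 2.0, acq.dt, rng
                )
                sub_steps = np.sqrt(2.0 * loc.D) * inc
        j = (i - 1) % params.mode_hold
        if mode == "directed-antero":
            dx = loc.v_antero * acq.dt
        elif mode == "directed-retro":
            dx = -loc.v_retro * acq.dt
        elif mode == "subdiffusive":
            dx = sub_steps[j]
        else:
            dx = rng.standard_normal() * np.sqrt(2.0 * loc.D * acq.dt)
        x[i] = x[i - 1] + dx
        # perpendicular: confined diffusion, reflecting walls at +/- hw
        dy = rng.standard_normal() * np.sqrt(2.0 * loc.D * acq.dt)
        y[i] = _reflect(y[i - 1] + dy, -hw, hw)
        modes[i] = mode
        segs[i] = seg

    noise = rng.normal(0.0, acq.localization_sigma, size=(n, 2))
    traj = pd.DataFrame(
        {
            "track_id": 0,
            "frame": np.arange(n),
            "t_s": np.arange(n) * acq.dt,
            "x_um": x + noise[:, 0],
            "y_um": y + noise[:, 1],
        }
    )
    return traj, GroundTruth(x_true=x, y_true=y, mode=modes, segment=segs)


def _reflect(v: float, lo: float, hi: float) -> float:
    width = hi - lo
    v = (v - lo) % (2 * width)
    return lo + (v if v <= width else 2 * width - v)


def generate_population(
    segment_table: SegmentTable,
    params: MotilityParams,
    acq: AcquisitionParams,
    n_tracks: int,
    seed: int = 0,
    start_range: tuple[float, float] = (0.0, 7.5),
) -> tuple[pd.DataFrame, list[GroundTruth]]:
    """Simulate ``n_tracks`` molecules with starts uniform over the cilium.

    Returns one concatenated trajectory table (distinct track_id per
    molecule) and the list of per-track ground truths. Fully deterministic
    for a fixed seed.
    """
    if n_tracks < 1:
        raise ConfigError("n_tracks must be >= 1")
    root = np.random.SeedSequence(seed)
    frames = []
    truths = []
    for tid, ss in enumerate(root.spawn(n_tracks)):
        rng = np.random.default_rng(ss)
        x0 = rng.uniform(*start_range)
        traj, gt = generate_trajectory(
            params, acq, start=(x0, 0.0), seed=rng, segment_table=segment_table
        )
        traj["track_id"] = tid
        frames.append(traj)
        truths.append(gt)
    return pd.concat(frames, ignore_index=True), truths


def render_frames(
    trajectories: pd.DataFrame,
    psf_sigma: float = 0.13,
    photon_count: float = 500.0,
    background: float = 2.0,
    seed: int = 0,
    pixel_size: float = 0.1,
    shape: tuple[int, int] = (32, 96),
    origin: tuple[float, float] = (0.0, 0.0),
    poisson_noise: bool = True,
) -> np.ndarray:
    """Render trajectories into a synthetic camera stack.

    Each molecule is a 2D Gaussian PSF of s.d. ``psf_sigma`` (μm) carrying
    ``photon_count`` photons on a constant background, with Poisson shot
    noise. Returns an array of shape (n_frames, ny, nx); pixel (0, 0) has
    its centre at ``origin``. Columns map x, rows map y.
    """
    if psf_sigma / pixel_size < 0.25:
        warnings.warn("PSF sigma below 0.25 px: localization will be undersampled")
    rng = np.random.default_rng(seed)
    n_frames = int(trajectories["frame"].max()) + 1 if len(trajectories) else 0
    ny, nx = shape
    xs = origin[0] + np.arange(nx) * pixel_size
    ys = origin[1] + np.arange(ny) * pixel_size
    stack = np.full((n_frames, ny, nx), float(background))
    norm = photon_count * pixel_size**2 / (2 * np.pi * psf_sigma**2)
    for _, row in trajectories.iterrows():
        f = int(row["frame"])
        gx = np.exp(-0.5 * ((xs - row["x_um"]) / psf_sigma) ** 2)
        gy = np.exp(-0.5 * ((ys - row["y_um"]) / psf_sigma) ** 2)
        stack[f] += norm * np.outer(gy, gx)
    if poisson_noise:
        stack = rng.poisson(stack).astype(float)
    return stack


def generate_frap_trace(
    pre_level: float = 100.0,
    mobile_fraction: float = 0.2,
    recovery_tau: float = 30.0,
    bleach_depth: float = 0.9,
    background: float = 10.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    dt: float = 1.0,
    n_pre: int = 10,
    n_post: int = 150,
):
    """Synthesize a FRAP intensity trace with known ground truth.

    Post-bleach ROI intensity follows
    ``background + pre_level * (residual + mobile_fraction * (1 - residual)
    * (1 - exp(-t / recovery_tau)))`` with ``residual = 1 - bleach_depth``
    and t measured from the bleach frame; Gaussian noise of s.d.
    ``noise_sigma`` is added to the ROI signal. Returns
    (:class:`ciliamotion.frap.FrapTrace`, ground-truth dict).
    """
    from .frap import FrapTrace

    if not 0 <= mobile_fraction <= 1:
        raise ConfigError("mobile_fraction must be in [0, 1]")
    if recovery_tau <= 0:
        raise ConfigError("recovery_tau must be > 0")
    if not 0 < bleach_depth <= 1:
        raise ConfigError("bleach_depth must be in (0, 1]")
    rng = np.random.default_rng(seed)
    times = np.arange(n_pre + n_post) * dt
    bleach_time = n_pre * dt
    residual = 1.0 - bleach_depth
    signal = np.full(times.size, float(pre_level))
    post = times >= bleach_time
    t_rel = times[post] - bleach_time
    signal[post] = pre_level * (
        residual
        + mobile_fraction * (1.0 - residual) * (1.0 - np.exp(-t_rel / recovery_tau))
    )
    roi = background + signal + rng.normal(0.0, noise_sigma, size=times.size)
    bg = np.full(times.size, float(background))
    trace = FrapTrace(
        times=times,
        roi_intensity=roi,
        background_intensity=bg,
        bleach_time=bleach_time,
    )
    truth = {
        "mobile_fraction": mobile_fraction,
        "recovery_tau": recovery_tau,
        "bleach_depth": bleach_depth,
        "pre_level": pre_level,
    }
    return trace, truth


def ballistic_params(v: float = 1.0, antero: bool = True) -> MotilityParams:
    """Convenience: a purely directed, noise-free motion table."""
    return MotilityParams(
        segments={
            "default": SegmentMotility(
                p_ift=1.0,
                v_antero=v,
                v_retro=v,
                p_antero=1.0 if antero else 0.0,
                D=0.0,
            )
        }
    )


def brownian_params(D: float = 0.03) -> MotilityParams:
    """Convenience: a purely diffusive motion table."""
    return MotilityParams(segments={"default": SegmentMotility(p_ift=0.0, D=D)})
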