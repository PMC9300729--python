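import numpy as np
import pytest

from ciliamotion import geometry, synthetic


@pytest.fixture
def straight_spline():
    """Straight spline along the x-axis covering the full cilium."""
    return geometry.fit_spline([(-2.0, 0.0), (8.0, 0.0)], sampling_step=0.01)


@pytest.fixture
def segment_table():
    return geometry.SegmentTable()


def make_ciliary_track(s_par, d_perp=None, dt=0.1, track_id=0,
                       table=None):
    """Build a CiliaryTrack directly from coordinate arrays."""
    s_par = np.asarray(s_par, dtype=float)
    if d_perp is None:
        d_perp = np.zeros_like(s_par)
    table = table or geometry.SegmentTable()
    return geometry.CiliaryTrack(
        track_id=track_id,
        times=np.arange(s_par.size) * dt,
        s_par=s_par,
        d_perp=np.asarray(d_perp, dtype=float),
        segment=table.assign(s_par),
    )


def brownian_tracks(n_tracks, n_frames, D, dt=0.1, seed=0, noise=0.0):
    """Ensemble of 1D Brownian paths as an (n_tracks, n_frames) array."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_tracks, n_frames - 1))
    x = np.concatenate(
        [np.zeros((n_tracks, 1)), np.cumsum(steps, axis=1)], axis=1
    )
    if noise:
        x = x + rng.normal(0.0, noise, size=x.shape)
    return x
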