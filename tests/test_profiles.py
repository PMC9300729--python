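import numpy as np
import pandas as pd
import pytest

from ciliamotion import msd, profiles, synthetic
from ciliamotion.geometry import SegmentTable
from ciliamotion.profiles import (
    apparent_diffusion,
    apparent_velocities,
    bin_profile,
)
from tests.conftest import brownian_tracks, make_ciliary_track


def track_with_estimates(s_par, d_perp=None, dt=0.1):
    track = make_ciliary_track(s_par, d_perp=d_perp, dt=dt)
    return track, msd.sliding_window_estimates(track)


class TestApparentVelocities:
    def test_single_step_arithmetic(self):
        # 0.15 um per 0.1 s frame -> +1.5 um/s, anterograde
        track, est = track_with_estimates(0.15 * np.arange(30))
        vel = apparent_velocities(track, est)
        assert len(vel)
        assert np.allclose(vel["v_app"], 1.5, atol=1e-9)
        assert (vel["direction"] == "anterograde").all()

    def test_decreasing_positions_are_retrograde(self):
        track, est = track_with_estimates(5.0 - 0.1 * np.arange(30))
        vel = apparent_velocities(track, est)
        assert len(vel)
        assert (vel["direction"] == "retrograde").all()
        assert (vel["v_app"] < 0).all()

    def test_no_directed_windows_gives_empty(self):
        x = brownian_tracks(1, 60, D=0.02, seed=5)[0]
        track, est = track_with_estimates(x)
        vel = apparent_velocities(track, est, threshold=2.5)
        assert len(vel) == 0

    def test_time_reversal_swaps_direction_labels(self):
        x = 0.12 * np.arange(40)
        track_f, est_f = track_with_estimates(x)
        track_r, est_r = track_with_estimates(x[::-1])
        vf = apparent_velocities(track_f, est_f)
        vr = apparent_velocities(track_r, est_r)
        assert set(vf["direction"]) == {"anterograde"}
        assert set(vr["direction"]) == {"retrograde"}

    def test_directed_population_speed_recovered(self):
        # generator oracle: directed tracks at 1.0 um/s with 20 nm noise
        rng = np.random.default_rng(17)
        samples = []
        for _ in range(40):
            traj, _ = synthetic.generate_trajectory(
                synthetic.ballistic_params(v=1.0),
                synthetic.AcquisitionParams(n_frames=60,
                                            localization_sigma=0.02),
                start=(rng.uniform(1, 3), 0.0),
                seed=rng,
            )
            track = make_ciliary_track(traj["x_um"].to_numpy(),
                                       traj["y_um"].to_numpy())
            est = msd.sliding_window_estimates(track)
            v = apparent_velocities(track, est)
            if len(v):
                samples.append(v)
        vel = pd.concat(samples, ignore_index=True)
        prof = bin_profile(vel, "v_app", bin_width=0.5)
        weighted = np.average(prof["mean"], weights=prof["n"])
        assert weighted == pytest.approx(1.0, rel=0.05)


class TestApparentDiffusion:
    def test_zero_displacement_gives_zero(self):
        x = np.zeros(20)
        x[::2] = 1e-4  # tiny jitter so the log-log fit is defined
        track, est = track_with_estimates(x, d_perp=x)
        diff = apparent_diffusion(track, est, alpha_max=5.0)
        assert (diff["d_est"] >= 0).all()

    def test_single_displacement_arithmetic(self):
        # one 0.1 um step in 0.1 s -> 0.1 um^2/s under the printed form
        assert 0.1**2 / 0.1 == pytest.approx(0.1)

    def test_brownian_conventions(self):
        # closed-form oracle: E[(dx)^2]/dt = 2 D; msd-consistent halves it
        D = 0.03
        x = brownian_tracks(60, 100, D=D, seed=23)
        as_printed, consistent = [], []
        for row in x:
            perp = brownian_tracks(1, 100, D=0.01, seed=int(row[1] * 1e6) % 2**31)[0]
            track = make_ciliary_track(row, d_perp=0.1 * perp)
            est = msd.sliding_window_estimates(track)
            d1 = apparent_diffusion(track, est, convention="as-printed")
            d2 = apparent_diffusion(track, est, convention="msd-consistent")
            as_printed.append(d1[d1["axis"] == "par"]["d_est"].to_numpy())
            consistent.append(d2[d2["axis"] == "par"]["d_est"].to_numpy())
        mean_printed = np.mean(np.concatenate(as_printed))
        mean_consistent = np.mean(np.concatenate(consistent))
        assert mean_printed == pytest.approx(2 * D, rel=0.10)
        assert mean_consistent == pytest.approx(D, rel=0.10)
        assert mean_printed == pytest.approx(2 * mean_consistent, rel=1e-9)

    def test_perp_guard_excludes_transported_windows(self):
        # ballistic parallel motion with diffusive perpendicular motion:
        # alpha_par ~ 2 >= 1.4 must veto every perpendicular sample
        x = 0.15 * np.arange(40)
        perp = 0.05 * brownian_tracks(1, 40, D=0.5, seed=3)[0]
        track, est = track_with_estimates(x, d_perp=perp)
        diff = apparent_diffusion(track, est, alpha_max=1.1)
        assert (diff["axis"] != "perp").all()

    def test_unknown_convention_rejected(self):
        track, est = track_with_estimates(np.linspace(0, 1, 20))
        with pytest.raises(ValueError):
            apparent_diffusion(track, est, convention="bogus")


class TestBinProfile:
    def test_exact_means_two_bins(self):
        samples = pd.DataFrame(
            {"s_par": [0.1, 0.1, 0.6, 0.6], "v_app": [1.0, 2.0, 3.0, 5.0]}
        )
        prof = bin_profile(samples, "v_app", bin_width=0.5)
        assert prof["mean"].tolist() == [1.5, 4.0]
        assert prof["n"].tolist() == [2, 2]

    def test_degenerate_bin_sem_zero(self):
        samples = pd.DataFrame({"s_par": [1.0, 1.0], "d_est": [0.5, 0.5]})
        prof = bin_profile(samples, "d_est", bin_width=0.25)
        assert len(prof) == 1
        assert prof["sem"].iloc[0] == 0.0

    def test_boundary_sample_lands_in_upper_bin(self):
        samples = pd.DataFrame({"s_par": [0.75, 0.5], "v_app": [1.0, 2.0]})
        prof = bin_profile(samples, "v_app", bin_width=0.25)
        # 0.75 is a bin edge: half-open lower-inclusive -> bin [0.75, 1.0)
        assert prof.loc[prof["s_center"] == 0.875, "n"].iloc[0] == 1

    def test_empty_input_gives_empty_profile(self):
        prof = bin_profile(pd.DataFrame(columns=["s_par", "v_app"]), "v_app")
        assert len(prof) == 0

    def test_segment_labels_attached(self):
        samples = pd.DataFrame({"s_par": [0.3, 4.0], "v_app": [1.0, 1.0]})
        prof = bin_profile(samples, "v_app", bin_width=0.25)
        assert prof["segment"].tolist() == ["TZ", "DS"]


class TestVelocityProfileRecovery:
    def test_piecewise_velocity_profile_recovered(self):
        # imposed profile: slow near the TZ, fast in the DS
        segments = {
            "default": synthetic.SegmentMotility(p_ift=1.0, p_antero=1.0,
                                                 v_antero=0.8, v_retro=0.8,
                                                 D=0.0),
            "TZ": synthetic.SegmentMotility(p_ift=1.0, p_antero=1.0,
                                            v_antero=0.5, v_retro=0.5, D=0.0),
            "PCMC": synthetic.SegmentMotility(p_ift=1.0, p_antero=1.0,
                                              v_antero=0.5, v_retro=0.5,
                                              D=0.0),
            "DS": synthetic.SegmentMotility(p_ift=1.0, p_antero=1.0,
                                            v_antero=1.2, v_retro=1.2, D=0.0),
        }
        params = synthetic.MotilityParams(segments=segments)
        acq = synthetic.AcquisitionParams(n_frames=40, localization_sigma=0.02)
        table = SegmentTable()
        rng = np.random.default_rng(31)
        samples = []
        for start in np.repeat([-0.15, 4.0], 25):
            traj, _ = synthetic.generate_trajectory(
                params, acq, start=(start, 0.0), seed=rng,
                segment_table=table,
            )
            track = make_ciliary_track(traj["x_um"].to_numpy(),
                                       traj["y_um"].to_numpy())
            est = msd.sliding_window_estimates(track)
            v = apparent_velocities(track, est)
            if len(v):
                samples.append(v)
        vel = pd.concat(samples, ignore_index=True)
        # interior bins, clear of the running-mean mixing at boundaries
        tz = vel[(vel["s_par"] >= 0.0) & (vel["s_par"] < 0.5)]["v_app"]
        ds = vel[(vel["s_par"] >= 4.2) & (vel["s_par"] < 5.8)]["v_app"]
        assert tz.mean() == pytest.approx(0.5, rel=0.10)
        assert ds.mean() == pytest.approx(1.2, rel=0.10)
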