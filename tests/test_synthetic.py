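import numpy as np
import pandas as pd
import pytest

from ciliamotion import synthetic
from ciliamotion.geometry import SegmentTable
from ciliamotion.synthetic import (
    AcquisitionParams,
    ConfigError,
    MotilityParams,
    SegmentMotility,
    ballistic_params,
    brownian_params,
    fractional_gaussian_noise,
    generate_population,
    generate_trajectory,
    render_frames,
)


def noiseless_acq(n_frames=20):
    return AcquisitionParams(n_frames=n_frames, localization_sigma=0.0)


class TestGenerateTrajectory:
    def test_deterministic_ballistic_limit(self):
        traj, gt = generate_trajectory(
            ballistic_params(v=1.5), noiseless_acq(), seed=0
        )
        steps = np.diff(traj["x_um"].to_numpy())
        assert np.allclose(steps, 1.5 * 0.1, atol=1e-12)
        assert set(gt.mode[1:]) == {"directed-antero"}

    def test_frozen_particle(self):
        params = MotilityParams(
            segments={"default": SegmentMotility(p_ift=0.0, D=0.0)}
        )
        traj, _ = generate_trajectory(params, noiseless_acq(), seed=1)
        assert np.allclose(traj["x_um"], traj["x_um"].iloc[0])
        assert np.allclose(traj["y_um"], traj["y_um"].iloc[0])

    def test_brownian_one_frame_moment(self):
        # closed-form oracle: E[(dx)^2] = 2 D dt = 0.006 um^2
        D, dt = 0.03, 0.1
        sq = []
        rng = np.random.default_rng(123)
        for _ in range(1000):
            traj, _ = generate_trajectory(
                brownian_params(D), noiseless_acq(50), seed=rng
            )
            sq.append(np.diff(traj["x_um"].to_numpy()) ** 2)
        assert np.mean(np.concatenate(sq)) == pytest.approx(2 * D * dt, rel=0.03)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SegmentMotility(D=-0.1)
        with pytest.raises(ConfigError):
            SegmentMotility(v_antero=-1.0)
        with pytest.raises(ConfigError):
            AcquisitionParams(dt=0.0)

    def test_bleaching_geometric_track_length(self):
        p_surv = 0.9
        acq = AcquisitionParams(n_frames=500, bleach_survival=p_surv,
                                localization_sigma=0.0)
        rng = np.random.default_rng(7)
        lengths = [
            len(generate_trajectory(brownian_params(), acq, seed=rng)[0])
            for _ in range(10_000)
        ]
        # geometric mean length 1/(1-p) = 10
        assert np.mean(lengths) == pytest.approx(10.0, rel=0.05)

    def test_perpendicular_confinement(self):
        params = MotilityParams(
            segments={"default": SegmentMotility(p_ift=0.0, D=0.05)},
            perp_halfwidth=0.1,
        )
        traj, gt = generate_trajectory(params, noiseless_acq(500), seed=5)
        assert np.all(np.abs(gt.y_true) <= 0.1 + 1e-12)


class TestFractionalGaussianNoise:
    @pytest.mark.parametrize("alpha", [0.5, 0.8])
    def test_ensemble_msd_slope_recovers_alpha(self, alpha):
        rng = np.random.default_rng(99)
        n, dt = 32, 0.1
        incs = np.array(
            [fractional_gaussian_noise(n, alpha / 2, dt, rng)
             for _ in range(1000)]
        )
        x = np.cumsum(incs, axis=1)
        lags = np.arange(1, 7)
        msd = [np.mean((x[:, k:] - x[:, :-k]) ** 2) for k in lags]
        slope = np.polyfit(np.log(lags * dt), np.log(msd), 1)[0]
        assert slope == pytest.approx(alpha, abs=0.05)

    def test_hurst_half_is_brownian(self):
        rng = np.random.default_rng(0)
        inc = fractional_gaussian_noise(10_000, 0.5, 0.1, rng)
        assert np.std(inc) == pytest.approx(np.sqrt(0.1), rel=0.05)

    def test_subdiffusive_windows_scale_as_2d_tau_alpha(self):
        # TA-MSD amplitude check: MSD(tau) ~ 2 D tau^alpha
        D, alpha, dt = 0.02, 0.5, 0.1
        params = MotilityParams(
            segments={
                "default": SegmentMotility(p_ift=0.0, p_sub=1.0, D=D,
                                           alpha_sub=alpha)
            }
        )
        rng = np.random.default_rng(21)
        d2 = []
        for _ in range(600):
            traj, _ = generate_trajectory(params, noiseless_acq(16), seed=rng)
            d2.append(np.diff(traj["x_um"].to_numpy()) ** 2)
        assert np.mean(np.concatenate(d2)) == pytest.approx(
            2 * D * dt**alpha, rel=0.05
        )


class TestGeneratePopulation:
    def test_zero_tracks_rejected(self):
        with pytest.raises(ConfigError):
            generate_population(SegmentTable(), brownian_params(),
                                noiseless_acq(), n_tracks=0)

    def test_same_seed_identical_output(self):
        args = (SegmentTable(), brownian_params(), noiseless_acq(30), 5, 42)
        t1, _ = generate_population(*args)
        t2, _ = generate_population(*args)
        pd.testing.assert_frame_equal(t1, t2)

    def test_distinct_track_ids_and_lengths(self):
        traj, truths = generate_population(
            SegmentTable(), brownian_params(), noiseless_acq(30), 7, seed=1
        )
        assert traj["track_id"].nunique() == 7
        assert len(truths) == 7

    def test_mode_mix_matches_ground_truth_labels(self):
        # label-count oracle: windows drawn 80/20 diffusive/directed
        params = MotilityParams(
            segments={"default": SegmentMotility(p_ift=0.2, v_antero=1.0,
                                                 v_retro=1.0, D=0.02)}
        )
        _, truths = generate_population(
            SegmentTable(), params, noiseless_acq(151), 250, seed=8
        )
        modes = np.concatenate([t.mode[1:] for t in truths])
        # count one draw per mode window
        window_modes = modes[::15]
        frac_directed = np.mean(
            [m.startswith("directed") for m in window_modes]
        )
        assert frac_directed == pytest.approx(0.2, abs=0.05)


class TestRenderFrames:
    def test_noiseless_peak_at_true_position(self):
        traj = pd.DataFrame(
            {"track_id": [0], "frame": [0], "t_s": [0.0],
             "x_um": [3.0], "y_um": [1.5]}
        )
        stack = render_frames(traj, photon_count=1000, background=0.0,
                              poisson_noise=False)
        iy, ix = np.unravel_index(np.argmax(stack[0]), stack[0].shape)
        assert ix * 0.1 == pytest.approx(3.0, abs=0.1)
        assert iy * 0.1 == pytest.approx(1.5, abs=0.1)

    def test_empty_field_is_pure_background(self):
        traj = pd.DataFrame(
            columns=["track_id", "frame", "t_s", "x_um", "y_um"]
        )
        stack = render_frames(traj, background=5.0, seed=0)
        assert stack.shape[0] == 0

    def test_undersampled_psf_warns(self):
        traj = pd.DataFrame(
            {"track_id": [0], "frame": [0], "t_s": [0.0],
             "x_um": [1.0], "y_um": [1.0]}
        )
        with pytest.warns(UserWarning):
            render_frames(traj, psf_sigma=0.01, pixel_size=0.1)

    def test_localization_error_decreases_with_photons(self):
        # Monte-Carlo oracle: RMSE shrinks monotonically with photon count
        from ciliamotion.detection import localize_spots

        rng = np.random.default_rng(4)
        rmses = []
        for photons in (100, 1000, 10000):
            errs = []
            for k in range(20):
                x0, y0 = 2.0 + rng.uniform(-0.05, 0.05), 0.8
                traj = pd.DataFrame(
                    {"track_id": [0], "frame": [0], "t_s": [0.0],
                     "x_um": [x0], "y_um": [y0]}
                )
                stack = render_frames(traj, photon_count=photons,
                                      background=2.0, seed=1000 + k,
                                      shape=(16, 40))
                # candidate threshold ~ background + 5 sigma of shot noise
                dets = [d for d in localize_spots(stack[0], 9.0) if d.fit_ok]
                if not dets:
                    continue
                best = min(dets, key=lambda d: abs(d.x * 0.1 - x0))
                errs.append(np.hypot(best.x * 0.1 - x0, best.y * 0.1 - y0))
            rmses.append(np.sqrt(np.mean(np.square(errs))))
        assert rmses[0] > rmses[1] > rmses[2]
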