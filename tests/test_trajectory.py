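"""MSD computation, diffusion/alpha fits, phase calls, colocalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import smber
from smber.trajectory import DEFAULT_MOTILE_THRESHOLD

from conftest import make_trajectory


def msd_brute_force(x, n):
    """Independent oracle: explicit double loop over all start indices."""
    N = len(x)
    return sum((x[i + n] - x[i]) ** 2 for i in range(N - n)) / (N - n)


class TestComputeMsd:
    def test_constant_positions_give_zero_msd(self):
        p = smber.compute_msd(make_trajectory(np.full(20, 3.7)))
        assert np.all(p.msd == 0.0)

    def test_ballistic_drift_closed_form(self):
        # x_i = v * i * dt with v = 1 um/s, dt = 1 s -> msd = (n dt)^2
        traj = make_trajectory(np.arange(10, dtype=float), dt=1.0)
        p = smber.compute_msd(traj)
        assert p.msd[:3] == pytest.approx([1.0, 4.0, 9.0], abs=0)

    def test_hand_computed_example(self):
        traj = make_trajectory([0.0, 1.0, 0.0, 2.0, 1.0], dt=1.0)
        p = smber.compute_msd(traj)
        assert p.msd[:3] == pytest.approx([1.75, 2.0 / 3.0, 2.0])
        assert list(p.n_pairs[:3]) == [4, 3, 2]

    def test_matches_brute_force_oracle_bitwise(self, rng):
        for _ in range(20):
            n_frames = int(rng.integers(5, 200))
            x = rng.integers(-5, 6, size=n_frames).astype(float)
            p = smber.compute_msd(make_trajectory(x))
            for j, n in enumerate(p.lags):
                assert p.msd[j] == msd_brute_force(x, int(n))

    def test_max_lag_fraction_truncates(self):
        traj = make_trajectory(np.arange(100, dtype=float))
        p = smber.compute_msd(traj, max_lag_fraction=0.25)
        assert p.lags[-1] == 24
        assert p.n_frames == 100

    def test_too_short_trajectory_rejected(self):
        with pytest.raises(ValueError, match="at least 2 frames"):
            make_trajectory([1.0])

    @given(shift=st.floats(-100, 100), seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_shift_and_time_reversal(self, shift, seed):
        x = np.random.default_rng(seed).normal(size=30)
        base = smber.compute_msd(make_trajectory(x)).msd
        shifted = smber.compute_msd(make_trajectory(x + shift)).msd
        reversed_ = smber.compute_msd(make_trajectory(x[::-1])).msd
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-12)
        assert reversed_ == pytest.approx(base, rel=1e-12, abs=0)


class TestLinearFit:
    def test_exact_line_recovers_d_and_intercept(self):
        t = np.arange(1, 41) * 0.08
        profile = smber.MSDProfile(
            lags=np.arange(1, 41), lag_times=t, msd=0.2 * t + 0.01,
            n_pairs=41 - np.arange(1, 41), n_frames=41,
        )
        est = smber.fit_msd_linear(profile, fit_fraction=1.0)
        assert est.D == pytest.approx(0.1, rel=1e-12)
        assert est.y_intercept == pytest.approx(0.01, rel=1e-9)
        assert est.r_squared == pytest.approx(1.0)
        assert est.valid

    def test_noisy_profile_fails_r2_filter(self, rng):
        t = np.arange(1, 101) * 0.08
        noise = rng.normal(0, 1.0, size=t.size)
        profile = smber.MSDProfile(
            lags=np.arange(1, 101), lag_times=t,
            msd=np.abs(0.01 * t + noise), n_pairs=101 - np.arange(1, 101),
            n_frames=101,
        )
        est = smber.fit_msd_linear(profile, fit_fraction=1.0)
        assert est.r_squared < 0.8
        assert not est.valid

    def test_fraction_of_plot_filter(self):
        # profile truncated to 5% of the available lags -> invalid
        traj = make_trajectory(np.cumsum(np.random.default_rng(0).normal(size=200)))
        profile = smber.compute_msd(traj, max_lag_fraction=0.05)
        est = smber.fit_msd_linear(profile, fit_fraction=1.0)
        assert est.fraction_of_plot_used < 0.10
        assert not est.valid

    def test_fewer_than_three_points_invalid_not_raising(self):
        profile = smber.MSDProfile(
            lags=np.array([1, 2]), lag_times=np.array([0.08, 0.16]),
            msd=np.array([0.1, 0.2]), n_pairs=np.array([9, 8]), n_frames=10,
        )
        est = smber.fit_msd_linear(profile, fit_fraction=1.0)
        assert not est.valid and math.isnan(est.D)

    def test_filter_monotone_in_r2_threshold(self, rng):
        # lowering the R^2 cut never invalidates a previously valid estimate
        from smber.trajectory import _apply_filter
        for _ in range(50):
            r2 = rng.uniform(0, 1)
            frac = rng.uniform(0, 1)
            if _apply_filter(r2, frac, r2_min=0.8):
                assert _apply_filter(r2, frac, r2_min=0.5)

    def test_brownian_ensemble_recovers_d(self, short_window_config):
        cfg = short_window_config(D_true=3.01e-2, alpha_true=1.0)
        trajs, _ = smber.simulate_tightrope_particles(cfg)
        ds = [smber.fit_msd_linear(smber.compute_msd(t)).D for t in trajs]
        assert np.mean(ds) == pytest.approx(3.01e-2, rel=0.15)


class TestAlphaFit:
    @staticmethod
    def power_law_profile(alpha, d=0.1, n=50):
        t = np.arange(1, n + 1) * 0.08
        return smber.MSDProfile(
            lags=np.arange(1, n + 1), lag_times=t, msd=2 * d * t**alpha,
            n_pairs=n + 1 - np.arange(1, n + 1), n_frames=n + 1,
        )

    def test_brownian_limit_alpha_one(self):
        est = smber.fit_alpha(self.power_law_profile(1.0))
        assert est.alpha == pytest.approx(1.0, abs=1e-12)

    def test_ballistic_limit_alpha_two(self):
        est = smber.fit_alpha(self.power_law_profile(2.0))
        assert est.alpha == pytest.approx(2.0, abs=1e-12)

    def test_linear_and_loglog_agree_on_exact_brownian_msd(self):
        profile = self.power_law_profile(1.0, d=0.037)
        d_lin = smber.fit_msd_linear(profile, fit_fraction=1.0).D
        d_log = smber.fit_alpha(profile, fit_fraction=1.0).D
        assert d_log == pytest.approx(d_lin, rel=1e-12)

    def test_nonpositive_msd_lags_dropped(self):
        t = np.arange(1, 11) * 1.0
        msd = 0.2 * t
        msd[0] = 0.0
        profile = smber.MSDProfile(
            lags=np.arange(1, 11), lag_times=t, msd=msd,
            n_pairs=11 - np.arange(1, 11), n_frames=11,
        )
        est = smber.fit_alpha(profile, fit_fraction=1.0)
        assert est.n_points_used == 9
        assert est.alpha == pytest.approx(1.0, abs=1e-9)

    def test_fbm_ensemble_recovers_alpha(self, short_window_config):
        cfg = short_window_config(D_true=3.75e-3, alpha_true=1.19)
        trajs, _ = smber.simulate_tightrope_particles(cfg)
        alphas = [smber.fit_alpha(smber.compute_msd(t)).alpha for t in trajs]
        assert np.mean(alphas) == pytest.approx(1.19, abs=0.1)


class TestPhasesAndMotility:
    def test_pure_noise_is_one_stationary_segment(self, rng):
        traj = make_trajectory(rng.normal(0, 0.03, size=300))
        segs = smber.segment_phases(traj, motile_threshold=0.09)
        assert len(segs) == 1
        assert segs[0].label == "stationary"
        assert smber.classify_motility(segs) == "stationary"

    def test_brownian_track_is_motile(self):
        # full 300 s observation window, the regime the rolling-SD rule targets
        cfg = smber.SimulationConfig(n_particles=1, motile_fraction=1.0,
                                     D_true=1e-2, half_life_true=1e9, seed=7)
        trajs, truth = smber.simulate_tightrope_particles(cfg)
        segs = smber.segment_phases(trajs[0])
        assert truth[0].is_motile
        assert smber.classify_motility(segs) == "motile"

    def test_constructed_three_phase_track(self, rng):
        window = 10
        still1 = rng.normal(0, 0.01, 150)
        moving = np.cumsum(rng.normal(0, 0.12, 150))
        still2 = moving[-1] + rng.normal(0, 0.01, 150)
        traj = make_trajectory(np.concatenate([still1, moving, still2]))
        segs = smber.segment_phases(traj, window_frames=window)
        labels = [s.label for s in segs]
        assert labels == ["stationary", "motile", "stationary"]
        assert abs(segs[0].end_frame - 149) <= window
        assert abs(segs[1].end_frame - 299) <= window
        # segments tile the trajectory without overlap
        assert segs[0].start_frame == 0
        assert segs[-1].end_frame == 449
        for prev, nxt in zip(segs, segs[1:]):
            assert nxt.start_frame == prev.end_frame + 1

    def test_short_trajectory_single_segment(self):
        traj = make_trajectory([0.0, 0.01, 0.0, 0.02, 0.01])
        segs = smber.segment_phases(traj, window_frames=10)
        assert len(segs) == 1

    def test_cohort_fractions(self):
        assert smber.motile_fraction(["stationary"] * 5) == 0.0
        assert smber.motile_fraction(["motile"] * 4) == 1.0
        assert smber.motile_fraction(["motile", "stationary"]) == 0.5

    def test_mixture_cohort_recovers_motile_fraction(self):
        cfg = smber.SimulationConfig(
            n_particles=100, motile_fraction=0.10, D_true=1e-2,
            half_life_true=1e9, seed=42,
        )
        trajs, truth = smber.simulate_tightrope_particles(cfg)
        calls = [smber.classify_motility(smber.segment_phases(t)) for t in trajs]
        assert smber.motile_fraction(calls) == pytest.approx(0.10, abs=0.06)


class TestColocalization:
    def test_identical_series_fully_colocalized(self, rng):
        x = rng.normal(0, 0.03, size=50)
        a = [make_trajectory(x, particle_id=0, channel="605")]
        b = [make_trajectory(x, particle_id=1, channel="705")]
        res = smber.colocalization_fraction(a, b)
        assert res.n_colocalized == 1
        assert res.fraction_colocalized == 1.0

    def test_distant_particles_never_colocalize(self, rng):
        a = [make_trajectory(rng.normal(0, 0.03, 50), 0.08, 0, "605")]
        b = [make_trajectory(rng.normal(5.0, 0.03, 50), 0.08, 1, "705")]
        res = smber.colocalization_fraction(a, b, distance_threshold=0.2)
        assert res.n_colocalized == 0
        assert res.fraction_colocalized == 0.0

    def test_empty_channel_warns(self):
        a = [make_trajectory([0.0, 0.0, 0.0], channel="605")]
        res = smber.colocalization_fraction(a, [])
        assert res.fraction_colocalized == 0.0
        assert res.empty_channel_warning

    def test_same_channel_rejected(self):
        a = [make_trajectory([0.0, 0.0], channel="605")]
        with pytest.raises(ValueError, match="distinct"):
            smber.colocalization_fraction(a, a)

    def test_greedy_matching_is_one_to_one(self, rng):
        # two A particles near one B particle: only one pair may form
        x = rng.normal(0, 0.01, 40)
        a = [make_trajectory(x, 0.08, 0, "605"),
             make_trajectory(x + 0.05, 0.08, 1, "605")]
        b = [make_trajectory(x + 0.02, 0.08, 2, "705")]
        res = smber.colocalization_fraction(a, b)
        assert res.n_colocalized == 1
        assert res.fraction_colocalized == pytest.approx(1 / 2)

    def test_simulated_field_recovers_cobound_fraction(self):
        cfg = smber.SimulationConfig(
            n_particles=200, coloc_fraction=0.24, motile_fraction=0.0,
            window=8.0, half_life_true=1e9, seed=99,
        )
        trajs, truth = smber.simulate_tightrope_particles(cfg)
        a = [t for t in trajs if t.channel == "605"]
        b = [t for t in trajs if t.channel == "705"]
        res = smber.colocalization_fraction(a, b)
        assert res.fraction_colocalized == pytest.approx(0.24, abs=0.05)
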