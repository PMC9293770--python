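"""Windowed MSD, anomalous-diffusion fits, the alpha mixture, and
segment labeling, checked against brute-force and closed-form oracles."""

import inspect

import numpy as np
import pytest

from conftest import brute_force_window_msd
from phagotrack import (
    AnalysisConfig,
    MotionSegment,
    MSDCurve,
    SimulationConfig,
    Trajectory,
    WindowFit,
    fit_alpha_distribution,
    fit_msd,
    fit_windows,
    label_segments,
    simulate_trajectory,
    validate_separation,
    windowed_msd,
)
from phagotrack.msd import DegenerateMixtureError, per_frame_alpha
from phagotrack.trajectory import DIFFUSIVE, DIRECTED


def make_traj(x, y, dt=0.05):
    n = len(x)
    return Trajectory(frames=np.arange(n), times=np.arange(n) * dt, x=x, y=y)


class TestWindowedMSD:
    def test_motionless_track_msd_is_zero(self):
        traj = make_traj(np.zeros(60), np.zeros(60))
        for curve in windowed_msd(traj, 40):
            assert np.all(curve.msd == 0.0)

    def test_ballistic_msd_closed_form(self):
        v, dt = 400.0, 0.05
        t = np.arange(100) * dt
        traj = make_traj(v * t, np.zeros(100))
        for curve in windowed_msd(traj, 40):
            assert curve.msd == pytest.approx(v**2 * curve.lags**2, rel=1e-12)

    def test_equals_brute_force_pair_average(self, short_diffusive_traj):
        traj = short_diffusive_traj
        curves = windowed_msd(traj, 40, stride_frames=17)
        for curve in curves:
            ref = brute_force_window_msd(traj.x, traj.y, curve.window[0],
                                         40, 10)
            np.testing.assert_allclose(curve.msd, ref, rtol=1e-12)
            assert np.array_equal(curve.n_pairs, 40 - np.arange(1, 11))

    def test_too_short_trajectory_is_error(self):
        traj = make_traj(np.zeros(30), np.zeros(30))
        with pytest.raises(ValueError, match="shorter"):
            windowed_msd(traj, 40)


class TestFitMSD:
    def _curve(self, msd, dt=0.05, nlags=10):
        lags = np.arange(1, nlags + 1) * dt
        return MSDCurve(lags=lags, msd=msd(lags),
                        n_pairs=np.full(nlags, 30), window=(0, 39))

    def test_recovers_brownian_parameters_to_4_significant_figures(self):
        sig = 9.8
        curve = self._curve(lambda t: 4 * 100.0 * t + 2 * sig**2)
        fit = fit_msd(curve, sigma=sig)
        assert fit.fit_ok
        assert fit.alpha == pytest.approx(1.0, abs=5e-5)
        assert fit.D == pytest.approx(100.0, rel=5e-4)

    def test_recovers_ballistic_exponent(self):
        sig = 9.8
        curve = self._curve(lambda t: (500.0 * t) ** 2 + 2 * sig**2)
        fit = fit_msd(curve, sigma=sig)
        assert fit.alpha == pytest.approx(2.0, abs=1e-4)
        assert 4 * fit.D == pytest.approx(500.0**2, rel=1e-3)

    def test_sigma_is_held_fixed_not_fitted(self):
        curve = self._curve(lambda t: 4 * 100.0 * t + 2 * 9.8**2)
        fit = fit_msd(curve, sigma=9.8)
        assert fit.sigma == 9.8
        # a wrong fixed sigma must change the fit: it is part of the model
        fit_wrong = fit_msd(curve, sigma=0.0)
        assert fit_wrong.alpha != pytest.approx(fit.alpha, abs=1e-3)

    def test_too_few_lags_flags_not_raises(self):
        curve = MSDCurve(lags=np.array([0.05, 0.1, 0.15]),
                         msd=np.array([1.0, 2.0, 3.0]),
                         n_pairs=np.array([3, 2, 1]), window=(0, 3))
        fit = fit_msd(curve)
        assert not fit.fit_ok and "lags" in fit.reason

    def test_batch_fit_agrees_with_single_curve_fit(self, short_diffusive_traj):
        cfg = AnalysisConfig()
        batch = fit_windows(short_diffusive_traj, cfg)
        curves = windowed_msd(short_diffusive_traj, 40)
        for i in (0, 100, 250):
            single = fit_msd(curves[i], sigma=cfg.sigma_loc_nm)
            assert batch[i].alpha == pytest.approx(single.alpha, abs=2e-3)


class TestAlphaDistribution:
    def test_tight_clusters_give_midpoint_cutoff(self):
        rng = np.random.default_rng(1)
        alphas = np.concatenate([rng.normal(1.0, 0.05, 500),
                                 rng.normal(2.0, 0.05, 500)])
        model = fit_alpha_distribution(alphas)
        assert model.means[0] == pytest.approx(1.0, abs=0.02)
        assert model.means[1] == pytest.approx(2.0, abs=0.02)
        assert model.cutoff == pytest.approx(1.5, abs=0.05)

    def test_known_mixture_parameters_recovered(self):
        # Monte-Carlo oracle: sampling SEs at n=2000, estimated from 30
        # independent replicates, are ~(0.005, 0.009) for the means,
        # ~(0.003, 0.005) for the sds and ~0.011 for the weights; allow 3 SE
        rng = np.random.default_rng(2)
        n = 2000
        comp = rng.random(n) < 0.6
        alphas = np.where(comp, rng.normal(1.0, 0.15, n),
                          rng.normal(1.9, 0.2, n))
        model = fit_alpha_distribution(alphas)
        assert model.means[0] == pytest.approx(1.0, abs=3 * 0.005)
        assert model.means[1] == pytest.approx(1.9, abs=3 * 0.009)
        assert model.sds[0] == pytest.approx(0.15, abs=3 * 0.003)
        assert model.sds[1] == pytest.approx(0.2, abs=3 * 0.005)
        assert model.weights == pytest.approx([0.6, 0.4], abs=3 * 0.011)
        assert model.means[0] < model.cutoff < model.means[1]

    def test_equal_density_property_of_cutoff(self):
        rng = np.random.default_rng(3)
        alphas = np.concatenate([rng.normal(1.0, 0.12, 1200),
                                 rng.normal(1.9, 0.25, 800)])
        model = fit_alpha_distribution(alphas)
        x = np.array([model.cutoff])
        d0 = model.component_density(x, 0)[0]
        d1 = model.component_density(x, 1)[0]
        assert d0 == pytest.approx(d1, rel=1e-6)

    def test_deterministic_given_seed_and_order_invariant(self):
        rng = np.random.default_rng(4)
        alphas = np.concatenate([rng.normal(1.0, 0.15, 700),
                                 rng.normal(1.9, 0.2, 700)])
        a = fit_alpha_distribution(alphas, seed=5)
        b = fit_alpha_distribution(alphas[::-1], seed=5)
        assert a.cutoff == pytest.approx(b.cutoff, abs=1e-9)

    def test_vanishing_component_rejected_as_degenerate(self):
        rng = np.random.default_rng(6)
        alphas = np.concatenate([rng.normal(1.0, 0.1, 2000),
                                 np.full(4, 2.5)])
        with pytest.raises(DegenerateMixtureError, match="weight"):
            fit_alpha_distribution(alphas)

    def test_requires_minimum_sample(self):
        with pytest.raises(ValueError, match="50"):
            fit_alpha_distribution(np.linspace(1, 2, 20))


def _const_fits(alphas_per_frame, n, window=40):
    """WindowFits with prescribed per-frame alpha at window centers."""
    fits = []
    for s in range(n - window + 1):
        c = s + window // 2
        fits.append(WindowFit(alpha=alphas_per_frame[c], D=1.0, sigma=9.8,
                              center_frame=c, fit_ok=True, residual=0.0,
                              window=(s, s + window - 1)))
    return fits


class TestLabelSegments:
    def test_uniform_alpha_gives_single_segment(self):
        n = 120
        traj = make_traj(np.zeros(n), np.zeros(n))
        fits = _const_fits(np.full(n, 1.9), n)
        segs = label_segments(traj, fits, cutoff=1.5)
        assert len(segs) == 1
        assert segs[0].state == DIRECTED
        assert (segs[0].start_frame, segs[0].end_frame) == (0, n - 1)

    def test_segments_tile_and_alternate(self):
        n = 400
        rngs = np.random.default_rng(7)
        alpha = np.where(rngs.random(n) < 0.5, 0.9, 2.0)
        traj = make_traj(np.zeros(n), np.zeros(n))
        segs = label_segments(traj, _const_fits(alpha, n), cutoff=1.5,
                              min_segment_frames=5)
        assert segs[0].start_frame == 0 and segs[-1].end_frame == n - 1
        for a, b in zip(segs[:-1], segs[1:]):
            assert b.start_frame == a.end_frame + 1
            assert a.state != b.state
        assert all(s.n_frames >= 5 for s in segs[:])

    def test_short_segment_absorbed_into_longer_neighbour(self):
        n = 140
        alpha = np.full(n, 0.9)
        alpha[60:63] = 2.0  # 3-frame flicker
        traj = make_traj(np.zeros(n), np.zeros(n))
        segs = label_segments(traj, _const_fits(alpha, n), cutoff=1.5,
                              min_segment_frames=5)
        assert len(segs) == 1 and segs[0].state == DIFFUSIVE

    def test_agreement_with_ground_truth_on_separated_simulation(self):
        # long sojourns relative to the window: boundaries resolvable
        import dataclasses
        cfg = SimulationConfig(seed=12, duration=150, k_off=0.2, k_on=0.2,
                               v_mean=500, v_sd=0.0)
        acc = []
        for i in range(6):
            traj = simulate_trajectory(dataclasses.replace(cfg, seed=12 + i))
            fits = fit_windows(traj)
            segs = label_segments(traj, fits, cutoff=1.45)
            pred = np.empty(len(traj), dtype=object)
            for s in segs:
                pred[s.start_frame:s.end_frame + 1] = s.state
            acc.append(np.mean(pred == traj.state))
        assert np.mean(acc) >= 0.90

    def test_no_valid_fits_is_error(self):
        traj = make_traj(np.zeros(50), np.zeros(50))
        bad = [WindowFit(np.nan, np.nan, 9.8, 20, False, np.nan)]
        with pytest.raises(ValueError, match="valid"):
            label_segments(traj, bad, cutoff=1.5)

    def test_edge_frames_take_nearest_window(self):
        n = 100
        alpha = np.full(n, 0.9)
        fits = _const_fits(alpha, n)
        out = per_frame_alpha(fits, n)
        assert out[0] == alpha[40 // 2]
        assert out[-1] == alpha[n - 1 - 40 + 40 // 2]


class TestValidateSeparation:
    def _cohort_segments(self, forced, n=12, duration=40):
        pairs = []
        for i in range(n):
            cfg = SimulationConfig(seed=100 + i, duration=duration,
                                   forced_state=forced, D_diff=1e4,
                                   v_mean=500, v_sd=0.0)
            traj = simulate_trajectory(cfg)
            state = DIRECTED if forced == "directed" else DIFFUSIVE
            seg = MotionSegment(0, len(traj) - 1, state, 0.0)
            pairs.append((traj, [seg]))
        return pairs

    def test_pure_diffusion_class_alpha_near_one(self):
        out = validate_separation(self._cohort_segments("diffusive"),
                                  n_sample=200, seed=1)
        assert out[DIFFUSIVE]["alpha"] == pytest.approx(1.0, abs=0.15)

    def test_pure_ballistic_class_alpha_near_two(self):
        out = validate_separation(self._cohort_segments("directed"),
                                  n_sample=200, seed=1)
        assert out[DIRECTED]["alpha"] == pytest.approx(2.0, abs=0.15)

    def test_small_class_flagged_and_default_sample_size(self):
        out = validate_separation(self._cohort_segments("diffusive", n=3),
                                  n_sample=10, seed=1)
        assert out[DIFFUSIVE]["too_few"]
        assert out[DIRECTED]["n_segments"] == 0
        sig = inspect.signature(validate_separation)
        assert sig.parameters["n_sample"].default == 1500
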