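"""Unscented-Kalman-filter tractography: filter, seeding, tracking."""

import numpy as np
import pytest

import ukftract as u
from ukftract.ukf import (SignalInterpolator, UKFFilter, UKFState,
                          init_seed_state, interpolate_signal, kalman_gain,
                          track, track_from_seed)

AX = np.array([1.0, 0.0, 0.0])


def filter_for(dwi, **kwargs):
    cfg = u.UKFConfig(**kwargs)
    return cfg, UKFFilter(cfg, dwi.weighted_gradients, dwi.b_weighted)


class TestInterpolateSignal:
    def test_voxel_center_identity(self, tiny_phantom):
        dwi = tiny_phantom.dwi_clean
        point = dwi.index_to_world(np.array([5, 3, 4]))
        np.testing.assert_allclose(interpolate_signal(dwi, point),
                                   dwi.normalized()[5, 3, 4], rtol=1e-12)

    def test_midpoint_is_mean_of_neighbors(self, tiny_phantom):
        dwi = tiny_phantom.dwi_clean
        point = dwi.index_to_world(np.array([5.5, 3.0, 4.0]))
        expected = 0.5 * (dwi.normalized()[5, 3, 4] + dwi.normalized()[6, 3, 4])
        np.testing.assert_allclose(interpolate_signal(dwi, point), expected,
                                   rtol=1e-12)

    def test_constant_volume(self, tiny_phantom):
        dwi = tiny_phantom.dwi_clean
        flat = u.DWIVolume(np.full_like(dwi.data, 0.5), dwi.gradients,
                           dwi.bvalues, dwi.spacing, dwi.origin)
        s = interpolate_signal(flat, np.array([7.3, 5.1, 9.9]))
        np.testing.assert_allclose(s, 1.0)   # 0.5 / 0.5 baseline

    def test_outside_bounds_raises(self, tiny_phantom):
        with pytest.raises(ValueError):
            interpolate_signal(tiny_phantom.dwi_clean,
                               np.array([-10.0, 0.0, 0.0]))


class TestInitSeedState:
    def test_seed_in_healthy_tissue(self, uniform_phantom):
        dwi = uniform_phantom.dwi_clean
        cfg = u.UKFConfig(model="2T")
        state = init_seed_state(dwi, dwi.index_to_world([2, 6, 6]), cfg)
        filt = UKFFilter(cfg, dwi.weighted_gradients, dwi.b_weighted)
        for m in filt.directions(state.mean):
            assert abs(m @ AX) > 0.999
        for l1, l2 in filt.eigenvalues(state.mean):
            assert l1 == pytest.approx(1100.0, rel=0.01)
            assert l2 == pytest.approx(450.0, rel=0.01)

    def test_deterministic(self, tiny_phantom):
        dwi = tiny_phantom.dwi
        cfg = u.UKFConfig(model="1T+FW")
        p = dwi.index_to_world([4, 3, 3])
        a = init_seed_state(dwi, p, cfg)
        b = init_seed_state(dwi, p, cfg)
        np.testing.assert_array_equal(a.mean, b.mean)
        np.testing.assert_array_equal(a.cov, b.cov)

    def test_state_dimensions(self, tiny_phantom):
        dwi = tiny_phantom.dwi_clean
        p = dwi.index_to_world([4, 3, 3])
        for model, dim in (("1T", 5), ("1T+FW", 6), ("2T", 10), ("2T+FW", 11)):
            state = init_seed_state(dwi, p, u.UKFConfig(model=model))
            assert state.mean.shape == (dim,)
            assert state.cov.shape == (dim, dim)


class TestUKFStep:
    def test_zero_innovation_leaves_mean(self, directions21):
        """Measurement equal to the predicted mean gives a vanishing update."""
        cfg = u.UKFConfig(model="1T", q_l=1e-12, q_m=1e-12)
        filt = UKFFilter(cfg, directions21, 1000.0)
        mean = np.array([*AX, 1100.0, 450.0])
        state = UKFState(mean, 1e-12 * np.eye(5))
        y = filt.predict(mean[None, :])[0]
        new, _ = filt.update(state, y)
        np.testing.assert_allclose(new.mean, mean, atol=1e-6)

    def test_gain_increases_with_ql(self, directions21):
        """Doubling the eigenvalue process-noise rate raises the Kalman gain."""
        state = UKFState(np.array([*AX, 1100.0, 450.0]),
                         np.diag([0.01] * 3 + [100.0] * 2))
        y = np.exp(-1000.0 * (450e-6 + 650e-6 * (directions21 @ AX) ** 2))
        norms = [np.linalg.norm(kalman_gain(
            state, y, u.UKFConfig(model="1T", q_l=ql), directions21, 1000.0))
            for ql in (25.0, 50.0, 100.0, 200.0)]
        assert norms == sorted(norms)
        assert norms[1] < norms[2] < norms[3]

    def test_covariance_stays_symmetric_psd(self, directions21):
        rng = np.random.default_rng(2)
        cfg = u.UKFConfig(model="2T+FW")
        filt = UKFFilter(cfg, directions21, 1000.0)
        mean = np.array([*AX, 1100.0, 450.0, *AX, 1100.0, 450.0, 0.05])
        state = UKFState(mean, np.diag([0.01] * 3 + [100.0] * 2
                                       + [0.01] * 3 + [400.0] * 2 + [0.01]))
        clean = np.exp(-1000.0 * (450e-6 + 650e-6 * (directions21 @ AX) ** 2))
        for _ in range(60):
            y = clean * (1 + rng.normal(0, 1 / 15, clean.shape))
            state, _ = filt.update(state, np.abs(y))
            np.testing.assert_allclose(state.cov, state.cov.T, atol=1e-12)
            assert np.linalg.eigvalsh(state.cov)[0] >= -1e-10

    def test_constraints_after_update(self, directions21):
        cfg = u.UKFConfig(model="2T+FW")
        filt = UKFFilter(cfg, directions21, 1000.0)
        mean = np.array([*AX, 1100.0, 450.0, *AX, 1100.0, 450.0, 0.05])
        state = UKFState(mean, np.diag([1.0] * 11))   # very loose prior
        y = np.full(len(directions21), 0.9)
        for _ in range(10):
            state, _ = filt.update(state, y)
        for m in filt.directions(state.mean):
            assert np.linalg.norm(m) == pytest.approx(1.0, abs=1e-12)
        for l1, l2 in filt.eigenvalues(state.mean):
            assert l1 >= l2 >= cfg.lambda_floor
        assert 0.0 <= filt.omega(state.mean) <= 1.0

    def test_parameter_recovery_single_tensor(self, directions21):
        """From a perturbed start the filter recovers a noise-free generating
        tensor: eigenvalues within 5%, direction within 2 degrees.  With the
        21-direction scheme each update carries less information than the
        81-direction study conditions, so more steps are allowed here."""
        true_dir = np.array([1.0, 1.0, 0.5])
        true_dir /= np.linalg.norm(true_dir)
        y = np.exp(-1000.0 * 1e-6 *
                   (400.0 + 1100.0 * (directions21 @ true_dir) ** 2))
        cfg = u.UKFConfig(model="1T")
        filt = UKFFilter(cfg, directions21, 1000.0)
        start = np.array([0.0, 0.0, 1.0, 1100.0, 450.0])   # >60 deg off
        state = UKFState(start, np.diag([0.01] * 3 + [100.0] * 2))
        for _ in range(150):
            state, _ = filt.update(state, y)
        m = state.mean[:3]
        angle = np.degrees(np.arccos(min(1.0, abs(m @ true_dir))))
        assert angle < 2.0
        assert state.mean[3] == pytest.approx(1500.0, rel=0.05)
        assert state.mean[4] == pytest.approx(400.0, rel=0.05)


class TestTracking:
    def test_fiber_geometry_on_uniform_phantom(self, uniform_phantom, fast_ukf):
        dwi = uniform_phantom.dwi_clean
        seed = dwi.index_to_world([3, 6, 6])
        fiber = track_from_seed(dwi, seed, fast_ukf,
                                uniform_phantom.masks["phantom"])
        assert fiber is not None
        steps = np.diff(fiber.points, axis=0)
        norms = np.linalg.norm(steps, axis=1)
        np.testing.assert_allclose(norms, fast_ukf.step_mm, atol=1e-6)
        # straight fiber along the true axis, spanning the volume
        assert np.mean(np.abs(steps[:, 0]) / norms) > 0.99
        assert fiber.points[:, 0].max() > 70.0
        assert fiber.reasons == ("left-mask", "left-mask")

    def test_direction_continuity(self, tiny_phantom, fast_ukf):
        dwi = tiny_phantom.dwi
        ts = track(dwi, tiny_phantom.masks["end_seed"], fast_ukf,
                   tiny_phantom.masks["phantom"])
        limit = np.cos(np.deg2rad(fast_ukf.max_angle_deg)) - 1e-9
        for fiber in ts:
            d = np.diff(fiber.points, axis=0)
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            assert np.all(np.sum(d[1:] * d[:-1], axis=1) > limit)

    def test_seed_outside_mask_rejected(self, tiny_phantom, fast_ukf):
        dwi = tiny_phantom.dwi
        inside_only = tiny_phantom.masks["end_seed"]
        seed = dwi.index_to_world([15, 4, 4])     # centre, not in mask
        assert track_from_seed(dwi, seed, fast_ukf, inside_only) is None

    def test_high_fa_threshold_rejects_all_seeds(self, tiny_phantom):
        cfg = u.UKFConfig(model="1T", min_fa=0.9, step_mm=0.6, max_steps=50)
        ts = track(tiny_phantom.dwi, tiny_phantom.masks["end_seed"], cfg)
        assert len(ts) == 0
        assert ts.meta["counts"]["rejected"] == ts.meta["counts"]["seeds"]

    def test_track_deterministic(self, tiny_phantom, fast_ukf):
        a = track(tiny_phantom.dwi, tiny_phantom.masks["end_seed"], fast_ukf)
        b = track(tiny_phantom.dwi, tiny_phantom.masks["end_seed"], fast_ukf)
        assert len(a) == len(b)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.points, fb.points)
            np.testing.assert_array_equal(fa.fa1, fb.fa1)

    def test_seeds_per_voxel_counting(self, tiny_phantom, fast_ukf):
        from dataclasses import replace
        cfg = replace(fast_ukf, seeds_per_voxel=3)
        ts = track(tiny_phantom.dwi, tiny_phantom.masks["end_seed"], cfg)
        nvox = int(tiny_phantom.masks["end_seed"].sum())
        assert ts.meta["counts"]["seeds"] == 3 * nvox
        assert len(ts) <= 3 * nvox

    def test_min_ga_monotone_stopping(self, tiny_phantom, fast_ukf):
        """Raising the GA stopping threshold never lengthens the bundle."""
        from dataclasses import replace
        ga_map = u.scalar_maps(tiny_phantom.dwi)["GA"]
        lo, hi = np.quantile(ga_map[ga_map > 0], [0.2, 0.9])
        totals, counts = [], []
        for thr in (0.0, float(lo), float((lo + hi) / 2), float(hi)):
            cfg = replace(fast_ukf, min_ga=thr)
            ts = track(tiny_phantom.dwi, tiny_phantom.masks["end_seed"], cfg)
            stats = u.length_stats(ts)
            totals.append(stats["total_mm"])
            counts.append(stats["count"])
        assert totals == sorted(totals, reverse=True)
        assert counts == sorted(counts, reverse=True)

    def test_model_nesting_2T_matches_1T(self, uniform_phantom):
        """On single-tensor data the two-tensor tracker follows the same
        trajectories as the single-tensor tracker."""
        seeds = np.zeros(uniform_phantom.dwi.shape3, dtype=bool)
        seeds[2, 6, 6] = True
        bundles = {}
        for model in ("1T", "2T"):
            cfg = u.UKFConfig(model=model, step_mm=0.6, max_steps=200,
                              min_length_mm=5.0, rng_seed=1)
            bundles[model] = track(uniform_phantom.dwi_clean, seeds, cfg)
        f1, f2 = bundles["1T"].fibers[0], bundles["2T"].fibers[0]
        n = min(len(f1), len(f2))
        d1 = np.diff(f1.points[:n], axis=0)
        d2 = np.diff(f2.points[:n], axis=0)
        cos = np.sum(d1 * d2, axis=1) / (
            np.linalg.norm(d1, axis=1) * np.linalg.norm(d2, axis=1))
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))).max() < 2.0
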