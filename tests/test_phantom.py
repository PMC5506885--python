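"""Synthetic edema phantom: omega profile, signal model, noise, assembly."""

import numpy as np
import pytest
from scipy import stats

import ukftract as u
from ukftract.phantom import (add_rician_noise, build_phantom,
                              hemisphere_directions, omega_profile,
                              simulate_signal)


class TestOmegaProfile:
    def test_endpoints_and_midpoint(self, tiny_spec):
        assert omega_profile(0.0, tiny_spec) == 0.0
        assert omega_profile(1.0, tiny_spec) == 0.0
        assert omega_profile(0.5, tiny_spec) == pytest.approx(0.65)

    def test_symmetry_and_monotonicity(self, tiny_spec):
        t = np.linspace(0.0, 0.5, 101)
        w = omega_profile(t, tiny_spec)
        np.testing.assert_allclose(w, omega_profile(1.0 - t, tiny_spec),
                                   atol=1e-15)
        assert np.all(np.diff(w) >= 0)
        assert omega_profile(0.25, tiny_spec) == pytest.approx(
            omega_profile(0.75, tiny_spec))
        assert 0 < omega_profile(0.25, tiny_spec) < 0.65

    def test_linear_shape(self):
        spec = u.PhantomSpec(omega_shape="linear", edema_extent=0.5)
        assert omega_profile(0.375, spec) == pytest.approx(0.325)
        assert omega_profile(0.2, spec) == 0.0

    def test_domain_error(self, tiny_spec):
        with pytest.raises(ValueError):
            omega_profile(1.2, tiny_spec)


class TestSimulateSignal:
    def test_hand_values_at_center(self):
        spec = u.PhantomSpec()
        par = np.array([[1.0, 0, 0]])
        perp = np.array([[0, 1.0, 0]])
        assert simulate_signal(0.65, par, spec)[0] == pytest.approx(0.14887,
                                                                    abs=1e-5)
        assert simulate_signal(0.65, perp, spec)[0] == pytest.approx(0.25553,
                                                                     abs=1e-5)

    def test_omega_zero_is_pure_tensor(self, directions21):
        spec = u.PhantomSpec()
        s = simulate_signal(0.0, directions21, spec)
        adc = 450e-6 + 650e-6 * (directions21 @ [1.0, 0, 0]) ** 2
        np.testing.assert_allclose(s, np.exp(-1000.0 * adc), rtol=1e-12)

    def test_signals_in_unit_interval(self, directions21):
        spec = u.PhantomSpec()
        for w in (0.0, 0.3, 0.65, 0.99):
            s = simulate_signal(w, directions21, spec)
            assert np.all((s > 0) & (s <= 1))

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError):
            simulate_signal(0.1, np.array([[2.0, 0, 0]]), u.PhantomSpec())


class TestRicianNoise:
    def test_mean_matches_rician_oracle(self):
        rng = np.random.default_rng(11)
        s = add_rician_noise(np.ones(10**6), snr=15.0, rng=rng)
        oracle = stats.rice(b=15.0, scale=1.0 / 15.0)
        se = oracle.std() / 1000.0
        assert s.mean() == pytest.approx(oracle.mean(), abs=3 * se)

    def test_std_matches_rician_oracle(self):
        rng = np.random.default_rng(12)
        s = add_rician_noise(np.full(10**5, 0.4), snr=15.0, rng=rng)
        oracle = stats.rice(b=15.0, scale=0.4 / 15.0)
        # sd of the sample sd ~ sd / sqrt(2(n-1))
        se = oracle.std() / np.sqrt(2 * (10**5 - 1))
        assert s.std() == pytest.approx(oracle.std(), abs=3 * se)

    def test_zero_signal_stays_zero(self):
        rng = np.random.default_rng(0)
        assert add_rician_noise(0.0, snr=15.0, rng=rng) == 0.0

    def test_deterministic_under_fixed_seed(self):
        a = add_rician_noise(np.linspace(0, 1, 100), 15.0,
                             np.random.default_rng(5))
        b = add_rician_noise(np.linspace(0, 1, 100), 15.0,
                             np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_nonnegative(self):
        rng = np.random.default_rng(1)
        s = add_rician_noise(np.full(1000, 0.01), snr=1.0, rng=rng)
        assert np.all(s >= 0)

    def test_bad_snr(self):
        with pytest.raises(ValueError):
            add_rician_noise(1.0, snr=0.0, rng=np.random.default_rng(0))


class TestHemisphereDirections:
    def test_unit_hemisphere_distinct(self):
        p = hemisphere_directions(81)
        np.testing.assert_allclose(np.linalg.norm(p, axis=1), 1.0, atol=1e-12)
        assert np.all(p[:, 2] >= 0)
        # pairwise angular separation (including antipodes) stays reasonable
        dots = np.abs(p @ p.T)
        np.fill_diagonal(dots, 0.0)
        assert np.degrees(np.arccos(dots.max())) > 8.0

    def test_deterministic(self):
        np.testing.assert_array_equal(hemisphere_directions(21),
                                      hemisphere_directions(21))


class TestBuildPhantom:
    def test_grid_and_baseline(self, tiny_phantom, tiny_spec):
        assert tiny_phantom.dwi.data.shape == (30, 8, 8, 22)
        np.testing.assert_array_equal(tiny_phantom.dwi_clean.data[..., 0], 1.0)

    def test_clean_signals_in_unit_interval(self, tiny_phantom):
        s = tiny_phantom.dwi_clean.data[..., 1:]
        assert np.all((s > 0) & (s <= 1))

    def test_omega_map_symmetric_and_bounded(self, tiny_phantom, tiny_spec):
        w = tiny_phantom.omega_map
        np.testing.assert_array_equal(w, w[::-1])
        assert w.min() >= 0.0
        assert w.max() <= tiny_spec.omega_max + 1e-15

    def test_masks(self, tiny_phantom):
        m = tiny_phantom.masks
        assert m["phantom"].all()
        assert not (m["end_seed"] & m["far_target"]).any()
        assert not (m["end_seed"] & m["edema"]).any()
        assert m["edema"].any() and m["center_seed"].any()
        # the edematous core is centred, away from both seed/target slabs
        assert (m["center_seed"] & m["edema"]).sum() == m["center_seed"].sum()

    def test_noise_reproducible(self, tiny_spec):
        a = build_phantom(tiny_spec)
        b = build_phantom(tiny_spec)
        np.testing.assert_array_equal(a.dwi.data, b.dwi.data)

    def test_uniform_phantom_constant_fa(self, uniform_phantom):
        maps = u.scalar_maps(uniform_phantom.dwi_clean,
                             uniform_phantom.masks["phantom"])
        np.testing.assert_allclose(maps["FA"], 0.51148, atol=1e-5)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            u.PhantomSpec(omega_max=1.0)
        with pytest.raises(ValueError):
            u.PhantomSpec(lambda1=300e-6, lambda23=450e-6)
        with pytest.raises(ValueError):
            u.PhantomSpec(dims_mm=(0.0, 110.0, 110.0))

    def test_noise_level_on_volume(self, tiny_phantom):
        """Empirical noise std across the volume matches sigma = S/15."""
        clean = tiny_phantom.dwi_clean.data[..., 1:]
        noisy = tiny_phantom.dwi.data[..., 1:]
        ratio = noisy / clean
        # At SNR 15 the Rician sd of S'/S is close to 1/15 with a small
        # correction; compare against the distribution oracle.
        oracle = stats.rice(b=15.0, scale=1.0 / 15.0)
        n = ratio.size
        se = oracle.std() / np.sqrt(2 * (n - 1))
        assert ratio.std() == pytest.approx(oracle.std(), abs=6 * se)
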