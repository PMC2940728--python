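"""Synthetic generators: determinism, stationary statistics, ground truth."""

import numpy as np
import pytest

import difftrace as dt
from difftrace.coords import all_pairs, pair_distances
from difftrace.profiles import histogram_profile
from difftrace.sim import (IntegrationInstabilityError, quartic_potential,
                           hysteresis_transition_count, toy_structures,
                           _fgn_cholesky)


class TestDoubleWell:
    def test_seed_determinism(self):
        cfg = dt.DoubleWellConfig(n_steps=20_000, seed=5)
        a = dt.simulate_doublewell(cfg)
        b = dt.simulate_doublewell(cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_free_diffusion_increment_variance(self):
        """Flat potential: Var of lag-tau increments = 2 D tau within 5%."""
        cfg = dt.DoubleWellConfig(barrier_height=0.0, diffusion_coeff=1.0,
                                  n_steps=1_000_000, dt_integrate=1e-3,
                                  save_stride=10, seed=1)
        s = dt.simulate_doublewell(cfg)
        for lag in (1, 4, 16):
            tau = lag * s.dt
            var = np.var(s.values[lag:] - s.values[:-lag])
            assert var == pytest.approx(2 * tau, rel=0.05)

    def test_boltzmann_density(self, doublewell_series):
        """Empirical density matches exp(-U) within 5% of the mode."""
        s = doublewell_series
        h = histogram_profile(s, 60)
        x = h.midpoints
        target = np.exp(-quartic_potential(x, 4.0, 2.0))
        target /= np.trapezoid(target, x)
        assert np.abs(h.density - target).max() < 0.06 * target.max()

    def test_frame_spacing_recorded(self):
        cfg = dt.DoubleWellConfig(n_steps=1000, dt_integrate=1e-3, save_stride=5)
        s = dt.simulate_doublewell(cfg)
        assert s.dt == pytest.approx(5e-3)

    def test_unstable_dt_rejected_at_construction(self):
        with pytest.raises(ValueError, match="dt_integrate"):
            dt.DoubleWellConfig(barrier_height=50.0, dt_integrate=0.05)

    def test_divergence_names_step(self):
        # shallow well + large D: noise escapes |y| > 10 L and the quartic
        # tail then makes the Euler step genuinely unstable
        # D*dt just under the construction bound: the Euler step is stable
        # inside |y| <= L but oscillates divergently at the thermal amplitude
        # of this ultra-soft quartic (~5 L), tripping the escape guard
        cfg = dt.DoubleWellConfig(barrier_height=0.002, diffusion_coeff=4000.0,
                                  n_steps=100_000, dt_integrate=1e-3,
                                  save_stride=10, seed=0)
        with pytest.raises(IntegrationInstabilityError, match="step"):
            dt.simulate_doublewell(cfg)


class TestFbm:
    def test_seed_determinism(self):
        cfg = dt.FbmConfig(hurst=0.3, n_steps=512, seed=9)
        np.testing.assert_array_equal(dt.simulate_fbm(cfg).values,
                                      dt.simulate_fbm(cfg).values)

    def test_brownian_limit_increments_uncorrelated(self):
        s = dt.simulate_fbm(dt.FbmConfig(hurst=0.5, n_steps=2 ** 15, seed=3))
        inc = np.diff(s.values)
        r1 = np.corrcoef(inc[:-1], inc[1:])[0, 1]
        assert abs(r1) < 3 / np.sqrt(inc.size)

    def test_terminal_variance_scaling(self):
        """Var(B_n) ~ n^{2H}: ratio within [0.8, 1.2] across 50 seeds."""
        n, hurst = 2048, 0.25
        finals = [dt.simulate_fbm(dt.FbmConfig(hurst=hurst, n_steps=n,
                                               seed=sd)).values[-1]
                  for sd in range(50)]
        ratio = np.var(finals) / n ** (2 * hurst)
        assert 0.8 < ratio < 1.2

    def test_covariance_matches_closed_form(self):
        """n = 8: empirical covariance vs closed form, entrywise 3 SE."""
        n, hurst = 8, 0.3
        n_rep = 20_000
        samples = np.array([dt.simulate_fbm(
            dt.FbmConfig(hurst=hurst, n_steps=n, seed=sd)).values[1:]
            for sd in range(n_rep)])
        emp = samples.T @ samples / n_rep
        t = np.arange(1, n + 1, dtype=float)
        lag = np.abs(t[:, None] - t[None, :])
        h2 = 2 * hurst
        true = 0.5 * (t[:, None] ** h2 + t[None, :] ** h2 - lag ** h2)
        # SE of a covariance entry ~ sqrt((c_ii c_jj + c_ij^2) / n)
        se = np.sqrt((np.outer(np.diag(true), np.diag(true)) + true ** 2) / n_rep)
        assert np.all(np.abs(emp - true) < 3.5 * se)

    def test_dense_fallback_agrees_with_circulant_in_law(self):
        """Cholesky fallback gives the same marginal scale as the FFT path."""
        rng1 = np.random.default_rng(0)
        x = np.array([_fgn_cholesky(64, 0.35, np.random.default_rng(s))
                      for s in range(2000)])
        assert np.var(x[:, 0]) == pytest.approx(1.0, rel=0.1)

    def test_increment_variance_scaling_exponent(self):
        """Var of lag-tau increments ~ tau^{2H}, fitted within 0.05."""
        hurst = 0.4
        s = dt.simulate_fbm(dt.FbmConfig(hurst=hurst, n_steps=2 ** 17, seed=2))
        taus = np.array([1, 2, 4, 8])
        var = [np.var(s.values[t:] - s.values[:-t]) for t in taus]
        slope = np.polyfit(np.log(taus), np.log(var), 1)[0]
        assert abs(slope - 2 * hurst) < 0.05

    def test_bad_hurst_rejected(self):
        with pytest.raises(ValueError):
            dt.FbmConfig(hurst=1.2, n_steps=100)


class TestTwoStateAtoms:
    def test_noiseless_pinned_latent_reproduces_struct_a(self):
        a, b = toy_structures()
        latent = dt.DoubleWellConfig(barrier_height=8.0, n_steps=20_000,
                                     dt_integrate=1e-4, save_stride=10, seed=1)
        cfg = dt.TwoStateAtomsConfig(struct_a=a, struct_b=b, latent=latent,
                                     switch_width=1e-3, noise_amp=0.0, seed=0)
        traj, s = dt.simulate_two_state_atoms(cfg)
        # the latent never leaves the left well, so sigma is exactly 0 at
        # this switch width and every frame is struct_a
        assert np.all(s.values < -0.3)
        np.testing.assert_allclose(
            traj.coords, np.broadcast_to(a, traj.coords.shape), atol=1e-9)

    def test_noiseless_distances_perfectly_correlated_with_sigma(self):
        a, b = toy_structures()
        latent = dt.DoubleWellConfig(barrier_height=1.0, n_steps=100_000,
                                     dt_integrate=1e-3, save_stride=10, seed=3)
        cfg = dt.TwoStateAtomsConfig(struct_a=a, struct_b=b, latent=latent,
                                     noise_amp=0.0, seed=0)
        traj, s = dt.simulate_two_state_atoms(cfg)
        from scipy.stats import spearmanr
        sigma = 1 / (1 + np.exp(-s.values / cfg.switch_width))
        d = pair_distances(traj, all_pairs(8))
        sub = slice(None, None, 10)      # rank correlation on a thinned set
        for col in d.T:
            r = spearmanr(col[sub], sigma[sub]).statistic
            assert abs(abs(r) - 1.0) < 1e-6

    def test_discriminating_pair_tracks_latent_crossings(self, twostate):
        """Crossings counted on the best pair distance match the latent
        ground truth within 25%."""
        traj, latent = twostate
        a, b = toy_structures()
        pairs = all_pairs(8)
        delta = [abs(np.linalg.norm(a[i] - a[j]) - np.linalg.norm(b[i] - b[j]))
                 for i, j in pairs]
        best = pairs[int(np.argmax(delta))]
        d = pair_distances(traj, [best])[:, 0]
        true = hysteresis_transition_count(latent.values, -0.5, 0.5)
        lo, hi = np.quantile(d, [0.15, 0.85])
        got = hysteresis_transition_count(d, lo, hi)
        assert true > 10
        assert abs(got - true) <= 0.25 * true

    def test_mismatched_structures_rejected(self):
        a, b = toy_structures()
        with pytest.raises(ValueError):
            dt.TwoStateAtomsConfig(struct_a=a, struct_b=b[:5])

    def test_determinism(self):
        latent = dt.DoubleWellConfig(barrier_height=2.0, n_steps=5000,
                                     dt_integrate=1e-3, save_stride=10, seed=2)
        cfg = dt.TwoStateAtomsConfig(latent=latent, noise_amp=0.3, seed=9)
        t1, s1 = dt.simulate_two_state_atoms(cfg)
        t2, s2 = dt.simulate_two_state_atoms(cfg)
        np.testing.assert_array_equal(t1.coords, t2.coords)
        np.testing.assert_array_equal(s1.values, s2.values)


class TestToyStructures:
    def test_distance_change_span(self):
        a, b = toy_structures()
        pairs = all_pairs(8)
        dd = [abs(np.linalg.norm(a[i] - a[j]) - np.linalg.norm(b[i] - b[j]))
              for i, j in pairs]
        assert min(dd) > 3.0 and max(dd) < 12.0

    def test_mutual_information_rank_property(self):
        """The most A/B-discriminating pair carries the strongest dependence
        on the latent state (noiseless case, rank by |corr|)."""
        a, b = toy_structures()
        latent = dt.DoubleWellConfig(barrier_height=2.0, n_steps=200_000,
                                     dt_integrate=1e-3, save_stride=10, seed=4)
        cfg = dt.TwoStateAtomsConfig(struct_a=a, struct_b=b, latent=latent,
                                     noise_amp=0.5, noise_corr_time=5.0, seed=1)
        traj, s = dt.simulate_two_state_atoms(cfg)
        sigma = 1 / (1 + np.exp(-s.values / cfg.switch_width))
        pairs = all_pairs(8)
        d = pair_distances(traj, pairs)
        corr = [abs(np.corrcoef(d[:, k], sigma)[0, 1]) for k in range(len(pairs))]
        delta = [abs(np.linalg.norm(a[i] - a[j]) - np.linalg.norm(b[i] - b[j]))
                 for i, j in pairs]
        # the top-delta pair must sit in the top tier of dependence
        assert corr[int(np.argmax(delta))] > 0.95 * max(corr)


def test_hysteresis_count_telegraph():
    v = np.array([0, 0, 1, 1, 0, 1, 0, 0, 1], float)
    assert hysteresis_transition_count(v, 0.25, 0.75) == 5
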