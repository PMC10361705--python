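import numpy as np
import pytest

from mbrot import landscape as ls
from mbrot import toy_systems


class TestFreeEnergy:
    def test_uniform_samples_flat_profile(self):
        samples = np.concatenate([np.full(500, 0.25), np.full(500, 0.75)])
        profile = ls.free_energy(samples, bins=[0.0, 0.5, 1.0])
        assert profile.values[0] == pytest.approx(profile.values[1])

    def test_log_ratio_identity(self):
        """Bins with population ratio 1:e differ by exactly 1 k_B T."""
        n = 10000
        samples = np.concatenate(
            [np.full(n, 0.25), np.full(int(round(n / np.e)), 0.75)]
        )
        profile = ls.free_energy(samples, bins=[0.0, 0.5, 1.0])
        assert profile.values[1] - profile.values[0] == pytest.approx(1.0, abs=1e-3)

    def test_empty_bins_are_nan(self):
        profile = ls.free_energy(np.array([0.1, 0.9]), bins=[0, 0.25, 0.5, 0.75, 1.0])
        assert np.isnan(profile.values[1])
        assert np.isnan(profile.values[2])
        assert np.nanmin(profile.values) == 0.0

    def test_recovers_generator_ground_truth(self, double_well_run):
        """Histogram free energy of the Brownian fixture matches the analytic
        landscape on well-sampled bins."""
        profile = ls.free_energy(double_well_run.coordinate, bins=40)
        centers = profile.centers()
        truth = toy_systems.analytic_free_energy(double_well_run.spec, centers)
        good = profile.counts > 500
        # align offsets on the sampled region, then compare shapes
        diff = profile.values[good] - truth[good]
        assert np.std(diff) < 0.25
        assert np.max(np.abs(diff - diff.mean())) < 0.6


class TestTransitionPaths:
    def test_confined_series_has_no_paths(self, basin_states):
        series = np.full(2000, -1.0) + 0.05 * np.sin(np.arange(2000))
        stats = ls.transition_path_probability(series, basin_states, bins=10,
                                               min_samples_per_bin=1)
        assert stats.n_transitions == 0
        assert stats.segments == []
        occupied = stats.counts > 0
        assert np.all(stats.p_tp[occupied] == 0.0)

    def test_monotone_sweep_is_all_transition_path(self, basin_states):
        series = np.linspace(-1.0, 1.0, 400)
        stats = ls.transition_path_probability(series, basin_states, bins=20,
                                               min_samples_per_bin=1)
        assert stats.n_transitions == 1
        centers = 0.5 * (stats.bin_edges[:-1] + stats.bin_edges[1:])
        strictly_between = (centers > -0.8) & (centers < 0.8)
        assert np.all(stats.p_tp[strictly_between] == 1.0)

    def test_failed_excursion_is_not_a_path(self, basin_states):
        """Leaving a state and returning to it does not count as a
        transition path."""
        series = np.array([-1.0, -0.5, 0.0, -0.5, -1.0, 0.0, 0.5, 1.0])
        stats = ls.transition_path_probability(series, basin_states, bins=8,
                                               min_samples_per_bin=1)
        assert stats.n_transitions == 1
        # the first excursion (indices 1-3) returned to the left basin
        tp_frames = {f for a, b in stats.segments for f in range(a, b + 1)}
        assert tp_frames == {5, 6}

    def test_diffusive_peak_near_half(self, double_well_run, basin_states):
        stats = ls.transition_path_probability(
            double_well_run.coordinate, basin_states, bins=40,
            min_samples_per_bin=50,
        )
        assert stats.n_transitions > 20
        # a few dozen crossings locate the peak only roughly; the tight
        # +/-0.05 check runs on the long fixture in the acceptance suite
        assert 0.3 < stats.peak_value < 0.7

    def test_corrupted_coordinate_lowers_peak(self, double_well_run, basin_states):
        """Mixing an orthogonal noise dimension into the coordinate degrades
        the transition-path peak."""
        x = double_well_run.coordinate
        rng = np.random.default_rng(0)
        corrupted = 0.55 * x + 0.45 * rng.normal(0.0, 1.0, len(x))
        good = ls.transition_path_probability(x, basin_states, bins=40)
        states_c = ls.StateDefinition(unrotated=(-1.2, -0.8), rotated=(0.8, 1.2))
        bad = ls.transition_path_probability(corrupted, states_c, bins=40)
        assert bad.peak_value < good.peak_value


class TestDiffusionInference:
    def test_flat_landscape_recovers_d(self, flat_run):
        x = flat_run.coordinate
        profile = ls.free_energy(x, bins=40)
        model = ls.infer_diffusion(
            x, profile, lag=0.1, frame_interval=flat_run.frame_interval
        )
        assert model.D == pytest.approx(flat_run.spec.d0, rel=0.10)

    def test_lag_consistency(self, flat_run):
        x = flat_run.coordinate
        profile = ls.free_energy(x, bins=40)
        d1 = ls.infer_diffusion(x, profile, 0.1, flat_run.frame_interval).D
        d2 = ls.infer_diffusion(x, profile, 0.2, flat_run.frame_interval).D
        assert d1 == pytest.approx(d2, rel=0.15)

    def test_double_well_recovers_d(self, double_well_run):
        x = double_well_run.coordinate
        profile = ls.free_energy(x, bins=30)
        model = ls.infer_diffusion(
            x, profile, lag=0.1, frame_interval=double_well_run.frame_interval
        )
        assert model.D == pytest.approx(double_well_run.spec.d0, rel=0.15)

    def test_lag_below_frame_interval_errors(self, flat_run):
        profile = ls.free_energy(flat_run.coordinate, bins=10)
        with pytest.raises(ls.LandscapeError, match="lag"):
            ls.infer_diffusion(
                flat_run.coordinate, profile, flat_run.frame_interval / 10,
                flat_run.frame_interval,
            )


def _analytic_profile(f_of_x, lo, hi, n_bins=200, temperature=1.0):
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    values = f_of_x(centers)
    values = values - values.min()
    return ls.FreeEnergyProfile(
        bin_edges=[edges], values=values, counts=np.ones(n_bins),
        temperature=temperature,
    )


class TestMFPT:
    def test_flat_landscape_analytic(self):
        """With flat F and constant D, <tau> from 0 to L with a reflecting
        lower bound is L^2 / 2D."""
        profile = _analytic_profile(lambda x: np.zeros_like(x), 0.0, 2.0)
        model = ls.DiffusionModel(D=0.5)
        tau = ls.mfpt_from_profile(profile, model, 0.0, 2.0, 0.0)
        assert tau == pytest.approx(2.0**2 / (2 * 0.5), rel=1e-3)

    def test_kramers_high_barrier_limit(self):
        """A deep double well reproduces the overdamped Kramers closed form
        within 10%."""
        barrier = 8.0
        f = lambda x: barrier * (x**2 - 1.0) ** 2  # noqa: E731
        profile = _analytic_profile(f, -1.6, 1.6, n_bins=800)
        model = ls.DiffusionModel(D=1.0)
        tau = ls.mfpt_from_profile(profile, model, -1.0, 1.0, -1.6)
        omega_min = np.sqrt(8.0 * barrier)
        omega_top = np.sqrt(4.0 * barrier)
        tau_kramers = 2.0 * np.pi / (omega_min * omega_top) * np.exp(barrier)
        assert tau == pytest.approx(tau_kramers, rel=0.10)

    def test_monotone_in_barrier_height(self):
        model = ls.DiffusionModel(D=1.0)
        taus = []
        for barrier in (2.0, 4.0, 6.0):
            profile = _analytic_profile(
                lambda x, b=barrier: b * (x**2 - 1.0) ** 2, -1.5, 1.5, 400
            )
            taus.append(ls.mfpt_from_profile(profile, model, -1.0, 1.0, -1.5))
        assert taus[0] < taus[1] < taus[2]

    def test_variants_agree_for_uniform_d(self):
        profile = _analytic_profile(lambda x: 3.0 * (x**2 - 1.0) ** 2, -1.5, 1.5, 400)
        model = ls.DiffusionModel(D=2.0)
        outer = ls.mfpt_from_profile(profile, model, -1.0, 1.0, -1.5, variant="outer")
        inner = ls.mfpt_from_profile(profile, model, -1.0, 1.0, -1.5, variant="inner")
        assert outer == pytest.approx(inner, rel=1e-12)


class TestRateConversion:
    def test_zero_barrier_is_inverse_attempt_frequency(self):
        assert ls.rate_from_barrier(0.0, 4.0) == pytest.approx(0.25)

    def test_seven_kbt_barrier(self):
        assert ls.rate_from_barrier(7.0, 1.0) == pytest.approx(np.exp(7.0))

    def test_doubling_barrier_squares_boltzmann_factor(self):
        c = 2.0
        t1 = ls.rate_from_barrier(3.0, c) * c
        t2 = ls.rate_from_barrier(6.0, c) * c
        assert t2 == pytest.approx(t1**2, rel=1e-12)

    def test_endpoint_stabilization_arithmetic(self):
        """500 unique contacts x 0.2 r.u. x 2% x (2 k_B T / r.u.) = 4 k_B T."""
        assert ls.contact_strength_perturbation() == pytest.approx(4.0, abs=1e-12)


class TestFEP:
    def test_identity_at_same_temperature(self, double_well_run):
        x = double_well_run.coordinate[:50000]
        u = double_well_run.potential_energy[:50000]
        weights, ess = ls.fep_weights(u, 1.0, 1.0)
        assert np.all(weights == 1.0)
        assert ess == pytest.approx(len(u))
        reweighted, _ = ls.fep_reweight(x, u, 1.0, 1.0, bins=20)
        direct = ls.free_energy(x, bins=20)
        np.testing.assert_allclose(reweighted.values, direct.values, atol=1e-12)

    def test_two_level_system_closed_form(self):
        """Discrete two-level reweighting reproduces the analytic Boltzmann
        ratio at the new temperature exactly."""
        e1, e2, t0, tp = 0.0, 1.0, 1.0, 1.02
        n1, n2 = 6000, int(round(6000 * np.exp(-(e2 - e1) / t0)))
        series = np.concatenate([np.zeros(n1), np.ones(n2)])
        u = np.concatenate([np.full(n1, e1), np.full(n2, e2)])
        weights, _ = ls.fep_weights(u, t0, tp)
        p1 = weights[series == 0].sum()
        p2 = weights[series == 1].sum()
        expected = (n2 / n1) * np.exp(-(e2 - e1) * (1 / tp - 1 / t0))
        assert p2 / p1 == pytest.approx(expected, rel=1e-12)

    def test_large_shift_refused_unless_forced(self):
        x = np.linspace(-1, 1, 100)
        u = x**2
        with pytest.raises(ls.LandscapeError, match="bound"):
            ls.fep_reweight(x, u, 1.0, 1.1, bins=10)
        profile, diag = ls.fep_reweight(x, u, 1.0, 1.1, bins=10, force=True)
        assert diag["relative_shift"] == pytest.approx(0.1)


class TestDeltaF:
    def test_equal_populations_zero(self, basin_states):
        series = np.concatenate([np.full(5000, -1.0), np.full(5000, 1.0)])
        df, err = ls.delta_f_ensembles(series, basin_states, n_blocks=5)
        assert df == pytest.approx(0.0, abs=1e-12)

    def test_log_ratio_identity(self, basin_states):
        n_rot = 1000
        n_unrot = int(round(1000 * np.e))
        series = np.concatenate([np.full(n_unrot, -1.0), np.full(n_rot, 1.0)])
        df, _ = ls.delta_f_ensembles(series, basin_states, n_blocks=4)
        assert df == pytest.approx(np.log(n_unrot / n_rot), abs=1e-12)

    def test_designed_seventy_thirty_split(self, basin_states):
        """A noisy series engineered to spend 70/30 in the two windows gives
        dF = ln(70/30) within the bootstrap error."""
        rng = np.random.default_rng(9)
        n = 20000
        labels = rng.random(n) < 0.7
        series = np.where(labels, -1.0, 1.0) + rng.normal(0.0, 0.1, n)
        df, err = ls.delta_f_ensembles(series, basin_states, n_blocks=20)
        assert df == pytest.approx(np.log(0.7 / 0.3), abs=max(3 * err, 0.1))

    def test_empty_window_errors(self, basin_states):
        series = np.full(100, -1.0)
        with pytest.raises(ls.LandscapeError, match="window"):
            ls.delta_f_ensembles(series, basin_states)
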