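"""Synthetic generators: Matsuoka network, spiral population, nerve, perturbations."""

import numpy as np
import pytest

from spiralscope.errors import IntegrationError, ParameterError
from spiralscope.synth import (
    LatentSpiralParams,
    MatsuokaParams,
    generate_nerve_output,
    generate_spiral_population,
    inject_perturbation,
    mutual_inhibition_weights,
    simulate_matsuoka,
    spiral_trajectory,
)


class TestMatsuoka:
    def test_uncoupled_neuron_converges_to_closed_form(self):
        """Equilibrium of a single neuron with r = a > 0 is r* = c / (1 + gamma)."""
        for c, gamma in [(3.0, 2.0), (1.0, 0.0), (5.0, 4.0), (0.5, 1.5)]:
            p = MatsuokaParams(W=np.zeros((1, 1)), c=c, gamma=gamma)
            tr = simulate_matsuoka(p, 5.0, dt=0.001)
            assert abs(tr.r[-1, 0] - c / (1 + gamma)) < 1e-3

    def test_coupled_network_oscillates_sustained(self):
        """Mutual inhibition + adaptation yields a non-decaying alternating rhythm."""
        tr = simulate_matsuoka(MatsuokaParams(), 30.0, dt=0.001)
        half = tr.r[len(tr.r) // 2 :]
        assert half.max() > 1.0
        # each neuron's rate crosses (near-)zero: alternation
        assert np.all(half.min(axis=0) < 0.05)
        # cycle-peak amplitudes stable: CV of peaks < 5% over the last half
        r0 = half[:, 0]
        peaks = r0[1:-1][(r0[1:-1] > r0[:-2]) & (r0[1:-1] > r0[2:]) & (r0[1:-1] > 0.5)]
        assert peaks.size > 10
        assert peaks.std() / peaks.mean() < 0.05

    def test_dt_halving_convergence(self):
        tr1 = simulate_matsuoka(MatsuokaParams(), 10.0, dt=0.002)
        tr2 = simulate_matsuoka(MatsuokaParams(), 10.0, dt=0.001)
        m1 = tr1.r[-int(1 / 0.002) :].mean(axis=0)
        m2 = tr2.r[-int(1 / 0.001) :].mean(axis=0)
        assert np.all(np.abs(m1 - m2) / np.maximum(m2, 1e-9) < 0.01)

    def test_decaying_drive_shrinks_amplitude_not_period(self):
        """Fine-step reference: zero-crossing interval stays within 10% as c decays."""
        const = simulate_matsuoka(MatsuokaParams(), 20.0, dt=0.001)

        def ramp(t):
            return np.full(3, 3.0 * max(0.0, 1.0 - t / 40.0))

        dec = simulate_matsuoka(MatsuokaParams(c=ramp), 20.0, dt=0.001)
        dec_fine = simulate_matsuoka(MatsuokaParams(c=ramp), 20.0, dt=0.0001)

        def up_crossings(r, dt, thresh=0.05):
            x = r[int(5 / dt) :, 0]
            up = np.flatnonzero((x[:-1] <= thresh) & (x[1:] > thresh))
            return np.diff(up) * dt

        iv_const = np.median(up_crossings(const.r, 0.001))
        iv_dec = np.median(up_crossings(dec.r, 0.001))
        iv_fine = np.median(up_crossings(dec_fine.r, 0.0001))
        assert abs(iv_dec - iv_const) / iv_const < 0.10
        assert abs(iv_dec - iv_fine) / iv_fine < 0.02  # integrator consistency
        # amplitude decays
        early = dec.r[int(5 / 0.001) : int(10 / 0.001), 0].max()
        late = dec.r[int(15 / 0.001) :, 0].max()
        assert late < early

    def test_divergence_reported_with_time(self):
        p = MatsuokaParams(W=np.zeros((1, 1)), c=lambda t: np.array([np.inf]))
        with pytest.raises(IntegrationError) as exc:
            simulate_matsuoka(p, 1.0, dt=0.001)
        assert exc.value.t_fail is not None

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            MatsuokaParams(W=np.array([[0.0, 1.0], [-1.0, 0.0]]))  # excitatory
        with pytest.raises(ParameterError):
            mutual_inhibition_weights(3, w=0.5)
        with pytest.raises(ParameterError):
            simulate_matsuoka(MatsuokaParams(), 1.0, dt=0.1)  # dt > tau_a/5


class TestSpiralPopulation:
    def test_baseline_only_poisson_count(self):
        """Gains all 0: the spike count follows Poisson statistics (99.7% interval)."""
        params = LatentSpiralParams(
            n_neurons=2, baseline_rate=10.0, gains=np.zeros(2), phases=np.zeros(2),
            pre_s=0.0, post_s=100.0, transient=0.0, seed=5,
        )
        spikes, _ = generate_spiral_population(params)
        n = spikes.spikes[0].size
        assert abs(n - 1000) <= 3 * np.sqrt(1000)

    def test_zero_intensity_zero_spikes(self):
        params = LatentSpiralParams(
            n_neurons=2, baseline_rate=0.0, gains=np.zeros(2), phases=np.zeros(2),
            seed=1,
        )
        spikes, _ = generate_spiral_population(params)
        assert spikes.total_spikes() == 0

    def test_ground_truth_by_construction(self):
        params = LatentSpiralParams(period=10.0, contraction_per_s=0.98, seed=0)
        _, truth = generate_spiral_population(params)
        assert truth.true_eigen_imag[0] == pytest.approx(2 * np.pi * 0.01 / 10.0)
        assert truth.true_contraction == pytest.approx(98.0)
        assert truth.true_period == pytest.approx(2 * np.pi * 0.01 / truth.true_eigen_imag[0])
        # per-second amplitude ratio of the orbit-only envelope
        t, z = spiral_trajectory(10.0, 0.98, 95.0, dt=0.01)
        amp = np.hypot(z[:, 0], z[:, 1])
        ratios = amp[100::100] / amp[:-100:100]
        np.testing.assert_allclose(ratios, 0.98, atol=1e-9)

    def test_population_envelope_contraction(self, default_population):
        """Per-cycle amplitude ratio of the population envelope matches 0.98/s within 2%."""
        spikes, truth = default_population
        # pooled population rate in 1 s bins, post-transient
        pooled = np.concatenate(spikes.spikes)
        edges = np.arange(45.0, 125.0, 1.0)
        counts, _ = np.histogram(pooled, bins=edges)
        t_mid = edges[:-1] + 0.5
        base = spikes.n_neurons * 0.5
        log_env = np.log(np.maximum(counts - base, 1.0))
        slope = np.polyfit(t_mid, log_env, 1)[0]
        assert np.exp(slope) == pytest.approx(0.98, abs=0.02)

    def test_seed_reproducibility(self):
        a, _ = generate_spiral_population(LatentSpiralParams(n_neurons=10, seed=3))
        b, _ = generate_spiral_population(LatentSpiralParams(n_neurons=10, seed=3))
        for s, t in zip(a.spikes, b.spikes):
            np.testing.assert_array_equal(s, t)

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ParameterError):
            LatentSpiralParams(n_neurons=1)


class TestNerve:
    def test_constant_beta0_gives_homogeneous_rate(self):
        P = np.zeros((2000, 2))
        times, rate = generate_nerve_output(P, np.log(5.0), np.zeros((2, 5)), seed=2)
        assert np.allclose(rate[5:], 5.0)
        n = times.size
        expected = 5.0 * (2000 * 0.01)
        assert abs(n - expected) < 4 * np.sqrt(expected)

    def test_phase_locking_to_orbit(self):
        """Direct evaluation oracle: rate is phase-locked to the latent."""
        t, z = spiral_trajectory(10.0, 1.0, 95.0, dt=0.01)
        beta = np.zeros((2, 10))
        beta[0, :] = 2.0 / 10
        _, rate = generate_nerve_output(z, np.log(20.0), beta, seed=0)
        phase = np.arctan2(z[:, 1], z[:, 0])
        # circular correlation of log-rate with cos(phase)
        lr = np.log(rate[10:])
        c = np.corrcoef(lr, np.cos(phase[10:]))[0, 1]
        assert c > 0.9

    def test_empty_or_short_projection_rejected(self):
        with pytest.raises(ParameterError):
            generate_nerve_output(np.empty((0, 2)), 0.0, np.zeros((2, 5)))
        with pytest.raises(ParameterError):
            generate_nerve_output(np.zeros((4, 2)), 0.0, np.zeros((2, 5)))

    def test_overflow_advises_rescaling(self):
        P = np.full((100, 1), 10.0)
        with pytest.raises(ParameterError, match="rescale"):
            generate_nerve_output(P, 0.0, np.full((1, 5), 2.0))


class TestPerturbation:
    def test_full_suppression_silences_window(self, small_population):
        spikes, _ = small_population
        out = inject_perturbation(spikes, (15.0, 20.0), mode="suppress", thinning=1.0)
        for orig, new in zip(spikes.spikes, out.spikes):
            assert not np.any((new >= 15.0) & (new < 20.0))
            np.testing.assert_array_equal(new[new < 15.0], orig[orig < 15.0])
            np.testing.assert_array_equal(new[new >= 20.0], orig[orig >= 20.0])

    def test_zero_length_window_is_identity(self, small_population):
        spikes, _ = small_population
        out = inject_perturbation(spikes, (15.0, 15.0), mode="remap")
        for orig, new in zip(spikes.spikes, out.spikes):
            np.testing.assert_array_equal(orig, new)

    def test_remap_preserves_population_count(self, small_population):
        spikes, _ = small_population
        out = inject_perturbation(spikes, (15.0, 25.0), mode="remap", seed=4)
        assert out.total_spikes() == spikes.total_spikes()
        pooled_in = np.sort(np.concatenate([s[(s >= 15) & (s < 25)] for s in spikes.spikes]))
        pooled_out = np.sort(np.concatenate([s[(s >= 15) & (s < 25)] for s in out.spikes]))
        np.testing.assert_allclose(pooled_in, pooled_out)

    def test_window_outside_recording_rejected(self, small_population):
        spikes, _ = small_population
        with pytest.raises(ParameterError):
            inject_perturbation(spikes, (30.0, 100.0))
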