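"""Local linear models, attractor summary, weighted Spearman, period drift."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from spiralscope.errors import ParameterError, UndefinedStatisticError
from spiralscope.lineardyn import (
    fit_along_trajectory,
    fit_local_linear,
    period_drift,
    summarize_attractor,
    weighted_spearman,
)
from spiralscope.recurrence import (
    WindowDensity,
    detect_periodic_orbit,
    find_recurrence,
)
from spiralscope.synth import spiral_trajectory


def _linear_map_trajectory(rho, ang, T=4000, x0=(1.0, 0.0)):
    """Trajectory of the per-step map x <- M x with eigenvalues rho*exp(+-i*ang)."""
    M = rho * np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    X = np.empty((T, 2))
    X[0] = x0
    for k in range(T - 1):
        X[k + 1] = M @ X[k]
    return X, M


class TestLocalLinear:
    def test_known_map_eigenvalue_recovery(self):
        """Oracle: eigenvalues of the generating M - I, recovered within 1%."""
        rho, ang = 0.9995, 0.00628
        X, M = _linear_map_trajectory(rho, ang, T=4000)
        true = np.linalg.eigvals(M - np.eye(2))
        lam_true = true[np.argmax(true.real)]
        fit = fit_local_linear(X, anchor=2000, theta=1.0, radius_mult=1e9, min_points=100)
        assert fit.valid
        lam = fit.eigvals[np.argmax(fit.eigvals.real)]
        assert abs(lam.real - lam_true.real) <= 0.01 * abs(lam_true.real) + 1e-12
        assert abs(abs(lam.imag) - abs(lam_true.imag)) <= 0.01 * abs(lam_true.imag)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        st.floats(0.995, 0.99999), st.floats(0.002, 0.02),
    )
    def test_recovery_across_spectral_radii(self, rho, ang):
        """Per-step linear systems: (a, b) recovered within 2% (noiseless)."""
        X, M = _linear_map_trajectory(rho, ang, T=3000)
        true = np.linalg.eigvals(M - np.eye(2))
        lam_true = true[np.argmax(true.real)]
        fit = fit_local_linear(X, anchor=1500, theta=1e9, min_points=100)
        lam = fit.eigvals[np.argmax(fit.eigvals.real)]
        assert abs(lam.real - lam_true.real) <= 0.02 * max(abs(lam_true.real), 1e-6)
        assert abs(abs(lam.imag) - abs(lam_true.imag)) <= 0.02 * abs(lam_true.imag)

    def test_constant_trajectory_invalid(self):
        X = np.ones((500, 2))
        fit = fit_local_linear(X, anchor=250, theta=1.0)
        assert not fit.valid

    def test_short_neighbourhood_invalid(self):
        _, P = spiral_trajectory(10.0, 1.0, 40.0, dt=0.01)
        fit = fit_local_linear(P, anchor=2000, theta=1e-4, min_points=100)
        assert not fit.valid and fit.n_points < 100


class TestAttractorSummary:
    @pytest.fixture(scope="class")
    def latent_estimate(self):
        # mild temporally correlated radial noise, as a kernel-smoothed
        # trajectory carries; heavy noise biases the first-difference fit
        rng = np.random.default_rng(5)
        _, P = spiral_trajectory(
            10.0, 0.98, 95.0, dt=0.01, radial_noise=0.01, noise_smooth_s=0.1, rng=rng
        )
        rec = detect_periodic_orbit(find_recurrence(P, dt=0.01, scan=(0.0, 85.0)))
        anchors = np.round(rec.times[rec.dominant_mask()] / 0.01).astype(int)
        fits = fit_along_trajectory(P, anchors, rec.theta, dt=0.01)
        return summarize_attractor(fits, rec, dt=0.01)

    def test_stable_spiral_recovered(self, latent_estimate):
        est = latent_estimate
        assert est.classification == "stable_spiral"
        assert est.period_est == pytest.approx(10.0, rel=0.05)
        assert est.contraction_pct_per_s == pytest.approx(98.0, abs=0.5)
        assert est.rotation_fraction > 0.9

    def test_rotation_invariance(self):
        """Period and contraction are unchanged by an orthogonal rotation of axes."""
        rng = np.random.default_rng(6)
        _, P = spiral_trajectory(
            10.0, 0.98, 95.0, dt=0.01, radial_noise=0.01, noise_smooth_s=0.1, rng=rng
        )
        # embed in 3-D with small independent structure in the third
        # dimension (an exactly planar trajectory is rank-deficient)
        from scipy.ndimage import gaussian_filter1d

        extra = 0.02 * gaussian_filter1d(rng.standard_normal(P.shape[0]), 20)
        P3 = np.column_stack([P, extra])
        Q, _ = np.linalg.qr(np.random.default_rng(7).standard_normal((3, 3)))
        PR = P3 @ Q.T
        out = {}
        for name, traj in (("plain", P3), ("rotated", PR)):
            rec = detect_periodic_orbit(find_recurrence(traj, dt=0.01, scan=(0.0, 85.0)))
            anchors = np.round(rec.times[rec.dominant_mask()] / 0.01).astype(int)[::5]
            fits = fit_along_trajectory(traj, anchors, rec.theta, dt=0.01)
            out[name] = summarize_attractor(fits, rec, dt=0.01)
        assert out["rotated"].period_est == pytest.approx(out["plain"].period_est, rel=1e-6)
        assert out["rotated"].contraction_pct_per_s == pytest.approx(
            out["plain"].contraction_pct_per_s, abs=1e-6
        )

    def test_node_classification_when_no_rotation(self):
        """Real-eigenvalue contraction along a line -> stable node, period unset."""
        t = np.arange(6000) * 0.01
        # two distinct decay rates: a curved, full-rank planar trajectory
        X = np.column_stack([np.exp(-0.02 * t), np.exp(-0.035 * t)])
        X += 1.0  # away from origin; affine centring handles it
        from spiralscope.recurrence import RecurrenceResult, Peak

        fits = [fit_local_linear(X, k, theta=1e9, min_points=100)
                for k in range(500, 5500, 100)]
        rec = RecurrenceResult(
            theta=1.0, theta_percentile=10.0, scan_range=(0.0, 60.0),
            times=0.01 * np.arange(500, 5500), recurrent=np.ones(5000, bool),
            rec_time=np.full(5000, 6.0), dt=0.01,
            peaks=[Peak(5.0, 7.0, 5000, 6.0)], dominant=0, period=6.0,
        )
        est = summarize_attractor(fits, rec, dt=0.01)
        assert est.classification == "stable_node"
        assert est.period_est is None


class TestWeightedSpearman:
    def test_uniform_weights_reduce_to_spearman(self):
        rng = np.random.default_rng(8)
        for n in (5, 20, 100):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            rho = weighted_spearman(x, y, np.ones(n))
            assert rho == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_monotone_relation_gives_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        y = np.exp(x)
        w = np.array([2.0, 1.0, 1.0, 1.0, 1.0, 2.0])
        assert weighted_spearman(x, y, w) == pytest.approx(1.0, abs=1e-12)

    def test_six_point_hand_case(self):
        """Direct arithmetic evaluation of the weighted-correlation formula."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        w = np.array([2.0, 1.0, 1.0, 1.0, 1.0, 2.0])
        rx, ry = x, y  # already ranks
        sw = w.sum()
        mx = (w * rx).sum() / sw
        my = (w * ry).sum() / sw
        sxy = (w * (rx - mx) * (ry - my)).sum() / sw
        sxx = (w * (rx - mx) ** 2).sum() / sw
        syy = (w * (ry - my) ** 2).sum() / sw
        assert weighted_spearman(x, y, w) == pytest.approx(
            sxy / np.sqrt(sxx * syy), abs=1e-14
        )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 1000))
    def test_antisymmetry_under_reversal(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        w = rng.uniform(0.1, 2.0, 12)
        assert weighted_spearman(x, y, w) == pytest.approx(
            -weighted_spearman(x, -y, w), abs=1e-12
        )

    def test_zero_weight_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            weighted_spearman([1, 2, 3], [1, 2, 3], [0, 0, 0])
        with pytest.raises(ParameterError):
            weighted_spearman([1, 2], [1, 2], [1, 1])


def _drift_windows(delays, density=0.95, sd=0.2, t0=10.0):
    return [
        WindowDensity(win_mid=t0 + k, density=density, mean_delay=d, delay_sd=sd)
        for k, d in enumerate(delays)
    ]


class TestPeriodDrift:
    def test_monotone_slowing_detected(self):
        """Delays drifting 9 -> 11 s give rho > 0 with small p."""
        rng = np.random.default_rng(9)
        delays = np.linspace(9.0, 11.0, 40) + 0.05 * rng.standard_normal(40)
        res = period_drift(_drift_windows(delays), coalescence=10.0, n_perm=10000, seed=1)
        assert res.rho > 0.8
        assert res.p < 0.01

    def test_constant_delays_degenerate(self):
        res = period_drift(_drift_windows(np.full(20, 10.0)), coalescence=10.0,
                          n_perm=100, seed=0)
        assert res.rho == 0.0 and res.p == 1.0

    def test_zero_sd_weight_capped(self):
        delays = np.linspace(9, 10, 20)
        wins = _drift_windows(delays)
        wins[3].delay_sd = 0.0
        res = period_drift(wins, coalescence=10.0, n_perm=100, seed=0)
        assert np.all(np.isfinite(res.weights))

    def test_windows_after_last_recurrent_excluded(self):
        delays = np.concatenate([np.linspace(9, 10, 20), [30.0, 31.0]])
        wins = _drift_windows(delays)
        wins[-1].density = 0.2
        wins[-2].density = 0.2
        res = period_drift(wins, coalescence=10.0, n_perm=100, seed=0)
        assert res.n_windows == 20
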