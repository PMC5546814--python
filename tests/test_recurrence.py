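"""Recurrence detection, periodic-orbit extraction, densities, perturbations."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from spiralscope.errors import DegenerateInputError
from spiralscope.recurrence import (
    RecurrenceResult,
    WindowDensity,
    coalescence_time,
    detect_periodic_orbit,
    detect_perturbations,
    find_recurrence,
    window_density,
)
from spiralscope.synth import spiral_trajectory


def brute_force_recurrence(P, dt, i0, i1, theta):
    """O(T^2) reference: per-point forward scan with contiguous-run exclusion.

    Distances follow the same float32 squared-Euclidean convention as the
    implementation, so flag/delay agreement can be asserted exactly.
    """
    D2 = cdist(P, P, "sqeuclidean").astype(np.float32)
    th2 = np.float32(theta) ** 2
    flags = np.zeros(i1 - i0, dtype=bool)
    delays = np.full(i1 - i0, np.nan)
    for i in range(i0, i1):
        j = i + 1
        while j < len(P) and D2[i, j] <= th2:  # skip the within-theta run
            j += 1
        if j >= len(P) and i + 1 < len(P):
            continue  # never left the ball
        while j < len(P):
            if D2[i, j] <= th2:
                flags[i - i0] = True
                delays[i - i0] = (j - i) * dt
                break
            j += 1
    return flags, delays


@pytest.mark.parametrize("kind", ["circle", "noisy_spiral", "random_walk"])
def test_oracle_equivalence_on_small_instances(kind):
    """Flags and delays match the brute-force all-pairs reference exactly."""
    rng = np.random.default_rng(11)
    dt = 0.01
    if kind == "circle":
        _, P = spiral_trajectory(5.0, 1.0, 18.0, dt=dt)
    elif kind == "noisy_spiral":
        _, P = spiral_trajectory(5.0, 0.97, 18.0, dt=dt, radial_noise=0.05, rng=rng)
    else:
        P = np.cumsum(rng.standard_normal((1800, 3)), axis=0) * 0.1
    res = find_recurrence(P, dt=dt, scan=(0.0, P.shape[0] * dt - 5.0))
    i0, i1 = 0, res.recurrent.size
    flags, delays = brute_force_recurrence(P, dt, i0, i1, res.theta)
    np.testing.assert_array_equal(res.recurrent, flags)
    np.testing.assert_allclose(res.rec_time, delays, atol=1e-9)


def test_noiseless_circle_every_point_recurrent_at_period():
    _, P = spiral_trajectory(10.0, 1.0, 95.0, dt=0.01)
    res = find_recurrence(P, dt=0.01, scan=(0.0, 85.0))
    assert res.recurrent.all()
    assert np.nanmax(np.abs(res.rec_time - 10.0)) <= 10.0 * 0.1  # first-entry bias < theta arc


def test_straight_line_has_no_recurrence():
    P = np.column_stack([np.linspace(0, 100, 3000), np.zeros(3000)])
    res = find_recurrence(P, dt=0.01, scan=(0.0, 25.0))
    assert not res.recurrent.any()


def test_threshold_monotonicity():
    """Recurrent set at theta(5%) is a subset of the set at theta(10%)."""
    rng = np.random.default_rng(3)
    _, P = spiral_trajectory(8.0, 0.98, 60.0, dt=0.01, radial_noise=0.08, rng=rng)
    r5 = find_recurrence(P, dt=0.01, theta_percentile=5.0, scan=(0.0, 50.0))
    r10 = find_recurrence(P, dt=0.01, theta_percentile=10.0, scan=(0.0, 50.0))
    assert np.all(~r5.recurrent | r10.recurrent)


def _result_from_delays(delays, dt=0.01):
    n = delays.size
    return RecurrenceResult(
        theta=1.0, theta_percentile=10.0, scan_range=(0.0, n * dt),
        times=dt * np.arange(n), recurrent=np.isfinite(delays),
        rec_time=delays, dt=dt,
    )


def test_orbit_detection_histogram_oracle():
    """1000 delays uniform in [9.5, 10.5] plus 80 at 20 s -> one peak near 10."""
    rng = np.random.default_rng(0)
    delays = np.concatenate([rng.uniform(9.5, 10.5, 1000), np.full(80, 20.0)])
    res = detect_periodic_orbit(_result_from_delays(delays))
    assert len(res.peaks) == 1
    assert res.period == pytest.approx(np.mean(delays[:1000]), abs=1e-12)
    assert abs(res.period - 10.0) < 0.05


def test_all_short_delays_yield_no_orbit():
    delays = np.full(500, 3.0)
    res = detect_periodic_orbit(_result_from_delays(delays))
    assert res.dominant is None and res.period is None


def test_dominant_peak_tie_prefers_smaller_delay():
    rng = np.random.default_rng(1)
    delays = np.concatenate([
        rng.uniform(7.05, 7.95, 200), rng.uniform(14.05, 14.95, 200)
    ])
    res = detect_periodic_orbit(_result_from_delays(delays), min_peak_points=100)
    assert len(res.peaks) == 2
    assert res.period < 10.0


def test_window_density_all_and_alternating():
    n = 2000
    delays = np.full(n, 8.0)
    res = _result_from_delays(delays)
    dens = window_density(res, win=5.0, step=1.0)
    assert all(w.density == 1.0 for w in dens)
    alt = delays.copy()
    alt[::2] = np.nan
    res2 = _result_from_delays(alt)
    dens2 = window_density(res2, win=5.0, step=1.0)
    assert all(abs(w.density - 0.5) < 0.01 for w in dens2)


def test_coalescence_first_window_midpoint():
    wins = [WindowDensity(win_mid=2.5 + k, density=d, mean_delay=8.0, delay_sd=0.1)
            for k, d in enumerate([0.2, 0.5, 0.95, 0.99])]
    assert coalescence_time(wins) == pytest.approx(4.5)
    low = [WindowDensity(win_mid=2.5, density=0.5, mean_delay=8.0, delay_sd=0.1)]
    assert coalescence_time(low) is None


def _win(mid, density, mean_delay=8.0, sd=0.2):
    return WindowDensity(win_mid=mid, density=density, mean_delay=mean_delay, delay_sd=sd)


def test_perturbation_detection_and_end_rule():
    """A mid-recording dip is an event; one near the end is dropped."""
    delays = np.full(12000, 8.0)
    res = _result_from_delays(delays)  # times 0..120 s
    period = 8.0
    densities = [_win(2.5 + k, 0.95) for k in range(114)]
    for k in range(50, 58):
        densities[k] = _win(2.5 + k, 0.3)
    evs = detect_perturbations(res, densities, period, coalescence=2.5,
                               recording_end=120.0)
    assert len(evs) == 1
    assert evs[0].outcome.startswith("returned")
    assert evs[0].span[0] < 55 < evs[0].span[1]
    # same dip placed within two cycles of the end is dropped
    densities2 = [_win(2.5 + k, 0.95) for k in range(114)]
    for k in range(108, 114):
        densities2[k] = _win(2.5 + k, 0.3)
    evs2 = detect_perturbations(res, densities2, period, coalescence=2.5,
                                recording_end=120.0)
    assert evs2 == []


def test_not_returned_when_density_never_recovers():
    delays = np.full(12000, 8.0)
    res = _result_from_delays(delays)
    densities = [_win(2.5 + k, 0.95) for k in range(60)] + \
                [_win(62.5 + k, 0.2) for k in range(52)]
    evs = detect_perturbations(res, densities, 8.0, coalescence=2.5,
                               recording_end=120.0)
    assert len(evs) == 1
    assert evs[0].outcome == "not_returned"


def test_degenerate_scan_rejected():
    with pytest.raises(DegenerateInputError):
        find_recurrence(np.zeros((100, 2)), dt=0.01, scan=(0.0, 0.005))
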