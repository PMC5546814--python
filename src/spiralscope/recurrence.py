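"""Recurrence analysis of the low-dimensional trajectory.

A trajectory point P(t) *recurs* if the trajectory re-enters a ball of radius
theta around it at some later time; the delay delta until the first such
return is the recurrence time.  The contiguous stretch of trajectory that
never leaves the ball around P(t) is excluded before searching, so delta
measures a genuine return, not local smoothness.  theta is set per program as
a percentile (default 10%) of all pairwise distances between scanned points,
scaling the criterion to that program's activity level.

A histogram of recurrence times (1 s bins, delays < 5 s excluded) exposes
periodic orbits as peaks; the peak holding the most recurrent points is the
dominant orbit and its mean delay estimates the orbital period.  Windowed
recurrence density (5 s windows, 1 s steps) tracks when the trajectory is on
the orbit: the first window with >= 90% recurrent points marks *coalescence*
onto the manifold, and later sustained falls in density mark spontaneous
perturbations, classified by whether and where the trajectory returns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateInputError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class Peak:
    """One contiguous recurrence-time histogram peak."""

    lo: float          # s, inclusive lower edge
    hi: float          # s, exclusive upper edge
    n_points: int
    mean_delay: float  # s


@dataclass
class RecurrenceResult:
    """Per-time recurrence flags and delays, plus the detected orbit."""

    theta: float
    theta_percentile: float
    scan_range: tuple[float, float]
    times: np.ndarray            # absolute times of scanned points (s)
    recurrent: np.ndarray        # bool per scanned point
    rec_time: np.ndarray         # delay delta (s); nan where not recurrent
    dt: float
    histogram: tuple[np.ndarray, np.ndarray] | None = None  # (bin_edges, counts)
    peaks: list[Peak] = field(default_factory=list)
    dominant: int | None = None
    period: float | None = None
    min_delay: float | None = None

    @property
    def recurrence_fraction(self) -> float:
        return float(np.mean(self.recurrent)) if self.recurrent.size else 0.0

    def dominant_mask(self) -> np.ndarray:
        """Scanned points recurrent with a delay inside the dominant peak."""
        if self.dominant is None:
            return np.zeros_like(self.recurrent)
        pk = self.peaks[self.dominant]
        with np.errstate(invalid="ignore"):
            return self.recurrent & (self.rec_time >= pk.lo) & (self.rec_time < pk.hi)


@dataclass
class WindowDensity:
    """Recurrence statistics in one 5 s sliding window."""

    win_mid: float
    density: float
    mean_delay: float   # nan if no recurrent point in window
    delay_sd: float     # nan if < 2 recurrent points
    n_points: int = 0


@dataclass
class PerturbationEvent:
    """A sustained divergence of the trajectory from the orbit."""

    span: tuple[float, float]
    divergent_point: float
    outcome: str  # returned_same | returned_different | not_returned
    same_manifold_fraction: float | None = None


# ---------------------------------------------------------------------------

def find_recurrence(
    P: np.ndarray,
    dt: float = 0.01,
    t_start: float = 0.0,
    theta_percentile: float = 10.0,
    scan: tuple[float, float] | None = None,
    theta: float | None = None,
    chunk: int = 1024,
) -> RecurrenceResult:
    """Flag recurrent points of a trajectory and measure their delays.

    Parameters
    ----------
    P
        Trajectory, time x dimensions; row k is at time ``t_start + k*dt``.
    scan
        Absolute time range of points to scan.  Defaults to the whole
        trajectory except the final 10 s (so every scanned point has a
        future to recur into).  The future search itself extends to the end
        of the trajectory.
    theta_percentile
        Percentile of all pairwise distances between scanned points used as
        the recurrence threshold theta (Euclidean); ignored if ``theta`` is
        given explicitly.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if P.ndim != 2:
        raise ParameterError("trajectory must be 2-D (time x dims)")
    T = P.shape[0]
    t_end = t_start + T * dt
    if scan is None:
        scan = (t_start, max(t_start, t_end - 10.0))
    i0 = int(np.ceil((scan[0] - t_start) / dt - 1e-9))
    i1 = int(np.floor((scan[1] - t_start) / dt + 1e-9))
    i0 = max(i0, 0)
    i1 = min(i1, T)
    if i1 - i0 < 2:
        raise DegenerateInputError("fewer than 2 points in the scan range")

    n_scan = i1 - i0
    fut0 = i0 + 1  # columns cover all strictly-future points i0+1 .. T-1

    # one chunked pass of squared distances, reused for the threshold
    # percentile (scanned-scanned pairs) and the forward search (all pairs)
    chunks: list[np.ndarray] = []
    tri: list[np.ndarray] = []
    for c0 in range(0, n_scan, chunk):
        c1 = min(c0 + chunk, n_scan)
        D2 = cdist(P[i0 + c0 : i0 + c1], P[fut0:], "sqeuclidean").astype(np.float32)
        chunks.append(D2)
        if theta is None:
            for r in range(c1 - c0):
                tri.append(D2[r, c0 + r : n_scan - 1])
    if theta is None:
        dists = np.sqrt(np.concatenate(tri))
        theta = float(np.quantile(dists, theta_percentile / 100.0))
        del dists, tri
    if theta <= 0:
        raise DegenerateInputError("recurrence threshold theta is zero (constant trajectory?)")
    theta2 = np.float32(theta) ** 2

    recurrent = np.zeros(n_scan, dtype=bool)
    rec_time = np.full(n_scan, np.nan)
    for ci, c0 in enumerate(range(0, n_scan, chunk)):
        D2 = chunks[ci]
        for r in range(D2.shape[0]):
            # future of scanned index c0+r starts at column c0+r (point i0+c0+r+1)
            row = D2[r, c0 + r :]
            if row.size == 0:
                continue
            within = row <= theta2
            # skip the contiguous within-theta run around the point itself
            if within[0]:
                exits = np.flatnonzero(~within)
                if exits.size == 0:
                    continue  # never leaves the ball: no true return
                start = exits[0]
            else:
                start = 0
            hits = np.flatnonzero(within[start:])
            if hits.size:
                j = start + hits[0]
                recurrent[c0 + r] = True
                rec_time[c0 + r] = (j + 1) * dt

    times = t_start + dt * np.arange(i0, i1)
    return RecurrenceResult(
        theta=theta,
        theta_percentile=theta_percentile,
        scan_range=(float(times[0]), float(times[-1] + dt)),
        times=times,
        recurrent=recurrent,
        rec_time=rec_time,
        dt=dt,
    )


def detect_periodic_orbit(
    result: RecurrenceResult,
    bin_s: float = 1.0,
    min_delay: float = 5.0,
    min_peak_points: int = 100,
) -> RecurrenceResult:
    """Histogram the recurrence times and pick out the dominant periodic orbit.

    Delays below ``min_delay`` are excluded (they reflect quasi-periodic
    noise in otherwise contiguous trajectories, not an orbit).  Peaks are
    maximal contiguous runs of non-empty 1 s bins holding more than
    ``min_peak_points`` recurrent points; the peak with the most points is
    dominant and its mean delay is the orbital period.  With no qualifying
    peak the program is left flagged aperiodic (``dominant`` unset).
    """
    delays = result.rec_time[result.recurrent]
    delays = delays[delays >= min_delay]
    out = replace(result, min_delay=min_delay)
    if delays.size == 0:
        out.histogram = (np.array([min_delay]), np.array([], dtype=int))
        out.peaks, out.dominant, out.period = [], None, None
        return out

    hi_edge = min_delay + bin_s * int(np.ceil((delays.max() - min_delay) / bin_s + 1e-12))
    hi_edge = max(hi_edge, min_delay + bin_s)
    edges = np.arange(min_delay, hi_edge + bin_s / 2, bin_s)
    counts, _ = np.histogram(delays, bins=edges)
    out.histogram = (edges, counts)

    peaks: list[Peak] = []
    k = 0
    while k < counts.size:
        if counts[k] == 0:
            k += 1
            continue
        j = k
        while j < counts.size and counts[j] > 0:
            j += 1
        lo, hi = edges[k], edges[j]
        in_peak = delays[(delays >= lo) & (delays < hi)]
        if in_peak.size > min_peak_points:
            peaks.append(Peak(lo=float(lo), hi=float(hi), n_points=int(in_peak.size),
                              mean_delay=float(in_peak.mean())))
        k = j
    out.peaks = peaks
    if not peaks:
        out.dominant, out.period = None, None
        return out
    best = max(range(len(peaks)), key=lambda i: (peaks[i].n_points, -peaks[i].mean_delay))
    ties = [i for i in range(len(peaks)) if peaks[i].n_points == peaks[best].n_points]
    if len(ties) > 1:
        logger.info("dominant-peak tie (%d peaks); choosing smaller mean delay", len(ties))
    out.dominant = best
    out.period = peaks[best].mean_delay
    return out


def window_density(
    result: RecurrenceResult,
    win: float = 5.0,
    step: float = 1.0,
) -> list[WindowDensity]:
    """Recurrence density and delay statistics in sliding windows."""
    t = result.times
    densities = []
    start = t[0]
    while start + win <= t[-1] + result.dt + 1e-9:
        mask = (t >= start - 1e-9) & (t < start + win - 1e-9)
        n = int(mask.sum())
        if n == 0:
            start += step
            continue
        rec = result.recurrent[mask]
        dl = result.rec_time[mask][rec]
        densities.append(
            WindowDensity(
                win_mid=float(start + win / 2),
                density=float(rec.mean()),
                mean_delay=float(dl.mean()) if dl.size else float("nan"),
                delay_sd=float(dl.std(ddof=1)) if dl.size > 1 else float("nan"),
                n_points=n,
            )
        )
        start += step
    return densities


def coalescence_time(
    densities: list[WindowDensity],
    threshold: float = 0.90,
) -> float | None:
    """Mid-point of the first window whose recurrence density reaches threshold.

    Returns None if the trajectory never becomes stably recurrent -- a valid
    outcome, treated downstream as "never coalesced".
    """
    if not densities:
        raise ParameterError("empty density series")
    for w in densities:
        if w.density >= threshold:
            return w.win_mid
    return None


def detect_perturbations(
    result: RecurrenceResult,
    densities: list[WindowDensity],
    period: float,
    coalescence: float,
    recover_threshold: float = 0.90,
    diverge_threshold: float = 0.50,
    same_manifold_min: float = 0.10,
    win: float = 5.0,
    recording_end: float | None = None,
) -> list[PerturbationEvent]:
    """Detect sustained divergences from the orbit and classify their outcome.

    Candidate divergent periods are maximal runs of post-coalescence windows
    with density < ``recover_threshold`` that dip below ``diverge_threshold``
    at least once.  The window of lowest density is the divergent point;
    candidates whose divergent point lies within two oscillation cycles of
    the end of the recording are dropped (a fall in recurrence there may only
    reflect the finite time horizon).  An event is ``returned_*`` if density
    later climbs back above ``recover_threshold``; it returned to the *same*
    manifold if at least ``same_manifold_min`` of the recurrence delays in the
    final pre-divergence window extend beyond the divergent period's end.
    """
    if coalescence is None:
        raise ParameterError("perturbation detection requires a defined coalescence time")
    if recording_end is None:
        recording_end = result.scan_range[1]
    wins = [w for w in densities if w.win_mid >= coalescence]
    events: list[PerturbationEvent] = []
    k = 0
    while k < len(wins):
        if wins[k].density >= recover_threshold:
            k += 1
            continue
        j = k
        while j < len(wins) and wins[j].density < recover_threshold:
            j += 1
        run = wins[k:j]
        if any(w.density < diverge_threshold for w in run):
            span = (run[0].win_mid - win / 2, run[-1].win_mid + win / 2)
            div_pt = min(run, key=lambda w: w.density).win_mid
            if div_pt < recording_end - 2.0 * period:
                recovered = any(w.density >= recover_threshold for w in wins[j:])
                if not recovered:
                    events.append(
                        PerturbationEvent(span=span, divergent_point=div_pt,
                                          outcome="not_returned")
                    )
                else:
                    frac = _same_manifold_fraction(result, span, win)
                    outcome = ("returned_same" if frac is not None and frac >= same_manifold_min
                               else "returned_different")
                    events.append(
                        PerturbationEvent(span=span, divergent_point=div_pt,
                                          outcome=outcome, same_manifold_fraction=frac)
                    )
        k = j
    return events


def _same_manifold_fraction(
    result: RecurrenceResult, span: tuple[float, float], win: float
) -> float | None:
    """Fraction of pre-divergence recurrence delays landing beyond the span end."""
    pre_hi = span[0]
    pre_lo = pre_hi - win
    mask = (result.times >= pre_lo - 1e-9) & (result.times < pre_hi - 1e-9) & result.recurrent
    if not np.any(mask):
        return None
    t_land = result.times[mask] + result.rec_time[mask]
    return float(np.mean(t_land > span[1]))
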