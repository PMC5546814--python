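"""Local linear models along the trajectory, and the attractor they imply.

Around each anchor point P(t) we take the stretch of trajectory contiguous in
time that stays within 2.5 x theta of P(t), and -- if it holds at least 100
points -- fit the discrete linear model dP = A P by least squares, with dP the
first-order difference of the trajectory (so A is in per-time-step units).
The eigenvalues of A describe the local flow: the eigenvalue with the largest
real part, lambda = a + ib, is the dominant local dynamics -- contracting
(a < 0) or expanding (a > 0), rotating (b != 0) or not.

Averaging (a, b) over the fits at all recurrent points of the dominant
periodic orbit summarises the attractor: orbital period 2*pi*dt / b, per-
second contraction 100 * exp(a / dt) %, and a classification by sign
(stable/unstable spiral or node).

Period drift over a program is tracked by correlating window time against
window mean recurrence delay with a *weighted* Spearman rank correlation,
weighting windows that are clearly on the orbit (high recurrence fraction,
low delay spread); significance comes from a permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import (
    ParameterError,
    SummaryUnavailableError,
    UndefinedStatisticError,
)
from .recurrence import RecurrenceResult, WindowDensity

logger = logging.getLogger(__name__)


@dataclass
class LocalLinearFit:
    t: float
    A: np.ndarray | None
    eigvals: np.ndarray | None
    n_points: int
    valid: bool


@dataclass
class AttractorEstimate:
    a_mean: float
    a_sem: float
    b_mean: float
    b_sem: float
    period_est: float | None        # s
    contraction_pct_per_s: float    # % of amplitude retained per second
    classification: str
    per_dim_real: np.ndarray        # mean real eigenvalue per unique dimension
    rotation_fraction: float
    n_fits: int


@dataclass
class DriftResult:
    rho: float
    p: float
    n_windows: int
    weights: np.ndarray


# ---------------------------------------------------------------------------

def fit_local_linear(
    P: np.ndarray,
    anchor: int,
    theta: float,
    dt: float = 0.01,
    radius_mult: float = 2.5,
    min_points: int = 100,
    t_start: float = 0.0,
    max_extent: int | None = None,
) -> LocalLinearFit:
    """Fit dP = A P to the trajectory's neighbourhood of one anchor point.

    The neighbourhood extends forwards and backwards from the anchor while
    the trajectory stays within ``radius_mult * theta`` of P(anchor) and
    remains contiguous in time; the first exit ends it on each side.  Both
    the points and their first differences are centred on the neighbourhood
    before the regression (an affine local model: the orbit is not locally
    centred at the origin, and the intercept leaves A unchanged for linear
    systems).
    """
    P = np.asarray(P, dtype=float)
    T, d = P.shape
    if not (0 <= anchor < T):
        raise ParameterError(f"anchor {anchor} outside trajectory of length {T}")
    radius = radius_mult * theta
    cap = max_extent if max_extent is not None else T

    p0 = P[anchor]
    hi = anchor
    fwd = P[anchor + 1 : min(anchor + 1 + cap, T)]
    if fwd.size:
        out = np.flatnonzero(np.linalg.norm(fwd - p0, axis=1) > radius)
        hi = anchor + (out[0] if out.size else fwd.shape[0])
    lo = anchor
    bwd = P[max(anchor - cap, 0) : anchor][::-1]
    if bwd.size:
        out = np.flatnonzero(np.linalg.norm(bwd - p0, axis=1) > radius)
        lo = anchor - (out[0] if out.size else bwd.shape[0])

    n_points = hi - lo + 1
    t_anchor = t_start + anchor * dt
    if n_points < min_points:
        return LocalLinearFit(t=t_anchor, A=None, eigvals=None, n_points=n_points, valid=False)

    seg = P[lo : min(hi + 2, T)]  # one extra row for the final difference
    X = seg[:-1]
    Y = np.diff(seg, axis=0)
    if X.shape[0] < min_points:
        return LocalLinearFit(t=t_anchor, A=None, eigvals=None, n_points=X.shape[0], valid=False)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    At, residuals, rank, sv = np.linalg.lstsq(Xc, Yc, rcond=None)
    if rank < d:
        cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        logger.info("rank-deficient neighbourhood at t=%.2f (cond=%.2g)", t_anchor, cond)
        return LocalLinearFit(t=t_anchor, A=None, eigvals=None, n_points=X.shape[0], valid=False)
    A = At.T
    return LocalLinearFit(
        t=t_anchor, A=A, eigvals=np.linalg.eigvals(A), n_points=X.shape[0], valid=True
    )


def fit_along_trajectory(
    P: np.ndarray,
    anchors: np.ndarray,
    theta: float,
    dt: float = 0.01,
    radius_mult: float = 2.5,
    min_points: int = 100,
    t_start: float = 0.0,
    max_extent: int | None = None,
) -> list[LocalLinearFit]:
    """Fit local linear models at a set of anchor indices."""
    return [
        fit_local_linear(P, int(a), theta, dt=dt, radius_mult=radius_mult,
                         min_points=min_points, t_start=t_start, max_extent=max_extent)
        for a in anchors
    ]


def _max_eig(eigvals: np.ndarray) -> complex:
    """Eigenvalue with the largest real part, conjugate resolved to b >= 0."""
    lam = eigvals[np.argmax(eigvals.real)]
    return complex(lam.real, abs(lam.imag))


def summarize_attractor(
    fits: list[LocalLinearFit],
    recurrence: RecurrenceResult,
    dt: float = 0.01,
    min_fits: int = 10,
    b_tol: float = 1e-9,
) -> AttractorEstimate:
    """Average local eigenvalues over the dominant orbit's recurrent points.

    Only valid fits anchored at scan times that are recurrent with a delay in
    the dominant peak contribute.  ``a_mean``/``b_mean`` are plain means with
    standard errors; period and contraction are derived from them, and the
    classification follows the signs (b = 0 within ``b_tol`` -> node).
    """
    if recurrence.dominant is None:
        raise SummaryUnavailableError("no dominant periodic orbit: program is aperiodic")
    mask = recurrence.dominant_mask()
    rec_times = set(np.round(recurrence.times[mask] / dt).astype(int).tolist())
    sel = [f for f in fits if f.valid and int(round(f.t / dt)) in rec_times]
    if len(sel) < min_fits:
        raise SummaryUnavailableError(
            f"only {len(sel)} valid fits at dominant-orbit recurrent points (need {min_fits})"
        )
    lams = np.array([_max_eig(f.eigvals) for f in sel])
    a = lams.real
    b = lams.imag
    a_mean, b_mean = float(a.mean()), float(b.mean())
    a_sem = float(a.std(ddof=1) / np.sqrt(a.size))
    b_sem = float(b.std(ddof=1) / np.sqrt(b.size))

    period = 2 * np.pi * dt / b_mean if b_mean > b_tol else None
    contraction = 100.0 * float(np.exp(a_mean / dt))
    if b_mean > b_tol:
        classification = "stable_spiral" if a_mean < 0 else "unstable_spiral"
    else:
        classification = "stable_node" if a_mean < 0 else "unstable_node"

    # mean real eigenvalue per unique dimension: conjugate pairs count once
    per_dim_rows = []
    for f in sel:
        ev = f.eigvals[np.argsort(-f.eigvals.real)]
        uniq = []
        k = 0
        while k < ev.size:
            uniq.append(ev[k].real)
            if abs(ev[k].imag) > b_tol and k + 1 < ev.size and \
                    np.isclose(ev[k + 1].real, ev[k].real) and \
                    np.isclose(ev[k + 1].imag, -ev[k].imag):
                k += 2
            else:
                k += 1
        per_dim_rows.append(uniq)
    width = max(len(r) for r in per_dim_rows)
    padded = np.full((len(per_dim_rows), width), np.nan)
    for i, r in enumerate(per_dim_rows):
        padded[i, : len(r)] = r
    per_dim_real = np.nanmean(padded, axis=0)

    top2_complex = [
        np.any(np.abs(f.eigvals[np.argsort(-f.eigvals.real)][:2].imag) > b_tol) for f in sel
    ]
    return AttractorEstimate(
        a_mean=a_mean, a_sem=a_sem, b_mean=b_mean, b_sem=b_sem,
        period_est=period, contraction_pct_per_s=contraction,
        classification=classification, per_dim_real=per_dim_real,
        rotation_fraction=float(np.mean(top2_complex)), n_fits=len(sel),
    )


# ---------------------------------------------------------------------------

def weighted_spearman(x, y, w) -> float:
    """Weighted Spearman rank correlation.

    Ranks x and y (average ranks for ties), then computes the weighted
    correlation rho = s_xy / sqrt(s_xx * s_yy) with weighted means
    m = sum(w x)/sum(w) and covariances s_xy = sum(w (x-m_x)(y-m_y))/sum(w).
    Uniform weights reduce exactly to the classical Spearman rho.  Returns
    nan if either variable has zero weighted rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.size == y.size == w.size):
        raise ParameterError("x, y, w must have equal lengths")
    if x.size < 3:
        raise ParameterError("need at least 3 observations")
    if np.any(w < 0):
        raise ParameterError("weights must be non-negative")
    if w.sum() <= 0:
        raise UndefinedStatisticError("total weight is zero")
    rx = rankdata(x)
    ry = rankdata(y)
    return _weighted_corr(rx, ry, w)


def _weighted_corr(rx: np.ndarray, ry: np.ndarray, w: np.ndarray) -> float:
    sw = w.sum()
    mx = (w * rx).sum() / sw
    my = (w * ry).sum() / sw
    sxy = (w * (rx - mx) * (ry - my)).sum() / sw
    sxx = (w * (rx - mx) ** 2).sum() / sw
    syy = (w * (ry - my) ** 2).sum() / sw
    if sxx <= 0 or syy <= 0:
        return float("nan")
    return float(sxy / np.sqrt(sxx * syy))


def period_drift(
    densities: list[WindowDensity],
    coalescence: float,
    n_perm: int = 10000,
    seed: int = 0,
    tail: str = "two",
    recover_threshold: float = 0.90,
) -> DriftResult:
    """Weighted Spearman correlation of window time vs window mean delay.

    Windows between coalescence and the final window with recurrence density
    >= ``recover_threshold`` qualify.  Each window is weighted by
    w_i = (delay SD)^-1 * (recurrent fraction), favouring windows where the
    trajectory is clearly on the orbit; zero-SD windows would get infinite
    weight and are capped at the 99th percentile of the finite weights
    (logged).  The permutation p-value (default two-sided) uses the add-one
    convention (count+1)/(n_perm+1), so p is always in (0, 1].
    """
    if coalescence is None:
        raise ParameterError("period drift requires a defined coalescence time")
    wins = [w for w in densities if w.win_mid >= coalescence]
    last = None
    for i, w in enumerate(wins):
        if w.density >= recover_threshold:
            last = i
    if last is not None:
        wins = wins[: last + 1]
    wins = [w for w in wins if np.isfinite(w.mean_delay)]
    if len(wins) < 3:
        raise ParameterError(f"only {len(wins)} qualifying windows (need >= 3)")

    x = np.array([w.win_mid for w in wins])
    y = np.array([w.mean_delay for w in wins])
    sd = np.array([w.delay_sd for w in wins])
    q = np.array([w.density for w in wins])
    with np.errstate(divide="ignore"):
        wts = q / sd
    finite = np.isfinite(wts)
    if not np.all(finite):
        cap = np.percentile(wts[finite], 99) if np.any(finite) else 1.0
        logger.info("capping %d zero-SD window weights at %.3g", int((~finite).sum()), cap)
        wts[~finite] = cap

    rx = rankdata(x)
    ry = rankdata(y)
    rho = _weighted_corr(rx, ry, wts)
    if not np.isfinite(rho):  # e.g. constant delays: report rho=0, p=1
        return DriftResult(rho=0.0, p=1.0, n_windows=len(wins), weights=wts)

    rng = np.random.default_rng(seed)
    n = len(wins)
    perm_rho = np.empty(n_perm)
    # vectorised permutations of the y-ranks against fixed x-ranks and weights
    sw = wts.sum()
    mx = (wts * rx).sum() / sw
    sxx = (wts * (rx - mx) ** 2).sum() / sw
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    RY = ry[perms]                      # (n_perm, n)
    MY = (RY * wts).sum(axis=1) / sw
    DY = RY - MY[:, None]
    SXY = (wts * (rx - mx) * DY).sum(axis=1) / sw
    SYY = (wts * DY**2).sum(axis=1) / sw
    with np.errstate(invalid="ignore", divide="ignore"):
        perm_rho = SXY / np.sqrt(sxx * SYY)
    perm_rho[~np.isfinite(perm_rho)] = 0.0

    if tail == "two":
        count = int(np.sum(np.abs(perm_rho) >= abs(rho) - 1e-12))
    elif tail == "greater":
        count = int(np.sum(perm_rho >= rho - 1e-12))
    elif tail == "less":
        count = int(np.sum(perm_rho <= rho + 1e-12))
    else:
        raise ParameterError(f"unknown tail {tail!r}")
    p = (count + 1) / (n_perm + 1)
    return DriftResult(rho=float(rho), p=float(p), n_windows=n, weights=wts)
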