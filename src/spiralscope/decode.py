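"""Decoding nerve output from the low-dimensional trajectory.

The motor-nerve firing rate is modelled as a log-link function of the recent
history of the population trajectory::

    f(t) = exp( beta0 + sum_{i=1..d} sum_{h=1..m} beta_{i,h} P_i(t - h) )

with lags h in 10 ms steps spanning a 50-200 ms history.  The model is fitted
as a Poisson-type generalised linear model (log link, Poisson variance) to
the smoothed nerve rate on a 40 s window, then used to *forecast* the next
10 s from the trajectory alone; sliding both windows in 1 s steps yields a
forecast-quality profile (correlation R and median absolute error) over the
whole program.  A short history is deliberate: it rules out contributions
from population neurons that are merely phase-offset copies of the nerve.

A separate screen checks the population for putative motorneurons whose
spikes are near-1:1 locked to nerve spikes at some fixed delay.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from sklearn.linear_model import Ridge

from .errors import ConvergenceError, ParameterError
from .spikes import SpikeData

logger = logging.getLogger(__name__)


@dataclass
class DecodingModel:
    beta0: float
    beta: np.ndarray        # (d, m): coefficient for dimension i at lag h
    history_ms: float
    lag_step_ms: float
    dt: float
    fit_window: tuple[float, float]
    family: str = "poisson"

    @property
    def n_lags(self) -> int:
        return self.beta.shape[1]


@dataclass
class ForecastScore:
    window_start: float
    R: float      # nan when the observed rate has zero variance
    MAE: float    # spikes/s


@dataclass
class LockingScreen:
    """Per-neuron maximum spike-locking probability to the nerve."""

    max_prob: np.ndarray      # nan for neurons with zero spikes
    best_delay_ms: np.ndarray
    n_spikes: np.ndarray
    delays_ms: np.ndarray


@dataclass
class DecodingSummary:
    history_ms: np.ndarray
    median_MAE: np.ndarray
    median_R: np.ndarray
    mean_R: np.ndarray
    sem_R: np.ndarray
    mean_MAE: np.ndarray
    sem_MAE: np.ndarray
    best_history_ms: float
    scores: dict = field(default_factory=dict)  # history_ms -> list[ForecastScore]


# ---------------------------------------------------------------------------

def screen_motorneurons(
    spikes: SpikeData,
    nerve: np.ndarray,
    max_delay_ms: float = 25.0,
    jitter_ms: float = 2.0,
) -> LockingScreen:
    """Fraction of each neuron's spikes echoed in the nerve at a fixed delay.

    For each delay on a 1 ms grid from 0 to ``max_delay_ms``, a neuron spike
    at time t is *locked* if a nerve spike falls in [t+delay-jitter,
    t+delay+jitter].  A putative motorneuron with an axon in the nerve shows
    ~1:1 locking (probability near 1) at some delay.
    """
    nerve = np.sort(np.asarray(nerve, dtype=float))
    delays = np.arange(0.0, max_delay_ms + 0.5, 1.0)
    n = spikes.n_neurons
    max_prob = np.full(n, np.nan)
    best_delay = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    for i, train in enumerate(spikes.spikes):
        counts[i] = train.size
        if train.size == 0 or nerve.size == 0:
            continue
        probs = np.empty(delays.size)
        for k, d_ms in enumerate(delays):
            lo = train + (d_ms - jitter_ms) / 1000.0
            hi = train + (d_ms + jitter_ms) / 1000.0
            hit = np.searchsorted(nerve, hi, side="right") > np.searchsorted(nerve, lo, side="left")
            probs[k] = hit.mean()
        best = int(np.argmax(probs))
        max_prob[i] = probs[best]
        best_delay[i] = delays[best]
    return LockingScreen(max_prob=max_prob, best_delay_ms=best_delay,
                         n_spikes=counts, delays_ms=delays)


# ---------------------------------------------------------------------------

def _lag_matrix(P: np.ndarray, m: int, steps_per_lag: int) -> tuple[np.ndarray, int]:
    """Design matrix of lagged trajectory values; row k predicts time index k + offset."""
    T, d = P.shape
    offset = m * steps_per_lag
    X = np.empty((T - offset, d * m))
    for h in range(1, m + 1):
        X[:, (h - 1) * d : h * d] = P[offset - h * steps_per_lag : T - h * steps_per_lag]
    return X, offset


def fit_decoder(
    P: np.ndarray,
    nerve_rate: np.ndarray,
    window: tuple[float, float],
    history_ms: float = 100.0,
    dt: float = 0.01,
    lag_step_ms: float = 10.0,
    t_start: float = 0.0,
    ridge: float = 1e-6,
    family: str = "poisson",
) -> DecodingModel:
    """Fit the log-link history model on one time window.

    ``nerve_rate`` must be on the same grid as ``P`` (both starting at
    ``t_start``).  ``family="poisson"`` fits by iteratively reweighted least
    squares with a log link and Poisson variance; collinear lags are handled
    by the pseudoinverse solve.  ``family="gaussian_log"`` is a ridge
    least-squares fallback on log(rate + eps), penalty ``ridge``.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    y_full = np.asarray(nerve_rate, dtype=float)
    if y_full.shape[0] != P.shape[0]:
        raise ParameterError("nerve_rate and trajectory must share the same grid")
    steps_per_lag = int(round(lag_step_ms / 1000.0 / dt))
    if steps_per_lag < 1 or abs(steps_per_lag * dt * 1000 - lag_step_ms) > 1e-6:
        raise ParameterError("lag_step_ms must be an integer multiple of the grid step")
    m = int(round(history_ms / lag_step_ms))
    if m < 1:
        raise ParameterError("history shorter than one lag step")
    d = P.shape[1]

    X_all, offset = _lag_matrix(P, m, steps_per_lag)
    t_rows = t_start + dt * (offset + np.arange(X_all.shape[0]))
    sel = (t_rows >= window[0] - 1e-9) & (t_rows < window[1] - 1e-9)
    X = X_all[sel]
    y = y_full[offset:][sel]
    if X.shape[0] < 2 * (d * m + 1):
        raise ParameterError(
            f"fit window holds {X.shape[0]} samples for {d * m + 1} coefficients"
        )

    # standardise regressors for the fit; map coefficients back after.
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    if family == "poisson":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(np.maximum(y, 0.0), sm.add_constant(Xs, has_constant="add"),
                         family=sm.families.Poisson())
            try:
                res = glm.fit(maxiter=200, tol=1e-8)
            except Exception as err:  # perfect separation, numerical failure
                raise ConvergenceError(f"Poisson decoder IRLS failed: {err}") from err
        if not res.converged:
            raise ConvergenceError(
                "Poisson decoder did not converge",
                diagnostics={"n_iter": res.fit_history.get("iteration"),
                             "n_samples": X.shape[0]},
            )
        params = np.asarray(res.params)
    elif family == "gaussian_log":
        eps = max(1e-3, 1e-3 * max(y.max(), 1.0))
        reg = Ridge(alpha=ridge, fit_intercept=True)
        reg.fit(Xs, np.log(np.maximum(y, 0.0) + eps))
        params = np.concatenate([[reg.intercept_], reg.coef_])
    else:
        raise ParameterError(f"unknown family {family!r}")
    coef = params[1:] / sd
    beta0 = float(params[0] - np.dot(params[1:], mu / sd))

    beta = np.empty((d, m))
    for h in range(1, m + 1):
        beta[:, h - 1] = coef[(h - 1) * d : h * d]
    return DecodingModel(
        beta0=beta0, beta=beta, history_ms=history_ms, lag_step_ms=lag_step_ms,
        dt=dt, fit_window=window, family=family,
    )


def forecast(
    model: DecodingModel,
    P: np.ndarray,
    window: tuple[float, float],
    t_start: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict the nerve rate over a window from the trajectory alone.

    Returns ``(times, rate)``.  By construction no nerve data enters: the
    prediction is exp(beta0 + beta . lagged trajectory).  A window reaching
    past the trajectory is truncated with a warning.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    steps_per_lag = int(round(model.lag_step_ms / 1000.0 / model.dt))
    m = model.n_lags
    X_all, offset = _lag_matrix(P, m, steps_per_lag)
    t_rows = t_start + model.dt * (offset + np.arange(X_all.shape[0]))
    if window[1] > t_rows[-1] + model.dt:
        logger.warning("forecast window truncated at trajectory end (%.2f s)", t_rows[-1])
    sel = (t_rows >= window[0] - 1e-9) & (t_rows < window[1] - 1e-9)
    coef = model.beta.T.reshape(-1)  # matches _lag_matrix column order
    eta = model.beta0 + X_all[sel] @ coef
    return t_rows[sel], np.exp(np.minimum(eta, 30.0))


def score_forecast(pred: np.ndarray, observed: np.ndarray, window_start: float = 0.0) -> ForecastScore:
    """Correlation and median absolute error of a forecast against observation.

    R is reported as nan when the observed rate is constant over the window
    (zero variance); the MAE is kept.
    """
    pred = np.asarray(pred, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if pred.shape != observed.shape:
        raise ParameterError("forecast and observation must align")
    mae = float(np.median(np.abs(pred - observed)))
    if observed.std() == 0 or pred.std() == 0:
        return ForecastScore(window_start=window_start, R=float("nan"), MAE=mae)
    r = float(np.corrcoef(pred, observed)[0, 1])
    return ForecastScore(window_start=window_start, R=r, MAE=mae)


def evaluate_decoding(
    P: np.ndarray,
    nerve_rate: np.ndarray,
    history_grid_ms: tuple[float, ...] = tuple(range(50, 201, 10)),
    fit_s: float = 40.0,
    forecast_s: float = 10.0,
    step_s: float = 1.0,
    dt: float = 0.01,
    t_start: float = 0.0,
    eval_range: tuple[float, float] | None = None,
    family: str = "poisson",
) -> DecodingSummary:
    """Sliding fit/forecast evaluation over a grid of history durations.

    For each history duration the model is fitted on a ``fit_s`` window and
    scored on the following ``forecast_s`` window, sliding both in ``step_s``
    steps until the final pair fits in the evaluation range.  The history
    with the smallest median absolute forecast error is selected.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    y = np.asarray(nerve_rate, dtype=float)
    t_grid = t_start + dt * np.arange(P.shape[0])
    if eval_range is None:
        eval_range = (t_start, t_start + dt * P.shape[0])
    if eval_range[1] - eval_range[0] < fit_s + forecast_s:
        raise ParameterError("evaluation range shorter than one fit+forecast pair")

    all_scores: dict[float, list[ForecastScore]] = {}
    for hist in history_grid_ms:
        scores = []
        w0 = eval_range[0]
        while w0 + fit_s + forecast_s <= eval_range[1] + 1e-9:
            try:
                model = fit_decoder(P, y, (w0, w0 + fit_s), history_ms=hist, dt=dt,
                                    t_start=t_start, family=family)
            except ConvergenceError as err:
                logger.warning("decoder fit failed at window %.1f s: %s", w0, err)
                w0 += step_s
                continue
            fw = (w0 + fit_s, w0 + fit_s + forecast_s)
            tf, pred = forecast(model, P, fw, t_start=t_start)
            obs = y[np.searchsorted(t_grid, tf - 1e-9)]
            scores.append(score_forecast(pred, obs, window_start=fw[0]))
            w0 += step_s
        all_scores[float(hist)] = scores

    hists = np.array(sorted(all_scores))
    med_mae = np.array([np.median([s.MAE for s in all_scores[h]]) for h in hists])
    med_r = np.array([np.nanmedian([s.R for s in all_scores[h]]) for h in hists])
    mean_r = np.array([np.nanmean([s.R for s in all_scores[h]]) for h in hists])
    sem_r = np.array([
        np.nanstd([s.R for s in all_scores[h]], ddof=1) / np.sqrt(len(all_scores[h]))
        for h in hists
    ])
    mean_mae = np.array([np.mean([s.MAE for s in all_scores[h]]) for h in hists])
    sem_mae = np.array([
        np.std([s.MAE for s in all_scores[h]], ddof=1) / np.sqrt(len(all_scores[h]))
        for h in hists
    ])
    best = float(hists[int(np.argmin(med_mae))])
    return DecodingSummary(
        history_ms=hists, median_MAE=med_mae, median_R=med_r,
        mean_R=mean_r, sem_R=sem_r, mean_MAE=mean_mae, sem_MAE=sem_mae,
        best_history_ms=best, scores=all_scores,
    )
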