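"""Single-neuron participation in the low-dimensional trajectory.

A neuron's *participation* in a program is the eigenvalue-weighted absolute
sum of its loadings on the retained principal axes::

    rho_i = sum_{j=1..d} | lambda_j W_j(i) |

-- an L1 measure of how much of the low-dimensional trajectory is carried by
that neuron, combining its firing rate and its synchrony with the rest of the
population.  Within a program, participation is normalised to the program's
maximum (so exactly one neuron sits at 100%).

Between repeated programs, most participation changes are measurement noise;
a Gaussian noise model fitted by iterative outlier elimination separates the
bulk from *strongly variable* neurons (changes beyond mean +/- 3 SD of the
fitted bulk).  Two further analyses relate participation variability to the
programs themselves: the correlation of participation change with manifold
distance, and the correlation of participation with firing rate and
synchrony.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr

from .embed import Embedding
from .errors import InsufficientDataError, ParameterError
from .spikes import RateMatrix

logger = logging.getLogger(__name__)


@dataclass
class ParticipationTable:
    """Per-neuron participation in one program."""

    rho: np.ndarray        # raw L1 participation
    rho_norm: np.ndarray   # normalised to the program maximum, in %
    neuron_ids: list[str]
    source: str = ""


@dataclass
class NoiseModel:
    """Gaussian bulk model of participation changes, with outlier thresholds."""

    mu: float
    sd: float
    threshold_lo: float
    threshold_hi: float
    outliers: np.ndarray  # indices into the delta vector
    n_iterations: int
    log_likelihood: float


def participation_scores(embedding: Embedding, source: str = "") -> ParticipationTable:
    """L1 participation of each neuron over the retained principal axes."""
    W = embedding.axes[:, : embedding.d]
    lam = embedding.eigvals[: embedding.d]
    rho = np.abs(W * lam[None, :]).sum(axis=1)
    mx = rho.max()
    if mx <= 0:
        raise ParameterError("all-zero participation; degenerate embedding")
    return ParticipationTable(
        rho=rho,
        rho_norm=100.0 * rho / mx,
        neuron_ids=list(embedding.neuron_ids),
        source=source or embedding.source,
    )


def fit_noise_model(
    changes: np.ndarray,
    outlier_sd: float = 3.0,
    min_n: int = 10,
) -> NoiseModel:
    """Fit a Gaussian to the bulk of participation changes by iterative trimming.

    Starting from the maximum-likelihood Gaussian on all deltas, the point
    furthest from the current mean is eliminated and the model refitted,
    iterating while the eliminated candidate is a genuine outlier of the
    current fit (further than ``outlier_sd`` SDs from the mean) and the data
    likelihood does not decrease.  The final model is the last fit before
    either stopping rule fires; deltas beyond mean +/- ``outlier_sd`` * SD of
    that model are flagged as outliers (the strongly-variable neurons).
    """
    deltas = np.asarray(changes, dtype=float).ravel()
    if deltas.size < min_n:
        raise InsufficientDataError(f"need >= {min_n} participation changes, got {deltas.size}")

    keep = np.ones(deltas.size, dtype=bool)

    def fit(mask):
        x = deltas[mask]
        mu = float(x.mean())
        sd = float(x.std(ddof=0))
        ll = float(np.sum(norm.logpdf(x, mu, sd))) if sd > 0 else np.inf
        return mu, sd, ll

    mu, sd, ll = fit(keep)
    n_iter = 0
    while keep.sum() > max(min_n, 3):
        cand = np.flatnonzero(keep)[np.argmax(np.abs(deltas[keep] - mu))]
        if sd == 0 or abs(deltas[cand] - mu) <= outlier_sd * sd:
            break  # no remaining point is an outlier of the current fit
        trial = keep.copy()
        trial[cand] = False
        mu_t, sd_t, ll_t = fit(trial)
        if np.isfinite(ll) and ll_t < ll:
            break  # likelihood decreased: previous model is the best fit
        keep, mu, sd, ll = trial, mu_t, sd_t, ll_t
        n_iter += 1

    lo, hi = mu - outlier_sd * sd, mu + outlier_sd * sd
    outliers = np.flatnonzero((deltas < lo) | (deltas > hi))
    return NoiseModel(
        mu=mu, sd=sd, threshold_lo=lo, threshold_hi=hi,
        outliers=outliers, n_iterations=n_iter,
        log_likelihood=ll if np.isfinite(ll) else float("nan"),
    )


def participation_changes(
    tables: list[ParticipationTable],
    pairs: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Participation deltas (normalised %) pooled over program pairs.

    Default pairs are all unordered pairs, matching the pooled noise-model
    fit; pass consecutive pairs ``[(0, 1), (1, 2)]`` for per-neuron maximum
    consecutive change.
    """
    if len(tables) < 2:
        raise ParameterError("need at least two programs")
    if pairs is None:
        pairs = [(i, j) for i in range(len(tables)) for j in range(i + 1, len(tables))]
    out = []
    for i, j in pairs:
        if tables[i].neuron_ids != tables[j].neuron_ids:
            raise ParameterError("participation tables have differing neuron sets")
        out.append(tables[j].rho_norm - tables[i].rho_norm)
    return np.concatenate(out)


def max_consecutive_change(tables: list[ParticipationTable]) -> np.ndarray:
    """Per-neuron maximum |delta rho_norm| between consecutive programs."""
    deltas = [np.abs(tables[k + 1].rho_norm - tables[k].rho_norm) for k in range(len(tables) - 1)]
    return np.max(np.vstack(deltas), axis=0)


def hellinger_distance(p_sample: np.ndarray, q_sample: np.ndarray,
                       bins: int = 20, value_range: tuple[float, float] = (0.0, 100.0)) -> float:
    """Hellinger distance between two binned participation distributions.

    Both samples are histogrammed on ``bins`` equal-width bins over
    ``value_range`` and normalised to probabilities; the distance is
    sqrt(1 - sum_k sqrt(p_k q_k)), which is 0 for identical histograms and 1
    for non-overlapping ones.
    """
    edges = np.linspace(value_range[0], value_range[1], bins + 1)
    p, _ = np.histogram(np.clip(p_sample, *value_range), bins=edges)
    q, _ = np.histogram(np.clip(q_sample, *value_range), bins=edges)
    p = p / p.sum()
    q = q / q.sum()
    bc = np.sum(np.sqrt(p * q))
    return float(np.sqrt(max(0.0, 1.0 - bc)))


def variability_vs_distance(
    tables: list[ParticipationTable],
    normalized_distances: dict[tuple[int, int], float],
    hellinger_bins: int = 20,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Relate participation change between program pairs to manifold distance.

    For each pair: the summed absolute change in participation, the Hellinger
    distance between the two participation distributions, and the pair's
    normalised manifold distance.  Returns the per-pair table and the Pearson
    correlations of each variability measure with the distance.
    """
    if len(normalized_distances) < 3:
        raise ParameterError("need at least 3 program pairs")
    rows = []
    for (i, j), ndist in sorted(normalized_distances.items()):
        total = float(np.sum(np.abs(tables[j].rho_norm - tables[i].rho_norm)))
        hell = hellinger_distance(tables[i].rho_norm, tables[j].rho_norm, bins=hellinger_bins)
        rows.append({"pair": (i, j), "total_change": total,
                     "hellinger": hell, "normalized_distance": float(ndist)})
    df = pd.DataFrame(rows)
    corrs = {}
    for col in ("total_change", "hellinger"):
        if df[col].std() == 0 or df["normalized_distance"].std() == 0:
            corrs[f"r_{col}"] = float("nan")
        else:
            corrs[f"r_{col}"] = float(pearsonr(df[col], df["normalized_distance"]).statistic)
    return df, corrs


def synchrony(rates: RateMatrix, window: tuple[float, float] | None = None) -> np.ndarray:
    """Per-neuron synchrony: total absolute SDF correlation with all others."""
    mask = rates.time_slice(*window) if window else np.ones(rates.t.size, bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(rates.F[mask], rowvar=False)
    np.fill_diagonal(C, 0.0)
    return np.nansum(np.abs(C), axis=1)


def participation_correlates(
    table: ParticipationTable,
    rates: RateMatrix,
    window: tuple[float, float] | None = None,
) -> dict[str, float]:
    """Correlate participation with firing rate and synchrony within a program.

    The rate window defaults to stimulus offset through the end of the
    recording.  Zero-variance neurons are excluded (logged).
    """
    if window is None:
        t0 = rates.stim_off if rates.stim_off is not None else rates.window_range[0]
        window = (t0, rates.window_range[1])
    mask = rates.time_slice(*window)
    mean_rate = rates.F[mask].mean(axis=0)
    sync = synchrony(rates, window)
    rho = table.rho_norm
    ok = np.isfinite(mean_rate) & np.isfinite(sync) & (rates.F[mask].std(axis=0) > 0)
    if (~ok).any():
        logger.info("excluding %d zero-variance neurons from correlates", int((~ok).sum()))
    out = {}
    for name, x in (("rate", mean_rate), ("synchrony", sync)):
        if rho[ok].std() == 0 or x[ok].std() == 0:
            out[f"r_{name}"] = float("nan")
        else:
            out[f"r_{name}"] = float(pearsonr(rho[ok], x[ok]).statistic)
    return out


def participation_map(
    tables: list[ParticipationTable],
    coords: np.ndarray,
) -> pd.DataFrame:
    """Tabulate per-neuron maximum and range of participation with coordinates.

    Rendering is left to the user; this only carries (x, y) through so
    ganglion maps can be plotted downstream.
    """
    if coords is None or len(coords) != len(tables[0].neuron_ids):
        raise ParameterError("need one (x, y) coordinate per neuron")
    M = np.vstack([t.rho_norm for t in tables])
    return pd.DataFrame({
        "neuron_id": tables[0].neuron_ids,
        "x": coords[:, 0],
        "y": coords[:, 1],
        "max_participation": M.max(axis=0),
        "range_participation": M.max(axis=0) - M.min(axis=0),
    })
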