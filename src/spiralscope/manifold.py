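"""Do sequentially evoked programs share one manifold?

Three complementary tests, all operating on pairs of programs projected into
a common set of principal axes:

* **Hausdorff distance** between the two programs' sets of recurrent points,
  judged against the distance expected from *shuffled projections* (the same
  time series, with their assignment to neurons permuted before projection) --
  this controls for agreement that is due to the choice of axes alone.
* **Three-state distances**: separation of the pair at stimulus onset, the
  maximum separation during the transient (between onset and coalescence),
  and the Hausdorff distance of the post-coalescence recurrent sets.
  Convergence from differing initial conditions shows up as
  transient >> post-coalescence.
* **Pairwise-similarity correlation**: neuron-by-neuron similarity matrices
  of the two programs are correlated (off-diagonal entries), against an
  analytic null matrix E with E_ij = s_i s_j / T that preserves each neuron's
  total similarity s_i while randomising its distribution over partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import directed_hausdorff

from .embed import Embedding, project_onto, shuffled_projection
from .errors import ParameterError, UndefinedComparisonError
from .recurrence import RecurrenceResult
from .spikes import RateMatrix

logger = logging.getLogger(__name__)


@dataclass
class ManifoldComparison:
    pair: tuple[str, str]
    hausdorff: float
    control_mean: float
    control_sem: float
    normalized: float
    n_shuffles: int


@dataclass
class StateDistances:
    spontaneous: float          # at stimulus onset
    pre_coalescence_max: float  # max separation between onset and coalescence
    post_coalescence: float     # Hausdorff of post-coalescence recurrent sets


@dataclass
class SimilarityComparison:
    S_A: np.ndarray
    S_B: np.ndarray
    E: np.ndarray
    r_data: float
    r_control: float
    excluded: list[int]


def hausdorff_distance(setA: np.ndarray, setB: np.ndarray) -> float:
    """Symmetric Hausdorff distance max(h(A->B), h(B->A)) between point sets.

    h(X->Y) is the largest distance from a point of X to its nearest
    neighbour in Y -- the "maximum minimum distance needed to travel" from
    one set to the other.
    """
    A = np.atleast_2d(np.asarray(setA, dtype=float))
    B = np.atleast_2d(np.asarray(setB, dtype=float))
    if A.size == 0 or B.size == 0:
        raise UndefinedComparisonError("Hausdorff distance undefined for an empty point set")
    return max(directed_hausdorff(A, B)[0], directed_hausdorff(B, A)[0])


def _recurrent_points(
    traj: np.ndarray,
    t: np.ndarray,
    rec: RecurrenceResult,
    after: float | None = None,
) -> np.ndarray:
    """Rows of ``traj`` at recurrent scan times (optionally only after ``after``)."""
    sel_times = rec.times[rec.recurrent]
    if after is not None:
        sel_times = sel_times[sel_times >= after]
    idx = np.searchsorted(t, sel_times - 1e-9)
    idx = idx[idx < traj.shape[0]]
    return traj[idx]


def compare_manifolds(
    ratesA: RateMatrix,
    ratesB: RateMatrix,
    embedding: Embedding,
    recA: RecurrenceResult,
    recB: RecurrenceResult,
    n_shuffles: int = 100,
    seed: int = 0,
    pair: tuple[str, str] = ("A", "B"),
) -> ManifoldComparison:
    """Hausdorff distance between recurrent sets vs the shuffled-projection null.

    Both programs are projected onto ``embedding`` (typically the first
    program's axes).  The control distance is the mean over ``n_shuffles``
    draws of max(h(A -> B*), h(B -> A*)), where the starred programs have
    their neuron assignment shuffled before projection.  ``normalized`` is
    data / control-mean: < 1 means the programs lie closer to each other than
    random projections do.
    """
    PA = project_onto(embedding, ratesA)
    PB = project_onto(embedding, ratesB)
    ptsA = _recurrent_points(PA, ratesA.t, recA)
    ptsB = _recurrent_points(PB, ratesB.t, recB)
    if ptsA.size == 0 or ptsB.size == 0:
        raise UndefinedComparisonError(f"program pair {pair}: no recurrent points")
    h_data = hausdorff_distance(ptsA, ptsB)

    rng = np.random.default_rng(seed)
    controls = np.empty(n_shuffles)
    for s in range(n_shuffles):
        PBs = shuffled_projection(ratesB, embedding, seed=rng)
        PAs = shuffled_projection(ratesA, embedding, seed=rng)
        ptsBs = _recurrent_points(PBs, ratesB.t, recB)
        ptsAs = _recurrent_points(PAs, ratesA.t, recA)
        controls[s] = max(
            directed_hausdorff(ptsA, ptsBs)[0], directed_hausdorff(ptsB, ptsAs)[0]
        )
    cm = float(controls.mean())
    sem = float(controls.std(ddof=1) / np.sqrt(n_shuffles)) if n_shuffles > 1 else 0.0
    return ManifoldComparison(
        pair=pair,
        hausdorff=float(h_data),
        control_mean=cm,
        control_sem=sem,
        normalized=float(h_data / cm) if cm > 0 else 0.0,
        n_shuffles=n_shuffles,
    )


def state_distances(
    ratesA: RateMatrix,
    ratesB: RateMatrix,
    embedding: Embedding,
    recA: RecurrenceResult,
    recB: RecurrenceResult,
    coalescenceA: float,
    coalescenceB: float,
    stim_on: float,
) -> StateDistances:
    """Separation of a program pair in three epochs of the response.

    Point-wise distances (same elapsed time) are used for the spontaneous
    state and the transient; the post-coalescence epoch compares the
    recurrent point *sets* by Hausdorff distance, since the two programs may
    traverse the shared orbit with different phases.
    """
    if coalescenceA is None or coalescenceB is None:
        raise ParameterError("state distances require coalescence times for both programs")
    PA = project_onto(embedding, ratesA)
    PB = project_onto(embedding, ratesB)
    n = min(PA.shape[0], PB.shape[0])
    t = ratesA.t[:n]
    gap = np.linalg.norm(PA[:n] - PB[:n], axis=1)

    k_on = int(np.searchsorted(t, stim_on - 1e-9))
    k_on = min(k_on, n - 1)
    spont = float(gap[k_on])
    coal = max(coalescenceA, coalescenceB)
    mask = (t >= stim_on) & (t <= coal)
    pre_max = float(gap[mask].max()) if np.any(mask) else float("nan")
    post = hausdorff_distance(
        _recurrent_points(PA, ratesA.t, recA, after=coalescenceA),
        _recurrent_points(PB, ratesB.t, recB, after=coalescenceB),
    )
    return StateDistances(
        spontaneous=spont, pre_coalescence_max=pre_max, post_coalescence=float(post)
    )


def similarity_matrix(rates: RateMatrix, window: tuple[float, float] | None = None,
                      metric: str = "pearson") -> np.ndarray:
    """Neuron x neuron similarity of spike-density functions.

    ``pearson`` (default) and ``abs_pearson`` use the correlation matrix of
    the SDF columns (the latter takes magnitudes); ``cosine`` uses cosine
    similarity of the mean-centred columns.  Constant neurons yield nan rows,
    handled by the caller.
    """
    mask = rates.time_slice(*window) if window else np.ones(rates.t.size, bool)
    X = rates.F[mask]
    if metric in ("pearson", "abs_pearson"):
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.corrcoef(X, rowvar=False)
        if metric == "abs_pearson":
            S = np.abs(S)
    elif metric == "cosine":
        Xc = X - X.mean(axis=0)
        nrm = np.linalg.norm(Xc, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            S = (Xc.T @ Xc) / np.outer(nrm, nrm)
    else:
        raise ParameterError(f"unknown similarity metric {metric!r}")
    return S


def similarity_null_test(
    ratesA: RateMatrix,
    ratesB: RateMatrix,
    window: tuple[float, float] | None = None,
    metric: str = "pearson",
) -> SimilarityComparison:
    """Correlate two programs' similarity matrices, against the analytic null.

    The null matrix ``E`` preserves each neuron's total (absolute) similarity
    s_i from program B while randomising how that similarity is distributed
    over partners: E_ij = s_i s_j / T with T = sum_i s_i, so that
    sum_j E_ij = s_i exactly.  ``r_data`` is the Pearson correlation of the
    off-diagonal entries of S_A and S_B; ``r_control`` correlates S_A with E.
    Neurons with constant SDFs are excluded (logged).
    """
    # exclude constant-SDF neurons first: their correlations are undefined
    maskA = ratesA.time_slice(*window) if window else np.ones(ratesA.t.size, bool)
    maskB = ratesB.time_slice(*window) if window else np.ones(ratesB.t.size, bool)
    bad = sorted(
        set(np.flatnonzero(ratesA.F[maskA].std(axis=0) == 0))
        | set(np.flatnonzero(ratesB.F[maskB].std(axis=0) == 0))
    )
    if bad:
        logger.info("excluding %d constant neurons from similarity test", len(bad))
    keep = np.setdiff1d(np.arange(ratesA.n_neurons), bad)
    S_A = similarity_matrix(ratesA, window, metric)[np.ix_(keep, keep)]
    S_B = similarity_matrix(ratesB, window, metric)[np.ix_(keep, keep)]
    n = S_A.shape[0]
    if n < 3:
        raise ParameterError("too few usable neurons for similarity comparison")

    s = np.abs(S_B).sum(axis=1)
    T = s.sum()
    E = np.outer(s, s) / T

    off = ~np.eye(n, dtype=bool)
    r_data = float(np.corrcoef(S_A[off], S_B[off])[0, 1])
    r_control = float(np.corrcoef(S_A[off], E[off])[0, 1])
    return SimilarityComparison(
        S_A=S_A, S_B=S_B, E=E, r_data=r_data, r_control=r_control, excluded=list(bad)
    )
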