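"""Low-dimensional embedding of population rates by principal components.

The population's joint activity at each time point is a point in
neuron-space; principal component analysis of the neuron-by-neuron covariance
of the spike-density functions yields orthonormal axes ordered by explained
variance.  The trajectory P(t) is the projection of the mean-centred rates
onto the leading ``d`` axes, where ``d`` is the smallest dimension count whose
cumulative explained variance reaches the threshold (80% by default).

Because the sign of a principal axis is arbitrary, each axis is flipped so
that its largest-magnitude loading is positive; repeated runs are therefore
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, DegenerateInputError, ParameterError
from .spikes import RateMatrix


@dataclass
class Embedding:
    """Principal axes and low-dimensional trajectory of one program.

    ``axes`` holds *all* principal axes as columns (neurons x n_axes);
    ``eigvals`` the corresponding variances, sorted descending.  ``P`` is the
    trajectory over the full time grid of the source rates, restricted to the
    leading ``d`` axes.  ``mean`` is the per-neuron centring vector computed
    over ``fit_range``.
    """

    axes: np.ndarray
    eigvals: np.ndarray
    var_explained: np.ndarray  # cumulative fraction per dimension count
    d: int
    P: np.ndarray
    t: np.ndarray
    mean: np.ndarray
    fit_range: tuple[float, float]
    neuron_ids: list[str] = field(default_factory=list)
    source: str = ""
    dt: float = 0.01


def _fix_signs(axes: np.ndarray) -> np.ndarray:
    flip = np.sign(axes[np.argmax(np.abs(axes), axis=0), np.arange(axes.shape[1])])
    flip[flip == 0] = 1.0
    return axes * flip[None, :]


def _pca(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the column covariance of ``X`` (rows = samples)."""
    cov = np.cov(X, rowvar=False, ddof=1)
    eigvals, axes = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    return eigvals, _fix_signs(axes[:, order])


def _choose_d(eigvals: np.ndarray, var_threshold: float) -> tuple[int, np.ndarray]:
    total = eigvals.sum()
    if total <= 0:
        raise DegenerateInputError("rate matrix has zero variance; nothing to embed")
    cum = np.cumsum(eigvals) / total
    d = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    return d, cum


def embed_population(
    rates: RateMatrix,
    var_threshold: float = 0.80,
    fit_range: tuple[float, float] | None = None,
    source: str = "",
) -> Embedding:
    """PCA-embed a program's rate matrix.

    Parameters
    ----------
    fit_range
        Time window (t0, t1) over which covariance and centring means are
        computed -- typically the post-stimulus window.  Defaults to the full
        evaluation window of ``rates``.  The trajectory ``P`` is returned over
        the *full* grid regardless, so pre-stimulus state distances remain
        available.
    var_threshold
        Cumulative variance fraction that the retained dimensions must reach.
    """
    if not (0 < var_threshold <= 1):
        raise ParameterError("var_threshold must be in (0, 1]")
    if fit_range is None:
        fit_range = rates.window_range
    mask = rates.time_slice(*fit_range)
    X = rates.F[mask]
    if X.shape[0] < 2:
        raise DegenerateInputError("fewer than 2 time points in the fit window")
    if np.count_nonzero(X.std(axis=0) > 0) < 2:
        raise DegenerateInputError("need >= 2 neurons with nonzero variance")
    eigvals, axes = _pca(X)
    d, cum = _choose_d(eigvals, var_threshold)
    mean = X.mean(axis=0)
    P = (rates.F - mean) @ axes[:, :d]
    return Embedding(
        axes=axes,
        eigvals=eigvals,
        var_explained=cum,
        d=d,
        P=P,
        t=rates.t.copy(),
        mean=mean,
        fit_range=fit_range,
        neuron_ids=list(rates.neuron_ids),
        source=source,
        dt=rates.dt,
    )


def _check_alignment(embedding: Embedding, rates: RateMatrix) -> None:
    if embedding.neuron_ids != list(rates.neuron_ids):
        offenders = [
            (i, a, b)
            for i, (a, b) in enumerate(zip(embedding.neuron_ids, rates.neuron_ids))
            if a != b
        ]
        raise AlignmentError(
            "neuron sets/order differ between embedding and rates; "
            f"mismatches (index, embedding, rates): {offenders[:10]}"
        )


def project_onto(
    embedding: Embedding,
    rates: RateMatrix,
    centering: str = "self",
) -> np.ndarray:
    """Project a program onto a reference program's principal axes.

    ``centering="self"`` (default) centres the new program with its own means
    over the reference's fit window; ``"reference"`` reuses the reference
    program's mean vector.
    """
    _check_alignment(embedding, rates)
    if centering == "self":
        lo, hi = embedding.fit_range
        mask = rates.time_slice(lo, hi)
        if not np.any(mask):
            mask = np.ones(rates.t.size, dtype=bool)
        mean = rates.F[mask].mean(axis=0)
    elif centering == "reference":
        mean = embedding.mean
    else:
        raise ParameterError(f"unknown centering {centering!r}")
    return (rates.F - mean) @ embedding.axes[:, : embedding.d]


def common_axes(
    programs: list[RateMatrix],
    var_threshold: float = 0.80,
    fit_ranges: list[tuple[float, float]] | None = None,
) -> Embedding:
    """Principal axes of the time-concatenated programs (a robustness control).

    All programs must share the same neuron set and order.  The returned
    embedding's trajectory is the projection of the concatenated mean-centred
    series; individual programs are projectable via :func:`project_onto`.
    """
    if not programs:
        raise ParameterError("need at least one program")
    ids = list(programs[0].neuron_ids)
    for p in programs[1:]:
        if list(p.neuron_ids) != ids:
            raise AlignmentError("programs passed to common_axes have differing neuron sets")
    if fit_ranges is None:
        fit_ranges = [p.window_range for p in programs]
    blocks = [p.F[p.time_slice(*fr)] for p, fr in zip(programs, fit_ranges)]
    X = np.vstack(blocks)
    if np.count_nonzero(X.std(axis=0) > 0) < 2:
        raise DegenerateInputError("need >= 2 neurons with nonzero variance")
    eigvals, axes = _pca(X)
    d, cum = _choose_d(eigvals, var_threshold)
    mean = X.mean(axis=0)
    P = (X - mean) @ axes[:, :d]
    dt = programs[0].dt
    return Embedding(
        axes=axes,
        eigvals=eigvals,
        var_explained=cum,
        d=d,
        P=P,
        t=dt * np.arange(X.shape[0]),
        mean=mean,
        fit_range=fit_ranges[0],
        neuron_ids=ids,
        source="common",
        dt=dt,
    )


def shuffled_projection(
    rates: RateMatrix,
    embedding: Embedding,
    seed: int | np.random.Generator = 0,
    permutation: np.ndarray | None = None,
    centering: str = "self",
) -> np.ndarray:
    """Null trajectory: shuffle which neuron carries which time series, project.

    The permutation reassigns the *time series* to neuron labels before
    projection onto the reference axes, preserving every single-neuron firing
    pattern while destroying its pairing with the loadings.  Used as the
    control for manifold distances.  Passing the identity ``permutation``
    reproduces :func:`project_onto` exactly.
    """
    _check_alignment(embedding, rates)
    n = rates.n_neurons
    if permutation is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        permutation = rng.permutation(n)
    permutation = np.asarray(permutation)
    if sorted(permutation.tolist()) != list(range(n)):
        raise ParameterError("permutation must be a permutation of neuron indices")
    F = rates.F[:, permutation]
    if centering == "self":
        lo, hi = embedding.fit_range
        mask = rates.time_slice(lo, hi)
        if not np.any(mask):
            mask = np.ones(rates.t.size, dtype=bool)
        mean = F[mask].mean(axis=0)
    else:
        mean = embedding.mean
    return (F - mean) @ embedding.axes[:, : embedding.d]
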