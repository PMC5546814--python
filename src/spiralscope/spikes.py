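"""Spike trains, spike-density functions, and firing-rate trend classification.

The raw input to the whole analysis is a set of per-neuron spike-time lists
(:class:`SpikeData`).  Before any state-space analysis the trains are converted
to continuous firing rates by convolving each spike with a normalised Gaussian
kernel, evaluated on a fixed 10 ms grid (:func:`spike_density`).  The kernel
width is tied to the population's firing statistics: by default the standard
deviation is the median inter-spike interval of the whole population divided
by 12.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr
from scipy.stats import pearsonr

from .errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)

#: half-width of the truncated Gaussian kernel, in units of sigma
KERNEL_SPAN_SIGMA = 5.0


@dataclass
class SpikeData:
    """Population spike-train recording.

    Parameters
    ----------
    spikes
        One sorted array of spike times (seconds) per neuron.
    duration
        Total recording span in seconds; all spike times lie in [0, duration].
    stim_on, stim_off
        Onset and offset of the evoking stimulus, in seconds.
    neuron_ids
        Per-neuron labels.  Defaults to ``"n000", "n001", ...``.
    coords
        Optional per-neuron (x, y) positions, shape (n_neurons, 2).
    """

    spikes: list[np.ndarray]
    duration: float
    stim_on: float
    stim_off: float
    neuron_ids: list[str] = field(default_factory=list)
    coords: np.ndarray | None = None

    def __post_init__(self):
        self.spikes = [np.asarray(s, dtype=float) for s in self.spikes]
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i:03d}" for i in range(len(self.spikes))]
        if len(self.neuron_ids) != len(self.spikes):
            raise ValidationError(
                f"{len(self.neuron_ids)} neuron ids for {len(self.spikes)} spike trains"
            )
        if not (0.0 <= self.stim_on <= self.stim_off <= self.duration):
            raise ValidationError(
                f"stimulus window [{self.stim_on}, {self.stim_off}] outside "
                f"recording span [0, {self.duration}]"
            )
        for i, s in enumerate(self.spikes):
            if s.size == 0:
                continue
            if np.any(np.diff(s) < 0):
                raise ValidationError(f"spike times of neuron {self.neuron_ids[i]} not sorted")
            if s[0] < 0 or s[-1] > self.duration:
                raise ValidationError(
                    f"neuron {self.neuron_ids[i]} has spikes outside [0, {self.duration}]"
                )

    @property
    def n_neurons(self) -> int:
        return len(self.spikes)

    def total_spikes(self) -> int:
        return int(sum(s.size for s in self.spikes))


@dataclass
class RateMatrix:
    """Spike-density functions on a fixed time grid.

    ``F[k, i]`` is the firing rate of neuron ``i`` (spikes/s) at time ``t[k]``.
    Grid times are bin centres: ``t[k] = t0 + k*dt``, with ``t0`` inclusive and
    ``t1`` exclusive.
    """

    t: np.ndarray
    F: np.ndarray
    sigma: float
    dt: float
    window_range: tuple[float, float]
    neuron_ids: list[str] = field(default_factory=list)
    stim_on: float | None = None
    stim_off: float | None = None

    def __post_init__(self):
        if self.F.shape[0] != self.t.shape[0]:
            raise ValidationError("rate matrix rows do not align with time grid")
        if self.sigma <= 0:
            raise ValidationError("kernel sigma must be positive")
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i:03d}" for i in range(self.F.shape[1])]

    @property
    def n_neurons(self) -> int:
        return self.F.shape[1]

    def time_slice(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask of grid points with ``t0 <= t < t1``."""
        return (self.t >= t0 - 1e-12) & (self.t < t1 - 1e-12)


def median_population_isi(spikes: SpikeData) -> float:
    """Median inter-spike interval pooled over every neuron in the population."""
    isis = [np.diff(s) for s in spikes.spikes if s.size >= 2]
    if not isis:
        raise ParameterError("no inter-spike interval in the population; cannot set sigma=auto")
    return float(np.median(np.concatenate(isis)))


def spike_density(
    spikes: SpikeData,
    t0: float,
    t1: float,
    dt: float = 0.01,
    sigma: float | str = "auto",
    sigma_divisor: float = 12.0,
) -> RateMatrix:
    """Convolve each neuron's spike train with a normalised Gaussian kernel.

    Each spike at time ``ts`` inside the evaluation window (t0, t1) contributes
    a Gaussian of SD ``sigma``, truncated at +/-5 sigma and normalised so that
    its integral over the window is 1 (edge spikes therefore do not lose mass).
    The resulting function is evaluated on the ``dt`` grid.

    Parameters
    ----------
    sigma
        Kernel SD in seconds, or ``"auto"`` to use the median population ISI
        divided by ``sigma_divisor`` (default 12; pass ``sqrt(12)`` via
        ``sigma_divisor`` to follow the square-root convention instead).

    Returns
    -------
    RateMatrix
        Rates in spikes/s; neurons without spikes in the window get an
        all-zero row (logged, not an error).
    """
    if t1 <= t0:
        raise ParameterError(f"empty evaluation window [{t0}, {t1}]")
    if sigma == "auto":
        if sigma_divisor <= 0:
            raise ParameterError("sigma_divisor must be positive")
        sigma_val = median_population_isi(spikes) / sigma_divisor
    else:
        sigma_val = float(sigma)
    if sigma_val <= 0:
        raise ParameterError("sigma must be positive")

    n_grid = int(round((t1 - t0) / dt))
    t = t0 + dt * np.arange(n_grid)
    F = np.zeros((n_grid, spikes.n_neurons))
    span = KERNEL_SPAN_SIGMA * sigma_val
    half_w = int(np.ceil(span / dt)) + 1
    norm = sigma_val * np.sqrt(2.0 * np.pi)

    for i, train in enumerate(spikes.spikes):
        ts = train[(train > t0) & (train < t1)]
        if ts.size == 0:
            logger.debug("neuron %s has no spikes in [%g, %g)", spikes.neuron_ids[i], t0, t1)
            continue
        # per-spike mass over (window intersect +/-5 sigma), via the normal CDF
        z_hi = np.minimum((t1 - ts) / sigma_val, KERNEL_SPAN_SIGMA)
        z_lo = np.maximum((t0 - ts) / sigma_val, -KERNEL_SPAN_SIGMA)
        mass = ndtr(z_hi) - ndtr(z_lo)
        centres = np.round((ts - t0) / dt).astype(int)
        offsets = np.arange(-half_w, half_w + 1)
        idx = centres[:, None] + offsets[None, :]
        valid = (idx >= 0) & (idx < n_grid)
        dtime = (t0 + dt * idx) - ts[:, None]
        kern = np.exp(-0.5 * (dtime / sigma_val) ** 2) / norm
        kern[~valid | (np.abs(dtime) > span)] = 0.0
        kern /= mass[:, None]
        np.add.at(F[:, i], np.where(valid, idx, 0).ravel(), kern.ravel())

    return RateMatrix(
        t=t,
        F=F,
        sigma=sigma_val,
        dt=dt,
        window_range=(t0, t1),
        neuron_ids=list(spikes.neuron_ids),
        stim_on=spikes.stim_on,
        stim_off=spikes.stim_off,
    )


def classify_rate_trend(
    spikes: SpikeData,
    group: list[int] | None = None,
    win: float = 20.0,
    step: float = 5.0,
    threshold: float = 0.2,
) -> str:
    """Classify the post-stimulus firing-rate trend of a group of neurons.

    Spikes of the group are counted in ``win``-second windows advanced by
    ``step`` seconds from stimulus onset; the Pearson correlation R between
    window time and spike count classifies the trend:
    R < -threshold -> ``"decreasing"``, R > threshold -> ``"increasing"``,
    otherwise ``"flat"``.  Zero-variance counts are treated as R = 0.
    """
    if spikes.duration < spikes.stim_on + win:
        raise ParameterError("recording must extend at least one window past stimulus onset")
    idx = range(spikes.n_neurons) if group is None else group
    pooled = np.sort(np.concatenate([spikes.spikes[i] for i in idx])) if idx else np.array([])

    starts = []
    s = spikes.stim_on
    while s + win <= spikes.duration + 1e-9:
        starts.append(s)
        s += step
    counts = np.array(
        [np.searchsorted(pooled, s + win) - np.searchsorted(pooled, s) for s in starts],
        dtype=float,
    )
    times = np.asarray(starts)
    if counts.std() == 0 or times.std() == 0:
        return "flat"
    r = pearsonr(times, counts).statistic
    if r < -threshold:
        return "decreasing"
    if r > threshold:
        return "increasing"
    return "flat"
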