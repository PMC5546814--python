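"""End-to-end orchestration: from spike tables to a preparation report.

A *preparation* is a set of sequentially evoked programs recorded from the
same population (three, in the emulated protocol), optionally with a
simultaneous nerve recording per program.  :func:`run_pipeline` runs every
analysis stage over a preparation -- rates, embedding, recurrence, attractor
estimation, manifold comparisons, decoding, participation -- isolating stage
failures so one aperiodic or degenerate program cannot sink the rest, and
returns a JSON-serialisable report plus the intermediate objects.

:func:`make_synthetic_preparation` packages the synthetic generators into a
complete preparation with ground truth, used for fixtures and self-tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import decode as dec
from . import lineardyn as ld
from . import manifold as mf
from . import participation as part
from . import recurrence as rc
from .config import RunConfig
from .embed import Embedding, embed_population
from .errors import SpiralscopeError
from .spikes import SpikeData, classify_rate_trend, spike_density
from .synth import (
    LatentSpiralParams,
    SyntheticGroundTruth,
    generate_nerve_output,
    generate_spiral_population,
    spiral_trajectory,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PreparationBundle:
    """Programs (plus optional nerve recordings) from one preparation."""

    programs: list[SpikeData]
    nerve: list[np.ndarray | None] = field(default_factory=list)
    coords: np.ndarray | None = None
    ground_truth: SyntheticGroundTruth | None = None
    seed: int | None = None

    def __post_init__(self):
        ids = self.programs[0].neuron_ids
        for p in self.programs[1:]:
            if p.neuron_ids != ids:
                raise SpiralscopeError("programs in a bundle must share one neuron set")
        if not self.nerve:
            self.nerve = [None] * len(self.programs)


def make_synthetic_preparation(
    seed: int = 0,
    n_programs: int = 3,
    n_neurons: int = 150,
    period: float = 10.0,
    contraction_per_s: float = 0.98,
    transient: float = 10.0,
    baseline_rate: float = 0.5,
    gain_jitter: float = 0.25,
    with_nerve: bool = True,
    pre_s: float = 30.0,
    post_s: float = 95.0,
) -> PreparationBundle:
    """A complete synthetic preparation: programs on one latent orbit.

    All programs share the preparation's neurons (base gains and phases);
    each program jitters the gains log-normally (``gain_jitter`` SD in log
    units, emulating the between-bout variability of single-neuron
    participation), starts the orbit at a different phase (different initial
    conditions), and draws independent spikes.  The nerve output, when
    requested, is generated from the latent orbit with a known log-link
    history filter, phase-locked to the first latent dimension.
    """
    rng = np.random.default_rng(seed)
    base_gains = rng.lognormal(mean=np.log(40.0), sigma=0.3, size=n_neurons)
    phases = rng.uniform(0, 2 * np.pi, size=n_neurons)

    # nerve filter: multi-unit scale (mean ~60 spikes/s) locked to latent
    # dimension 1 with modulation depth 3 (near-silent between bursts)
    H = 10
    beta0 = np.log(60.0)
    beta = np.zeros((2, H))
    beta[0, :] = 3.0 / H

    programs, nerves = [], []
    truth = None
    for m in range(n_programs):
        gains = base_gains * rng.lognormal(mean=0.0, sigma=gain_jitter, size=n_neurons)
        params = LatentSpiralParams(
            period=period,
            contraction_per_s=contraction_per_s,
            n_neurons=n_neurons,
            baseline_rate=baseline_rate,
            gains=gains,
            phases=phases,
            transient=transient,
            pre_s=pre_s,
            post_s=post_s,
            phase0=float(rng.uniform(0, 2 * np.pi)),
            kick_angle=float(rng.uniform(0, 2 * np.pi)),
            seed=int(rng.integers(2**31 - 1)),
        )
        spikes, gt = generate_spiral_population(params)
        programs.append(spikes)
        if truth is None:
            truth = gt
        if with_nerve:
            # nerve driven by the orbit-only latent (no approach kick), so the
            # log-link exponent stays bounded by beta0 + sum(beta)
            _, z_orbit = spiral_trajectory(
                period, contraction_per_s, post_s, dt=params.dt,
                phase0=params.phase0,
            )
            nerve_times, _ = generate_nerve_output(
                z_orbit, beta0, beta, dt=params.dt,
                seed=int(rng.integers(2**31 - 1)), t0=float(gt.latent_t[0]),
            )
            nerves.append(nerve_times)
        else:
            nerves.append(None)
    truth.true_beta = {"beta0": float(beta0), "beta": beta.tolist(), "basis": "latent"}
    return PreparationBundle(
        programs=programs, nerve=nerves, ground_truth=truth, seed=seed
    )


# ---------------------------------------------------------------------------

@dataclass
class ProgramResult:
    """Intermediate objects for one program (not serialised)."""

    rates: object = None
    embedding: Embedding | None = None
    recurrence: rc.RecurrenceResult | None = None
    densities: list | None = None
    coalescence: float | None = None
    events: list | None = None
    attractor: ld.AttractorEstimate | None = None
    drift: ld.DriftResult | None = None
    participation: part.ParticipationTable | None = None


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _json_safe(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _json_safe(dataclasses.asdict(obj))
    return obj


def run_pipeline(
    bundle: PreparationBundle,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    decode_history_grid: tuple[float, ...] | None = None,
) -> tuple[dict, list[ProgramResult]]:
    """Run every analysis stage over a preparation.

    Returns ``(report, results)``: a JSON-serialisable preparation report
    (periods, coalescence, attractor class, perturbation events, decoding
    scores, strongly-variable neurons, provenance) and the per-program
    intermediate objects.  A stage failure is recorded in
    ``report["failures"]`` and downstream stages that depend on it are
    skipped for that program only.
    """
    config = config or RunConfig()
    report: dict = {
        "programs": [],
        "cross": {},
        "participation": {},
        "failures": [],
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": bundle.seed,
            "version": __version__,
            "n_programs": len(bundle.programs),
            "n_neurons": bundle.programs[0].n_neurons,
        },
    }
    results = [ProgramResult() for _ in bundle.programs]

    def fail(stage: str, prog: int | None, err: Exception):
        logger.warning("stage %s failed for program %s: %s", stage, prog, err)
        report["failures"].append({"stage": stage, "program": prog, "error": str(err)})

    cfg_r = config.recurrence
    for m, spikes in enumerate(bundle.programs):
        prog_report: dict = {"index": m}
        res = results[m]
        try:
            res.rates = spike_density(
                spikes, 0.0, spikes.duration, dt=config.sdf.dt,
                sigma=config.sdf.sigma, sigma_divisor=config.sdf.sigma_divisor,
            )
            prog_report["sigma_s"] = res.rates.sigma
            prog_report["rate_trend"] = classify_rate_trend(spikes)
        except SpiralscopeError as err:
            fail("sdf", m, err)
            report["programs"].append(prog_report)
            continue
        try:
            res.embedding = embed_population(
                res.rates, var_threshold=config.embed.var_threshold,
                fit_range=(spikes.stim_off, spikes.duration), source=f"program{m}",
            )
            prog_report["embedding_dims"] = res.embedding.d
            prog_report["var_explained_at_d"] = float(
                res.embedding.var_explained[res.embedding.d - 1]
            )
        except SpiralscopeError as err:
            fail("embed", m, err)
            report["programs"].append(prog_report)
            continue
        try:
            scan = (
                spikes.stim_on + cfg_r.scan_start_after_stim,
                spikes.duration - cfg_r.scan_end_margin,
            )
            rec = rc.find_recurrence(
                res.embedding.P, dt=config.sdf.dt, t_start=0.0,
                theta_percentile=cfg_r.theta_percentile, scan=scan,
            )
            rec = rc.detect_periodic_orbit(
                rec, bin_s=cfg_r.bin_s, min_delay=cfg_r.min_delay,
                min_peak_points=cfg_r.min_peak_points,
            )
            res.recurrence = rec
            res.densities = rc.window_density(rec, win=cfg_r.window, step=cfg_r.step)
            res.coalescence = rc.coalescence_time(res.densities, threshold=cfg_r.coalesce)
            prog_report["theta"] = rec.theta
            prog_report["recurrence_fraction"] = rec.recurrence_fraction
            prog_report["period_s"] = rec.period
            prog_report["aperiodic"] = rec.dominant is None
            prog_report["coalescence_s"] = res.coalescence
        except SpiralscopeError as err:
            fail("recurrence", m, err)
            report["programs"].append(prog_report)
            continue

        if rec.dominant is not None and res.coalescence is not None:
            try:
                res.events = rc.detect_perturbations(
                    rec, res.densities, period=rec.period, coalescence=res.coalescence,
                    recover_threshold=cfg_r.coalesce, diverge_threshold=cfg_r.diverge_low,
                    same_manifold_min=cfg_r.same_manifold_min, win=cfg_r.window,
                    recording_end=spikes.duration,
                )
                prog_report["perturbations"] = [
                    {"span": list(e.span), "divergent_point": e.divergent_point,
                     "outcome": e.outcome,
                     "same_manifold_fraction": e.same_manifold_fraction}
                    for e in res.events
                ]
            except SpiralscopeError as err:
                fail("perturbations", m, err)
            try:
                anchors = np.flatnonzero(
                    np.isin(np.round(res.embedding.t / config.sdf.dt).astype(int),
                            np.round(rec.times[rec.dominant_mask()] / config.sdf.dt).astype(int))
                )
                fits = ld.fit_along_trajectory(
                    res.embedding.P, anchors, rec.theta, dt=config.sdf.dt,
                    radius_mult=config.lineardyn.radius_mult,
                    min_points=config.lineardyn.min_points,
                )
                res.attractor = ld.summarize_attractor(fits, rec, dt=config.sdf.dt)
                est = res.attractor
                prog_report["attractor"] = {
                    "a_mean": est.a_mean, "b_mean": est.b_mean,
                    "a_sem": est.a_sem, "b_sem": est.b_sem,
                    "period_est_s": est.period_est,
                    "contraction_pct_per_s": est.contraction_pct_per_s,
                    "classification": est.classification,
                    "rotation_fraction": est.rotation_fraction,
                    "n_fits": est.n_fits,
                }
            except SpiralscopeError as err:
                fail("lineardyn", m, err)
            try:
                drift = ld.period_drift(
                    res.densities, res.coalescence, n_perm=config.drift.n_perm,
                    seed=(config.seed or 0) + 7919 * (m + 1), tail=config.drift.tail,
                    recover_threshold=cfg_r.coalesce,
                )
                res.drift = drift
                prog_report["drift"] = {"rho": drift.rho, "p": drift.p,
                                        "n_windows": drift.n_windows}
            except SpiralscopeError as err:
                fail("drift", m, err)
        try:
            res.participation = part.participation_scores(res.embedding)
        except SpiralscopeError as err:
            fail("participation_scores", m, err)

        nerve = bundle.nerve[m] if m < len(bundle.nerve) else None
        if nerve is not None and len(nerve) > 0:
            try:
                screen = dec.screen_motorneurons(spikes, nerve)
                prog_report["motorneuron_screen_max"] = float(np.nanmax(screen.max_prob))
                nerve_data = SpikeData(
                    spikes=[np.asarray(nerve)], duration=spikes.duration,
                    stim_on=spikes.stim_on, stim_off=spikes.stim_off, neuron_ids=["nerve"],
                )
                nerve_rates = spike_density(
                    nerve_data, 0.0, spikes.duration, dt=config.sdf.dt,
                    sigma=res.rates.sigma,
                )
                grid = decode_history_grid or config.decode.history_grid()
                summary = dec.evaluate_decoding(
                    res.embedding.P, nerve_rates.F[:, 0],
                    history_grid_ms=grid,
                    fit_s=config.decode.fit_s, forecast_s=config.decode.forecast_s,
                    step_s=config.decode.slide_s, dt=config.sdf.dt, t_start=0.0,
                    eval_range=(spikes.stim_off, spikes.duration),
                    family=config.decode.family,
                )
                k = int(np.flatnonzero(summary.history_ms == summary.best_history_ms)[0])
                prog_report["decoding"] = {
                    "best_history_ms": summary.best_history_ms,
                    "median_R": float(summary.median_R[k]),
                    "median_MAE": float(summary.median_MAE[k]),
                    "n_windows": len(summary.scores[summary.best_history_ms]),
                }
            except SpiralscopeError as err:
                fail("decode", m, err)
        report["programs"].append(prog_report)

    # ----- cross-program stages -------------------------------------------
    ok = [m for m, r in enumerate(results)
          if r.embedding is not None and r.recurrence is not None]
    ref = results[ok[0]].embedding if ok else None
    norm_dist: dict[tuple[int, int], float] = {}
    if ref is not None and len(ok) >= 2:
        pairs = [(a, b) for i, a in enumerate(ok) for b in ok[i + 1:]]
        comparisons = []
        for a, b in pairs:
            try:
                comp = mf.compare_manifolds(
                    results[a].rates, results[b].rates, ref,
                    results[a].recurrence, results[b].recurrence,
                    n_shuffles=config.shuffles,
                    seed=(config.seed or 0) + 104729 * (a * 10 + b),
                    pair=(f"program{a}", f"program{b}"),
                )
                entry = {"pair": [a, b], "hausdorff": comp.hausdorff,
                         "control_mean": comp.control_mean,
                         "control_sem": comp.control_sem,
                         "normalized": comp.normalized}
                norm_dist[(a, b)] = comp.normalized
                if results[a].coalescence is not None and results[b].coalescence is not None:
                    sd = mf.state_distances(
                        results[a].rates, results[b].rates, ref,
                        results[a].recurrence, results[b].recurrence,
                        results[a].coalescence, results[b].coalescence,
                        stim_on=bundle.programs[a].stim_on,
                    )
                    entry["state_distances"] = dataclasses.asdict(sd)
                sim = mf.similarity_null_test(
                    results[a].rates, results[b].rates,
                    window=(bundle.programs[a].stim_off, bundle.programs[a].duration),
                )
                entry["similarity"] = {"r_data": sim.r_data, "r_control": sim.r_control}
                comparisons.append(entry)
            except SpiralscopeError as err:
                fail("manifold", f"{a},{b}", err)
        report["cross"]["comparisons"] = comparisons

    # ----- participation over the preparation ------------------------------
    tables = [r.participation for r in results if r.participation is not None]
    if len(tables) >= 2:
        try:
            deltas = part.participation_changes(tables)
            model = part.fit_noise_model(deltas, outlier_sd=config.participation.outlier_sd)
            n_neurons = len(tables[0].neuron_ids)
            n_pairs = deltas.size // n_neurons
            per_neuron = deltas.reshape(n_pairs, n_neurons)
            variable = np.flatnonzero(
                np.any((per_neuron < model.threshold_lo)
                       | (per_neuron > model.threshold_hi), axis=0)
            )
            report["participation"] = {
                "noise_model": {"mu": model.mu, "sd": model.sd,
                                "threshold_lo": model.threshold_lo,
                                "threshold_hi": model.threshold_hi,
                                "n_iterations": model.n_iterations},
                "strongly_variable": [tables[0].neuron_ids[i] for i in variable],
                "fraction_strongly_variable": float(variable.size / n_neurons),
            }
        except SpiralscopeError as err:
            fail("participation_noise", None, err)
        try:
            if len(norm_dist) >= 3:
                _, corrs = part.variability_vs_distance(
                    tables, norm_dist, hellinger_bins=config.participation.hellinger_bins
                )
                report["participation"]["variability_vs_distance"] = corrs
        except SpiralscopeError as err:
            fail("participation_distance", None, err)
        try:
            report["participation"]["correlates"] = [
                part.participation_correlates(t, r.rates)
                for t, r in zip(tables, results)
                if r.rates is not None
            ]
        except SpiralscopeError as err:
            fail("participation_correlates", None, err)

    report = _json_safe(report)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report, results
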