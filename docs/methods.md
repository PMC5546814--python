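# Methods

This note documents the models and procedures implemented in `spiralscope`,
the defaults they use, the design choices made where the method left room,
and the known limits of what the synthetic tests demonstrate.

## The analysis in one paragraph

Population spike trains are converted to spike-density functions (SDFs) on a
10 ms grid, embedded by PCA into the fewest dimensions capturing 80% of the
variance, and examined for *recurrence*: a trajectory point recurs if the
trajectory later re-enters a ball of radius θ around it, where θ is the 10th
percentile of all pairwise distances between analysed points. A histogram of
recurrence delays (1 s bins, delays < 5 s discarded) exposes periodic orbits;
the peak holding the most points is the dominant orbit and its mean delay the
orbital period. Sliding-window recurrence density (5 s windows, 1 s steps)
gives the coalescence time (first window ≥ 90% recurrent) and flags
spontaneous perturbations (sustained dips below 90% reaching below 50%).
Local linear models `ΔP = A P` fitted around each dominant-orbit point give
Jacobian eigenvalues; averaging the eigenvalue with the largest real part,
λ = a + ib, over those points classifies the attractor (stable spiral when
a < 0, b > 0) with orbital period 2πΔt/b and per-second contraction
100·exp(a/Δt) %. Motor-nerve rate is decoded from the trajectory with a
log-link history GLM (40 s fits, 10 s forecasts, 50–200 ms histories), and
per-neuron participation is the eigenvalue-weighted L1 loading
ρ_i = Σ_j |λ_j W_j(i)|, with between-program changes screened against an
iteratively trimmed Gaussian noise model (±3 SD outliers).

## Spike-density functions

Each spike contributes a Gaussian truncated at ±5σ and normalised to unit
mass *over the evaluation window*, so edge spikes lose no mass; grid times
are bin centres, start inclusive, end exclusive. By default σ is the median
inter-spike interval pooled over the population divided by 12. The divisor
is configurable (`sdf.sigma_divisor`), including √12: kernel-width rules in
the earlier literature use √12, the divisor-12 form is the convention this
pipeline standardises on, and both are defensible.

**Poisson caveat.** The ISI/12 rule is calibrated to the near-regular
bursting of real neurons, whose smoothed SDFs are almost deterministic.
Under Poisson spiking (our synthetic populations) the same rule
under-smooths: the shot-noise variance of the SDF, λ/(2√π σ), stays
comparable to the modulation variance for *any* rate scale, because σ
shrinks as rates rise. Synthetic analyses therefore fix σ = 0.12 s
(`synthetic_run_config()`), which is still ≪ the 10 s orbit period. This is
a property of the synthetic spiking model, not of the method.

## Embedding

PCA is applied to the neuron covariance of the SDFs over the post-stimulus
window; the trajectory is projected over the full recording so pre-stimulus
state distances remain available. The retained dimension count d is the
smallest reaching 80% cumulative variance. Axis signs are fixed by forcing
each axis's largest-magnitude loading positive, making repeated runs
bit-identical. When projecting program B onto program A's axes, B is centred
on its own means by default (`embed.centering = "self"`); reference centring
is available, and the common-axes control (PCA of the concatenated programs)
provides the robustness check.

## Recurrence

Distances are Euclidean in the d-dimensional projection. θ is the 10th
percentile (linear interpolation) of all pairwise distances between scanned
points — scanned means from 5 s after stimulation to 10 s before the end;
the forward search for a return extends to the end of the trajectory. The
contiguous run of points around the anchor that never leaves the θ-ball is
skipped before searching, so the delay measures a genuine return; a point
whose trajectory never leaves the ball at all is *not* recurrent. Squared
distances are computed in float32 blocks; the brute-force reference in the
test suite follows the same convention so agreement can be asserted exactly.

Orbit detection: delays ≥ 5 s are histogrammed in 1 s bins; peaks are
maximal contiguous runs of non-empty bins holding more than 100 points;
the dominant peak has the most points (ties resolved toward the smaller mean
delay, logged); programs with no qualifying peak are flagged aperiodic and
the attractor summary is skipped. Coalescence is the midpoint of the first
5 s window with ≥ 90% recurrent points. Perturbation spans are maximal
window runs below 90% dipping below 50%, dropped when the lowest-density
window falls within two orbital periods of the recording end; a span is
`returned_*` when density later recovers to ≥ 90%, and `returned_same` when
at least 10% (`recurrence.same_manifold_min`; the fraction itself is the
primary readout; the cut-off is our operationalisation) of the final pre-span window's
recurrence delays land beyond the span's end.

**First-entry bias.** The delay is measured to the *first* entry into the
θ-ball, which on a closed orbit occurs up to ~θ/(orbit speed) before a full
revolution; on a contracting orbit the inward drift advances first entry
further as the radius decays toward θ. Period estimates from recurrence are
therefore biased slightly low (≈ −0.5 s on a noisy 10 s circle; ≈ −1.1 s on
the default decaying synthetic), and windowed mean delays fall over a
decaying program, which the drift statistic reads as "speeding". Both are
inherent to recurrence-based period tracking on contracting orbits; the
local-linear-model estimate of the period does not share this bias.

## Local linear models and attractor summary

The neighbourhood of an anchor is the time-contiguous stretch staying within
2.5·θ of it; fits with fewer than `lineardyn.min_points` points are
discarded. Points and their first differences are both centred on the
neighbourhood (affine local model: the orbit is not locally centred at the
origin; the intercept leaves A unchanged for linear dynamics), and A solves
the least-squares regression of ΔP on P, making A per-time-step. The
reported period is 2πΔt/b — the alternative form ω = 2πbΔt sometimes
quoted for this estimator is dimensionally inconsistent with ~10 s orbits at b ≈ 6×10⁻³ rad/step and Δt = 0.01 s, and
with the observation that larger b means faster orbits.

Defaults: `min_points = 100` at the 10 ms-smoothing regime of real data.
For synthetic analyses at σ = 0.12 s the floor scales with the smoothing
ratio to 1000 (a 100-point window at 120 ms smoothing holds only ~8
independent observations, far too few to identify a d×d Jacobian).

**Degenerate mode selection.** "Maximum eigenvalue" means largest real
part, conjugates resolved to b ≥ 0. When several modes contract at the same
rate — e.g. the envelope and harmonic pairs of a rectified-coupling
population, which all decay at κ — the selection among them is decided by
estimation noise, and the averaged b mixes rotation rates. Classification
(sign of a) and contraction are robust to this; the recurrence histogram
remains the primary period readout for such orbits.

**Noise sensitivity.** On noiseless linear systems the estimator recovers
(a, b) to machine precision (tested to 2% across spectral radii and rotation
rates). White per-sample observation noise is an errors-in-variables regime:
it attenuates A toward −(noise var/signal var)·I per step, which swamps a
(|a| ~ 2×10⁻⁴) long before it harms b. Temporally smooth noise, as a
kernel-smoothed trajectory actually carries, is far more benign; tests
assert b-recovery at 10% under 5% white noise and full (a, b) recovery under
mild smooth noise.

## Decoding

The nerve rate is modelled as
f(t) = exp(β₀ + Σ_{i≤d} Σ_{h=1..m} β_{i,h} P_i(t−h)) with 10 ms lag steps
and histories of 50–200 ms — short enough that a phase-offset copy of the
nerve inside the population cannot carry the prediction. Fitting is a
Poisson GLM (log link) by IRLS on standardised regressors (statsmodels),
coefficients mapped back; a ridge-penalised Gaussian fit on log-rate is the
configurable fallback. Forecasts use the trajectory only — the function
signature admits no nerve data — and are scored by Pearson R and median
absolute error over 10 s windows following each 40 s fit window, slid in
1 s steps; the history with the smallest median absolute error is selected.
The motorneuron screen reports, per neuron, the maximum over 0–25 ms delays
of the fraction of its spikes echoed by a nerve spike within ±2 ms.

## Participation

ρ_i = Σ_{j≤d} |λ_j W_j(i)| uses variance (λ) weighting (not √λ),
normalised to the program maximum (%). The noise model for between-program
changes is fitted by iterative trimming: fit the ML Gaussian, remove the
point furthest from the mean, refit, and stop when the candidate is within
3 SD of the current fit or the retained-data likelihood decreases.
(Termination on the likelihood alone is scale-dependent — removing any
point with negative log-density raises the total — so the 3 SD guard is
what fires in practice.) Strongly variable neurons are those with any
pairwise change beyond mean ± 3 SD of the final model. Pooling uses all
program pairs; consecutive pairs define each neuron's maximum change.
Participation distributions are compared by Hellinger distance over 20
equal-width bins on [0, 100]% (bin count configurable; the binning is our
choice). Rate and synchrony correlates use the window from stimulus offset
to the recording end, with synchrony the summed absolute SDF correlation
with all other neurons.

## Synthetic data

The generator emulates an evoked escape-locomotion program: 150 neurons,
30 s spontaneous + 95 s evoked, a planar latent orbit
z(t) = e^(−κt)(cos ωt, sin ωt) with period 10 s and contraction 98 %/s, an
off-orbit approach kick decaying logistically over the `transient` (default
10 s), per-neuron intensity
λ_i(t) = baseline + gain_i · max(0, z(t)·u(φ_i)) — a half-rectified
projection onto the neuron's preferred phase direction — and spikes drawn by
exact thinning of an inhomogeneous Poisson process. Defaults: baseline
0.5 Hz, gains log-normal (median 40 Hz, log-SD 0.3), phases uniform. These
rates put the latent signal above the Poisson shot noise in the covariance
spectrum so that the 80% threshold retains 3–5 dimensions, matching the 4–8
seen in real recordings; the rectified coupling contributes genuine harmonic
and envelope dimensions, also as in real data. A preparation bundles three
programs sharing neurons (gains jittered log-normally with SD 0.25 between
programs, emulating variable participation; start phases and kick directions
random), plus a nerve generated from the orbit-only latent through a known
log-link history filter at whole-nerve scale (β₀ = log 60 Hz, modulation
depth 3 on latent dimension 1).

**Perturbation-return detectability.** Classifying a return to the *same*
manifold requires pre-perturbation recurrence delays that skip over the
divergent span, i.e. successive orbit turns must stay within θ of each other
across a 1.5–3 period gap. At 2%/s decay the turns are 16–30% of the radius
apart over such a gap — comparable to θ, so the call flips with the draw;
at 1%/s (well inside the range of observed contraction rates) it is robust.
Perturbation-return demonstrations therefore use a 0.99/s program; this is a
geometric condition for detectability, not a tuning of the detector.

The approach kick is 2× the initial orbit radius; its logistic gate is
parameterised so the displacement falls below typical θ (~15% of the kick)
at ≈ 0.77·transient and below 1% by the transient's end, placing detected
coalescence near the nominal transient. The `remap` perturbation permutes
neuron identities inside the window (each neuron adopts another's phase
pattern), moving the joint state off the manifold while preserving the
population spike count; `suppress` thins spikes. Ground truth records the
per-step map eigenvalues a = ln(c)·Δt, b = ωΔt; note the discrete-map real
part c^Δt·cos(ωΔt) − 1 makes the exact recoverable contraction 97.8%/s
rather than 98.0 — within the tolerance used throughout.

**What the synthetic data do not share with real recordings:** spiking is
Poisson (real bursts are near-regular, hence real SDFs are cleaner at the
ISI/12 kernel width); the latent is strictly planar with a fixed angular
velocity (so "period drift" in the synthetic reflects only the recurrence
first-entry bias); spontaneous activity is unstructured baseline firing; and
no slow behavioural transitions (gallop→crawl) are modelled. Passing tests
therefore validate the estimators and the pipeline plumbing, not the
biological claims.

## The Matsuoka demonstration network

Three rate neurons with mutual inhibition and adaptation:
τ_a ȧ_i = −a_i + c_i + Σ_j w_ji r_j − γ y_i, τ_y ẏ_i = −y_i + r_i,
r_i = max(0, a_i), with τ_a = 25 ms, τ_y = 200 ms, γ = 2, c = 3. The
inhibitory weight is a free choice of the model; we use w = −2 between all
pairs (configurable). Integration is fixed-step RK4 at 1 ms
(dt ≤ τ_a/5 enforced; halving dt changes late-time mean rates by < 1%).
Default initial conditions are small distinct positive activations
a_i(0) = 0.1·i — the symmetric network would otherwise sit on its unstable
symmetric equilibrium. A single uncoupled neuron converges to
r* = c/(1+γ), the closed form used as an integration oracle.

## Numerical and degenerate-input conventions

- Recurrence on a trajectory whose scanned points are mostly identical
  (e.g. a fully silenced recording) yields θ = 0 and is rejected as
  degenerate rather than guessed around.
- Permutation p-values use the add-one convention (count+1)/(n_perm+1), so
  p ∈ (0, 1] and is exactly uniform under the null; the drift test is
  two-sided by default (`drift.tail`).
- Drift windows with zero delay-SD would get infinite weight w = Q/s; they
  are capped at the 99th percentile of the finite weights (logged).
- Constant-rate forecast windows report MAE with R as missing; constant
  similarity columns are excluded (logged); zero-variance trend counts are
  classified flat.
- All randomness flows from explicit seeds; reports are byte-identical
  under a fixed seed and configuration, and the configuration hash in each
  report's provenance changes iff any constant changes.

## Problem sizes used by the test suite and acceptance script

Unit tests run on reduced populations (40–60 neurons, 30–60 s evoked);
acceptance checks run the full 150-neuron, 95 s conditions with 20 seeds for
period recovery, 10 starting phases for spiral-parameter recovery, and a
4-point history grid (50/100/150/200 ms) for the decoder sweep; drift-null
calibration uses 200 runs of 1000 permutations. These sizes keep the whole
suite and the acceptance script each within a few minutes on one core while
leaving every tolerance at its stated value.

## Known limitations

- The 80% variance rule inflates d on data whose per-neuron noise rivals
  the shared signal; on such data recurrence distances are noise-dominated.
  This is a property of the variance-threshold rule itself, kept for
  fidelity to the standard analysis.
- The peak rule (contiguous non-empty 1 s bins, > 100 points) can qualify
  broad delay distributions from long smooth-noise recordings as "orbits";
  aperiodicity detection is reliable for drifting or short programs but is
  not a general chaos test.
- Eigenvalue summaries on orbits with several equal-decay modes mix
  rotation rates (see above).
- `detect_perturbations` classifies manifold return from recurrence delays
  alone; it does not re-embed or compare manifolds across the span.
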