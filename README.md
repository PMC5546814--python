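# spiralscope

Recurrence-based identification of low-dimensional periodic attractors in
neural population spike-train recordings.

## The problem

Rhythmic motor behaviour — the escape gallop of *Aplysia*, driven by its
pedal ganglion — is produced by populations of 100+ neurons whose joint
activity is high-dimensional and heterogeneous, yet is hypothesised to arise
from a much simpler underlying dynamical system. `spiralscope` implements a
complete analysis chain for testing that hypothesis on population spike
trains: does the joint activity fall onto a low-dimensional periodic orbit,
does it behave like a true attractor (repeated evocations converge to the
same manifold; transient perturbations return to it), what *kind* of
attractor is it, does its trajectory encode the motor output, and how much
does any single neuron matter to it?

The package is a library: `import spiralscope` and compose the stages, or
call `run_pipeline` for the whole chain. The `examples/` directory holds one
short narrative script per capability.

## The method

1. **Rates.** Spike trains → spike-density functions: each spike convolved
   with a Gaussian (σ = median population ISI / 12 by default), 10 ms grid.
2. **Embedding.** PCA of the neuron covariance; keep the fewest dimensions
   d reaching 80% variance; trajectory `P(t)` = projection of the
   mean-centred rates.
3. **Recurrence.** `P(t)` *recurs* if the trajectory later re-enters the
   θ-ball around it (θ = 10th percentile of pairwise distances); the delay δ
   to first return is its recurrence time. The histogram of delays (1 s
   bins, δ ≥ 5 s) exposes periodic orbits; the peak with the most points is
   the dominant orbit, its mean δ the orbital period. Windowed recurrence
   density gives the coalescence time (first 5 s window ≥ 90% recurrent) and
   spontaneous perturbations (sustained dips below 90% reaching 50%), each
   classified as returning to the same manifold, a different one, or not at
   all.
4. **Attractor estimation.** Around every dominant-orbit point, fit the
   local linear model ΔP = **A**P; the eigenvalue of **A** with largest real
   part, λ = a + ib, gives the local dynamics. Averaged over the orbit:
   a < 0, b > 0 ⇒ **stable spiral**, with period 2πΔt/b and contraction
   100·e^(a/Δt) % per second. A weighted Spearman permutation test tracks
   drift of the orbital period over the program.
5. **Decoding.** Nerve rate modelled as
   f(t) = exp(β₀ + Σᵢ Σₕ β_{i,h} P_i(t−h)) over 50–200 ms histories
   (Poisson GLM); validated by forecasting 10 s ahead from the trajectory
   alone, sliding a 40 s fit window in 1 s steps.
6. **Participation.** Per neuron, ρᵢ = Σⱼ |λⱼ Wⱼ(i)| over the retained
   axes; between-program changes are screened against an iteratively
   trimmed Gaussian noise model (±3 SD) to find strongly variable neurons.

Everything is exercisable on synthetic data with known ground truth: a
Matsuoka mutual-inhibition network (the minimal periodic-attractor model), a
latent decaying-spiral population with Poisson spiking, a phase-locked
synthetic nerve, and perturbation injection. See `docs/methods.md` for the
models, defaults, and design choices.

## A worked example

```python
import spiralscope as ss
from spiralscope.config import synthetic_run_config

bundle = ss.make_synthetic_preparation(seed=1)   # 3 programs + nerve, known truth
report, results = ss.run_pipeline(bundle, synthetic_run_config())
```

On the default synthetic preparation (latent orbit period 10 s, contraction
98 %/s, 150 neurons) this prints into `report` — values from an actual run:

```
program 0: d=3, recurrence period 8.82 s, coalescence 40.5 s, stable_spiral,
           contraction 98.96 %/s, decode median R 0.95
program 1: d=3, recurrence period 8.87 s, coalescence 38.5 s, stable_spiral,
           contraction 99.03 %/s, decode median R 0.93
program 2: d=3, recurrence period 8.85 s, coalescence 42.5 s, stable_spiral,
           contraction 98.65 %/s, decode median R 0.93
pair (0,1): Hausdorff 411.6 vs shuffle control 523.0  (normalized 0.79)
pair (0,2): Hausdorff 438.4 vs shuffle control 522.2  (normalized 0.84)
pair (1,2): Hausdorff  48.8 vs shuffle control 154.3  (normalized 0.32)
similarity r_data ≈ 0.91 vs r_control ≈ 0.04;  3/150 strongly variable neurons
```

Reading it: each evoked program lands on a ~3-dimensional orbit of roughly
the generating 10 s period (recurrence reads it slightly short — first-entry
bias; see the methods note), coalesces onto the manifold shortly after the
10 s approach transient, and is classified a stable spiral with contraction
within a point of the generating 98 %/s. Every program pair lies closer to
the others than shuffled projections do (normalized < 1): repeated
evocations reach the same manifold. The nerve rate is forecast from the
trajectory alone with median R ≈ 0.93, and a small fraction of neurons
change their participation between programs far beyond measurement noise —
the program is stable while its participants are not.

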