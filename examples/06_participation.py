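"""How much does each neuron contribute to the low-dimensional trajectory?

Participation is the eigenvalue-weighted absolute sum of a neuron's PCA
loadings. Comparing repeated programs from one preparation, a Gaussian noise
model (iteratively trimmed, +-3 SD thresholds) separates measurement noise
from genuinely strongly-variable neurons.
"""

import numpy as np

from spiralscope import (
    embed_population,
    fit_noise_model,
    make_synthetic_preparation,
    participation_scores,
    spike_density,
)
from spiralscope.participation import participation_changes

bundle = make_synthetic_preparation(seed=1, with_nerve=False)
tables = []
for m, spikes in enumerate(bundle.programs):
    rates = spike_density(spikes, 0, spikes.duration, sigma=0.12)
    emb = embed_population(rates, fit_range=(spikes.stim_off, spikes.duration))
    tables.append(participation_scores(emb, source=f"program{m}"))

p0 = tables[0].rho_norm
print(f"program 1 participation: median {np.median(p0):.1f}%, "
      f"top neuron {tables[0].neuron_ids[int(np.argmax(p0))]} at 100%")
print(f"long tail: {np.sum(p0 > 50)} of {p0.size} neurons above 50% of the maximum")

deltas = participation_changes(tables)
model = fit_noise_model(deltas)
n_neurons = p0.size
per_pair = deltas.reshape(-1, n_neurons)
variable = np.flatnonzero(np.any(
    (per_pair < model.threshold_lo) | (per_pair > model.threshold_hi), axis=0))
print(f"noise model over {deltas.size} between-program changes: "
      f"mu = {model.mu:.2f}, sd = {model.sd:.2f} "
      f"({model.n_iterations} trimming iterations)")
print(f"strongly variable neurons (beyond +-3 SD): {variable.size} "
      f"({100 * variable.size / n_neurons:.1f}% of the population)")
print()
print("The generator jitters each neuron's coupling between programs; neurons")
print("in the tail of the jitter distribution change their role far beyond the")
print("noise model while the orbit itself stays put -- participation varies,")
print("the program does not. (How many clear the 3 SD bar depends on the draw.)")
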