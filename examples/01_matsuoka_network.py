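"""The Matsuoka mutual-inhibition network: oscillation without oscillators.

Three rate neurons with adaptation and all-to-all inhibition settle into a
self-sustained alternating rhythm under constant drive, even though a single
uncoupled neuron just relaxes to a fixed point -- the rhythm is an emergent
network property, the minimal model of a periodic attractor.
"""

import numpy as np

from spiralscope import MatsuokaParams, simulate_matsuoka

# one uncoupled neuron: relaxes to the closed-form equilibrium c / (1 + gamma)
single = simulate_matsuoka(MatsuokaParams(W=np.zeros((1, 1))), duration=3.0)
print(f"single neuron final rate: {single.r[-1, 0]:.4f}  (closed form: {3 / (1 + 2):.4f})")

# the coupled three-neuron network: sustained alternating oscillation
net = simulate_matsuoka(MatsuokaParams(), duration=30.0)
late = net.r[len(net.r) // 2 :]
r0 = late[:, 0]
peaks = np.flatnonzero((r0[1:-1] > r0[:-2]) & (r0[1:-1] > r0[2:]) & (r0[1:-1] > 0.5)) + 1
period = np.median(np.diff(peaks)) * 0.001  # each neuron peaks once per cycle
print(f"network oscillation: amplitude {late.max():.2f}, period {period:.3f} s per cycle")
print(f"cycle-peak stability (CV): {r0[peaks].std() / r0[peaks].mean():.4f}")
print()
print("The near-zero CV shows a non-decaying limit cycle: with constant input")
print("the network is a periodic attractor; each neuron alone is not.")
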