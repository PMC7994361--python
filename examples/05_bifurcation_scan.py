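"""Bifurcation scan of the synchronized dynamics over the bias of neuron 1.

The reduced 2-neuron core (weights [[-4, 1.6], [-1.6, 0]], second bias
fixed at 0) is scanned over theta1 in [-6, 0].  Recorded is the mean
output (o1 + o2)/2; a chaotic window sits around -4.75 < theta1 < -3.1,
with periodic windows and coexisting branches inside it.
"""

import numpy as np

from syncore import bifurcation_scan, load_fixture

core = load_fixture("chaotic_core")
grid = np.linspace(-6.0, 0.0, 121)
data = bifurcation_scan(core, 0, grid, n_inits=6, n_transient=3_000, n_record=80, seed=0)

print("theta1   #distinct_mean_outputs   spread")
for value, block in zip(data.param_values, data.samples):
    distinct = np.unique(np.round(block, 4)).size
    print(f"{value:+7.2f}   {distinct:22d}   {np.ptp(block):.4f}")
# A single repeated value marks a fixed point, a handful of values a
# periodic orbit, and hundreds of distinct values with a wide spread mark
# quasiperiodicity or chaos.  Export data.to_frame() for plotting.
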