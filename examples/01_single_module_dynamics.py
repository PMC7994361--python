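"""Iterate a single neuromodule and inspect its graph structure.

The inhibitory 2-cycle (two neurons, w12 = 1.6 = -w21, zero bias) is the
smallest network with nontrivial dynamics: its only cycle carries one
inhibitory connection (an odd cycle), and at this weight it has a global
period-4 attractor.
"""

import numpy as np

from syncore import cycle_census, iterate, load_fixture, structure_matrix

mod = load_fixture("odd2cycle_w16")

print("structure (sign of each synapse, rows are targets):")
print(structure_matrix(mod).entries)

for rec in cycle_census(mod):
    print(
        f"cycle through neurons {tuple(i + 1 for i in rec.node_sequence)}: "
        f"length {rec.length}, {rec.n_inhibitory} inhibitory edge(s) -> {rec.parity}"
    )

traj = iterate(mod, a0=[0.5, 0.1], n_transient=5_000, n_record=8)
print("\neight post-transient activation states (note the repeat after 4):")
for t, state in enumerate(traj.states):
    print(f"  t+{t}: ({state[0]:+.6f}, {state[1]:+.6f})")
# The states repeat with minimal period 4: the odd 2-cycle supports either
# a global fixed point (weak weights) or this period-4 oscillation.
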