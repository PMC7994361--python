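"""Decompose an even-dimensional network into synchronizable submodules.

Given only a 4-neuron weight matrix (here: the assembled strongly coupled
pair with its neurons shuffled), the exhaustive split search recovers the
two 2-neuron submodules, their coupling, and the generative/conservative
label.  A network admitting no such split is *basic*.
"""

import numpy as np

from syncore import Neuromodule, assemble, is_basic, load_fixture, s_decompose

mod = assemble(load_fixture("pair_generative"))
perm = np.array([2, 0, 3, 1])  # relabel neurons to hide the block structure
shuffled = Neuromodule(
    theta=mod.theta[perm], weights=mod.weights[np.ix_(perm, perm)]
)

print("shuffled weight matrix:")
print(shuffled.weights)
for d in s_decompose(shuffled):
    print(
        f"\nsplit A={[i + 1 for i in d.partition_a]} "
        f"paired with B={[i + 1 for i in d.partition_b]}"
    )
    print(f"coupling label: {d.label}")
    print(f"core signs:\n{d.core.structure.entries}")

ring_w = np.zeros((4, 4))
for k in range(4):
    ring_w[(k + 1) % 4, k] = 1.0
ring = Neuromodule(theta=np.zeros(4), weights=ring_w)
print(f"\nall-excitatory 4-ring is basic: {is_basic(ring)}")
# The search enumerates every balanced bipartition and pairing, so an
# empty result is a proof (at the given tolerance) that no synchronizable
# split exists.
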