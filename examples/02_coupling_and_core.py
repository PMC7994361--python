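"""Couple two identical modules and read off the synchronization structure.

Two copies of the inhibitory 2-cycle are joined by a single strong
connection between the first neurons of each module.  The synchronized
dynamics on the diagonal a = b is governed by the synchronization matrix
w+ = wA + wAB; its sign pattern (the synchronization core) gains a
negative self-connection neither module had — the coupling is generative,
and the 2-neuron core supports chaos that the isolated 2-cycles cannot.
"""

from syncore import (
    classify_coupling,
    load_fixture,
    obstruction_eigen,
    obstruction_matrix,
    sync_matrix,
    sync_residual,
)

for name in ("pair_generative", "pair_conservative"):
    pair = load_fixture(name)
    core = sync_matrix(pair)
    w_minus = obstruction_matrix(pair)
    eig = obstruction_eigen(w_minus)
    cls = classify_coupling(pair)
    print(f"== {name} ==")
    print(f"condition residual: {sync_residual(pair):g}")
    print(f"w+ =\n{core.w_plus}")
    print(f"core signs =\n{core.structure.entries}")
    print(f"w- =\n{w_minus}")
    print(
        "coupling:", cls.label,
        f"(new connections at {list(cls.witnesses)})" if cls.witnesses else "",
    )
    print(
        "obstruction eigenvalues:",
        ", ".join(f"{e.real:+.3f}" for e in eig.eigenvalues),
        "-> manifold", "stable" if eig.stable else "unstable",
    )
    print()
# Both pairs share the same core (they are synchronization equivalent) but
# differ in the obstruction spectrum: the generative pair destabilizes the
# manifold (|eps|max = 3.2) and so admits asynchronous attractors, while
# the conservative rewiring keeps every |eps| < 1 and synchronizes globally.
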