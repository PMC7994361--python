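# Methods

## Model

A neuromodule is a discrete-time dynamical system on ℝⁿ,

    a_i(t+1) = θ_i + Σ_j w_ij · tanh(a_j(t)),

with bias vector θ (housing both the intrinsic bias and any stationary
external input, merged into one effective parameter) and weight matrix w
(`w[i, j]` is the synapse j → i).  The transfer function is fixed to
tanh; this keeps the coordinate identities used by the coupled-system
reduction exact and is not pluggable.  Outputs `o = tanh(a)` live in the
open cube (−1, 1)ⁿ, and after one step every activation obeys
|a_i| ≤ |θ_i| + Σ_j |w_ij|, so orbits of finite systems never diverge.

Two n-modules A, B with coupling blocks `wAB` (B→A) and `wBA` (A→B) form
the 2n-system with block weight matrix [[wA, wAB], [wBA, wB]].  Under the
synchronization condition (equal biases, `wA − wBA = wB − wAB`, both
blocks nonzero) the diagonal a = b is invariant; in the adapted
coordinates ξ = (a+b)/2, η = (a−b)/2 the on-manifold dynamics is the
n-module with the synchronization matrix `w⁺ = wA + wAB` and the
transversal linearization along a synchronized orbit ξ(t) is
`w⁻ · diag(tanh′ ξ(t))` with the obstruction matrix `w⁻ = wA − wBA`.
Everything the package computes — cores, coupling classes, stability
verdicts, exponent splits, decompositions — derives from these two
matrices.

## Tolerances and defaults

* **Synchronization condition**: absolute entry-wise tolerance 1e−9
  (`DEFAULT_SYNC_TOL`).  Weights are specified constants, not estimates;
  anything beyond rounding noise is a genuine violation, and a loose
  tolerance would silently break manifold invariance.
* **Census** (`CensusSettings`): transient 10⁴ steps, record 2·10³,
  max period 64, recurrence tolerance `point_tol` 1e−6, synchronization
  tolerance 1e−6 per neuron, chaos threshold 5e−3 on λ₁, Hausdorff merge
  thresholds 1e−2 (periodic/fixed point) and 0.2 (aperiodic clouds),
  exponent window 2·10⁴ steps.  These sizes resolve the reference
  example's attractors — separated by order 0.1 in output space — with
  two orders of margin on the periodic side, and are small enough that a
  2000-initial-condition census of a 4-neuron system runs in about a
  minute on one core.
* **Lyapunov spectra**: QR re-orthonormalization every step, defaults
  10⁴ transient + 10⁵ averaging steps for full spectra (resolves 2-D
  exponents to a few 1e−3 in seconds); the census uses a shorter 2·10⁴
  window for its per-attractor largest exponent.
* **Decomposition search cap**: n ≤ 12 by default (C(11,5)·6! = 332,640
  candidate splits); larger networks require an explicit override.

## Attractor detection and deduplication

Initial conditions are drawn uniformly in the output cube (−1, 1)^dim and
mapped through arctanh (clipped at ±(1−1e−9)).  After the transient, a
recorded block of states is tested for the smallest shift p ≤ max_period
under which the *whole block* repeats within `point_tol` — far stronger
than a single near-return, so chaotic near-recurrences cannot alias as
periods, and the first hit is the minimal period.  Orbits with no period
get a largest-exponent estimate: λ₁ > 5e−3 is chaotic, |λ₁| ≤ 5e−3
quasiperiodic; aperiodic orbits whose estimate is clearly negative are
flagged low-confidence (unresolved transients).  For periodic orbits λ₁
is exact: the log-modulus of the top eigenvalue of the Jacobian product
over one period.

Orbits are merged into attractors by symmetric Hausdorff (Chebyshev)
distance between recorded output clouds, conditioned on equal period and
synchronization flag.  Two thresholds are needed: periodic orbits are
resolved to `point_tol`, so 1e−2 separates them cleanly, but two finite
2000-step samples of the *same* chaotic attractor differ by ≈0.1 in
Hausdorff distance (sampling gaps of the cloud itself), while distinct
attractors in the reference system are ≥0.8 apart — hence the looser 0.2
cloud threshold.  Clouds are compared as contiguous records, never
strided subsamples: chaotic attractors born from periodic windows cycle
through bands, and a stride resonant with the band period splits one
attractor into disjoint aliases (observed with stride 2 on the reference
system).  Counts of chaotic attractors are reported with the sample size
and settings used and should be read as lower bounds.

## Censuses of coupled systems: sampling the manifold

A synchronized attractor whose largest transversal exponent is positive
is an attractor *of the manifold dynamics only* (a relative attractor in
the Milnor sense): it attracts no open set of the full state space, so no
off-manifold initial condition ever reaches it.  Worse, in floating-point
arithmetic the diagonal is not exactly invariant — the two half-updates
sum different values in different orders, and in transversally expanding
regimes the resulting one-ulp asymmetry grows exponentially — so even
initial conditions placed on the diagonal desynchronize numerically.

`coupled_census` therefore samples both regimes: a fraction (default 20%)
of the initial conditions is devoted to the manifold and iterated under
the *exact* reduced dynamics (the w⁺-module), then embedded back as
(ξ, ξ); the rest sample the full output cube and find asynchronous
attractors plus any transversally stable synchronized ones.  All orbits
deduplicate jointly.  Largest exponents of synchronized aperiodic
attractors are likewise computed along the reduced dynamics (they equal
the synchronization exponents λ₁ˢ); transversal exponents come from
`split_spectrum`, which runs the reduced orbit and iterates the two
tangent blocks `w⁺·diag(tanh′ ξ)` and `w⁻·diag(tanh′ ξ)` by QR.

The same floating-point fact shapes the invariance tests: manifold
invariance in the (a, b) coordinates is asserted on couplings with
transversally contracting obstruction matrices (where rounding noise is
damped and orbits stay synchronized to ~1e−15 over 10³ steps), while for
arbitrary exactly-synchronizable pairs the adapted-coordinate route is
asserted to keep η = 0 *bitwise* (both half-updates there are the same
computation on the same arrays).  Trajectory-level comparisons between
equivalent computational routes are made per-step on arbitrary systems
and chained only on contractive systems, since independent iteration of
two routes amplifies per-step rounding by e^{λ₁ t}.

## Stability criteria

Two matrix-level criteria complement the exponents: spectral — all
eigen-moduli of w⁻ below 1 imply an asymptotically stable manifold
(since 0 < tanh′ ≤ 1, every transversal exponent is bounded by
log max|ε_i|); and an entry-wise contraction bound — max|w⁻_ij| < 1/n
certifies a globally attracting origin of the transversal dynamics.  The
contraction bound is applied to magnitudes: a signed reading would
certify any strongly negative matrix, contradicting the spectral
criterion.  It is sufficient, not necessary: the shipped conservative
coupling violates it (|−1.35| ≥ 1/2) yet is spectrally stable
(eigenvalues −0.984, −0.366).  "Stable for all orbits" is operationalized
by evaluating λ₁⊥ on each attractor found by a census; global claims are
labelled as sampled, not proven.

## Decomposition

`s_decompose` searches every balanced bipartition (neuron 0 fixed in A,
which quotients the A/B exchange symmetry) and all m! pairings, testing
the condition on the induced blocks, recurrence of the coupling, and
strong connectivity of both submodules (relaxable: even feedforward parts
can share a core; biases can be ignored to decompose parameterized
families).  The structure-level variant asks whether *any* weight
configuration with a given sign pattern decomposes: each paired entry
position imposes one linear relation x_A − x_BA = x_B − x_AB on
magnitudes of prescribed sign, feasible iff the nonzero coefficients of
(s_A, −s_BA, −s_B, s_AB) are not all of one sign (positions are
independent, so per-position feasibility is jointly sufficient).

## Synthetic systems

`random_sync_pair` draws module matrices as a random Hamiltonian cycle
(guaranteeing strong connectivity) plus density-controlled extra edges,
with all weights on a dyadic grid (multiples of 1/64, magnitudes
0.125–1.5 by default — the scale at which few-neuron tanh networks
oscillate rather than saturate or die).  On that grid the defining sums
are exact in double precision, so generated pairs satisfy the
synchronization condition with *zero* residual.  Options force a
generative witness (a coupling entry where both modules vanish) or a
transversally contracting obstruction matrix (dense, |entries| < 1/n).
What the generator does not emulate: weight heterogeneity across orders
of magnitude, near-degenerate configurations exactly on bifurcation
manifolds, and modules larger than the search cap — tests passing on
generated systems say nothing about those regimes.

The shipped catalog contains the reference systems used throughout the
tests: the isolated inhibitory 2-cycle, the strongly coupled generative
pair and its conservative rewiring (same core, stable obstruction
spectrum), their obstruction matrices, an odd 3-ring, and an
*approximate* Freeman-KII sign structure (two excitatory, two inhibitory
populations; synthetic, encoded from a textual description only, and
excluded from quantitative checks).

## Problem sizes

The shipped analyses run at: 500 initial conditions for the
strong-coupling census (5 attractors), 2000 for the richer census at
bias −3 (≥8 attractors), 10⁵ exponent-averaging steps, 200 random pairs
for the bulk invariance and planted-decomposition checks.  These sizes
reproduce the reference landscape stably across seeds on a single core.

## Known limitations

* Attractor counts from finite censuses are lower bounds; basins thinner
  than the sampling density are missed.
* Period detection is capped (default 64); longer periodic orbits are
  labelled quasiperiodic, with the cap recorded in the settings.
* Chaos classification rests on a finite-window exponent estimate; near
  bifurcations the low-confidence flag should be heeded.
* The exhaustive decomposition search is factorial in n/2 and capped at
  n = 12.
* Anti-synchronization, partial synchronization of unequal-dimension
  modules, and couplings of more than two modules are out of scope.
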