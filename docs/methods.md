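# Methods

## Model

A generalized Ising model on a weighted undirected graph: `n` binary spins
`s_i = ±1` coupled by a symmetric, zero-diagonal, nonnegative matrix
`J_ij ∈ [0, 1]`, with configuration energy

    H(s) = − Σ_{i<j} J_ij s_i s_j        (each unordered pair counted once)

and no external field; temperature is dimensionless (`k_B = 1`).  The
pair-once convention matters quantitatively: with weights drawn
Uniform(0, 1) and rescaled so the strongest coupling is 1, a 5-node
complete graph has typical row sums near 2.2, which places the
susceptibility peak of the ensemble near `T_c ≈ 1.8`; counting pairs twice
would double every energy scale and move the peak near 3.5.  Exact
enumeration of the ensemble confirms the peak position under the pair-once
convention, so that convention is used throughout.

## Random network ensemble

The study ensemble consists of fully connected `n`-node graphs whose
`n(n−1)/2` upper-triangle weights are drawn independently Uniform(0, 1),
mirrored to the lower triangle, and divided by the maximum weight.
Couplings are strictly positive (excitatory); zero draws have probability
zero and receive no special handling.  Ensemble member `k` derives its seed
from `(master_seed, k)` via `numpy.random.SeedSequence` spawning, so
ensembles are reproducible and members independent.  A degenerate all-zero
matrix cannot be normalized and is rejected; such matrices are still
constructible directly (bypassing normalization) because they are useful
reducibility fixtures.

## Metropolis dynamics: two update schemes

A single-site move flips spin `i` with probability `exp(−ΔE/T)` if
`ΔE = 2 s_i Σ_j J_ij s_j > 0` and probability 1 otherwise.

* **Sequential** — one uniformly chosen site per iteration.  This chain
  satisfies detailed balance for the Boltzmann measure (verified
  analytically state-pair by state-pair in the tests), so its time averages
  estimate canonical expectations.  All equilibrium claims (χ, C_v,
  magnetization curves, comparisons against exact enumeration) use this
  scheme.
* **Synchronous** — every site attempts a flip simultaneously against the
  current configuration.  This is the Markov kernel that the
  state-by-node TPM encodes, and the object integrated-information theory
  analyses.  It does *not* satisfy detailed balance; empirically it
  collapses into near-deterministic complement oscillations over much of
  the temperature range (all spins with `ΔE ≤ 0` flip with probability 1),
  which drives the time-averaged magnetization toward zero and flattens
  the susceptibility curve.  It therefore cannot reproduce the physical
  `χ(T)` peak, and temperature sweeps default to sequential sampling while
  Φ is always computed from the synchronous kernel.  This split — sample
  with the equilibrium chain, analyse the synchronous kernel — is the
  package's reading of the pipeline, and the single deliberate deviation
  from treating one update scheme as serving both purposes.

Protocol defaults: uniform random ±1 initialization, 500 discarded
thermalization iterations, 2000 recorded iterations, 200 log-spaced
temperatures in [0.1, 4] (tests and the acceptance script use 50 or 25
temperatures and ensembles of 10–20 networks; these sizes are the
package's desk-scale defaults, chosen so the full suite completes in one
sitting while leaving the estimators' error bands well inside the
acceptance tolerances).

Per-step randomness is drawn in a fixed documented order (synchronous: one
uniform per node in node order; sequential: site then acceptance), so
traces are bit-reproducible for a given seed, and per-(network,
temperature) seeds are derived independently so work units can run in any
order.

## State coding

Configurations are indexed little-endian: node 0 is the least significant
bit, spin −1 ↔ 0 and +1 ↔ 1.  This matches the IIT 3.0 reference toolbox,
so state codes are directly comparable across the simulator, the TPM and
the Φ engine.

## The state-by-node TPM

Under the synchronous scheme nodes update independently given the current
state, so the kernel factorizes into per-node Bernoulli laws: entry
`(s, i)` of the `2^n × n` state-by-node TPM is the probability node `i` is
up next step.  The `2^n × 2^n` state-by-state kernel is their product; its
unique stationary distribution validates synchronous simulation by
comparing visit frequencies.  Because energy-lowering flips are certain,
synchronous kernels contain structural zeros and are essentially never
irreducible over the whole state space; the stationary law is therefore
defined (and checked) under the correct weaker condition — a unique
aperiodic recurrent class, with transient states carrying zero mass.  The
zero-coupling kernel is the deterministic complement permutation — every
state sits in a 2-cycle, so no unique law exists — and raising an explicit
error there is a deliberate choice.  Dense `2^n`-row matrices
are guarded at `n ≤ 12`.

## Integrated information (IIT 3.0)

Φ follows the published IIT 3.0 reference algorithm, with the toolbox's
documented defaults: earth-mover repertoire distance, mechanism/purview
bipartitions for the mechanism-level MIP, unidirectional system bipartition
cuts, and all distances rounded to 1e-6 (the toolbox's precision constant —
the rounding is semantic, since minimum/maximum selections compare rounded
values).  In outline:

* **Repertoires.**  The cause repertoire of a mechanism over a purview is
  the normalized product over mechanism nodes of each node's likelihood of
  its current state, marginalized (maximum-entropy) over non-purview
  inputs; the effect repertoire factorizes over purview nodes conditioned
  on the mechanism's state.
* **Small phi.**  For each mechanism and direction, φ is the EMD (Hamming
  ground metric) between the repertoire and the closest product repertoire
  over all mechanism/purview bipartitions, maximized over purviews
  (ties: larger purview, then earlier subset order).  Purviews whose
  connectivity block-factorizes are skipped.
* **Big Phi.**  Concepts (mechanisms with φ > 0) form the cause-effect
  structure; each unidirectional cut (A → B severs connections from A to
  B, replacing them with noise) yields a cut structure, and Φ is the
  minimum over cuts of the generalized concept-space EMD between the two
  structures, where a concept's ground distance is the summed cause and
  effect EMDs over expanded union purviews and destroyed concepts move to
  the null concept.  Irreducible causes/effects untouched by a cut
  (mechanism not split, purview–mechanism connections intact) are reused
  rather than recomputed, mirroring the reference toolbox's cache
  inheritance.

Oracle equivalence was established by freezing reference values (Φ,
concept counts, concept φ values, repertoires) computed with the reference
toolbox on 60 random 3-node and 12 random 4-node (TPM, state) cases drawn
from this package's own generator; the suite regenerates the TPMs from
seeds and checks agreement to 1e-6 (repertoires to 1e-10).

### Exact earth-mover distances

Because 1e-6 differences decide MIP selections, all transport problems are
solved exactly: a successive-shortest-path min-cost flow (Dijkstra with
potentials, numba-compiled) with a linear-programming fallback for
numerically degenerate instances.  The solver is validated against an
independent `scipy.optimize.linprog` oracle.  Effect-side EMDs use the
closed per-node form valid for factorized repertoires (sum of Bernoulli
marginal differences), and cause-side searches order candidates by two
exact lower bounds (total variation; summed marginal shifts) so most
candidates never reach the flow solver.

### Caching and symmetry

Φ depends only on (TPM, state); per temperature at n = 5 at most 32
evaluations are ever needed regardless of trace length.  Three exact
sharing rules make sweeps feasible:

1. severing a connection outside a mechanism/purview pair is identical to
   the maximum-entropy marginalization already applied there, so
   mechanism-level MIPs are cached by the severed pairs that actually
   intersect the pair and shared across all system cuts;
2. a mechanism's concept depends on the system state only through the
   mechanism's own bits, so concepts are shared across system states;
3. the field-free kernel is exactly symmetric under a global spin flip
   (`P(i up | s) = P(i down | ~s)` entry for entry), so Φ(s) = Φ(~s) and
   complement states share a cache slot.  The flip invariance is also
   verified through two independent computations in the tests.

## Observables and summary statistics

`M = |Σ s_i|/N` (absolute value included, so exact and sampled values are
comparable), time averages over the measurement window, and population
(1/N) variances everywhere: `χ = (⟨M²⟩−⟨M⟩²)/T`, `χ_O = ⟨O²⟩−⟨O⟩²` (no
temperature division — applied to Φ this is `χ_Φ`), and across-network
variance `σ_J²(O)`.  The specific heat uses the canonical fluctuation form
`C_v = (⟨E²⟩−⟨E⟩²)/T²`, consistent with the fluctuation-over-temperature
style of χ and verified in the tests against the thermodynamic identity
`C_v = d⟨E⟩/dT` from exact enumeration.  ⟨Φ⟩ and `χ_Φ` weight per-state Φ
by visit frequency over the trace (default); weighting by the exact
stationary distribution of the synchronous kernel is available as an
option and agrees on long ergodic traces.

## Peak detection and the critical temperature

Raw 2000-iteration Monte-Carlo curves are noisy, so a centered 5-point
moving average is applied before locating the maximum (raw mode
available); ties break toward the lowest temperature and a flat curve
raises a degenerate-peak warning.  The consensus `T_c` is the peak of the
ensemble-*mean* curve (the quantity the summary figures plot); per-network
peaks are also reported.

## Exact enumeration backbone

For `n ≤ 12`, canonical expectations are computed by summing Boltzmann
weights over all `2^n` states, in a temperature-stable form (the maximum
of `−H/T` is subtracted before exponentiation).  This backs every
simulator claim: sequential-mode time averages within Monte-Carlo error
(standard errors estimated by batch means, since sequential samples are
autocorrelated), detailed balance, fluctuation–dissipation, and the
two-spin closed forms `⟨E⟩ = −tanh(J/T)`, `C_v = sech²(J/T)/T²`.

## What the synthetic ensemble does and does not show

The generator reproduces the study conditions: fully connected,
ferromagnetic, max-normalized random couplings.  Real tractography
matrices are sparser, heavier-tailed and larger; passing tests therefore
demonstrate the pipeline's correctness and the criticality phenomenology
on this ensemble class, not that any particular brain network is critical.
Φ is computed exactly and is limited to `n ≤ 5`; no approximate Φ
surrogate is provided.

## Known limitations

* The synchronous chain's degenerate low-temperature behaviour (complement
  oscillation) means `phi_over_trace` with synchronous traces samples very
  few states there; sequential traces avoid this.
* Mechanism-level MIP ties are broken deterministically but the reported
  minimizing partition (not its φ value) may differ from other
  implementations when several partitions achieve the minimum.
* Stationary distributions require an ergodic kernel; the zero-coupling
  complement map raises an explicit error.
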