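# Methods

## Model

The unit of state is a *type*: a cluster of genotypes treated as
homogeneous in fitness and in its mutational connections.  A landscape is
a finite undirected graph over types with a strictly positive fitness
value per type; fitness is identified with the reproduction rate, so time
is measured in reproductions and fitness values are dimensionless rates of
order 1.  Fitness values must be pairwise distinct: a tie makes the
selection coefficient between the tied pair zero, and every timescale of
the theory (ln N / s sweeps, dwell/sweep separation) degenerates.
Construction therefore rejects exact ties and warns when the smallest gap
falls below 10⁻⁹ (configurable).

The population of constant size N evolves as a continuous-time pure-jump
Markov process on count vectors:

* reproduction–replacement: pair rate N f_i x_i x_j for the transition
  (c_i, c_j) → (c_i + 1, c_j − 1), i ≠ j.  Same-type replacements leave
  the state unchanged and are excluded from the event space; this is an
  exact thinning of the process (a differential test in the suite verifies
  that re-including them leaves the law unchanged).
* mutation: rate N λ x_i per incident edge for one i-individual becoming
  an adjacent type j.  Mutation is a replacement, not a birth, so N is
  conserved exactly.

Because types are exchangeable, counts are a sufficient state and no
per-individual bookkeeping is needed.  Whether the displaced individual
may be the newborn's parent is immaterial at the level of these rates; the
event log narrates the "pre-birth removal" convention.

## Deterministic limit and heteroclinic structure

With λ = 0 and N → ∞ the process follows the replicator ODE
dx_i/dt = x_i (f_i − f̄).  The closed form
x_i(t) = x_i(0) e^{f_i t}/Z(t) is the primary computational path; the
numerical integrator exists only as a cross-check and for didactic use.
The closed form is evaluated in the log domain (the maximum of f_i t over
the support is subtracted before exponentiation), which makes it
overflow-safe for arbitrarily long horizons and exactly invariant under
adding a constant to all fitness values.  Types with zero initial fraction
are excluded from the active set before analysis; the flow lives on the
face spanned by the initial support.

Vertex analysis reports the within-face spectrum {f_i − f_k} only.  The
transversal eigenvalue −f_k (eigenvector off the simplex) is excluded
because the dynamics is confined to the simplex; tests that compare with
finite-difference Jacobians in ambient coordinates add it back explicitly.

## Origin–fixation theory

For two competing types the embedded jump chain of the fitter type's copy
number is an asymmetric walk with up/down odds f*/f**, giving the
gambler's-ruin fixation probability π(m) = (1 − ρ^m)/(1 − ρ^N),
ρ = f**/f*.  The losing types during a sweep are stochastically dominated
by a subcritical linear birth–death process, whose extinction law
p_k(t) = (1 − (B − A)/(B e^{(B−A)t} − A))^k is implemented in closed form
and cross-checked against direct simulation.

The stasis clock multiplies production and survival: successful beneficial
mutants arrive as a thinned Poisson stream of rate λ N Σ_j π_j over the
fitter neighbors j, so the expected dwell is the inverse of that rate.
The bare production time (k λ N)⁻¹ is reported separately, because the
theory's published timescales count production only; wherever simulation
is compared to theory the fixation thinning is applied explicitly and the
report says so.  Expected times to reach a landscape peak are computed by
dynamic programming over the fitness-ordered DAG (each move fixes a fitter
neighbor with probability ∝ its single-copy fixation probability); sweep
durations are omitted from that expectation since they are lower-order in
the weak-mutation regime.

Regime classification uses r_N = λ N ln N / s and the deleterious load
λ L ln N / s with a configurable "≪ 1" cutoff, default 0.1 (the theory
states no cutoff; 0.1 keeps both corrections below ten percent).  When a
type has several fitter neighbors, s is taken as the *minimum* gap — the
worst case, which maximizes r_N and makes the verdict conservative; all
gaps are available via the landscape API.  At a local peak (k = 0) the
waiting time is infinite and the report is flagged peak-trapped rather
than given a number, since escape times are exponentially large in N and
outside this theory.

All timescale claims are order-of-magnitude; tests therefore assert
scalings (ratios across parameter doublings, log-linear slopes) and the
prefactor-free comparisons above, never constants the asymptotics do not
provide.

## Stochastic simulation

The simulator is the exact direct (Gillespie) method: exponential waiting
times at the total rate, events chosen proportionally to their rates.  Two
engines implement identical semantics.  The production engine is a numba
kernel that maintains the set of present types (O(|support|) work per
event) and supports four recording policies: grid snapshots at spacing
Δt (default ln N/(10 s), ten samples per sweep), support-change snapshots,
a compact dominance log, and none.  The reference engine is a pure-Python
full-recompute implementation that records every jump; replaying its event
log must reproduce the final state exactly, and its fixation statistics
must agree with the kernel's — both are tested.

The dominance log records a row exactly when the identity of the most
common type changes or its fraction crosses the 1 − ε threshold, which
makes segmentation of arbitrarily long runs exact at negligible memory
cost.  Reproducibility: every run takes one root seed; replicate sets
derive independent 31-bit child seeds via numpy SeedSequence spawning.

## Trajectory analysis

The discrepancy D(t) is the L1 distance between the simulated state and
the replicator flow started from the run's own initial state, with the
running maximum D*(t).  A "patched" mode re-anchors the flow whenever the
sampled support changes (for runs with mutations, where new types enter);
the default anchored mode is the definition used for the mutation-free
convergence checks.

Segmentation labels maximal epochs with top-type fraction ≥ 1 − ε as
stasis and the complement as transitions; ε defaults to 0.05 ("near a
vertex" has no canonical radius, so every reported statistic states its
ε).  Two definitions matter in practice and are kept distinct:

* a *reign* is a maximal run of stasis epochs with the same dominant type.
  Dwell times are reported per completed reign (total stasis time), because
  a failed sweep attempt — a challenger crossing ε and dying back — is part
  of the waiting epoch that the origin–fixation clock describes, not the
  end of it.  The final, censored reign is excluded (unless it is the only
  one, in which case the observed duration is reported as-is).
* *sweep durations* are transition epochs whose flanking stasis epochs
  have different dominants; failed attempts are thereby excluded.

Threshold flicker (the count random-walking around (1 − ε)N) produces
micro-segments; the `min_duration` merge parameter absorbs them (default
0 for determinism of the raw tiling; analyses here use 1 time unit, far
above the per-event scale 1/(N f) and far below a sweep).

Clonal interference is detected on copy counts, not fractions, because
the vulnerable phase is the challenger's establishment: an event is a type
strictly fitter than the currently sweeping type (the fittest type with
fraction inside [ε, 1 − ε)) holding at least √N copies while still below
ε N.  The upper cap excludes the sweeping or fixing lineage itself; the
√N default is configurable and requires √N < ε N to be meaningful.  Runs
without mutation report no events by definition — sorting of standing
variation is competitive exclusion, not interference.

## Synthetic landscapes: what they emulate, and what not

The staircase (path graph, additive steps) isolates the saddle-to-saddle
succession with exactly one beneficial and one deleterious mutation per
interior type.  The hypercube generator models the approach to a local
optimum over k₀ remaining sites; its default fitness assignment is
multiplicative per level (factor 1.25) with a seeded multiplicative jitter
of 10⁻³ so that values are distinct — chosen so the fitness *ratio*, and
hence the single-copy fixation probability, is uniform across the lattice,
which is what makes climb times follow the harmonic-number law cleanly.
Random landscapes draw i.i.d. uniform fitness on [1, 2].

These generators realize exactly the model's assumptions: types are
atomic, fitness is constant in time, the population is well-mixed, and
mutation rates are uniform across edges.  Passing tests therefore validate
the mathematics of this model class, not the behavior of real populations:
no epistatic fitness measured from data, no environmental change, no
within-type neutral structure, no spatial subdivision, and no
drift-dominated small-N regime are represented.

## Problem sizes and numerical choices

The standard study conditions used by the test suite and the acceptance
script: discrepancy scaling at N = 10², 10³, 10⁴ with 200 replicates over
the horizon T = ln N / s on a three-type landscape; the staircase run at
N = 10³, s = 0.1, r_N = 10⁻³, sized by the origin–fixation clock for ~115
transitions; interference episodes at N = 10³ with 200 completed sweeps
per condition; hypercube climbs at N = 10³, λN = 10⁻³, 200 runs for
k₀ ∈ {2, 4, 8}.  Monte-Carlo checks use 3-standard-error bands; relative
comparisons against order-one theory use 25 % (means over ≥ 100
exponential-ish samples) or a factor of two (medians against a timescale
with no prefactor).  The ODE cross-check integrates with DOP853 at
rtol 10⁻¹⁰ and asserts L1 agreement ≤ 10⁻⁸; finite-difference spectra use
central differences with h = 10⁻⁶ at tolerance 10⁻⁶.

## Known limitations

* The type set must be finite and is expanded eagerly; countable
  landscapes would need a lazy neighbor callback, which nothing in scope
  requires (the largest lattice used is 2⁸ types).
* Grid recording needs a finite horizon; for open-ended runs use the
  dominance or support-change policies.
* The interference detector is snapshot-based; a challenger racing through
  the [√N, εN) detection band between samples can be missed, so measured
  frequencies are (slightly) conservative — appropriate for comparison
  against an upper bound.
* `estimate_fixation_probability` requires an explicit resident type on
  landscapes with more than two types.
* Exactness is the point: there is no tau-leaping or diffusion
  approximation, so runs with N ≫ 10⁵ and high heterozygosity are slow.
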