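# Methods

This note documents the model, the algorithmic choices, and the limits of
what the bundled tests demonstrate.

## Model and assumptions

The package analyzes **synchronous, deterministic Boolean networks**: a
directed graph of `n` automata, each updated in discrete time by a
look-up table (LUT) over its ordered inputs.  Multi-valued automata and
asynchronous or stochastic update schemes are out of scope.  Constant
environmental inputs are represented as self-copy nodes (`i* = i`), which
makes them pinnable like any other node and lets a pulse on an input be
self-sustaining.

All module-level analysis is performed on the **dynamics canalization
map** (DCM), not on the state space.  The consequence — and the point —
is that every state a pathway module derives is *guaranteed* in the
original dynamics whenever the seeds are held, regardless of the unknown
variables.  The converse does not hold: states that are reached in every
attractor but require knowledge of initial conditions are not derived.
The exhaustive-simulation oracle `brute_force_stabilization` (vectorized
over all completions of the unpinned variables, feasible to ~20 free
variables) is used throughout the tests to certify this soundness
direction.

## Schemata redescription

* Prime implicants are computed by Quine–McCluskey separately for the ON
  and OFF rows of each LUT.  **All** prime implicants are retained; no
  minimal-cover step is applied.  Dropping covered implicants would be
  harmless for full-state evaluation but can hide canalizing paths from
  *partial* configurations, which is exactly what unfolding consumes.
* Two-symbol regrouping greedily merges input positions of each wildcard
  schema into permutation groups; a merge is accepted only if the whole
  orbit (the expansion) is contained in F′, so regrouping is always
  lossless (flattening F″ reproduces F′ exactly — a tested invariant).
  Because any valid group is reached through valid pairwise merges, the
  greedy search finds maximal groups; when several incompatible
  symmetries exist the tie is resolved by deterministic position order,
  which may split one symmetry class into two schemata with overlapping
  expansions — semantics are unaffected since matching is defined on
  expansions.  Beyond `max_k = 12` inputs the search degrades to
  pass-through (each F′ schema its own F″ schema), preserving semantic
  equivalence.
* A schema is *matched* by a partial configuration only when the known
  entries guarantee it: fixed positions must be known and equal, and each
  permutation bundle needs, per required state, at least as many known
  positions in that state (an injective assignment).  An unknown entry
  never certifies a requirement.

## DCM semantics

Canonical t-unit firing is **schema matching** on the firing partial
configuration.  The threshold/fibre-bundle representation (τ = number of
enputs; merged fibres deliver up to `m` signals per group-invariant
enput) is maintained for structure and export, and the test suite asserts
its equivalence with schema matching on random LUTs.  This avoids any
ambiguity in counting merged-fibre signals for bundles that mix required
states.  t-units with τ=1 and no permutation redundancy are retained
internally; graph exports take a `simplify` flag that omits them, which
matches the usual visual convention for these maps.

## Unfolding

* Timing: seeds fire at t=0; a t-unit fires at t when its schema is
  matched by the s-units firing at t (dt=0); its target s-unit fires at
  t+1 (dt=1).
* **Pinning** is a monotone closure: `S^t ⊆ S^{t+1}`; a pinned seed
  permanently blocks its opposite s-unit, and among derived s-units the
  first-fired state of a variable wins.  Termination is the closure
  fixpoint; the module length T is the index of the last novel slice
  (so an inert seed has size 1, length 0).
* **Pulse / mixed**: each slice is recomputed from the currently firing
  s-units (pinned seeds always included).  Different states of a variable
  may fire at different steps; both states in *one* step would violate
  schema disjointness and raise.  Termination is detected by hashing
  slices: fixpoint, repetition of an earlier slice (reported with its
  period — limit cycles), or an empty slice.
* Multi-input t-units require all their sources to fire *simultaneously*;
  no temporal-window relaxation is implemented.  Periodic or
  press-and-release perturbation schedules are out of scope.

## Module algebra and covers

Synergy, obstruction and decoupling are evaluated on pinning module sets
(`μ(S_i⁰ ∪ S_j⁰)` vs `μ(S_i⁰) ∪ μ(S_j⁰)`), with witnesses reported.  A
contradictory seed union (a variable seeded in both states) is marked as
obstruction-by-seed-contradiction and never unfolded.  Maximality uses
the proper-subset test against all modules with seed size ≤ s; modules
with *equal* sets are both retained (downstream pools deduplicate by
module set, keeping the lexicographically smallest seed set).  Complex
modules check synergy over all `2^(s−1)−1` unordered seed bipartitions;
the seed size is capped (default 6).  One deliberate reading: the
count of two complex modules at s=2 usually reported for the six-node
example corresponds to the **core** (maximal-seed) subset; the
bipartition definition itself admits two further modules whose single
seeds are non-maximal, and the same literal definition is what
reproduces the segment-polarity catalog counts at every seed size, so
the package keeps the literal `complex_modules` and exposes
`core_filter` separately.

Independence scores and `D̄` are computed in exact rational arithmetic
(`fractions.Fraction`); printed values use half-up decimal rounding, so
0.825 rounds to 0.83.  The exact cover search is depth-first
branch-and-bound over candidates ordered by decreasing module-set size,
pruning on coverage infeasibility, on the cover-size cap `q`, and on an
optimistic bound that assumes every further module is fully independent.
Ties are broken deterministically (higher mean, then fewer modules, then
lexicographic seed sets).  Greedy selection picks the candidate with the
highest independence from the current selection (ties: larger module
set, smaller seed set, lexicographic names) and runs to full coverage by
default, with `q` as an optional early stop; it is a lower bound on the
exact optimum (tested).  The plateau test for `s*` uses an epsilon of
1e-9 on exact rationals, i.e. effectively exact equality.

## Fixtures and problem sizes

* `or_gate` and `example_grn` are fully hand-checkable: every module set,
  interaction classification and cover score asserted in the tests was
  derived by hand from the six rules and cross-checked against the
  exhaustive oracle.
* `tests/data/spn_single_cell_synthetic.txt` is a **synthetic
  reconstruction** of the 17-node *Drosophila* segment-polarity
  single-cell Boolean model (segment-polarity logic with the neighbor
  signals collapsed to the inputs nWG and nHH).  It reproduces the
  published dynamical portrait of that model — module sizes
  (|S(en-1)|=9, the 17-state input-triple attractor, …), the catalog
  counts 14/34, 9/544, 19/5440, 14/38080 and none at s=5, and the s=1
  and s=2 cover statistics — but it is not the published file, and a
  handful of reported cover statistics that depend on the reference
  analysis' exact candidate pool differ (the formal definitions admit
  two additional core complex modules).
* The 4-cell parasegment (n=60) is built by `compose_lattice` from the
  single-cell template with nWG/nHH coupled to the neighbors' WG/HH on a
  periodic ring; the s=1 analysis (120 modules, 40 complex, greedy cover
  at 0.83) runs in seconds.
* Randomized property suites use seeded generators only (hypothesis-free
  reproducibility): 500 random LUTs (k ≤ 8) for F/F′/F″ equivalence, 200
  random networks (n ≤ 12, k ≤ 3) for unfolding soundness against the
  exhaustive oracle and for the interaction set-algebra identities, and
  ~30 small networks (n ≤ 8) for greedy-vs-exact and curve monotonicity.
  These sizes keep the full suite in the minutes range on one CPU while
  covering the input regimes where exhaustive verification is possible.
  Passing them shows correctness of the combinatorial machinery on
  networks of desk scale; it says nothing about models whose in-degrees
  exceed the two-symbol search cap or whose relevant seed sets exceed
  the complexity cap.

## Known limitations

* The optimal-cover problem contains set cover; exact search is only
  feasible for pools of a few dozen candidates (with `q` small).  Greedy
  estimates are lower bounds and can be visibly suboptimal (the example
  GRN greedy s=2 cover scores ≈0.64 vs 0.825 exact).
* Pulse-mode maximality (via temporal subsumption) is implemented but
  not validated against any published result; module-algebra defaults
  are pinning.
* Pathway modules certify guaranteed states only under sustained seeds
  and no outside interference; robustness to asynchronous update is not
  addressed.
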