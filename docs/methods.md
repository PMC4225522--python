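# Methods

## Model and procedure

`dtlcoev` decides whether two gene families co-evolved along a known dated
species tree `S`.  A family is represented by a rooted binary gene tree whose
leaves are assigned to extant species.  The decision procedure has three
stages: extract weighted event sets from reconciliations, score their
overlap, and test the score against an exact combinatorial null.

### Reconciliation and the time-sliced subdivision

Reconciliation uses the DTL parsimony model on the *subdivision* `S'` of the
dated tree: on every edge spanning the age of some internal node an
artificial degree-2 node is inserted at that age, so that every subdivided
edge lies in exactly one time slice and transfers can be constrained to
contemporaneous branches, which guarantees time-consistency of the inferred
scenarios.  The atomic events and their costs are: contemporary (C, 0),
speciation (S, 0), duplication (D, δ), transfer (T, τ),
speciation-with-loss (SL, λ), transfer-with-loss (TL, τ+λ), and the
no-event boundary crossing (∅, 0).  Default costs are δ = τ = λ = 1; the
test's operating characteristics are insensitive to moderate cost changes.

Conventions the dynamic program commits to (each validated against an
independent brute-force scenario enumerator in the test suite):

* **Origin of a family.**  The gene root may start on any subdivided branch
  (the family originates wherever that is cheapest); its first move may not
  be a ∅ crossing, otherwise scenarios differing only by an eventless prefix
  of the root path would be counted as distinct reconciliations.
* **No stem branch.**  There is no branch above the species root, so at the
  root node only S/SL apply.  A duplication that predates the first
  speciation is therefore represented by events inside the tree instead; see
  Limitations.
* **TL chains.**  Within one time slice a lineage may take at most one TL
  between boundary crossings.  This keeps the recursion acyclic; chained
  jumps remain representable across slices and are anyway cost-dominated
  whenever τ + λ > 0.
* **Scenario identity.**  Reconciliations are distinct mappings: different
  transfer receivers, different speciation child orientations and different
  loss sides all count separately.  Counting uses exact Python integers
  (the reference engine); the numba engine carries counts in float64, which
  is exact below 2^53 and leaves frequencies — ratios — accurate regardless,
  since both the scenario total and every event count are sums of the same
  well-conditioned products.

The counting DP makes one bottom-up pass (optimal cost and number of optimal
completions per state) and one top-down pass (number of optimal contexts per
state); the number of MPRs containing an event is context × completions, and
dividing by the total MPR count gives the event's *support frequency*.

### Projection to weighted event sets

Only D, T and L events are informative about co-evolution — S and C events
are dictated by the species tree and ∅ by the subdivision — so the
projection keeps D/T/L only: each SL contributes its loss on the branch
where the lost side entered; each TL contributes a transfer and a loss, both
on the donor branch (the non-transferred child dies there); transfers of the
same gene node departing from the same original branch are merged by summing
their frequencies, receivers deliberately ignored (receiver-resolved
transfers would fragment support and inflate later computation).  All
positions are mapped through the subdivision back-map onto branches of the
original tree.  Merged frequencies above 1 would indicate a counting defect
and raise an error.  The result per branch `b` and type `E` is a *multiset*
`W(b)_E` of weights in (0,1] — a multiset because two different gene nodes
can each contribute weight 0.5 to the same bin.

The expected event count of a family, `N = ⌈Σ weights⌉`, is computed after
projection (i.e. after receiver merging), on the same sets that are scored.

### Score

Weights are treated as independent occurrence probabilities (a deliberately
strong assumption; the null model below absorbs part of its error).  Per bin
the actual event count is then Poisson-binomial, evaluated by the standard
recursion, and the score is the expected number of events in common,
`Σ_bins E[min(X, Y)]`.  The score is symmetric, nonnegative, and zero
exactly when no bin is populated on both sides.

### Null model and p-value

Under independence, each family's `N_i` events are placed i.i.d. over the
`N = 3|E(S)|` (branch, type) bins with probabilities proportional to branch
durations — the three types share each branch's duration, since nothing in
the projection justifies per-type placement propensities.  The p-value is
the exact tail probability `f(X; N1, N2, N)` of the shared-event count,
computed by conditioning bin by bin on the Binomial(n, π_n) counts in the
last bin.  Implementation notes:

* The shared-event count is an integer, so `f(x) = f(⌈x⌉)` and the table
  lives on an integer lattice; this is identical to running the recursion
  directly on the real score.
* The textbook three-term recursion is regrouped as a double sum over the
  two per-bin counts (j, k) weighted by `f(x - min(j,k); n1-j, n2-k, n-1)`
  and evaluated with suffix-sum tables, costing O(x·n1·n2·(n1+n2)) per bin
  in a numba kernel.
* Bins with zero duration get π = 0 and are skipped (they cannot receive
  events); an all-zero bin vector is rejected.
* `f` depends only on the species tree; one table at the batch maxima of
  (⌈X⌉, N1, N2) serves every pair, and out-of-range queries transparently
  rebuild the table (with a logged notice).
* Scores ≤ 0 and families with N = 0 give p = 1 by the initial conditions —
  the source of the visible atom at p = 1 in benchmark histograms.

The test is one-sided; p below the threshold (default 0.05) is called
co-evolution.  No multiple-testing correction is applied across pairs.

## Simulator

The generator emulates co-evolving prokaryote-scale gene families.  Two
lineages start paired at the species root and speciate immediately.  Paired
lineages draw exponential waiting times at rate `2a/(1+c)` (with
`a = r_D + r_T + r_L`); crossing the branch end triggers speciation (both
genes) or extant sampling; otherwise the event type is drawn proportional to
the rates, a uniformly chosen primary gene is always affected, and the
partner is affected with probability `c`.  Shared duplications/transfers
re-pair like children (shared transfers use the same receiver); one-sided
duplications and transfers keep the first/stay child paired and set the
other copy free; one-sided losses unpair the survivor.  Free lineages run
the ordinary process at rate `a`.  Because a pair event affects a given gene
with probability `(1+c)/2`, the `2/(1+c)` correction makes each family's
marginal process exactly the single-family birth–death at rate `a` for any
`c` — verified in the tests by two-sample comparison with an independently
written single-family simulator.

Defaults reproduce the benchmark conditions: a random Yule species tree with
37 leaves rescaled to 500 My (the scale of a typical dated proteobacterial
phylogeny), and
per-pair rates in events/gene/My drawn as

* loss `r_L ~ U[0.001, 0.0018]`,
* birth (`r_D + r_T`) = `r_L × U[0.5, 1.1]`,
* duplication share `r_D / (r_D + r_T) ~ U[0.7, 1]`,

values in line with observed prokaryotic gene-family dynamics.  One rate set
is drawn per pair and shared by both families: the paired exponential clock
requires a single joint activity, so independent per-family rates would be
incompatible with the coupling construction.  Transfer receivers are uniform
over the branches alive at the event date, donor excluded.

What the simulator does **not** emulate: gene-tree estimation error (gene
trees are handed to the detector exactly as generated, so benchmark power is
an upper bound relative to trees inferred from sequences), rate
heterogeneity across branches (a per-branch multiplier would be a
straightforward extension; rates here are branch-homogeneous), replacement
transfers, and incomplete lineage sorting.  Families whose lineages all die
leave no tree and cannot be scored; benchmarks report them separately and
exclude them from rate denominators.

## Benchmarks and problem sizes

The package's operating characteristics are measured by simulating pairs at
each coupling level and running the full reconciliation-based pipeline
(never the ground-truth event logs) on every pair.  The shipped benchmark
and the acceptance script use 1000 pairs per `c` on a 37-leaf/500-My tree —
a batch that runs in about a minute per coupling level with the numba
engine — with the null table built once across the whole batch.  Under
these conditions the false-positive rate at the 0.05 threshold is
consistently below nominal (≈ 0.02–0.04 across seeds; the test is
conservative because the independence assumption of step 2 spreads scores
out) and power at `c = 0.7` is ≈ 0.82–0.87.  The exact numbers vary with the
random species tree; the qualitative picture — conservative at `c = 0`,
power > 0.8 from moderate coupling upward, p = 1 atom shrinking as `c`
grows — is stable.

## Numerical choices

* Ultrametricity tolerance: relative 1e-6 of tree height; ages are then
  renormalised (leaves exactly 0) and internal ages within tolerance are
  snapped to a shared value, so slice boundaries compare exactly.  Nodes
  with equal ages share one boundary and no zero-length artificial edges
  are created.
* Cost-tie detection in the DP uses an absolute tolerance of 1e-9; with the
  default integer costs all comparisons are exact in floating point.
* Poisson-binomial vectors are renormalised only if they drift beyond 1e-9
  (they essentially never do); p-values are clamped to [0, 1].
* `N = ⌈total weight⌉` uses a 1e-12 guard so that totals that are integers
  up to float error do not round up twice.
* Seeding: benchmark randomness flows through `numpy` `SeedSequence` spawns
  (one substream per pair), so any single pair can be re-simulated in
  isolation and reports are bit-reproducible for a fixed seed.

## Limitations

* Pre-root duplications are outside the reconciliation model (no stem
  branch): a family that expanded before the first speciation will have that
  event explained by in-tree events instead.  The projection and the null
  model would otherwise need a bin with no defined duration.
* The score's independence assumption across weighted events is known to be
  wrong in detail; the exact null makes the test conservative rather than
  anti-conservative under these conditions, but the p-values at c = 0 are
  not perfectly uniform.
* Equal event costs are the default and only lightly explored; the
  enumeration oracle covers non-unit integer costs, but cost inference is
  out of scope.
* Only most-parsimonious reconciliations feed the event weights; support
  from near-optimal scenarios can be supplied externally through the
  event-set TSV interface but is not computed here.
* Exactly two families per test; clustering many families is downstream
  work.
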