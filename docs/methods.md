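# Methods

## The microarray game and its Shapley values

A family of named, non-empty sets `F = {P_1, …, P_N}` over universe
`G = ∪ P_i`, `M = |G|`, defines a cooperative game on the sets: a
coalition `T` is worth `v*(T) = |{g : sp(g) ⊆ T}| / M`, where the
support `sp(g)` is the collection of sets containing `g`.  Because the
universe is defined as the union, every support is non-empty, `v*(∅) = 0`
and `v*(F) = 1`.  The game decomposes into one unanimity game per
element (on that element's support), which yields the closed-form
Shapley values

    ϕ(P_i) = (1/M) Σ_j 1(P_i ∈ sp(g_j)) / |sp(g_j)|,

computed here as a single weighted row-sum of the N×M incidence matrix
(O(nnz) time).  An exhaustive oracle (`shapley_bruteforce`) evaluates
the permutation-average definition over all 2^N coalitions with weights
`t!(N−t−1)!/N!` and is capped at N ≤ 20; it exists purely to verify the
closed form and the two agree element-wise to 1e-12 on randomized
games.  The classical weight denominator `N!` is used: it is the unique
choice under which the marginal-contribution weights for each player
sum to one, so efficiency (Σϕ = v*(F) = 1) holds, which the tests check
numerically.

## Rankings

**SV** sorts by ϕ descending.  The four penalized orderings are greedy:
having ranked `P̃_1 … P̃_{n−1}`, the Shapley values ϕ_n are re-computed
on the family restricted to the un-ranked sets and the winner maximizes
`ϕ_n(P) − penalty_n(P)`.

Decisions that the construction leaves open, and how they are resolved
here:

- **Restriction semantics.** Restricting the game to the un-ranked sets
  shrinks the universe to their union: elements supported only by
  already-ranked sets leave the game.  This restores efficiency at
  every iteration (Σ ϕ_n = 1 over un-ranked sets, asserted to 1e-12).
- **Penalties use original membership.** Jaccard penalties compare the
  sets as given, not their restricted versions; restriction applies
  only to the Shapley game.
- **PO keeps a raw accumulator.** The running sum `Σ_{i<n} J(P̃_i, P)`
  is stored un-rescaled; POR re-scales a *copy* of it each iteration to
  `[0, max_P ϕ_n(P)]`.  Re-scaling in place instead would compound the
  scaling factor across iterations and destroy the recursive sum; the
  copy semantics keeps the accumulated penalty well-defined while the
  applied penalty remains bounded by the current largest Shapley value.
- **Degenerate re-scale.** When the raw penalty vector is all zero
  (e.g. disjoint candidates), re-scaling is skipped — avoiding 0/0 and
  guaranteeing all four penalized methods coincide with SV on disjoint
  families.
- **Ties** at argmax are broken by construction order (first index
  wins), fixed once when the family is built.  This is also why all
  methods rank the global argmax-ϕ set first: penalties are zero at the
  first step.
- **Negative scores** are allowed for PO/AO (accumulated penalties can
  exceed ϕ); the argmax is taken regardless of sign.
- **Final iteration.** When one set remains it is appended without
  re-computation; its restricted Shapley value is 1 by efficiency, and
  the log records it as such.

`select_top` truncates a ranking to a count or a fraction of N;
fractions are rounded half-up (40% of 10 → 4, 25% of 10 → 3).

## Diagnostics

- *Jaccard score*: mean pairwise Jaccard over a sub-family (ordered-pair
  normalization `1/(k(k−1))`, identical to the unordered mean).  Prefix
  curves start at position 2 (one set has no pairs) and are re-scaled
  by the maximum pairwise Jaccard of the *full* collection; when that
  maximum is 0 the re-scaling is undefined and the raw curve is the
  fallback.
- *Coverage*: percent of the universe covered by a prefix's union;
  non-decreasing, 100 at the full family.
- *Size–rank correlation*: Kendall τ-b (tie-corrected — set sizes tie
  frequently) between set size and *earliness* `N − position`, so
  ranking large sets first gives positive τ.  All-equal sizes make τ
  undefined; 0 is returned with a degenerate flag.
- *Enrichment*: one-sided (over-representation) Fisher exact test per
  set, computed as the hypergeometric upper tail; adjustment by
  Bonferroni or Benjamini–Hochberg via statsmodels.  The background
  defaults to the family universe (plus any target elements outside
  it) and is overridable; within a truncated collection the correction
  multiplicity is the truncated size — the practical benefit of
  pruning.  Tests cross-check the tail computation against
  `scipy.stats.fisher_exact` and a direct enumeration of 2×2 tables.

## Synthetic collections

The generator emulates the structure of curated collections without
reproducing real gene vocabularies: log-normal set sizes (defaults
`exp(N(3.3, 0.6²))`, min 5 — median ≈ 27, heavy right tail), planted
clusters of overlapping sets (default one cluster per five sets) built
around a shared core, per-set private elements, and a low-rate (2%)
swap of members into a global background pool shared across clusters.
One integer seed drives all draws; no global random state is touched.

The core size per cluster is calibrated numerically: a set of size `s`
takes `min(core, s)` core elements, a pair is predicted to intersect in
`n_i·n_k/core` elements, and the smallest core whose predicted mean
pairwise Jaccard matches the target is used.  With equal sizes this
reduces to the closed form `c = 2st/(1+t)` and is exact (target 1.0 →
identical sets); with strongly heterogeneous sizes the achievable mean
Jaccard is capped by the size ratios (J(A,B) ≤ |A|/|B| for |A| ≤ |B|),
so high targets saturate — the calibration tests therefore use a
moderate size spread.  Infeasible requests (element demand exceeding
the universe budget) fail loudly rather than silently shrinking sets.

Target lists for enrichment are sampled per element with base inclusion
rate 0.05, elevated to `odds·p/(1+(odds−1)p)` inside enriched sets.

What the generator does **not** emulate: real gene-symbol vocabularies,
annotation quality differences between collections, hierarchical
pathway nesting, and the exact size laws of specific databases.
Passing tests on these families demonstrate the algebraic and
qualitative behaviour of the rankings (duplicate separation, lower
prefix redundancy, reduced size bias), not performance claims on any
particular real collection.

## Problem sizes

Tests and the acceptance script run on families of 8–200 sets over
universes up to ~9000 elements; the qualitative contrasts (prefix
redundancy and size-correlation of SV vs PO/AO) are evaluated on 20
seeded replicates of the default 100-set clustered spec, and the
oracle equivalence on 100 random games with at most 12 players.  The
full ranking of a 100-set family takes well under a second; the greedy
loop is O(N) Shapley re-computations of O(nnz) each plus O(N²) Jaccard
lookups from a precomputed pairwise table.

## Known limitations

- The greedy penalized orderings are heuristics: no optimality claim is
  made for the implicit min-overlap/max-coverage trade-off.
- Scores are floats; exact rational arithmetic appears only in unit
  tests on tiny fixtures.
- Membership is crisp and identifiers are opaque strings — no weighted
  membership, no gene-symbol normalization or alias resolution.
- Phenotype-aware (supervised) penalties are out of scope.
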