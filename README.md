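# shapsets

Redundancy-aware, unsupervised ranking of gene-set collections (or any
family of named sets) using Shapley values of microarray games.

## The problem

Curated gene-set collections (MSigDB-style GMT files) contain hundreds
to thousands of pathways with heavy overlap: the same genes recur in
many sets, so the collections are redundant and hard to interpret, and
every enrichment analysis pays a multiple-testing price proportional to
the collection size.  `shapsets` ranks the sets of a collection by
importance *without any phenotype information*, so that a truncated
collection keeps high gene coverage while shedding redundancy — and it
does so without merging or editing the sets themselves.

## The model

The collection `F = {P_1, …, P_N}` over gene universe `G` (`M = |G|`,
the union of all sets) is read as a cooperative game whose *players are
the sets*.  A coalition `T ⊆ F` is worth the fraction of genes whose
entire *support* `sp(g)` (the sets containing `g`) lies inside `T`:

    v*(T) = |{g ∈ G : sp(g) ⊆ T}| / M

This game is a sum of unanimity games (one per gene), so its Shapley
values have a closed form, linear in the size of the incidence matrix:

    ϕ(P_i) = (1/M) Σ_g  1(P_i ∈ sp(g)) / |sp(g)|

Each gene distributes `1/M` of the total value evenly among the sets
containing it; scores lie in `[0, 1]` and sum to 1 (efficiency).
Sorting by `ϕ` gives the **SV** ranking — which is blind to overlap: a
duplicated set scores identically to the original and lands right next
to it.  Four greedy penalized orderings repair this.  At each step the
Shapley values are re-computed on the game restricted to the
not-yet-ranked sets and the candidate score is

    S_n(P) = ϕ_n(P) − penalty_n(P)

* **PO** — penalty is the accumulated pairwise Jaccard index
  `Σ_{i<n} J(P̃_i, P)` with every previously ranked set;
* **POR** — PO's penalty re-scaled each iteration to
  `[0, max_P ϕ_n(P)]`, keeping scores non-negative;
* **AO** — penalty is the single Jaccard index `J(AP_n, P)` with the
  *artificial set* `AP_n`, the union of all ranked sets, so each shared
  gene is penalized exactly once;
* **AOR** — AO with the same re-scaling.

Diagnostics: the **Jaccard score** (mean pairwise Jaccard) of top-j
prefixes, re-scaled by the collection's maximum pairwise Jaccard;
cumulative **coverage** `c_G(S) = 100·|∪S| / M`; **Kendall τ-b**
between set size and rank earliness; and Fisher exact
over-representation tests (Bonferroni / Benjamini–Hochberg) comparing
truncated collections against the full one.

## Worked example

```python
import shapsets as ss

fam, labels = ss.generate_family(ss.SyntheticSpec(n_sets=20, n_clusters=4, seed=7))
sv, po = ss.rank(fam, "SV"), ss.rank(fam, "PO")
for m, r in (("SV", sv), ("PO", po)):
    top = ss.select_top(fam, r, 0.2)
    print(f"{m}: top-20% Jaccard score = {ss.jaccard_score(top):.3f}, "
          f"tau = {ss.size_rank_correlation(r, fam).tau:+.2f}")
```

prints

```
SV: top-20% Jaccard score = 0.146, tau = +0.84
PO: top-20% Jaccard score = 0.000, tau = +0.11
```

The generated collection has 4 planted clusters of overlapping sets.
Plain Shapley ranking (SV) puts large, overlapping sets first: its top
20% has a mean pairwise Jaccard of 0.146 and set size strongly predicts
rank (τ = +0.84).  The penalized ordering (PO) picks the same first set
(penalties start at zero) but then avoids everything overlapping it:
its top 20% is pairwise disjoint and the size bias largely disappears.
The top-4 PO sets cover 83% of the 20-set universe versus 57% for SV —
redundancy-aware pruning buys coverage per set.

The same pipeline runs from the shell on GMT files:

```
shapsets simulate --seed 7 --out sim.gmt
shapsets rank --gmt sim.gmt --method po --out rank.tsv
shapsets metrics --gmt sim.gmt --ranking rank.tsv --curves jaccard --curves coverage --kendall --out curves.tsv
shapsets prune --gmt sim.gmt --ranking rank.tsv --top 0.2 --out pruned.gmt
shapsets enrich --gmt pruned.gmt --target genes.txt --adjust fdr_bh --alpha 0.05 --out enrich.tsv
```

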