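# Methods

## Network model

A metabolic network is a set of reactions over compartment-specific
metabolites. Each reaction carries signed stoichiometry (negative =
substrate), flux bounds, and optionally a gene–protein–reaction (GPR)
rule. Reversibility is encoded in the bounds only (`lb < 0 < ub`);
reactions are never split into forward/backward halves, because the
landscape MILP operates on signed fluxes directly.

GPR rules are Boolean formulas over gene identifiers, normalised to
disjunctive normal form: an OR over AND-clauses, where an AND-clause
models an enzyme complex and alternative clauses model isozymes.
Formulas not already in DNF are distributed, with a hard cap of 4096
clauses — curated reconstructions ship DNF rules, so the cap only
guards pathological inputs. Clauses are deduplicated and sorted so
that semantically identical rules compare equal; this normalised
equality defines the *rule groups* (reactions sharing one rule) that
the entropy diagnostics and the adjustment operate on. Gene ids are
opaque strings; no symbol mapping is attempted.

SBML I/O is delegated to cobrapy; GPR strings are re-parsed into the
package's own DNF representation on load. Boundary species are
excluded from the steady-state constraint, matching the usual FBA
convention. Reaction classes are derived when the input carries no
tag: rule-bearing → enzymatic; boundary/single-sided → exchange;
multi-compartment → transport; demand only from an explicit tag.

## Gene activity

Raw counts are scaled per sample by total coverage and renormalised by
the median total, so the activity threshold keeps count-like units;
the threshold (default 5 reads) is then applied *after* scaling, and
inclusively (`count ≥ 5` → active). Both choices are configurable:
the strictness of the comparison is not fixed by any convention, and
an inclusive cut is the more permissive one, in line with keeping the
binarisation as permissive as possible. Genes referenced by rules but
absent from the expression table count as inactive, logged once per
process.

## The landscape MILP

Per sample, rule evaluation splits rule-bearing reactions into
expression-active `A` and expression-inactive `I`. The MILP maximises
`Σ_A (y⁺ + y⁻) + Σ_I y⁺` subject to `S·v = 0`, the bounds, and
indicator constraints: for `r ∈ A`, `y⁺ = 1` forces `v_r ≥ ε` and
`y⁻ = 1` forces `v_r ≤ −ε`; for `r ∈ I`, `y⁺ = 1` collapses the
bounds to `v_r = 0`. ε defaults to 1 flux unit — the additive unit
indicator term in the printed constraints — and is exposed in
`MilpConfig`.

A reaction is *active* when `|v_r| ≥ ε`, applied uniformly to `A`,
`I` and rule-free reactions, so reactions without rules also receive
states; the indicators are kept in the solution for audit. Reactions
whose state contradicts their expression call are reported as
post-transcriptional changes.

Solving uses HiGHS (scipy `milp`), single-threaded, with a fixed
variable ordering (fluxes in network order, then indicators), so runs
are bit-reproducible. The MILP can have many alternate optimal
landscapes; an optional second solve pins the objective at its optimum
and minimises the L1 norm of the flux vector, giving a canonical
(minimal-flux) representative. Whenever all bounds admit zero flux
the all-zero vector is feasible, so the solver can never legitimately
report infeasibility; infeasibility is surfaced faithfully when bounds
exclude zero.

The suite validates the solver against an independent brute-force
oracle that enumerates every indicator assignment and LP-checks each
flux polytope, on hundreds of random networks of up to 8 reactions
with up to 4 constrained reactions (3^|A|·2^|I| assignments each,
enumerated in descending reward order with early exit).

## Graph entropy

Reactions are projected to an undirected graph: vertices are all
reactions, an edge joins two reactions sharing at least one
compartment-specific metabolite. The projection choice (rather than
the bipartite metabolite–reaction graph, which is available as an
alternative) follows from the quantity of interest being the entropy
of *groups of reactions*; edges are undirected because the entropy
formula uses only neighbour counts. A user-supplied exclusion list
can drop currency metabolites (ATP, H₂O, H⁺ …) from the projection;
nothing is excluded by default.

For a vertex subset V′ and member v with I(v) neighbours inside and
N(v) in total, `PI = I/N`, `PO = 1 − PI`, `H(v) = −PI log₂ PI −
PO log₂ PO` (with `0·log 0 ≡ 0`; isolated vertices score 0 by the
0/0 convention, logged). The group's induced entropy is `Σ_{v∈V′}
H(v)`. H is bounded by [0,1] per vertex, maximal exactly at an even
split, and symmetric under swapping inner and outer counts; a group
fully wired inside and disconnected outside scores exactly 0 — the
hub signature.

Entropies are ranked against envelopes of uniformly drawn random
groups of matching size (default 1000 draws; quantiles 1/5/25/50/75/95/99,
percentile = fraction of draws strictly below the group's value),
seeded and reproducible.

## Binary statistics

PCA centres columns but does not scale them — the columns are binary
with comparable variance, and scaling would blow up near-constant
columns. The sign of each component is fixed by making its
largest-magnitude loading coordinate positive. The selection rule
`L_{f,k}` takes, per component `i ≤ k`, every coordinate with
`|loading| ≥ f(component)`; `f = "max"` keeps exactly the
largest-magnitude coordinates (ties all kept, with a 1e−9 relative
slack so analytically equal loadings are not split by floating
point), `f = "frac:q"` keeps everything within `q` of the maximum.

The Jaccard index is implemented in its count form
`[min(x₁,y₁)+min(x₀,y₀)] / [max(x₁,y₁)+max(x₀,y₀)]` over one/zero
counts, which is position-free and defined for unequal lengths; the
classical positional one-set reading is available as `mode="sets"`.
Its length-dependent maximum `jaccard_max(n, m)` is found by
exhaustive search over count pairs (the definition itself). A
reaction differentiates two sample groups when the Jaccard index of
its two activity columns is at most 0.25 of that maximum; the 0.25
cut is a similarity threshold, not a statistical test, so no
multiple-testing correction applies.

Tanimoto similarity `(n − d)/(n + d)` with Hamming distance `d` is
the clustering similarity; `1 − T` the distance. Fractional
activities produced by aggregation use the L1 generalisation
`d = Σ|xᵢ − yᵢ|`. Hierarchical clustering uses average linkage
(UPGMA) — a middle ground between the chaining of single and the
compactness bias of complete linkage; note average linkage is only
order-invariant when merge heights are untied.

## Adjustment

Each reaction gets a compartment label `s₁…s_k-p₁…p_j`: alphabetically
sorted unique substrate-side compartments, a dash, product-side
likewise; an empty side renders as an empty string, multi-character
compartment codes are comma-joined to stay unambiguous. Reversible
reactions are labelled in their written direction by default (no
canonical orientation is implied by the data); a canonical mode
orients the lexicographically smaller side first.

Within each gene rule, reactions with equal labels are aggregated
into one representative column whose value is the arithmetic mean of
the member activities; singleton groups and rule-free reactions pass
through unchanged under their original ids. Aggregation conserves
per-sample activity mass (Σ size×value = Σ member activities) and is
idempotent.

A rule group is *flagged* for adjustment when (a) at least half of
its members appear in the `L_{f,k}` selection and (b) its entropy
percentile is below 5. Groups of size 1 are never flagged.
By default only flagged groups are aggregated — the adjustment is a
targeted correction, not a blanket transform — with an
`--aggregate-all` switch to aggregate every rule group.

## Synthetic benchmark

The planted-hub generator builds a random background (each reaction a
one-to-one conversion between random background metabolites, gated by
its own unique gene, plus a reversible exchange per background
metabolite so that any single reaction can carry flux independently)
and `n_hubs` hubs: `hub_size` reversible reactions over a small
hub-private metabolite pool, all sharing one gene rule, attached to
the background by `external_links` rule-free link reactions. The
pool size is derived from the requested internal wiring density; at
density 1 all members interconvert the same two pool metabolites, so
they are pairwise adjacent in the projection and can all carry
`|v| ≥ ε` simultaneously (fluxes summing to zero around the pool).
All bounds contain zero, so every per-sample MILP is feasible.

Defaults — 40 background reactions, 2 hubs of 40 reactions, density
1.0, 2 external links — mirror, at reduced scale, the situation in a
genome-scale reconstruction where the ten most common rules govern
hundreds of reactions and the largest flagged hubs hold 79–94
reactions. Random gene activities are i.i.d. Bernoulli(0.5) per gene
and sample; the null input has no sample structure by construction.

`artifact_benchmark` keys each sample by the ground-truth activity
states of the hub genes (2^n_hubs combinations) and reports the
silhouette of that keying on 3-component PCA scores before and after
adjustment. "Artifact present" = pre-silhouette > 0.5; "artifact
removed" = post-silhouette < 0.25. Using ground-truth keying rather
than unsupervised cluster-number selection makes the benchmark
deterministic in expectation. The acceptance suite requires the
contrast to hold in ≥ 4 of 5 seeds at 100 samples.

What the benchmark does *not* emulate: realistic expression marginals
and gene–gene correlation, multi-gene rules in the background,
currency-metabolite hairballs, and genome-scale problem sizes. A
passing benchmark shows that the pipeline detects and removes
topology-induced cluster structure under controlled conditions; it
does not certify behaviour on real reconstructions, where hub wiring
is messier and entropy envelopes wider.

## Numerical choices

- MILP: HiGHS defaults, `mip_rel_gap = 0`, single thread; activity
  cut `|v| ≥ ε − 1e−9` to absorb solver tolerance.
- PCA via dense SVD of the centred matrix (landscape matrices at the
  sizes handled here are small and dense).
- Entropy percentile: strict `draws < value − 1e−12`.
- Problem sizes in the test and acceptance suites (networks of ≤ 130
  reactions, 100 samples, 500-draw envelopes) are the package's
  chosen desk-scale study conditions; all generators are pure
  functions of (spec, seed).
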