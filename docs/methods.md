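# Methods

## Model and procedure

`orthosig` quantifies how much of a PPI network's functional-complex
structure is attributable to an orthology signal. Given a weighted
undirected network `G(V, E)` and an ortholog protein set `O ⊆ V`, it runs
three clustering branches and compares them per GO function:

1. **Global (GC).** MCL on the whole network.
2. **Ortholog (OC).** MCL on the induced subnetwork `G[O]`.
3. **Random (RC).** MCL on `G[R_i]` for `N` uniform random samples `R_i`
   of size `|O|` drawn from `V` without replacement (singletons of the
   parent network are eligible; the sampling universe is all of `V`).

Each branch turns its size-≥3 clusters into putative complexes via the
three-criterion coherence rule (below), takes `S(X)` = union of complex
proteins, `B(X)` = non-singleton nodes of `G[X]`, and computes the
retrieval index `ϱ(f, X) = |S(X) ∩ C(f)| / |B(X) ∩ C(f)|` for every
function `f` carried by the background. `C(f)` counts proteins annotated
to `f` or any descendant under the evidence whitelist. A function with no
carrier in the background (0/0) is *undefined* and excluded from
comparisons — such a function could not be enriched in that sample anyway.

A function is orthology-related iff
`ϱ(f, O) > max{ϱ(f, V), ϱ(f, R95%)}`, both inequalities strict. Functions
eligible for the rule are those with a defined `ϱ(f, O)`, i.e. at least
one candidate protein in `B(O)`. A missing global value counts as 0, and a
function never observed in any random run has a null threshold of 0:
absence of retrieval is zero retrieval. For the same reason every null
distribution holds exactly `N` values — runs in which a function's
retrieval is undefined or zero contribute 0 rather than being dropped,
which would bias the percentile upward.

### MCL

The transition matrix is built from edge weights; every node receives a
self-loop equal to its maximum incident edge weight (1 for isolated
nodes) before column normalisation — the standard damping choice; the
original description of the pipeline is silent on loop weights.
Expansion (matrix squaring) and inflation (entrywise power, default 1.8,
plus column renormalisation) alternate until the maximum absolute matrix
change falls below `tol = 1e-6` or 100 iterations elapse (then a warning
and best-effort clusters). Entries below `1e-8` are pruned each iteration
for sparsity. Clusters are read from the attractor structure of the limit
matrix; attractor rows sharing members merge into one system, and a node
flowing to several systems (a rare, tie-induced event) is assigned to the
system receiving its largest flow, ties broken by the smallest attractor
index. This keeps the output a strict partition, which the retrieval
index requires. The procedure is deterministic: identical input and
parameters give identical partitions.

### Coherence criteria

A term is significantly coherent in a cluster iff

1. Bonferroni-corrected one-sided Fisher p < 0.001 (`alpha`), correction
   scope = number of terms tested within that cluster;
2. strictly more than half the cluster's proteins carry the term — via
   true-path propagation, consistent with how `C(f)` counts carriers;
3. term level ≥ 4, where level is the *longest* path from the namespace
   root (computed per namespace; the GO has three roots).

All three bounds are strict/inclusive exactly as stated; the tests pin
the boundary cases (p = alpha rejected, exactly half rejected, level 3
rejected). Coherent terms are reduced to the filial frontier (no retained
term an ancestor of another); the complex's full annotation set adds all
ancestors of the filial terms, namespace roots excluded.

**Enrichment population.** Fisher's test uses the whole network node set
`V` as its population for every branch, not the per-sample background
`B(X)`. Two reasons. First, comparability: a single constant population
is how a GO-enrichment tool is normally configured when one study set is
swapped in and out, and it makes p-values commensurable across the GC/OC/
RC classes. Second, power: with a small induced sample the hypergeometric
tail has a floor of `C(N−n, K−k)/C(N, K)`-scale magnitude; at
`|B(O)| ≈ 2×` cluster size even a perfect module cannot reach corrected
p < 0.001, so the `B(X)` population makes the criterion undecidable
exactly where the method should fire. The retrieval index itself keeps
its per-sample background, as its definition requires.

Fisher p-values come from `scipy.stats.hypergeom.sf` (Boost backend); the
test suite verifies them against exact integer tail enumeration over all
2×2 tables with N ≤ 60 at 1e-12 relative error.

### Percentile

`ϱ(f, R95%)` is an order statistic, not an interpolated quantile: sort
the `N` values ascending and take the element of 1-based rank
`ceil(0.95·N)`. The threshold is therefore always an actually observed
sample value.

### Uniqueness and verification

An OC complex predicts each of its filial functions for each of its
proteins (including previously unannotated ones — that is the prediction
mechanism). A complex is *unique* if at least one of its (protein,
function) pairs is predicted by no GC complex containing that protein;
requiring *all* pairs to be new is the other defensible reading, but the
at-least-one rule matches the idea that a single genuinely new prediction
suffices to distinguish the complex. Unique pairs are *verified* when the
reference annotation set — parsed with a wider whitelist that adds
curated and computational evidence codes — contains the function (via
itself or a descendant) for that protein, else *novel*; one complex can
hold both kinds.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `inflation` | 1.8 | MCL granularity (dimensionless; >1) |
| `min_cluster_size` | 3 | smallest cluster kept as complex candidate |
| `alpha` | 0.001 | corrected-p bound of coherence criterion 1 |
| `min_level` | 4 | minimum ontology depth of a coherent term |
| `n_runs` | 1000 | random-sampling runs per null (tests use 200) |
| `percentile` | 0.95 | order-statistic rank of the null threshold |
| `evidence_whitelist` | EXP,IDA,IPI,IMP,IGI,IEP | experimental GO codes |
| `min_weight` | none | optional confidence cutoff on input edges |

The evidence whitelist defaults to the GO experimental codes — the
conventional reading of "experimentally verified"; the exact codes are a
package choice and configurable. Ontology levels use `is_a` edges only by
default (`part_of` optional): longest-path level semantics are cleanest
over a single subsumption relation.

## The synthetic study

`orthosig.synth` generates a self-contained miniature of the real inputs,
emitted in the actual external formats (edge list, OBO 1.2, GAF 2.1,
plain ID lists) so all parsers are exercised. Defaults:

* **Network.** Planted-partition graph, 8 communities × 10 proteins,
  `p_in = 0.9`, `p_out = 0.02`, weights uniform in [0.5, 1].
* **Ontology.** One namespace; per community a root→…→marker chain with
  the marker at level 4 and the level-1 chain head doubling as the
  GO-slim term; two decoy terms on chains of their own.
* **Annotations.** Each community annotates exactly
  `round(0.9 × 10) = 9` random members to its marker. The exact count
  (rather than i.i.d. coin flips at 0.9) keeps the ">half" criterion
  satisfiable by construction, so the planted ground truth is
  unambiguous. Decoys are annotated to a random half of the community
  proteins, excluding the shrouded community (below).
* **Ortholog set.** Communities 0 and 1 in full, plus random scatter from
  the rest, sized to 22% of `|V|` (within the span of ortholog fractions
  typical for cross-species comparisons, and small enough for the null
  analysis below).
* **Halo.** Each signal community gets 6 extra carrier proteins of its
  marker, outside the ortholog set, wired into one 12-clique. No function
  covers more than half of that clique, so it is never a complex: its
  carriers stay in `B(V)` but outside `S(V)`, pinning `ϱ(marker, V)`
  at 9/15 = 0.6 while `ϱ(marker, O) = 1`. This is the mechanism the
  statistic is designed to detect; without it a fully recovered global
  clustering retrieves every marker perfectly and the strict inequality
  can never fire.
* **Shroud.** The second signal community is additionally wired (at
  `p_in`) to 12 unannotated proteins excluded from the ortholog set. In
  the global run the merged 22-node cluster has no majority function and
  yields no complex (`ϱ(marker, V) = 0`); in the ortholog run the
  community stands alone and is recovered. This plants unique complexes
  and verified/novel predictions end to end. Decoys avoid this community
  so that they remain negative controls: every decoy carrier is
  retrieved globally (`ϱ(decoy, V) = 1`), hence a decoy can never pass
  the strict global filter; a decoy with carriers hidden in the shroud
  would carry a genuine differential signal by construction.
* **Reference set.** The experimental annotations plus computational
  (IEA-style) marker annotations for half of each community's
  non-carriers, so unique predictions split into verified and novel.

**Null saturation analysis.** The recovery experiment (200 runs, 20
seeds) requires the null threshold `ϱ(marker, R95%)` not to saturate at
1. A random 23-sample of the 104-node network places on average ~2.2
nodes in a given community; a partial community only becomes a complex
when ≥5 sampled members are all carriers and survive Bonferroni, and a
run only reaches `ϱ = 1` when additionally no halo carrier lands in the
background. The joint per-run probability is ~0.3%, so ≥10 such runs in
200 (what rank-190 saturation needs) has probability ~1e-9. The ortholog
fraction and halo size were chosen from this analysis.

**What the fixture does not emulate:** realistic degree distributions,
the true GO topology (multi-parent diamonds exist only in the test DAGs,
not the generated chains), inter-annotation correlations beyond
community membership, or weight-confidence structure. Passing tests
demonstrate the machinery — parsing, clustering, the statistic, the
filters — under controlled truth; they do not certify biological
conclusions on real interactomes.

## Numerical and degenerate-input choices

* Duplicate edges keep the maximum weight (conservative merge of
  redundant evidence); self-loop rows are dropped.
* Protein-set IDs absent from the network are ignored with a logged
  count — ortholog lists routinely contain proteins missing from the
  interactome — but an empty intersection is an error.
* An empty cluster set after size filtering simply yields zero
  complexes; report rows with zero denominators are printed flagged
  (`*`) rather than erroring.
* Random-class table rows print means (± sample standard deviation) over
  runs; ratio cells are recomputed from the printed (rounded) count
  cells so every emitted table is internally consistent.
* Per-run null seeds derive as `seed + i`; each ortholog set's null uses
  `seed + 100000·(index+1)`. Everything downstream of a `RunConfig` is
  reproducible byte for byte.

## Problem sizes used by the test suite

Unit and acceptance tests run the default synthetic study (104 nodes,
~570 edges) with 200-run nulls for the recovery experiment and 4–20-run
nulls for smoke and determinism checks; the Fisher oracle sweeps all 2×2
tables with N ≤ 60; the MCL oracle covers 150 random graphs of ≤ 20
nodes at three inflation values. These sizes were chosen so a full
`pytest` pass and the acceptance script each complete in about a minute
on a single CPU while still exercising every code path at the scale the
statistics need.

## Known limitations

* MCL is implemented with sparse matrices but the pipeline is designed
  and tested at fixture scale; very large interactomes would want a
  blocked or compiled MCL.
* Orthology-relatedness is not propagated along GO paths between related
  terms; each function is judged independently.
* The random-class branch executes sequentially; per-run seeding makes
  parallel execution produce identical results, but no worker pool is
  wired in.
* Confidence weighting of interactions and construction of ortholog sets
  are out of scope: inputs arrive pre-weighted and as flat ID lists.
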