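# Methods

## The joint-significance model

A gene's two-sided DGEA p-value `T_i` is mapped to the upper-tail normal
score `t_i = Φ⁻¹(1 − T_i)`: standard normal under the null, shifted upward
for genes with evidence of modulation (regardless of the direction of the
fold change — the transform uses the p-value only, so up- and
down-regulated genes both push the score up). P-values are clamped to
`[1e-15, 1 − 1e-15]` before the transform; Φ⁻¹ diverges at the endpoints
and the clamp keeps scores finite while preserving ordering.

A connected gene set is scored with the weighted inverse-normal statistic
for dependent tests,

    t(ρ) = Σ λ_i t_i / sqrt((1 − ρ) Σ λ_i² + ρ (Σ λ_i)²),

which is standard normal under the joint null when the scores are
equicorrelated with correlation ρ. All weights are 1. The combined
p-value is `1 − Φ(t(ρ))`; for a singleton it is defined as the gene's own
(clamped) p-value, bypassing ρ entirely. The statistic is invariant to a
uniform rescaling of the weights and strictly increasing in every single
score, so lowering any member's p-value can only strengthen the set.

### The correlation parameter

`estimate_rho` implements the one-sample moment estimator
`ρ̂ = 1 − s²(t)` (sample variance, `ddof = 1`), clamped to the admissible
range `[−1/(n−1), 1]`: under the equicorrelated model the scores have
variance `1 − ρ`. Two consequences matter:

* With unit weights the squared denominator of `t(ρ)` is
  `n(1 + ρ(n−1))`, which is **exactly zero** at the lower clamp
  `ρ = −1/(n−1)`. Heterogeneous score sets — a couple of strong genes
  plus one near-null gene is already enough — drive `ρ̂` to that clamp,
  where the statistic is undefined, and just inside it the statistic
  explodes in magnitude. `combine_pvalues` raises on the exactly
  degenerate case rather than returning an arbitrary number.
* As a greedy search objective the estimated-ρ̂ score is therefore
  unusable: near the clamp, adding an *uninformative* gene can send the
  combined significance to machine zero, so noise genes would be
  preferred over signal genes.

The search consequently evaluates every candidate at a **fixed** ρ,
`score_rho = 0` by default — the Stouffer special case `Σt/√n` of the same
formula. This is the well-behaved end of the family: monotone, bounded,
and exactly calibrated when the member p-values are independent. A fixed
positive ρ (making the score mean-like for large sets and hence more
conservative) or `score_rho="estimate"` can be set in `SearchConfig`;
we verified that small positive values (ρ ≲ 0.07) leave the search's
qualitative behaviour on the worked fixtures unchanged while shrinking
the sub-graphs it grows.

## The four-step search

The search operates on the genes shared by the network and the DGEA table
that carry a usable p-value; genes without a p-value contribute no
evidence and are invisible (they cannot be members, extension genes or
connectors). Membership decisions use undirected adjacency — regulatory
evidence is symmetric at the level of co-modulation — while the original
edge directions are preserved for reporting and topology annotation.

1. **Initialize.** While an unassigned gene with `p ≤ seed_alpha`
   (default 0.05) exists: seed at the smallest-p unassigned gene (ties
   broken lexicographically), then repeatedly scan its unassigned
   neighbours in ascending `(p, gene)` order and accept the first whose
   addition strictly raises the combined statistic (equivalently,
   strictly lowers the combined p-value). `neighbor_rule="best"` instead
   scans all neighbours and takes the best improving one. Without the
   seed gate every gene would eventually seed a singleton; the gate plus
   the reporting filter keeps the output to a handful of sub-graphs.
2. **Extend.** For each sub-graph, enumerate all simple paths of
   1..`max_extension_len` (default 2) unassigned genes anchored at member
   nodes, deduplicated by gene set. Candidates are tried in ascending
   order of their *own* combined p-value (tie: lexicographic sequence); a
   path is accepted iff adding all its genes strictly improves the
   sub-graph. Enumeration restarts after each acceptance and the step
   iterates to a fixpoint over all sub-graphs. This is what lets the
   search cross one or two genes with no individual signal.
3. **Merge.** Pairs are processed in ascending order of their better
   parent's combined p-value. For a pair, all connectors of
   0..`max_connector_len` (default 2) unassigned genes linking the two
   sub-graphs are enumerated by depth-bounded DFS; the connector
   minimizing the merged combined p-value (tie: shortest, then
   lexicographic) defines the merge candidate, accepted iff it strictly
   beats *both* parents. The pair list is rebuilt after each acceptance;
   the step iterates to a fixpoint.
4. **Finalize and annotate.** Sub-graphs with fewer than
   `report_min_size` (default 2) genes or combined p above `report_alpha`
   (default 0.05) are dropped; survivors are renumbered 1..k by ascending
   combined p and their directed induced edge sets are computed from the
   full network. Sources (in-degree 0, out-degree ≥ 1 within the induced
   edges) and sinks (the converse) are identified; cycles can leave a
   sub-graph with neither.

Strict (`<`) improvement with no tolerance guarantees termination: steps
1–2 strictly grow the assigned gene set (bounded by the network), step 3
strictly reduces the sub-graph count, and ties reject. There is no
randomness anywhere in the search; identical inputs give byte-identical
outputs.

### Impact and reliability

A source's impact score is `100 × n_down / (|genes| − 1)` where `n_down`
counts the members reachable from it along directed induced edges. The
prose notion "relative number of downstream genes" is ambiguous between
immediate out-degree and full reachability; reachability is the default
because the score is meant as an upper bound on how much of the
sub-graph's modulation the source could have triggered, and a
configuration switch (`impact="immediate"`) provides the out-degree
variant. Downstream sets of different sources may overlap; impacts are
deliberately not normalised across sources and may sum beyond 100%.

Reliability is a Welch (unequal-variance) two-sided t-test on
natural-log-transformed p-values of the source's immediate out-neighbours
inside the sub-graph versus its immediate in-neighbours in the *global*
network (a source has no upstream members inside the sub-graph by
definition, so only the global network can supply the upstream regime).
The t statistic is invariant to the log base, since a base change rescales
both groups equally. If either group has fewer than two members the test
is flagged not-computable (`None`), never raised. No multiple-testing
correction is applied across sources.

## Synthetic instances

`generate_instance` builds a directed network (Erdős–Rényi with expected
out-degree 3, or a Barabási–Albert skeleton with random edge orientation),
selects a connected planted module by undirected random walk, and draws
p-values: planted genes from Beta(a, 1) — `a = 0.1` by default, mean
p ≈ 0.09, strongly right-skewed, with `a = 1` recovering the uniform null
— and background genes from Uniform(0, 1). Log-fold changes are
Normal(±2, 1) for planted genes (random sign) and Normal(0, 1) otherwise.
The default class used throughout the benchmark and the acceptance script
is 500 nodes with a 40-gene module, large enough for the seed, extension
and merge machinery all to engage while a full pipeline run stays in the
hundreds of milliseconds.

Noise is injected in score space: each gene's `t_i` receives independent
Normal(0, `noise_sd`) and the p-value is re-derived. This is a stand-in
for count-level noise propagated through a DGEA — it exercises the
search's sensitivity to p-value perturbations across the whole range, but
it does not reproduce the mean–variance coupling, library-size effects or
gene–gene correlation of real RNA-seq counts. Recall of the planted genes
(fraction of the planted module covered by the union of reported
sub-graphs) is the benchmark metric; with `noise_sd = 0.5` the median
recall over 100 replicates on the default class is above 0.9.

Passing these benchmarks shows that the search machinery recovers a
coherently significant connected structure planted under this generative
model and that the advantage over hard p-value cut-offs (far fewer,
larger connected units at equal or better planted-gene coverage) is
systematic; it does not certify behaviour on real networks, whose degree
distributions, motif structure and p-value dependence differ.

## Known limitations

* **Greedy growth is anti-conservative.** Any strict-improvement rule on
  a combined p-value selects genes favourably; at ρ = 0 the acceptance
  threshold for the next gene decays like `s/(2√n)`, so on a pure-null
  instance the search still assembles sub-graphs with nominally tiny
  combined p-values (on the default 500-node null class it typically
  reports one large unit). The combined p-value of a reported sub-graph
  must therefore be read as a *ranking and description* of the selected
  set, not as a calibrated significance test of the selection procedure.
  A positive `score_rho` dampens (but does not remove) this growth.
* The estimated-ρ̂ variant of the objective is provided for completeness
  but degenerates on heterogeneous sets, as described above.
* Sub-graphs are disjoint by construction; a hub gene genuinely shared by
  two modules is assigned to whichever grew first.
* The reliability test treats neighbour p-values as independent samples,
  which they are not in a real network; it is a screening heuristic.
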