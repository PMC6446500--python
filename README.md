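# msfinder — Modulated Sub-graph Finder

`msfinder` detects *modulated sub-graphs*: connected sets of genes in a
directed gene-interaction network that, scored jointly, show significant
differential expression — even when few (or none) of the individual genes
pass a conventional p-value cut-off. It is aimed at people who already have
a whole-genome differential-expression result (edgeR, DESeq2, or any table
of per-gene p-values and log-fold changes) and a directed interaction
network (e.g. Reactome functional interactions restricted to direct
interactions), and who want to read how a perturbation propagates through
the network instead of staring at a flat gene list. Because the search
works on the raw network rather than on pathway gene sets, the reported
sub-graphs freely span pathway boundaries and expose cross-talk.

## Model

Each gene's DGEA p-value `T_i` is transformed to its upper-tail normal
score `t_i = Φ⁻¹(1 − T_i)`. A gene set's joint significance is the
weighted inverse-normal statistic for dependent tests

```
t(ρ) = Σ λ_i t_i / sqrt((1 − ρ) Σ λ_i² + ρ (Σ λ_i)²)
```

with equal weights `λ_i = 1` and score correlation ρ; the combined p-value
is `1 − Φ(t(ρ))`. The library exposes the moment estimator
`ρ̂ = 1 − s²(t)` (clamped to `[−1/(n−1), 1]`); the sub-graph search scores
candidates at a fixed ρ (0 by default, the Stouffer special case) because
the estimated ρ̂ is degenerate at its lower clamp for heterogeneous score
sets — see `docs/methods.md`.

Sub-graphs are found by a deterministic four-step heuristic:

1. **Initialize** — seed at the most significant unassigned gene, greedily
   add neighbouring genes while the combined p-value strictly drops.
2. **Extend** — add whole paths of up to 2 (configurable 1–3) unassigned
   genes, bridging short gaps of individually unremarkable genes.
3. **Merge** — join two sub-graphs through a connector of up to 2
   (configurable 0–3) genes when the merged score beats both parents.
4. **Annotate** — report each sub-graph's *sources* (members with only
   outgoing induced edges: candidate perturbation entry points) and *sinks*
   (only incoming). Every source gets an **impact score**, the percentage
   of the sub-graph's other genes reachable from it along directed edges,
   and a **reliability** Welch t-test contrasting log-transformed p-values
   of its immediate downstream (in-sub-graph) versus upstream (global
   network) neighbours.

## Worked example

```python
from msfinder import ModulatedSubgraphFinder
from msfinder.simulate import generate_instance, recall

inst = generate_instance(n_nodes=200, module_size=20,
                         signal_beta_a=0.1, rng_seed=42)
finder = ModulatedSubgraphFinder().fit(inst.network, inst.dgea)
for sg in finder.subgraphs_:
    print(f"subgraph {sg.id}: {len(sg.genes)} genes, "
          f"combined_p = {sg.score.combined_p:.3g}, "
          f"{len(sg.induced_edges)} directed edges")
sources = [a for a in finder.annotations_ if a.role == "source"]
top = max(sources, key=lambda a: a.impact_score)
rel = f"{top.reliability_p:.3g}" if top.reliability_p is not None else "n/a"
print(f"{len(sources)} sources; top impact: {top.gene_id} "
      f"({top.impact_score:.1f}%, reliability p = {rel})")
print(f"planted-gene recall: {recall(finder.subgraphs_, inst.planted_genes):.2f}")
```

prints

```
subgraph 1: 73 genes, combined_p = 2.93e-45, 108 directed edges
16 sources; top impact: g195 (68.1%, reliability p = n/a)
planted-gene recall: 1.00
```

The synthetic instance plants a connected 20-gene module with Beta(0.1, 1)
p-values in a 200-gene background; the search recovers every planted gene
inside one jointly significant sub-graph (combined p ≈ 3·10⁻⁴⁵) along with
neighbouring genes whose addition still strengthened the joint signal. The
top source `g195` can reach 68.1% of the sub-graph's other genes along
directed edges; its reliability test is not computable (`n/a`) because it
has fewer than two upstream neighbours in the global network.

The same pipeline runs from the shell on real files:

```sh
msf run dgea.tsv network.tsv -o msf_out          # edgeR/DESeq2/generic table
msf simulate --replicates 100 --noise-sd 0.5     # planted-module benchmark
```

`msf run` writes a Cytoscape-importable `subgraphs.sif`, a
`node_attributes.tsv` (log-fold changes, source/sink flags, impact
scores), a `sources_sinks.tsv` report and a `manifest.tsv` recording the
exact configuration. Runs are deterministic: identical inputs and options
give byte-identical outputs.

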