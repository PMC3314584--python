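# gsmod — greedy functional-module detection in protein interaction networks

Protein–protein interaction (PPI) networks hide functional modules —
protein complexes and co-functioning groups — as densely wired regions
separated by sparse background. `gsmod` implements two greedy detectors
built on a common edge weight, together with the standard evaluation stack
and seeded synthetic benchmarks, for bioinformaticians who want to cluster
an interaction network from an edge list and score the result against a
complex catalog and functional annotations.

## The model

Every interaction (u, v) is weighted once by

```
w_uv = |N_uv| + α · |E_uv|
```

where `N_uv = N_u ∩ N_v` is the common-neighbour set of u and v, `E_uv`
the set of network edges among those common neighbours, and α (default 1)
the interaction factor. `hw_n = max_u w_nu` is a node's highest edge
weight. Two detectors consume these quantities:

**GSM-CA (core-attachment search)** grows modules one at a time. The
unclustered edge of maximal weight seeds a core, which is valid only while
that weight is strictly above 1 (a lone triangle, all weights 1, never
seeds). The core absorbs, one node per step, the neighbour u with the
largest `hw_u` among those whose highest-weight edge leads to a core
member v and whose closeness

```
cn_uv = |NC_u ∩ NC_v| / |NC_v|      (NC_x = N_x restricted to the core)
```

reaches the threshold `cn_in` (default 0.5). A single sweep then adds
attachments: neighbours u whose highest-weight edge ends in the core at v
and for which strictly more than half of `N_uv` lies inside the core.
The finished module's incident edges are masked, hw is updated, and the
search repeats. An optional overlap mode re-opens the finished clustering
and lets every module absorb further neighbours — including nodes owned by
other modules — under the same attachment criterion.

**GSM-FC (fast clustering)** is parameter-free and single-pass: all nodes
start as singletons and each edge (u, v) is visited exactly once, merging
the two clusters iff `w_uv = hw_u` or `w_uv = hw_v`. The result is
provably independent of the traversal order.

**Evaluation.** A predicted module p matches a benchmark complex b when
the overlap score `OS(p, b) = i² / (|p|·|b|) ≥ ω` (i the intersection
size; ω default 0.20). From the matched sets, sensitivity
`|TP|/(|TP|+|FN|)`, specificity `|TP|/(|TP|+|FP|)` and their harmonic mean
(the s-measure) summarize agreement. Functional coherence is scored per
module by the upper-tail hypergeometric p-value of its best annotation
term and by the best-term f-measure (harmonic mean of recall and
precision).

## Worked example

Generate a 4-module core-attachment benchmark (5-clique cores, 3
attachments each wired to 2 core proteins, 1% inter-module noise, 6
decoy annotation terms), cluster it, and evaluate:

```
$ gsmod simulate --model core-attachment --n-modules 4 --attach-frac 0.4 \
    --p-out 0.01 --background-terms 6 --noise-rate 0.1 --seed 11 \
    --out-prefix bench
32 nodes, 65 edges -> bench.*

$ gsmod cluster-ca bench.edges.tsv --output modules.tsv
6 modules -> modules.tsv

$ gsmod evaluate modules.tsv bench.complexes.tsv
{ ... "tp": 6, "fp": 0, "fn": 0, "tb": 4,
  "sensitivity": 1.0, "specificity": 1.0, "s_measure": 1.0 ... }

$ gsmod enrich modules.tsv bench.annotations.tsv --output enrich.tsv
{ "avg_f_measure": 0.718..., "avg_neglog10_p": 3.68...,
  "n_modules": 6, "n_significant": 4, ... }
```

The clustering TSV labels every protein `core` or `attachment` (25 core
and 7 attachment rows here). All 6 predicted modules match a planted
complex at ω = 0.20 and all 4 planted complexes are matched, so
sensitivity, specificity and s-measure are all 1.0; two planted modules
were each recovered as a core plus a separate fragment, which is why 6
modules cover 4 complexes and only 4 of the 6 reach the 0.01 enrichment
cutoff against their planted terms. `gsmod cluster-fc` runs the
parameter-free single-pass detector on the same edge list, and every
subcommand writes a `*.manifest.json` recording parameters and input
digests for exact re-runs.

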