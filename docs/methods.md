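# Methods

## Model and assumptions

Both detectors assume the structural premise that functional modules in a
PPI network are densely connected regions separated by sparse background
wiring, and both read that structure through one statistic: the
common-neighbour edge weight `w_uv = |N_uv| + α·|E_uv|`. The second term
distinguishes edges whose common neighbourhood is itself interconnected
(the signature of a dense module interior) from star-like neighbourhoods
of equal size. Weights are computed once on the full input network and
never recomputed; during iterative clustering only the per-node highest
edge weight `hw_n` is maintained over the still-unclustered (unmasked)
edges. The input is an undirected simple graph: the edge-list reader
drops self-interactions, collapses duplicate pairs in either orientation,
and reports what it dropped so interaction counts can be reconciled with
the source database.

GSM-CA additionally assumes the core-attachment organization of protein
complexes: a small dense core that determines the complex's role, plus
peripheral attachments. Its two admission tests encode that reading —
core candidates need closeness `cn_uv ≥ cn_in` to the growing core
through their strongest remaining edge, and attachments need a strict
majority of the relevant common neighbourhood inside the finished core.
GSM-FC drops the role split entirely in exchange for a single pass.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `alpha` | 1 | weight of the interconnection term `|E_uv|`; 0 reduces to plain common-neighbour counting |
| `cn_in` | 0.5 | minimum closeness for core growth (GSM-CA); higher values push cores towards cliques |
| `min_seed_weight` | 1 (strict) | a seed edge must weigh strictly more than this; rules out triangle-only remnants |
| `min_size` | 3 | smallest module reported; clusters of every size are still formed and removed so a seed never repeats |
| `omega` | 0.20 | overlap-score threshold for declaring a predicted/benchmark match |
| p-value cutoff | 0.01 | raw per-module significance threshold for the best-term hypergeometric test |
| `min_merge_weight` | 0 (inactive) | GSM-FC escape hatch: suppress merges across edges lighter than this |

All defaults are plain numbers with no units; networks are unweighted on
input. GSM-FC has no tunable parameter in its merge rule — `min_size`
only filters the report, and `edge_order` provably does not affect the
partition (the merge condition selects a fixed edge subset whose
union-find closure is order-independent; the test suite verifies the
resulting partition equals the connected components of that subset on
hundreds of random graphs).

## Numerical and tie-break choices

- **Determinism.** Wherever the procedure is underdetermined, ties break
  towards the lexicographically smallest name: seed edges (smallest
  (u, v) pair among maximal-weight edges), core growth (smallest
  candidate among equal `hw_u`), the stored hw partner, and the partner
  used in admission tests (below). Identical inputs and parameters give
  byte-identical outputs.
- **hw ties in admission tests.** The tests "u's highest-weight edge
  leads into the core" are evaluated as *some* unmasked edge attaining
  `hw_u` ending in the core; among several, the smallest-named in-core
  partner supplies the closeness/attachment ratio. With unique maxima
  this is the same as using the single stored partner; under ties it is
  what lets a node sit at the junction of two modules in overlap mode.
- **Closeness denominator.** `cn_uv` is 0 when v has no neighbours inside
  the cluster (the candidate then simply fails the threshold); the
  candidate u is evaluated with u still outside the cluster.
- **Attachment boundary.** The attachment ratio is a strict inequality:
  exactly half of the common neighbours inside the core rejects.
  Candidates with an empty common neighbourhood reject too.
- **Degenerate GSM-FC merges.** Weight-0 edges whose endpoints have
  hw = 0 (isolated edges, trees) satisfy the merge rule literally and do
  merge by default; `min_merge_weight` exists for users who consider
  those spurious.
- **Hypergeometric tail.** `p = Σ_{i=m}^{min(n,M)} C(M,i)·C(N−M,n−i)/C(N,n)`,
  evaluated via the scipy survival function (log-space internally);
  `m = 0` returns exactly 1. The module size n counts only members inside
  the annotation background, the GO::TermFinder convention; modules with
  no annotated member are flagged and excluded from summary averages.
  −log averages use base 10, with p floored at 1e−300 before the log.
- **Multiple testing.** The 0.01 cutoff applies to raw p-values by
  default, matching how such per-module significance counts are usually
  reported; a Bonferroni flag (multiply by the number of terms, cap at 1)
  is available.

## Open design points, resolved

- The overlap extension admits candidates that already belong to other
  modules (that is what makes clusters overlap) and runs one sweep per
  module against the frozen member set, mirroring attachment selection;
  it does not iterate to a fixpoint. hw for the extension is recomputed
  on the original graph minus edges with both endpoints clustered, so an
  unclustered candidate keeps its pull towards every module it touches.
- Seeds are chosen globally (the maximal-weight unclustered edge) rather
  than per-node; the two readings coincide at the maximal-weight node.
- Size filtering happens at reporting time only; the run log counts the
  clusters formed below `min_size`.
- A documented extension of the weight to paths of length 3–4 in sparse
  graphs has no defined formula and is deliberately not implemented.

## Synthetic benchmarks

The generators produce the structure the detectors assume, nothing more:

- `planted_partition_graph` — Bernoulli blocks at density `p_in`,
  background at `p_out` (sampled through networkx's stochastic block
  model); truth catalog = the blocks.
- `core_attachment_graph` — per module, a core wired at `p_core`
  (default 1.0: small, dense, reliable cliques of 5) plus attachments
  each wired to `ceil(attach_frac·core_size)` random core nodes
  (default 0.7), attachments mutually unwired, inter-module noise at
  `p_out` (default 0.01); truth records the planted roles.
- `annotate_truth` — one term per planted module (optionally widened by
  `noise_rate` random outside proteins) plus random background terms of
  3–20 proteins, over a background equal to the node set.

All generators are pure functions of (parameters, seed), and node names
are zero-padded for stable lexicographic tie-breaking. What they do *not*
emulate: scale-free degree distributions, false-negative/false-positive
interaction noise within modules beyond the Bernoulli model, overlapping
ground-truth complexes, and annotation DAG structure. Passing the
recovery suites therefore shows the algorithms read dense-vs-sparse
structure correctly, not that they match any particular experimental
dataset's accuracy.

Test problem sizes are chosen at desk scale: recovery suites use 5
planted modules of 8 nodes (p_in = 0.9, p_out = 0.01) over 20 seeds and
5-clique cores with 3 attachments over 20 seeds; the order-independence
oracle uses 500 random graphs of ≤ 12 nodes; the hypergeometric
enumeration covers every population size up to 15; one I/O round-trip
runs at the 4930-node scale of a full yeast interaction network.

## Known limitations

- Weighted input networks (confidence-scored interactions) are not
  supported; the weight is purely topological.
- Matching counts follow the asymmetric TP/FN/FP/TB bookkeeping used in
  the comparative literature (sensitivity mixes predicted-side TP with
  benchmark-side FN); the s-measure simplifies to
  `2|TP| / ((|TP|+|FN|) + (|TP|+|FP|))`.
- GSM-CA's worst case is quadratic in practice on dense remnants; the
  single-pass GSM-FC is the scalable option.
- Enrichment treats terms as flat sets; no ontology propagation.
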