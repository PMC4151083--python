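# Methods

## Model and pipeline

`recolink` treats a collection of expression datasets over one shared gene
universe as a multi-layer graph: one unweighted coexpression layer per
dataset. The pipeline is

1. **Layer construction** (optional, when starting from expression
   matrices): an edge joins genes whose Pearson correlation is significant
   at `p_cutoff` (default 0.01, inclusive). The p-value comes from the
   exact t transform of r with `n − 2` degrees of freedom; at least three
   samples are required, and any pair involving a constant-expression gene
   is excluded because its correlation is undefined. Significance is
   two-sided by default — strongly negative correlation is coexpression
   evidence of the anticorrelated kind — with a `positive_only` switch for
   users who want the classical positive-coexpression convention. No
   multiple-testing correction is applied: the raw per-pair cutoff *is*
   the edge-calling rule, and its type-I behavior is verified directly
   (see calibration below).
2. **Summary graph**: the union of all layer edge sets, each link
   annotated with its binary occurrence vector across layers. Links
   occurring in fewer than `min_edge_freq` layers (default 10) are pruned;
   the threshold is inclusive (`frequency ≥ min_edge_freq`). Pruning both
   removes links with weak recurrence evidence and keeps the downstream
   link graph tractable, since the hybrid graph grows roughly with the
   square of per-gene degree.
3. **Hybrid link graph**: every pair of distinct links sharing exactly one
   gene endpoint is scored with `S = α·S_t + (1−α)·S_a` and kept when
   `S ≥ β`. Non-adjacent pairs are never scored: occurrence similarity
   alone would connect links that are far apart in the network. Pairs are
   enumerated through per-gene incident-link lists; in a simple graph two
   distinct links share at most one endpoint, so each pair is discovered
   exactly once and the enumeration never touches the quadratic all-pairs
   grid.
4. **Markov Clustering** of the hybrid graph (in-package, deterministic),
   inflation 2.0.
5. **Module statistics**: edge ratio RE, density ρ, and γ-approximate
   support over the γ grid {0.5, 0.75, 1.0}, with clusters of fewer than 4
   links dropped and a frequency call at `minsup = 5` layers; modules with
   ≥ 5 genes are exported as GMT gene sets.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `p_cutoff` | 0.01 | two-sided correlation p-value for an edge (inclusive) |
| `min_edge_freq` | 10 | minimum layers a summary link must occur in |
| `alpha` | 0.5 | weight of topological vs occurrence similarity |
| `beta` | 0.5 | minimum retained hybrid similarity (inclusive) |
| `inflation` | 2.0 | MCL granularity |
| `gammas` | 0.5, 0.75, 1.0 | approximate-support grid |
| `minsup` | 5 | layers needed for a cluster to be called frequent |
| `min_cluster_links` | 4 | smallest reported edge cluster (≥ 4 genes) |
| `min_module_genes` | 5 | smallest exported gene set |

α balances where a link sits in the summary graph against where it occurs
across layers; α = 0 clusters on co-occurrence alone, α = 1 on topology
alone. β controls hybrid-graph size directly: the retained edge set at a
larger β is always a subset of the set at a smaller β (tested). β
retention is inclusive (`S ≥ β`, with a 1e−12 absolute tolerance so pairs
landing exactly on β are not lost to rounding).

## Numerical and design choices

- **Canonical links.** Undirected links are stored as lexicographically
  ordered pairs; all file output is sorted by that canonical order, so
  reruns are byte-identical and artifacts diff cleanly.
- **Gene universe.** The universe defaults to the union of genes seen in
  any layer; edge-list inputs typically omit isolated genes, and an
  explicit universe can be supplied where they matter.
- **Zero-weight hybrid edges.** At α = 0 an adjacent pair with disjoint
  occurrence sets scores S = 0; with β = 0 such pairs are retained, since
  β = 0 means "keep every adjacent pair". For any β > 0 all retained
  weights are strictly positive.
- **MCL details.** Self-loops of weight 1.0 are added before column
  normalization (standard practice; prevents period-2 oscillation on
  bipartite-like graphs). After each inflation, entries below
  `prune_threshold` (default 1e−6) are zeroed and columns renormalized —
  an absolute-threshold realization of bounded column fill-in. Convergence
  is a maximum entrywise change below 1e−9, capped at 200 iterations
  (non-convergence returns the current matrix with a warning; clusters are
  still extracted). Dense arrays are used below 5 000 nodes and CSC sparse
  above; the two paths give identical clusterings (tested near the
  switchover by forcing both). Attractors (positive diagonal mass) are
  merged into systems when they carry mass in each other's columns; a node
  attracted to several systems is assigned to the system containing the
  smallest node index, a deterministic tie-break. Module *overlap* in this
  method comes from shared genes between edge clusters, never from MCL
  attractor overlap.
- **γ threshold.** `⌈γ·|EC|⌉` is computed as `ceil(round(γ·|EC|, 9))` so
  that binary floating point (e.g. 0.7 × 10 = 7.000000000000001) does not
  inflate the ceiling.
- **Summary percentages** in the run-level table are rounded to whole
  percent and are relative to the size-filtered cluster set (clusters with
  ≥ `min_cluster_links` links).
- **Missing expression values** drop the whole gene row at load time (with
  a logged count) rather than switching to pairwise-complete correlation,
  which would silently change n per pair.

## The synthetic benchmark

`synthetic.default_planted_spec` generates the stock benchmark: 60 genes,
10 layers, background edge probability 0.01 per pair per layer, and two
disjoint 6-gene modules whose within-module pairs appear with probability
0.9 in each of 8 active layers (chosen uniformly per module). These sizes
keep a full pipeline run under a tenth of a second while leaving the
signal genuinely stochastic: per-link frequencies are Binomial(8, 0.9), so
occasional module links fall below the pruning threshold, and background
links occasionally recur.

The generator emulates *recurrent link co-occurrence*, the signal the
method mines — not expression-level noise, probe effects, correlated
backgrounds, or the heavy-tailed degree structure of real coexpression
networks. Passing the recovery test therefore shows the pipeline finds
planted recurrent link structure under sparse independent noise; it does
not certify behavior on dense, correlated real data, where the pruning
threshold and β do the heavy lifting.

The matched random control resamples each layer as a uniform random edge
set with exactly the original node and edge counts (degree sequences are
deliberately *not* preserved). This destroys co-occurrence: planted-clique
γ = 1 support drops to zero, pruning at the same threshold empties the
summary graph, and no frequent cluster is ever reported — the expected
negative-control outcome.

All randomness derives from one user seed via
`numpy.random.SeedSequence.spawn`, with one child stream per layer and one
for module placement, so every artifact is reproducible and layers are
independent of each other's draw order.

## Problem sizes used in the checks

The oracle-equivalence suite cross-checks the full hybrid-graph
construction against a quadratic brute-force double loop on 50 random
multi-layer graphs of up to 30 genes, 100 links, and 6 layers at
α ∈ {0, 0.5, 1}, to 1e−12. MCL is cross-checked against an independent
dense reference on disconnected-clique and barbell fixtures and on random
weighted graphs. Planted-module recovery is run over 10 generator seeds;
the type-I calibration pools 200 replicates of 50-gene × 30-sample i.i.d.
normal noise (245 000 gene pairs) and checks the edge fraction against the
nominal 0.01 within five binomial standard errors.

## Known limitations

- Layers must be unweighted; weighted coexpression (and cosine/correlation
  attribute similarity over real-valued occurrence profiles) is out of
  scope.
- Enrichment analysis is delegated: the package exports GMT gene sets but
  computes no enrichment statistics.
- MCL inflation is exposed but only 2.0 is exercised by the shipped
  benchmarks; sensitivity to inflation is the user's to explore.
- The edge-ratio denominator uses the *pruned* summary graph's induced
  edge set — genes and links removed by frequency pruning do not count
  anywhere downstream.
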