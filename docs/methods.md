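# Methods

## Problem

Given two protein–protein interaction (PPI) networks `G1` and `G2`, a global
alignment is an injective mapping `g` from the nodes of the smaller network
into the nodes of the larger one. A good alignment maps as many nodes as
possible while pairing proteins that are functionally related. `salign`
scores candidate pairs by fusing three evidence channels — network topology,
sequence similarity and structure similarity — and extracts the mapping
greedily or by seeded Monte Carlo sampling.

## Scoring model

**Topological importance.** Each network is reduced by the minimum-degree
heuristic: node weights start at 0, edge weights at 1, and the
lowest-degree node is repeatedly removed (ties broken by lexicographic node
ID) until every survivor has degree greater than the threshold `d`
(default 10). Removing node `v` with current degree `k` transfers its mass:

* `k = 0` — nothing transfers;
* `k = 1`, neighbor `u` — `w(u) += w(v) + w(v,u)`;
* `k >= 2` — for every unordered neighbor pair `(u, z)`,
  `w(u,z) += [w(v) + w(v,u) + w(v,z)] / C(k,2)`, creating the skeleton edge
  `(u, z)` with weight 0 first when absent.

Skeleton edges participate in later degrees and in the final sums, so mass
keeps flowing toward hubs and bottlenecks. A node's importance is
`S(v) = w(v) + sum of surviving incident edge weights`; removed nodes freeze
`w(v)` at removal time. The cross-network topological score is the
scale-aware ratio `T(i,j) = min(S_i, S_j) / max(S_i, S_j)` (0 when the larger
importance is 0), which lands in `[0, 1]` without further normalization and
equals 1 exactly for equal positive importances.

**Biological score.** Raw sequence scores (BLAST bit scores) and structure
scores (TM-align TM-scores, normalized by the shorter chain; the larger of
the two printed scores) are each normalized by their global maximum —
a monotone, parameter-free rescaling to `[0, 1]` — and blended:

```
B(i,j) = (1 - beta) * SS(i,j) + beta * SQ(i,j)
```

`beta` (default 0.7) is the sequence weight; 0.9 is the recommended preset
when few proteins have solved structures. A pair with no structure
comparison scores `B = SQ`: absence of a solved structure is missing
knowledge, and zero-filling would systematically punish unresolved proteins.
Bit scores were chosen over e-values because they are positive,
database-size independent and additive-scale; multiple chains per protein
keep the maximum TM-score (best-evidence principle).

**Final score.**

```
A(i,j) = alpha * T(i,j) + (1 - alpha) * B(i,j)
```

`alpha` (default 0.1) trades topology against biology; at 0.1 the biological
channel carries 90% of the final score. Both defaults follow the grid-tuned
operating point for species pairs with good structural coverage; recovery
experiments on synthetic bundles reproduce the qualitative finding that
biology-heavy weighting beats topology-only alignment.

## Alignment extraction

**Greedy.** Seed with the globally best-scoring pair, then repeatedly take
the best pair from the frontier — pairs `(u, v)` where `u` is an unaligned
neighbor of an aligned node `u'` and `v` an unaligned neighbor of `g(u')` —
so neighbors of aligned nodes are prioritized and the alignment stays
topologically consistent. When the frontier empties, re-seed from the best
remaining pair; stop when the smaller network is exhausted or no scored
pairs remain. Ties break by larger score, then lexicographic IDs, making the
output fully deterministic. Re-seeding (rather than stopping at the first
exhausted frontier) is a deliberate choice: it is what lets the aligner
cover all of the smaller network whenever scores exist, at the cost of
starting fresh components.

**Monte Carlo (semi-greedy).** Identical loop and node-visit order, but the
partner of the visited node `u` is drawn from its top-`n_top` (default 10)
eligible candidates with Boltzmann probabilities over proportionally
normalized scores:

```
NS_i   = n_i / s,   s = sum of the top-n scores
Prob_i = exp(-(best - NS_i)/KT) / sum_j exp(-(best - NS_j)/KT)
```

with `K*T = 0.1` held constant (no annealing schedule). Candidate pools are
restricted to the frontier partners of `u` during extension (all unaligned
scored partners when seeding) and aligned partners are removed *before*
taking the top `n`; together these make `n_top = 1` reproduce the greedy
alignment bit for bit, which pins the MC aligner to the greedy baseline as
its zero-temperature/deterministic limit. An all-zero candidate pool falls
back to uniform sampling (the `s = 0` division has no other symmetric
completion). Each seed yields one reproducible alignment; sweeping seeds
yields alternative alignments of similar quality.

## Evaluation

Term-level similarity uses Wang's graph-based measure with the canonical
contribution factors 0.8 (`is_a`) and 0.6 (`part_of`): S-values propagate up
the ancestor DAG by max-product (implemented as a best-first traversal,
exact because every factor is below 1), and
`sim(a,b) = sum over common ancestors of (S_a + S_b) / (SV(a) + SV(b))`.
Protein pairs combine their term sets by Best-Match Average — the mean of
row-wise and column-wise best-match averages. The Average Functional
Similarity (AFS) of an alignment is the arithmetic mean of per-pair BMA
scores over pairs where *both* proteins carry at least one annotation in the
namespace (MF or BP). Unannotated pairs are excluded rather than scored 0 —
missing annotation is not evidence of dissimilarity — and the companion
metric `pct_aligned_nodes = 100 * scored pairs / annotated smaller-network
nodes` keeps that exclusion visible. With no scorable pair AFS is reported
as undefined (NA), never 0. All GAF evidence codes, including IEA, are
accepted.

## Synthetic studies

The generator plants a known answer behind every input format the pipeline
consumes:

* **Networks** — an Erdős–Rényi draw `G(n, p)` (default `n = 200`,
  `p = 0.05`, mean degree 10, comparable to the degree threshold `d`) and a
  relabeled copy with a `rewire_fraction` (default 0.1) of edges re-drawn
  uniformly. ER graphs were preferred as the default because the
  hub-dominance behavior of the reduction is easiest to falsify on them and
  on the star/path hand traces.
* **Similarity** — true pairs draw `Normal(0.5 + signal_mean, noise_sd)`,
  non-pairs `Normal(0.5, noise_sd)` (defaults `signal_mean = 1.0`,
  `noise_sd = 0.25`), clipped at 0. The 0.5 baseline puts the non-pair /
  true-pair score ratio near 1:3, echoing how unrelated-protein bit scores
  sit far below homolog scores while staying two standard deviations clear
  of the clip. A `missing_struct_fraction` (default 0.3, the order of
  structural coverage in curated interactomes) of proteins per side has no
  structure entries at all.
* **Ontology** — one rooted 3-ary `is_a` tree of 40 terms per namespace with
  sparse `part_of` cross-links, annotations of 3 terms per protein per
  namespace, true partners sharing `shared_fraction = 0.8` of them.

What the generator does *not* emulate: scale-free degree distributions,
correlated noise between sequence and structure channels, annotation-depth
bias, shallow vs. deep GO term placement, or interactome incompleteness
beyond uniform rewiring. Passing recovery tests therefore demonstrate the
machinery is correct under controlled signal/noise, not that real
interactomes will reach the same recovery.

## Numerical and design notes

* Problem sizes: pipeline experiments run at 200 nodes (or 60–80 nodes where
  20-seed sweeps are averaged), where every stage is exact and the full
  suite completes in seconds.
* Determinism: every tie-break is lexicographic; alignment files are written
  in sorted order, so equal alignments are byte-identical on disk.
* Degenerate inputs: empty candidate sets are skipped by the caller;
  all-zero similarity matrices normalize to themselves with a warning;
  isolated (degree-0) nodes are alignable and carry topological importance 0,
  though plain edge-list files cannot represent them; scored pairs naming
  proteins absent from either network are ignored with a log message.
* Duplicate similarity rows keep the maximum score; duplicate edges collapse
  to presence; self-loops are dropped (the heuristic and the alignment are
  defined on simple graphs).
* The `alpha = 1` configuration aligns on `T` alone and is the control used
  to show that topology by itself carries little functional signal.

## Known limitations

* The min/max importance ratio is one reasonable combination rule for
  cross-network topological similarity; alternatives (e.g. rank-based
  normalization) are not implemented.
* MC exact-recovery is intentionally lower than greedy at the default
  temperature: proportional normalization compresses score differences
  across ten candidates, so sampling explores aggressively. This is the
  designed alternate-alignment behavior, not an accuracy target.
* No identifier mapping between accession systems is attempted; node IDs
  must agree across all input files.
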