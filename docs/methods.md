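# Methods

## Model and assumptions

`pathcom` treats a pathway collection as a weighted undirected graph.
Nodes are pathways; the weight of edge *(i, j)* is the significance of
the gene overlap between the two sets under a hypergeometric null: the
one-sided Fisher's exact test p-value for drawing at least the observed
intersection when |A<sub>j</sub>| genes are sampled without replacement
from a universe of *N* genes of which |A<sub>i</sub>| are "marked".
The test is one-sided (enrichment only): depletion of shared genes is
not a meaningful similarity signal. Tail probabilities are computed in
log space (`hypergeom.logsf`), so the Bonferroni product and the
−log₁₀ transform remain accurate long after the p-value itself
underflows double precision; weights are capped (default 300, i.e.
p = 1e-300) as the final guard.

The null assumes gene sets are unstructured samples from the universe.
Real pathways violate this (genes co-annotate), which is exactly why
overlap significance is a useful redundancy signal rather than a
calibrated error rate.

### Background universe

The hypergeometric *N* defaults to the union of all genes in the loaded
collection — the only background computable from the inputs alone. An
explicit universe (e.g. all annotated human genes) can be supplied; it
must be a superset of the union. A larger universe makes every overlap
more surprising, so graphs built against different universes are not
comparable.

### Multiple-testing correction and the edge threshold

All *T = n(n−1)/2* pairs form the correction family; corrected
p-values are min(1, p·T). The default rule weights each surviving edge
by −log₁₀(p_corr) and removes edges with p_corr > α (α = 0.01).
`--threshold-on raw` instead thresholds the uncorrected p at α while
still weighting by the corrected value; edges whose corrected p rounds
to 1 carry weight 0 and are likewise dropped, so raw mode sits between
a purely-raw and a fully-corrected graph.

Bonferroni over all pairs grows quadratically with collection size. At
database scale (thousands of pathways, tens of thousands of background
genes, heavily nested gene sets) overlaps of interest reach p ≪ 1/T and
the correction is immaterial. At desk scale it dominates: for the
default synthetic collection (100 pathways, universe ≈ 1600, planted
mean intra-community overlap ≈ 5 of 40 genes) a pair must share ≥ 9
genes to survive, which only ~4% of planted intra-community pairs do.
The corrected-threshold graph of that collection therefore fragments
(~60 components), and planted-community recovery there is capped at
NMI ≈ 0.59 — a property of the edge rule at small *n*, not of the
detection stage. With fully separated pools (`within_fraction 1.0`)
enough pairs survive that recovery is exact (NMI = 1.0), and with
`--threshold-on raw` the default collection is recovered at NMI ≈ 0.99.
The corrected rule remains the default because it is the method's
definition; the raw flag is the documented escape hatch for small
collections.

## Community detection

Modularity at resolution γ:

    Q = Σ_c [ Σ_in(c)/(2m) − γ·(Σ_tot(c)/(2m))² ]

with Σ_in counted in both directions, Σ_tot the summed weighted member
degrees, and m the total edge weight. γ scales only the null-model
term; the default 0.4 favours larger communities than plain modularity.

Louvain is implemented natively — two phases (greedy single-node moves,
then aggregation into super-nodes with self-loops) repeated until no
move improves Q by more than 1e-12 (a float-noise guard) — so that the
query stage can reuse the identical ΔQ arithmetic:

    ΔQ(join C) = k_in/m − γ·Σ_tot(C)·k_i/(2m²)

Determinism: node visit order is a permutation drawn from a generator
seeded per run and reshuffled each pass; a node stays in its community
on ties, and among new communities with equal gain the lowest community
id wins. `restarts = r` runs seeds `s..s+r−1` and keeps the best-Q
partition (earliest seed on ties). Community ids are canonicalised:
0..C−1 by decreasing size, ties by smallest member id. Isolated nodes
become singleton communities.

Greedy modularity optimisation is a heuristic. On dense random weighted
8-node graphs a single run matches the exhaustive optimum (all 4140
partitions) about 87% of the time — igraph's independent
`community_multilevel` lands at 86% on identical instances — and ten
restarts raise this to ~95%, where it saturates: the residual instances
are local optima that this move set cannot escape. The verification
battery therefore runs Louvain with 10 restarts for that check.

Community-level aggregation reports, for each community pair, the
*average* pairwise weight over all member pairs (absent edges count as
0; within-community values use unordered pairs), making edge values
comparable across community sizes. "Hubness" is the node's weighted
degree within its own community's induced subgraph — the simplest
centrality consistent with hub terminology; HITS-style scores are a
possible alternative and deliberately out of scope.

## Labelling

Names are split on underscores/whitespace, lower-cased; a leading
database identifier (kegg, reactome, gobp, gomf, go, hallmark) is
dropped; stop words are removed. The shipped stop-word list (a short
standard English function-word list, configurable via a one-per-line
file) deliberately keeps domain words like "pathway", "process" and
"regulation": in GO/REACTOME names they distinguish otherwise identical
concepts. Candidate labels are contiguous token 3-mers counted across
members (each member supports an n-gram at most once); candidates need
≥ 3 supporting members, rank by (support, mean hubness of supporters,
lexicographic), and fall back to 2-mers, then 1-mers, then 1-mers with
no support floor — the last two rungs are an extension so that small
communities (the method allows them down to a handful of members)
always receive a label.

## Querying

The query replicates the enrichment test a user would run: one-sided
hypergeometric p per pathway against the graph's stored universe size,
Bonferroni over the number of *pathways* (not pairs — the family of the
user's test). Temporary edges for the query node follow the graph's own
weighting rule (same α, cap and threshold mode, correction family = the
pathway count). ΔQ for adopting the query into community C is evaluated
on the augmented graph: m grows by the query's total edge weight, and
Σ_tot(C) additionally grows by the query weight into C because the
query's edges raise its endpoints' degrees. The stored graph and
partition are never modified; query genes outside the universe are
dropped with a logged count rather than expanding the universe, which
would silently change every stored edge's null. If no ΔQ is positive
the query is reported as best left a singleton.

## Evaluation

NMI uses natural-log entropies over the joint contingency table,
normalized by the arithmetic mean of the marginal entropies (the common
default; min/geometric/max variants would change absolute values but
rarely rankings). Conventions: two single-cluster labellings score 1,
exactly one zero-entropy labelling scores 0. Category evaluation
restricts to pathways present in both the partition and the map and
logs the exclusion count.

Redundancy profiling reports, per pathway, the maximum |A∩B|/|A| over
eligible partners (same- or different-source scope); the focal
pathway's own size is the denominator, so containment scores 1.0.
Gene over-representation tests each (gene, community) pair with the
hypergeometric upper tail (x of the community's n pathways contain the
gene, of K containing it anywhere among N pathways), adjusted by
Benjamini–Hochberg across all pairs (Bonferroni via flag). Founder
agreement compares query-based group assignments with the community
holding the most of each group's founder pathways; ties count as
agreement when the assignment is among the maxima.

## Synthetic data

The generator plants K disjoint community gene pools plus a shared
background; each pathway draws round(within_fraction·size) genes from
its own pool and the rest uniformly from the background. Defaults —
K = 5, 20 pathways per community, 200-gene pools, 2000-gene background,
40-gene sets, within_fraction 0.8, four source tags assigned
round-robin, seed 7 — give clearly separated communities whose members
overlap by ~5 genes on average while unrelated pathways share almost
nothing. Names embed a community-specific 3-token core drawn from a
biology-flavoured vocabulary, plus a recognised database tag and a
unique suffix, so label recovery has an exact ground truth. Generation
is fully determined by the seed (byte-identical outputs).

What the generator does not emulate: the heavy-tailed size distribution
of real databases, nested sub-pathways (subset relations), hierarchical
category structure, and genes shared systematically between processes.
Passing recovery tests therefore demonstrates the pipeline's arithmetic
and its behaviour under clean planted structure, not performance on
real MSigDB-scale redundancy.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` use: the full hypergeometric
oracle sweep (every N ≤ 30, set sizes ≤ 10, all feasible overlaps);
50 random graphs for the closed-form modularity check; 100 random
8-node graphs against exhaustive search; 100 (graph, query) instances
for the ΔQ oracle (12-pathway collections); the default 100-pathway
synthetic collection for recovery, labelling, query and determinism
checks; 100 random labellings for the NMI oracle. The battery completes
in seconds on one CPU.

## Known limitations

- Bonferroni-over-pairs makes small-collection graphs very sparse (see
  above); use `--threshold-on raw` or an explicit α for desk-scale
  collections.
- Louvain offers no optimality guarantee; use restarts and compare
  partitions across seeds (NMI between runs) to gauge stability.
- Multi-label category maps are flattened to a single label per
  pathway before NMI.
- The query's correction family (pathway count) intentionally differs
  from the graph's (pair count); query edge weights are therefore not
  directly comparable to stored edge weights between pathways.
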