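# Methods

## Scope and model

The package implements a target-nomination workflow for case/control
transcriptomics plus curated disease-gene knowledge: genes implicated
either by differential expression or by disease databases are projected
onto a high-confidence protein–protein interaction (PPI) network, and a
gene is nominated as a candidate target when it simultaneously (i) belongs
to the top-scoring dense module of that network, (ii) ranks among the
top-k nodes by the Nim node-importance score, and (iii) belongs to a
chosen, biologically focal pathway. The intersection — not any single
criterion — is the result; an empty intersection is a valid outcome and is
reported as such.

## Differential-expression screen

Input is assumed to be on the log2 scale already; the only optional
within-package normalization is quantile normalization (off by default,
since upstream preprocessing conventions vary and silently re-normalizing
calibrated data is worse than not normalizing). Duplicate gene symbols are
collapsed to the row with the highest mean expression — a deterministic,
widely used convention.

Two statistics are provided.

* `welch`: the unequal-variance two-sample t test. A gene constant in both
  groups yields t = 0, p = 1 with a logged warning (the test is undefined
  there; treating it as a non-discovery is the only downstream-safe
  choice).
* `moderated` (default): pooled per-gene variances s²_g with
  d = n₁+n₂−2 degrees of freedom are shrunk toward a scaled
  inverse-chi-square prior (d₀, s₀²) estimated by the method of moments on
  z_g = log s²_g, using the analytic mean/variance of z under the
  hierarchical model (digamma/trigamma terms; the trigamma inverse is
  solved by bracketed root finding). Posterior variances
  s̃²_g = (d₀s₀² + d s²_g)/(d₀+d) feed a t statistic on d+d₀ degrees of
  freedom. When the observed spread of z is no larger than its sampling
  noise, d₀ = ∞ and all genes share s₀². The test suite cross-checks this
  implementation against the reference empirical-Bayes implementation in
  R (limma) on a heteroscedastic fixture; they agree to ~1e-14 in p.

Screening uses strict inequalities — |log2FC| > 1.0 and p < 0.05 — so
boundary genes are excluded, matching the usual reading of ">".

## Disease-gene assembly

Each source snapshot is filtered by the rule native to that database
(CTD Direct-Evidence tag in {marker/mechanism, marker/mechanism|therapeutic,
therapeutic}, whitespace-insensitive; DisGeNET gene–disease score > 0.1;
GeneCards relevance > 5; OMIM non-empty Entrez id; PharmGKB/TTD/custom
keep all). All score comparisons are strict. Records that should carry a
score but do not are dropped with a warning rather than silently kept.
Symbols are canonicalized case-insensitively through an offline
alias→canonical table (idempotent by construction); symbols outside the
table pass through upper-cased with a logged count, because discarding
them would silently shrink the analysis universe.

## Network construction

Edges survive when their confidence score strictly exceeds the threshold
(default 0.9 on the 0–1 scale). Files using the 0–1000 integer dialect are
detected by the presence of any score above 1 and rescaled. The graph is
simple and undirected; duplicate/reversed rows collapse to the maximum
score; isolated nodes are dropped. Shortest paths are unweighted hop
counts: the score gates which edges exist but does not weight them, so the
centrality below is the classic path-count kind. The analysis runs on the
full (possibly disconnected) graph, with unreachable pairs contributing
zero to both centrality factors — the only limit-consistent convention.

## Nim centrality

Nim(s) = sqrt(B(s) · C(s)) with B(s) the unnormalized betweenness over
unordered pairs (endpoints excluded, each pair counted once) and
C(s) = Σ_{x≠s} exp(−d(s,x)). B is accumulated with Brandes' dependency
recursion — one BFS per source, O(nm) total — and the same BFS distances
supply C. No normalization is applied to either factor (the definition has
none; normalizing would rescale but not re-rank). Counting ordered instead
of unordered pairs would multiply every Nim by √2 and change nothing
downstream. Hub selection: `top_k` (default k = 30; ties broken by higher
betweenness, then lexicographic symbol) or `above_mean` (strict >, mean
over all nodes including zeros). Both rules are exposed because both are
legitimate hub conventions; the pipeline default is top-30. The test suite
checks B against exhaustive shortest-path enumeration and against an
independent library implementation, and the closed forms on a 3-path
(√(2e⁻¹) ≈ 0.857764) and a 4-leaf star (√(24e⁻¹) ≈ 2.971381).

## Dense-module detection

A reconstruction of the MCODE algorithm with its documented defaults
(degree cutoff 2, node-score cutoff 0.2, k-core floor 2, depth limit 100,
haircut on, fluff off). Vertex weight = k_max × density of the highest
k-core of the closed neighborhood, zero when the degree is below the
cutoff or no k-core at the floor exists (a star neighborhood, say, is
cycle-free). Growth starts from the highest-weight unvisited seed and
admits neighbors whose weight ≥ seed weight × (1 − cutoff); zero-weight
seeds are skipped (a zero threshold would otherwise admit arbitrary
sprawl). Haircut removes members with fewer than two intra-module links;
fluff, when enabled, pads the boundary with unvisited neighbors whose
closed-neighborhood density exceeds 0.1 (kept vertex-disjoint, unlike the
original plugin, so modules remain non-overlapping — documented
deviation). Members grown but removed by the haircut stay visited.
Modules with fewer than three members are discarded; the module score is
density × size. All tie-breaks (weight, then degree, then symbol) are
deterministic. Byte-level equivalence with the Cytoscape plugin on
arbitrary graphs is not claimed; the planted-structure fixtures (6-clique
plus path, two disjoint 5-cliques, planted cliques in random graphs) are
the contract.

## Over-representation analysis

One-sided hypergeometric tail P[X ≥ k] via the survival function
(log-space stable; validated against exact rational arithmetic over the
entire N ≤ 25 grid). The universe is the union of annotated symbols — not
the genome — and query genes outside it are dropped with a logged count,
matching the behaviour of the standard enrichment tools. Only sets with
overlap k ≥ 1 are tested, and the Benjamini–Hochberg adjustment runs over
exactly those tests. The reported q-value *is* the BH-adjusted p: the
dual screen "p < 0.05 and q < 0.05" therefore reduces to adjusted
p < 0.05. This is deterministic and conservative relative to a Storey-type
q-value, and is stated here so results are interpretable.

## Synthetic studies and what they show

The generators produce every pipeline input with planted truth:

* expression — two groups of n (default 32) samples over 400 genes,
  gene-wise baselines uniform on log2 ∈ [4, 12], i.i.d. Gaussian noise
  (σ = 0.5), 80 planted effects of ±3 log2 units split half up/half down
  (odd remainder up);
* disease-gene sources — six snapshot tables whose records straddle each
  database's filter boundary, including exact boundary scores;
* PPI — an Erdős–Rényi background (150 nodes, p = 0.05) with a planted
  12-clique whose edges carry confidence scores in (0.9, 1], background
  edges uniform in (0, 1], so the 0.9 filter preserves the module while
  thinning the background tenfold;
* gene sets — 20 random sets of 10–25 genes with one planted set.

The composite study generator wires these together: the clique is drawn
from the planted DE genes (so it survives restriction to the disease
set); the planted pathway holds the targets plus DE fill drawn away from
the rest of the clique; and each of the 5 target genes receives 4
exclusive high-confidence edges to disease genes outside the module.
That last step plants the targets as *bridging hubs* — the structural role
hub genes play in real disease networks — and is what makes the module,
centrality and pathway criteria simultaneously and non-vacuously
satisfiable: a clique-interior node mediates no shortest paths, so without
bridges its betweenness term (and hence Nim) would be near zero and the
"planted target" would not actually satisfy the hub criterion. Under
these defaults the pipeline recovers the planted targets exactly, seed
after seed.

What the generators deliberately do not emulate: probe-level microarray
artifacts, batch effects, correlated expression noise, scale-free PPI
topology, and annotation redundancy (GO term ancestry). Passing tests
therefore demonstrate the algorithms' correctness and the workflow's
internal consistency, not robustness to those real-data complications.

## Numerical and degenerate-input choices

* Strict thresholds throughout; boundary values excluded.
* exp(−∞) = 0 for unreachable pairs; BFS distances are exact integers.
* Constant genes: p = 1 under Welch; excluded from the variance-prior
  moment fit, shrunk fully to the prior under the moderated t.
* Empty disease set, empty network, or a query disjoint from the
  annotation universe abort with explicit stage-named errors; an empty
  *intersection* does not.
* All randomness flows from one integer seed through
  `numpy.random.default_rng`; reports are byte-identical across runs.

## Problem sizes

Default study sizes (400 genes × 64 samples, 150-node network, 20 gene
sets) were chosen so that a full end-to-end run takes tens of
milliseconds and the entire validation battery — including ten end-to-end
recovery runs, a 10,000-gene null calibration, 200 null enrichment
queries, 50 brute-force betweenness comparisons and the exhaustive
N ≤ 25 hypergeometric grid — completes in seconds. These sizes are an
analysis design choice: large enough for every criterion to bind (the
top-30 hub rule actually filters; the clique is not the whole network),
small enough to iterate on.

## Known limitations

* The moderated t assumes a common variance prior across genes; intensity-
  dependent variance trends (limma-trend style) are not modelled.
* The GeneCards relevance filter silently depends on the export carrying a
  score column; records without one are dropped with a warning, which may
  under-count that source.
* MCODE here is a faithful-but-independent reconstruction; ordering of
  equal-score modules and boundary behaviour of fluff may differ from the
  original plugin.
* Real accession-based expression data can be loaded via the
  series-matrix reader, but upstream probe preprocessing (RMA etc.) is out
  of scope, so DEG counts on public datasets will depend on how the
  matrix was prepared.
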