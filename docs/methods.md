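# Methods

This note documents the statistical models, algorithms and design choices
behind `coexnet`, in the order the pipeline runs them.

## Input model and differential-expression screen

The input is a genes × samples matrix of continuous expression values (the
intended scale is log-intensity; the pipeline itself is scale-agnostic
because Pearson correlation is invariant to per-gene affine rescaling, and
the t-test operates on whatever scale is supplied) together with a
two-group sample assignment. Non-numeric cells are treated as missing;
genes with no finite values are dropped; missing values are removed
pairwise per gene before testing.

The DE screen is an unpaired two-sample t-test per gene, two-sided, with
the pooled-variance (Student) form by default and Welch's form by option.
Significance is unadjusted *P* < α (default α = 0.05); an optional
Benjamini–Hochberg column can be added downstream but is off by default,
matching the classical microarray screen this pipeline models. Genes with
zero variance in both groups and equal means are defined as null (t = 0,
*p* = 1); zero variance with unequal means is treated as maximally
significant. Genes with fewer than two finite values in a group are
excluded from testing and logged, not fatal. "Up" means the first
configured group's mean exceeds the second's; the group order is explicit
to avoid sign ambiguity.

## Correlation networks and threshold selection

Per group, pairwise-complete Pearson correlations are computed over that
group's samples only (at least 3 required). Genes constant within the group
are excluded; pairs with fewer than 3 jointly finite samples get an
undefined correlation that no threshold can turn into an edge. Edges use
the **absolute** correlation — planted and biological covariation can be
positive or negative — with the signed r kept as an edge attribute. After
thresholding, the network is restricted to its largest connected component
(ties broken toward the component containing the lexicographically smallest
node), which is what makes reported node counts smaller than the input gene
sets.

The threshold τ is selected from an ascending grid as the **largest** value
satisfying:

1. *Major-component dominance* — the largest component holds at least
   `min_component_frac` (default 0.8) of the nodes that have any edge at
   that τ.
2. *Partition stability* — the ARI between the network's community
   partition at τ and at the neighbouring grid values (or τ ± δ if a
   stability step δ is given) is at least `stability_min` (default 0.8),
   computed on the shared nodes.

The stability criterion is a quantitative proxy for the qualitative
requirement that small threshold changes should not reorganise the
network's topology. During the scan, community detection runs with fewer
restarts (default 2) than the final partition (default 10); the scan is a
feasibility screen, not the reported result. If no grid value passes, the
error carries the full per-τ report (N, L, giant-component fraction,
neighbour ARIs) so the caller can judge whether the grid, the data or the
criteria are at fault. Default grids mirror a high-threshold microarray
setting (0.930–0.980 step 0.005 for DE universes, 0.990–0.998 step 0.001
for CO); for small synthetic designs the appropriate scan range is much
lower (see below) and is always configurable.

## Scale-free diagnostics

Degrees are positive integers, so the tail model is the discrete power law
P(X = x) = x^(−α)/ζ(α, x_min). For every candidate x_min among the attained
degree values (by default requiring ≥ 10 distinct tail values, relaxed
automatically for coarse samples), α is fitted by numerically maximising
the exact zeta-likelihood, and x_min is chosen to minimise the KS distance
between the empirical and fitted tail CDFs. The goodness-of-fit *p*-value
is a semi-parametric bootstrap: synthetic datasets draw the body from the
observed sub-x_min values and the tail from the fitted law, are refitted
from scratch, and *p* is the fraction of synthetic KS distances at least
the observed one. Bootstrap tail draws use the standard continuous-
approximation inverse transform; an exact truncated inverse-CDF sampler is
also provided and is used for calibration. Calibration behaviour: the
exponent of 5000 exact draws at α = 2.5 is recovered to ±0.1;
preferential-attachment graphs are accepted (*p* > 0.1) and Erdős–Rényi
graphs rejected (*p* < 0.05) in ≥ 90% of seeds at 100 bootstrap replicates.
All degrees equal is a fit-undefined error.

## Concentric node hierarchy

For node u with neighbourhood ring1 and second ring ring2 (nodes at
shortest-path distance 2), k₀ = |ring1| and k₁ = the number of edges with
one endpoint in ring1 and the other in ring2. Edges inside ring1 and edges
back to u are *not* counted: k₁ measures connectivity leaving the immediate
neighbourhood. On trees k₁ = Σ_{v∈N(u)} (deg v − 1) exactly.

Categories are assigned from quantile cut-offs: with Tk₀, Tk₁ the
`hub_quantile` (default 0.9) quantiles of k₀ and k₁ and Lk₀ the
`vip_k0_quantile` (default 0.5) quantile of k₀ —

* high-hub: k₀ ≥ Tk₀ and k₁ ≥ Tk₁;
* hub: k₀ ≥ Tk₀ and k₁ < Tk₁;
* VIP: k₀ ≤ Lk₀ and k₁ ≥ Tk₁;
* other: the rest.

Quantiles are nearest-rank (inclusive) over the **distinct attained
values** of each measure, so cut-offs are always values that occur in the
network. Distinct-value ranks (rather than multiset ranks) are what make
the intended semantics work on skewed degree distributions: in a star
graph, the single centre is the hub and the leaves (whose entire k₁ comes
through the centre) are VIPs; a low-degree node bridging two large hubs is
a VIP rather than being absorbed into the bulk. If a network attains only
one distinct k₀ or k₁ value the rule degenerates and every node is "other"
(logged). Exact cut-offs are a per-study choice; both quantiles are
config-exposed and echoed in the report.

## Communities and coarse-graining

Modularity is the Newman–Girvan quality at resolution 1 on the unweighted
graph (edges are already the result of thresholding; a correlation-weighted
variant would conflate edge strength with edge existence). Community
detection is multilevel greedy modularity optimisation (Blondel-style, via
igraph's implementation) with seeded restarts; the best-Q partition of
`n_restarts` (default 10) runs is returned, with communities relabelled
0, 1, 2, … by descending size (letters A, B, C, … in reports). The reported
Q is always recomputed from the returned assignment by the package's own
modularity function. On graphs small enough for exhaustive partition
enumeration the restart scheme reaches the global optimum in ≥ 95% of
seeded runs, and on strong planted partitions (200 nodes, 4 blocks,
p_in = 0.5, p_out = 0.01) it recovers the planted blocks at NMI ≥ 0.9.

The coarse-grained community structure contracts each community to one
node. Intra-community edge counts sit on the diagonal of the mixing matrix,
inter-community counts off the diagonal, and every inter-community weight
is also expressed as a fraction of the total edge count L; edge
conservation (Σ intra + Σ inter = L) holds exactly by construction. Reports
keep the top-k communities by size (default 9) plus an optional keep-list
for smaller communities that carry nodes of interest.

## Synthetic data generator

The expression generator emulates a small two-group microarray design:
log-scale baseline 8.0, default 7 samples per group, genes assigned to
contiguous equal-sized modules. Gene g in module m on sample s is

x[g,s] = baseline + noise_sd·(sign_g·√c·f[m,s] + √(1−c)·ε[g,s]) (+ shift),

so the expected within-module correlation is exactly c = `module_corr`, the
marginal variance is noise_sd², and half of each module's loadings are
negative. DE genes (a seeded uniform draw of `de_fraction`·n_genes genes,
half up / half down) receive a mean shift of ±`effect_size`·noise_sd in the
first group only. Per-gene noise streams are spawned hierarchically from
the single seed, so enlarging the gene set never perturbs earlier genes'
draws, and identical specs give bit-identical output.

**Minimum-coherence factors.** Module factors are not drawn independently.
With only S samples, independent factor vectors collide by chance — for 8
standard-normal factors on 7 samples, pairwise sample correlations above
0.7 are routine and above 0.9 occur regularly — and a collision merges two
planted modules in correlation space, making the ground truth unrecoverable
by *any* method. A benchmark with unrecoverable truth is not a benchmark
(the same reason the planted-partition generator rejects p_in ≤ p_out), so
the factor matrix is initialised from seeded Gaussians, centred and
standardised, and its pairwise correlations are minimised by projected
gradient descent on the Gram matrix. This brings the maximum pairwise
factor |r| down to the packing limit the sample size allows (≈ 0.2–0.33 for
8 factors on 7 samples, versus a Welch lower bound of 0.22 in the 6-dim
centred space). The procedure is deterministic given the seed.

What the generator does *not* emulate: array-specific artifacts (dye bias,
spot flags), batch effects, heavy-tailed intensity distributions,
gene-length or GC effects, overlapping pathway membership, or
between-module correlation beyond the residual coherence floor. Passing
tests on this generator therefore demonstrate correctness of the pipeline's
computations and recoverability under the planted model — not performance
on real microarray data, where module structure is weaker and confounded.

Benchmark graphs: planted-partition graphs via the stochastic block model
(near-equal blocks, p_in > p_out enforced), preferential-attachment graphs
(positive control for the power-law test) and Erdős–Rényi graphs (negative
control), all seed-deterministic.

## Study conditions used by the acceptance script and end-to-end tests

The synthetic study runs at 2000 genes, 8 modules, module_corr = 0.8,
de_fraction = 0.05, effect_size = 3, noise_sd = 1, 7 samples per group —
the DE screen's power at these settings exceeds 0.99 per the noncentral-t
closed form, and the planted modules are recoverable as communities. The
τ grid for this design is 0.30–0.95 in steps of 0.05: with near-orthogonal
modules, the cross-module edges that connect the giant component only
appear at moderate τ (the sampling spread of Pearson r at n = 7 is wide),
and the selection rule then picks the largest feasible τ on its own
(0.70–0.90 across the four networks at seed 1). Community detection uses
10 restarts; the threshold scan 2. The four published (N, L) pairs used by
the connectivity worked examples are inputs taken from the literature this
pipeline's report format mirrors.

## Numerical conventions and degenerate inputs

* Correlations are clipped to [−1, 1]; diagonals set to exactly 1.
* A threshold that yields zero edges raises an error reporting the maximum
  off-diagonal |r|.
* Modularity of an edgeless graph is defined as 0 (with a warning); a
  single-node graph has one community and Q = 0.
* ARI/NMI between partitions require identical node sets; comparisons
  across different networks are made on the node intersection (threshold-
  stability scans), with fewer than 2 shared nodes scored as unstable.
* Community tie-breaks: seeded restart streams are spawned from a
  SeedSequence; equal-Q restarts keep the first.
* All file artifacts are TSV/JSON/GraphML; reports are JSON with sorted
  keys so reruns are byte-comparable.

## Known limitations

* The stability criterion (ARI ≥ 0.8 at neighbouring thresholds) is a
  stated proxy for a qualitative robustness requirement; other choices
  (variation of information, edge-set Jaccard) are defensible.
* Hierarchy categories depend on the two quantile cut-offs; exact category
  membership on real data is sensitive to them.
* The power-law bootstrap refits x_min per replicate but, like all
  semi-parametric bootstraps, inherits the empirical body distribution.
* Louvain restarts mitigate but do not eliminate local optima on large
  graphs; Q values on different machines may differ in the last restart
  tie-break only if igraph's RNG behaviour changes.
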