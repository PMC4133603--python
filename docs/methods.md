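# Methods

This note documents the models, statistics, numerical choices and known
limitations of the package, in the order the pipeline runs them.

## Expression clustering

**Z-score transform.** Clustering operates on per-gene standardized log2
expression: z = (log2 x − mean)/sd across conditions, with the sample
(n−1) standard deviation. The divisor is not dictated by the transform
itself; (n−1) was chosen for consistency with the ANOVA variance
estimator used in filtering. Rows that are constant after the log
transform have sd = 0 and carry no pattern information; they are flagged
and excluded rather than imputed. Zero expression values require an
explicit pseudocount — the reader refuses to log-transform zeros silently.
Replicate columns, when present, are averaged on the log2 scale (geometric
mean on the linear scale) before Z-scoring, because clustering operates on
one value per condition.

**ANOVA filter.** A one-way fixed-effects ANOVA across condition groups on
log2 values, retaining genes with p ≤ α. The factorial structure of the
four-condition design (vehicle/hormone/LPS/both) could support a two-way
ANOVA with interaction; the one-way four-level design was chosen because
it is the weakest assumption that captures "differential across any
condition", and is noted here as an assumption.

**k-means and the elbow.** Lloyd's algorithm with Euclidean distance, best
of `n_init` random initializations, deterministic under the seed
(delegated to scikit-learn's KMeans). The number of clusters is chosen by
the elbow of the within-cluster sum-of-squares (wss) curve,
operationalized as the k maximizing the discrete second difference
wss(k−1) − 2·wss(k) + wss(k+1) over the interior of the scanned range —
"elbow" alone is not a reproducible rule; the second difference makes it
one. Each k in the scan is additionally warm-started from the previous
solution's centroids plus the point farthest from them, which guarantees
the reported wss curve is non-increasing in k. When the largest second
difference is below 5% of the wss at the smallest scanned k the curve is
flagged as having no distinct elbow (structureless data).

**Condition tests.** Within-cluster condition contrasts use the two-sided
Mann-Whitney U test with midrank ties: exact enumeration when the pooled
sample has ≤ 20 observations and no ties, otherwise the normal
approximation with tie and continuity corrections. Contrasts of a
condition with itself (or identical value vectors) short-circuit to p = 1.
Clusters below 3 genes are reported but flagged underpowered, never
silently dropped.

## Network modules

**Girvan-Newman.** Divisive community detection: repeatedly remove the
edge with the largest betweenness (summed fraction of all-pairs shortest
paths through the edge, unweighted BFS), recomputing betweenness after
every removal. Ties are broken lexicographically by edge id so the removal
history is exactly reproducible. Two stop rules are exposed: a fixed
component-count target, and the default `"auto"`, which runs the full
removal sequence and returns the partition of maximal Newman modularity
(evaluated on the original graph). The auto rule is the default because a
fixed component count is fragile when the input graph is not connected —
a single isolated node consumes one component slot and forces two true
communities to stay merged — whereas the modularity criterion places
singletons in their own module without disturbing the rest. Edge weights,
when present in input files, are kept as annotations only; partitioning
and all metrics use connectivity alone.

**Topology metrics** follow the Cytoscape NetworkAnalyzer conventions:
density 2E/(N(N−1)); per-node clustering coefficient
2·triangles/(deg·(deg−1)) with 0 for degree < 2; heterogeneity defined as
the coefficient of variation of the degree distribution (population
standard deviation) — the common convention when a numeric heterogeneity
is reported without a formula; neighborhood connectivity of a node is the
mean degree of its neighbors; and the shared-neighbor histogram counts all
node pairs by common-neighbor count. Every metric is verified against an
independent naive implementation on random graphs of up to 8 nodes.

**Hub edge fraction.** The fraction of edges incident to the top-n nodes
by degree (ties broken by node id). Counting incident edges avoids double
counting hub-hub edges; the summed-degree alternative (which counts them
twice) is exposed as `mode="degree"` since the convention behind reported
percentages is often ambiguous.

**Module composition.** Per module, a 2×2 Yates-corrected χ² of
(in module / out) × (in class / out), χ² = n(|ad−bc| − n/2)²/∏marginals
with the correction floored at zero, df = 1. Zero marginals make the
statistic undefined and raise; modules smaller than 2 nodes are flagged
and skipped.

## I1-FFL dynamics

**Model.** The raw two-gene system (repressor R driven by the master
input, target Z produced proportionally to input/repressor in the
strong-repression limit) is nondimensionalized by its basal steady state,
leaving three parameters: the input fold change F ≥ 1 and the two mRNA
relaxation rates α_R, α_Z (1/h). This matches how RT-qPCR data are
reported — fold changes with basal ≡ 1 — and makes the basal state an
exact fixed point (F = 1 ⇒ r = z = 1 for all t). The basal input is
treated as small but nonzero (the receptor is largely inactive without
ligand), so F is a ratio and no divide-by-zero arises. A Hill-repression
variant (production F/(1+(r/K)^h), normalized so z = 1 is stationary
pre-stimulus) is provided for when repression is not effectively complete;
strong repression is the default and is what the closed form solves.

**Closed form and integrator.** With equal rates the solution is
r(t) = F + (1−F)e^{−αt}, z(t) = 1 + ((F−1)/F)e^{−αt}·ln(1−F+Fe^{αt}); it
was verified by symbolic substitution into the ODE before use, and the
log term is evaluated as αt + ln(F + (1−F)e^{−αt}) to avoid overflow at
large αt. The free-rates model integrates only z (r has a closed form)
with LSODA at rtol 1e-10 / atol 1e-12; numeric and analytic solutions
agree to better than 1e-8 across the tested F/α grid.

**Fitting.** Two stages, mirroring how such time courses are analysed:
stage 1 is a global least-squares fit of the equal-rates closed form over
(F, α); stage 2 fits the numeric free-rates model over (F, α_R, α_Z),
initialized at the stage-1 estimate. Optimization is multi-start
(≥ 5 seeded starts) Nelder-Mead in log10-parameter space with box bounds
F ∈ [1, 10³], rates ∈ [10⁻², 10²]/h, followed by a tighter polish pass
from the best start. On noiseless simulated trajectories over the 0–9 h
grid the stage-2 fit recovers all three parameters to ~1e-11 % and
R² = 1 to machine precision.

**Identifiability.** With realistic noise (5% CV, 3 replicates, 8 time
points) the three-parameter fit is sloppy: solutions drift along an
F/α_R ridge that preserves the curve shape, so the stage-2 F estimate is
not trustworthy even when its R² is excellent. The stage-1 equal-rates F
is well identified (median error ~6% under those conditions) and is the
estimate to report; stage 2 is the better *curve* model. This is why both
stages are always returned.

**Knockout uncoupling.** Clamping r ≡ 1 gives
z(t) = F + (1−F)e^{−α_Z t}: monotone, no interior maximum, within 5% of
the plateau F by t = 3/α_Z. Fitting the full model to such a saturating
course drives it into a pulseless regime whose maximum sits at the
observed plateau level (within 2% under the default bounds) — the
model-level mirror of the experimental loss of peak-like kinetics when
the intermediate repressor is removed. Note the fitted I1-FFL always
adapts eventually, so its curve sags slightly (~4%) below its peak by 9 h;
the pulse, not the sag, is the diagnostic.

**Repressor prediction.** The fitted parameters imply a repressor
trajectory r(t) rising monotonically from 1 to F; a candidate
intermediate repressor's measured time course is scored against this
prediction by R².

**C-FFL variant.** For delayed-activation genes, a coherent FFL with an
AND gate: the intermediate activator rises as y(t) = F − (F−y₀)e^{−α_Y t}
and target production switches on only while y ≥ K, giving an onset delay
T = (1/α_Y)·ln((F−y₀)/(F−K)). Both y₀ = 1 (fold-change basal) and y₀ = 0
(absolute-zero basal) conventions are supported.

## Binding-site association and enrichment

**Association rule.** Coordinates are 1-based closed internally (mm9
annotation style); BED I/O converts at the boundary (0-based half-open →
+1 on start). A gene is associated with a TF when any peak overlaps the
gene body extended by a symmetric window (default 15 kb per side) by at
least one nucleotide: peak.start ≤ gene.end + W and
peak.end ≥ max(1, gene.start − W). Strand is stored but ignored for
flanking — the window is symmetric. The implementation is a
per-chromosome sweep over peaks sorted by start with a running prefix
maximum of peak ends (O((n+m) log n)) and is verified to equal the
all-pairs brute force exactly. A gene counts once per TF regardless of
peak multiplicity.

**Frequency comparisons.** Gene groups are compared against
expression-tier backgrounds (non-expressors RPKM < 1, low expressors
1 < RPKM < 10, expressors RPKM > 1) by the same Yates χ² used for module
composition, for consistency across the pipeline's 2×2 tests. Degenerate
tables (identical proportions, empty marginals) report χ² = 0, p = 1
rather than erroring inside a report loop.

**Enrichment.** One-sided upper-tail hypergeometric
(overrepresentation only), p = P(X ≥ k) via scipy's exact survival
function, with Benjamini-Hochberg step-up q-values across the tested
categories. The population defaults to the annotation universe and can be
overridden (e.g. to expressed genes). Gene-set similarity networks use the
overlap coefficient |A∩B|/min(|A|,|B|) — the "fraction of shared genes"
relative to the smaller set, as in Enrichment Map practice — with Jaccard
exposed as an option.

**Motif scan.** IUPAC-aware sliding-window scan; a window's score is the
number of non-N consensus positions whose IUPAC class contains the
sequence base. The default consensus is the canonical 15-mer GRE
pseudo-palindrome AGAACANNNTGTTCT (self-reverse-complementary, so plus-
and minus-strand scans of a palindromic hit score identically); the motif
is user-overridable because published GRE capitalizations frequently imply
laboratory-specific consensus variants.

## Synthetic data: what it emulates, and what it does not

The generators produce inputs with the *statistical* structure the
analyses assume, with defaults chosen to mimic the study setting:

- **Expression** (4 conditions, planted co-regulation templates): Normal
  noise on the log2 scale (multiplicative on the linear scale, matching
  RNA-seq dispersion at moderate expression), between-gene baseline sd 0.5
  and residual sd 0.25 log2 units, ~3 log2-unit condition effects, 40–50
  genes per cluster.
- **Time courses**: the I1-FFL model curve times lognormal noise with
  fixed CV (RT-qPCR fold-change error is multiplicative), 3 replicates,
  5% CV, on the 0–9 h sampling grid (0, 0.5, 1, 2, 3, 5, 7, 9 h); the
  lognormal is unit-mean so replicate means are unbiased.
- **Networks**: planted-partition graphs (three 20-node communities,
  p_in = 0.3, p_out = 0.02 in the benchmark), the canonical model for
  community-recovery benchmarks.
- **Intervals**: a 2-chromosome × 10 Mb synthetic genome — small enough
  for exhaustive overlap oracles — with 200 bp intervals, uniform
  background placement, and planted intervals uniform within target
  gene ± window.
- **Annotations**: uniform random categories (10–50 genes) plus planted
  overrepresented categories.

What passing tests on these data do **not** show: real RNA-seq has
count-based mean-variance structure, batch effects and correlated genes;
real association networks have degree heterogeneity and overlapping
communities that planted-partition graphs lack; real ChIP peaks cluster in
regulatory regions rather than uniformly; real GO annotations are nested
and strongly correlated. Recovery rates measured here are therefore upper
bounds on real-data performance, and the FFL identifiability conclusions
(stage-1 F is the reportable estimate) are about the model-noise
combination, not about biology.

## Determinism and degenerate inputs

Every stochastic operation takes a seed and is exactly reproducible.
Readers validate and raise rather than coerce: duplicate gene ids,
malformed cells (with row/column named), empty or inverted BED intervals,
single-column edge lines. Self-loops are dropped with a warning. Constant
expression rows, empty background tiers, sub-minimum clusters and
sub-minimum modules are flagged in outputs rather than silently removed.
The problem sizes used by the test suite and acceptance script (e.g.
160-gene expression matrices, 60-node graphs, 500-gene/2000-peak interval
fixtures, 10-seed recovery loops) were chosen as the smallest sizes at
which the planted structure is unambiguous.
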