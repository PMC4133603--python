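# grffl

Analysis toolkit for dissecting early glucocorticoid/LPS transcriptional
regulation in macrophages: expression clustering, network-module discovery
with topology statistics, incoherent feed-forward-loop (I1-FFL) dynamic
modeling and fitting, and binding-site/gene-set enrichment — with a
synthetic-data module that generates inputs carrying the statistical
structure every stage assumes, so the full pipeline runs and is testable
without external downloads.

## Who this is for

Computational biologists studying how a hormone-activated master regulator
(the glucocorticoid receptor, GR) propagates a signal through intermediate
transcription factors. The package takes condition × gene expression tables
(RPKM-like), gene association networks (edge lists), fold-change time
courses, TF binding intervals (BED) and gene-set annotations (GMT), and
chains four analysis stages behind one library + CLI surface.

## The core model

The centerpiece is the type-1 incoherent feed-forward loop in normalized
fold-change variables. GR activity steps up by a fold change *F* at *t* = 0
and drives both an intermediate repressor *r* and a target *z*; the
repressor in turn represses the target (strong repression: production ∝
*F*/*r*):

    dr/dt = α_R (F − r),        r(0) = 1
    dz/dt = α_Z (F/r − z),      z(0) = 1

With equal relaxation rates α_R = α_Z = α the system has the closed form

    r(t) = F + (1 − F) e^{−αt}
    z(t) = 1 + ((F − 1)/F) e^{−αt} ln(1 − F + F e^{αt})

which gives the motif its signature behaviour: for any sustained *F* > 1
the target pulses above baseline exactly once and relaxes back to *z* = 1
(fold-change detection). Clamping the repressor at basal — the knockout
experiment — collapses the pulse to monotone activation
*z*(t) = F + (1 − F) e^{−α_Z t}.

Around the model sit the other stages:

- **Clustering** (`grffl.clustering`): per-gene Z-scores of log2 expression,
  one-way ANOVA filtering, k-means with elbow selection of *k*, and
  Mann-Whitney condition contrasts within clusters.
- **Network modules** (`grffl.network`): Girvan-Newman divisive community
  detection (edge betweenness recomputed after every removal), Cytoscape-
  style topology metrics (density, clustering coefficient, degree-CV
  heterogeneity, neighborhood connectivity, shared-neighbor histogram),
  hub edge fractions, Yates χ² module-composition tests.
- **Binding & enrichment** (`grffl.enrichment`): binding-site-to-gene
  association within gene ± 15 kb (1-based closed coordinates, overlap by
  ≥ 1 nt), association-frequency comparisons against expression-tier
  backgrounds, upper-tail hypergeometric gene-set enrichment with
  Benjamini-Hochberg FDR, gene-set similarity networks (overlap
  coefficient), TF co-occurrence, and IUPAC consensus motif scans (default:
  the 15-mer GRE pseudo-palindrome `AGAACANNNTGTTCT`).

## Worked example

Simulate the I1-FFL at F = 10, α_R = α_Z = 1/h, then fit a noisy synthetic
time course back:

```
$ grffl ffl-simulate --f 10 --ar 1 --az 1 --t-max 9 --out traj.tsv
peak z = 2.0990 at t = 0.50 h

$ grffl simulate-data --kind timecourse --seed 1 --out tc
$ grffl ffl-fit --timecourse tc.tc.tsv --seed 1 --out fit.json
analytic_equal_rates: F=10.296 aR=1.033 aZ=1.033 R^2=0.9985
numeric_free_rates: F=18.710 aR=1.264 aZ=0.865 R^2=0.9989
```

The target peaks at about twice baseline half an hour after stimulation and
then adapts back — the pulse the I1-FFL is known for. The equal-rates fit
recovers the generating parameters (F = 10, α = 1/h) to within a few
percent from three replicates with 5% multiplicative noise; the free-rates
fit matches the curve slightly better but its *F* is only weakly
identified, which is why the equal-rates stage is the parameter-estimation
workhorse (see `docs/methods.md`).

The worked module-composition test from the library:

```python
>>> from grffl.datatypes import ContingencyTable
>>> from grffl.network import chi_square_yates
>>> r = chi_square_yates(ContingencyTable(22, 403, 32, 253))
>>> round(r.statistic, 2), round(r.p_value, 5)
(8.05, 0.00455)
```

i.e. 22/425 gene-expression-related categories in one module versus 32/285
in another is a significant compositional difference at df = 1.

## Layout

```
src/grffl/
  datatypes.py    core types (ExpressionMatrix, GeneModel, intervals, config)
  io.py           TSV/BED/edge-list/GMT readers and writers
  config.py       key:value config file + overrides
  synthetic.py    planted-structure data generators (+ ground truth)
  clustering.py   Z-score, ANOVA filter, k-means + elbow, Mann-Whitney
  network.py      Girvan-Newman, topology metrics, Yates chi-square
  ffl.py          I1-FFL / C-FFL simulation, closed form, two-stage fitting
  enrichment.py   interval association, hypergeometric + BH, motif scan
  cli.py          `grffl` command-line interface
```
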