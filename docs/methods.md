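# Methods

## Study model

The pipeline targets small longitudinal microarray-style designs: a
gene × sample log2 expression matrix already normalized to a common
scale, sample metadata giving group (control/patient), tissue source and
sampling time in hours, and a GMT gene-set collection.  Analyses are run
per source and for the pooled sample set, mirroring designs in which the
same subjects contribute whole-blood, lymphocyte and monocyte arrays at
t = 0, 8, 24 and 72 h.

## Synthetic data generator

`simulate_study` draws, per source, `n_controls` control and
`n_patients` patient subjects, each observed at every time point
(defaults 3 and 8 subjects, three sources, four time points).  Gene
baselines are Normal(7, 1.5) in log2 units, mimicking RMA-scale
intensities; this distribution is a modeling choice, not a property the
pipeline depends on.  Pathways are drawn with sizes uniform in
`pathway_size_range`; a configurable fraction of member genes is placed
in exactly two pathways to create the overlap structure the elastic-net
stage decomposes.

Active pathways (default 2) have all member genes follow
`effect_size * shape(t)` in patient samples only, where `shape` is
normalized to max |shape| = 1 and can be `linear` (proportional rise),
`peak` (Gaussian bump centered mid-course; the default, an
onset-and-resolution response) or `decay` (exponential fall-off from
admission).  Controls and inactive genes have constant expectation over
time.

Within-pathway noise is exchangeable with pairwise correlation `q`,
built from a shared per-pathway latent factor:
`eps = noise_sd * (sqrt(q) z_pathway + sqrt(1-q) z_gene)`.  This is the
cheapest construction whose pairwise correlation is exactly q.  Genes in
two pathways receive the factor of their first-assigned pathway, which
keeps the joint covariance valid at the cost of slightly diluting the
realized mean correlation of pathways that contain foreign-factor
overlap genes.  Defaults: `effect_size = 2`, `noise_sd = 0.5` log2
units, `q = 0.1` — a clearly detectable but noisy signal with mild
inter-gene dependence.

What the generator does **not** emulate: probe-level artifacts, batch
effects, missing arrays, subject-level random effects, heavy-tailed
noise, and hub topology inside pathways (all member genes are
exchangeable).  Passing recovery tests therefore demonstrates the
statistical machinery under its own model assumptions, not performance
on real arrays.

## Stage-by-stage choices

**Quartile filter.** The per-gene statistic is the IQR across all
samples (robust low-variability filter; `mean` is available).  The
threshold is the empirical `quartile_cut` quantile of the statistics,
computed once on the input study; genes at or below it are removed.
`quartile_cut = 0` disables filtering.  A constant matrix with the IQR
statistic is rejected (degenerate quantile).

**Enrichment.** One-sided over-representation p-values are the
hypergeometric upper tail; sidedness is fixed to "greater" because
enrichment, not depletion, defines the differential universe.  The
background is the set of measured genes appearing in at least one
pathway, and the query is the filtered genes within that background, so
the test asks which pathways are over-represented among
high-variability genes.  BH FDR is reported; selection uses the raw
p < 0.05 with overlap > 1, both overridable.  A stricter reporting
convention (set size > 5, p < 0.01) is available at the gene-set-test
stage via `min_set_size` and the caller's cut.

**FPCA.** With only four time points, functional PCA reduces to PCA of
the 4-dimensional mean-profile vectors across genes; no spline basis is
used because one is unidentifiable at so few points.  Profiles are
patient samples only by default (the temporal signal of interest is the
patient course; a flag includes controls).  The number of components is
the smallest L reaching 90% of centered variance, capped at
(#time points − 1).  Both residual sums are computed on replicate-level
observations — RSS⁰ against the gene's grand mean, RSS¹ against the
truncated reconstruction — so replicate noise enters numerator and
denominator and F behaves as a signal-to-noise ratio.  F is floored at 0
(ε = 1e−12 guards exact fits) and capped at 1e9.  Eigenfunction signs
are fixed by making the largest-magnitude component positive; top-N
selection breaks F ties by gene symbol.

**Elastic-net weights.** Each pathway's basis is the FPCA of its own
member genes' profiles — the only construction that can apportion an
overlapping gene *between* pathways.  The objective uses the squared L2
term λ₂‖β‖₂² (standard elastic net), solved by cyclic coordinate
descent to 1e−12; defaults λ₁ = λ₂ = 0.01, no cross-validation.
Single-pathway genes get weight 1 directly; genes whose fit is entirely
shrunk to zero fall back to uniform 1/|K_i|.  Per-gene weights sum to 1,
so pathway sum weights conserve the number of weighted genes.

**Gene-set test.** The statistic is the weighted mean midrank of member
F-values in the scored universe (all filtered pathway genes).  The null
variance under sampling without replacement from the observed ranks is
σ²ᵣ (N Σaᵢ² − 1)/(N − 1) with aᵢ the normalized weights, reducing to the
classical mean-rank variance for equal weights; ties are handled through
the midrank variance.  The variance is inflated by VIF = 1 + (m−1)·q̄,
the exact inflation of an equicorrelated mean, and a two-sided normal
p-value is reported.  q̄ is the mean pairwise Pearson correlation of
member genes after centering expression within each
(group, source, time) cell — the residual correlation, which estimates
the noise correlation q of the model without letting the planted group
signal masquerade as inter-gene correlation (raw correlation would make
the correction sharply conservative under strong signal).  Sets smaller
than 6 genes are skipped with a reason.  The Welch-t ordering of
pathways is reported for ranking only; selection is strict p < 0.05.

At N = 6 the normal approximation was compared against exhaustive
rank-sum enumeration: it tracks the mid-p exact value within 0.05 and
the conservative exact value within 0.20 (the exact two-sided law at
N = 6 is a five-step function; these budgets are asserted in the tests).

**Network.** Spearman correlation is computed as Pearson on midranks
over patient samples of the source, pooled across time points; edges
require |ρ| > 0.6 (absolute thresholding by default; a signed mode
exists).  Constant genes keep their node with no edges.  Hubs are nodes
with degree strictly above the mean degree, isolated nodes included in
the mean.  Hub sets of all groupings that produced a network are
intersected into exclusive Venn regions; "common markers" is the full
intersection and requires at least two networks.

**Pipeline.** Statistically empty outcomes — no enriched pathway, no
significant gene-set — are valid results; downstream stages for that
grouping are skipped with a log line and the run completes (a no-signal
study typically ends with an empty hub intersection).  Structural
problems (no samples, no gene-set coverage, missing files) raise
stage-named errors.  All stages are deterministic given the input study;
the only randomness in the package is the simulator's seed.

## Problem sizes

Tests and the acceptance script use scaled-down but structurally
faithful studies: 160–1000 genes, 6–12 pathways of 12–30 genes, one to
three sources with 3 control / 8 patient subjects at four time points.
Null calibration uses 100–200 simulation replicates; recovery and power
checks average 5–20 seeds.  These sizes give Monte-Carlo error well
inside the asserted bounds while keeping a full run in minutes.

## Known limitations

- The variance-inflation correction treats q̄ as known; its sampling
  error is ignored (adequate at the tested set sizes, conservative for
  very small sets).
- The normal approximation of the rank test is crude below ~10 genes per
  set; exact enumeration is used only as a test oracle.
- With four time points the FPCA basis has at most three components;
  subtle temporal shapes beyond that rank are invisible by construction.
- The elastic-net decomposition assumes pathway bases differ; pathways
  with nearly collinear eigenfunctions split overlap weight arbitrarily
  (the uniform fallback covers the fully degenerate case).
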