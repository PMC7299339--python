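# Methods

This note records the statistical models behind `sproutnet`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer would want written
down. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The inference problem

Input: raw-count matrices for miRNAs and protein-coding genes over two
conditions (control vs stimulated) with ≥ 2 replicates each, and a table of
predicted miRNA→gene interactions with a conservation class and a weighted
context++ score percentile. Output: an undirected bipartite graph whose
edges are candidate repressive interactions, plus the enrichment, topology
and cohort statistics used to interpret it.

The guiding assumption is the standard model of miRNA action: a miRNA that
rises under stimulation pushes its functional targets down, so a *true*
regulatory pair shows a negative expression correlation across samples, and
conserved predicted sites are far more likely to be functional than
non-conserved ones. The pipeline therefore intersects four weak signals —
prediction, negative correlation, correlation significance, and opposite
differential expression — each of which is individually noisy at small
sample sizes.

## Stage by stage

**Expression filter.** A feature is "expressed" when its mean raw count
over all samples is strictly greater than 5. The exact semantics of a
raw-count cutoff (mean vs minimum, which sample set) are a genuinely open
choice; the mean over all samples is the default and the cutoff is a
parameter. The filter applies to raw counts only, never normalized values.

**Normalization.** Median-of-ratios: each sample's size factor is the
median over all-positive features of count/geometric-mean, the standard
RNA-seq library-size estimator. Matrices where every feature contains a
zero have no reference features and raise a dedicated error.

**Differential expression.** The fold change is
log2((mean_treated + 1)/(mean_control + 1)) on normalized counts (the
pseudocount bounds it at zero counts). The *p*-value comes from a
pooled-variance *t* on log2(x+1) values with empirical-Bayes variance
moderation: the per-feature pooled variance s² (df = n₁+n₂−2) is shrunk
toward the across-feature mean s₀² as (d₀·s₀² + df·s²)/(d₀+df) with prior
df d₀ = 4, and the statistic is referred to t(df+d₀). This is the standard
small-n expression practice (limma's idea in its simplest form): with three
replicates per condition an unmoderated two-sample *t* has so few degrees
of freedom — Welch's variant can drop to df ≈ 2 — that even a 4-fold change
cannot produce *p* below ~10⁻², and after multiplicity correction
essentially nothing is callable. Moderation borrows strength across
features, which is well justified here because the log transform largely
stabilizes negative-binomial variance, making the per-feature variances
exchangeable. Setting `moderation_prior_df=0` recovers the plain pooled
*t*. FDR is Benjamini–Hochberg over all features; a feature is "up" iff
log2FC > 0.5 *and* FDR < 0.05 (both strict), symmetrically "down", else
"ns". This stage is deliberately *not* a count-model reimplementation —
dispersion shrinkage on the count scale, Wald/LRT tests and independent
filtering are out of scope, and externally computed DE tables can be
ingested in their place (directions are then recomputed from the same
thresholds).

**Correlation and the permutation null.** All miRNA×gene Pearson
correlations are computed on log2(normalized+1) values (the scale is
configurable; correlation is invariant to per-feature affine rescaling, so
only the log choice matters). Analytic two-sided *p* uses the *t*
transform with n−2 df. The empirical null shuffles the miRNA matrix's
sample labels once per permutation — one shuffle keeps the null joint
across all pairs, and shuffling one matrix is equivalent to shuffling
either under exchangeability — and pools all pair correlations;
per-pair empirical *p* is the add-one two-sided count
(1 + #{null |r| ≥ |r_obs|})/(1 + N). With six samples only 6! = 720
distinct orderings exist, so permutations are sampled with replacement.
Zero-variance profiles yield records flagged undefined and excluded
downstream. Network edges use the analytic *p* by default (the empirical
*p* is attached and selectable): both are computed because which one the
original analysis used is not recoverable, and they agree in rank order.

**Stratified distribution test.** The correlator distribution of a
prediction stratum (conserved or non-conserved) is compared against all
evaluated pairs with a two-sample Kolmogorov–Smirnov statistic; the
one-sided variant (stratum ECDF above the background ECDF) tests the
stochastic shift toward negative *r* that repression produces. Histogram
summaries over [−1, 1] are returned for plotting elsewhere.

**GSEA.** The ranked list orders genes by Pearson correlation with a
continuous phenotype (a miRNA profile, or a per-sample score) or by
signal-to-noise (μ₁−μ₂)/(σ₁+σ₂) for two classes, each σ floored at
max(0.2·|μ|, 0.2); ties break lexicographically by gene id so ranking is
deterministic. The enrichment score walks the list adding
|metric|^w/Σ_set|metric|^w per hit (weight w = 1 by default) and
subtracting 1/(N−N_hits) per miss; ES is the signed maximum deviation, and
the leading edge holds the members at or before the maximum (at or after
the minimum for negative ES). The null uses gene-set permutation by
default — random member sets of equal size, exhaustively enumerated when
C(N, k) is small enough — because with six samples phenotype permutation is
degenerate; phenotype permutation is available for cohorts. NES divides ES
by the mean |null ES| of matching sign; *p* is one-sided against the
sign-matched null with add-one smoothing; FDR *q* is the sign-stratified
ratio of pooled-null to observed NES tail fractions, with add-one smoothing
on the null fraction so that a sparse matched-sign null (common when the
ranked list carries strong signal and the null skews one way) cannot
produce spurious *q* = 0. The association matrix runs one
continuous-phenotype GSEA per miRNA with a shared permutation seed
(identical profiles therefore give identical columns), masks NES sign by
FDR < 0.05, clusters rows and columns by complete-linkage Euclidean
hierarchy, and reports per row-cluster the union of leading-edge genes of
significant cells.

**Network assembly and topology.** Edges require a predicted pair (best
record per pair decides the attributes; conserved-only by default, with
non-conserved available as a control), r < 0 with p below threshold, and —
switchable — both endpoints differentially expressed with opposite
directions. The both-endpoints-DE requirement is implied, not stated, by
the two-component description of the original analysis; relaxing it yields
a prediction-plus-anticorrelation network. Isolated nodes are dropped.
Summaries report counts, components, out/in-degree sequences and hubs
(out-degree ranking, ties lexicographic — degree is the working hub
definition). Subnetwork extraction takes gene seeds plus their targeting
miRNAs, or miRNA seeds plus their targets, preserving edge attributes.

**Power-law fitting.** For each candidate xmin the discrete MLE maximizes
−n·log ζ(α, xmin) − α·Σ log x over α ∈ (1.01, 20) (ζ is the Hurwitz zeta);
xmin minimizes the KS distance between the tail ECDF and the fitted CDF
evaluated over the full integer support of the tail. Candidate xmins are
the unique observed degrees thinned to at most 75, *constrained to tails
holding at least 5% of the sample*: without that floor the KS-minimizing
xmin drifts into sparse tails where any distribution fits and the
goodness-of-fit test loses all power against non-power-law alternatives.
The GOF *p* is the fraction of semi-parametric bootstrap replicates
(observed values below xmin resampled empirically, the fitted law — sampled
exactly by inverse CDF over a tabulated support, not by the continuous
approximation, which misplaces ~6% of mass at x = 1 for α = 2.5 — at and
above it, full refit per replicate) whose KS distance reaches the observed
one; the fit is deemed plausible when *p* > 0.1. Note that this *p* is
itself approximately uniform when the model is true, so single-dataset
accept decisions carry the usual type-I trade-off; the acceptance checks
use the median over independent datasets.

**Hypergeometric test.** P(X ≥ k) is computed with exact rational
arithmetic (Python integers/Fractions); the universe size N is always an
explicit argument, never inferred.

**Endothelial score and module correlation.** The score is the mean over
present signature genes of per-gene z-scored expression (the signature
itself is user-supplied — any gene list works); constant genes are excluded
with a warning, and samples are returned ranked. The module–score
correlation z-scores module genes before averaging, then reports Pearson r
with analytic p. Both choices (z-scoring, mean aggregation) are package
decisions where the upstream definition is delegated to prior literature.

**ΔΔCt.** Per sample, ΔCt subtracts the mean Ct of reference assays
(global per-sample mean when no references are given); replicates are
averaged on the Ct scale within condition; ΔΔCt = ΔCt_treated −
ΔCt_control per treated condition and Rq = 2^(−ΔΔCt). The |ΔΔCt| > 2
filter is strict; surviving rows are ordered by complete-linkage Euclidean
clustering of −ΔΔCt.

**Pipeline.** One YAML file configures every stage; the master seed is
split per stage by hashing (seed, stage-name), so re-running one stage
never disturbs another, and identical config+seed reproduce byte-identical
summaries (floats are rounded to 10 digits before serialization to keep
the JSON stable). Contract violations abort with the offending stage
logged. The CLI (`sproutnet run|synth|network|gsea|cohort`) is a thin
wrapper; exit code 2 signals a contract/configuration error.

## The synthetic-data generator

`generate_experiment` emulates the statistical structure the analysis
assumes. Counts are negative-binomial with mean μ and variance μ + d·μ²
(d = `nb_dispersion`; Poisson at d = 0), per-feature baselines log2-normal
(mean 8, sd 1.5 — mid-expressed features, so the dispersion term dominates
the noise), and per-sample size factors uniform within ±20% (the real
data's library-size spread is unknown; this is the exposed default).
Regulator miRNAs shift by ±`effect_lfc` in the treated condition; each
regulator draws an out-degree from a discrete power law (α = 2.5) and its
targets — sampled without replacement from a direction-specific pool —
shift the opposite way. Anti-correlation is induced solely through the
condition means (no per-sample coupling): with 3+3 samples this already
produces the strong negative correlators the pipeline must detect.

Reference conditions (the generator defaults, used by the acceptance
checks): 40 miRNAs, 400 genes, 300 planted edges, |log2FC| = 2,
dispersion 0.05, 3+3 replicates, decoy ratio 3. Two structure parameters
are not dictated by those conditions and were fixed once from the
proportions a real sprouting study shows (roughly a quarter of expressed
miRNAs modulated; individual genes targeted by up to ~11 miRNAs): 5 up-
and 5 down-regulators, and direction-specific target pools of 15% of the
genes each. When `n_planted_edges` is set, the drawn out-degree sequence
is rescaled to hit that total (so the α of a 10-regulator run is not
meaningful; the pooled-over-seeds sequence at `n_planted_edges=None` is
what matches α). Decoy predictions are sampled uniformly from non-planted
pairs — which deliberately includes regulator–target pairs that pass every
filter and bound the achievable precision — and are split between the
conserved class (percentile in (50, 100]) and the non-conserved class
(percentile in (90, 100], so they survive the strict read filter and give
the non-conserved stratum its decoy-only control role). Gene sets comprise
one set per planted module plus random sets.

`generate_cohort` draws a latent per-sample score z ~ N(0,1); signature
genes load on it with coefficient 1, module genes with coefficient β, and
module genes additionally share a per-sample noise component (sd 0.8 by
default). The shared component is what keeps the module *mean* from
trivially converging to z when ~40 genes are averaged — it models
stromal-content confounding in bulk tumors and is the reason a β chosen
for module-score r ≈ 0.5 still leaves each gene individually correlated
enough for set-level enrichment. Responders receive a constant
`responder_effect` on module genes. `generate_ct_card` plants Ct shifts on
chosen assays and always emits two never-shifted reference assays
(returned in the truth) so that reference-normalized ΔΔCt recovers the
planted values exactly; global-mean normalization would smear a shift of s
on |S| of n assays into −s·|S|/n everywhere else.

What the generator does **not** emulate: read-level artifacts (FASTQ, GC
bias, mapping multi-hits), batch effects, isomiR complexity, correlated
baseline co-expression between genes beyond the planted modules, partial
or saturating repression, and real TargetScan percentile distributions.
Passing the recovery tests therefore shows the pipeline's filters compose
correctly and are calibrated under the assumed noise model — not that the
same precision/recall would hold on sequencing data, where prediction
error and biological confounding are far less benign.

## Problem sizes and runtime choices

The test suite and acceptance script run everything at the reference
conditions above; the permutation null uses 1000 shuffles (16M pooled
draws), GSEA 1000 permutations, and the power-law analysis five
independent 5000-draw datasets with 200 bootstrap replicates each (the
fitter accepts any bootstrap count; 1000 is the single-fit default in the
pipeline summary at a smaller problem size). The Monte-Carlo calibration
checks use 50–200 seeds at reduced matrix sizes. These sizes keep a full
run in the minutes range on one core while leaving every statistical
margin (binomial noise on calibration fractions, MLE standard errors)
comfortably inside the asserted bounds.

## Known limitations

- The DE stage is a stand-in with matched thresholding semantics, not a
  count-model tool; its variance moderation uses a fixed prior df rather
  than estimating it from the data.
- Gene/miRNA identifiers are compared literally (after whitespace
  stripping); symbol aliasing and historical TargetScan layouts are out of
  scope, and site-level prediction records are assumed pre-aggregated to
  one record per (miRNA, gene, conservation class).
- The GSEA FDR follows the sign-stratified ratio procedure; it is not a
  BH-style step-up and can be non-monotone in NES across sets.
- With six samples the ES sign at an exact positive/negative tie of the
  running-sum extrema is implementation-defined (float summation order).
- The power-law xmin floor (5% tail) trades a small bias on genuinely
  heavy-bodied data for falsifiability; sequences shorter than ~10 values
  are rejected and tails under 10 points only flagged.
- Indirect miRNA–miRNA effects, partial correlations and time-lagged
  measures are out of scope; the network is correlational, and the
  two-component structure follows from the sign filters, not from any
  causal claim.
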