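# sproutnet

miRNA-centered post-transcriptional co-expression network inference for
two-condition expression studies.

When endothelial cells are driven from quiescence into sprouting
angiogenesis, microRNAs reinforce the transcriptional switch by repressing
their target mRNAs. `sproutnet` reconstructs that regulatory layer from the
kind of data such a study produces — miRNA and mRNA count matrices over a
control and a stimulated condition with a few replicates each, plus a
TargetScan-style target-prediction table — and carries the analysis through
to the downstream statistics used to interpret it. It is a library first
(everything is importable; see `examples/`), with a thin `sproutnet` CLI for
running the whole pipeline from one YAML file.

## What it computes

The core object is a **signed bipartite regulatory network**: an edge joins
miRNA *m* to gene *g* iff

1. *m*→*g* is a predicted interaction (conserved sites with weighted
   context++ score percentile > 50; non-conserved > 90 when enabled),
2. the **correlator** *r* = Pearson(*m*, *g*) across samples (on
   log2-normalized expression) is negative with *p* < 0.05 — analytically
   via the *t* transform, or against a permutation null built by sample
   randomization (1000 shuffles), and
3. both endpoints are differentially expressed (|log2FC| > 0.5,
   Benjamini–Hochberg FDR < 0.05) in opposite directions.

Around the network the package provides, all from scratch where the method
is the point:

- **GSEA engine** — weighted running-sum enrichment score, continuous
  (Pearson-ranked) and two-class (signal-to-noise) phenotypes, gene-set or
  phenotype permutation with NES, one-sided add-one *p* and sign-stratified
  FDR *q*; a per-miRNA **association matrix** with hierarchical clustering
  and leading-edge ("core enrichment") extraction.
- **Degree-distribution analysis** — discrete power-law fit
  *p(x) ∝ x^(−α)* by Hurwitz-zeta maximum likelihood over candidate *x*min
  values, with semi-parametric bootstrap goodness of fit (plausible when
  *p* > 0.1), hub ranking and subnetwork extraction.
- **Downstream statistics** — exact hypergeometric over-representation,
  endothelial-signature cohort scoring (mean per-gene *z*-score) with
  module–score correlation, and comparative-Ct qPCR card analysis
  (ΔΔCt, Rq = 2^(−ΔΔCt), strict |ΔΔCt| > 2 filter).
- **Synthetic data with ground truth** — negative-binomial counts with
  planted regulator miRNAs and oppositely shifted targets, power-law
  out-degrees, decoy predictions, module-aligned gene sets, a tumor cohort
  with a latent angiogenesis score, and qPCR cards with planted shifts.
  Every generator returns the truth key, so recovery is measurable.

## Worked example

```bash
python examples/build_network.py
```

```
network: 10 miRNAs, 121 genes, 297 edges in 2 components
top hub: miR-001 (out-degree 53)
precision 0.963, recall 0.953
```

The generator planted 300 repressive interactions (five up- and five
downregulated miRNAs, |log2FC| = 2, NB dispersion 0.05, 3+3 replicates,
three decoy predictions per planted one). The assembled network splits into
exactly two components — upregulated miRNAs with their downregulated
targets, and the mirror image — and recovers the planted edges with 96%
precision and 95% recall. The other scripts in `examples/` demonstrate the
correlator null and its conserved-stratum enrichment, the miRNA×gene-set
association matrix, cohort scoring with responder GSEA, and ΔΔCt card
processing; `examples/run.yaml` drives the full pipeline:

```bash
sproutnet run --config examples/run.yaml --out out/ --seed 42
```

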