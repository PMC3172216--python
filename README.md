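# persig

Derive a **perturbation-response gene signature** from a small two-condition
microarray experiment and **project it onto an independent cohort** to ask
which patient subsets show the same transcriptional program.

The package is aimed at transcriptomics analysts working with classic
perturbation designs: a transcription factor (or cytokine) is overexpressed
in cultured cells, expression is profiled against a control at one or two
time points with very few replicates, and the resulting signature is then
evaluated in a clinical expression dataset whose samples carry molecular
subset labels (for example the intrinsic subsets of systemic-sclerosis skin
biopsies: diffuse-proliferation, inflammatory, limited, normal-like).

## What it computes

The pipeline mirrors the standard bead-array analysis chain:

1. **Detection filtering** — probes called "absent" (at or below array
   background) in *every* sample are removed.
2. **Variance-stabilizing transformation** — the generalized log
   `glog2(x) = log2((x + √(x² + c²))/2)`, with the offset `c` fitted from
   the replicate mean–variance trend `Var ≈ a + b·mean²` as `c = √(a/b)`.
3. **Quantile normalization** — every sample is forced onto the mean
   empirical distribution.
4. **Empirical-Bayes moderated t** — per-gene variances `s²_g` are shrunk
   toward a prior estimated across all genes,

       s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
       t_g = lfc_g / √(s̃²_g·(1/n₁ + 1/n₂)),   t_g ~ t(d₀ + d_g) under H₀,

   with `(d₀, s₀²)` from moment matching on `log s²_g` (the limma
   methodology, re-implemented and cross-checked against Bioconductor
   limma in the tests). Benjamini–Hochberg step-up FDR control follows.
5. **Signature derivation** — genes with `q < 0.01` and `|lfc| ≥ 1`
   (fold-change > 2) form a named, directional, weighted signature.
6. **Enrichment** — hypergeometric upper-tail over-representation
   `P(X ≥ k)` of signature genes in user-supplied GMT gene sets.
7. **Projection** — the signature's fold-change vector is the *centroid*;
   each cohort sample is scored by the Pearson correlation between the
   centroid and its (gene-centered) expression over the matched genes.
   Per-subset summaries, a Welch t contrast (target subsets vs. rest),
   per-subset direction-concordance fractions, and average-linkage
   1−Pearson clustering of the samples complete the analysis.

A synthetic-data module (`simulate_perturbation`, `simulate_cohort`)
generates both study designs with known ground truth, so the entire chain
is testable end to end without any external downloads.

## Worked example

```python
from persig import (PerturbationSimConfig, CohortSimConfig, ModeratedTTest,
                    SignatureProjection, preprocess, simulate_perturbation,
                    simulate_cohort)

dataset, truth = simulate_perturbation(PerturbationSimConfig(seed=1))
normalized, removed, vst = preprocess(dataset)
results = ModeratedTTest(normalized, time="48h").fit()
print(results.summary())
```

```
Moderated two-group comparison
==============================================
contrast:        perturbed - control
time point:      48h
genes tested:    12090
prior d0:        8.18
prior s0^2:      0.0398531
q<0.01 & |lfc|>=log2(2): 523 (220 up, 303 down)
```

12,090 of 13,000 simulated probes survive the all-absent filter; the
moderated test with ~8 extra prior degrees of freedom calls 523 genes at
FDR < 0.01 with more than 2-fold change (600 were planted). Projecting the
signature onto a simulated 75-biopsy cohort:

```python
signature = results.derive_signature(name="late-response")
cohort, _ = simulate_cohort(signature, CohortSimConfig(seed=2))
projection = SignatureProjection(cohort, signature).fit()
print(projection.summary())
```

```
per-subset scores (mean +/- sd):
                mean     sd   n
subset
diffuse1      0.7446 0.0147   9
diffuse2      0.7487 0.0206   9
inflammatory -0.1407 0.0445  18
limited      -0.3429 0.0374  21
normal-like  -0.3458 0.0354  18

target ['diffuse1', 'diffuse2']: 0.7467 +/- 0.0175 (n=18)
rest: -0.2800 +/- 0.1029 (n=57)
Welch t = 72.0824, two-sided p = 1.07e-63

concordance fractions (null band 0.5):
  diffuse1: 0.861
  diffuse2: 0.876
  inflammatory: 0.070
  limited: 0.000
  normal-like: 0.000
```

The two diffuse subsets — where the signature was planted — score far
above the rest, most of their signature genes move in the signature's
direction, and only the small planted fraction does so in the inflammatory
subset.

The same stages are available from the shell via the `persig` CLI
(`simulate | preprocess | de | signature | enrich | score | overlap |
report`); `persig report --seed 1 --outdir out/` writes every stage's
output as plain TSV/JSON/Newick files.

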