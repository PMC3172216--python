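# Methods

This note documents the models, parameter choices and numerical conventions
behind `persig`, and what the synthetic-data generators do and do not
emulate.

## Preprocessing

**Detection filtering.** The primary rule removes a probe iff its detection
flag is `False` in every sample. When no flags are available a fallback
rule can be enabled: a probe is removed iff its intensity lies below a
per-sample background quantile (default suggestion 0.05) in *every* sample.
The boundary is deliberate: a single present call anywhere retains the
probe.

**Variance-stabilizing transform.** Bead-array intensities carry
two-component noise — additive background noise (variance `a`) plus
multiplicative noise proportional to signal (squared CV `b`) — so
`Var(x) ≈ a + b·mean²`. The generalized log

    glog2(x) = log2((x + sqrt(x² + c²)) / 2),   c = sqrt(a/b)

is asymptotically `log2(x)` for `x ≫ c` and linear near zero, which makes
the transformed variance approximately constant in intensity. `c` is
fitted from the replicate mean–variance trend: per-probe within-group
variances (pooled over all condition×time groups with ≥2 replicates) are
binned by per-probe mean into 50 quantile bins and the binned variance is
regressed on binned squared mean. Two numerical conventions matter:

* within-group variances use the **population (ddof=0) denominator**, so
  the fit is invariant to duplicating every sample; the constant bias
  factor `(n−1)/n` cancels in the ratio `a/b`;
* the slope comes from the OLS fit, but the intercept is re-estimated from
  the dimmest decile of bins (where the multiplicative term vanishes),
  because the OLS intercept is dominated by high-leverage bright bins.
  The intercept is set to zero when it is not at least twice its standard
  error across those bins — pure multiplicative noise then drives `c` to
  its lower cap rather than to an arbitrary noise-sized value.

`c` is capped to `[1e-3, 1e6]`; a zero slope (no multiplicative
component) yields the upper cap, i.e. an essentially linear transform.
Inputs below `−c` (impossible for data from the generators, which clip at
zero) are mapped to the transform's value at 0 and counted in a warning.

**Quantile normalization.** Each column's sorted values are replaced by
the across-column mean of sorted values; a run of tied values within a
column receives the mean of the quantile values the run spans. The tie
rule is deterministic and order-independent, but it means exact
column-distribution equality and exact idempotence hold only for tie-free
columns (continuous data); with ties the operation is idempotent only up
to the tie-averaging. A single-sample matrix is returned unchanged with a
warning.

The pipeline order is fixed: filter → VST → quantile normalization.

## Moderated differential testing

Each time point is analysed as an independent two-group contrast
(perturbation − control). Per gene: `lfc` is the difference of group
means, `s²` the pooled within-group variance (ddof=1), `df = n₁+n₂−2`.
The prior on residual variances is scaled inverse-chi-square with
hyper-parameters `(d₀, s₀²)` estimated by moment matching on
`z = log s²`: under `s² ~ s₀²·F(df, d₀)`,

    E[z]   = log s₀² + ψ(df/2) − log(df/2) − ψ(d₀/2) + log(d₀/2)
    Var[z] = ψ′(df/2) + ψ′(d₀/2),

so the excess of the empirical `Var(z)` over the sampling term
`ψ′(df/2)` identifies `d₀` through a Newton inversion of the trigamma
function. No excess (or `d₀ ≥ 1e6`) is reported as `d₀ = ∞`: variances
are exchangeable, every shrunken variance equals `s₀²`, and the reference
distribution becomes normal. The edge `d₀ = 0` is admitted for testing
and reproduces the ordinary pooled t exactly. At least 10 finite positive
variances are required; otherwise the caller must supply a fixed prior.
The estimator is cross-checked against Bioconductor limma's
`lmFit`/`eBayes` in the test suite (agreement ~1e-6 relative).

p-values are two-sided on `d₀ + df` degrees of freedom, floored at the
smallest positive double; Benjamini–Hochberg step-up adjustment (via
statsmodels) yields q-values, verified in the tests against a direct
transcription of the step-up definition.

**Signature thresholds.** A gene enters the signature iff `q < 0.01` and
`|lfc| ≥ log2(2) = 1` on the transformed scale; both thresholds are
configurable and a raw-p option is exposed, since small-sample studies
sometimes report raw-p criteria alongside FDR. The inclusive `≥` on the
fold bound is fixed for reproducibility. Weights are the log2
fold-changes; directions are their signs.

## Enrichment

One-sided hypergeometric over-representation, `P(X ≥ k)` computed through
`scipy.stats.hypergeom.sf` (log-gamma based, stable for large margins; the
tests verify exact agreement with rational-arithmetic enumeration for all
universes up to 25 genes). The universe defaults to all probes surviving
the detection filter — a conservative, configurable choice. Sets are
flat GMT collections; no ontology traversal. The default significance
flag is unadjusted `p < 0.001`, with BH q reported alongside.

## Cohort projection

**Centroid.** The signature's per-gene log2 fold-changes, restricted to
genes present on the cohort platform (matching by uppercased symbol;
duplicate rows per symbol collapsed by highest IQR, keeping the most
informative probe). A sign-only weighting (`±1`) is available for
sensitivity analysis. Coverage below 50% triggers a warning; below two
matched genes the centroid is refused.

**Scoring.** Pearson correlation between the centroid and each sample's
expression over the matched genes. Cohort rows are median-centered per
gene by default — the cohort is ratio-style data and the "not activated"
state is only defined relative to the gene's typical level. NA genes are
dropped pairwise per sample; a sample with fewer than two usable genes
scores NA with a warning. Scores are affinely invariant per sample
(Pearson contract).

**Subset contrast.** Welch's t (unequal variances, two-sided,
Welch–Satterthwaite df) between the target subsets (default the two
diffuse-proliferation labels, configurable) and all other samples; group
SDs use ddof=1. A p-value that underflows to zero (zero within-group
variance) is reported as the smallest positive double.

**Concordance.** For each subset and each matched signature gene, the
gene is concordant iff the sign of its mean centered expression over the
subset equals its signature direction *and* the magnitude of that mean
exceeds a null band. The low-level function defaults to a pure sign test
(band 0). The model-level default band is **0.5 log2 units**: under a
sign test alone, every unshifted gene still counts as concordant with
probability ~1/2, so the reported fraction for a subset expressing only a
small part of the signature would be dominated by chance agreement; a
half-unit band (half the default planted effect) counts only genes with a
material shift. Empty subsets yield NaN; an exactly zero mean is not
concordant.

**Clustering.** Average-linkage agglomeration on `1 − Pearson` distance
between samples over the signature genes, via scipy's deterministic
implementation; leaf order is scipy's canonical traversal and the tree
serializes to Newick. Genes are median-centered first, consistent with
scoring: without centering, unactivated ratio-style samples are mutually
near-orthogonal and the dendrogram's top split reflects noise rather than
the activated/unactivated contrast. A constant sample vector (undefined
correlation) is rejected with the sample named.

**Overlap.** Two signatures are compared by uppercased gene id:
concordant-up, concordant-down and discordant counts always partition the
intersection.

## Synthetic data

`simulate_perturbation` emulates a two-condition (control vs.
transcription-factor overexpression) × two-time-point × two-replicate
bead-array experiment on 13,000 probes:

* raw intensity `x = 2^(μ + δ)·(1 + ε_m) + ε_a`, clipped at zero, with
  per-probe baseline `μ ~ N(7, 1.5²)` (log2 scale), multiplicative noise
  `ε_m ~ N(0, 0.12²)` and additive background noise `ε_a ~ N(0, 30²)` —
  the mean–variance relationship that motivates the VST;
* 7% of probes are all-absent: pure additive noise around the background
  level, detection flag `False` in every sample (present probes are
  flagged `True` everywhere — the filter only ever uses the all-absent
  rule, so per-sample mosaic flags are not modelled);
* 600 genes carry a planted log2 effect at the late time point, magnitude
  uniform on [1.2, 3.0], 40% up-regulated; a nested subset of 220 carries
  the same effect already at the early time point;
* planted genes are drawn from the **expressed** present probes — baseline
  at or above `log2(additive_sd / cv)`, the intensity at which signal
  noise starts to dominate background noise (~26% of probes at the
  defaults). A gene sitting at array background cannot exhibit a
  measurable fold-change in either direction, so planting effects there
  would create "truth" that no analysis of this platform could recover;
  real perturbation signatures consist of detected, expressed genes.

`simulate_cohort` emulates a 75-sample ratio-scale cohort partitioned into
five molecular subsets (12/12/24/28/24%, allocated by the deterministic
largest-remainder method). 85% of signature genes appear on the cohort
platform, alongside 4,000 background genes (a free platform-size choice —
large enough that signature genes are a minority, as on a real array).
Per-gene noise is `N(0, 0.6²)`; in the two diffuse subsets every covered
signature gene is shifted by `effect × direction` (default effect 1.0); in
the inflammatory subset only a random 14% of covered genes are shifted.
The cohort is generated directly on a centered log scale — the projection
target in practice is a preprocessed public dataset, so no VST stage
applies to it.

Both generators use a single `numpy` Generator stream seeded from the
config; identical configs give bit-identical outputs.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: probe-level bead replicates, batch and dye
effects, per-sample detection mosaics, correlated gene–gene noise
(co-expression), platform-specific probe biases, and any real biological
covariance between cohort subsets. Recovery results on this synthetic
truth demonstrate that the machinery is correct and well-calibrated under
its assumed noise model, not that the thresholds are optimal for any
particular real platform.

## Problem sizes and runtimes

The default study conditions (13,000 probes × 8 arrays; 75-sample cohort)
run the full chain in ~2 s, so the test suite exercises the pipeline at
full size; multi-seed checks use 5–20 seeds. The end-to-end determinism
check and CLI tests use a 2,500–3,000-probe design — byte-level
reproducibility does not depend on matrix size, and the smaller design
keeps repeated full-pipeline runs quick.

## Known limitations

* Gene identity is uppercased-symbol based throughout; no probe-to-gene
  annotation handling beyond IQR collapse of case collisions.
* The fold threshold applies to the VST scale. Near the additive-noise
  regime the glog compresses fold-changes (a 2-fold change of a dim gene
  moves less than one transformed unit), so dim genes are intrinsically
  harder to call — a property of the transform, not a bug, but worth
  remembering when interpreting signature sizes.
* Quantile normalization's tie rule sacrifices exact idempotence under
  ties for determinism and order-independence.
* The concordance null band is a convention; reported fractions move with
  it and should be quoted together with the band.
* Enrichment offers no gene-length or expression bias correction and no
  ontology structure.
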