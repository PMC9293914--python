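# Methods

This note records the models, parameter choices and numerical
conventions behind `dciscope`, and what the synthetic-data validation
does and does not establish about real data.

## The synthetic experiment

The generator (`dciscope.synthetic`) emulates a staged mammary
tumor-progression study: three disease states (normal prepubertal duct,
DCIS-like in-situ lesion, invasive tumor), two replicate animals per
state, each sample a mixture of epithelial, fibroblast and immune cells,
with the malignant fraction of epithelial cells rising along the
progression (5% → 30% → 60% in the standard configuration).

Counts are negative binomial with a gamma–Poisson draw:

    count_gc ~ Poisson( Gamma(θ, μ_gc/θ) ),
    μ_gc = L_c · λ_g(type_c) · dosage_gc · program_gc · batch_gs

* **λ(type)** — relative expression per cell type, drawn once per type
  from Gamma(shape 0.6, scale 1) and normalized to sum to 1. Ten marker
  genes per type are boosted 8-fold before normalization so that
  marker-based cell typing is solvable (accuracy ≥ 0.95 on the standard
  fixture). Malignant and normal epithelial cells share the *same* λ:
  with no planted segments or programs they are distributionally
  identical, which is the package's null.
* **L_c** — library size, lognormal(ln 5000, 0.3); typical droplet depths.
* **θ = 2** — a single shared dispersion (splatter-style
  simplification); gene-specific dispersion is not modeled.
* **dosage** — arm-level events as contiguous gene-index ranges with a
  multiplier (standard: 200 genes on chr1 at 1.5×, 200 on chr3 at 0.5×),
  applied only to malignant cells. Means are deliberately *not*
  re-normalized after dosage, so the malignant/normal mean-count ratio
  over segment genes recovers the planted multiplier exactly
  (Monte-Carlo check: ratio within [1.45, 1.55] for m = 1.5).
* **program** — fold effects on a gene set in a target subpopulation
  (a cell type, or the malignant cells), optionally restricted to given
  states; these plant the ground truth for signature scoring, marker
  recovery and conserved-marker tests.
* **batch_gs** — a per-sample lognormal gene factor (σ = 0.2 in the
  standard fixtures). Replicates and, especially, an external reference
  experiment realistically differ in per-gene capture efficiency; this
  term is what gives the composition GLM a batch signal to absorb and
  the CNA chain an inter-sample offset to remove.
* **dying cells** — 2% of cells have their mitochondrial gene mass
  raised to 50% of the transcriptome, so QC filtering has real targets.
  Mitochondrial genes are a flagged trailing block (names `mt-*`), 2% of
  the universe.

Geometry: 2,000 genes over 10 chromosomes of 200 genes each, ordered by
a synthetic start coordinate. This gives each chromosome roughly two
independent values after 101-gene smoothing — coarse, but it preserves
the property that matters: segments are contiguous in genome order and
smoothing must not cross chromosome boundaries.

Bulk data use the same NB machinery with a shared baseline, 50-gene
subtype marker sets at 4-fold, lognormal(ln 1e6, 0.2) library sizes and
θ = 20 (bulk is far less dispersed than single cells). Composition
labels are drawn directly as multinomial cells with per-batch logit
jitter (σ = 0.1, "mild batch noise"); the generator returns its
post-jitter planted probabilities, because that — not the nominal
prevalence — is the parameter a recovery analysis should be compared to.

## Preprocessing

QC defaults: genes kept if expressed in ≥ 3 cells; cells kept if they
express ≥ 200 genes and carry ≤ 10% mitochondrial counts (the
conventional upper end of the usual 5–10% range; configurable).
Cell-level filters run before the gene-level filter so dying cells
cannot rescue genes. The filter is idempotent.

Normalization is ln(1 + count/total × 10⁴); scaling is a per-gene
z-score across cells using the sample (n−1) standard deviation — fixed
for bit-reproducibility — clipped at ±10, with zero-variance genes
mapped to zero.

Variable-gene selection is vst-style: a degree-2 polynomial of
log10(variance) on log10(mean) over expressed genes serves as the
mean–variance trend (in place of a local regression); values are
standardized by the trend SD, clipped at √N, and genes are ranked by the
variance of the clipped standardized values, ties broken by gene
identifier. This is a deterministic, dependency-light approximation and
is *not* numerically identical to any particular package's
implementation.

Cell typing is marker-signature argmax on scaled expression (ties by
signature order). Graph clustering is intentionally out of scope: every
downstream computation needs only type labels, which in practice come
from marker-annotated clusters or prior annotation.

## CNA inference

Order of operations: expression filter (mean lognorm ≥ 0.1) → subtract
reference-cell mean per gene → optional per-sample residual centering →
clip at ±3 → 101-gene uniform moving average within chromosome (edge
truncation, shorter windows near ends) → subtract per-cell median. The
uniform unweighted window is a deliberate fixed choice; published tools
vary in their window weighting across versions, and only the window
length is treated as canonical. Reference centering uses the mean (not
median), configurable. Unannotated genes raise in strict mode and are
dropped with a warning otherwise.

**Per-sample centering** deserves emphasis. When the diploid reference
comes from a different experiment (here: a separate normal-mammary
sample), every cell of an observation sample shares a systematic
residual offset against it. Removing each sample's per-gene mean
residual absorbs that batch offset — and has a second effect: profiles
become relative to the sample average, so the normal cells of a
malignancy-bearing sample show the *mirror image* of the aberrations
carried by its malignant cells. This is precisely what makes the
normal-correlation axis of the classifier informative, and it is the
mechanism exploited by the widely used average-cell-reference variant of
expression-based CNA inference. The cost: an aberration shared by
essentially every cell of a sample cancels and becomes invisible. The
flag is optional; without it the chain still detects segments but the
dual-correlation rule loses most of its sensitivity.

## Malignancy classification

Burden is the mean squared profile value — the ranking statistic behind
"top 5% most aberrant" (alternative: mean absolute value). The aberrant
pole averages the ceil(0.05 · n) highest-burden candidate cells of the
sample (ties broken by cell id); the normal pole averages either an
explicit list of known-diploid cells or, by default, the sample's
bottom-half-burden candidates — the operational stand-in for "the
average profile of the sample's normal cells" that requires no truth
labels.

The default decision rule is the median conjunction (strict
inequalities, fixed for determinism): malignant iff above the median
correlation to the aberrant pole and below the median correlation to
the normal pole, both medians taken over the classified set. The rule
can call at most ~50% of cells malignant per condition; the conjunction
does much better on nulls (≈ 5–7% called, uncorrelated with truth). The
alternative `mean_sd` rule places the cutoffs at mean + k·SD
(aberrant axis) and mean − k·SD (normal axis), k = 2 by default; the
directionality of the published mean ± 2SD limits is not recoverable, so
this implementation documents its choice rather than claiming fidelity.
Constant (all-zero) profiles get r = 0 and can never be called
malignant — a flat profile is the definition of "no aberration".
Classification is per sample; a pooled mode exists for small samples.

Measured on the standard scenario (3,000 cells, 20% malignant, 1.5×
gain + 0.5× loss of 200 genes each): sensitivity ≥ 0.93 and specificity
≥ 0.94 across 8 seeds; with no planted segments, |phi| against truth
< 0.07 and < 7% of cells called. Median sensitivity rises monotonically
with the planted dosage between 1.2× and 1.8×.

## Signature statistics

Signature scores are computed on the scaled matrix over **all** genes
(not a variable-gene subset), so signature genes are never silently
dropped; missing genes are logged and `n_genes_used` reported. Scores
are linear in the matrix.

Wilcoxon DE: log fold change is ln((mean expm1 + ε)/(mean expm1 + ε)),
ε = 1e-9; genes tested only if |logFC| ≥ 0.25 and expressed in ≥ 10% of
one group. The exact rank-sum distribution is used when both groups have
≤ 25 cells and no ties (matching full enumeration to 1e-9), the normal
approximation with tie and continuity correction otherwise. BH
adjustment runs over tested genes. Conserved markers require adjusted
p < 0.05 with positive logFC in *every* condition; the reported p is the
worst across conditions. Bulk group comparisons use Welch t-tests
(unequal variances; the pooled-variance choice is not recoverable from
convention) with BH across group pairs.

Bulk preparation: each sample's nonzero-count upper quartile is scaled
to the geometric mean of all samples' upper quartiles, then log2(x+1),
then per-gene median centering. The bulk path uses log2 and the
single-cell path natural log, following the conventions of their
respective source workflows.

Ortholog mapping keeps only one-to-one pairs by default (`policy="all"`
keeps every target), preserves signature gene order, deduplicates
targets and reports unmapped genes.

## Composition regression

One-vs-rest Bernoulli GLM per cluster rather than a single multinomial
model: it reproduces per-cluster odds ratios with a simpler, separately
testable likelihood, and without batch terms it is numerically identical
to the closed-form 2×2 contingency odds ratio (verified to 1e-6 on
random tables). Batch enters as fixed effects with within-state
sum-to-zero (effect) coding, so the state coefficient is the state
contrast at the *average* of its batch effects — a marginal-means-style
contrast; with ordinary dummy coding the state coefficient would compare
only the two baseline batches and carry their full batch noise. Two
replicates cannot identify a random-effect variance, hence fixed
effects. Inference is Wald (deterministic, adequate at these cell
counts); BH across clusters within each contrast. Perfect separation
(a cluster absent from a state) falls back to the Haldane–Anscombe
0.5-corrected contingency estimate and is flagged, never fatal.

## Subtyping

Gene-median centering (idempotent) followed by nearest-centroid
correlation over the genes shared with the centroid model. Spearman is
the default metric — the classical intrinsic-subtype predictors are
rank-based, and rank correlation is invariant to monotone transforms of
the sample vector — with Pearson available for sensitivity analysis.
`min_overlap` defaults to half the model's genes to guard against calls
from meaningless overlap. Centroid values are an external input; the
test fixtures derive synthetic centroids from the bulk generator's
expected log profiles, which stand in for a published predictor without
embedding third-party data.

## What the validation shows, and what it does not

All recovery results are against the generator above. It reproduces the
features the methods rely on — genome-contiguous dosage effects,
cell-type marker structure, batch offsets, overdispersed counts,
mitochondrial artifacts — but not ambient RNA, doublets, UMI saturation,
gene-length effects, gene-specific dispersion, subclonal CNA
heterogeneity, or realistic chromosome lengths. Passing tests therefore
demonstrate that the implementations are correct and that the procedures
recover planted structure under the stated noise model; they do not
certify performance on any particular real dataset. In particular, real
malignant populations are subclonal and their "normal" cells are a
mixture of epithelial subtypes, both of which blur the dual-correlation
separation relative to the clean two-cloud geometry seen here.

## Fixture scales

Test and acceptance fixtures run at 2,000 genes and 300–5,000 cells per
sample, 2,000–4,000 cells per state for composition, and 20 bulk
samples — sizes chosen so the full validation completes in minutes on a
single CPU while keeping every statistical check comfortably powered.
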