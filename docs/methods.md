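# Methods

## The problem

Some sequence-specific transcription factors (TFs) establish or maintain
open chromatin at their binding sites — chromatin accessibility
regulators (CARs), of which pioneer factors (able to engage nucleosomal
DNA) are the best-known subclass.  Knock-down screens identify CARs one
TF at a time; `carscan` instead infers them statistically from two
genome-scale observations collected over the same panel of cell lines:
open-chromatin peak maps (e.g. DNase-seq) and gene expression.  The
premise is that if a TF keeps chromatin open, cell lines expressing more
of it should show more open chromatin around its binding motif.

## Motif accessibility scores

For each cell line, peaks are trimmed to the top `n_top` (default
90,000) by signal so cell lines are comparable in total open coverage.
For each TF binding motif, the score is the number of retained peaks
overlapping at least one genome-wide motif instance (half-open BED
coordinates, ≥1 shared base, strand ignored; instances come from an
upstream motif scan thresholded at p < 1e-5).  Motifs found in fewer
than 150 peaks on average across cell lines are dropped as
uninformative.  Counting uses merged sorted instance blocks and one
binary search per peak, O((n+m) log m) per pair.

The count matrix is then normalized in four stages:

1. per-motif rank-based inverse-normal transform (rankit offset
   (r−0.5)/n, ties share average ranks);
2. bi-standardization — alternating row and column centering/scaling
   (population sd) until all row/column means are 0 and sds 1 within
   1e-8 (warn after 100 sweeps);
3. removal of the leading principal component of the cell-line
   covariance.  In real accessibility panels this component is dominated
   by assay batch rather than tissue identity; each motif row is
   replaced by its component orthogonal to the leading eigenvector.
   This stage is optional (`remove_pc=False` gives the plain
   mixed-model variant);
4. a final per-motif inverse-normal transform, so every response vector
   fed to the model is exactly a permutation of the Gaussian grid.

Expression matrices are replicate-averaged (arithmetic mean per cell
line), then bi-standardized.  RNA-seq counts are first filtered (mean
count strictly above 50), log(count+1)-transformed and
quantile-normalized to the mean order-statistic distribution; ties
within a sample receive the mean of the reference quantiles they span.

## The mixed model

For motif accessibility y and gene i's expression x_i across n cell
lines:

    y = x_i β_i + δ_i + ε_i,   ε_i ~ N(0, σ_r² I),   δ_i ~ N(0, σ_e² C_e),

with C_e = (1/p) Σ_i x_i x_iᵀ the cell-line covariance of the
standardized expression matrix.  The random effect absorbs whatever
structure is shared across the whole transcriptome — cell-line
relatedness, batch — which is exactly the confounding that inflates
naive per-gene regression.

Estimation is maximum likelihood in the eigenbasis of C_e = U S Uᵀ.
After rotating by Uᵀ the covariance is diagonal,
σ_r² (λ S_j + 1) with λ = σ_e²/σ_r², so for fixed λ both β and the
scale have closed forms, leaving a 1-D search over λ: 64 log-spaced
grid points in [1e-5, 1e5] followed by bounded refinement of every
local minimum of the grid profile (the profile can be bimodal; refining
only the global grid bracket occasionally returns a slightly
sub-optimal mode).  Endpoints make the pure-OLS (σ_e²→0) and
pure-random-effect limits reachable.  The profiled residual variance is
floored at 1e-300 so noiseless inputs keep a finite log-likelihood.

β_i = 0 is tested by a likelihood ratio test on a χ²₁ reference (one
extra df per additionally tested covariate); variance components are
re-estimated under the null.  Because the null depends only on y, it is
fitted once per motif and reused across all genes.  No intercept is fit
by default — both sides are standardized upstream — and no boundary
correction is applied since the tested parameter is the fixed effect,
not a variance component.  Optional fixed covariates (e.g. the same
motif's accessibility in a second assay modality) are profiled jointly.

The comparator `ols_pvalues` is the per-gene no-intercept t-test that
demonstrates the inflation the random effect removes.

## CAR ranks

Gene level: the CAR rank of a motif is the competition rank (ties share
the minimum rank) of its annotated TF's association p-value among all
genes.

Subfamily level: homologous TFs bind nearly identical motifs, so
associations are aggregated over TFClass-style subfamilies.  For each
(motif subfamily M, TF subfamily T) the score is
min{p(m,t): m∈M, t∈T} × |pairs|, a Bonferroni-style size correction
(values may exceed 1; only ranks are consumed).  The subfamily CAR rank
is the rank of M's own TF subfamily among all TF-subfamily columns;
pairs with no expressed member are excluded from the domain rather than
imputed.  The ranking domain is all TF subfamilies with expression
data, not only motif-bearing ones.

The enrichment curve reports, per rank cutoff r, the fraction of tested
subfamilies at or below r and its ratio to the uniform expectation
r/domain; the k-fold threshold (default k=10, equivalent to a 10% false
discovery proportion under uniformity) is the largest r still k-fold
enriched.  The genome-wide Bonferroni scan uses α divided by
(#motifs × #genes) — 344 × 15,119 at α=0.05 gives 9.6e-9 — and reports
hits with their effect signs, since repressive (negative-β)
associations occur.

## Pioneer enrichment

Given an external pioneer annotation, three tests:

* hypergeometric upper tail on the count of pioneer subfamilies with
  CAR rank below the 10-fold cutoff;
* rank-sum permutation: the statistic is the sum of pioneer CAR ranks;
  each of 50,000 permutations draws the same number of ranks without
  replacement from non-pioneer subfamilies.  p uses the +1 correction
  and the *lower* tail by default (small rank sums = enrichment); the
  literal upper tail is available via `tail="upper"`.  When the draw
  space is smaller than the permutation budget the test enumerates all
  subsets exactly;
* variance-matched permutation: because the method favours TFs with
  variable expression, null draws are stratified on the pioneer set's
  own maximal-expression-variance distribution — per-TF variances are
  inverse-normal transformed, each subfamily keeps its maximum, and
  each permutation draws ⌈k/2⌉ subfamilies from the [min, median] and
  ⌊k/2⌋ from the [median, max] pioneer-variance stratum (boundaries
  inclusive; a subfamily sitting exactly on the median is eligible for
  both strata but is never drawn twice within one permutation).

`combine_rank_lists` merges two rank lists (e.g. CAR ranks with an
external pioneer score) by re-ranking each with the min-tie rule on the
shared universe and taking the per-subfamily maximum, so a low combined
rank requires agreement; `precision_recall` sweeps rank thresholds
against a truth set.

## ChIP-seq validation

`bound_motif_enrichment` partitions DHS peaks by ChIP-peak overlap and
returns the ratio of motif-containing fractions (bound over unbound).
`tpr_guided_cutoff` sweeps the observed best-motif p-values per peak
(recorded only below the 5e-5 scan ceiling) and returns the largest
cutoff at which the bound fraction among motif-bearing peaks still
meets the target validation rate (0.3/0.5/0.7 are the conventional
targets); an unreachable target returns a typed sentinel, and
per-experiment cutoffs are summarized by the median (midpoint for even
counts).  Candidate cutoffs are restricted to observed values because
the bound-fraction step function only changes there.

## Synthetic data

The matrix-level generator draws latent confounders z_k ~ N(0,1) per
cell line and lets them drive *both* modalities: gene expression
x_g = γ_g·z + noise and motif accessibility
y_m = α·x_tf(m)·[planted] + w_m·z + noise.  Loadings are scaled so the
confounder component has variance `confounder_strength`² (default 1,
i.e. confounding as strong as the independent noise).  TF genes are
grouped into subfamilies of 4 sharing an extra latent factor (loading
0.6), mimicking correlated homolog expression; each motif is annotated
to the first TF of its own subfamily.  Defaults are n_cells=100,
48 TF genes, 150 additional genes, 12 motifs, 4 confounders, α=0.8 for
planted effects.  The 150-gene panel keeps the generator in the regime
the method assumes — more genes than cell lines, so C_e is a
well-estimated covariance; the real data had 15,119 genes across 109
cell lines.  A monotone discretization (`as_counts=True`) produces
integer matrices for the raw-count pathway.  The BED-level generator is
separate (statistics tests never pay interval-processing cost) and
ships a brute-force expected-count table beside the interval files; all
parameters and the seed are serialized so regeneration is
byte-identical.

What the generator does *not* emulate: genome sequence content and PWM
energetics, microarray probe noise, peak-calling artifacts, and the
heavy-tailed, tissue-clustered covariance of real cell-line panels.
Passing tests therefore demonstrate correctness of the statistical
machinery under the model's own assumptions, not performance on real
ENCODE-scale data.

## Packaged experiments and problem sizes

`experiments.null_calibration` measures type-I error on 2,000
independent confounded null pairs (n_cells=100, generator defaults):
the mixed-model rate at nominal 0.05 lands inside the binomial 99% CI
while the naive-regression rate is several-fold inflated.
`experiments.planted_recovery` runs the full pipeline (normalization,
association against all TF genes with C_e from the full panel,
subfamily aggregation) on 25 replicates with one planted subfamily,
at α=0.8 and again at α=0 for the uniformity control.  These sizes are
the package's chosen simulation scale; they complete in a few minutes
on one core.

## Numerical choices and limitations

* Convergence: bi-standardization tol 1e-8, max 100 sweeps;
  λ-refinement xatol 1e-8 in log-λ.
* Ties: competition/min ranks everywhere (configurable to average);
  floating-point p-value ties are not perturbed.
* Degenerate inputs: constant vectors are rejected by the INT; constant
  gene rows are dropped with a log message; a degenerate leading
  eigenpair only warns (the projection is still well defined up to the
  eigenspace).
* The LRT is mildly anti-conservative in small samples: at n=100 the
  χ²₁ reference alone gives ≈0.052 at nominal 0.05, and estimating C_e
  from a small gene panel adds to this (≈0.06 at 162 genes in the
  calibration study).  Both effects shrink with more cell lines and
  more genes; with transcriptome-scale panels the reference is
  accurate.
* Permutation p-values are never 0 (+1 correction) and are exact
  whenever the draw space fits the permutation budget.
* Stage orchestration in the CLI is deliberately stateless: a stage
  requires its inputs to exist and overwrites its outputs; the resolved
  config echoed into the output directory is sufficient to rerun
  everything.
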