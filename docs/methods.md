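# Methods

This note documents the statistical models the package implements, the
generative design of the synthetic data, the numerical choices, and what the
passing tests do and do not establish about real data.

## Measurement scales

Array methylation is carried as β (methylated fraction, [0, 1]) with `NaN`
for missing; modelling steps that assume additivity (batch adjustment, PCA,
peak correction) work on M-values, M = log₂(β/(1−β)), and convert back.
Missing β is encoded `NA` on disk. WGBS coordinates are 1-based inclusive,
matching Bismark coverage output; interval logic converts to half-open
internally and back on output.

## Pre-processing chain

The QC order mirrors the array-study convention: probe/sample exclusions
(with a sequential ledger whose remaining counts must always reconcile with
the matrix shape), kNN imputation, empirical-Bayes batch adjustment, then
type-II peak correction. "Not detected" is operationalised as the
missing-value fraction — detection p-values require raw intensities, which
are out of scope — with strict-inequality thresholds (a probe missing in
exactly 20% of samples is kept). Whether imputation should precede or follow
batch adjustment is genuinely ambiguous in practice; both orders are
possible with this API, and the examples impute first so the batch model
sees a complete matrix.

**kNN imputation** uses probe-space neighbours: rows are probes, distances
are nan-aware Euclidean over shared samples (scaled by the fraction of
usable coordinates, the scikit-learn convention), and the imputed value is
the unweighted mean of the k = 10 nearest probes' values in that sample.
k = 10 is the common default for methylation arrays; the method contract
only names nearest-neighbour averaging.

**Batch adjustment** (`combat_adjust`) is the parametric empirical-Bayes
location/scale model: per-probe standardisation against the batch-design
fit, a normal prior on standardised batch means and an inverse-gamma prior
on batch variances with method-of-moments hyperparameters, posterior
estimates by the usual fixed-point iteration (relative convergence 10⁻⁴),
shrunken effects removed, and data rescaled. After rescaling, each probe is
recentred so its pooled mean is preserved exactly — shrinkage otherwise
perturbs it by a small seed-dependent amount. The implementation is
cross-checked in the test suite against Bioconductor's `sva::ComBat` on a
fixture (agreement ~10⁻⁶ after removing the recentring). Singleton batches
are an error; a single batch is a no-op.

**Peak-based type-II correction** estimates, per sample, the unmethylated
and methylated density modes of type I and type II probes separately on the
M scale — binned Gaussian kernel density with fixed 0.5 M bandwidth, taking
the two highest local maxima at least 2 M apart — and linearly maps the
type II modes onto type I's. Type I is never altered. A unimodal sample is
an error naming the sample. The correction is idempotent to well under
10⁻³ M because a corrected sample's modes already coincide. Any alternative
β-normaliser (e.g. a quantile-mixture method) can be substituted through
`apply_type2_normalization`.

## Cell-type handling

The discriminating-probe filter regresses β on a purified-type-vs-baseline
indicator per probe — with two groups this is the pooled-variance t-test,
and the closed form is used — flagging probes with p < 10⁻⁷ **and**
|Δβ| > 0.05. The Δβ criterion is applied as an absolute value. The baseline
is the pooled PBMC pseudo-type when the panel has one, else the
replicate-wise panel average (configurable — the right baseline for
granulocytes is genuinely unclear). Proportion estimation solves
min ‖Pᵀw − y‖² subject to w ≥ 0, Σw ≤ 1 (non-negative least squares start,
SLSQP refinement, ftol 10⁻¹⁴), reporting the residual norm; rank-deficient
references are an error.

## Exposure construction

The exposure is the per-sample arithmetic mean (or median) β over a probe
subset. Quartile boundaries are linear-interpolation sample quantiles of
the **control** distribution (no quantile rule is canonical; interpolation
is the numpy default), all samples are labelled against them, and boundary
ties go to the lower quartile. The pseudo-continuous variable assigns each
sample the median of its quartile's control values, then standardises by
the control-only mean and SD of the per-sample summary — control-only so
the exposure scale is defined without reference to outcome; `sd_scope="all"`
is available. Quartile labels are invariant to monotone transforms for
control samples; a non-control value lying strictly between adjacent
control order statistics can shift, a side effect of interpolated
boundaries.

## Matched-pair risk models

1:1 conditional logistic regression maximises ∏ expit(dᵢ′β) over within-pair
differences dᵢ (case − control) by Newton–Raphson with step halving, to
score norm < 10⁻⁸. Age enters as the within-pair age difference (matching
is to within a few years, leaving residual differences). Separation —
all informative exposure differences of one sign, or diverging estimates —
raises an explicit error rather than returning a huge finite coefficient.
A zero-variance difference column is reported with coefficient 0 and
infinite SE rather than failing the whole fit. Wald inference throughout,
with z = 1.959964 for 95% intervals.

The spline risk-distribution model fits the conditional likelihood on a
cubic B-spline basis of the continuous exposure (interior knots at exposure
quantiles, df = 4 by default). Because the basis sums to one, constants
cancel within pairs and the difference matrix is rank-deficient; the fit is
performed in the singular-value row space with unit column scaling and
mapped back. Per-subject log relative risk is the fitted linear predictor
centred at the population mean (median available), and the reported range
is the 2.5th–97.5th percentile of RR across subjects.

Companions: robust (pair-clustered sandwich) logistic regression as a
confirmation analysis; paired Wilcoxon with the exact sign-flip null for
n ≤ 25 (dynamic programming over doubled mid-ranks, so ties are exact too)
and the tie- and continuity-corrected normal approximation above; AUC as
Mann–Whitney concordance with DeLong variance; stratum heterogeneity by
Cochran's Q over stratum log-ORs (the conventional choice where the test
behind a printed heterogeneity p is unnamed); two-sample KS with asymptotic
p.

## Probe-wise EWAS

Stage 1 fits, per probe, a beta-distributed-response GLM (logit mean link,
single precision φ) on chip and chip-position factors by Fisher scoring
(score norm < 10⁻⁸, β clamped to [10⁻⁶, 1−10⁻⁶] for finite likelihood) and
takes response residuals (standardised residuals available). The
implementation matches `statsmodels` `BetaModel` to ~10⁻⁴ on fixtures and
exists in-package because the scan needs thousands of fast per-probe fits.
With no technical variation, stage 1 reduces to centring each probe — an
identity the test suite asserts against the full path.

Stage 2 is a Poisson GLM of the case indicator with log person-years offset
and age at blood draw (linear), fitted by batched IRLS across probes; on
simulated exponential-hazard survival data its coefficient tracks the true
log hazard ratio, the Cox-like property that motivates the
parameterisation. One calibration caveat is inherent to the design: with a
nested case-control sample, roughly half the subjects are cases, so the
Poisson variance (μ) exceeds the binary outcome's variance (μ(1−μ)) and
Wald p-values are conservative — family-wise error of the Bonferroni scan
sits well below the nominal α rather than at it. Per-probe failures are
flagged and skipped; the scan continues and reports the failure count and
the hypo-/hyper-methylation direction tally among significant probes.

## Pooled WGBS

Raw mean methylation across CpGs depends on coverage, so per-site fractions
get coverage weights: w = 1 at or above the pool-wide median coverage
(equality takes full weight — the boundary site should not be penalised;
switchable), then 1 − 0.1k where k counts **complete** 10%-of-median
decrements below the median (a started-decrement mode is provided, the
wording "0.9, 0.8, 0.7, etc." admitting either), floored at 0. Decrements
are computed in exact rational arithmetic of read counts so boundaries are
never blurred by floating point. The median is computed once per pool,
before any feature subsetting. Feature summaries use 1-based inclusive
intervals; pool contrasts average each arm's pools unweighted and report
case − control in percentage points.

## Meta-analysis

Study SEs are recovered from 95% CIs as (ln U − ln L)/(2 × 1.959964);
heterogeneity is Cochran's Q on k−1 df; pooling is DerSimonian–Laird with
τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)) and random-effects weights
1/(SE² + τ²), without the Knapp–Hartung small-sample adjustment (matching
the default of the classic meta-analysis tooling this mirrors). A
zero-width CI yields SE 0 and is rejected by the downstream checks as
degenerate.

## Synthetic data: what it emulates and what it does not

Per-probe baselines come from a three-component logit-scale mixture
(unmethylated/intermediate/methylated modes at −2.8/0/2.2 with
category-dependent weights), so islands are mostly low-β and
shelf/open-sea probes mostly high-β, giving the familiar bimodal marginal.
Subject values add, on the logit scale: a per-subject **global methylation
offset** (pair-shared SD 0.008 plus individual SD 0.055) scaled by island
relation (islands damped ×0.3, shores ×0.6, shelf/open sea ×1) — the
between-subject epigenome-wide variation that the mean-β exposure measures;
per-probe pair-shared and individual noise (SD 0.15 each); chip-batch ×
probe offsets (SD 0.10, 8 chips, whole pairs sharing a chip); and optional
explicit case shifts by category. Case status within a pair is assigned
from the conditional-logistic model P(member 1 is the case) =
expit(b·(x₁−x₂)) on the standardized per-sample mean β, so the injected
per-SD log-odds b is exactly the estimand of the downstream matched
analysis.

The default parameters were calibrated once, jointly, to the study-level
conditions being emulated: per-SD OR 0.61; control SD of per-sample means
≈ 0.4 percentage points; genome-wide case deficit ≈ 0.2 pp concentrated in
gene-body/shelf/open-sea probes; AUC of mean methylation ≈ 0.62. These
four are mutually consistent under the single assignment mechanism —
a −0.5 SD marginal case-control separation yields both the ≈0.2 pp deficit
and AUC ≈ 0.62 — which requires the within-pair correlation of the global
offset to be low; matching on age and recruitment factors plausibly
controls little of a subject's global methylation level. Within-pair
correlation is exposed (`global_pair_sd`, `global_subject_sd`) rather than
asserted.

WGBS pools draw per-site depth from a negative binomial (mean = target
depth, dispersion 20 — mild overdispersion; only the target coverage is
given by the emulated design) and methylated reads binomially; the case
pool's true methylation is shifted additively at gene-body sites. The
reference panel plants exactly `n_discriminating` probes with ±0.2 β
shifts (directed away from the nearer bound) against a shared base profile,
replicate noise SD 0.01, six replicates.

Not emulated: raw fluorescence intensities, SNP artefacts under probes,
genomic autocorrelation of methylation, cell-composition differences
between cases and controls, non-random missingness, and tumour-tissue
methylation. Passing tests therefore establish that the estimators recover
what the generative model injects at the stated sizes — not that real blood
methylation satisfies the model.

## Problem sizes used in tests and the acceptance script

Simulated studies use 150–2,000 probes; per-sample mean statistics
stabilise long before array scale, so these sizes measure the same
estimands with more Monte Carlo replicates per minute. The standard runs:
effect recovery at 500 pairs × 200 replicates; type-I error at 200 pairs ×
2,000 replicates; probe-scan family-wise error at 162 pairs × 1,000 probes
× 500 replicates; batch efficacy over 100 simulations; WGBS contrasts over
four matched pool pairs × 100,000 sites at 50× (mirroring the four-pool
design, with Monte Carlo error ≈ 0.015 pp).

## Known limitations

- The Poisson offset device is conservative at high event fractions (see
  above); it is implemented as specified rather than replaced by a
  conditional or Cox fit.
- Beta regression uses a constant precision φ; precision covariates are not
  supported.
- `estimate_cell_proportions` does not propagate reference uncertainty.
- The exclusion-ledger API records counts; it does not itself verify that
  the named exclusion reasons are disjoint.
- Quartile labels of non-control samples can shift under monotone
  transforms (interpolated boundaries); control labels cannot.
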