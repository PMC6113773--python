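# Methods

## Scope and data model

The package implements the statistical chain of a large case-control
fracture GWAS and its downstream causal-inference analyses: per-study
genomic control, fixed-effects meta-analysis across stages, LD score
regression, instrument selection, and a two-sample Mendelian
randomisation (MR) suite.  The unit of exchange is a validated per-SNP
summary-statistics table (rsID, alleles, effect-allele frequency, beta,
standard error, p, sample size); individual-level data appear only
inside the synthetic-data generator.  Only biallelic A/C/G/T SNPs are
accepted; indels and multi-allelic records are dropped at read time.
Matching across tables is by rsID, not position, because published
instrument lists are rsID-keyed.

## Harmonisation

Exposure and outcome effects are aligned to the exposure's effect
allele. A swapped allele pair (directly or after strand complementing)
flips the outcome beta and complements its frequency.  Strand-ambiguous
(A/T, C/G) SNPs cannot be oriented from alleles alone: those with
either frequency within a configurable window of 0.5 (default 0.08)
are excluded; outside the window they are oriented by frequency
concordance.  The default window is conservative — the source analyses
do not state their convention — and every exclusion is logged with its
reason.

## Genomic control and pooling

λ is the median association χ² divided by the χ²₁ median (0.454936…
internally; 0.455 at reporting precision). Correction (se × √λ, p
recomputed) is applied only when λ > 1, per input study and never to
the pooled result; whether the original analysis applied a second
round of control to the meta-analysis is not stated, so the default
here is no.  Pooling is fixed-effects inverse-variance with Cochran's
Q and I²; the 95% normal quantile is fixed at 1.959964 so printed
confidence intervals reproduce at stated precision.  Published stages
available only as `OR (95% CI)` cells are converted to standard errors
from the log-scale CI width; a robust variant (largest one-sided
half-width) handles typographically inconsistent cells, which the
packaged locus table contains two of.  Comparisons against printed
values round half-away-from-zero to the table's precision.

## Instrument selection

Gates are p < 5×10⁻⁸ and minor-allele frequency strictly above 5%.
Clumping is greedy on ascending p (ties broken lexicographically by
rsID for platform-independent determinism): a SNP is kept iff its r²
with every previously kept SNP is ≤ 0.05 — the boundary value is
retained because the grouping criterion is stated as r² > 0.05.  The
LD matrix is an explicit input (file or simulated); no reference panel
is fetched.  The greedy rule is provably the lexicographically-first
maximal low-LD subset under the p-ordering, which the tests verify
against brute-force enumeration.

## MR estimators

* **Wald ratio** `b_Y/b_X` with first-order delta-method standard
  error `se_Y/|b_X|`; this matches the inverse-variance weighting used
  by IVW.  A second-order option adds the exposure-uncertainty term.
* **IVW** is fixed-effects with no residual overdispersion scaling, as
  the source tables specify; inference is normal.
* **MR-Egger** orients all instruments to non-negative `b_X` (joint
  sign flips; required for the intercept to measure *directional*
  pleiotropy), then fits weighted least squares with weights
  `1/se_Y²`.  Inference uses the t distribution on k − 2 degrees of
  freedom with residual-variance-scaled standard errors.  Requires
  more than two instruments.
* **Weighted median** sorts per-SNP ratios, forms normalised
  cumulative weights and interpolates at 0.5 with the midpoint
  convention `s'_j = s_j − w_j/2`.  Standard errors are the standard
  deviation of seeded parametric-bootstrap replicates (default 1000)
  that redraw `(b_X, b_Y)` from their normal errors.
* **Penalised weighted median** multiplies weights by
  `min(1, 20·q_j)` where `q_j` is the χ²₁ upper-tail probability of
  the per-SNP heterogeneity `Q_j = w_j (r_j − β_anchor)²`.  The anchor
  is the weighted-median estimate, not IVW: anchoring at IVW lets a
  single outlier drag the anchor and penalise precise *valid*
  instruments, which in Monte-Carlo makes the penalised estimator
  worse than the plain median; the robust anchor restores the intended
  dominance.  The penalty scale (20) and anchor are configurable.

Binary exposures are rescaled per doubling of the odds of the exposure
disease by multiplying the causal log-effect, its standard error and
CI bounds by 0.693 — the conventional printed constant, applied as
printed rather than as ln 2 (the difference is below reporting
precision); z-statistics and p-values are unchanged.  Bonferroni
significance uses strict `p < 0.05/n_tests` (15 MR exposures → 3.3×10⁻³;
12 genetic correlations → 4.2×10⁻³).  Power for a binary outcome uses
the non-centrality `ln(OR)·√(N·R²_GX·K(1−K))`.

## LD score regression

LD scores are r² row sums including the diagonal.  The single-trait
fit regresses χ² on ℓ, the cross-trait fit regresses `z₁z₂` on ℓ; both
use `1/ℓ` weights in a single step — a deliberate simplification of
the original method's iterative variance-based weighting.  Heritability
is `slope·M/N`; genetic covariance `slope·M/√(N₁N₂)`; the intercept
absorbs confounding (single-trait) or sample overlap (cross-trait).
Standard errors are a delete-one block jackknife over 20 contiguous
SNP blocks; the whole rg ratio is jackknifed, not just the slope.
rg outside [−1, 1] is clamped with a warning and the raw value kept.
Null calibration shows the simple weighting leaves the slope jackknife
mildly anticonservative (observed t-spread ≈ 1.2 under the null), a
consequence of heavy-tailed χ² influence; the intercept and rg
jackknives are well calibrated, which is what the recovery checks rely
on.

## Synthetic data

The generators are pure functions of (parameters, seed); all
randomness flows from one master seed through named substreams, so any
stage can be regenerated in isolation bit-identically.

* **Cohort GWAS**: genotypes from autoregressive LD blocks
  (correlation ρ^|i−j| via a Gaussian copula per haplotype); case
  status from a logistic model with sex, age, age², height and weight
  covariates plus specified per-allele effects; cases/controls sampled
  from an oversized pool; one covariate-adjusted logistic regression
  per SNP fitted by iteratively reweighted least squares (tolerance
  1e-8, capped iterations; non-converged SNPs dropped), cross-checked
  against a reference logistic implementation in the tests.
* **Two-sample MR**: instrument effect magnitudes uniform on
  [0.03, 0.15] per allele on a unit-variance exposure, random signs by
  default (`positive_bx` emulates effect alleles pre-oriented to
  increase the exposure — the convention under which directional
  pleiotropy is directional).  Outcome effects are
  `β b_X + α`, with α zero for valid instruments and
  Normal(mean, sd²) for the invalid fraction; an optional correlation
  knob couples α with |b_X| to violate InSIDE.  Sampling noise uses
  the two samples' sizes, with the binary-outcome variance at case
  fraction K (default 0.33, the fracture study's combined proportion).
  Calibration scenarios use an exposure sample of 200 000 so every
  simulated instrument is strong at genome-wide significance, as real
  instruments are by construction.
* **Polygenic pair**: per-SNP true effects bivariate normal with
  variances h²/M and correlation rg; z-scores add LD tagging through
  the signed block correlation matrix and residual noise whose
  cross-trait correlation is n_shared/√(N₁N₂), reproducing the
  overlap-inflated intercept.  The default LD architecture cycles
  block specs (1, 0.0), (5, 0.4), (20, 0.6), (50, 0.9): a mixture is
  needed because a homogeneous architecture leaves the LD-score
  regressor with too little spread to identify the slope.

What the generators do **not** emulate: genome-scale SNP counts (10⁶),
family structure, imputation uncertainty, allele-frequency
misspecification between samples, selection/winner's-curse effects on
instrument discovery, and real LD panels.  Passing tests therefore
demonstrate correctness of the statistical machinery under its own
model assumptions, not robustness to those real-data complications.

## Problem sizes and numerical choices

Default simulation sizes are chosen so each analysis identifies its
parameters comfortably: 500 Monte-Carlo replicates of 20-instrument MR
per calibration scenario; 5 000 SNPs and N = 50 000 per trait for LD
score regression; 400-SNP two-cohort GWAS (1 000 cases/1 000 controls
each) for genomic-control calibration; discovery-like 6:1
control:case imbalance scaled to 2 000 cases for effect recovery.
Degenerate inputs are handled explicitly: empty estimator inputs,
exposure effects of exactly zero, fewer SNPs than jackknife blocks and
non-positive estimated heritability (rg flagged undefined rather than
returned) all raise or flag rather than propagate NaNs.

## Known limitations

Single-step 1/ℓ LDSC weighting (no iterative reweighting, no
partitioned heritability); no PLINK-style positional clumping windows;
no MR-PRESSO/mode-based/multivariable estimators; published real-data
genetic correlations and power percentages are not reproducible here
because they require external full summary statistics and unprinted
R²_GX inputs — they are covered by parameter-recovery simulations
instead.
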