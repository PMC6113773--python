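# osteomr

Statistical machinery for fracture genetics: multi-stage fixed-effects
GWAS meta-analysis with genomic control, LD score regression for
heritability and genetic correlation, and a two-sample Mendelian
randomisation (MR) estimator suite — built for epidemiologists and
statistical geneticists who want each step of the published fracture
GWAS + MR analysis chain as tested, reusable code, exercised on
synthetic data with known ground truth and on the published stage-level
estimates.

## Methods at the core

**Fixed-effects meta-analysis.** Stage estimates `b_i` with standard
errors `se_i` are pooled with inverse-variance weights `w_i = 1/se_i²`:

    b = Σ w_i b_i / Σ w_i ,   se = 1/√(Σ w_i)

with Cochran's `Q = Σ w_i (b_i − b)²` and `I² = max(0, (Q − (k−1))/Q)`.
Before pooling, each study is corrected by genomic control:
`λ = median(χ²)/0.455`, and when `λ > 1` every standard error is
inflated by `√λ`.  Published stages printed only as `OR (95% CI)` are
re-entered via `se = (ln CI_hi − ln CI_lo)/(2·1.959964)`.

**LD score regression.** Under a polygenic model
`E[χ²_j] = 1 + N h² ℓ_j / M`, where `ℓ_j = Σ_k r²_jk` is SNP j's LD
score. Regressing `χ²` on `ℓ` separates polygenic signal (slope, scaled
to `h²`) from confounding (intercept); regressing `z_1 z_2` on `ℓ`
gives the genetic covariance, and `r_g = cov_g/√(h₁² h₂²)`. Standard
errors come from a 20-block jackknife.

**Two-sample MR.** With per-SNP exposure effects `b_X` and outcome
effects `b_Y`, the suite provides the Wald ratio `b_Y/b_X`, the
fixed-effects IVW estimate `Σ b_X b_Y/se_Y² / Σ b_X²/se_Y²`, MR-Egger
regression (free intercept = directional pleiotropy), and the weighted
and penalised weighted median estimators (bootstrap standard errors).
Instruments are selected at `p < 5×10⁻⁸` and MAF > 5%, greedily clumped
at `r² ≤ 0.05` keeping the lowest-p SNP per group; binary exposures are
rescaled per doubling of odds (×0.693); Bonferroni correction uses
0.05/15 for MR and 0.05/12 for genetic correlations.

## Worked example

Simulated genetic correlation recovery (`python analysis/04_ldsc_recovery.py`):

```
         quantity  estimate     se  truth
               rg   -0.5963 0.0642   -0.6
        h2_trait1    0.3403 0.0369    0.3
     rg_intercept    0.4316 0.6692    0.0
null_h2_intercept    0.9910 0.0382    1.0
```

Two traits simulated with heritability 0.3 each and genetic correlation
−0.6 over 5 000 LD-structured SNPs: the cross-trait regression recovers
`r_g = −0.60 ± 0.06`, and the null single-trait intercept sits at 0.99,
the signature of a well-calibrated GWAS.

Two-sample MR at the published headline effect
(`python analysis/02_two_sample_mr.py`): 43 strong valid instruments
simulated with a true causal odds ratio of 1.55 per SD decrease in bone
density give

```
  method  n_markers  odds_ratio             ci   egger_intercept
     ivw         43       1.550 (1.53 to 1.57)               NaN
   egger         43       1.583 (1.52 to 1.65)           -0.0021
 wmedian         43       1.547 (1.51 to 1.58)               NaN
pwmedian         43       1.548 (1.51 to 1.59)               NaN
```

— all four estimators agree with the generating truth and the Egger
intercept is compatible with zero (no simulated pleiotropy).

The other numbered scripts under `analysis/` recombine the packaged
published locus table (01), calibrate the estimator suite over 500
Monte-Carlo replicates (03) and check the cohort-level GWAS simulator's
genomic-control behaviour (05); each writes its table under `results/`.

## Command line

```sh
osteomr simulate mr --seed 7 --out sim/         # synthetic exposure/outcome pair
osteomr clump --sumstats sim/exposure.tsv --ld sim/ld.tsv --out instruments.tsv
osteomr mr --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
           --ld sim/ld.tsv --seed 7 --out mr_results.tsv
osteomr meta --inputs cohort_1.tsv cohort_2.tsv --gc --out combined.tsv
osteomr run --config run.yaml                   # full configured pipeline
```

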