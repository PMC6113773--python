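# Packaged reference tables

Stage-level estimates transcribed verbatim from the published fracture
GWAS and Mendelian randomisation study this pipeline re-implements.

- `fracture_loci_stages.tsv` — the fifteen genome-wide-significant fracture
  loci with per-stage odds ratios, 95% CIs and p-values (discovery:
  37 857 cases / 227 116 controls; replication: 147 200 / 150 085;
  combined: 185 057 / 377 201), combined fracture case counts and I².
  Two replication cells (rs4233949, rs7851693) are internally inconsistent
  as printed (the CI does not bracket the point estimate and has zero
  width); they are kept verbatim and handled by the robust CI-to-SE
  fallback when the table is recombined.
- `fracture_mr_results.tsv` — the reported two-sample MR results for the
  15 clinical risk factors: instrument counts, IVW odds ratio (95% CI, p),
  power to detect OR 1.15 at α = 3.3×10⁻³, and the Egger intercept
  (95% CI, p). Binary exposures are on the per-doubling-of-odds scale.

These are consumed as *inputs* by the recombination and consistency
analyses; nothing in the pipeline reads them to produce its estimates.
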