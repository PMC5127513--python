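# mrkit

Two-sample Mendelian randomisation (MR) at desk scale, built around the
question of whether circulating branched-chain amino acid (BCAA) levels —
isoleucine, leucine and valine — are causally implicated in type 2 diabetes,
or whether their strong observational association reflects confounding and
reverse causality.

MR treats genetic variants as natural instruments: alleles are fixed at
conception, so a variant that raises a biomarker but is otherwise unrelated
to the disease provides a confounding-free handle on the biomarker's causal
effect. `mrkit` implements the full statistical tool-chain around that idea:

- **Summary statistics** (`mrkit.sumstats`): typed per-variant association
  records, tab-delimited readers/writers, odds-ratio/CI conversion to
  log-odds and SE, LD-matrix IO with positive-semidefinite repair, and
  effect-allele harmonisation across files (sign flips, strand complements,
  palindromic-variant policy).
- **GWAS scanning** (`mrkit.gwas`): per-SNP additive linear/logistic scans,
  sample-size-weighted Z-score meta-analysis
  `z = Σ √nᵢ zᵢ / √Σ nᵢ`, greedy lead-SNP selection (p < 5×10⁻⁸ within a
  ±1 Mb window), all-pairs LD pruning (r² < 0.8), and dosage-correlation LD
  estimation.
- **Causal estimation** (`mrkit.mr`): per-instrument Wald ratios
  θⱼ = Γⱼ/γⱼ with first-order SE σⱼ/|γⱼ|, fixed-effect inverse-variance
  pooling (θ̂ = Σwⱼθⱼ/Σwⱼ, wⱼ = seⱼ⁻²), and a correlated-instrument
  generalised-least-squares estimator
  θ̂ = (γᵀΩ⁻¹γ)⁻¹ γᵀΩ⁻¹Γ with Ωⱼₖ = σⱼσₖρⱼₖ, plus sensitivity refits after
  excluding named (e.g. pleiotropic) instruments. Results are log-odds per
  1 SD of exposure, with an odds-ratio view.
- **Observational arm** (`mrkit.meta`): fixed-effect inverse-variance
  meta-analysis of per-SD study estimates with Cochran's Q and I², and a
  genetic-vs-observational concordance report.
- **Genetic scores** (`mrkit.scores`): weighted/unweighted risk scores,
  per-SD scaling, variance explained (R²), heritability fractions (R²/h²),
  and Bonferroni-controlled metabolome-wide specificity scans.
- **Synthetic cohorts** (`mrkit.simulate`): seeded generators for HWE
  genotypes with Gaussian-copula block LD, additive exposures with a shared
  confounder, logistic disease outcomes at a target prevalence, and a fast
  two-sample summary-statistic route — so every stage is testable without
  cohort data.
- **Pipeline** (`mrkit.pipeline` / `mrkit` CLI): a deterministic
  simulate → scan → select → estimate → meta-analyse → report run with a
  reproducibility manifest.

## Worked example

The published lead-variant table for the BCAA genome-wide meta-analysis ships
with the package as example input. Converting the four isoleucine
instruments to Wald ratios and pooling them:

```python
from mrkit import published
from mrkit.mr import ivw_pool, to_or_scale, wald_ratio, exclude_and_refit

pairs = published.instrument_pairs("isoleucine")   # GCKR excluded (pleiotropic)
pooled = ivw_pool([wald_ratio(p) for p in pairs])
print(to_or_scale(pooled))                         # OR per 1 SD isoleucine
```

Running `python examples/01_published_instruments_mr.py` prints:

```
IVW pooled (4 SNPs): OR per 1 SD isoleucine = 1.406 (95% CI 1.202-1.644, p=1.9e-05)
sensitivity (without CBLN1, 3 SNPs): OR = 1.451 (95% CI 1.226-1.716)
valine single-instrument Wald ratio: OR per SD = 1.480
```

i.e. each genetically predicted SD of isoleucine is associated with ~41%
higher odds of type 2 diabetes, robust to removing the CBLN1 instrument.
The other scripts in `examples/` each demonstrate one capability (parameter
recovery on synthetic data, the end-to-end pipeline, specificity scans, the
observational meta-analysis) and print a line explaining their numbers.

## Command line

```sh
mrkit mr --exposure exp.tsv --outcome out.tsv [--ld ld.tsv] [--method ivw|gls] [--exclude rsID,...]
mrkit run --config run.yaml --out results/     # full simulated pipeline
mrkit scan | metaz | leads | prune | ld | meta-obs | score | simulate
```

See `docs/methods.md` for the statistical model, generator assumptions,
numerical choices and limitations.
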