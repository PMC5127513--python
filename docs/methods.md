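# Methods

## Model and estimators

`mrkit` implements two-sample Mendelian randomisation for a quantitative
exposure X (standardised to SD units) and a binary outcome D. Each genetic
instrument j carries two per-allele association estimates: γ̂ⱼ (SNP→exposure,
SD per allele, with standard error se(γ̂ⱼ)) and Γ̂ⱼ (SNP→outcome, log-odds per
allele, with standard error σⱼ). Under the instrumental-variable assumptions
(relevance, independence from confounders, no pathway to the outcome other
than through the exposure), every instrument estimates the same causal
log-odds per SD:

    θ̂ⱼ = Γ̂ⱼ / γ̂ⱼ                    (Wald ratio)
    se(θ̂ⱼ) = σⱼ / |γ̂ⱼ|              (first order)

The first-order SE ignores sampling error in γ̂ⱼ. This is the package
default; `wald_ratio(..., second_order=True)` adds the delta-method term
Γ̂ⱼ²·se(γ̂ⱼ)²/γ̂ⱼ⁴ for users with weaker instruments. With lead-SNP-strength
instruments (γ ≈ 0.07–0.11 SD per allele estimated in ~16,600 individuals)
the first-order approximation is accurate to a few percent, which the
parameter-recovery suite confirms empirically.

Independent instruments are pooled by fixed-effect inverse-variance
weighting (IVW): θ̂ = Σwⱼθ̂ⱼ/Σwⱼ with wⱼ = se(θ̂ⱼ)⁻², se(θ̂) = (Σwⱼ)^(−1/2).
No overdispersion/heterogeneity scaling is applied: the genetic arm reports
a single fixed-effect pooled estimate.

Instruments in linkage disequilibrium violate the independence the IVW
weights assume. The correlated-instrument estimator solves the generalised
least-squares problem with covariance Ωⱼₖ = σⱼσₖρⱼₖ, ρ the LD correlation:

    θ̂ = (γᵀΩ⁻¹γ)⁻¹ γᵀΩ⁻¹Γ,   se = (γᵀΩ⁻¹γ)^(−1/2)

Ω is built from outcome-side SEs only; exposure-side correlation is not
double-counted (standard for this estimator family). With ρ = I the GLS
estimator reduces to IVW exactly, which is property-tested to 1e-10.

The observational arm pools per-study log relative risks per SD by the same
inverse-variance kernel (one pooling function, two entry points; they agree
to 1e-12 by construction) and quantifies heterogeneity by Cochran's
Q = Σwᵢ(θᵢ−θ̂)² and I² = max(0, (Q−(k−1))/Q)·100, truncated at zero. Hazard,
odds and risk ratios are pooled on the log scale as a common "relative
risk"; for an uncommon outcome the three are close, and the approximation is
the price of combining heterogeneous study designs. The genetic and
observational arms are compared descriptively (point estimates, ratio, CI
overlap); no significance test is invented for their difference.

## Harmonisation

Exposure and outcome records are matched by variant id and aligned to the
exposure's effect allele. An outcome recorded on the other allele has its
beta negated and frequency complemented; records on the opposite strand are
resolved through base complementing. Palindromic variants (A/T, G/C) whose
effect-allele frequency lies in (0.42, 0.58) cannot be strand-resolved from
frequency and are excluded under the default policy (`policy="keep"` retains
them, flagged). The window and action are configurable because strand
handling between cohorts is a judgement call; exclusion is the conservative
default. Irreconcilable allele pairs are excluded with a reason code, never
silently.

## Scan, lead selection and pruning

Per-SNP scans fit one additive-coded regression per variant — OLS for
quantitative phenotypes (standardised first, so betas are SD per allele),
logistic for binary ones — and report two-sided p-values from the normal
(Wald) approximation in both models for cross-model consistency. Missing
dosages are mean-imputed per variant. Monomorphic variants and non-converged
logistic fits are flagged untestable instead of raising.

Study-level results are combined by sample-size-weighted Z meta-analysis
(z = Σ√nᵢzᵢ/√Σnᵢ), the appropriate form when effect sizes live on
platform-dependent scales; √n weighting for quantitative traits is
implemented.

Lead SNPs are selected greedily: the smallest p-value strictly below
5×10⁻⁸ claims ±1 Mb around it (the window is interpreted as centred on the
lead; ties broken by chromosome then position). Instrument sets for the
correlated analysis are pruned greedily by ascending p-value so that every
kept pair satisfies r² < 0.8. Both procedures are verified against
exhaustive re-derivations on random instances. No genomic-control correction
is applied.

LD is estimated as the Pearson correlation of mean-imputed dosage vectors
and repaired to positive semidefiniteness by eigenvalue clipping (negative
eigenvalues set to zero, diagonal renormalised to 1); repairs beyond
numerical noise emit a warning. A GLS system whose Ω condition number
exceeds 1e12 raises an error advising stronger pruning rather than returning
a numerically meaningless estimate; the solve uses a factorisation, never an
explicit inverse.

## Genetic scores and specificity scans

A risk score is Sᵢ = Σⱼ wⱼGᵢⱼ over effect-allele dosages (weights are
per-allele exposure betas; unweighted scores force wⱼ = 1). To express
effects per SD of the target trait, the score is multiplied by the
regression slope of the standardised trait on the raw score, so a one-unit
change in the scaled score predicts 1 SD of trait; a non-positive or
statistically null slope is an error (instruments incoherent with the
exposure). Variance explained is the R² of the joint regression of the
standardised phenotype on all lead dosages, and the heritability fraction is
that R² divided by an externally supplied heritability estimate.

The metabolome-wide scan regresses each standardised trait on the score,
residualising both on covariates first (Frisch–Waugh), with exact
t-distribution p-values. Multiplicity control is Bonferroni at α/m by
default — conservative, appropriate for claiming *specificity* (few false
positives) — with Benjamini–Hochberg available. Constant traits are flagged
untestable.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

- **Genotypes**: each haplotype carries the effect allele when a latent
  standard normal falls below Φ⁻¹(f); two independent haplotypes sum to the
  dosage, so Hardy–Weinberg equilibrium holds exactly by construction.
  Block LD is induced by correlating the latent normals (Gaussian copula).
  Thresholding attenuates the dosage-level correlation relative to the
  latent target (latent 0.7 realises roughly 0.5 at f = 0.4); the cohort
  object records the realised correlation for oracle use, and analyses
  always consume estimated or realised LD, never the latent target.
- **Exposure**: X = Σγⱼ(Gⱼ−2fⱼ) + aU + ε with a single standard-normal
  confounder U and noise variance chosen so X has unit variance — the
  minimal structure that biases observational estimates while leaving the
  instruments valid. Default per-allele effects are drawn from 0.06–0.13 SD,
  the magnitude range of metabolite lead SNPs; default confounder loadings
  are a = b = 0.3, enough to visibly inflate the observational estimate
  without dominating it. A target genetic R² may be requested instead, and
  the variance budget is validated (genetic + confounder share < 1).
- **Outcome**: P(D=1) = logistic(β₀ + θX + bU), with β₀ solved by root
  finding so the sample-average risk equals the configured prevalence
  (default 10%, a plausible cumulative incidence for type 2 diabetes).
  The default causal effect is θ = ln 1.5 per SD. Optional case-control
  subsampling retains all cases and a fraction of controls; odds ratios are
  invariant to outcome-dependent sampling, so downstream logistic fits stay
  valid. A pleiotropy vector (direct SNP→outcome log-odds) is available for
  negative-control experiments and is zero by default.
- **Summary-statistic route**: γ̂ⱼ ~ N(γⱼ, se) and Γ̂ⱼ ~ N(θγⱼ, σⱼ) with
  errors correlated across variants per the LD matrix, and analytic SEs
  se(γ̂ⱼ) = (n_exp·2fⱼ(1−fⱼ))^(−1/2), σⱼ = (n_out·v(1−v)·2fⱼ(1−fⱼ))^(−1/2)
  for case share v. Defaults mirror the motivating study's scale:
  n_exp = 16,596 and n_out = 50,000. A replication test confirms the two
  routes give statistically indistinguishable causal-estimate distributions
  at matched sample sizes.

Every artefact is a pure function of (configuration, seed); seeds are
mandatory. Functions called individually draw from per-operation substreams
of the seed so that, e.g., exposure noise never replays the genotype draws.

What the generator does **not** emulate: genome-scale LD maps, population
structure and relatedness, platform-specific measurement error, winner's
curse in instrument discovery, and time-to-event outcome structure. Passing
tests therefore demonstrate the estimators' correctness and calibration
under the assumed model, not robustness to these real-data complications.

## Pipeline

`pipeline.run` executes simulate → exposure/outcome scans → lead selection →
LD + pruning → MR (independent IVW and correlated GLS) → observational
fixed-effect meta-analysis over cohort splits → specificity scan → report.
The top-level seed is split per stage by hashing the stage name (all derived
seeds < 2³¹), so adding a stage never perturbs earlier stages' draws, and an
identical configuration reproduces byte-identical numeric outputs; the
manifest records config and output digests. The bundled default simulates
30,000 individuals with four instruments of per-allele effect 0.07–0.11 SD —
large enough that all four variants clear genome-wide significance with high
probability while the whole run stays under two seconds.

## Numerical conventions

- z₀.₉₇₅ is fixed at 1.959964 so CI↔SE conversions are bit-for-bit
  reproducible; 95% CIs are θ̂ ± 1.959964·se everywhere.
- Odds ratios are carried internally as log-odds; display layers
  exponentiate.
- Genomic coordinates are 1-based; only biallelic A/C/G/T variants are
  modelled (no liftover, no multi-allelic records, no imputation-quality
  filtering).
- Two-sided p-values are floored at the smallest positive double rather
  than reported as zero.
- Q values below 1e-10 (Q is scale-free) are treated as exactly zero so a
  single-study meta-analysis reports I² = 0.

## Test problem sizes

Stochastic suites use deliberately modest, fixed-seed problem sizes chosen to
give comfortable statistical margins: parameter recovery uses 500 summary-
statistic replicates at outcome n = 50,000 with 4 (independent) or 12
(block-correlated) instruments; scan calibration uses 1,000 null traits at
n = 500 for uniformity, 20 such runs for family-wise error control, and 100
runs at n = 5,000 with a planted R² = 0.05 trait for power; the null-effect
pipeline check uses 25 seeded repeats of a 3,000-individual cohort. The
family-wise-error criterion is intrinsically knife-edged — the true
probability of a clean Bonferroni run is (1−α/m)^m ≈ e^(−α) ≈ 0.951 against
a 0.95 bound — so that test's verdict depends on the fixed seed more than
the others.

## Known limitations

- Weak-instrument bias: with estimated IVW weights the pooled estimate is
  attenuated by roughly a factor 1/(1 + Σse(γ̂ⱼ)²/Σγⱼ²); at default
  instrument strengths this is ~1% and invisible next to sampling error,
  but the package does not correct for it.
- First-order Wald SEs yield mild undercoverage when instruments are weak;
  the second-order option mitigates this.
- MR-Egger, weighted-median and mode-based pleiotropy-robust estimators,
  multivariable MR, and winner's-curse corrections are out of scope; the
  pleiotropy defence implemented here is exclusion of known pleiotropic
  instruments plus specificity scanning.
- The observational pooling treats log-HR/OR/RR as exchangeable; for common
  outcomes this approximation degrades.
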