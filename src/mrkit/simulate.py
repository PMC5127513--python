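"""Generative models for genotypes, exposures, binary outcomes and summary
statistics with the statistical structure the MR analysis assumes.

Genotypes are biallelic SNP dosages in Hardy-Weinberg equilibrium: each of the
two haplotypes carries the effect allele when a latent standard normal falls
below the allele-frequency quantile, and linkage disequilibrium between
nearby variants is induced by giving the latent normals a target correlation
(a Gaussian copula).  The realised dosage correlation is slightly weaker than
the latent one; the generator records it for oracle use.

The quantitative exposure follows the additive model

    X = sum_j gamma_j (G_j - 2 f_j) + a U + eps,

with a single standard-normal confounder U and noise variance chosen so X has
unit variance — so the configured per-allele effects are already in SD units.
The binary outcome is drawn from logistic(beta0 + theta X + b U), with beta0
solved numerically for the configured prevalence.  Because U affects both X
and D, naive observational estimates are biased while the genetic instruments
remain valid.

A fast summary-statistic route bypasses individual-level data: it draws
gamma_hat ~ N(gamma, se_gamma) and Gamma_hat ~ N(theta gamma, se_Gamma) with
errors correlated across variants according to the LD matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats as sps
from scipy.special import expit

from .gwas import GenotypeMatrix
from .sumstats import AssocStat, LDMatrix, ValidationError, VariantRecord

#: Per-allele exposure-effect range (SD units) typical of metabolite lead SNPs;
#: used when a configuration does not specify effects explicitly.
DEFAULT_GAMMA_RANGE = (0.06, 0.13)


def block_ld(sizes: list[int], rhos: list[float], ids: list[str] | None = None) -> LDMatrix:
    """Block-diagonal LD with constant within-block correlation."""
    if len(sizes) != len(rhos):
        raise ValidationError("sizes and rhos must have the same length")
    total = sum(sizes)
    r = np.eye(total)
    start = 0
    for size, rho in zip(sizes, rhos):
        if not (-1.0 <= rho <= 1.0):
            raise ValidationError(f"block correlation {rho} outside [-1, 1]")
        block = np.full((size, size), float(rho))
        np.fill_diagonal(block, 1.0)
        r[start : start + size, start : start + size] = block
        start += size
    if ids is None:
        ids = [f"snp{j + 1}" for j in range(total)]
    return LDMatrix(ids, r)


@dataclass
class SimulationConfig:
    """Full generative model for a synthetic MR cohort.

    ``theta`` is the causal log-odds of disease per 1 SD of exposure
    (default ln 1.5); ``confounder_exposure``/``confounder_outcome`` are the
    loadings of the shared confounder on exposure (SD units) and outcome
    (log-odds).  ``n_exposure``/``n_outcome`` are the GWAS sample sizes used
    by the summary-statistic route.  The seed is mandatory: every artefact is
    a pure function of (config, seed).
    """

    n_individuals: int
    eaf: np.ndarray
    gamma: np.ndarray
    ld: LDMatrix | None = None
    confounder_exposure: float = 0.3
    confounder_outcome: float = 0.3
    theta: float = math.log(1.5)
    prevalence: float = 0.10
    case_fraction: float = 1.0
    control_fraction: float = 1.0
    genetic_r2: float | None = None
    pleiotropy: np.ndarray | None = None
    n_exposure: int = 16_596
    n_outcome: int = 50_000
    outcome_case_share: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        self.eaf = np.asarray(self.eaf, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.seed is None:
            raise ValidationError("a seed is mandatory: simulations must be reproducible")
        if np.any((self.eaf <= 0) | (self.eaf >= 1)):
            raise ValidationError("allele frequencies must lie strictly inside (0, 1)")
        if self.gamma.shape != self.eaf.shape:
            raise ValidationError("gamma and eaf must have the same length")
        if self.ld is not None and len(self.ld) != self.eaf.shape[0]:
            raise ValidationError("LD matrix dimension does not match number of variants")
        if not (0.0 < self.prevalence < 1.0):
            raise ValidationError("prevalence must lie in (0, 1)")
        if self.genetic_r2 is not None and not (0.0 <= self.genetic_r2 < 1.0):
            raise ValidationError("requested genetic R^2 must lie in [0, 1)")
        if self.pleiotropy is not None:
            self.pleiotropy = np.asarray(self.pleiotropy, dtype=float)
            if self.pleiotropy.shape != self.eaf.shape:
                raise ValidationError("pleiotropy vector must match number of variants")
        if not (0.0 < self.outcome_case_share < 1.0):
            raise ValidationError("outcome_case_share must lie in (0, 1)")

    @property
    def n_variants(self) -> int:
        return self.eaf.shape[0]

    def variant_records(self) -> list[VariantRecord]:
        """Synthetic variant metadata: one locus per 2 Mb on chromosome 1."""
        ids = self.ld.ids if self.ld is not None else [f"snp{j + 1}" for j in range(self.n_variants)]
        return [
            VariantRecord(vid, "1", 1 + 2_000_000 * j, "A", "G", float(f))
            for j, (vid, f) in enumerate(zip(ids, self.eaf))
        ]


def default_config(
    n_variants: int = 10,
    n_individuals: int = 10_000,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """A realistic default configuration: per-allele effects in the
    0.06-0.13 SD range, EAF in (0.2, 0.8), independent variants."""
    rng = np.random.default_rng(seed)
    lo, hi = DEFAULT_GAMMA_RANGE
    cfg = SimulationConfig(
        n_individuals=n_individuals,
        eaf=rng.uniform(0.2, 0.8, size=n_variants),
        gamma=rng.uniform(lo, hi, size=n_variants),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class SyntheticCohort:
    """Individual-level synthetic data plus the exact truth used to generate it."""

    genotypes: GenotypeMatrix
    exposure: np.ndarray
    confounder: np.ndarray
    outcome: np.ndarray
    truth: SimulationConfig
    realised_ld: np.ndarray | None = None
    sampled: np.ndarray | None = None  # indices retained by case-control sampling


def _rng_for(
    config: SimulationConfig, rng: np.random.Generator | None, stream: int
) -> np.random.Generator:
    """Per-operation random stream.

    Each generator function gets its own substream of the config seed, so
    calling e.g. genotype and exposure generation separately never replays
    the same draws (which would correlate noise with genotypes).  Passing an
    explicit ``rng`` (as :func:`simulate_cohort` does) overrides this.
    """
    return rng if rng is not None else np.random.default_rng([config.seed, stream])


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Draw HWE dosages with block LD via a latent Gaussian copula.

    Each haplotype's latent vector is multivariate normal with the target
    correlation; the allele is carried where the latent value falls below the
    allele-frequency quantile.  Two independent haplotypes per individual sum
    to the dosage, so Hardy-Weinberg equilibrium holds by construction.
    """
    rng = _rng_for(config, rng, stream=1)
    m = config.n_variants
    n = config.n_individuals
    thresholds = sps.norm.ppf(config.eaf)
    if config.ld is not None:
        if config.ld.min_eigenvalue() < -1e-10:
            raise ValidationError("target LD matrix is not positive semidefinite")
        # eigenvalue square root tolerates the PSD-repaired (rank-deficient) case
        w, v = np.linalg.eigh(config.ld.r)
        L = v * np.sqrt(np.clip(w, 0.0, None))
        z1 = rng.standard_normal((n, m)) @ L.T
        z2 = rng.standard_normal((n, m)) @ L.T
    else:
        z1 = rng.standard_normal((n, m))
        z2 = rng.standard_normal((n, m))
    dosages = (z1 < thresholds).astype(float) + (z2 < thresholds).astype(float)
    samples = [f"id{i + 1}" for i in range(n)]
    return GenotypeMatrix(samples, config.variant_records(), dosages)


def simulate_exposure(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Additive-genetic exposure with confounding, standardised to SD units.

    Returns ``(exposure, confounder)``.  Noise variance is set so that the
    genetic component explains its configured share of variance and the total
    variance is 1, keeping the per-allele effects in SD units.
    """
    rng = _rng_for(config, rng, stream=2)
    gamma = config.gamma.copy()
    centred = genotypes.mean_imputed() - 2.0 * config.eaf
    g = centred @ gamma
    var_g = float(g.var(ddof=0))
    if config.genetic_r2 is not None and var_g > 0:
        scale = math.sqrt(config.genetic_r2 / var_g)
        gamma = gamma * scale
        g = g * scale
        var_g = config.genetic_r2
    a = config.confounder_exposure
    eps_var = 1.0 - var_g - a**2
    if eps_var <= 0:
        raise ValidationError(
            f"genetic variance {var_g:.3f} plus confounding {a**2:.3f} reaches or "
            "exceeds total exposure variance 1"
        )
    U = rng.standard_normal(len(g))
    X = g + a * U + math.sqrt(eps_var) * rng.standard_normal(len(g))
    X = (X - X.mean()) / X.std(ddof=0)
    return X, U


def simulate_outcome(
    exposure: np.ndarray,
    confounder: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    genotypes: GenotypeMatrix | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary disease outcome from a logistic model, plus case-control sampling.

    P(D=1) = logistic(beta0 + theta X + b U), with beta0 solved so the mean
    risk equals the configured prevalence.  Optional direct variant->outcome
    (pleiotropic) effects are added when configured.  Returns ``(outcome,
    sampled_indices)``: all cases are retained with probability
    ``case_fraction`` and controls with ``control_fraction``, and the index
    vector keeps downstream logistic fits valid for odds ratios.
    """
    rng = _rng_for(config, rng, stream=3)
    X = np.asarray(exposure, dtype=float)
    eta = config.theta * X + config.confounder_outcome * np.asarray(confounder, dtype=float)
    if config.pleiotropy is not None:
        if genotypes is None:
            raise ValidationError("pleiotropic effects need the genotype matrix")
        eta = eta + (genotypes.mean_imputed() - 2.0 * config.eaf) @ config.pleiotropy

    def excess(b0: float) -> float:
        return float(np.mean(expit(b0 + eta))) - config.prevalence

    try:
        beta0 = optimize.brentq(excess, -40.0, 40.0, xtol=1e-12)
    except ValueError as err:
        raise ValidationError(
            f"prevalence {config.prevalence} unreachable given theta={config.theta}, "
            f"confounding={config.confounder_outcome}: {err}"
        ) from err
    D = (rng.random(len(X)) < expit(beta0 + eta)).astype(float)
    keep_p = np.where(D == 1, config.case_fraction, config.control_fraction)
    sampled = np.nonzero(rng.random(len(X)) < keep_p)[0]
    return D, sampled


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a complete individual-level cohort from one seed."""
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config, rng)
    exposure, confounder = simulate_exposure(genotypes, config, rng)
    outcome, sampled = simulate_outcome(exposure, confounder, config, rng, genotypes)
    dos = genotypes.dosages
    realised = np.corrcoef(dos, rowvar=False) if config.n_variants > 1 else np.ones((1, 1))
    return SyntheticCohort(
        genotypes=genotypes,
        exposure=exposure,
        confounder=confounder,
        outcome=outcome,
        truth=config,
        realised_ld=np.atleast_2d(realised),
        sampled=sampled,
    )


def sumstat_standard_errors(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Analytic GWAS standard errors implied by the configured sample sizes.

    For a standardised quantitative trait the per-allele SE is approximately
    1/sqrt(n 2f(1-f)); for the logistic outcome scan the effective sample
    size is deflated by the case share v through v(1-v).
    """
    info = 2.0 * config.eaf * (1.0 - config.eaf)
    se_gamma = 1.0 / np.sqrt(config.n_exposure * info)
    v = config.outcome_case_share
    se_Gamma = 1.0 / np.sqrt(config.n_outcome * v * (1.0 - v) * info)
    return se_gamma, se_Gamma


def simulate_sumstats(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[AssocStat], list[AssocStat], LDMatrix]:
    """Two-sample summary statistics drawn directly around the true effects.

    gamma_hat_j ~ N(gamma_j, se_gamma_j) and Gamma_hat_j ~ N(theta gamma_j +
    pleiotropy_j, se_Gamma_j), with estimation errors correlated across
    variants according to the LD matrix (as they are when computed from one
    sample of correlated genotypes).
    """
    rng = _rng_for(config, rng, stream=4)
    m = config.n_variants
    se_g, se_G = sumstat_standard_errors(config)
    if config.ld is not None:
        w, v = np.linalg.eigh(config.ld.r)
        L = v * np.sqrt(np.clip(w, 0.0, None))
        e1 = L @ rng.standard_normal(m)
        e2 = L @ rng.standard_normal(m)
        ld = config.ld
    else:
        e1 = rng.standard_normal(m)
        e2 = rng.standard_normal(m)
        ld = LDMatrix([f"snp{j + 1}" for j in range(m)], np.eye(m))
    gamma_hat = config.gamma + se_g * e1
    mean_Gamma = config.theta * config.gamma
    if config.pleiotropy is not None:
        mean_Gamma = mean_Gamma + config.pleiotropy
    Gamma_hat = mean_Gamma + se_G * e2

    variants = config.variant_records()
    v_share = config.outcome_case_share
    n_cases = int(round(config.n_outcome * v_share))
    exp_stats, out_stats = [], []
    for j, var in enumerate(variants):
        zg = gamma_hat[j] / se_g[j]
        zG = Gamma_hat[j] / se_G[j]
        exp_stats.append(
            AssocStat(
                variant=var,
                trait="exposure",
                beta=float(gamma_hat[j]),
                se=float(se_g[j]),
                p=max(float(2 * sps.norm.sf(abs(zg))), 5e-324),
                n=config.n_exposure,
            )
        )
        out_stats.append(
            AssocStat(
                variant=var,
                trait="outcome",
                beta=float(Gamma_hat[j]),
                se=float(se_G[j]),
                p=max(float(2 * sps.norm.sf(abs(zG))), 5e-324),
                n=config.n_outcome,
                n_cases=n_cases,
                n_controls=config.n_outcome - n_cases,
            )
        )
    return exp_stats, out_stats, ld
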