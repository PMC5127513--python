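"""Genetic risk scores, variance-explained arithmetic, and specificity scans.

A weighted genetic risk score for individual i is S_i = sum_j w_j G_ij over
risk-allele dosages G; unweighted scores set all weights to 1.  To express
score effects per SD of the target trait, the score is rescaled by the
regression slope of the (standardised) trait on the raw score, so that a
one-unit change in the scaled score predicts a 1 SD change in the trait.

The metabolome-wide scan regresses every standardised metabolite on the score
(optionally covariate-adjusted via Frisch-Waugh residualisation) and flags
associations passing a Bonferroni threshold alpha/m — a conservative default
for judging whether a score is specific to its own pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gwas import GenotypeMatrix
from .sumstats import ValidationError, VariantRecord


@dataclass(frozen=True)
class ScoreDefinition:
    """Variants and per-allele weights defining a genetic risk score."""

    variants: tuple[tuple[VariantRecord, float], ...]
    mode: str = "weighted"

    def __post_init__(self) -> None:
        if self.mode not in ("weighted", "unweighted"):
            raise ValidationError(f"unknown score mode {self.mode!r}")
        ws = np.array([w for _, w in self.variants], dtype=float)
        if not np.all(np.isfinite(ws)):
            raise ValidationError("score weights must be finite")
        if self.mode == "unweighted" and not np.all(ws == 1.0):
            object.__setattr__(
                self, "variants", tuple((v, 1.0) for v, _ in self.variants)
            )

    @classmethod
    def unweighted(cls, variants: list[VariantRecord]) -> "ScoreDefinition":
        return cls(tuple((v, 1.0) for v in variants), mode="unweighted")


@dataclass
class ScanResult:
    """Per-trait association of a score, with multiplicity-controlled flags."""

    table: pd.DataFrame  # columns: trait, beta, se, p, significant, untestable
    m: int
    alpha: float
    method: str

    @property
    def significant_traits(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "trait"])


def build_score(
    genotypes: GenotypeMatrix,
    score: ScoreDefinition,
    missing: str = "mean-impute",
) -> np.ndarray:
    """Per-individual weighted allele-dosage sum S_i = sum_j w_j G_ij.

    Dosages are aligned to each score variant's effect allele (a genotype
    column coded on the opposite allele contributes 2 - G).  ``missing`` is
    either ``"mean-impute"`` (per-variant mean) or ``"drop"`` (individuals
    with any missing dosage get NaN).
    """
    if missing not in ("mean-impute", "drop"):
        raise ValidationError(f"unknown missing-data policy {missing!r}")
    geno_by_id = {v.id: (j, v) for j, v in enumerate(genotypes.variants)}
    absent = [v.id for v, _ in score.variants if v.id not in geno_by_id]
    if absent:
        raise ValidationError(f"score variants absent from genotypes: {', '.join(absent)}")
    dos = genotypes.mean_imputed() if missing == "mean-impute" else genotypes.dosages
    total = np.zeros(genotypes.n_samples)
    for v, w in score.variants:
        j, gv = geno_by_id[v.id]
        g = dos[:, j]
        if gv.effect_allele == v.effect_allele:
            pass
        elif gv.effect_allele == v.other_allele and gv.other_allele == v.effect_allele:
            g = 2.0 - g
        else:
            raise ValidationError(
                f"{v.id}: score alleles {v.effect_allele}/{v.other_allele} do not match "
                f"genotype alleles {gv.effect_allele}/{gv.other_allele}"
            )
        total = total + w * g
    return total


def scale_score_to_sd(score: np.ndarray, exposure: np.ndarray) -> np.ndarray:
    """Rescale a raw score so one scaled unit predicts 1 SD of the exposure.

    The exposure must already be standardised.  The scaling factor is the
    regression slope of exposure on score; a non-positive (or statistically
    null) slope means the instruments do not predict the exposure and is an
    error.
    """
    score = np.asarray(score, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if score.shape != exposure.shape:
        raise ValidationError("score and exposure lengths differ")
    sv = score.var(ddof=0)
    if sv == 0:
        raise ValidationError("score has zero variance")
    slope = float(np.cov(score, exposure, ddof=0)[0, 1] / sv)
    resid = exposure - slope * (score - score.mean())
    se = float(np.sqrt(resid.var(ddof=0) / (len(score) * sv)))
    if slope <= 0 or (se > 0 and slope / se < 2.0):
        raise ValidationError(
            f"score does not positively predict the exposure (slope {slope:.4g}, "
            f"SE {se:.4g}); instruments incoherent with exposure"
        )
    return score * slope


def variance_explained(phenotype: np.ndarray, lead_genotypes: GenotypeMatrix) -> float:
    """R-squared of the joint linear regression of a standardised phenotype on lead-SNP dosages."""
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != lead_genotypes.n_samples:
        raise ValidationError("phenotype length does not match genotype matrix")
    if len(lead_genotypes.variants) < 1:
        raise ValidationError("need at least one lead variant")
    X = np.column_stack([np.ones(len(y)), lead_genotypes.mean_imputed()])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            "collinear lead variants; variance explained computed via pseudoinverse",
            stacklevel=2,
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValidationError("phenotype is constant")
    return 1.0 - float(np.sum(resid**2)) / tss


def heritability_fraction(r2: float, h2: float) -> float:
    """Proportion of trait heritability captured by the lead SNPs: r2 / h2."""
    if not (0.0 <= r2 <= 1.0):
        raise ValidationError(f"explained variance {r2} outside [0, 1]")
    if not (0.0 < h2 <= 1.0):
        raise ValidationError(f"heritability {h2} must lie in (0, 1]")
    return r2 / h2


def metabolome_scan(
    score: np.ndarray,
    metabolites: pd.DataFrame,
    covariates: np.ndarray | pd.DataFrame | None = None,
    alpha: float = 0.05,
    method: str = "bonferroni",
) -> ScanResult:
    """Regress each standardised metabolite on the score; flag significant hits.

    Traits are standardised internally; with covariates, both score and traits
    are residualised on the covariates first (Frisch-Waugh), so the reported
    slope equals the covariate-adjusted regression coefficient.  P-values come
    from the exact t distribution.  Constant traits are flagged untestable.

    ``method`` is ``"bonferroni"`` (flag p < alpha/m) or ``"bh"``
    (Benjamini-Hochberg at FDR alpha).
    """
    if method not in ("bonferroni", "bh"):
        raise ValidationError(f"unknown multiplicity method {method!r}")
    s = np.asarray(score, dtype=float)
    Y = metabolites.to_numpy(dtype=float)
    n, m = Y.shape
    if m < 1:
        raise ValidationError("need at least one trait")
    if s.shape[0] != n:
        raise ValidationError("score length does not match trait matrix")

    k_cov = 0
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        k_cov = C.shape[1]
        Cc = np.column_stack([np.ones(n), C])
        s = s - Cc @ np.linalg.lstsq(Cc, s, rcond=None)[0]
        Y = Y - Cc @ np.linalg.lstsq(Cc, Y, rcond=None)[0]

    sd = Y.std(axis=0, ddof=0)
    untestable = sd == 0
    sd_safe = np.where(untestable, 1.0, sd)
    Yz = (Y - Y.mean(axis=0)) / sd_safe

    sc = s - s.mean()
    ssx = float(np.sum(sc**2))
    if ssx == 0:
        raise ValidationError("score has zero variance")
    beta = (sc @ Yz) / ssx
    resid = Yz - np.outer(sc, beta)
    dof = n - 2 - k_cov
    if dof <= 0:
        raise ValidationError("not enough individuals for the scan")
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(sigma2 / ssx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    p = 2.0 * sps.t.sf(np.abs(tstat), dof)
    p = np.clip(p, 5e-324, 1.0)

    if method == "bonferroni":
        sig = p < alpha / m
    else:
        order = np.argsort(p)
        ranked = p[order]
        thresh = alpha * (np.arange(1, m + 1)) / m
        passing = ranked <= thresh
        cutoff = ranked[passing].max() if passing.any() else -1.0
        sig = p <= cutoff
    sig = sig & ~untestable

    table = pd.DataFrame(
        {
            "trait": list(metabolites.columns),
            "beta": np.where(untestable, np.nan, beta),
            "se": np.where(untestable, np.nan, se),
            "p": np.where(untestable, np.nan, p),
            "significant": sig,
            "untestable": untestable,
        }
    )
    return ScanResult(table=table, m=m, alpha=alpha, method=method)
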