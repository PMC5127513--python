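"""Causal-effect estimation from harmonised summary statistics.

Each genetic instrument j yields a Wald ratio

    theta_j = Gamma_j / gamma_j,     se(theta_j) = se(Gamma_j) / |gamma_j|,

where gamma_j is the per-allele SNP->exposure effect (SD units) and Gamma_j
the per-allele SNP->outcome effect (log-odds).  Independent instruments are
pooled by fixed-effect inverse-variance weighting (IVW); instruments in
mutual linkage disequilibrium are pooled by generalised least squares with
covariance Omega_jk = se(Gamma_j) se(Gamma_k) rho_jk:

    theta = (gamma' Omega^-1 gamma)^-1 gamma' Omega^-1 Gamma
    se    = (gamma' Omega^-1 gamma)^-1/2

With rho = I this reduces exactly to IVW over the Wald ratios.  Results are
log-odds of disease per 1 SD of genetically predicted exposure; use
:func:`to_or_scale` for the odds-ratio scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import stats as sps

from .sumstats import Z_975, HarmonisedPair, LDMatrix, ValidationError


class SingularCorrelationError(ValueError):
    """The instrument correlation matrix is numerically singular; prune harder."""


@dataclass(frozen=True)
class WaldEstimate:
    """Single-instrument causal estimate: log-odds of outcome per 1 SD exposure."""

    variant_id: str
    theta: float
    se: float
    p: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError(f"{self.variant_id}: SE must be positive")


@dataclass(frozen=True)
class MRResult:
    """Pooled causal estimate with its 95% CI, method tag and instrument count."""

    method: str
    theta: float
    se: float
    ci95: tuple[float, float]
    p: float
    n_snps: int
    excluded_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValidationError("an MR result needs at least one instrument")
        lo, hi = self.theta - Z_975 * self.se, self.theta + Z_975 * self.se
        if abs(self.ci95[0] - lo) > 1e-9 or abs(self.ci95[1] - hi) > 1e-9:
            raise ValidationError("ci95 inconsistent with theta +/- 1.959964 se")


def _mk_result(method: str, theta: float, se: float, n_snps: int, excluded=()) -> MRResult:
    p = max(float(2.0 * sps.norm.sf(abs(theta / se))), 5e-324)
    return MRResult(
        method=method,
        theta=theta,
        se=se,
        ci95=(theta - Z_975 * se, theta + Z_975 * se),
        p=p,
        n_snps=n_snps,
        excluded_ids=tuple(excluded),
    )


def pool_inverse_variance(thetas: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    """Fixed-effect inverse-variance pooling kernel: (pooled estimate, pooled SE).

    Shared by :func:`ivw_pool` and the observational fixed-effect
    meta-analysis so the two entry points agree exactly.
    """
    thetas = np.asarray(thetas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if thetas.size == 0:
        raise ValidationError("cannot pool an empty set of estimates")
    if np.any(ses <= 0):
        raise ValidationError("all standard errors must be positive")
    w = ses**-2.0
    theta = float(np.sum(w * thetas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return theta, se


def wald_ratio(pair: HarmonisedPair, second_order: bool = False) -> WaldEstimate:
    """Per-instrument causal estimate Gamma/gamma.

    The default SE is first order, se(Gamma)/|gamma|, ignoring uncertainty in
    the SNP->exposure effect; ``second_order=True`` adds the delta-method term
    for var(gamma).
    """
    g, G = pair.gamma.beta, pair.Gamma.beta
    if g == 0:
        raise ValidationError(f"{pair.variant_id}: SNP->exposure effect is zero; instrument undefined")
    theta = G / g
    var = pair.Gamma.se**2 / g**2
    if second_order:
        var += G**2 * pair.gamma.se**2 / g**4
    se = float(np.sqrt(var))
    p = max(float(2.0 * sps.norm.sf(abs(theta / se))), 5e-324)
    return WaldEstimate(variant_id=pair.variant_id, theta=theta, se=se, p=p)


def ivw_pool(estimates: list[WaldEstimate]) -> MRResult:
    """Fixed-effect inverse-variance-weighted pooling of Wald ratios.

    No overdispersion scaling is applied: weights are se^-2 and the pooled SE
    is (sum of weights)^-1/2.
    """
    if not estimates:
        raise ValidationError("ivw_pool needs at least one estimate")
    theta, se = pool_inverse_variance(
        np.array([e.theta for e in estimates]), np.array([e.se for e in estimates])
    )
    return _mk_result("ivw", theta, se, len(estimates))


def gls_pool(
    gammas: np.ndarray,
    Gammas: np.ndarray,
    ses: np.ndarray,
    ld: LDMatrix,
    ids: list[str] | None = None,
) -> MRResult:
    """Correlated-instrument pooling by generalised least squares.

    ``gammas``/``Gammas``/``ses`` are the per-allele exposure effects, outcome
    effects and outcome SEs in the order of ``ids`` (default: the LD matrix
    order).  The weight matrix Omega = outer(se, se) * rho is inverted via a
    linear solve, never explicitly.
    """
    gammas = np.asarray(gammas, dtype=float)
    Gammas = np.asarray(Gammas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    sub = ld if ids is None else ld.submatrix(list(ids))
    k = len(sub)
    if not (gammas.shape == Gammas.shape == ses.shape == (k,)):
        raise ValidationError(
            f"gls_pool: vectors of shape {gammas.shape}/{Gammas.shape}/{ses.shape} "
            f"not conformable with {k}-variant LD matrix"
        )
    if np.any(ses <= 0):
        raise ValidationError("all outcome standard errors must be positive")
    omega = np.outer(ses, ses) * sub.r
    cond = np.linalg.cond(omega)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularCorrelationError(
            f"instrument correlation matrix is near-singular (condition number "
            f"{cond:.3g}); prune instruments more aggressively (lower r2_max)"
        )
    solved = sla.solve(omega, np.column_stack([gammas, Gammas]), assume_a="pos")
    gOg = float(gammas @ solved[:, 0])
    gOG = float(gammas @ solved[:, 1])
    theta = gOG / gOg
    se = gOg**-0.5
    return _mk_result("gls", theta, se, k)


def fit(
    pairs: list[HarmonisedPair],
    method: str = "ivw",
    ld: LDMatrix | None = None,
    excluded_ids: tuple[str, ...] = (),
) -> MRResult:
    """Pool a set of harmonised instrument pairs with the chosen method."""
    if not pairs:
        raise ValidationError("no instruments to fit")
    if method == "ivw":
        result = ivw_pool([wald_ratio(p) for p in pairs])
    elif method == "gls":
        if ld is None:
            raise ValidationError("gls fitting requires an LD matrix")
        ids = [p.variant_id for p in pairs]
        result = gls_pool(
            np.array([p.gamma.beta for p in pairs]),
            np.array([p.Gamma.beta for p in pairs]),
            np.array([p.Gamma.se for p in pairs]),
            ld,
            ids=ids,
        )
    else:
        raise ValidationError(f"unknown MR method {method!r}")
    return _mk_result(result.method, result.theta, result.se, result.n_snps, excluded_ids)


def exclude_and_refit(
    pairs: list[HarmonisedPair],
    exclude_ids: list[str],
    method: str = "ivw",
    ld: LDMatrix | None = None,
) -> MRResult:
    """Sensitivity refit after removing named instruments (e.g. pleiotropic loci).

    The result records the excluded ids; all other settings are unchanged.
    """
    ids = {p.variant_id for p in pairs}
    unknown = [e for e in exclude_ids if e not in ids]
    if unknown:
        raise ValidationError(f"exclusion ids not among instruments: {', '.join(unknown)}")
    kept = [p for p in pairs if p.variant_id not in set(exclude_ids)]
    if not kept:
        raise ValidationError("exclusion removes every instrument")
    return fit(kept, method=method, ld=ld, excluded_ids=tuple(exclude_ids))


def to_or_scale(result: MRResult) -> tuple[float, tuple[float, float], float]:
    """Exponentiate a log-odds-per-SD result to (OR, 95% CI, p)."""
    return (
        float(np.exp(result.theta)),
        (float(np.exp(result.ci95[0])), float(np.exp(result.ci95[1]))),
        result.p,
    )
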