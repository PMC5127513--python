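"""Fixed-effect meta-analysis of observational biomarker -> disease estimates.

Per-study log relative risks (hazard ratios, odds ratios and risk ratios are
pooled on the log scale as a common "relative risk" — a standard
approximation for uncommon outcomes) are combined by inverse-variance
weighting, sharing the pooling kernel with the genetic IVW estimator.
Between-study heterogeneity is quantified by Cochran's Q and

    I^2 = max(0, (Q - (k - 1)) / Q) * 100   (0 when Q = 0),

the percentage of between-study variability attributable to heterogeneity
rather than chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mr import MRResult, pool_inverse_variance
from .sumstats import Z_975, ValidationError, se_from_ci


@dataclass(frozen=True)
class StudyEstimate:
    """One study's log relative risk per 1 SD of biomarker, with its SE."""

    study: str
    theta: float
    se: float
    n_cases: int | None = None
    n_noncases: int | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError(f"{self.study}: SE must be positive")


@dataclass(frozen=True)
class MetaResult:
    """Pooled fixed-effect estimate with Cochran's Q and I-squared."""

    theta: float
    se: float
    ci95: tuple[float, float]
    p: float
    Q: float
    I2: float
    k: int


@dataclass(frozen=True)
class ConcordanceReport:
    """Side-by-side comparison of the genetic and observational arms.

    Both estimates are log relative risk per 1 SD of the biomarker.  No
    significance test is computed — the report states the point estimates,
    their ratio, and whether the 95% CIs overlap.
    """

    genetic_theta: float
    genetic_ci95: tuple[float, float]
    observational_theta: float
    observational_ci95: tuple[float, float]
    ratio: float
    ci_overlap: bool


def fixed_effect_meta(studies: list[StudyEstimate]) -> MetaResult:
    """Fixed-effect inverse-variance meta-analysis with Q and I-squared."""
    if not studies:
        raise ValidationError("fixed_effect_meta needs at least one study")
    thetas = np.array([s.theta for s in studies])
    ses = np.array([s.se for s in studies])
    theta, se = pool_inverse_variance(thetas, ses)
    w = ses**-2.0
    Q = float(np.sum(w * (thetas - theta) ** 2))
    k = len(studies)
    if Q < 1e-10:  # numerically zero (Q is scale-free)
        Q = 0.0
    I2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if Q > 0 else 0.0
    p = max(float(2.0 * sps.norm.sf(abs(theta / se))), 5e-324)
    return MetaResult(
        theta=theta,
        se=se,
        ci95=(theta - Z_975 * se, theta + Z_975 * se),
        p=p,
        Q=Q,
        I2=I2,
        k=k,
    )


def compare_arms(genetic: MRResult, observational: MetaResult) -> ConcordanceReport:
    """Compare genetic (MR) and observational (meta-analysed) per-SD estimates."""
    g_lo, g_hi = genetic.ci95
    o_lo, o_hi = observational.ci95
    overlap = g_lo <= o_hi and o_lo <= g_hi
    ratio = (
        float("nan")
        if observational.theta == 0
        else genetic.theta / observational.theta
    )
    return ConcordanceReport(
        genetic_theta=genetic.theta,
        genetic_ci95=genetic.ci95,
        observational_theta=observational.theta,
        observational_ci95=observational.ci95,
        ratio=ratio,
        ci_overlap=overlap,
    )


def read_studies(path) -> list[StudyEstimate]:
    """Read per-study estimates from TSV: STUDY, EFFECT (RR/OR/HR), SE or L95/U95, N_CASES, N_NONCASES.

    EFFECT is on the ratio scale and is logged on the way in; L95/U95 are on
    the ratio scale too.
    """
    df = pd.read_csv(path, sep="\t", na_values=["."])
    for col in ("STUDY", "EFFECT"):
        if col not in df.columns:
            raise ValidationError(f"mandatory column {col!r} missing from {path}")
    out: list[StudyEstimate] = []
    for _, row in df.iterrows():
        theta = float(np.log(row["EFFECT"]))
        if "SE" in df.columns and not pd.isna(row.get("SE")):
            se = float(row["SE"])
        else:
            se = se_from_ci(float(row["L95"]), float(row["U95"]), log_scale=True)
        out.append(
            StudyEstimate(
                study=str(row["STUDY"]),
                theta=theta,
                se=se,
                n_cases=None if pd.isna(row.get("N_CASES")) else int(row["N_CASES"]),
                n_noncases=None if pd.isna(row.get("N_NONCASES")) else int(row["N_NONCASES"]),
            )
        )
    return out
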