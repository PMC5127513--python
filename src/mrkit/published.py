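"""Published lead-variant association estimates used by the worked examples.

These are the printed per-allele summary statistics from the genome-wide
meta-analysis of branched-chain amino acid (BCAA) levels in 16,596 individuals
and the companion type 2 diabetes case-control meta-analyses (up to 47,877
cases / 267,694 controls), plus the pooled observational per-SD estimates from
the prospective-study meta-analysis (1,992 incident cases, 4,319 non-cases).
Metabolite betas are per effect-allele copy in SD units; disease effects are
odds ratios with 95% CIs, converted to log-odds internally.

The GCKR locus (rs1260326) is associated with many traits beyond BCAA levels;
as a known pleiotropic locus it is excluded from the isoleucine instrument
set by default, mirroring standard MR practice.
"""

from __future__ import annotations

import pandas as pd

from .meta import MetaResult, StudyEstimate, fixed_effect_meta
from .sumstats import AssocStat, HarmonisedPair, VariantRecord, se_from_ci
import math

#: Lead-variant per-allele associations: metabolite level (SD units) and
#: type 2 diabetes (OR with 95% CI).  ``pleiotropic`` marks the GCKR locus.
_LEAD_ROWS = [
    # metabolite, locus, rsid, chrom, pos, EA, OA, EAF, beta, se, p_met, n_cases, n_controls, OR, L95, U95, p_t2d, pleiotropic
    ("isoleucine", "PPM1K", "rs7678928", "4", 89222827, "T", "C", 0.46, 0.09, 0.013, 5.6e-19, 25208, 209575, 1.03, 1.01, 1.05, 0.0055, False),
    ("isoleucine", "GCKR", "rs1260326", "2", 27730940, "T", "C", 0.41, 0.06, 0.012, 1.1e-09, 47877, 267694, 0.94, 0.92, 0.96, 3.9e-11, True),
    ("isoleucine", "DDX19A", "rs75950518", "16", 70378917, "C", "T", 0.89, 0.11, 0.019, 2.1e-08, 13037, 152713, 1.05, 1.01, 1.10, 0.016, False),
    ("isoleucine", "TRMT61A", "rs58101275", "14", 104008420, "G", "A", 0.79, 0.09, 0.015, 2.8e-08, 13037, 152713, 1.04, 1.01, 1.08, 0.012, False),
    ("isoleucine", "CBLN1", "rs1420601", "16", 49085649, "C", "T", 0.40, 0.07, 0.013, 3.7e-08, 13037, 152713, 1.01, 0.98, 1.04, 0.53, False),
    ("leucine", "PPM1K", "rs1440581", "4", 89226422, "C", "T", 0.53, 0.08, 0.013, 3.9e-25, 30169, 215523, 1.04, 1.02, 1.07, 0.00034, False),
    ("valine", "PPM1K", "rs1440581", "4", 89226422, "C", "T", 0.53, 0.10, 0.013, 4.4e-24, 30169, 215523, 1.04, 1.02, 1.07, 0.00034, False),
]

#: Total sample size of the metabolite genome-wide meta-analysis.
N_METABOLITE_GWAS = 16_596

#: Pooled observational estimates: relative risk of incident type 2 diabetes
#: per 1 SD of baseline amino acid level (prospective-study meta-analysis).
_OBSERVATIONAL_ROWS = [
    ("isoleucine", 1.31, 1.11, 1.54, 1992, 4319),
    ("leucine", 1.22, 1.03, 1.43, 1992, 4319),
    ("valine", 1.34, 1.12, 1.61, 1992, 4319),
]


def bcaa_lead_variants() -> pd.DataFrame:
    """The lead-variant table as a DataFrame (one row per metabolite-locus pair)."""
    return pd.DataFrame(
        _LEAD_ROWS,
        columns=[
            "metabolite", "locus", "rsid", "chrom", "pos", "ea", "oa", "eaf",
            "beta", "se", "p_met", "n_cases", "n_controls", "or_t2d", "l95",
            "u95", "p_t2d", "pleiotropic",
        ],
    )


def instrument_pairs(metabolite: str, include_pleiotropic: bool = False) -> list[HarmonisedPair]:
    """Harmonised exposure/outcome instrument pairs for one amino acid.

    Disease ORs are logged and their CIs converted to log-odds SEs.  The
    pleiotropic GCKR variant is excluded unless explicitly requested.
    """
    rows = [r for r in _LEAD_ROWS if r[0] == metabolite]
    if not rows:
        raise ValueError(f"unknown metabolite {metabolite!r}; expected isoleucine/leucine/valine")
    pairs = []
    for (_, locus, rsid, chrom, pos, ea, oa, eaf, beta, se, p_met,
         n_cases, n_controls, or_t2d, l95, u95, p_t2d, pleio) in rows:
        if pleio and not include_pleiotropic:
            continue
        variant = VariantRecord(rsid, chrom, pos, ea, oa, eaf)
        gamma = AssocStat(
            variant=variant, trait=metabolite, beta=beta, se=se, p=p_met,
            n=N_METABOLITE_GWAS,
        )
        Gamma = AssocStat(
            variant=variant, trait="type 2 diabetes",
            beta=math.log(or_t2d), se=se_from_ci(l95, u95, log_scale=True),
            p=p_t2d, n=n_cases + n_controls, n_cases=n_cases, n_controls=n_controls,
        )
        pairs.append(HarmonisedPair(variant_id=rsid, gamma=gamma, Gamma=Gamma))
    return pairs


def observational_estimates() -> pd.DataFrame:
    """Pooled observational per-SD relative risks for the three BCAAs."""
    return pd.DataFrame(
        _OBSERVATIONAL_ROWS,
        columns=["metabolite", "rr", "l95", "u95", "n_cases", "n_noncases"],
    )


def observational_pooled(metabolite: str) -> MetaResult:
    """The pooled observational estimate wrapped as a single-'study' MetaResult."""
    rows = [r for r in _OBSERVATIONAL_ROWS if r[0] == metabolite]
    if not rows:
        raise ValueError(f"unknown metabolite {metabolite!r}")
    _, rr, l95, u95, n_cases, n_noncases = rows[0]
    est = StudyEstimate(
        study="pooled prospective studies",
        theta=math.log(rr),
        se=se_from_ci(l95, u95, log_scale=True),
        n_cases=n_cases,
        n_noncases=n_noncases,
    )
    return fixed_effect_meta([est])
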