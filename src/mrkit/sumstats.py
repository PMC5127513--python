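"""GWAS summary-statistic data model, readers/writers, and allele harmonisation.

Summary statistics are the per-variant association estimates produced by a
genome-wide scan: an effect size per copy of the *effect allele* (in SD units
of a quantitative trait, or log-odds for a binary one), its standard error,
p-value and sample size.  Two-sample Mendelian randomisation combines an
exposure file and an outcome file, which requires that every variant's effect
be expressed relative to the same allele on the same strand — the job of
:func:`harmonise`.

Odds ratios are carried internally as log-odds; confidence intervals are
converted to standard errors with a fixed normal quantile so the conversion is
reproducible bit-for-bit.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Standard-normal 97.5% quantile, fixed at 6 decimal places so that
#: CI <-> SE conversions round-trip identically everywhere in the package.
Z_975 = 1.959964

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Effect-allele-frequency window inside which a palindromic (A/T or G/C)
#: variant's strand cannot be inferred from frequency alone.
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)


class SumstatsFormatError(ValueError):
    """A summary-statistics file is structurally unreadable (missing columns, non-square LD block, ...)."""


class ValidationError(ValueError):
    """A value violates a domain invariant (EAF out of range, non-positive SE, ...)."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP: identifier, 1-based position, alleles and effect-allele frequency."""

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float

    def __post_init__(self) -> None:
        if self.effect_allele not in _COMPLEMENT or self.other_allele not in _COMPLEMENT:
            raise ValidationError(
                f"{self.id}: alleles must be single bases A/C/G/T, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.id}: effect and other allele are identical")
        if self.pos < 1:
            raise ValidationError(f"{self.id}: position must be >= 1 (1-based coordinates)")
        if not (0.0 < self.eaf < 1.0):
            raise ValidationError(f"{self.id}: EAF {self.eaf} outside (0, 1)")

    @property
    def is_palindromic(self) -> bool:
        """True for A/T or G/C variants, whose strand is ambiguous."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    def flipped(self) -> "VariantRecord":
        """The same variant coded on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf,
        )


@dataclass(frozen=True)
class AssocStat:
    """One variant <-> trait association.

    ``beta`` is per effect-allele copy: SD units for quantitative traits,
    log-odds for binary ones.
    """

    variant: VariantRecord
    trait: str
    beta: float
    se: float
    p: float
    n: int
    n_cases: int | None = None
    n_controls: int | None = None
    z: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError(f"{self.variant.id}: SE must be positive, got {self.se}")
        if not (0.0 < self.p <= 1.0):
            raise ValidationError(f"{self.variant.id}: p-value {self.p} outside (0, 1]")
        if self.n <= 0:
            raise ValidationError(f"{self.variant.id}: sample size must be positive")
        if self.z is not None:
            implied = self.beta / self.se
            if abs(self.z - implied) > 1e-6 * max(1.0, abs(self.z)):
                raise ValidationError(
                    f"{self.variant.id}: z={self.z} inconsistent with beta/se={implied}"
                )

    def flipped(self) -> "AssocStat":
        """The same association coded on the other allele (beta negated)."""
        return replace(
            self,
            variant=self.variant.flipped(),
            beta=-self.beta,
            z=None if self.z is None else -self.z,
        )


class LDMatrix:
    """Pairwise linkage-disequilibrium correlations r between variants.

    The matrix is symmetrised on construction; ``repair=True`` additionally
    clips negative eigenvalues to zero and restores the unit diagonal, which
    is needed for downstream Cholesky-based solvers.
    """

    def __init__(self, ids: list[str], r: np.ndarray, repair: bool = True):
        r = np.asarray(r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise SumstatsFormatError(f"LD matrix must be square, got shape {r.shape}")
        if len(ids) != r.shape[0]:
            raise SumstatsFormatError(
                f"{len(ids)} ids but {r.shape[0]}x{r.shape[1]} matrix"
            )
        asym = np.abs(r - r.T).max() if r.size else 0.0
        if asym > 1e-8:
            warnings.warn(
                f"LD matrix asymmetric (max deviation {asym:.3g}); symmetrised as (R+R')/2",
                stacklevel=2,
            )
        r = (r + r.T) / 2.0
        if np.abs(r).max(initial=0.0) > 1.0 + 1e-9:
            raise ValidationError("LD correlations must satisfy |r| <= 1")
        np.fill_diagonal(r, 1.0)
        if repair:
            r = _repair_psd(r)
        self.ids = list(ids)
        self.r = r

    def __len__(self) -> int:
        return len(self.ids)

    def submatrix(self, ids: list[str]) -> "LDMatrix":
        index = {v: i for i, v in enumerate(self.ids)}
        missing = [v for v in ids if v not in index]
        if missing:
            raise ValidationError(f"variants absent from LD matrix: {', '.join(missing)}")
        idx = [index[v] for v in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)], repair=False)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.r).min())


def _repair_psd(r: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to zero and renormalise to unit diagonal."""
    w, v = np.linalg.eigh(r)
    if w.min(initial=0.0) >= 0.0:
        return r
    if w.min() < -1e-10:  # below numerical noise: a genuinely inconsistent matrix
        warnings.warn(
            f"LD matrix not positive semidefinite (min eigenvalue {w.min():.3g}); "
            "repaired by eigenvalue clipping",
            stacklevel=3,
        )
    w = np.clip(w, 0.0, None)
    repaired = (v * w) @ v.T
    d = np.sqrt(np.diag(repaired))
    d[d == 0] = 1.0
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return repaired


@dataclass(frozen=True)
class HarmonisedPair:
    """An exposure/outcome association pair expressed on a common effect allele."""

    variant_id: str
    gamma: AssocStat  # SNP -> exposure, SD units per allele
    Gamma: AssocStat  # SNP -> outcome, log-odds per allele
    flipped: bool = False
    palindromic_flag: bool = False

    def __post_init__(self) -> None:
        if self.gamma.variant.effect_allele != self.Gamma.variant.effect_allele:
            raise ValidationError(
                f"{self.variant_id}: exposure/outcome effect alleles differ after alignment"
            )


@dataclass
class HarmoniseResult:
    """Kept pairs plus the variants excluded during alignment, with reasons."""

    pairs: list[HarmonisedPair]
    excluded: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# CI <-> SE conversion


def se_from_ci(lower: float, upper: float, level: float = 0.95, log_scale: bool = True) -> float:
    """Standard error implied by a symmetric confidence interval.

    For ratio measures (odds/hazard/risk ratios) the interval is symmetric on
    the log scale, so pass ``log_scale=True`` and the bounds on the ratio
    scale.
    """
    if lower > upper:
        raise ValidationError(f"CI lower bound {lower} exceeds upper bound {upper}")
    if not (0.0 < level < 1.0):
        raise ValidationError(f"confidence level {level} outside (0, 1)")
    if level == 0.95:
        zq = Z_975
    else:
        zq = float(sps.norm.ppf((1.0 + level) / 2.0))
    t = math.log if log_scale else (lambda x: x)
    return (t(upper) - t(lower)) / (2.0 * zq)


# ---------------------------------------------------------------------------
# Readers / writers

#: Canonical tab-separated dialect.  BETA/SE may be replaced by OR and either
#: SE (of the log-OR) or L95/U95 bounds of the OR.
DEFAULT_DIALECT = {
    "id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "or": "OR",
    "se": "SE",
    "l95": "L95",
    "u95": "U95",
    "p": "P",
    "n": "N",
    "n_cases": "N_CASES",
    "n_controls": "N_CONTROLS",
}

_MANDATORY = ("id", "chrom", "pos", "effect_allele", "other_allele", "eaf", "p", "n")


def read_sumstats(path, trait: str = "trait", dialect: dict[str, str] | None = None) -> list[AssocStat]:
    """Read per-variant association statistics from a delimited text file.

    Rows may report an effect as BETA+SE or as OR with either SE or a 95% CI;
    odds ratios are converted to log-odds on the way in.  Malformed rows are
    skipped and reported (with 1-based line numbers) via a warning; structural
    problems raise :class:`SumstatsFormatError`.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=True)
    for key in _MANDATORY:
        if d[key] not in df.columns:
            raise SumstatsFormatError(f"mandatory column {d[key]!r} missing from {path}")
    has_beta = d["beta"] in df.columns
    has_or = d["or"] in df.columns
    if not has_beta and not has_or:
        raise SumstatsFormatError(f"need a {d['beta']!r} or {d['or']!r} column in {path}")
    has_se = d["se"] in df.columns
    has_ci = d["l95"] in df.columns and d["u95"] in df.columns
    if not has_se and not has_ci:
        raise SumstatsFormatError(
            f"need an {d['se']!r} column or {d['l95']!r}/{d['u95']!r} bounds in {path}"
        )

    records: list[AssocStat] = []
    bad_lines: list[int] = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            records.append(_parse_row(row, d, trait, has_beta, has_se))
        except ValidationError:
            raise
        except (ValueError, TypeError, KeyError):
            bad_lines.append(line_no)
    if bad_lines:
        warnings.warn(
            f"{path}: skipped {len(bad_lines)} malformed row(s) at line(s) "
            + ", ".join(map(str, bad_lines)),
            stacklevel=2,
        )
    return records


def _parse_row(row, d, trait, has_beta, has_se) -> AssocStat:
    eaf = float(row[d["eaf"]])
    if not (0.0 < eaf < 1.0):
        raise ValidationError(f"{row[d['id']]}: EAF {eaf} outside (0, 1)")
    variant = VariantRecord(
        id=str(row[d["id"]]),
        chrom=str(row[d["chrom"]]),
        pos=int(row[d["pos"]]),
        effect_allele=str(row[d["effect_allele"]]).upper(),
        other_allele=str(row[d["other_allele"]]).upper(),
        eaf=eaf,
    )
    if has_beta and not pd.isna(row.get(d["beta"])):
        beta = float(row[d["beta"]])
        log_input = False
    else:
        beta = math.log(float(row[d["or"]]))
        log_input = True
    if has_se and not pd.isna(row.get(d["se"])):
        se = float(row[d["se"]])
    else:
        se = se_from_ci(float(row[d["l95"]]), float(row[d["u95"]]), log_scale=log_input)
    kwargs = {}
    for opt in ("n_cases", "n_controls"):
        if d[opt] in row.index and not pd.isna(row[d[opt]]):
            kwargs[opt] = int(float(row[d[opt]]))
    return AssocStat(
        variant=variant,
        trait=trait,
        beta=beta,
        se=se,
        p=float(row[d["p"]]),
        n=int(float(row[d["n"]])),
        **kwargs,
    )


def write_sumstats(records: list[AssocStat], path) -> None:
    """Write associations in the canonical tab-separated dialect (betas, not ORs)."""
    rows = []
    for s in records:
        rows.append(
            {
                "SNP": s.variant.id,
                "CHR": s.variant.chrom,
                "POS": s.variant.pos,
                "EA": s.variant.effect_allele,
                "OA": s.variant.other_allele,
                "EAF": repr(s.variant.eaf),
                "BETA": repr(s.beta),
                "SE": repr(s.se),
                "P": repr(s.p),
                "N": s.n,
                "N_CASES": "." if s.n_cases is None else s.n_cases,
                "N_CONTROLS": "." if s.n_controls is None else s.n_controls,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ld(path) -> LDMatrix:
    """Read an LD matrix from TSV whose first row and column carry variant ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise SumstatsFormatError(f"LD matrix in {path} is not square: {df.shape}")
    if list(df.index) != list(df.columns):
        raise SumstatsFormatError(f"row/column ids disagree in {path}")
    return LDMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_ld(ld: LDMatrix, path) -> None:
    df = pd.DataFrame(ld.r, index=ld.ids, columns=ld.ids)
    df.to_csv(path, sep="\t", float_format="%.12g")


# ---------------------------------------------------------------------------
# Harmonisation


def _alignment(exp_v: VariantRecord, out_v: VariantRecord) -> str | None:
    """How the outcome alleles map onto the exposure alleles.

    Returns ``"same"``, ``"flip"`` or ``None`` (irreconcilable).  Strand flips
    (both alleles complemented) are resolved transparently.
    """
    ea, oa = exp_v.effect_allele, exp_v.other_allele
    cand = (out_v.effect_allele, out_v.other_allele)
    comp = (_COMPLEMENT[out_v.effect_allele], _COMPLEMENT[out_v.other_allele])
    if cand == (ea, oa) or comp == (ea, oa):
        return "same"
    if cand == (oa, ea) or comp == (oa, ea):
        return "flip"
    return None


def harmonise(
    exposure: list[AssocStat],
    outcome: list[AssocStat],
    policy: str = "exclude",
    palindromic_window: tuple[float, float] = PALINDROMIC_EAF_WINDOW,
) -> HarmoniseResult:
    """Align exposure and outcome associations to a shared effect allele.

    When the outcome's effect allele is the exposure's other allele, its beta
    is negated and EAF complemented.  Palindromic variants (A/T or G/C) whose
    EAF lies inside ``palindromic_window`` cannot be strand-resolved; the
    default policy excludes them (``policy="keep"`` retains them, flagged).
    Variants present in only one list are dropped with a logged count.
    """
    if policy not in ("exclude", "keep"):
        raise ValidationError(f"unknown palindromic policy {policy!r}")
    out_by_id = {s.variant.id: s for s in outcome}
    pairs: list[HarmonisedPair] = []
    excluded: dict[str, str] = {}
    n_unpaired = 0
    for exp in exposure:
        vid = exp.variant.id
        out = out_by_id.get(vid)
        if out is None:
            n_unpaired += 1
            continue
        lo, hi = palindromic_window
        palindromic = exp.variant.is_palindromic
        if palindromic and lo < exp.variant.eaf < hi and policy == "exclude":
            excluded[vid] = "palindromic_ambiguous_eaf"
            continue
        mode = _alignment(exp.variant, out.variant)
        if mode is None:
            excluded[vid] = "allele_mismatch"
            continue
        if mode == "flip":
            out = out.flipped()
        # Express the outcome record on the exposure's exact allele pair so the
        # pair invariant (identical effect alleles) holds even across strands.
        out = replace(out, variant=replace(exp.variant, eaf=out.variant.eaf))
        pairs.append(
            HarmonisedPair(
                variant_id=vid,
                gamma=exp,
                Gamma=out,
                flipped=(mode == "flip"),
                palindromic_flag=palindromic,
            )
        )
    n_out_only = len(out_by_id) - sum(1 for e in exposure if e.variant.id in out_by_id)
    if n_unpaired or n_out_only:
        logger.info(
            "harmonise: dropped %d exposure-only and %d outcome-only variants",
            n_unpaired,
            n_out_only,
        )
    return HarmoniseResult(pairs=pairs, excluded=excluded)
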