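"""Desk-scale association scanning, Z-score meta-analysis, lead-SNP selection,
LD-aware instrument pruning, and LD estimation from genotype dosages.

The scan fits one additive-coded regression per variant (linear for
quantitative phenotypes, logistic for binary ones) and reports Wald statistics
from the normal approximation.  Study-level results are combined with the
sample-size-weighted Z-score meta-analysis commonly used when effect sizes are
not on a shared measurement scale:

    z_pooled = sum_i sqrt(n_i) z_i / sqrt(sum_i n_i)

Loci are then summarised by greedy lead-SNP selection (smallest p-value below
the genome-wide threshold, claiming a +/- window around each lead) and
instrument sets are pruned so that all pairwise LD satisfies r^2 < r2_max.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .sumstats import AssocStat, LDMatrix, ValidationError, VariantRecord

GENOME_WIDE_P = 5e-8
LEAD_WINDOW_BP = 1_000_000
R2_MAX_DEFAULT = 0.8


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with entries in [0, 2]; NaN = missing."""

    samples: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValidationError(
                f"dosage matrix {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(self.dosages, initial=0) > 2:
                raise ValidationError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def missingness(self) -> np.ndarray:
        """Per-variant fraction of missing dosages."""
        return np.isnan(self.dosages).mean(axis=0)

    def mean_imputed(self) -> np.ndarray:
        """Dosages with per-variant mean imputation of missing entries."""
        d = self.dosages.copy()
        if np.isnan(d).any():
            means = np.nanmean(d, axis=0)
            idx = np.where(np.isnan(d))
            d[idx] = np.take(means, idx[1])
        return d

    def column(self, variant_id: str) -> np.ndarray:
        try:
            j = self.variant_ids.index(variant_id)
        except ValueError:
            raise ValidationError(f"variant {variant_id} not in genotype matrix") from None
        return self.dosages[:, j]


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Read a dosage matrix TSV: rows = individuals, columns = variants.

    The header carries variant ids as ``id:chrom:pos:EA:OA:eaf`` (or bare ids,
    in which case placeholder metadata is synthesised).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    variants = []
    for j, col in enumerate(df.columns):
        parts = str(col).split(":")
        if len(parts) == 6:
            variants.append(
                VariantRecord(parts[0], parts[1], int(parts[2]), parts[3], parts[4], float(parts[5]))
            )
        else:
            freq = float(np.nanmean(df[col])) / 2.0
            freq = min(max(freq, 1e-6), 1 - 1e-6)
            variants.append(VariantRecord(str(col), "0", j + 1, "A", "G", freq))
    return GenotypeMatrix(list(df.index.astype(str)), variants, df.to_numpy(dtype=float))


def write_dosage_tsv(gm: GenotypeMatrix, path) -> None:
    cols = [
        f"{v.id}:{v.chrom}:{v.pos}:{v.effect_allele}:{v.other_allele}:{v.eaf:.6g}"
        for v in gm.variants
    ]
    pd.DataFrame(gm.dosages, index=gm.samples, columns=cols).to_csv(path, sep="\t")


def read_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a VCF, using DS when present, else GT allele counts.

    Dosages count copies of the ALT allele, which becomes the effect allele.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    variants: list[VariantRecord] = []
    rows: list[list[float]] = []
    for rec in vf:
        if len(rec.alts or ()) != 1:
            continue  # biallelic only
        dos: list[float] = []
        for s in samples:
            call = rec.samples[s]
            if "DS" in call and call["DS"] is not None:
                dos.append(float(call["DS"]))
            else:
                gt = call.get("GT")
                if gt is None or any(a is None for a in gt):
                    dos.append(float("nan"))
                else:
                    dos.append(float(sum(gt)))
        arr = np.array(dos)
        eaf = float(np.nanmean(arr)) / 2.0
        eaf = min(max(eaf, 1e-6), 1 - 1e-6)
        variants.append(
            VariantRecord(
                rec.id or f"{rec.chrom}:{rec.pos}",
                str(rec.chrom),
                rec.pos,
                str(rec.alts[0]),
                str(rec.ref),
                eaf,
            )
        )
        rows.append(dos)
    vf.close()
    dos_matrix = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, variants, dos_matrix)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write hard-call genotypes (rounded dosages) to an uncompressed VCF."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">')
    chroms = sorted({v.chrom for v in gm.variants}, key=str)
    for c in chroms:
        header.add_line(f"##contig=<ID={c}>")
    for s in gm.samples:
        header.add_sample(s)
    order = sorted(range(len(gm.variants)), key=lambda j: (gm.variants[j].chrom, gm.variants[j].pos))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in order:
            v = gm.variants[j]
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos, alleles=(v.other_allele, v.effect_allele)
            )
            rec.id = v.id
            for i, s in enumerate(gm.samples):
                d = gm.dosages[i, j]
                if np.isnan(d):
                    rec.samples[s]["GT"] = (None, None)
                else:
                    k = int(round(d))
                    rec.samples[s]["GT"] = ((0, 0), (0, 1), (1, 1))[k]
                    rec.samples[s]["DS"] = float(d)
            out.write(rec)


# ---------------------------------------------------------------------------
# Association scan


@dataclass
class AssociationScan:
    """Scan output: testable associations plus a map of untestable variants to reasons."""

    stats: list[AssocStat]
    untestable: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.stats)

    def __len__(self) -> int:
        return len(self.stats)


def _wald_p(beta: float, se: float) -> float:
    z = beta / se
    return max(float(2.0 * sps.norm.sf(abs(z))), 5e-324)


def snp_association(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    model: str = "linear",
) -> AssociationScan:
    """Per-variant additive association scan.

    Quantitative phenotypes are standardised to SD units before fitting, so
    betas are per allele in SD units.  Binary phenotypes use logistic
    regression and betas are per-allele log-odds.  Missing dosages are
    mean-imputed per variant.  Monomorphic variants and non-converged logistic
    fits are flagged untestable rather than raising.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != genotypes.n_samples:
        raise ValidationError("phenotype length does not match number of individuals")
    if model not in ("linear", "logistic"):
        raise ValidationError(f"unknown model {model!r}")
    if model == "linear":
        y = (y - y.mean()) / y.std(ddof=0)
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    dos = genotypes.mean_imputed()
    n = genotypes.n_samples
    is_binary = model == "logistic"
    n_cases = int(y.sum()) if is_binary else None

    stats: list[AssocStat] = []
    untestable: dict[str, str] = {}
    for j, variant in enumerate(genotypes.variants):
        g = dos[:, j]
        if np.std(g) == 0.0:
            untestable[variant.id] = "monomorphic"
            continue
        X = np.column_stack([np.ones(n), g] if cov is None else [np.ones(n), g, cov])
        try:
            if is_binary:
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
                if not fit.mle_retvals.get("converged", True):
                    untestable[variant.id] = "logistic_nonconvergence"
                    continue
            else:
                fit = sm.OLS(y, X).fit()
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError, ValueError):
            untestable[variant.id] = "fit_failure"
            continue
        beta, se = float(fit.params[1]), float(fit.bse[1])
        if not np.isfinite(beta) or not np.isfinite(se) or se <= 0:
            untestable[variant.id] = "unstable_fit"
            continue
        stats.append(
            AssocStat(
                variant=variant,
                trait="phenotype",
                beta=beta,
                se=se,
                p=_wald_p(beta, se),
                n=n,
                n_cases=n_cases,
                n_controls=None if n_cases is None else n - n_cases,
            )
        )
    return AssociationScan(stats=stats, untestable=untestable)


# ---------------------------------------------------------------------------
# Sample-size-weighted Z meta-analysis


def meta_z(per_study: list[tuple[float, float]]) -> tuple[float, float]:
    """Pool per-study Z-scores weighted by sqrt(sample size).

    ``per_study`` holds (z, n) tuples with signs already aligned to a common
    effect allele.  Returns (pooled z, two-sided p).
    """
    if not per_study:
        raise ValidationError("meta_z needs at least one study")
    zs = np.array([z for z, _ in per_study], dtype=float)
    ns = np.array([n for _, n in per_study], dtype=float)
    if np.any(ns <= 0):
        raise ValidationError("all sample sizes must be positive")
    z_pooled = float(np.sum(np.sqrt(ns) * zs) / math.sqrt(np.sum(ns)))
    return z_pooled, float(2.0 * sps.norm.sf(abs(z_pooled)))


# ---------------------------------------------------------------------------
# Lead-SNP selection and pruning


@dataclass
class LeadSelection:
    """Lead variants tagging independent loci, with the window/threshold used."""

    leads: list[AssocStat]
    window: int = LEAD_WINDOW_BP
    threshold: float = GENOME_WIDE_P

    def __post_init__(self) -> None:
        for s in self.leads:
            if not s.p < self.threshold:
                raise ValidationError(f"lead {s.variant.id} has p {s.p} >= {self.threshold}")
        by_chrom: dict[str, list[int]] = {}
        for s in self.leads:
            by_chrom.setdefault(s.variant.chrom, []).append(s.variant.pos)
        for chrom, positions in by_chrom.items():
            positions.sort()
            for a, b in zip(positions, positions[1:]):
                if b - a <= self.window:
                    raise ValidationError(
                        f"leads on chromosome {chrom} at {a} and {b} are within the "
                        f"{self.window} bp window"
                    )

    @property
    def ids(self) -> list[str]:
        return [s.variant.id for s in self.leads]


def select_lead_snps(
    stats: list[AssocStat],
    threshold: float = GENOME_WIDE_P,
    window: int = LEAD_WINDOW_BP,
) -> LeadSelection:
    """Greedy lead-SNP selection.

    Repeatedly takes the unclaimed variant with the smallest p strictly below
    the threshold and claims +/- ``window`` base pairs around it on the same
    chromosome.  Ties are broken by (chrom, pos) ascending.  An empty
    selection is a valid result.
    """
    candidates = sorted(
        (s for s in stats if s.p < threshold),
        key=lambda s: (s.p, s.variant.chrom, s.variant.pos),
    )
    leads: list[AssocStat] = []
    for s in candidates:
        if any(
            lead.variant.chrom == s.variant.chrom
            and abs(lead.variant.pos - s.variant.pos) <= window
            for lead in leads
        ):
            continue
        leads.append(s)
    return LeadSelection(leads=leads, window=window, threshold=threshold)


def prune_correlated(
    stats: list[AssocStat],
    ld: LDMatrix,
    r2_max: float = R2_MAX_DEFAULT,
) -> list[str]:
    """Greedy LD pruning by ascending p-value.

    A candidate is kept only if its squared correlation with every
    already-kept variant is strictly below ``r2_max``; the returned id list
    therefore satisfies the all-pairs constraint.
    """
    index = {v: i for i, v in enumerate(ld.ids)}
    missing = [s.variant.id for s in stats if s.variant.id not in index]
    if missing:
        raise ValidationError(f"variants absent from LD matrix: {', '.join(missing)}")
    kept: list[str] = []
    for s in sorted(stats, key=lambda s: (s.p, s.variant.chrom, s.variant.pos)):
        i = index[s.variant.id]
        if all(ld.r[i, index[k]] ** 2 < r2_max for k in kept):
            kept.append(s.variant.id)
    return kept


def compute_ld(genotypes: GenotypeMatrix, ids: list[str] | None = None) -> LDMatrix:
    """Pearson correlation of mean-imputed dosage vectors, PSD-repaired.

    Zero-variance (monomorphic) variants have no defined correlation; they are
    dropped from the returned matrix with a warning naming them.
    """
    if ids is None:
        ids = genotypes.variant_ids
    index = {v: i for i, v in enumerate(genotypes.variant_ids)}
    missing = [v for v in ids if v not in index]
    if missing:
        raise ValidationError(f"variants absent from genotypes: {', '.join(missing)}")
    dos = genotypes.mean_imputed()[:, [index[v] for v in ids]]
    if dos.shape[0] < 2:
        raise ValidationError("need at least 2 individuals to estimate LD")
    sd = dos.std(axis=0)
    degenerate = [v for v, s in zip(ids, sd) if s == 0.0]
    if degenerate:
        warnings.warn(
            "LD undefined for zero-variance variant(s), dropped: " + ", ".join(degenerate),
            stacklevel=2,
        )
        keep = [v for v in ids if v not in set(degenerate)]
        dos = dos[:, [ids.index(v) for v in keep]]
        ids = keep
    r = np.corrcoef(dos, rowvar=False)
    r = np.atleast_2d(r)
    np.clip(r, -1.0, 1.0, out=r)
    return LDMatrix(list(ids), r)
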