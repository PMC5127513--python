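"""End-to-end orchestration: simulate -> scan -> leads/prune -> MR ->
observational meta-analysis -> specificity scan -> report.

A run is a pure function of its configuration: the top-level seed is split
deterministically per stage by hashing the stage name, so adding a stage
never perturbs earlier stages' random draws, and re-running an identical
configuration reproduces byte-identical numeric outputs.  The report is
written both as JSON (machine-readable) and as TSV tables; the manifest
records the configuration digest, seed, package version and per-file SHA-256
digests.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gwas import (
    AssociationScan,
    GenotypeMatrix,
    compute_ld,
    prune_correlated,
    select_lead_snps,
    snp_association,
    write_dosage_tsv,
)
from .meta import ConcordanceReport, StudyEstimate, compare_arms, fixed_effect_meta
from .mr import fit, to_or_scale
from .scores import ScoreDefinition, build_score, metabolome_scan, scale_score_to_sd
from .simulate import SimulationConfig, SyntheticCohort, block_ld, simulate_cohort
from .sumstats import ValidationError, harmonise


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is carried for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of (base seed, stage name), below 2^31."""
    digest = hashlib.blake2b(f"{base_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulation": {
        "n_individuals": 30_000,
        "variants": [
            {"eaf": 0.46, "gamma": 0.09},
            {"eaf": 0.89, "gamma": 0.11},
            {"eaf": 0.79, "gamma": 0.09},
            {"eaf": 0.40, "gamma": 0.07},
        ],
        "ld_blocks": None,
        "theta_or": 1.5,
        "prevalence": 0.10,
        "confounding": {"a": 0.3, "b": 0.3},
        "sampling": {"case_fraction": 1.0, "control_fraction": 1.0},
    },
    "analysis": {
        "threshold": 5e-8,
        "window": 1_000_000,
        "r2_max": 0.8,
        "exclude": [],
    },
    "observational": {"n_studies": 3},
    "scan": {"n_null_traits": 50, "alpha": 0.05},
    "exposure_name": "exposure",
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(source) -> dict:
    """Load a run configuration from a YAML path or a dict, over defaults."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    elif isinstance(source, dict):
        user = source
    else:
        raise ValidationError(f"cannot interpret configuration of type {type(source)}")
    return _merge(DEFAULT_CONFIG, user)


def _simulation_config(cfg: dict, seed: int) -> SimulationConfig:
    sim = cfg["simulation"]
    variants = sim["variants"]
    eaf = np.array([v["eaf"] for v in variants], dtype=float)
    gamma = np.array([v["gamma"] for v in variants], dtype=float)
    ld = None
    if sim.get("ld_blocks"):
        sizes = [b["size"] for b in sim["ld_blocks"]]
        rhos = [b["rho"] for b in sim["ld_blocks"]]
        ld = block_ld(sizes, rhos)
    return SimulationConfig(
        n_individuals=int(sim["n_individuals"]),
        eaf=eaf,
        gamma=gamma,
        ld=ld,
        confounder_exposure=float(sim["confounding"]["a"]),
        confounder_outcome=float(sim["confounding"]["b"]),
        theta=math.log(float(sim["theta_or"])),
        prevalence=float(sim["prevalence"]),
        case_fraction=float(sim["sampling"]["case_fraction"]),
        control_fraction=float(sim["sampling"]["control_fraction"]),
        seed=seed,
    )


@dataclass
class RunManifest:
    """Reproducibility record: config digest, seed, version, file digests."""

    config_digest: str
    seed: int
    version: str
    file_digests: dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""


@dataclass
class Report:
    """Aggregated run results; every number traces to a stage output file."""

    mr_results: dict[str, dict]
    observational: dict
    concordance: dict
    scan_summary: dict
    lead_table: pd.DataFrame
    truth: dict


def _mr_to_dict(result, label: str) -> dict:
    or_, (l95, u95), p = to_or_scale(result)
    return {
        "analysis": label,
        "method": result.method,
        "n_snps": result.n_snps,
        "theta": result.theta,
        "se": result.se,
        "or": or_,
        "l95": l95,
        "u95": u95,
        "p": p,
        "excluded": list(result.excluded_ids),
    }


def run(config_source, out_dir) -> tuple[Report, RunManifest]:
    """Execute the full pipeline; stages fail loudly with the stage named."""
    cfg = load_config(config_source)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    manifest = RunManifest(
        config_digest=hashlib.sha256(canonical.encode()).hexdigest(),
        seed=seed,
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    exposure_name = cfg["exposure_name"]

    def _stage(name, fn):
        try:
            return fn()
        except Exception as err:  # noqa: BLE001 — re-raised with stage context
            raise StageError(name, err) from err

    # --- simulate ---------------------------------------------------------
    sim_cfg = _simulation_config(cfg, stage_seed(seed, "simulate"))
    cohort: SyntheticCohort = _stage("simulate", lambda: simulate_cohort(sim_cfg))

    # --- association scans ------------------------------------------------
    exp_scan: AssociationScan = _stage(
        "exposure_scan", lambda: snp_association(cohort.genotypes, cohort.exposure, model="linear")
    )
    sampled = cohort.sampled
    sub_geno = GenotypeMatrix(
        [cohort.genotypes.samples[i] for i in sampled],
        cohort.genotypes.variants,
        cohort.genotypes.dosages[sampled],
    )
    out_scan: AssociationScan = _stage(
        "outcome_scan",
        lambda: snp_association(sub_geno, cohort.outcome[sampled], model="logistic"),
    )

    # --- lead selection, LD, pruning -------------------------------------
    ana = cfg["analysis"]
    leads = _stage(
        "leads",
        lambda: select_lead_snps(exp_scan.stats, float(ana["threshold"]), int(ana["window"])),
    )
    significant = [s for s in exp_scan.stats if s.p < float(ana["threshold"])]
    ld = _stage("ld", lambda: compute_ld(cohort.genotypes, [s.variant.id for s in significant]))
    pruned = _stage(
        "prune", lambda: prune_correlated(significant, ld, float(ana["r2_max"]))
    )

    # --- Mendelian randomisation ------------------------------------------
    def _mr():
        harmonised = harmonise(exp_scan.stats, out_scan.stats)
        by_id = {p.variant_id: p for p in harmonised.pairs}
        results = {}
        lead_pairs = [by_id[v] for v in leads.ids if v in by_id]
        if not lead_pairs:
            raise ValidationError("no genome-wide significant instruments survived harmonisation")
        exclude = [e for e in ana["exclude"] if e in {p.variant_id for p in lead_pairs}]
        results["independent_ivw"] = _mr_to_dict(
            fit(lead_pairs, method="ivw", excluded_ids=tuple(exclude)), "independent variants"
        )
        pruned_pairs = [by_id[v] for v in pruned if v in by_id]
        if len(pruned_pairs) >= 1:
            results["correlated_gls"] = _mr_to_dict(
                fit(pruned_pairs, method="gls", ld=ld.submatrix([p.variant_id for p in pruned_pairs])),
                "correlated variants",
            )
        return results, lead_pairs

    mr_results, lead_pairs = _stage("mr", _mr)

    # --- observational arm -------------------------------------------------
    def _observational():
        import statsmodels.api as sm

        n_studies = int(cfg["observational"]["n_studies"])
        idx = np.array_split(np.arange(cohort.genotypes.n_samples), n_studies)
        studies = []
        x = (cohort.exposure - cohort.exposure.mean()) / cohort.exposure.std(ddof=0)
        for k, ix in enumerate(idx):
            X = np.column_stack([np.ones(len(ix)), x[ix]])
            fit_k = sm.Logit(cohort.outcome[ix], X).fit(disp=0)
            studies.append(
                StudyEstimate(
                    study=f"study{k + 1}",
                    theta=float(fit_k.params[1]),
                    se=float(fit_k.bse[1]),
                    n_cases=int(cohort.outcome[ix].sum()),
                    n_noncases=int(len(ix) - cohort.outcome[ix].sum()),
                )
            )
        return fixed_effect_meta(studies)

    obs = _stage("observational", _observational)

    # --- specificity scan ---------------------------------------------------
    def _scan():
        rng = np.random.default_rng(stage_seed(seed, "scan"))
        weights = {p.variant_id: p.gamma.beta for p in lead_pairs}
        score_def = ScoreDefinition(
            tuple((p.gamma.variant, weights[p.variant_id]) for p in lead_pairs)
        )
        raw = build_score(cohort.genotypes, score_def)
        scaled = scale_score_to_sd(raw, cohort.exposure)
        m_null = int(cfg["scan"]["n_null_traits"])
        traits = pd.DataFrame(
            rng.standard_normal((cohort.genotypes.n_samples, m_null)),
            columns=[f"null_trait_{j + 1}" for j in range(m_null)],
        )
        traits.insert(0, exposure_name, cohort.exposure)
        return metabolome_scan(scaled, traits, alpha=float(cfg["scan"]["alpha"]))

    scan_res = _stage("scan", _scan)

    # --- report -------------------------------------------------------------
    genetic_key = "independent_ivw"
    from .mr import MRResult
    from .sumstats import Z_975

    g = mr_results[genetic_key]
    genetic_result = MRResult(
        method=g["method"], theta=g["theta"], se=g["se"],
        ci95=(g["theta"] - Z_975 * g["se"], g["theta"] + Z_975 * g["se"]),
        p=g["p"], n_snps=g["n_snps"], excluded_ids=tuple(g["excluded"]),
    )
    conc: ConcordanceReport = compare_arms(genetic_result, obs)

    lead_table = pd.DataFrame(
        [
            {
                "rsid": p.variant_id,
                "chrom": p.gamma.variant.chrom,
                "pos": p.gamma.variant.pos,
                "ea": p.gamma.variant.effect_allele,
                "oa": p.gamma.variant.other_allele,
                "eaf": p.gamma.variant.eaf,
                "beta_exposure": p.gamma.beta,
                "se_exposure": p.gamma.se,
                "p_exposure": p.gamma.p,
                "or_outcome": math.exp(p.Gamma.beta),
                "l95_outcome": math.exp(p.Gamma.beta - Z_975 * p.Gamma.se),
                "u95_outcome": math.exp(p.Gamma.beta + Z_975 * p.Gamma.se),
                "p_outcome": p.Gamma.p,
            }
            for p in lead_pairs
        ]
    )

    report = Report(
        mr_results={exposure_name: mr_results},
        observational={
            "theta": obs.theta, "se": obs.se, "rr": math.exp(obs.theta),
            "l95": math.exp(obs.ci95[0]), "u95": math.exp(obs.ci95[1]),
            "p": obs.p, "Q": obs.Q, "I2": obs.I2, "k": obs.k,
        },
        concordance={
            "genetic_theta": conc.genetic_theta,
            "observational_theta": conc.observational_theta,
            "ratio": conc.ratio,
            "ci_overlap": conc.ci_overlap,
        },
        scan_summary={
            "m": scan_res.m,
            "significant_traits": scan_res.significant_traits,
            "alpha": scan_res.alpha,
            "method": scan_res.method,
        },
        lead_table=lead_table,
        truth={
            "theta": sim_cfg.theta,
            "theta_or": math.exp(sim_cfg.theta),
            "prevalence": sim_cfg.prevalence,
            "gamma": sim_cfg.gamma.tolist(),
            "eaf": sim_cfg.eaf.tolist(),
            "seed": seed,
        },
    )

    # --- write outputs -----------------------------------------------------
    report_json = {
        "mr_results": report.mr_results,
        "observational": report.observational,
        "concordance": report.concordance,
        "scan_summary": report.scan_summary,
        "truth": report.truth,
    }
    (out / "report.json").write_text(json.dumps(report_json, indent=2, sort_keys=True))
    lead_table.to_csv(out / "leads.tsv", sep="\t", index=False)
    mr_rows = [
        {"exposure": exposure_name, **d} for d in report.mr_results[exposure_name].values()
    ]
    pd.DataFrame(mr_rows).drop(columns=["excluded"]).to_csv(out / "mr_results.tsv", sep="\t", index=False)
    scan_res.table.to_csv(out / "scan.tsv", sep="\t", index=False)
    write_dosage_tsv(cohort.genotypes, out / "genotypes.tsv")
    pheno = pd.DataFrame(
        {"id": cohort.genotypes.samples, "exposure": cohort.exposure, "outcome": cohort.outcome}
    )
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)

    for f in ("report.json", "leads.tsv", "mr_results.tsv", "scan.tsv", "genotypes.tsv", "phenotypes.tsv"):
        manifest.file_digests[f] = hashlib.sha256((out / f).read_bytes()).hexdigest()
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(asdict(manifest), indent=2, sort_keys=True))
    return report, manifest
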