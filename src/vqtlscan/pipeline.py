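"""Config-driven orchestration of the full vQTL / interaction analysis.

Stages: simulate (or load) -> phenotype transforms -> scale test -> vQTL
call -> candidate-gene dispersion scan -> interaction scan(s) -> stratified
effects -> LD -> power report. Every stage writes its artifact under the
configured output directory, and a RunReport records per-stage counts and
timings. The run is fully deterministic given the config seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import GenotypeMatrix, covariate_columns, covariate_design
from .dglm import dispersion_scan
from .interaction import (
    interaction_scan,
    interactions_to_frame,
    strata_to_frame,
    stratified_trait_means,
)
from .io import (
    read_genotypes,
    write_dosage_tsv,
    write_phenotypes,
    write_table,
    write_vcf,
)
from .ld import em_haplotype_freqs
from .power import power_curve
from .scan import call_vqtls, results_to_frame, scale_test
from .simulate import TraitSpec, simulate_covariates, simulate_genotypes, simulate_trait
from .transforms import rint

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "simulate_cohort"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run.

    Either ``simulate`` (a generator spec, see :func:`simulate_cohort`) or
    ``genotype_path``/``phenotype_path`` must be provided. Thresholds follow
    the genome-wide defaults; ``n_pcs_mean``/``n_pcs_variance`` select the
    covariate set per stage (10 PCs for association, 5 for the variance
    phenotype by default).
    """

    seed: int = 0
    out_dir: str = "vqtlscan_out"
    simulate: dict | None = None
    genotype_path: str | None = None
    genotype_format: str = "vcf"
    phenotype_path: str | None = None
    trait: str = "trait"
    n_pcs_mean: int = 10
    n_pcs_variance: int = 5
    maf_min: float = 0.001
    missing_rate_max: float = 0.1
    var_threshold: float = 5e-8
    mean_threshold: float = 5e-8
    candidate_regions: list = field(default_factory=list)
    candidate_maf_min: float = 0.10
    focal_variants: str | list = "auto"
    ld_pairs: list = field(default_factory=list)
    power: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def validate(self) -> None:
        for name in ("var_threshold", "mean_threshold", "maf_min", "missing_rate_max"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise PipelineError("config", "threshold", f"{name}={v} outside (0,1)")
        for region in self.candidate_regions:
            chrom, start, end = region
            if start > end:
                raise PipelineError("config", "region", f"malformed region {region}")
        if self.simulate is None and self.genotype_path is None:
            raise PipelineError(
                "config", "input", "either 'simulate' or 'genotype_path' is required"
            )
        for path in (self.genotype_path, self.phenotype_path):
            if path is not None and not Path(path).exists():
                raise PipelineError("config", "missing_file", str(path))


@dataclass
class RunReport:
    version: str = __version__
    config: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def simulate_cohort(sim: dict, seed: int):
    """Build a synthetic cohort from a generator spec.

    Spec keys: ``n``; ``null_variants`` (``count`` + ``maf`` or ``mafs``
    list); optional planted ``focal``/``partner`` variants (``id``, ``maf``)
    with ``beta_int`` between them; ``compensate_mean`` adds the main effect
    ``-beta_int * E[g_partner]`` at the focal variant so the interaction
    produces a pure variance signal there; optional ``gamma_var`` and
    ``beta_mean`` maps; ``base_sd``; ``n_pcs``.
    """
    n = int(sim["n"])
    nv = sim.get("null_variants", {})
    mafs = list(nv.get("mafs", [])) or [float(nv.get("maf", 0.2))] * int(nv.get("count", 0))
    ids = [f"null{i}" for i in range(len(mafs))]
    planted = []
    for key in ("focal", "partner"):
        if key in sim:
            planted.append((sim[key]["id"], float(sim[key]["maf"])))
    all_ids = ids + [p[0] for p in planted]
    all_mafs = mafs + [p[1] for p in planted]
    genotypes = simulate_genotypes(n, all_mafs, seed=seed, ids=all_ids)

    n_pcs = int(sim.get("n_pcs", 10))
    covs = simulate_covariates(n, seed=seed + 1, n_pcs=n_pcs)

    beta_mean = dict(sim.get("beta_mean", {}))
    beta_int = {}
    if "beta_int" in sim and len(planted) == 2:
        focal_id, partner_id = planted[0][0], planted[1][0]
        b = float(sim["beta_int"])
        beta_int[(focal_id, partner_id)] = b
        if sim.get("compensate_mean", False):
            p_partner = planted[1][1]
            beta_mean[focal_id] = beta_mean.get(focal_id, 0.0) - b * 2.0 * p_partner
    spec = TraitSpec(
        beta_mean=beta_mean,
        gamma_var=dict(sim.get("gamma_var", {})),
        beta_int=beta_int,
        covariate_effects=dict(sim.get("covariate_effects", {})),
        base_sd=float(sim.get("base_sd", 1.0)),
        intercept=float(sim.get("intercept", 0.0)),
    )
    phenotypes = simulate_trait(genotypes, covs, spec, seed=seed + 2)
    return genotypes, phenotypes, spec


def run_pipeline(config: PipelineConfig, log=print) -> RunReport:
    """Execute all configured stages; see module docstring for the order."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    full_cfg = config.to_dict()
    # header hashes cover analysis parameters only, not output location
    cfg_dict = {k: v for k, v in full_cfg.items() if k != "out_dir"}
    report = RunReport(config=full_cfg)

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            report.timings_s[name] = round(time.perf_counter() - t0, 3)
            report.counts[name] = counts
            log(f"[{name}] " + " ".join(f"{k}={v}" for k, v in counts.items()))

        return done

    # --- input -----------------------------------------------------------
    done = stage("input")
    if config.simulate is not None:
        genotypes, phenotypes, _ = simulate_cohort(config.simulate, config.seed)
        write_vcf(genotypes, out / "genotypes.vcf")
        write_dosage_tsv(genotypes, out / "genotypes.dosage.tsv")
        write_phenotypes(phenotypes, out / "phenotypes.tsv")
        skipped: dict[str, str] = {}
    else:
        try:
            genotypes, skipped = read_genotypes(config.genotype_path, config.genotype_format)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("input", "parse", str(exc)) from exc
        phenotypes = pd.read_csv(config.phenotype_path, sep="\t")
    done(
        individuals=genotypes.n_individuals,
        variants_read=genotypes.n_variants + len(skipped),
        variants_skipped=len(skipped),
    )

    trait = phenotypes[config.trait].to_numpy(dtype=float)
    cov_mean = covariate_design(
        phenotypes, covariate_columns(config.n_pcs_mean)
    )
    cov_var = covariate_design(
        phenotypes, covariate_columns(config.n_pcs_variance)
    )

    # --- scale test ------------------------------------------------------
    done = stage("scale_test")
    mean_res, var_res, excluded = scale_test(
        genotypes,
        trait,
        cov_var,
        maf_min=config.maf_min,
        missing_rate_max=config.missing_rate_max,
    )
    write_table(results_to_frame(mean_res, genotypes), out / "scan_mean.tsv",
                "scale_test:mean", cfg_dict)
    write_table(results_to_frame(var_res, genotypes), out / "scan_variance.tsv",
                "scale_test:variance", cfg_dict)
    done(tested=len(mean_res), excluded=len(excluded))

    # --- vQTL call -------------------------------------------------------
    done = stage("vqtl_call")
    calls = call_vqtls(mean_res, var_res, config.var_threshold, config.mean_threshold)
    call_frame = pd.DataFrame(
        [
            {
                "variant": c.variant,
                "mean_p": c.mean_p,
                "var_p": c.var_p,
                "var_beta": c.var_beta,
                "is_vqtl": c.is_vqtl,
            }
            for c in calls
        ]
    )
    write_table(call_frame, out / "vqtl_calls.tsv", "vqtl_call", cfg_dict)
    vqtls = [c.variant for c in calls if c.is_vqtl]
    done(evaluated=len(calls), vqtls_called=len(vqtls))

    # --- candidate-gene dispersion scan ---------------------------------
    if config.candidate_regions:
        done = stage("dispersion_scan")
        frames = []
        for chrom, start, end in config.candidate_regions:
            region = genotypes.region(str(chrom), int(start), int(end))
            if region.n_variants == 0:
                continue
            frame, _ = dispersion_scan(
                region, trait, cov_var, maf_min=config.candidate_maf_min
            )
            if not frame.empty:
                frame.insert(0, "region", f"{chrom}:{start}-{end}")
                frames.append(frame)
        disp = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        write_table(disp, out / "dispersion_scan.tsv", "dispersion_scan", cfg_dict)
        done(fitted=len(disp), significant=int(disp["significant"].sum()) if len(disp) else 0)

    # --- interaction scans ----------------------------------------------
    done = stage("interaction_scan")
    focals = vqtls if config.focal_variants == "auto" else list(config.focal_variants)
    mean_pheno = rint(trait)
    all_frames = []
    n_tested = 0
    for focal in focals:
        results, _ = interaction_scan(
            genotypes,
            focal,
            mean_pheno,
            cov_mean,
            maf_min=config.maf_min,
            missing_rate_max=config.missing_rate_max,
        )
        n_tested += len(results)
        all_frames.append(interactions_to_frame(results, genotypes))
    inter = (
        pd.concat(all_frames, ignore_index=True).sort_values("p")
        if all_frames
        else pd.DataFrame()
    )
    write_table(inter, out / "interactions.tsv", "interaction_scan", cfg_dict)
    done(focal_variants=len(focals), interactions_tested=n_tested)

    # --- stratified effects for the top hit ------------------------------
    if len(inter):
        done = stage("stratified")
        top = inter.iloc[0]
        strata = stratified_trait_means(
            mean_pheno,
            genotypes.dosage(top["focal"]),
            genotypes.dosage(top["partner"]),
        )
        write_table(strata_to_frame(strata), out / "strata_top_hit.tsv",
                    "stratified", cfg_dict)
        done(strata=len(strata), focal=top["focal"], partner=top["partner"])

    # --- LD ---------------------------------------------------------------
    if config.ld_pairs:
        done = stage("ld")
        rows = []
        for v1, v2 in config.ld_pairs:
            res = em_haplotype_freqs(genotypes.dosage(v1), genotypes.dosage(v2))
            rows.append(
                {
                    "variant1": v1, "variant2": v2, "method": res.method,
                    "pAB": res.pAB, "D": res.D, "Dprime": res.d_prime,
                    "R2": res.r2, "n": res.n,
                }
            )
        write_table(pd.DataFrame(rows), out / "ld.tsv", "ld", cfg_dict)
        done(pairs=len(rows))

    # --- power report -----------------------------------------------------
    if config.power is not None:
        done = stage("power")
        p = config.power
        curve = power_curve(
            p.get("mafs", [0.01, 0.05, 0.1, 0.2, 0.5]),
            p.get("effects", [0.01, 0.05, 0.1, 0.5]),
            int(p.get("n", 400000)),
            float(p.get("alpha", 5e-8)),
            p.get("mode", "product"),
        )
        write_table(curve, out / "power_curve.tsv", "power", cfg_dict)
        done(rows=len(curve))

    (out / "run_report.json").write_text(report.to_json())
    return report
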