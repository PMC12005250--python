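"""End-to-end orchestration: simulate/load -> split -> per-sub-cohort GWAS
-> harmonize -> correlation -> combine -> inflate -> evaluate.

Per-sub-cohort association jobs run serially or on a bounded in-process
thread pool; each job receives only its sub-cohort's genotype rows and
results are assembled in sub-cohort order, so the output is identical
across execution modes.
"""

from __future__ import annotations

import json
import logging
import os
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml

from . import assoc, cma_core, evaluation, gwas_io, splitter, synthetic_data
from .datatypes import (
    GenotypeData,
    InflationConfig,
    MetaResult,
    PhenotypeTable,
    SimulationConfig,
)
from .errors import InvalidConfigError

logger = logging.getLogger("cma.pipeline")


@dataclass
class PipelineConfig:
    """Everything one run needs; either a simulation block or input paths."""

    sim: Optional[SimulationConfig] = None
    bed_prefix: Optional[str] = None
    dosage_path: Optional[str] = None
    pheno_path: Optional[str] = None
    covar_path: Optional[str] = None
    trait_type: str = "quantitative"
    k: int = 2
    method: str = "CMA"  # CMA | MA | standard
    snp_selection: str = "all"
    inflation: Optional[InflationConfig] = None
    qc_maf_min: float = 0.01
    qc_mac_min: int = 20
    qc_missing_max: float = 0.1
    do_eval: bool = False
    alpha: float = 5e-8
    prs_threshold: float = 5e-8
    target_frac: float = 0.2
    mode: str = "serial"  # serial | parallel
    max_parallel_subcohorts: int = 2
    split_seed: int = 1
    eval_split_seed: int = 2

    def validate(self) -> None:
        if self.k < 1:
            raise InvalidConfigError(f"split index k={self.k} must be >= 1")
        if self.method not in ("CMA", "MA", "standard"):
            raise InvalidConfigError(f"unknown method {self.method!r}")
        if self.mode not in ("serial", "parallel"):
            raise InvalidConfigError(f"unknown execution mode {self.mode!r}")
        if self.max_parallel_subcohorts < 1:
            raise InvalidConfigError("parallel degree must be >= 1")
        if self.sim is None and self.bed_prefix is None and self.dosage_path is None:
            raise InvalidConfigError("either a simulation block or genotype inputs are required")


def make_subcohort_jobs(assignment) -> list:
    """(index, sample_ids) for every sub-cohort; sample subsets are
    disjoint with sizes differing by at most one."""
    return [(i, assignment.ids_for(i)) for i in range(1, assignment.k + 1)]


def _run_job(geno: GenotypeData, pheno: PhenotypeTable, index: int, ids):
    sub_geno = geno.subset_samples(ids)
    sub_pheno = pheno.subset(ids)
    return assoc.run_gwas(sub_geno, sub_pheno, cohort_label=f"subcohort{index}")


def _load_inputs(config: PipelineConfig):
    if config.sim is not None:
        geno, relmap, y, effects = synthetic_data.simulate_cohort(config.sim)
        pheno = PhenotypeTable(
            geno.sample_ids, y, np.zeros((geno.n_samples, 0)), config.sim.trait_type
        )
        return geno, pheno, effects
    if config.bed_prefix is not None:
        geno = gwas_io.read_plink(config.bed_prefix)
    else:
        geno = gwas_io.read_dosage_tsv(config.dosage_path)
    pheno = gwas_io.phenotype_from_files(config.pheno_path, config.covar_path, config.trait_type)
    return geno, pheno, None


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages, write artifacts under ``out_dir`` and return the
    in-memory results (meta, corr, report, sumstats)."""
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    t0 = time.time()
    manifest = {
        "seeds": {
            "sim_seed": config.sim.seed if config.sim else None,
            "split_seed": config.split_seed,
            "eval_split_seed": config.eval_split_seed,
        },
        "k": config.k,
        "method": config.method,
        "mode": config.mode,
        "stages": [],
    }

    geno, pheno, effects = _load_inputs(config)
    logger.info("inputs: %d samples x %d variants", geno.n_samples, geno.n_variants)
    manifest["stages"].append({"stage": "inputs", "n": geno.n_samples, "m": geno.n_variants})

    geno_target = pheno_target = None
    if config.do_eval:
        discovery_ids, target_ids = evaluation.discovery_target_split(
            geno.sample_ids, config.target_frac, config.eval_split_seed
        )
        geno_target = geno.subset_samples(target_ids)
        pheno_target = pheno.subset(target_ids).y
        geno = geno.subset_samples(discovery_ids)
        pheno = pheno.subset(discovery_ids)

    geno, qc_report = assoc.qc_filter(
        geno, config.qc_maf_min, config.qc_mac_min, config.qc_missing_max
    )
    qc_report.to_csv(os.path.join(out_dir, "qc_removed.tsv"), sep="\t", index=False)
    manifest["stages"].append({"stage": "qc", "kept": geno.n_variants, "removed": len(qc_report)})

    k = 1 if config.method == "standard" else config.k
    corr = None
    if k == 1:
        ss = assoc.run_gwas(geno, pheno, cohort_label="cohort")
        gwas_io.write_sumstats(ss, os.path.join(out_dir, "subcohort1.sumstats.tsv"))
        meta = cma_core.sumstats_to_meta(ss)
        sumstats = [ss]
    else:
        assignment = splitter.split_cohort(geno.sample_ids, k, config.split_seed)
        splitter.write_assignment(assignment, os.path.join(out_dir, "assignments.tsv"))
        jobs = make_subcohort_jobs(assignment)
        if config.mode == "parallel":
            with ThreadPoolExecutor(max_workers=config.max_parallel_subcohorts) as pool:
                futures = [pool.submit(_run_job, geno, pheno, i, ids) for i, ids in jobs]
                sumstats = [f.result() for f in futures]  # submit order = sub-cohort order
        else:
            sumstats = [_run_job(geno, pheno, i, ids) for i, ids in jobs]
        for ss in sumstats:
            gwas_io.write_sumstats(
                ss, os.path.join(out_dir, f"{ss.cohort_label}.sumstats.tsv")
            )
        harmonized = gwas_io.harmonize(sumstats)
        corr = cma_core.estimate_correlation(harmonized, config.snp_selection)
        meta = cma_core.combine(harmonized, corr, method=config.method)
    manifest["stages"].append({"stage": "combine", "variants": len(meta)})

    meta_raw = meta
    if config.inflation is not None:
        meta = cma_core.inflate(meta, config.inflation)
    write_meta(meta, os.path.join(out_dir, "meta.tsv"))

    sidecar = {
        "method": config.method,
        "k": k,
        "stage": meta.stage,
        "lambda_gc": meta.lambda_gc,
        "inflation_factor": meta.inflation_factor,
        "n_skipped": len(meta.skipped),
        "skipped": meta.skipped[:100],
    }
    if corr is not None:
        sidecar.update(
            {
                "labels": corr.labels,
                "r": corr.r.tolist(),
                "r_raw": corr.r_raw.tolist(),
                "n12": corr.n12.tolist(),
                "n": corr.n.tolist(),
                "n_variants_used": corr.n_variants_used,
            }
        )
    with open(os.path.join(out_dir, "meta.sidecar.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)

    report = None
    if config.do_eval and effects is not None and len(effects.causal_ids):
        report = evaluation.evaluate(
            meta,
            effects,
            alpha=config.alpha,
            geno_target=geno_target,
            pheno_target=pheno_target,
            prs_threshold=config.prs_threshold,
        )
        with open(os.path.join(out_dir, "eval.json"), "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)

    manifest["wall_time_s"] = round(time.time() - t0, 3)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {
        "meta": meta,
        "meta_raw": meta_raw,
        "corr": corr,
        "report": report,
        "sumstats": sumstats,
        "effects": effects,
    }


META_HEADER = ["ID", "CHROM", "POS", "A1", "A2", "FREQ", "N_EFF", "N_COHORTS",
               "BETA", "SE", "Z", "T", "P"]


def write_meta(meta: MetaResult, path) -> None:
    t = meta.table
    with open(path, "w") as fh:
        header = list(META_HEADER)
        has_se_t = "se_t" in t.columns
        if has_se_t:
            header.append("SE_T")
        fh.write("\t".join(header) + "\n")
        for row in t.itertuples(index=False):
            fields = [
                str(row.id), str(int(row.chrom)), str(int(row.pos)),
                str(row.a1), str(row.a2), f"{row.freq:.12g}",
                f"{row.n_eff:.12g}", str(int(row.n_cohorts)),
                f"{row.beta:.12g}", f"{row.se:.12g}", f"{row.z:.12g}",
                f"{row.T:.12g}", f"{row.p:.12g}",
            ]
            if has_se_t:
                fields.append(f"{row.se_t:.12g}")
            fh.write("\t".join(fields) + "\n")


def read_meta(path, sidecar_path=None) -> MetaResult:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    table = pd.DataFrame(
        {
            "id": df["ID"].astype(str),
            "chrom": df["CHROM"],
            "pos": df["POS"],
            "a1": df["A1"].astype(str),
            "a2": df["A2"].astype(str),
            "freq": df["FREQ"].astype(float),
            "n_eff": df["N_EFF"].astype(float),
            "n_cohorts": df["N_COHORTS"].astype(int),
            "beta": df["BETA"].astype(float),
            "se": df["SE"].astype(float),
            "z": df["Z"].astype(float),
            "T": df["T"].astype(float),
            "p": df["P"].astype(float),
        }
    )
    stage = "raw"
    lam = factor = None
    if sidecar_path and os.path.exists(sidecar_path):
        with open(sidecar_path) as fh:
            side = json.load(fh)
        stage = side.get("stage", "raw")
        lam = side.get("lambda_gc")
        factor = side.get("inflation_factor")
    return MetaResult(table=table, stage=stage, lambda_gc=lam, inflation_factor=factor)


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file mirroring its fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("sim", None)
    inflation = raw.pop("inflation", None)
    cfg = PipelineConfig(
        sim=SimulationConfig(**sim) if sim else None,
        inflation=InflationConfig(**inflation) if inflation else None,
        **{key: val for key, val in raw.items() if hasattr(PipelineConfig, key)},
    )
    if sim is not None:
        cfg.sim.maf_range = tuple(cfg.sim.maf_range)
    return cfg
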