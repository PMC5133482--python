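"""End-to-end orchestration: simulate -> adjust -> null fit -> scan -> compare.

Every stage is a thin call into the library modules; the pipeline adds
visit filtering, file plumbing, logging and a manifest that records the
seed, config echo and per-stage row counts so a run can be reproduced
exactly.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .pedigree import kinship_matrix, parse_pedigree
from .sem import SemModel, assemble_families, fit_ml
from .scan import build_null_cache, compare_models, gwas_scan, qq_plot
from .simulate import (SimulationConfig, read_dosage, read_phenotypes,
                       read_vcf, simulate_dataset, write_dataset)
from .tobit import residualize_dataset

log = logging.getLogger("pedsem")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (one YAML file)."""

    outdir: str = "pedsem_run"
    seed: int = 0
    models: tuple = ("ar", "lg")
    visits_used: int = 3
    threshold: float = 1e-5
    stages: tuple = ("simulate", "adjust", "fit-null", "scan", "compare")
    # inputs (used when "simulate" is not among the stages)
    ped_file: str | None = None
    pheno_file: str | None = None
    geno_file: str | None = None
    # simulator settings (dict of SimulationConfig overrides)
    simulate: dict = field(default_factory=dict)
    n_starts: int = 3
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        return cfg


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in order and write a manifest.

    Returns the manifest dict.  A stage failure raises
    :class:`StageError` naming the stage; earlier outputs remain on
    disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "pedsem_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
    }
    stages = list(config.stages)

    ped_file, pheno_file, geno_file = (config.ped_file, config.pheno_file,
                                       config.geno_file)
    try:
        if "simulate" in stages:
            sim_kw = dict(config.simulate)
            sim_kw.setdefault("seed", config.seed)
            sim_cfg = SimulationConfig(**sim_kw)
            peds, geno, geno_ids, mafs, phenos, truth = simulate_dataset(sim_cfg)
            paths = write_dataset(out / "data", peds, geno, geno_ids,
                                  phenos, mafs=mafs, truth=truth)
            ped_file, pheno_file = paths["pedigree"], paths["phenotypes"]
            geno_file = paths["dosage"]
            manifest["stages"]["simulate"] = {
                "n_families": len(peds),
                "n_individuals": int(sum(len(p) for p in peds)),
                "n_snps": int(geno.shape[1]),
                "n_phenotype_rows": int(len(phenos)),
                "files": paths}
            log.info("simulate: %d families, %d individuals, %d SNPs",
                     len(peds), sum(len(p) for p in peds), geno.shape[1])
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    try:
        peds = parse_pedigree(ped_file)
        kinships = {p.family_id: kinship_matrix(p) for p in peds}
        phenos = read_phenotypes(pheno_file)
        n_before = len(phenos)
        phenos = phenos[phenos["visit"] <= config.visits_used].copy()
        log.info("visit filter: kept %d of %d rows (visits <= %d)",
                 len(phenos), n_before, config.visits_used)
    except Exception as exc:
        raise StageError("load", exc) from exc

    residuals = None
    if "adjust" in stages:
        try:
            residuals = residualize_dataset(phenos)
            residuals.to_csv(out / "residuals.csv")
            manifest["stages"]["adjust"] = {
                "n_rows_in": int(len(phenos)),
                "n_individuals_out": int(len(residuals)),
                "n_visits": int(phenos["visit"].nunique())}
        except Exception as exc:
            raise StageError("adjust", exc) from exc

    fits, caches, scan_tables = {}, {}, {}
    if "fit-null" in stages or "scan" in stages:
        try:
            families = assemble_families(kinships, residuals,
                                         config.visits_used)
            for kind in config.models:
                model = SemModel(kind, config.visits_used)
                fit = fit_ml(model, families, fix_gamma_zero=True,
                             n_starts=config.n_starts, seed=config.seed)
                fits[kind] = (model, fit, families)
                (out / f"fit_null_{kind}.json").write_text(
                    json.dumps(fit.summary(), indent=2))
                manifest["stages"].setdefault("fit-null", {})[kind] = {
                    "loglik": float(fit.loglik),
                    "converged": bool(fit.converged),
                    "n_obs_used": int(fit.n_obs_used)}
                log.info("fit-null[%s]: loglik=%.3f converged=%s",
                         kind, fit.loglik, fit.converged)
        except StageError:
            raise
        except Exception as exc:
            raise StageError("fit-null", exc) from exc

    if "scan" in stages:
        try:
            if str(geno_file).endswith(".vcf") or str(geno_file).endswith(".vcf.gz"):
                geno_df, _ = read_vcf(geno_file)
            else:
                geno_df, _ = read_dosage(geno_file)
            for kind in config.models:
                model, fit, families = fits[kind]
                cache = build_null_cache(fit, model, families)
                caches[kind] = cache
                summary, table = gwas_scan(cache, geno_df,
                                           threshold=config.threshold,
                                           model_label=kind)
                scan_tables[kind] = table
                table.to_csv(out / f"scan_{kind}.tsv", sep="\t", index=False,
                             float_format="%.10g")
                pd.DataFrame({"expected": summary.qq_expected,
                              "observed": summary.qq_observed}).to_csv(
                    out / f"qq_{kind}.tsv", sep="\t", index=False,
                    float_format="%.6g")
                if config.make_plots:
                    qq_plot(summary, out / f"qq_{kind}.png")
                manifest["stages"].setdefault("scan", {})[kind] = {
                    "n_tested": summary.n_tested,
                    "lambda_gc": summary.lambda_gc,
                    "n_suggestive": len(summary.suggestive_hits),
                    "n_dropped_individuals": summary.n_dropped_individuals}
                log.info("scan[%s]: %d SNPs, lambda_gc=%.3f, %d suggestive",
                         kind, summary.n_tested, summary.lambda_gc,
                         len(summary.suggestive_hits))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("scan", exc) from exc

    if "compare" in stages and len(scan_tables) == 2:
        try:
            kinds = list(scan_tables)
            cmp = compare_models(scan_tables[kinds[0]], scan_tables[kinds[1]],
                                 threshold=config.threshold,
                                 labels=tuple(kinds))
            cmp.merged.to_csv(out / "compare.tsv", sep="\t", index=False,
                              float_format="%.10g")
            manifest["stages"]["compare"] = {
                "rank_correlation": cmp.rank_correlation,
                "overlap_hits": cmp.overlap_hits,
                "hits": {kinds[0]: cmp.hits_a, kinds[1]: cmp.hits_b},
                "shared_hit_ids": cmp.shared_hit_ids}
            log.info("compare: rho=%.3f shared hits=%d",
                     cmp.rank_correlation, cmp.overlap_hits)
        except Exception as exc:
            raise StageError("compare", exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest
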