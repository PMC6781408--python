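"""End-to-end pipeline driver: simulate -> filter -> standardize -> h2 -> GWAS -> BSA -> overlap.

A :class:`RunConfig` bundles every stage's settings plus one master seed;
:func:`run_pipeline` executes the stages, writes each stage's table to the
run directory, and returns a machine-readable summary (marker counts before
and after filtering, heritability estimates, significant-SNP / region /
overlap counts).  Identical config + seed gives byte-identical numerical
outputs; wall-clock timings go only to the plain-text log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import bsa as bsa_mod
from . import corroborate, geno, gwas, pheno, simpop

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "simulate"  # 'simulate' or 'real-data'
    out_dir: str = "spgwas_run"
    seed: int = 0
    sim: simpop.SimConfig = field(default_factory=simpop.SimConfig)
    gwas: gwas.GwasConfig = field(default_factory=gwas.GwasConfig)
    min_maf: float = 0.05
    min_reads: int = 40
    bsa_outlier_q: float = 0.005
    bsa_window: int = 15
    bsa_gap: int = 15
    overlap_window: int = 150_000
    write_grm: bool = False
    # real-data inputs
    vcf_path: Optional[str] = None
    phenotype_path: Optional[str] = None
    gff_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "real-data"):
            raise ValueError("mode must be 'simulate' or 'real-data'")
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    # -- YAML round trip -------------------------------------------------

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim_d = d.pop("sim", {}) or {}
        for key in ("founder_freq_range", "qtl_freq_range"):
            if sim_d.get(key) is not None:
                sim_d[key] = tuple(sim_d[key])
        if sim_d.get("plot_effects") is not None:
            sim_d["plot_effects"] = tuple(tuple(p) for p in sim_d["plot_effects"])
        gwas_d = d.pop("gwas", {}) or {}
        return cls(sim=simpop.SimConfig(**sim_d), gwas=gwas.GwasConfig(**gwas_d), **d)


def setup_run_logging(log_path) -> logging.Handler:
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("spgwas").addHandler(handler)
    logging.getLogger("spgwas").setLevel(logging.INFO)
    return handler


def _covariate_matrix(phenos: pd.DataFrame) -> np.ndarray:
    """Generation and selection-regime 0/1 indicators."""
    gen = phenos["generation"].to_numpy(float)
    regime = (phenos["regime"].astype(str) == "short").to_numpy(float)
    return np.column_stack([gen, regime])


def _realized_h2_from_truth(result: simpop.ExperimentResult) -> float:
    """Breeder's-equation h2 averaged over plots, on environment-corrected heights.

    Simulation truth supplies the plot-year fixed effects and the selected
    parents, so S and R can be computed on heights with the location-year
    effect removed (the confounding that complicates the estimator on real
    data).
    """
    cfg, truth = result.config, result.truth
    names = cfg.plot_names()
    ph = result.phenos_full
    estimates = []
    for p, name in enumerate(names):
        base = ph[(ph["plot"] == name) & (ph["generation"] == 0)]
        off = ph[(ph["plot"] == name) & (ph["generation"] == 1)]
        e0 = truth.plot_effects[(name, 0)]
        e1 = truth.plot_effects[(name, 1)]
        base_mean = base["height_cm"].mean() - e0
        sel = base[base["plant_id"].isin(set(truth.selected_ids[name]))]
        sel_mean = sel["height_cm"].mean() - e0
        off_mean = off["height_cm"].mean() - e1
        S = sel_mean - base_mean
        R = off_mean - base_mean
        estimates.append(pheno.realized_h2(S, R).h2)
    return float(np.mean(estimates))


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and return the summary dictionary.

    Raises a ``RuntimeError`` naming the failing stage on any error.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = setup_run_logging(out / "run.log")
    summary: dict = {"mode": cfg.mode, "seed": cfg.seed}
    stage = "setup"
    try:
        cfg.to_yaml(out / "config.yaml")

        # ---------------- inputs ----------------
        stage = "simulate" if cfg.mode == "simulate" else "load"
        t0 = time.perf_counter()
        sim_result = None
        if cfg.mode == "simulate":
            sim_result = simpop.simulate_experiment(cfg.sim)
            observed = sim_result.observed
            phenos = sim_result.phenos
            bulks = sim_result.bulks
            geno.write_vcf(observed, out / "genotypes.vcf")
            simpop.write_phenotypes(phenos, out / "phenotypes.tsv")
            simpop.write_truth(sim_result.truth, out / "truth.json")
        else:
            if cfg.vcf_path is None or not Path(cfg.vcf_path).exists():
                raise FileNotFoundError(f"genotype VCF not found: {cfg.vcf_path}")
            if cfg.phenotype_path is None or not Path(cfg.phenotype_path).exists():
                raise FileNotFoundError(f"phenotype table not found: {cfg.phenotype_path}")
            observed = geno.read_vcf(cfg.vcf_path)
            phenos = pheno.read_phenotypes(cfg.phenotype_path)
            gen1 = phenos[phenos["generation"] == 1]
            bulks = {
                regime: gen1.loc[gen1["regime"] == regime, "plant_id"].to_numpy(object)
                for regime in ("tall", "short")
            }
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)

        # ---------------- marker filtering ----------------
        stage = "filter"
        t0 = time.perf_counter()
        summary["n_markers_initial"] = observed.n_markers
        filtered = geno.filter_markers(observed, min_maf=cfg.min_maf, min_reads=cfg.min_reads)
        summary["n_markers_filtered"] = filtered.n_markers
        geno.write_vcf(filtered, out / "genotypes_filtered.vcf")
        logger.info("stage filter done in %.2fs", time.perf_counter() - t0)

        # ---------------- phenotype standardization ----------------
        stage = "standardize"
        phenos_std = pheno.standardize(phenos)
        order = pd.Index(observed.individual_ids)
        phenos_std = phenos_std.set_index("plant_id").loc[order].reset_index()
        y = phenos_std["residual"].to_numpy(float)
        covariates = _covariate_matrix(phenos_std)
        phenos_std.to_csv(out / "phenotypes_std.tsv", sep="\t", index=False,
                          float_format="%.6g")
        pheno.describe(phenos_std).to_csv(out / "descriptive_stats.tsv", sep="\t",
                                          index=False, float_format="%.6g")

        # ---------------- heritability ----------------
        stage = "h2"
        t0 = time.perf_counter()
        imputed = geno.impute_missing(filtered)
        grm = geno.compute_grm(imputed)
        if cfg.write_grm:
            geno.write_grm(grm, imputed.individual_ids, out / "grm.tsv")
        est = pheno.greml_h2(grm, y, covariates=covariates)
        summary["h2_greml"] = est.h2
        summary["h2_greml_boundary"] = bool(est.boundary)
        if sim_result is not None:
            summary["h2_realized"] = _realized_h2_from_truth(sim_result)
            summary["h2_true"] = float(sim_result.truth.true_h2)
        logger.info("stage h2 done in %.2fs", time.perf_counter() - t0)

        # ---------------- GWAS ----------------
        stage = "gwas"
        t0 = time.perf_counter()
        scan, qtns = gwas.pseudo_qtn_scan(imputed, y, covariates=covariates, cfg=cfg.gwas)
        sig = gwas.call_significant(scan, alpha=cfg.gwas.alpha)
        scan.to_csv(out / "gwas_scan.tsv", sep="\t", index=False, float_format="%.6g")
        sig.to_csv(out / "gwas_significant.tsv", sep="\t", index=False, float_format="%.6g")
        summary["n_markers_tested_gwas"] = len(scan)
        summary["n_significant_snps"] = len(sig)
        summary["n_pseudo_qtns"] = len(qtns)
        logger.info("stage gwas done in %.2fs", time.perf_counter() - t0)

        # ---------------- BSA ----------------
        stage = "bsa"
        t0 = time.perf_counter()
        bsa_scan, threshold, regions = bsa_mod.run_bsa(
            filtered, bulks["tall"], bulks["short"],
            q=cfg.bsa_outlier_q, window=cfg.bsa_window, gap=cfg.bsa_gap,
        )
        bsa_scan.to_csv(out / "bsa_scan.tsv", sep="\t", index=False, float_format="%.6g")
        regions_df = bsa_mod.regions_to_frame(regions)
        regions_df.to_csv(out / "bsa_regions.tsv", sep="\t", index=False, float_format="%.6g")
        summary["n_markers_tested_bsa"] = len(bsa_scan)
        summary["bsa_threshold_neglog10p"] = threshold
        summary["n_bsa_significant_markers"] = int(
            (bsa_scan["neg_log10_p"] > threshold).sum()
        )
        summary["n_regions"] = len(regions)
        logger.info("stage bsa done in %.2fs", time.perf_counter() - t0)

        # ---------------- corroboration ----------------
        stage = "overlap"
        report = corroborate.overlap(sig, regions_df)
        report.table.to_csv(out / "overlap.tsv", sep="\t", index=False, float_format="%.6g")
        summary["n_overlaps"] = report.n_overlaps
        if cfg.gff_path:
            ann = corroborate.annotate_nearby_genes(sig, cfg.gff_path, window=cfg.overlap_window)
            ann.to_csv(out / "candidate_genes.tsv", sep="\t", index=False)
            summary["n_candidate_genes"] = int(ann["gene_id"].nunique()) if len(ann) else 0

        stage = "summary"
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    finally:
        logging.getLogger("spgwas").removeHandler(handler)
        handler.close()
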