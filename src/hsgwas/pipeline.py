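"""End-to-end orchestration: simulate -> exposures -> QC -> GRM -> REML ->
scan -> annotate, fanned out over (trait, week) cells, with a JSON manifest
recording inputs, seeds, artifact hashes and failures."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import io
from .errors import ConfigurationError, HsGwasError
from .geno_qc import QcThresholds, apply_qc, mean_impute, prune_related, subset_grm, vanraden_grm
from .gwas_inter import classify_hits, gls_scan
from .synthdata import CausalMarker, FactorSpec, SimulationConfig
from .varcomp import build_design, ratios, reml_fit


@dataclasses.dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    traits: tuple = ("y",)
    weeks: tuple = tuple(range(1, 9))
    truth_week: int = 1
    model: str = "whs"
    simulation: Optional[SimulationConfig] = None
    # externally supplied inputs (used when simulation is None)
    genotype_prefix: Optional[str] = None
    dosage_csv: Optional[str] = None
    markers_csv: Optional[str] = None
    phenotypes_csv: Optional[str] = None
    exposure_csv: Optional[str] = None
    genes_path: Optional[str] = None
    genes_format: str = "gff3"
    flank_bp: int = annotate_mod.DEFAULT_FLANK_BP
    r2_cutoff: float = 0.15
    ld_window: int = 500
    rel_cutoff: float = 0.95
    qc: QcThresholds = dataclasses.field(default_factory=QcThresholds)

    def validate(self):
        if not self.weeks:
            raise ConfigurationError("week list is empty")
        if not all(1 <= w <= 8 for w in self.weeks):
            raise ConfigurationError("weeks must lie in 1..8")


def load_run_config(path) -> RunConfig:
    """RunConfig from a YAML file; the ``simulation`` block maps onto
    :class:`SimulationConfig` (causal/fixed-effect specs as nested lists)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulation", None)
    qc = raw.pop("qc", None)
    for key in ("traits", "weeks"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    if sim is not None:
        if "causal_spec" in sim:
            sim["causal_spec"] = tuple(CausalMarker(**c) for c in sim["causal_spec"])
        if "fixed_effect_spec" in sim:
            sim["fixed_effect_spec"] = tuple(
                FactorSpec(f["n_levels"], tuple(f.get("effect_range", (-1.0, 1.0))))
                for f in sim["fixed_effect_spec"])
        for key in ("maf_range", "bounding_box", "date_range", "variance_components"):
            if key in sim:
                sim[key] = tuple(sim[key])
        cfg.simulation = SimulationConfig(**sim)
    if qc is not None:
        if "autosomes" in qc:
            qc["autosomes"] = frozenset(qc["autosomes"])
        cfg.qc = QcThresholds(**qc)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, resume: bool = False) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest.

    Stage failures are recorded per (trait, week) cell; downstream stages of
    the failed cell are skipped, other cells continue.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "cells": {}, "artifacts": {}}
    t_start = time.time()

    def note_stage(name, **info):
        manifest["stages"].append({"stage": name, "elapsed_s": round(time.time() - t_start, 3), **info})

    # --- inputs: simulate or load ---------------------------------------
    if config.simulation is not None:
        from .synthdata import simulate_dataset

        sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
        ds = simulate_dataset(sim_cfg, week=config.truth_week, exposure_mode="weather")
        genotypes, exposure = ds.genotypes, ds.exposure
        phenotypes = ds.phenotypes.rename(columns={"y": config.traits[0]})
        io.write_dosage_csv(genotypes, out / "genotypes.csv", out / "markers.csv")
        io.write_exposure_csv(exposure, out / "exposure.csv")
        phenotypes.to_csv(out / "phenotypes.csv", index=False)
        (out / "truth.json").write_text(json.dumps(ds.truth.to_dict()))
        note_stage("simulate", n_animals=genotypes.n_animals, n_markers=genotypes.n_markers)
    else:
        if config.genotype_prefix:
            genotypes = io.read_plink(config.genotype_prefix)
        elif config.dosage_csv:
            genotypes = io.read_dosage_csv(config.dosage_csv, config.markers_csv)
        else:
            raise ConfigurationError("no genotype input configured")
        phenotypes = io.read_phenotypes_csv(config.phenotypes_csv)
        exposure = io.read_exposure_csv(config.exposure_csv)
        note_stage("load", n_animals=genotypes.n_animals, n_markers=genotypes.n_markers)

    # --- QC + GRM --------------------------------------------------------
    kept, report = apply_qc(genotypes, config.qc)
    (out / "qc_report.json").write_text(report.to_json())
    complete = mean_impute(kept)
    grm = vanraden_grm(complete)
    retained = prune_related(grm, cutoff=config.rel_cutoff)
    if len(retained) < grm.n:
        keep_idx = np.flatnonzero(np.isin(complete.animal_ids, retained))
        complete = complete.select(animal_idx=keep_idx)
        grm = vanraden_grm(complete)
    io.write_grm(grm, out / "grm")
    note_stage("qc_grm", markers_kept=kept.n_markers, animals_kept=grm.n)

    genes = None
    if config.genes_path:
        reader = (annotate_mod.read_gff3_genes if config.genes_format == "gff3"
                  else annotate_mod.read_bed_genes)
        genes = reader(config.genes_path)

    # --- per (trait, week) cells -----------------------------------------
    for trait in config.traits:
        for week in config.weeks:
            cell = f"{trait}_wk{week}"
            cell_info: dict = {"trait": trait, "week": week}
            if resume and (out / f"scan_{cell}.tsv").exists() \
                    and (out / f"varcomp_{cell}.json").exists():
                cell_info["status"] = "resumed"
                manifest["cells"][cell] = cell_info
                continue
            try:
                spec = build_design(phenotypes, trait, week, exposure, grm)
                exposed_n = int(spec.exposed_mask.sum())
                cell_info["n_exposed"] = exposed_n
                vc_nhs = reml_fit(spec, model="nhs")
                if config.model == "whs" and exposed_n > 0:
                    vc = reml_fit(spec, model="whs")
                    h2c, rhs = ratios(vc)
                    vc_report = {
                        "model": "VC_wHS", "sigma2_g": vc.sigma2_g,
                        "sigma2_ghs": vc.sigma2_ghs, "sigma2_e": vc.sigma2_e,
                        "h2_c": h2c, "r_hs": rhs, "loglik": vc.loglik,
                        "n_iter": vc.n_iter, "converged": vc.converged,
                    }
                else:
                    vc = vc_nhs
                    if config.model == "whs":
                        cell_info["downgraded"] = "no exposed animals: VC_wHS -> VC_nHS"
                    vc_report = {
                        "model": "VC_nHS", "sigma2_g": vc.sigma2_g,
                        "sigma2_e": vc.sigma2_e, "h2_g": ratios(vc_nhs),
                        "loglik": vc.loglik, "n_iter": vc.n_iter,
                        "converged": vc.converged,
                    }
                vc_report["nhs"] = {
                    "sigma2_g": vc_nhs.sigma2_g, "sigma2_e": vc_nhs.sigma2_e,
                    "h2_g": ratios(vc_nhs), "loglik": vc_nhs.loglik,
                }
                (out / f"varcomp_{cell}.json").write_text(json.dumps(vc_report, indent=2))

                scan = gls_scan(spec, vc, complete, trait=trait, week=week,
                                model="GWA_wHS" if vc.sigma2_ghs is not None else "GWA_nHS",
                                r2_cutoff=config.r2_cutoff, ld_window=config.ld_window)
                labeled = classify_hits(scan)
                labeled.to_csv(out / f"scan_{cell}.tsv", sep="\t", index=False)
                run_info = {
                    "lambda_main": scan.lambda_main, "lambda_inter": scan.lambda_inter,
                    "n_snps": scan.thresholds.n_snps,
                    "n_independent": scan.thresholds.n_independent,
                    "p_bonf": scan.thresholds.p_bonf, "p_sugg": scan.thresholds.p_sugg,
                    "neglog_bonf": scan.thresholds.neglog_bonf,
                    "neglog_sugg": scan.thresholds.neglog_sugg,
                }
                (out / f"scanmeta_{cell}.json").write_text(json.dumps(run_info, indent=2))

                if genes is not None:
                    hits = labeled[(labeled["label_main"] != "none")
                                   | (labeled["label_inter"] != "none")]
                    assoc = annotate_mod.window_genes(hits, genes, flank=config.flank_bp)
                    assoc.to_csv(out / f"genes_{cell}.csv", index=False)
                cell_info["status"] = "ok"
            except HsGwasError as exc:
                cell_info["status"] = "failed"
                cell_info["error"] = str(exc)
            manifest["cells"][cell] = cell_info

    for path in sorted(out.glob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["artifacts"][path.name] = _sha256(path)
    manifest["elapsed_s"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
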