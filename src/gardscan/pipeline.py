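"""Stage orchestration: simulate -> annotate -> qc -> assoc -> genetest ->
calibrate -> enrich -> report.

The configuration is a flat ``key: value`` text file.  Recognised keys
(with defaults) are listed in :data:`DEFAULTS`.  Identical config + seed
give byte-identical outputs.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from . import annotate as ann
from . import io as gio
from .calibration import logit_adjust
from .enrichment import enrich_catalog
from .gene_tests import DEFAULT_TESTS, GeneBattery
from .panel import CohortPanel
from .qc import QcThresholds, filter_variants
from .report import method_concordance, qq_data, significance_thresholds
from .simulate import SimConfig, simulate_cohort, write_cohort_files
from .snp_assoc import SnpAssociation

log = logging.getLogger("gardscan")

STAGES = ["simulate", "annotate", "qc", "assoc", "genetest", "calibrate",
          "enrich", "report"]

DEFAULTS = {
    "seed": 1,
    "stages": ",".join(STAGES),
    "out": "gardscan_out",
    # simulate
    "n_cases": 500, "n_controls": 500, "n_snps": 120, "n_genes": 20,
    "n_causal_genes": 3, "causal_beta": float(np.log(1.3)),
    # annotate
    "flank_bp": 500,
    # genetest
    "tests": ",".join(DEFAULT_TESTS), "n_perm": 499,
    # enrich / report
    "alpha": 0.05, "k_tot_snp": 500_000, "k_tot_gene": 19_404,
}


def read_config(path) -> dict:
    """Flat ``key: value`` config file; unknown keys are fatal."""
    cfg = dict(DEFAULTS)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key: value'")
            key, value = (s.strip() for s in line.split(":", 1))
            if key not in DEFAULTS:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            default = DEFAULTS[key]
            if isinstance(default, bool):
                cfg[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                cfg[key] = int(value)
            elif isinstance(default, float):
                cfg[key] = float(value)
            else:
                cfg[key] = value
    return cfg


def _require(path: str, stage: str) -> str:
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"stage {stage!r} needs missing upstream output {path}")
    return path


def run_pipeline(config_path, seed: int | None = None,
                 outdir: str | None = None) -> int:
    """Run the configured stages in fixed order; returns 0 on success."""
    cfg = read_config(config_path)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = outdir or cfg["out"]
    os.makedirs(out, exist_ok=True)
    stages = [s.strip() for s in str(cfg["stages"]).split(",") if s.strip()]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage name(s): {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    paths = {
        "vcf": os.path.join(out, "cohort.vcf"),
        "covar": os.path.join(out, "covariates.tsv"),
        "genes": os.path.join(out, "genes.bed"),
        "enhancers": os.path.join(out, "enhancers.bed"),
        "gmt": os.path.join(out, "terms.gmt"),
        "assignment": os.path.join(out, "assignment.tsv"),
        "qc": os.path.join(out, "qc_report.tsv"),
        "kept": os.path.join(out, "kept_variants.txt"),
        "assoc": os.path.join(out, "snp_assoc.tsv"),
        "genetest": os.path.join(out, "gene_tests.tsv"),
        "calibrated": os.path.join(out, "gene_tests_calibrated.tsv"),
        "enrich": os.path.join(out, "enrichment.tsv"),
        "thresholds": os.path.join(out, "thresholds.tsv"),
        "qq": os.path.join(out, "qq_data.tsv"),
        "concordance": os.path.join(out, "concordance.tsv"),
    }

    for stage in stages:
        log.info("stage %s starting", stage)
        if stage == "simulate":
            sim = SimConfig(n_cases=cfg["n_cases"],
                            n_controls=cfg["n_controls"],
                            n_snps=cfg["n_snps"], n_genes=cfg["n_genes"],
                            n_causal_genes=cfg["n_causal_genes"],
                            causal_beta=cfg["causal_beta"],
                            seed=cfg["seed"])
            panel, genes, enhancers, catalog, truth = simulate_cohort(sim)
            write_cohort_files(panel, genes, enhancers, catalog, truth, out)
            log.info("simulate: %d samples, %d variants written",
                     panel.n_samples, panel.n_variants)
        elif stage == "annotate":
            panel = gio.read_cohort(_require(paths["vcf"], stage),
                                    _require(paths["covar"], stage))
            genes = gio.read_gene_bed(_require(paths["genes"], stage))
            enh = gio.read_enhancer_bed(_require(paths["enhancers"], stage))
            assignment = ann.assign_variants(
                panel, genes, ann.fuse_enhancers(enh),
                flank_bp=cfg["flank_bp"])
            rows = [{"variant": v, "gene": g, "reason": r}
                    for v, pairs in sorted(assignment.mapping.items())
                    for g, r in pairs]
            gio.write_results(pd.DataFrame(rows), paths["assignment"])
            log.info("annotate: %d variant-gene pairs", len(rows))
        elif stage == "qc":
            panel = gio.read_cohort(_require(paths["vcf"], stage),
                                    _require(paths["covar"], stage))
            kept_panel, rep = filter_variants(panel, QcThresholds())
            gio.write_results(rep.per_variant, paths["qc"])
            with open(paths["kept"], "w") as fh:
                fh.write("\n".join(kept_panel.variants["id"]) + "\n")
            log.info("qc: %d of %d variants kept",
                     kept_panel.n_variants, panel.n_variants)
        elif stage == "assoc":
            panel = _qc_panel(paths, cfg, stage)
            res = SnpAssociation(panel).fit()
            gio.write_results(res.table, paths["assoc"])
            log.info("assoc: %d rows", len(res.table))
        elif stage == "genetest":
            panel = _qc_panel(paths, cfg, stage)
            assignment = _read_assignment(_require(paths["assignment"],
                                                   stage))
            tests = tuple(t.strip() for t in str(cfg["tests"]).split(","))
            battery = GeneBattery(panel, assignment, tests=tests,
                                  n_perm=cfg["n_perm"], seed=cfg["seed"])
            gio.write_results(battery.fit().table, paths["genetest"])
            log.info("genetest: done")
        elif stage == "calibrate":
            table = gio.read_results(_require(paths["genetest"], stage))
            parts = []
            for test, grp in table.dropna(subset=["p"]).groupby("test"):
                cal = logit_adjust(grp["p"].to_numpy(), units=grp["gene"])
                part = cal.table.rename(columns={"unit": "gene"})
                part.insert(1, "test", test)
                parts.append(part)
                log.info("calibrate: %s centre %.4f", test, cal.center)
            gio.write_results(pd.concat(parts, ignore_index=True),
                              paths["calibrated"])
        elif stage == "enrich":
            cal = gio.read_results(_require(paths["calibrated"], stage))
            catalog = gio.read_gmt(_require(paths["gmt"], stage))
            sources = {t: dict(zip(g["gene"], g["p_adjusted"]))
                       for t, g in cal.groupby("test")}
            scheme = significance_thresholds(cfg["alpha"], len(catalog),
                                             len(catalog))
            table = enrich_catalog(catalog, sources, scheme,
                                   seed=cfg["seed"])
            gio.write_results(table, paths["enrich"])
            log.info("enrich: %d term-test rows", len(table))
        elif stage == "report":
            assoc = gio.read_results(_require(paths["assoc"], stage))
            genetest = gio.read_results(_require(paths["genetest"], stage))
            n_snps = assoc["variant"].nunique()
            n_genes = genetest["gene"].nunique()
            schemes = {
                "snp": significance_thresholds(cfg["alpha"], n_snps,
                                               cfg["k_tot_snp"]),
                "gene": significance_thresholds(cfg["alpha"], n_genes,
                                                cfg["k_tot_gene"]),
            }
            rows = [{"level": lvl, "threshold": name, "value": val}
                    for lvl, sch in schemes.items()
                    for name, val in sch.thresholds.items()]
            gio.write_results(pd.DataFrame(rows), paths["thresholds"])
            adj = assoc[(assoc["model"] == "adjusted")
                        & assoc["p"].notna()]
            qd = qq_data(adj["p"].to_numpy())
            qd.table["lambda_gc"] = qd.lambda_gc
            gio.write_results(qd.table, paths["qq"])
            conc = method_concordance(genetest.dropna(subset=["p"]))
            gio.write_results(conc.reset_index(names="test"),
                              paths["concordance"])
            log.info("report: lambda_gc %.4f", qd.lambda_gc)
        log.info("stage %s finished", stage)
    return 0


def _qc_panel(paths, cfg, stage) -> CohortPanel:
    panel = gio.read_cohort(_require(paths["vcf"], stage),
                            _require(paths["covar"], stage))
    kept = [line.strip()
            for line in open(_require(paths["kept"], stage))
            if line.strip()]
    return panel.subset_variants(kept)


def _read_assignment(path) -> ann.GeneAssignment:
    table = gio.read_results(path)
    mapping: dict = {}
    for _, r in table.iterrows():
        mapping.setdefault(r["variant"], []).append((r["gene"], r["reason"]))
    return ann.GeneAssignment(mapping=mapping)
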