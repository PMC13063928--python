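"""Readers and writers for the standard formats the pipeline consumes.

Genotypes come from VCF 4.x (GT hard calls and/or DS dosages; INFO keys
R2, IAM_HWE, HIQ are read when present and mark a variant as imputed);
sample covariates from a TSV keyed by sample id; gene models from BED
(0-based half-open, converted to 1-based inclusive on read); enhancer
links from a 4+-column BED; gene sets from GMT; ontology edges from a
two-column child/parent TSV.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .annotate import EnhancerInterval, GeneModel
from .panel import SAMPLE_COLUMNS, CohortPanel
from .qc import compute_variant_stats

log = logging.getLogger("gardscan")

__all__ = ["read_cohort", "read_covariates", "read_gene_bed",
           "read_enhancer_bed", "read_gmt", "read_ontology_edges",
           "read_exclusion_list", "write_results", "read_results"]


def read_covariates(path) -> pd.DataFrame:
    """Covariate TSV with columns id,status,sex,age,smoking,pc1..pc4."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"covariate file lacks columns: {sorted(missing)}")
    bad_status = set(df["status"]) - {"case", "control"}
    if bad_status:
        raise ValueError(f"unknown status values: {sorted(bad_status)}")
    if (df["age"] <= 0).any():
        raise ValueError("ages must be positive")
    return df[SAMPLE_COLUMNS]


def read_cohort(vcf_path, covar_path) -> CohortPanel:
    """Build a CohortPanel from a VCF and a covariate table.

    Samples present in only one input are dropped (logged).  Dosage comes
    from FORMAT/DS when present, else from the GT alt-allele count.
    Multi-allelic records are split per alternate allele.  Per-variant QC
    statistics are computed on read.
    """
    covars = read_covariates(covar_path)
    vcf = VCF(str(vcf_path), gts012=True)
    vcf_samples = list(vcf.samples)
    common = [s for s in vcf_samples if s in set(covars["id"])]
    if not common:
        raise ValueError("no overlapping samples between VCF and covariates")
    dropped = (set(vcf_samples) ^ set(covars["id"]))
    if dropped:
        log.info("dropping %d samples absent from one input", len(dropped))
    col_idx = np.array([vcf_samples.index(s) for s in common])

    rows, dosage_cols = [], []
    for rec in vcf:
        if rec.ALT is None or len(rec.ALT) == 0:
            raise ValueError(f"malformed VCF record at {rec.CHROM}:{rec.POS}")
        try:
            ds = rec.format("DS")
        except Exception:
            ds = None
        gt = np.asarray(rec.gt_types, dtype=float)   # 0,1,2; 3 = unknown
        gt[gt == 3] = np.nan
        r2 = rec.INFO.get("R2")
        iam = rec.INFO.get("IAM_HWE")
        hiq = rec.INFO.get("HIQ")
        imputed = any(v is not None for v in (r2, iam, hiq)) or ds is not None
        for ai, alt in enumerate(rec.ALT):
            if len(rec.ALT) == 1:
                if ds is not None:
                    d = np.asarray(ds, dtype=float).reshape(-1)[:len(vcf_samples)]
                    d = np.where(np.isfinite(d), d, np.nan)
                else:
                    d = gt
            else:
                # multi-allelic: count this alt per sample from phased calls
                g = np.array(rec.genotypes, dtype=object)
                d = np.array([
                    np.nan if any(a == -1 for a in s[:-1])
                    else float(sum(1 for a in s[:-1] if a == ai + 1))
                    for s in g])
            vid = rec.ID if rec.ID not in (None, ".") \
                else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            if len(rec.ALT) > 1:
                vid = f"{vid}_{alt}"
            rows.append({
                "id": vid, "chrom": str(rec.CHROM), "pos": int(rec.POS),
                "ref": rec.REF, "alt": alt,
                "source": "imputed" if imputed else "genotyped",
                "impute_r2": np.nan if r2 is None else float(r2),
                "iam_hwe": np.nan if iam is None else float(iam),
                "hiq": np.nan if hiq is None else float(hiq)})
            dosage_cols.append(np.clip(d[col_idx], 0, 2))
    if not rows:
        raise ValueError("VCF contains no variant records")
    variants = pd.DataFrame(rows)
    dosage = np.column_stack(dosage_cols)
    samples = covars.set_index("id").loc[common].reset_index()
    panel = CohortPanel(variants=variants, samples=samples, dosage=dosage)
    return compute_variant_stats(panel)


def read_gene_bed(path) -> list:
    """Gene BED (chrom, start0, end, symbol[, strand]) -> GeneModel list,
    converted to 1-based inclusive coordinates."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[4] if len(f) > 4 and f[4] in "+-" else "unknown"
            genes.append(GeneModel(symbol=f[3], chrom=f[0],
                                   start=int(f[1]) + 1, end=int(f[2]),
                                   strand=strand))
    return genes


def read_enhancer_bed(path) -> list:
    """Enhancer BED with 4th column = linked gene symbol."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(EnhancerInterval(
                chrom=f[0], start=int(f[1]) + 1, end=int(f[2]), gene=f[3],
                source=f[4] if len(f) > 4 else ""))
    return out


def read_gmt(path) -> dict:
    """GMT -> {term id: (name, [genes])}."""
    catalog = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"GMT line with <3 fields: {f[0]!r}")
            catalog[f[0]] = (f[1], [g for g in f[2:] if g])
    return catalog


def read_ontology_edges(path) -> list:
    """Two-column child/parent TSV -> list of (child, parent)."""
    edges = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            edges.append((f[0], f[1]))
    return edges


def read_exclusion_list(path) -> set:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


_P_COLUMNS = ("p", "p_raw", "p_adjusted", "hwe_p", "interaction_p",
              "ci_low", "ci_high")


def write_results(table: pd.DataFrame, path) -> None:
    """Tab-separated output with header; p-value-like columns rendered in
    scientific notation with 6 significant digits."""
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    out = table.copy()
    for col in out.columns:
        if col in _P_COLUMNS or col.startswith("p_"):
            out[col] = out[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.5e}")
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    out.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
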