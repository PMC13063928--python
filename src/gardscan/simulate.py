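"""Synthetic case-control cohorts with the structure the pipeline assumes.

The generator emulates an OncoArray-style case-control study: block-wise
LD among SNPs, genes tiled along one chromosome with distal enhancer
intervals, covariates (sex, age, smoking, 4 ancestry PCs), a log-additive
logistic disease model with optional marker x age interaction, imputed
dosages with quality scores, and an ontology-like gene-set catalog in
which designated terms are enriched for the causal genes.

LD is produced by a first-order copy chain: within a block all SNPs share
one allele frequency and each haplotype allele copies its left neighbour
with probability equal to the target D', which makes the realized
pairwise D' equal the target in expectation.  Blocks are mutually
independent.  Case-control ascertainment is by rejection sampling from
the population model, under which the logistic model for the covariates
remains valid (intercept aside).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import CohortPanel

__all__ = ["SimConfig", "TruthRecord", "simulate_haplotypes",
           "simulate_cohort", "write_cohort_files"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort."""
    n_cases: int = 1000
    n_controls: int = 1000
    n_snps: int = 120
    block_size: int = 5
    within_block_dprime: float = 0.8
    maf_range: tuple = (0.05, 0.40)
    n_genes: int = 20
    gene_length: int = 8000
    gene_gap: int = 2000
    flank: int = 500
    enhancer_rate: float = 0.5
    n_terms: int = 12
    term_size_range: tuple = (4, 10)
    n_enriched_terms: int = 1
    n_causal_genes: int = 3
    causal_beta: float = float(np.log(1.3))
    intercept_beta: float = -1.0
    sex_beta: float = 0.3
    smoke_beta: float = 0.7           # current vs never; former gets half
    pc_betas: tuple = (0.2, 0.0, 0.0, 0.0)
    age_interaction_beta: float = 0.0
    impute_fraction: float = 0.3
    miss_rate_max: float = 0.02
    seed: int = 1

    def __post_init__(self):
        for name in ("n_cases", "n_controls", "n_snps", "block_size",
                     "n_genes", "gene_length", "gene_gap", "n_terms",
                     "n_causal_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.within_block_dprime <= 1:
            raise ValueError("within_block_dprime must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class TruthRecord:
    causal_snp_ids: list
    causal_gene_ids: list
    enriched_term_ids: list
    true_betas: dict                     # snp id -> per-allele log-odds


def simulate_haplotypes(cfg: SimConfig, n_haplotypes: int,
                        rng: np.random.Generator | None = None,
                        freqs: np.ndarray | None = None) -> np.ndarray:
    """(n_haplotypes x n_snps) 0/1 matrix with block-wise copy-chain LD.

    One allele frequency per block, drawn uniformly from ``maf_range``;
    within a block each SNP copies the previous allele with probability
    ``within_block_dprime`` (so D' between adjacent equal-frequency SNPs
    equals the copy probability), else draws a fresh allele.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    m = cfg.n_snps
    n_blocks = int(np.ceil(m / cfg.block_size))
    if freqs is None:
        block_f = rng.uniform(*cfg.maf_range, size=n_blocks)
        freqs = np.repeat(block_f, cfg.block_size)[:m]
    hap = np.empty((n_haplotypes, m), dtype=np.int8)
    c = cfg.within_block_dprime
    for j in range(m):
        fresh = (rng.random(n_haplotypes) < freqs[j]).astype(np.int8)
        if j % cfg.block_size == 0:
            hap[:, j] = fresh
        else:
            copy = rng.random(n_haplotypes) < c
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    return hap


def _genome_layout(cfg: SimConfig, rng: np.random.Generator):
    """Tile genes along chromosome 1, scatter SNP positions, place
    enhancers in the inter-genic gaps."""
    pitch = cfg.gene_length + cfg.gene_gap
    genes = pd.DataFrame({
        "symbol": [f"G{i + 1:03d}" for i in range(cfg.n_genes)],
        "chrom": "1",
        "start": [i * pitch + 1 for i in range(cfg.n_genes)],
        "end": [i * pitch + cfg.gene_length for i in range(cfg.n_genes)],
        "strand": "+",
    })
    span = cfg.n_genes * pitch
    pos = np.sort(rng.choice(np.arange(1, span + 1), size=cfg.n_snps,
                             replace=False))
    enh_rows = []
    enh_len = 300
    for i in range(cfg.n_genes):
        for _ in range(rng.poisson(cfg.enhancer_rate)):
            # enhancer in a gap region, possibly far from its gene
            gap_gene = int(rng.integers(0, cfg.n_genes))
            gap_start = gap_gene * pitch + cfg.gene_length + cfg.flank + 50
            start = int(rng.integers(gap_start,
                                     gap_start + cfg.gene_gap - cfg.flank
                                     - enh_len - 100))
            enh_rows.append({"chrom": "1", "start": start,
                             "end": start + enh_len - 1,
                             "gene": genes["symbol"][i],
                             "source": "sim"})
    enhancers = pd.DataFrame(enh_rows,
                             columns=["chrom", "start", "end", "gene",
                                      "source"])
    return genes, pos, enhancers


def _draw_covariates(cfg: SimConfig, n: int, rng: np.random.Generator):
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    age = rng.uniform(40, 80, size=n)
    smoking = rng.choice(["never", "former", "current"], size=n,
                         p=[0.4, 0.3, 0.3])
    subpop = (rng.random(n) < 0.5).astype(float)
    pcs = rng.normal(0, 1, size=(n, 4)) * 0.5
    pcs[:, 0] += subpop * 1.0            # PC1 separates the subpopulations
    return sex, age, smoking, subpop, pcs


def simulate_cohort(cfg: SimConfig):
    """Full synthetic study: returns (panel, genes, enhancers, catalog,
    truth).

    The phenotype follows logit P(case) = intercept + sum_causal beta *
    dosage + sex/smoking/PC terms (+ optional dosage x standardized-age
    interaction); samples are drawn from the population model and
    accepted until the requested case and control counts are reached.
    """
    rng = np.random.default_rng(cfg.seed)
    genes, pos, enhancers = _genome_layout(cfg, rng)

    # choose causal genes among genes containing >= 1 SNP in the body
    in_body = {}
    for i, (s, e) in enumerate(zip(genes["start"], genes["end"])):
        snps = np.flatnonzero((pos >= s) & (pos <= e))
        if snps.size:
            in_body[genes["symbol"][i]] = snps
    eligible = sorted(in_body)
    if len(eligible) < cfg.n_causal_genes:
        raise ValueError("not enough genes contain SNPs; increase n_snps")
    causal_genes = sorted(rng.choice(eligible, size=cfg.n_causal_genes,
                                     replace=False).tolist())
    causal_snps = sorted(int(rng.choice(in_body[g])) for g in causal_genes)
    causal_snps = sorted(set(causal_snps))
    betas = np.zeros(cfg.n_snps)
    betas[causal_snps] = cfg.causal_beta

    n_target = cfg.n_cases + cfg.n_controls
    n_blocks = int(np.ceil(cfg.n_snps / cfg.block_size))
    block_f = rng.uniform(*cfg.maf_range, size=n_blocks)
    freqs = np.repeat(block_f, cfg.block_size)[:cfg.n_snps]
    # allele-frequency shift between subpopulations when PCs matter
    shift = (rng.uniform(-0.05, 0.05, size=cfg.n_snps)
             if any(b != 0 for b in cfg.pc_betas) else np.zeros(cfg.n_snps))

    kept_dos, kept_cov, n_case, n_ctrl = [], [], 0, 0
    max_rounds = 200
    rounds = 0
    while n_case < cfg.n_cases or n_ctrl < cfg.n_controls:
        rounds += 1
        if rounds > max_rounds:
            raise RuntimeError(
                "requested case/control counts unreachable; raise "
                "intercept_beta toward 0 or lower the requested counts")
        batch = max(n_target // 2, 500)
        sex, age, smoking, subpop, pcs = _draw_covariates(cfg, batch, rng)
        f2 = np.clip(freqs + shift, 0.01, 0.99)
        fmat = np.where(subpop[:, None] > 0, f2[None, :], freqs[None, :])
        hap1 = (rng.random((batch, cfg.n_snps)) < fmat).astype(np.int8)
        # copy-chain LD applied per haplotype
        c = cfg.within_block_dprime
        for j in range(1, cfg.n_snps):
            if j % cfg.block_size:
                copy = rng.random(batch) < c
                hap1[copy, j] = hap1[copy, j - 1]
        hap2 = (rng.random((batch, cfg.n_snps)) < fmat).astype(np.int8)
        for j in range(1, cfg.n_snps):
            if j % cfg.block_size:
                copy = rng.random(batch) < c
                hap2[copy, j] = hap2[copy, j - 1]
        dos = (hap1 + hap2).astype(float)

        age_std = (age - 60.0) / 11.5       # population moments of U(40,80)
        eta = (cfg.intercept_beta + dos @ betas
               + cfg.sex_beta * (sex == "male")
               + cfg.smoke_beta * (smoking == "current")
               + 0.5 * cfg.smoke_beta * (smoking == "former")
               + pcs @ np.asarray(cfg.pc_betas))
        if cfg.age_interaction_beta:
            eta = eta + cfg.age_interaction_beta * (dos @ (betas != 0)) * age_std
        case = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))

        for is_case in (True, False):
            need = (cfg.n_cases - n_case) if is_case else (cfg.n_controls - n_ctrl)
            if need <= 0:
                continue
            idx = np.flatnonzero(case == is_case)[:need]
            kept_dos.append(dos[idx])
            kept_cov.append(pd.DataFrame({
                "status": "case" if is_case else "control",
                "sex": sex[idx], "age": age[idx], "smoking": smoking[idx],
                "pc1": pcs[idx, 0], "pc2": pcs[idx, 1],
                "pc3": pcs[idx, 2], "pc4": pcs[idx, 3]}))
            if is_case:
                n_case += idx.size
            else:
                n_ctrl += idx.size

    dosage = np.vstack(kept_dos)
    samples = pd.concat(kept_cov, ignore_index=True)
    samples.insert(0, "id", [f"S{i + 1:05d}" for i in range(len(samples))])

    # variant metadata; a fraction of SNPs become noisy imputed dosages
    ids = [f"snp{j + 1:04d}" for j in range(cfg.n_snps)]
    ref_alt = rng.choice(["A", "C", "G", "T"], size=(cfg.n_snps, 2))
    same = ref_alt[:, 0] == ref_alt[:, 1]
    ref_alt[same, 1] = np.where(ref_alt[same, 0] == "A", "G", "A")
    n_imp = int(round(cfg.impute_fraction * cfg.n_snps))
    imputed = np.zeros(cfg.n_snps, dtype=bool)
    imp_idx = rng.choice(np.setdiff1d(np.arange(cfg.n_snps), causal_snps),
                         size=min(n_imp, cfg.n_snps - len(causal_snps)),
                         replace=False)
    imputed[imp_idx] = True
    r2 = np.full(cfg.n_snps, np.nan)
    iam_hwe = np.full(cfg.n_snps, np.nan)
    hiq = np.full(cfg.n_snps, np.nan)
    for j in np.flatnonzero(imputed):
        sd = rng.uniform(0.05, 0.45)
        noisy = np.clip(dosage[:, j] + rng.normal(0, sd, size=len(samples)),
                        0, 2)
        with np.errstate(invalid="ignore"):
            cc = np.corrcoef(noisy, dosage[:, j])[0, 1]
        r2[j] = max(0.0, cc ** 2) if np.isfinite(cc) else 0.0
        dosage[:, j] = noisy
        iam_hwe[j] = rng.uniform(0.4, 1.0)
        hiq[j] = rng.uniform(0.4, 1.0)
    # sparse missingness on genotyped SNPs
    for j in np.flatnonzero(~imputed):
        mr = rng.uniform(0, cfg.miss_rate_max)
        miss = rng.random(len(samples)) < mr
        dosage[miss, j] = np.nan

    variants = pd.DataFrame({
        "id": ids, "chrom": "1", "pos": pos, "ref": ref_alt[:, 0],
        "alt": ref_alt[:, 1],
        "source": np.where(imputed, "imputed", "genotyped"),
        "impute_r2": r2, "iam_hwe": iam_hwe, "hiq": hiq,
    })
    panel = CohortPanel(variants=variants, samples=samples, dosage=dosage)
    from .qc import compute_variant_stats
    compute_variant_stats(panel)

    # gene-set catalog; enriched terms preferentially sample causal genes
    all_symbols = genes["symbol"].tolist()
    catalog = {}
    enriched_ids = []
    for t in range(cfg.n_terms):
        size = int(rng.integers(cfg.term_size_range[0],
                                cfg.term_size_range[1] + 1))
        tid = f"HP:{9000000 + t + 1:07d}"
        if t < cfg.n_enriched_terms:
            members = list(causal_genes)
            others = [g for g in all_symbols if g not in causal_genes]
            extra = max(0, size - len(members))
            members += rng.choice(others, size=min(extra, len(others)),
                                  replace=False).tolist()
            enriched_ids.append(tid)
        else:
            members = rng.choice(all_symbols, size=min(size, len(all_symbols)),
                                 replace=False).tolist()
        catalog[tid] = (f"synthetic term {t + 1}", sorted(members))

    truth = TruthRecord(
        causal_snp_ids=[ids[j] for j in causal_snps],
        causal_gene_ids=causal_genes,
        enriched_term_ids=enriched_ids,
        true_betas={ids[j]: float(betas[j]) for j in causal_snps})
    return panel, genes, enhancers, catalog, truth


# ---------------------------------------------------------------------------
# file emission (VCF / TSV / BED / GMT)
# ---------------------------------------------------------------------------

def _vcf_lines(panel: CohortPanel):
    yield "##fileformat=VCFv4.2"
    yield '##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation r2">'
    yield ('##INFO=<ID=IAM_HWE,Number=1,Type=Float,'
           'Description="Individual-specificity fraction">')
    yield ('##INFO=<ID=HIQ,Number=1,Type=Float,'
           'Description="Inter-individual dosage heterogeneity">')
    yield '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    yield '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">'
    yield ("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
           + "\t".join(panel.samples["id"]))
    v = panel.variants
    for j in range(panel.n_variants):
        imputed = v["source"].iat[j] == "imputed"
        if imputed:
            info = (f"R2={v['impute_r2'].iat[j]:.4f};"
                    f"IAM_HWE={v['iam_hwe'].iat[j]:.4f};"
                    f"HIQ={v['hiq'].iat[j]:.4f}")
            fmt = "GT:DS"
        else:
            info = "."
            fmt = "GT"
        fields = []
        for d in panel.dosage[:, j]:
            if np.isnan(d):
                fields.append("./." if not imputed else "./.:.")
                continue
            g = int(min(2, np.floor(d + 0.5)))
            gt = ["0/0", "0/1", "1/1"][g]
            fields.append(f"{gt}:{d:.4f}" if imputed else gt)
        yield "\t".join([str(v["chrom"].iat[j]), str(v["pos"].iat[j]),
                         v["id"].iat[j], v["ref"].iat[j], v["alt"].iat[j],
                         ".", "PASS", info, fmt] + fields)


def write_cohort_files(panel: CohortPanel, genes: pd.DataFrame,
                       enhancers: pd.DataFrame, catalog: dict,
                       truth: TruthRecord, outdir) -> dict:
    """Emit VCF, covariates TSV, gene BED (0-based half-open), enhancer
    BED, GMT and truth TSV; returns the path map."""
    import os
    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, f)
             for k, f in [("vcf", "cohort.vcf"), ("covar", "covariates.tsv"),
                          ("genes", "genes.bed"), ("enhancers", "enhancers.bed"),
                          ("gmt", "terms.gmt"), ("truth", "truth.tsv")]}
    with open(paths["vcf"], "w") as fh:
        for line in _vcf_lines(panel):
            fh.write(line + "\n")
    panel.samples.to_csv(paths["covar"], sep="\t", index=False)
    bed = genes.copy()
    bed["start0"] = bed["start"] - 1          # 1-based -> 0-based half-open
    bed[["chrom", "start0", "end", "symbol", "strand"]].to_csv(
        paths["genes"], sep="\t", index=False, header=False)
    enh = enhancers.copy()
    if len(enh):
        enh["start0"] = enh["start"] - 1
        enh[["chrom", "start0", "end", "gene", "source"]].to_csv(
            paths["enhancers"], sep="\t", index=False, header=False)
    else:
        open(paths["enhancers"], "w").close()
    with open(paths["gmt"], "w") as fh:
        for tid, (name, members) in catalog.items():
            fh.write("\t".join([tid, name] + list(members)) + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write("kind\tid\tvalue\n")
        for s in truth.causal_snp_ids:
            fh.write(f"causal_snp\t{s}\t{truth.true_betas[s]:.6f}\n")
        for g in truth.causal_gene_ids:
            fh.write(f"causal_gene\t{g}\t.\n")
        for t in truth.enriched_term_ids:
            fh.write(f"enriched_term\t{t}\t.\n")
    return paths
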