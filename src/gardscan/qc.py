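"""Per-variant quality control and D'-based LD pruning.

Inclusion rules (all must hold for a variant to be kept):

* missing rate < 10%
* Hardy-Weinberg exact p > 1e-4
* heterozygosity excess (H_obs - H_exp)/H_exp within [-0.30, +0.20]
* for imputed variants: imputation r2 >= 0.5, Iam_HWE >= 0.5, hiQ >= 0.5

Survivors are then LD-pruned: within each pair of common markers
(MAF > 0.01) at most 15,000 bp apart with D' > 0.8, the lower-MAF member
is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .panel import CohortPanel

__all__ = [
    "QcThresholds", "QcReport", "genotype_counts", "hwe_exact_p",
    "het_excess", "dprime", "ld_prune", "filter_variants",
    "compute_variant_stats",
]


@dataclass(frozen=True)
class QcThresholds:
    """Variant inclusion thresholds; defaults follow standard OncoArray-era
    GWAS practice for hard-call and imputed-dosage QC."""
    max_miss: float = 0.10
    min_hwe_p: float = 1e-4
    het_excess_range: tuple = (-0.30, 0.20)
    prune_min_maf: float = 0.01
    prune_max_bp: int = 15_000
    prune_dprime: float = 0.8
    min_impute_r2: float = 0.50
    min_iam_hwe: float = 0.50
    min_hiq: float = 0.50


@dataclass
class QcReport:
    per_variant: pd.DataFrame          # id, kept, fail_rule, statistics
    summary: dict = field(default_factory=dict)  # rule -> n removed


def hard_calls(dosages: np.ndarray) -> np.ndarray:
    """Round dosages to {0,1,2}; halves round away from zero; NaN kept."""
    d = np.asarray(dosages, dtype=float)
    out = np.floor(d + 0.5)          # d >= 0, so this is round-half-up
    return np.clip(out, 0, 2, out=out)


def genotype_counts(dosages) -> tuple[int, int, int, int]:
    """(n_AA, n_Aa, n_aa, n_missing) from hard-called dosages.

    AA = 0 alt alleles, Aa = 1, aa = 2.
    """
    d = np.asarray(dosages, dtype=float)
    miss = np.isnan(d)
    g = hard_calls(d[~miss])
    return (int(np.sum(g == 0)), int(np.sum(g == 1)), int(np.sum(g == 2)),
            int(miss.sum()))


def _hwe_log_probs(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """Log conditional probabilities of every attainable heterozygote count
    given n genotypes and n_a copies of the rarer allele."""
    n_b = 2 * n - n_a
    hets = np.arange(n_a % 2, n_a + 1, 2)
    hets = hets[(n_a - hets) // 2 + hets <= n]     # always true; kept for clarity
    n_aa = (n_a - hets) // 2
    n_bb = n - n_aa - hets
    logp = (gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(hets + 1)
            - gammaln(n_bb + 1) + hets * np.log(2.0)
            + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1))
    return hets, logp


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact conditional Hardy-Weinberg test.

    Sums, over all heterozygote counts attainable at the observed allele
    counts, the probabilities no larger than that of the observed count
    (hypergeometric-type conditional distribution).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_alt = n_Aa + 2 * n_aa
    n_a = min(n_alt, 2 * n - n_alt)           # rarer allele copies
    if n_a == 0:
        return 1.0
    hets, logp = _hwe_log_probs(n, n_a)
    logp = logp - logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_Aa)]
    # tie rule: include configurations whose probability is <= observed,
    # with a tiny relative tolerance to keep exact ties stable in floats
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def het_excess(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Relative heterozygote excess (H_obs - H_exp)/H_exp.

    Undefined (NaN) for monomorphic variants.
    """
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    p_hat = (n_Aa + 2 * n_aa) / (2 * n)
    h_exp = 2 * p_hat * (1 - p_hat)
    if h_exp == 0:
        return float("nan")
    return (n_Aa / n - h_exp) / h_exp


# ---------------------------------------------------------------------------
# D' from unphased genotype pairs
# ---------------------------------------------------------------------------

def _two_locus_table(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """3x3 genotype count table from hard calls, complete pairs only."""
    g1, g2 = hard_calls(d1), hard_calls(d2)
    ok = ~(np.isnan(g1) | np.isnan(g2))
    tab = np.zeros((3, 3))
    np.add.at(tab, (g1[ok].astype(int), g2[ok].astype(int)), 1)
    return tab


def _em_haplotypes(tab: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 1000) -> tuple[np.ndarray, bool]:
    """EM estimate of haplotype frequencies (pAB,pAb,paB,pab); alleles A/a =
    ref/alt of locus 1, B/b of locus 2.  Only the double heterozygote is
    phase-ambiguous."""
    n = tab.sum()
    # known haplotype contributions: genotype (i,j) carries alleles
    # determined up to phase only for (1,1)
    pa = (tab.sum(axis=1) @ np.array([0, 1, 2])) / (2 * n)   # alt freq locus 1
    pb = (tab.sum(axis=0) @ np.array([0, 1, 2])) / (2 * n)
    # order: [AB, Ab, aB, ab] with A=ref1, B=ref2; alt freqs pa, pb
    h = np.array([(1 - pa) * (1 - pb), (1 - pa) * pb, pa * (1 - pb), pa * pb])
    h = np.clip(h, 1e-12, None)
    h /= h.sum()
    ndh = tab[1, 1]
    # fixed counts contributed by unambiguous cells
    fixed = np.zeros(4)
    fixed[0] = 2 * tab[0, 0] + tab[0, 1] + tab[1, 0]
    fixed[1] = 2 * tab[0, 2] + tab[0, 1] + tab[1, 2]
    fixed[2] = 2 * tab[2, 0] + tab[1, 0] + tab[2, 1]
    fixed[3] = 2 * tab[2, 2] + tab[2, 1] + tab[1, 2]
    for _ in range(max_iter):
        # E step: split double hets between AB/ab and Ab/aB phases
        cis = h[0] * h[3]
        trans = h[1] * h[2]
        tot = cis + trans
        w = 0.5 if tot == 0 else cis / tot
        counts = fixed + ndh * np.array([w, 1 - w, 1 - w, w])
        h_new = counts / counts.sum()
        if np.abs(h_new - h).max() < tol:
            return h_new, True
        h = h_new
    return h, False


def dprime(d1, d2) -> float:
    """Normalized LD coefficient D' in [0, 1] between two dosage vectors.

    Haplotype frequencies are estimated from the unphased two-locus
    genotype table by EM; D' = |D| / D_max given the allele frequencies.
    Returns NaN when either locus is monomorphic or EM fails to converge.
    """
    tab = _two_locus_table(np.asarray(d1, float), np.asarray(d2, float))
    if tab.sum() == 0:
        return float("nan")
    h, converged = _em_haplotypes(tab)
    if not converged:
        return float("nan")
    p_a = h[0] + h[1]          # freq of ref allele, locus 1
    p_b = h[0] + h[2]
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return float("nan")
    d = h[0] - p_a * p_b
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    if d_max <= 0:
        return float("nan")
    return float(min(1.0, abs(d) / d_max))


def ld_prune(panel: CohortPanel,
             t: QcThresholds = QcThresholds()) -> tuple[list, list]:
    """Greedy left-to-right D' pruning of common nearby marker pairs.

    For each pair with both MAFs > ``prune_min_maf`` and positions at most
    ``prune_max_bp`` apart: if D' > ``prune_dprime`` (strict), the
    lower-MAF member is removed (ties remove the right-hand variant).
    Removed variants take no part in later comparisons.

    Returns (kept ids, removed ids) in panel order.
    """
    v = panel.variants
    order = np.lexsort((v["pos"].to_numpy(), v["chrom"].astype(str).to_numpy()))
    maf = v["maf"].to_numpy(float)
    pos = v["pos"].to_numpy(int)
    chrom = v["chrom"].astype(str).to_numpy()
    ids = v["id"].to_numpy()
    kept: list[int] = []
    removed: set[int] = set()
    for j in order:
        if maf[j] <= t.prune_min_maf:
            kept.append(j)
            continue
        drop_j = False
        for i in list(kept):
            if i in removed or maf[i] <= t.prune_min_maf:
                continue
            if chrom[i] != chrom[j] or abs(pos[j] - pos[i]) > t.prune_max_bp:
                continue
            dp = dprime(panel.dosage[:, i], panel.dosage[:, j])
            if np.isnan(dp) or dp <= t.prune_dprime:
                continue
            if maf[i] < maf[j]:
                removed.add(i)
            else:               # ties remove the right-hand (later) variant
                drop_j = True
                break
        if drop_j:
            removed.add(j)
        else:
            kept.append(j)
    kept = [j for j in kept if j not in removed]
    kept_ids = [ids[j] for j in sorted(kept)]
    removed_ids = [ids[j] for j in sorted(removed)]
    return kept_ids, removed_ids


# ---------------------------------------------------------------------------
# panel-level statistics and the full filter
# ---------------------------------------------------------------------------

def compute_variant_stats(panel: CohortPanel) -> CohortPanel:
    """Fill maf, miss_rate, hwe_p and het_excess on the variant table.

    MAF is the folded mean dosage / 2 over non-missing samples (so imputed
    fractional dosages contribute); HWE and heterozygote excess use hard
    calls over all samples.
    """
    n = panel.n_samples
    d = panel.dosage
    miss = np.isnan(d)
    miss_rate = miss.mean(axis=0)
    with np.errstate(invalid="ignore"):
        af = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(af, 1 - af)
    hwe = np.empty(panel.n_variants)
    hx = np.empty(panel.n_variants)
    for j in range(panel.n_variants):
        n_aa, n_ab, n_bb, _ = genotype_counts(d[:, j])
        if n_aa + n_ab + n_bb == 0:
            hwe[j] = np.nan
            hx[j] = np.nan
            continue
        hwe[j] = hwe_exact_p(n_aa, n_ab, n_bb)
        hx[j] = het_excess(n_aa, n_ab, n_bb)
    v = panel.variants
    v["maf"] = maf
    v["miss_rate"] = miss_rate
    v["hwe_p"] = hwe
    v["het_excess"] = hx
    return panel


_RULES = ["missingness", "hwe", "het_excess", "impute_r2", "iam_hwe", "hiq",
          "ld_prune"]


def filter_variants(panel: CohortPanel,
                    t: QcThresholds = QcThresholds()) -> tuple[CohortPanel, QcReport]:
    """Apply the full inclusion filter, then LD-prune the survivors.

    The report records, per removed variant, the first failing rule in the
    order missingness, HWE, heterozygote excess, imputation quality
    (r2, Iam_HWE, hiQ), LD prune.
    """
    if panel.variants["maf"].isna().all():
        compute_variant_stats(panel)
    v = panel.variants
    lo, hi = t.het_excess_range
    fail = pd.Series([""] * len(v), index=v.index)

    def _flag(mask, rule):
        new = mask & (fail == "")
        fail[new] = rule

    _flag(v["miss_rate"].to_numpy(float) >= t.max_miss, "missingness")
    _flag(v["hwe_p"].to_numpy(float) <= t.min_hwe_p, "hwe")
    hx = v["het_excess"].to_numpy(float)
    _flag(~np.isnan(hx) & ((hx < lo) | (hx > hi)), "het_excess")
    imputed = (v["source"].to_numpy() == "imputed")
    for col, rule, thr in (("impute_r2", "impute_r2", t.min_impute_r2),
                           ("iam_hwe", "iam_hwe", t.min_iam_hwe),
                           ("hiq", "hiq", t.min_hiq)):
        x = v[col].to_numpy(float)
        _flag(imputed & ~np.isnan(x) & (x < thr), rule)

    survivors = panel.subset_variants(v.loc[fail == "", "id"])
    kept_ids, pruned_ids = ld_prune(survivors, t)
    fail[v["id"].isin(pruned_ids)] = "ld_prune"

    report_df = v[["id", "chrom", "pos", "maf", "miss_rate", "hwe_p",
                   "het_excess", "impute_r2", "iam_hwe", "hiq", "source"]].copy()
    report_df["kept"] = (fail == "").to_numpy()
    report_df["fail_rule"] = fail.to_numpy()
    summary = {rule: int((fail == rule).sum()) for rule in _RULES}
    summary["kept"] = int((fail == "").sum())
    out = panel.subset_variants(kept_ids)
    return out, QcReport(per_variant=report_df, summary=summary)
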