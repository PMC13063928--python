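"""Gene-set (ontology-term) enrichment by one-sided Kolmogorov-Smirnov.

For each term, the gene-level p-values of its member genes are compared
with those of all remaining scored genes.  The statistic is
D+ = sup_x [F_set(x) - F_bg(x)] over the pooled observed values: a set
whose members concentrate at small p (stochastically smaller) yields a
large D+.  The asymptotic one-sided two-sample tail
exp(-2 D+^2 mn/(m+n)) supplies the p-value; a label-permutation p
replaces it for small sets.  The leading-edge subset — the member genes
at or before the point where D+ attains its supremum — names the genes
carrying the enrichment signal.

Because D+ depends on gene p-values only through their ranks, any
strictly monotone recalibration of the gene-level p-values (such as the
logit adjustment) leaves the enrichment statistic unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import logit_adjust
from .report import SignificanceScheme, classify

__all__ = ["EnrichmentResult", "ks_enrichment", "leading_edge",
           "enrich_catalog", "GeneSetEnrichment", "GeneSetEnrichmentResults"]


@dataclass
class EnrichmentResult:
    term: str
    name: str
    source_test: str
    n_set: int
    n_background: int
    ks_statistic: float
    p: float
    p_adjusted: float
    leading_edge: list
    n_leading_nominal: int
    label: str = ""

    def to_row(self) -> dict:
        return {"term": self.term, "name": self.name,
                "test": self.source_test, "n_set": self.n_set,
                "n_background": self.n_background,
                "ks_statistic": self.ks_statistic, "p": self.p,
                "p_adjusted": self.p_adjusted,
                "n_leading_edge": len(self.leading_edge),
                "n_leading_nominal": self.n_leading_nominal,
                "leading_edge": ",".join(self.leading_edge),
                "label": self.label}


def _dplus_scan(values: np.ndarray, in_set: np.ndarray) -> tuple[float, float]:
    """D+ and the smallest pooled value attaining it.

    CDFs are evaluated at each distinct pooled value (ties handled by
    evaluating after all tied observations).
    """
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    z = in_set[order].astype(float)
    m = z.sum()
    n = z.size - m
    f_set = np.cumsum(z) / m
    f_bg = np.cumsum(1 - z) / n
    diff = f_set - f_bg
    # evaluate at last index of each run of tied values
    last = np.r_[v[1:] != v[:-1], True]
    diff = diff[last]
    vals = v[last]
    i = int(np.argmax(diff))            # argmax returns first (smallest x)
    return float(diff[i]), float(vals[i])


#: above this m*n product the exact path-counting p is skipped
_EXACT_LIMIT = 2_000_000


def ks_enrichment(gene_p: dict, set_genes, n_perm: int = 0,
                  seed: int = 0, method: str = "auto") -> tuple[float, float]:
    """One-sided two-sample KS test of a gene set against the background.

    Returns (D+, p).  ``gene_p`` maps every scored gene to its p-value;
    set members without scores are ignored.  With ``n_perm`` > 0 the
    p-value is estimated by label permutation.  Otherwise ``method``
    selects the tail computation: "auto" uses the exact path-counting
    distribution when the problem is small enough (the asymptotic
    formula is conservative for small sets) and the asymptotic
    one-sided tail exp(-2 D+^2 mn/(m+n)) beyond; "asymptotic" forces
    the formula.
    """
    set_genes = set(set_genes)
    genes = np.array(list(gene_p.keys()))
    values = np.array([gene_p[g] for g in genes], dtype=float)
    in_set = np.isin(genes, list(set_genes))
    m = int(in_set.sum())
    n = int((~in_set).sum())
    if m < 2:
        raise ValueError("need >= 2 set genes with p-values")
    if n < 2:
        raise ValueError("need >= 2 background genes with p-values")
    d_plus, _ = _dplus_scan(values, in_set)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = np.zeros(values.size, dtype=bool)
            perm[rng.choice(values.size, m, replace=False)] = True
            d_perm, _ = _dplus_scan(values, perm)
            if d_perm >= d_plus - 1e-12:
                count += 1
        p = (1 + count) / (n_perm + 1)
    elif method == "auto" and m * n <= _EXACT_LIMIT:
        from scipy import stats as _st
        try:
            p = float(_st.ks_2samp(values[in_set], values[~in_set],
                                   alternative="greater",
                                   method="exact").pvalue)
        except Exception:
            p = float(min(1.0, np.exp(-2.0 * d_plus ** 2 * m * n / (m + n))))
    else:
        p = float(min(1.0, np.exp(-2.0 * d_plus ** 2 * m * n / (m + n))))
    return float(max(d_plus, 0.0)), min(max(p, 0.0), 1.0)


def leading_edge(gene_p: dict, set_genes) -> list:
    """Set genes at or before the supremum point of D+ (empty if D+ <= 0).

    All genes tied at the supremum value are included.
    """
    set_genes = set(set_genes)
    genes = np.array(list(gene_p.keys()))
    values = np.array([gene_p[g] for g in genes], dtype=float)
    in_set = np.isin(genes, list(set_genes))
    if in_set.sum() < 2 or (~in_set).sum() < 2:
        raise ValueError("need >= 2 set and >= 2 background genes")
    d_plus, x_star = _dplus_scan(values, in_set)
    if d_plus <= 0:
        return []
    le = genes[in_set & (values <= x_star)]
    return sorted(le.tolist())


def enrich_catalog(catalog: dict, gene_results, scheme: SignificanceScheme,
                   nominal_p: float = 0.05, small_set: int = 10,
                   n_perm_small: int = 2000, seed: int = 0) -> pd.DataFrame:
    """KS enrichment of every catalog term against every gene-level test.

    Parameters
    ----------
    catalog : dict
        term id -> (name, list of genes) or term id -> list of genes.
    gene_results : dict or DataFrame
        test name -> {gene: calibrated p}; or a long DataFrame with
        columns gene, test, p.
    scheme : SignificanceScheme
        Used to label the calibrated term-level p-values.

    Term-level p-values are themselves logit-recalibrated across terms
    (per test source) before classification; output is sorted by
    p_adjusted.  Sets smaller than ``small_set`` use a label-permutation
    p-value instead of the asymptotic formula.
    """
    if not catalog:
        raise ValueError("empty catalog")
    if isinstance(gene_results, pd.DataFrame):
        sources = {t: dict(zip(g["gene"], g["p"]))
                   for t, g in gene_results.dropna(subset=["p"]).groupby("test")}
    else:
        sources = gene_results
    norm_catalog = {}
    for term, v in catalog.items():
        if isinstance(v, tuple):
            norm_catalog[term] = v
        else:
            norm_catalog[term] = (term, list(v))

    results = []
    for test, gene_p in sorted(sources.items()):
        per_test = []
        for term in sorted(norm_catalog):
            name, genes = norm_catalog[term]
            scored = [g for g in genes if g in gene_p]
            n_bg = len(gene_p) - len(scored)
            if len(scored) < 2 or n_bg < 2:
                continue        # covering-all or tiny terms are flagged out
            n_perm = n_perm_small if len(scored) < small_set else 0
            d_plus, p = ks_enrichment(gene_p, scored, n_perm=n_perm,
                                      seed=seed)
            le = leading_edge(gene_p, scored)
            n_nom = sum(1 for g in le if gene_p[g] < nominal_p)
            per_test.append(EnrichmentResult(
                term=term, name=name, source_test=test, n_set=len(scored),
                n_background=n_bg, ks_statistic=d_plus, p=p,
                p_adjusted=float("nan"), leading_edge=le,
                n_leading_nominal=n_nom))
        if len(per_test) >= 3:
            cal = logit_adjust([r.p for r in per_test],
                               units=[r.term for r in per_test])
            adj = cal.as_dict()
            for r in per_test:
                r.p_adjusted = float(adj[r.term])
        else:
            for r in per_test:
                r.p_adjusted = r.p
        for r in per_test:
            r.label = classify(min(r.p_adjusted, 1.0), scheme)
        results.extend(per_test)
    table = pd.DataFrame([r.to_row() for r in results])
    if len(table):
        table = table.sort_values(["p_adjusted", "term", "test"],
                                  kind="mergesort").reset_index(drop=True)
    return table


class GeneSetEnrichmentResults:
    def __init__(self, table: pd.DataFrame):
        self.table = table

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def summary(self, top: int = 5) -> str:
        lines = ["Gene-set KS enrichment",
                 f"  terms x tests scored : {len(self.table)}",
                 "  top terms (by adjusted p):"]
        for _, r in self.table.head(top).iterrows():
            lines.append(
                f"    {r['term']:<14} {r['test']:<16} "
                f"p_corr={r['p_adjusted']:.3e} "
                f"LE={r['n_leading_edge']} ({r['n_leading_nominal']} p<0.05) "
                f"[{r['label']}]")
        return "\n".join(lines)


class GeneSetEnrichment:
    """Gene-set enrichment model over a term catalog.

    Parameters mirror :func:`enrich_catalog`; ``fit()`` returns a results
    object carrying the Table-1-style output.
    """

    def __init__(self, catalog: dict, gene_results,
                 scheme: SignificanceScheme, **kwargs):
        self.catalog = catalog
        self.gene_results = gene_results
        self.scheme = scheme
        self.kwargs = kwargs

    def fit(self) -> GeneSetEnrichmentResults:
        return GeneSetEnrichmentResults(
            enrich_catalog(self.catalog, self.gene_results, self.scheme,
                           **self.kwargs))
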