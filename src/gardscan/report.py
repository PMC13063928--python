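"""Significance schemes, QQ-plot data and cross-method concordance.

Multiple-testing thresholds follow the standard GWAS ladder: nominal
(alpha), Bonferroni (alpha/k for k parallel tests), suggestive (1/k — one
expected false positive per scan), and genome-wide (alpha/k_tot with k_tot
the number of independent tests genome-wide — 0.05 expected false
positives per scan).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SignificanceScheme", "significance_thresholds", "classify",
           "QqData", "qq_data", "method_concordance"]

#: stringency order, strictest first
LABELS = ["genome_wide", "bonferroni", "suggestive", "nominal", "ns"]


@dataclass(frozen=True)
class SignificanceScheme:
    alpha: float
    k: int
    k_tot: int
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.thresholds:
            # suggestive and genome-wide both refer to the number of
            # independent tests in the genome (one expected false positive
            # per scan, resp. 0.05); Bonferroni to the tests actually run
            object.__setattr__(self, "thresholds", {
                "nominal": self.alpha,
                "bonferroni": self.alpha / self.k,
                "suggestive": 1.0 / self.k_tot,
                "genome_wide": self.alpha / self.k_tot,
            })


def significance_thresholds(alpha: float = 0.05, k: int = 1,
                            k_tot: int | None = None) -> SignificanceScheme:
    """Build the four-level significance scheme for k parallel tests among
    k_tot independent tests genome-wide (k_tot defaults to k)."""
    if k_tot is None:
        k_tot = k
    if k < 1 or k_tot < 1:
        raise ValueError("k and k_tot must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return SignificanceScheme(alpha=alpha, k=int(k), k_tot=int(k_tot))


def classify(p: float, scheme: SignificanceScheme) -> str:
    """Label a p-value with the strictest threshold it meets (p <= level)."""
    if not 0 < p <= 1:
        raise ValueError(f"p-value {p} outside (0, 1]")
    t = scheme.thresholds
    for label in ("genome_wide", "bonferroni", "suggestive", "nominal"):
        if p <= t[label]:
            return label
    return "ns"


@dataclass
class QqData:
    table: pd.DataFrame      # columns: expected, observed (-log10 p)
    lambda_gc: float


_CHI2_MEDIAN = stats.chi2.median(1)   # 0.4549364...


def qq_data(pvalues) -> QqData:
    """Expected vs observed -log10 p under uniform order statistics, plus
    the median-based genomic inflation factor lambda_GC."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    n = p.size
    obs = np.sort(p)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(np.clip(obs, 1e-300, 1.0))
    lam = stats.chi2.isf(np.median(p), 1) / _CHI2_MEDIAN
    return QqData(
        table=pd.DataFrame({"expected": expected, "observed": observed}),
        lambda_gc=float(lam),
    )


def method_concordance(gene_results: pd.DataFrame,
                       min_common: int = 3) -> pd.DataFrame:
    """Pairwise Spearman correlation of gene-level p-values across methods.

    ``gene_results`` needs columns gene, test, p.  Entries with fewer than
    ``min_common`` genes scored by both methods are NaN.
    """
    wide = gene_results.pivot_table(index="gene", columns="test", values="p")
    methods = list(wide.columns)
    if len(methods) < 2:
        raise ValueError("need >= 2 methods")
    out = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            both = wide[[a, b]].dropna()
            if len(both) < min_common or both[a].nunique() == 1 \
                    or both[b].nunique() == 1:
                r = np.nan
            else:
                r = stats.spearmanr(both[a], both[b]).statistic
            out.loc[a, b] = out.loc[b, a] = r
    return out
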