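"""Single-SNP logistic association under the log-additive model.

Each marker enters a logistic regression as a 0-2 alt-allele dosage, so
one extra allele multiplies the odds of being a case by exp(beta).  Three
models are offered: unadjusted (dosage only), adjusted (sex, smoking as
former/current indicators vs never, and 4 genetic-ancestry PCs), and an
interaction model adding standardized age and a marker x age product
term.  Effect sizes are reported with Wald standard errors and symmetric
95% CIs on the log-odds scale; a Rao score test sharing one null-model
fit across all markers provides the fast kernel reused by the gene-level
aggregation tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .panel import CohortPanel

__all__ = ["SnpAssocResult", "fit_logistic", "fit_interaction",
           "score_test_p", "NullLogistic", "SnpAssociation",
           "SnpAssociationResults"]

Z975 = 1.959964


@dataclass
class SnpAssocResult:
    variant_id: str
    model: str                      # unadjusted | adjusted | interaction
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    interaction_p: float = float("nan")
    flag: str = ""

    def to_row(self) -> dict:
        return {"variant": self.variant_id, "model": self.model,
                "beta": self.beta, "se": self.se, "or": self.or_,
                "ci_low": self.ci_low, "ci_high": self.ci_high,
                "p": self.p, "interaction_p": self.interaction_p,
                "flag": self.flag}


def mean_impute(x: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the variant mean (within the fit only)."""
    x = np.asarray(x, dtype=float).copy()
    miss = np.isnan(x)
    if miss.any():
        x[miss] = np.nanmean(x)
    return x


def _usable_covars(covars) -> np.ndarray | None:
    """Drop constant covariate columns (absorbed by the intercept)."""
    if covars is None:
        return None
    C = np.asarray(covars, dtype=float)
    if C.size == 0:
        return None
    if C.ndim == 1:
        C = C[:, None]
    keep = np.ptp(C, axis=0) > 0
    return C[:, keep] if keep.any() else None


def _glm_fit(y: np.ndarray, X: np.ndarray):
    """IRLS logistic fit; returns the statsmodels results object."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        return model.fit(maxiter=50, tol=1e-10)


def _check_fit(res, X: np.ndarray) -> str:
    """Flag non-convergence or (quasi-)separation."""
    if not res.converged:
        return "nonconvergence"
    mu = res.fittedvalues
    if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
        return "separation"
    if np.any(~np.isfinite(res.bse)) or np.any(res.bse > 1e3):
        return "separation"
    return ""


def fit_logistic(y, x, covars=None, variant_id: str = "",
                 model_name: str | None = None) -> SnpAssocResult:
    """Wald logistic fit of case status on dosage (+ optional covariates).

    Missing dosages are mean-imputed inside the fit.  A constant dosage
    is inestimable and raises; non-convergence or separation yields a
    flagged result with p = NaN.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("need both outcome classes")
    x = mean_impute(x)
    if np.ptp(x) == 0:
        raise ValueError("constant dosage is inestimable")
    cols = [np.ones_like(y), x]
    covars = _usable_covars(covars)
    if covars is not None:
        cols.append(covars)
        default_name = "adjusted"
    else:
        default_name = "unadjusted"
    X = np.column_stack(cols)
    name = model_name or default_name
    try:
        res = _glm_fit(y, X)
    except Exception:
        return SnpAssocResult(variant_id, name, *[float("nan")] * 6,
                              flag="nonconvergence")
    flag = _check_fit(res, X)
    beta, se = float(res.params[1]), float(res.bse[1])
    p = float("nan") if flag else float(2 * stats.norm.sf(abs(beta) / se))
    with np.errstate(over="ignore"):
        ci_low = float(np.exp(beta - Z975 * se))
        ci_high = float(np.exp(beta + Z975 * se))
    return SnpAssocResult(
        variant_id=variant_id, model=name, beta=beta, se=se,
        or_=float(np.exp(beta)), ci_low=ci_low, ci_high=ci_high,
        p=p, flag=flag)


def fit_interaction(y, x, age, covars=None,
                    variant_id: str = "") -> SnpAssocResult:
    """Log-additive model plus standardized age and marker x age product.

    ``interaction_p`` is the Wald p of the product term.
    """
    y = np.asarray(y, dtype=float)
    x = mean_impute(x)
    if np.ptp(x) == 0:
        raise ValueError("constant dosage is inestimable")
    age = np.asarray(age, dtype=float)
    sd = age.std()
    age_std = (age - age.mean()) / (sd if sd > 0 else 1.0)
    prod = x * age_std
    # degenerate design: product collinear with existing columns
    base = np.column_stack([np.ones_like(y), x, age_std])
    if np.linalg.matrix_rank(np.column_stack([base, prod])) <= base.shape[1]:
        return SnpAssocResult(variant_id, "interaction", *[float("nan")] * 6,
                              flag="collinear_interaction")
    cols = [base, prod[:, None]]
    covars = _usable_covars(covars)
    if covars is not None:
        cols.append(covars)
    X = np.column_stack(cols)
    try:
        res = _glm_fit(y, X)
    except Exception:
        return SnpAssocResult(variant_id, "interaction", *[float("nan")] * 6,
                              flag="nonconvergence")
    flag = _check_fit(res, X)
    beta, se = float(res.params[1]), float(res.bse[1])
    bi, si = float(res.params[3]), float(res.bse[3])
    p = float("nan") if flag else float(2 * stats.norm.sf(abs(beta) / se))
    pint = float("nan") if flag else float(2 * stats.norm.sf(abs(bi) / si))
    return SnpAssocResult(
        variant_id=variant_id, model="interaction", beta=beta, se=se,
        or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        p=p, interaction_p=pint, flag=flag)


class NullLogistic:
    """Covariate-only logistic null fit shared across markers.

    Caches the fitted probabilities and the weighted projection needed by
    the Rao score test, so testing a new column costs one matrix-vector
    product.
    """

    def __init__(self, y, covars=None):
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("need both outcome classes")
        cols = [np.ones_like(y)]
        covars = _usable_covars(covars)
        if covars is not None:
            cols.append(covars)
        X = np.column_stack(cols)
        res = _glm_fit(y, X)
        self.y = y
        self.X = X
        self.mu = np.asarray(res.fittedvalues, dtype=float)
        self.resid = y - self.mu
        self.v = self.mu * (1 - self.mu)
        self.VX = X * self.v[:, None]
        self.XtVX_inv = np.linalg.inv(X.T @ self.VX)

    def score_test(self, G) -> tuple[np.ndarray, np.ndarray]:
        """Rao score chi-square and p for each column of G (n x m)."""
        G = np.asarray(G, dtype=float)
        if G.ndim == 1:
            G = G[:, None]
        U = G.T @ self.resid
        B = G.T @ self.VX                       # m x k
        var = np.einsum("nj,nj->j", G, G * self.v[:, None]) \
            - np.einsum("jk,kl,jl->j", B, self.XtVX_inv, B)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(var > 0, U ** 2 / var, np.nan)
        p = stats.chi2.sf(chi2, 1)
        return chi2, p


def score_test_p(y, x, covars=None) -> float:
    """Rao score test p of one dosage column at the covariate-only null."""
    x = mean_impute(x)
    if np.ptp(x) == 0:
        raise ValueError("constant dosage is inestimable")
    null = NullLogistic(y, covars)
    _, p = null.score_test(x[:, None])
    return float(p[0])


# ---------------------------------------------------------------------------
# model/results wrappers
# ---------------------------------------------------------------------------

class SnpAssociationResults:
    """Per-variant association table with a human-readable summary."""

    def __init__(self, table: pd.DataFrame):
        self.table = table

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def summary(self, top: int = 10) -> str:
        t = self.table.sort_values("p").head(top)
        lines = ["Single-SNP logistic association",
                 f"  models fitted : {sorted(self.table['model'].unique())}",
                 f"  variants      : {self.table['variant'].nunique()}",
                 "  top hits (by p):"]
        for _, r in t.iterrows():
            lines.append(
                f"    {r['variant']:<16} {r['model']:<11} "
                f"OR={r['or']:.3f} (95%CI {r['ci_low']:.3f}-{r['ci_high']:.3f})"
                f"  p={r['p']:.3e}")
        return "\n".join(lines)


class SnpAssociation:
    """Single-SNP association scan over a cohort panel.

    Parameters
    ----------
    panel : CohortPanel
    models : sequence of {"unadjusted", "adjusted", "interaction"}
    """

    def __init__(self, panel: CohortPanel,
                 models=("unadjusted", "adjusted", "interaction")):
        self.panel = panel
        self.models = tuple(models)

    def fit(self) -> SnpAssociationResults:
        panel = self.panel
        y = panel.status
        covars = panel.covariate_matrix()
        age = panel.samples["age"].to_numpy(float)
        rows = []
        for j, vid in enumerate(panel.variants["id"]):
            x = panel.dosage[:, j]
            if np.ptp(mean_impute(x)) == 0:
                rows.append(SnpAssocResult(
                    vid, "all", *[float("nan")] * 6,
                    flag="monomorphic").to_row())
                continue
            if "unadjusted" in self.models:
                rows.append(fit_logistic(y, x, None, vid).to_row())
            if "adjusted" in self.models:
                rows.append(fit_logistic(y, x, covars, vid).to_row())
            if "interaction" in self.models:
                rows.append(fit_interaction(y, x, age, covars, vid).to_row())
        return SnpAssociationResults(pd.DataFrame(rows))
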