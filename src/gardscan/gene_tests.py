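"""Gene-level multi-marker association tests.

Five aggregation tests run on identical marker sets per gene:

* ``burden_add``     — unweighted dosage burden (score test)
* ``burden_zeggini`` — carrier-style collapsing, min(dosage, 1)
* ``burden_fp``      — frequency-weighted burden, w = 1/sqrt(p(1-p))
* ``skat``           — variance-component quadratic form, Beta(1,25) MAF
                       weights, mixture-chi-square p
* ``skato``          — optimal burden/SKAT combination over a rho grid
* ``permutation``    — mean chi-square of a greedily selected subset of
                       the most significant, mutually weakly correlated
                       markers; p by phenotype permutation

Burden tests collapse a gene's variants into one per-sample score and
are powerful when effects are common and same-signed; the
variance-component tests tolerate mixed effect directions; the optimal
combination interpolates between the two over a mixing grid rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

from ._quadform import liu_quantile, mixture_chi2_sf
from .annotate import GeneAssignment
from .panel import CohortPanel
from .snp_assoc import NullLogistic, mean_impute

__all__ = ["GeneMarkerSet", "GeneTestResult", "burden_test", "skat_test",
           "skato_test", "permutation_set_test", "run_gene_battery",
           "GeneBattery", "GeneBatteryResults", "DEFAULT_TESTS",
           "DEFAULT_RHO_GRID"]

DEFAULT_TESTS = ("burden_add", "burden_zeggini", "burden_fp",
                 "skat", "skato", "permutation")
DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)


@dataclass
class GeneMarkerSet:
    gene: str
    variant_ids: list
    dosage: np.ndarray          # n_samples x n_markers, mean-imputed
    maf: np.ndarray

    def __post_init__(self):
        if len(self.variant_ids) < 1:
            raise ValueError("marker set needs >= 1 variant")
        self.dosage = np.column_stack(
            [mean_impute(self.dosage[:, j])
             for j in range(self.dosage.shape[1])])

    @property
    def n_markers(self) -> int:
        return len(self.variant_ids)


@dataclass
class GeneTestResult:
    gene: str
    test: str
    n_markers: int
    statistic: float
    p: float
    flag: str = ""
    rho_pvalues: tuple = ()         # per-rho component p's (SKAT-O only)

    def to_row(self) -> dict:
        return {"gene": self.gene, "test": self.test,
                "n_markers": self.n_markers, "statistic": self.statistic,
                "p": self.p, "flag": self.flag}


def _polymorphic(gms: GeneMarkerSet) -> np.ndarray:
    return np.array([np.ptp(gms.dosage[:, j]) > 0
                     for j in range(gms.n_markers)])


def burden_test(gms: GeneMarkerSet, y, covars=None,
                scheme: str = "add",
                null: NullLogistic | None = None) -> GeneTestResult:
    """Collapse the marker set into one per-sample score and score-test it.

    Schemes: ``add`` (plain dosage sum), ``zeggini`` (min(dosage,1) carrier
    collapsing), ``fp`` (1/sqrt(p(1-p)) frequency weights on dosage).
    """
    G = gms.dosage
    if scheme == "add":
        s = G.sum(axis=1)
    elif scheme == "zeggini":
        s = np.minimum(G, 1.0).sum(axis=1)
    elif scheme == "fp":
        p_hat = np.clip(gms.maf, 1e-8, 0.5)
        w = 1.0 / np.sqrt(p_hat * (1 - p_hat))
        s = G @ w
    else:
        raise ValueError(f"unknown burden scheme {scheme!r}")
    name = f"burden_{scheme}"
    if np.ptp(s) == 0:
        return GeneTestResult(gms.gene, name, gms.n_markers,
                              float("nan"), float("nan"), "constant_burden")
    if null is None:
        null = NullLogistic(y, covars)
    chi2, p = null.score_test(s[:, None])
    return GeneTestResult(gms.gene, name, gms.n_markers,
                          float(chi2[0]), float(p[0]))


def _skat_weights(maf: np.ndarray, weight_beta=(1.0, 25.0)) -> np.ndarray:
    return stats.beta.pdf(np.clip(maf, 1e-8, 1 - 1e-8), *weight_beta)


def _permutation_moments(B: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Exact mean and variance of Q = r'BB'r when r is a uniformly drawn
    permutation of the centred vector c.

    All pattern sums reduce to the m x m Gram matrix and the row norms of
    the column-centred factor, so the cost is O(nm + m^2) per call.
    """
    n = c.size
    Bc = B - B.mean(axis=0, keepdims=True)      # centres M = BB' -> HMH
    p2 = float(np.sum(c ** 2))
    p4 = float(np.sum(c ** 4))
    G = Bc.T @ Bc
    T1 = float(np.trace(G))
    T2 = float(np.sum(G * G))                   # tr((HMH)^2)
    d = np.einsum("ij,ij->i", Bc, Bc)           # diagonal of HMH
    A2 = float(np.sum(d ** 2))
    e_q = p2 * T1 / (n - 1)
    nn = n * (n - 1)
    nnn = nn * (n - 2)
    nnnn = nnn * (n - 3)
    e_q2 = (A2 * p4 / n
            + 4 * A2 * p4 / nn
            + (T1 ** 2 - A2) * (p2 ** 2 - p4) / nn
            + 2 * (T2 - A2) * (p2 ** 2 - p4) / nn
            + 2 * (2 * A2 - T1 ** 2) * (2 * p4 - p2 ** 2) / nnn
            + 4 * (2 * A2 - T2) * (2 * p4 - p2 ** 2) / nnn
            + (T1 ** 2 + 2 * T2 - 6 * A2) * (3 * p2 ** 2 - 6 * p4) / nnnn)
    return e_q, max(e_q2 - e_q ** 2, 0.0)


def _moment_adjusted_q(Q: float, lam: np.ndarray, B: np.ndarray,
                       c: np.ndarray) -> float:
    """Map the observed quadratic form onto the asymptotic mixture scale
    so that its exact permutation mean and variance match the mixture's.

    Small-sample correction: the chi-square-mixture null assumes Gaussian
    scores, which overstates dispersion for binary outcomes at modest n;
    matching the first two exact permutation moments recentres the test.
    """
    e_q, v_q = _permutation_moments(B, c)
    mu = float(lam.sum())
    var = 2.0 * float(np.sum(lam ** 2))
    if v_q <= 0 or var <= 0:
        return Q
    return mu + (Q - e_q) * np.sqrt(var / v_q)


def _projected_Z(gms: GeneMarkerSet, null: NullLogistic,
                 weight_beta) -> np.ndarray:
    """Z1 = V^{1/2}(I - X(X'VX)^-1 X'V) G W, so Z1'Z1 is the null
    covariance of the weighted score vector."""
    W = _skat_weights(gms.maf, weight_beta)
    A = gms.dosage * W[None, :]
    sqv = np.sqrt(null.v)
    XtVA = null.VX.T @ A
    Z1 = sqv[:, None] * (A - null.X @ (null.XtVX_inv @ XtVA))
    return Z1, A


def skat_test(gms: GeneMarkerSet, y, covars=None,
              weight_beta=(1.0, 25.0),
              null: NullLogistic | None = None) -> GeneTestResult:
    """Variance-component score test Q = r'GW W G'r with mixture-chi2 p."""
    if null is None:
        null = NullLogistic(y, covars)
    Z1, A = _projected_Z(gms, null, weight_beta)
    S = A.T @ null.resid
    Q = float(S @ S)
    Sigma = Z1.T @ Z1
    lam = np.linalg.eigvalsh(Sigma)
    lam = lam[lam > 1e-10 * max(lam.max(initial=0.0), 1e-300)]
    if lam.size == 0:
        return GeneTestResult(gms.gene, "skat", gms.n_markers,
                              Q, float("nan"), "zero_variance")
    q_eval = Q
    if gms.n_markers > 1:
        q_eval = _moment_adjusted_q(Q, lam, A, null.resid)
    p, method = mixture_chi2_sf(q_eval, lam, return_method=True)
    flag = "liu_fallback" if method == "liu" else ""
    return GeneTestResult(gms.gene, "skat", gms.n_markers, Q, float(p), flag)


# ---------------------------------------------------------------------------
# SKAT-O: optimal combination over the rho grid
# ---------------------------------------------------------------------------

def _skato_params(Z1: np.ndarray, rho_grid: np.ndarray) -> dict:
    """Moments of the common decomposition used by the one-dimensional
    integration of the minimum-p statistic (optimal-test construction)."""
    m = Z1.shape[1]
    z_mean = Z1.mean(axis=1)
    denom = float(z_mean @ z_mean)
    if denom < 1e-300:
        raise ZeroDivisionError("degenerate mean direction")
    cof1 = (z_mean @ Z1) / denom
    Z_item1 = np.outer(z_mean, cof1)
    Z_item2 = Z1 - Z_item1
    W22 = Z_item2.T @ Z_item2
    lam = np.linalg.eigvalsh(W22)
    lam = lam[lam > 1e-10 * max(lam.max(initial=0.0), 1e-300)]
    var_remain = 4.0 * float(np.sum((Z_item1.T @ Z_item1) * W22))
    mu_q = lam.sum()
    var_q = 2 * np.sum(lam ** 2) + var_remain
    tau = np.array([m ** 2 * r * denom + (1 - r) * denom * np.sum(cof1 ** 2)
                    for r in rho_grid])
    return {"lambda": lam, "mu_q": mu_q, "var_q": var_q,
            "var_remain": var_remain, "tau": tau}


def skato_test(gms: GeneMarkerSet, y, covars=None,
               weight_beta=(1.0, 25.0),
               rho_grid=DEFAULT_RHO_GRID,
               null: NullLogistic | None = None) -> GeneTestResult:
    """Optimal SKAT/burden combination over the mixing grid rho.

    Q_rho = (1-rho) Q_SKAT + rho Q_burden; the minimum of the per-rho
    p-values is converted into one overall p by integrating the joint
    tail over the shared chi-square factor.  Safeguards clamp the result
    into [min_rho p_rho, grid_size * min_rho p_rho].
    """
    rho_grid = np.asarray(sorted(set(float(r) for r in rho_grid)))
    if np.any((rho_grid < 0) | (rho_grid > 1)):
        raise ValueError("rho values must lie in [0, 1]")
    if null is None:
        null = NullLogistic(y, covars)
    if rho_grid.size == 1:
        # degenerate grids collapse to the pure tests
        if rho_grid[0] == 1.0:
            res = burden_test(gms, y, covars, "add", null=null)
        else:
            res = skat_test(gms, y, covars, weight_beta, null=null)
        return GeneTestResult(gms.gene, "skato", gms.n_markers,
                              res.statistic, res.p, res.flag)

    m = gms.n_markers
    if m == 1:
        # one marker: every Q_rho coincides with the score test
        res = skat_test(gms, y, covars, weight_beta, null=null)
        return GeneTestResult(gms.gene, "skato", m, res.statistic, res.p,
                              res.flag)
    Z1, A = _projected_Z(gms, null, weight_beta)
    S = A.T @ null.resid
    Q_skat = float(S @ S)
    Q_burden = float(S.sum() ** 2)

    # per-rho p-values
    work_grid = np.where(rho_grid >= 1.0, 1 - 1e-4, rho_grid)
    p_rho = np.empty(rho_grid.size)
    q_obs = np.empty(rho_grid.size)
    lam_rho = []
    Sigma = Z1.T @ Z1
    for i, r in enumerate(work_grid):
        q_obs[i] = (1 - r) * Q_skat + r * Q_burden
        R = (1 - r) * np.eye(m) + r * np.ones((m, m))
        # eigenvalues of R^{1/2} Sigma R^{1/2} = eigenvalues of R Sigma
        lam = np.real(np.linalg.eigvals(R @ Sigma))
        lam = lam[lam > 1e-10 * max(lam.max(initial=0.0), 1e-300)]
        lam_rho.append(lam)
        if lam.size == 0:
            return GeneTestResult(gms.gene, "skato", m, Q_skat,
                                  float("nan"), "zero_variance")
        # small-sample recalibration of Q_rho = r' (A L)(A L)' r
        L = np.linalg.cholesky(R + 1e-12 * np.eye(m))
        q_obs[i] = _moment_adjusted_q(q_obs[i], lam, A @ L, null.resid)
        p_rho[i] = mixture_chi2_sf(q_obs[i], lam)
    t_min = float(p_rho.min())
    if t_min >= 1.0:
        return GeneTestResult(gms.gene, "skato", m, Q_skat, 1.0,
                              rho_pvalues=tuple(p_rho))

    # quantiles of each Q_rho at level t_min (moment-matched, as in the
    # published optimal-test construction)
    q_min = np.array([liu_quantile(t_min, lam_rho[i])
                      for i in range(rho_grid.size)])

    try:
        par = _skato_params(Z1, work_grid)
    except (ZeroDivisionError, FloatingPointError, np.linalg.LinAlgError):
        p = float(min(1.0, rho_grid.size * t_min))
        return GeneTestResult(gms.gene, "skato", m, Q_skat, p,
                              "minp_bonferroni")
    lam, mu_q = par["lambda"], par["mu_q"]
    if lam.size == 0:
        # columns all proportional to the mean direction: pure burden
        p = float(min(1.0, rho_grid.size * t_min))
        return GeneTestResult(gms.gene, "skato", m, Q_skat, p,
                              "minp_bonferroni")
    var_q, var_remain, tau = par["var_q"], par["var_remain"], par["tau"]
    scale = np.sqrt(max(var_q - var_remain, 0.0)) / np.sqrt(var_q)

    # CDF of the kappa mixture, tabulated once and interpolated
    from scipy.interpolate import PchipInterpolator

    from ._quadform import imhof_sf_grid
    q_hi = max(liu_quantile(1e-7, lam), q_min.max(), 1.0)
    grid_q = np.linspace(q_hi / 96, q_hi, 49)
    cdf_grid = 1.0 - imhof_sf_grid(grid_q, lam, eps=1e-6)
    grid_q = np.r_[0.0, grid_q]
    cdf_grid = np.r_[0.0, cdf_grid]
    cdf_grid = np.maximum.accumulate(np.clip(cdf_grid, 0.0, 1.0))
    kappa_cdf = PchipInterpolator(grid_q, cdf_grid, extrapolate=False)

    def integrand(t):
        # substitution x = t^2 turns the chi2_1 density into a half-normal
        x = t * t
        tmp = np.min((q_min[None, :] - np.outer(x, tau))
                     / (1 - work_grid)[None, :], axis=1)
        tq = (tmp - mu_q) * scale + mu_q
        cdf = np.where(tq <= 0, 0.0,
                       np.where(tq >= q_hi, 1.0,
                                np.nan_to_num(kappa_cdf(np.clip(tq, 0, q_hi)))))
        return cdf * np.sqrt(2.0 / np.pi) * np.exp(-0.5 * t * t)

    val = integrate.fixed_quad(integrand, 0.0, 6.5, n=200)[0]
    p = 1.0 - val
    # monotone safeguards
    p = float(min(max(p, t_min), min(1.0, rho_grid.size * t_min)))
    return GeneTestResult(gms.gene, "skato", m, Q_skat, p,
                          rho_pvalues=tuple(p_rho))


# ---------------------------------------------------------------------------
# phenotype-permutation set test
# ---------------------------------------------------------------------------

def _select_subset(chi2: np.ndarray, r2: np.ndarray, chi2_min: float,
                   set_r2: float, set_max: int) -> list:
    """Greedy pick of up to set_max markers with chi2 above threshold,
    skipping markers too correlated (r2 > set_r2) with one already picked."""
    order = np.argsort(-chi2)
    picked: list[int] = []
    for j in order:
        if not np.isfinite(chi2[j]) or chi2[j] <= chi2_min:
            break
        if any(r2[j, i] > set_r2 for i in picked):
            continue
        picked.append(j)
        if len(picked) == set_max:
            break
    return picked


def _null_refit_batch(Yperm: np.ndarray, X: np.ndarray,
                      max_iter: int = 25, tol: float = 1e-8) -> np.ndarray:
    """Batched IRLS over permuted phenotypes; returns fitted means P x n."""
    P, n = Yperm.shape
    k = X.shape[1]
    beta = np.zeros((P, k))
    beta[:, 0] = np.log(np.clip(Yperm.mean(axis=1), 1e-9, 1 - 1e-9)
                        / np.clip(1 - Yperm.mean(axis=1), 1e-9, 1))
    for _ in range(max_iter):
        eta = beta @ X.T
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = np.einsum("pn,nk->pk", Yperm - mu, X)
        H = np.einsum("pn,nk,nl->pkl", w, X, X)
        step = np.linalg.solve(H, grad[..., None])[..., 0]
        beta += step
        if np.abs(grad).max() < tol:
            break
    eta = beta @ X.T
    return 1.0 / (1.0 + np.exp(-eta))


class PermutationNulls:
    """Permuted phenotypes and their refitted null means, shared across
    genes so the expensive covariate-adjusted refits happen once."""

    def __init__(self, y, covars, n_perm: int, seed: int):
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(seed)
        self.Yperm = rng.permuted(
            np.broadcast_to(y, (n_perm, y.size)).copy(), axis=1)
        self.have_covars = covars is not None and np.asarray(covars).size > 0
        if self.have_covars:
            X = np.column_stack([np.ones_like(y),
                                 np.asarray(covars, dtype=float)])
            self.X = X
            chunks = []
            step = max(1, int(4e7 // (y.size * X.shape[1] ** 2)))
            for s in range(0, n_perm, step):
                chunks.append(_null_refit_batch(self.Yperm[s:s + step], X))
            self.Mu = np.vstack(chunks)
        else:
            self.X = np.ones((y.size, 1))
            self.Mu = np.broadcast_to(
                self.Yperm.mean(axis=1)[:, None], self.Yperm.shape)


def permutation_set_test(gms: GeneMarkerSet, y, covars=None,
                         set_p: float = 0.05, set_r2: float = 0.5,
                         set_max: int = 5, n_perm: int = 10_000,
                         seed: int = 0,
                         perm_cache: "PermutationNulls | None" = None
                         ) -> GeneTestResult:
    """Mean chi-square of a greedily selected marker subset, with an
    empirical p from phenotype permutation.

    Per-variant 1-df score chi-squares are computed at the covariate-only
    null; markers with per-variant p < ``set_p`` are selected in
    decreasing order of chi-square, skipping any with squared dosage
    correlation above ``set_r2`` to an already-selected marker, up to
    ``set_max``.  The statistic is the mean chi-square of the selection
    (0 when empty).  Phenotypes are permuted with covariate rows held
    fixed, the null model refitted and the selection redone per
    permutation; p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    y = np.asarray(y, dtype=float)
    G = gms.dosage
    m = gms.n_markers
    poly = _polymorphic(gms)
    if not poly.any():
        return GeneTestResult(gms.gene, "permutation", m, float("nan"),
                              float("nan"), "all_monomorphic")
    chi2_min = stats.chi2.isf(set_p, 1)
    with np.errstate(invalid="ignore"):
        r2 = np.corrcoef(G.T) ** 2 if m > 1 else np.ones((1, 1))
    r2 = np.nan_to_num(r2, nan=1.0)

    have_covars = covars is not None and np.asarray(covars).size > 0

    def stat_for(mu_vec, yv):
        resid = yv - mu_vec
        v = mu_vec * (1 - mu_vec)
        if have_covars:
            X = Xfull
            VX = X * v[:, None]
            XtVXi = np.linalg.inv(X.T @ VX)
            B = G.T @ VX
            var = np.einsum("nj,nj->j", G, G * v[:, None]) \
                - np.einsum("jk,kl,jl->j", B, XtVXi, B)
        else:
            gsum = G.sum(axis=0)
            n = G.shape[0]
            vs = v[0]  # intercept-only: v constant across samples
            var = vs * (np.einsum("nj,nj->j", G, G) - gsum ** 2 / n)
        U = G.T @ resid
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(var > 0, U ** 2 / var, np.nan)
        sel = _select_subset(c, r2, chi2_min, set_r2, set_max)
        return float(np.mean(c[sel])) if sel else 0.0

    if perm_cache is None:
        perm_cache = PermutationNulls(y, covars if have_covars else None,
                                      n_perm, seed)
    Xfull = perm_cache.X
    null = NullLogistic(y, covars if have_covars else None)
    obs = stat_for(null.mu, y)

    count_ge = 0
    if not have_covars:
        # intercept-only null: the fitted mean is the permutation-invariant
        # phenotype mean, so all per-variant chi-squares come from one matmul
        ybar = y.mean()
        v = ybar * (1 - ybar)
        gsum = G.sum(axis=0)
        n = G.shape[0]
        var = v * (np.einsum("nj,nj->j", G, G) - gsum ** 2 / n)
        U_all = perm_cache.Yperm @ G - ybar * gsum[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2_all = np.where(var[None, :] > 0,
                                U_all ** 2 / var[None, :], np.nan)
        for row in chi2_all:
            sel = _select_subset(row, r2, chi2_min, set_r2, set_max)
            s = float(np.mean(row[sel])) if sel else 0.0
            if s >= obs - 1e-12:
                count_ge += 1
    else:
        for i in range(perm_cache.Yperm.shape[0]):
            if stat_for(perm_cache.Mu[i], perm_cache.Yperm[i]) >= obs - 1e-12:
                count_ge += 1
    n_perm_eff = perm_cache.Yperm.shape[0]
    p = (1 + count_ge) / (n_perm_eff + 1)
    return GeneTestResult(gms.gene, "permutation", m, obs, float(p))


# ---------------------------------------------------------------------------
# battery over all genes
# ---------------------------------------------------------------------------

def build_marker_sets(assignment: GeneAssignment,
                      panel: CohortPanel) -> dict:
    """gene -> GeneMarkerSet for genes with >= 1 post-QC marker."""
    present = set(panel.variants["id"])
    out = {}
    for gene, vids in assignment.gene_sets().items():
        vids = [v for v in vids if v in present]
        if not vids:
            continue
        idx = [panel.variant_index(v) for v in vids]
        out[gene] = GeneMarkerSet(
            gene=gene, variant_ids=vids,
            dosage=panel.dosage[:, idx],
            maf=panel.variants["maf"].to_numpy(float)[idx])
    return out


def run_gene_battery(assignment: GeneAssignment, panel: CohortPanel,
                     y=None, covars=None, tests=DEFAULT_TESTS,
                     n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Run every requested test on every gene's (identical) marker set."""
    if not assignment.mapping:
        raise ValueError("empty gene assignment")
    if y is None:
        y = panel.status
    if covars is None:
        covars = panel.covariate_matrix()
    marker_sets = build_marker_sets(assignment, panel)
    null = NullLogistic(y, covars)
    perm_cache = (PermutationNulls(y, covars, n_perm, seed)
                  if "permutation" in tests else None)
    rows = []
    for gene in sorted(marker_sets):
        gms = marker_sets[gene]
        poly = _polymorphic(gms)
        for test in tests:
            if not poly.any():
                rows.append(GeneTestResult(
                    gene, test, gms.n_markers, float("nan"),
                    float("nan"), "all_monomorphic").to_row())
                continue
            if test.startswith("burden_"):
                res = burden_test(gms, y, covars, test[len("burden_"):],
                                  null=null)
            elif test == "skat":
                res = skat_test(gms, y, covars, null=null)
            elif test == "skato":
                res = skato_test(gms, y, covars, null=null)
            elif test == "permutation":
                res = permutation_set_test(gms, y, covars,
                                           n_perm=n_perm, seed=seed,
                                           perm_cache=perm_cache)
            else:
                raise ValueError(f"unknown test {test!r}")
            rows.append(res.to_row())
    return pd.DataFrame(rows)


class GeneBatteryResults:
    def __init__(self, table: pd.DataFrame):
        self.table = table

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def pvalues(self, test: str) -> dict:
        t = self.table[(self.table["test"] == test)
                       & self.table["p"].notna()]
        return dict(zip(t["gene"], t["p"]))

    def summary(self, top: int = 5) -> str:
        lines = ["Gene-level multi-marker tests",
                 f"  genes : {self.table['gene'].nunique()}",
                 f"  tests : {sorted(self.table['test'].unique())}"]
        for test, grp in self.table.groupby("test"):
            best = grp.loc[grp["p"].idxmin()] if grp["p"].notna().any() else None
            if best is not None:
                lines.append(f"  {test:<16} best {best['gene']} "
                             f"p={best['p']:.3e} ({int(best['n_markers'])} markers)")
        return "\n".join(lines)


class GeneBattery:
    """Gene-level test battery as a model object.

    ``fit()`` runs the requested tests over every gene of the assignment
    and returns a :class:`GeneBatteryResults`.
    """

    def __init__(self, panel: CohortPanel, assignment: GeneAssignment,
                 tests=DEFAULT_TESTS, n_perm: int = 1000, seed: int = 0):
        self.panel = panel
        self.assignment = assignment
        self.tests = tuple(tests)
        self.n_perm = n_perm
        self.seed = seed

    def fit(self) -> GeneBatteryResults:
        table = run_gene_battery(self.assignment, self.panel,
                                 tests=self.tests, n_perm=self.n_perm,
                                 seed=self.seed)
        return GeneBatteryResults(table)
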