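"""Tail probabilities of positive mixtures of chi-square(1) variables.

Used by the variance-component (SKAT-type) tests: the score statistic is
asymptotically distributed as sum_k lambda_k * chi2_1.  The survival
function is computed by Imhof's exact characteristic-function inversion
(numerical integration); when the integration fails or returns a value
outside [0, 1], the Liu-Tang-Zhang moment-matching approximation is used
and the caller is told via the returned flag.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

__all__ = ["mixture_chi2_sf", "mixture_chi2_quantile", "liu_sf",
           "liu_quantile", "imhof_sf_grid"]


def imhof_sf_grid(qs, lam: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Imhof survival function at many quantiles in one vectorized pass.

    The inversion integral for each quantile is truncated once the
    oscillation envelope (an alternating-tail bound) falls below ``eps``;
    integration proceeds in Simpson panels whose step tracks the fastest
    oscillation still active, so large quantiles retire early and the
    long slow tail is only walked for the small ones.
    """
    qs = np.atleast_1d(np.asarray(qs, dtype=float))
    lam = np.asarray(lam, dtype=float)
    # the distribution is scale-equivariant: normalise to mean eigenvalue 1
    scale = lam.mean()
    lam = np.sort(lam / scale)
    qs = qs / scale
    # near-zero eigenvalues stall the decay of the inversion integrand;
    # drop those carrying <0.2% of the total mass and compensate by
    # shifting q by their expected contribution (error ~ their SD)
    cum = np.cumsum(lam)
    keep = cum > 2e-3 * cum[-1]
    shift = float(lam[~keep].sum())
    lam = lam[keep]
    qs = qs - shift
    k = lam.size
    sum_lam = lam.sum()
    q_eff = np.maximum(qs, 0.05 * sum_lam)
    # endpoint where the half-period envelope bound drops below eps:
    # amp(U) * (pi/q) <= eps, with the exact envelope
    # amp(u) = 1 / (u * prod(1 + lam^2 u^2)^{1/4}) inverted on a log grid
    lug = np.logspace(-3, 7, 120)
    env = -np.log(lug) - 0.25 * np.sum(
        np.log1p((lam[:, None] * lug[None, :]) ** 2), axis=0)
    neg_log_target = -np.log(eps * q_eff / np.pi)
    u_stop = 10 ** np.interp(neg_log_target, -env, np.log10(lug))
    u_stop = np.clip(u_stop, 1.0, 1e7)
    F = np.zeros(qs.size)
    u_cur = 0.0
    active = np.ones(qs.size, dtype=bool)
    panel_pts = 1024
    guard = 0
    while active.any() and guard < 2000:
        guard += 1
        qa_max = q_eff[active].max()
        du = 2 * np.pi / (qa_max * 10.0)
        # also resolve the phase term sum(arctan(lam u))/2 near the origin
        du = min(du, 0.5 / max(lam.max(), 1e-12)) if u_cur == 0.0 else du
        u_hi = min(u_cur + panel_pts * du, float(u_stop.max()))
        n = int(np.ceil((u_hi - u_cur) / du))
        if n < 2:
            n = 2
        if n % 2:
            n += 1
        u = np.linspace(u_cur, u_hi, n + 1)
        uu = u.copy()
        if uu[0] == 0.0:
            uu[0] = 1e-30                     # integrand limit handled below
        lu = lam[:, None] * uu[None, :]
        a = 0.5 * np.sum(np.arctan(lu), axis=0)
        logamp = -np.log(uu) - 0.25 * np.sum(np.log1p(lu ** 2), axis=0)
        h = u[1] - u[0]
        w = np.ones(n + 1)
        w[1:-1:2] = 4.0
        w[2:-1:2] = 2.0
        w *= h / 3.0
        idx = np.flatnonzero(active)
        phase = a[None, :] - 0.5 * qs[idx, None] * u[None, :]
        vals = np.sin(phase) * np.exp(logamp)[None, :]
        if u[0] == 0.0:
            # finite limit of the integrand at u -> 0
            vals[:, 0] = 0.5 * (sum_lam - qs[idx])
        F[idx] += vals @ w
        u_cur = u_hi
        active &= u_stop > u_cur
    return np.clip(0.5 + F / np.pi, 0.0, 1.0)


def liu_sf(q: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang non-central chi-square moment-matching survival."""
    c1, c2, c3, c4 = (np.sum(lam ** k) for k in (1, 2, 3, 4))
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2 * delta
    else:
        delta = 0.0
        df = 1 / s2
    mu_q = c1
    sigma_q = np.sqrt(2 * c2)
    t_star = (q - mu_q) / sigma_q
    mu_x = df + delta
    sigma_x = np.sqrt(2 * (df + 2 * delta))
    x = t_star * sigma_x + mu_x
    return float(stats.ncx2.sf(x, df, delta) if delta > 0
                 else stats.chi2.sf(x, df))


def mixture_chi2_sf(q: float, lambdas, return_method: bool = False):
    """P(sum_k lambda_k chi2_1 > q) by Imhof integration, Liu fallback.

    Eigenvalues below 1e-10 * max are dropped.  Returns the probability,
    or (probability, method) when ``return_method``.
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12 * max(lam.max(initial=0.0), 1e-300)]
    if lam.size == 0:
        raise ValueError("all eigenvalues are (numerically) zero")
    # drop eigenvalues carrying a negligible share of the total mass:
    # they perturb the distribution below the working accuracy but make
    # the oscillatory inversion integral converge orders slower
    lam = np.sort(lam)[::-1]
    cum_dropped = np.cumsum(lam[::-1])[::-1]
    lam = lam[cum_dropped > 1e-6 * lam.sum()]
    if q <= 0:
        out = (1.0, "exact")
        return out if return_method else 1.0
    if lam.size == 1:
        p = float(stats.chi2.sf(q / lam[0], 1))
        return (p, "exact") if return_method else p
    try:
        p = float(imhof_sf_grid([q], lam, eps=1e-8)[0])
        if np.isfinite(p) and p > 1e-6:
            return (p, "imhof") if return_method else p
    except Exception:
        pass
    # deep tail: absolute inversion accuracy is exhausted, fall back to
    # the moment-matching approximation
    p = max(liu_sf(q, lam), 1e-14)
    return (p, "liu") if return_method else p


def _liu_params(lam: np.ndarray) -> tuple[float, float, float, float]:
    c1, c2, c3, c4 = (np.sum(lam ** k) for k in (1, 2, 3, 4))
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2 * delta
    else:
        delta = 0.0
        df = 1 / s2
    return c1, np.sqrt(2 * c2), df, delta


def liu_quantile(p_tail: float, lambdas) -> float:
    """Upper quantile of the mixture by Liu moment matching (the quantile
    convention used by the optimal-combination test)."""
    lam = np.asarray(lambdas, dtype=float)
    mu_q, sigma_q, df, delta = _liu_params(lam)
    x = (stats.ncx2.isf(p_tail, df, delta) if delta > 0
         else stats.chi2.isf(p_tail, df))
    mu_x = df + delta
    sigma_x = np.sqrt(2 * (df + 2 * delta))
    return float((x - mu_x) / sigma_x * sigma_q + mu_q)


def mixture_chi2_quantile(p_tail: float, lambdas) -> float:
    """q such that P(sum lambda_k chi2_1 > q) = p_tail (upper quantile)."""
    lam = np.asarray(lambdas, dtype=float)
    total = lam.sum()
    lo, hi = 0.0, max(total, 1.0)
    while mixture_chi2_sf(hi, lam) > p_tail:
        hi *= 2
        if hi > 1e12:
            break
    return float(optimize.brentq(
        lambda q: mixture_chi2_sf(q, lam) - p_tail, lo, hi,
        xtol=1e-10, rtol=1e-12))
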