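"""Independent reference implementations used only as test oracles.

Each oracle deliberately takes a different computational route from the
package code it checks (recurrence instead of log-gamma, grid search
instead of EM, explicit Newton iterations instead of IRLS, permutation
instead of asymptotics).
"""

from __future__ import annotations

import numpy as np


def hwe_recurrence_pvalues(n: int, n_a: int) -> dict:
    """Exact conditional HWE p for every heterozygote count attainable
    with n genotypes and n_a copies of the rarer allele, via the
    multiplicative recurrence on heterozygote probabilities."""
    if n_a == 0:
        return {0: 1.0}
    hets = list(range(n_a % 2, n_a + 1, 2))
    probs = np.empty(len(hets))
    probs[0] = 1.0
    for i in range(len(hets) - 1):
        h = hets[i]
        n_aa = (n_a - h) // 2
        n_bb = n - n_aa - h
        probs[i + 1] = probs[i] * 4.0 * n_aa * n_bb / ((h + 2) * (h + 1))
        # rescale to avoid overflow; normalization fixes the scale later
        if probs[i + 1] > 1e250:
            probs[: i + 2] /= 1e250
    probs /= probs.sum()
    out = {}
    for i, h in enumerate(hets):
        out[h] = float(min(1.0, probs[probs <= probs[i] * (1 + 1e-12)].sum()))
    return out


def newton_logistic(y, X, max_iter=100, tol=1e-12):
    """Plain Newton-Raphson logistic MLE; returns (beta, se)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        grad = X.T @ (y - mu)
        H = X.T @ (X * (mu * (1 - mu))[:, None])
        beta = beta + np.linalg.solve(H, grad)
        if np.abs(grad).max() < tol:
            break
    eta = X @ beta
    mu = 1 / (1 + np.exp(-eta))
    H = X.T @ (X * (mu * (1 - mu))[:, None])
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se


def dprime_grid_search(tab: np.ndarray, step: float = 1e-5) -> float:
    """D' from a profile-likelihood grid search over the cis-haplotype
    frequency, margins fixed at the sample allele frequencies."""
    n = tab.sum()
    pa = (tab.sum(axis=1) @ np.array([0, 1, 2])) / (2 * n)   # alt freq loc 1
    pb = (tab.sum(axis=0) @ np.array([0, 1, 2])) / (2 * n)
    qa, qb = 1 - pa, 1 - pb            # ref-allele freqs
    lo = max(0.0, qa + qb - 1.0)
    hi = min(qa, qb)
    grid = np.arange(lo, hi + step, step)
    best_ll, best = -np.inf, None
    for p_ab in grid:                   # freq of ref-ref haplotype
        h = np.array([p_ab, qa - p_ab, qb - p_ab, 1 - qa - qb + p_ab])
        if (h < -1e-12).any():
            continue
        h = np.clip(h, 1e-12, 1)
        # genotype probabilities under random haplotype pairing
        hm = h.reshape(2, 2)            # [ref1,alt1] x [ref2,alt2]
        gp = np.zeros((3, 3))
        for a1 in (0, 1):
            for b1 in (0, 1):
                for a2 in (0, 1):
                    for b2 in (0, 1):
                        gp[a1 + a2, b1 + b2] += hm[a1, b1] * hm[a2, b2]
        ll = np.sum(tab * np.log(np.clip(gp, 1e-300, 1)))
        if ll > best_ll:
            best_ll, best = ll, p_ab
    d = best - qa * qb
    if d >= 0:
        d_max = min(qa * (1 - qb), (1 - qa) * qb)
    else:
        d_max = min(qa * qb, (1 - qa) * (1 - qb))
    return float(min(1.0, abs(d) / d_max))


def dplus_brute_force(values, in_set) -> tuple[float, float]:
    """D+ and its supremum location by direct evaluation of both CDFs at
    every distinct pooled value."""
    values = np.asarray(values, float)
    in_set = np.asarray(in_set, bool)
    sv = values[in_set]
    bv = values[~in_set]
    best, best_x = -np.inf, None
    for x in np.unique(values):
        d = np.mean(sv <= x) - np.mean(bv <= x)
        if d > best + 1e-15:
            best, best_x = d, x
    return float(best), float(best_x)


def ks_label_permutation_p(values, in_set, n_perm, seed) -> float:
    """Label-permutation p-value for the observed D+."""
    rng = np.random.default_rng(seed)
    values = np.asarray(values, float)
    in_set = np.asarray(in_set, bool)
    m = in_set.sum()
    obs, _ = dplus_vectorized(values, in_set[None, :])
    order = np.argsort(values, kind="mergesort")
    count = 0
    chunk = 2000
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.zeros((b, values.size), dtype=bool)
        for i in range(b):
            perms[i, rng.choice(values.size, m, replace=False)] = True
        d, _ = dplus_vectorized(values, perms)
        count += int(np.sum(d >= obs[0] - 1e-12))
        done += b
    return (1 + count) / (n_perm + 1)


def dplus_vectorized(values, in_set_rows):
    """D+ for many label rows at once (shared sorted values)."""
    values = np.asarray(values, float)
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    last = np.r_[v[1:] != v[:-1], True]
    z = in_set_rows[:, order].astype(float)
    m = z.sum(axis=1, keepdims=True)
    n = z.shape[1] - m
    f_set = np.cumsum(z, axis=1) / m
    f_bg = np.cumsum(1 - z, axis=1) / n
    diff = (f_set - f_bg)[:, last]
    idx = np.argmax(diff, axis=1)
    vals = v[last]
    return diff[np.arange(diff.shape[0]), idx], vals[idx]
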