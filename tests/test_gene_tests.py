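import numpy as np
import pytest
from scipy import stats

from gardscan.annotate import GeneAssignment
from gardscan.gene_tests import (GeneBattery, GeneMarkerSet, burden_test,
                                 permutation_set_test, run_gene_battery,
                                 skat_test, skato_test, _skat_weights)
from gardscan.snp_assoc import NullLogistic, score_test_p


def _marker_set(rng, n=200, m=5, mafs=None, name="GENE"):
    if mafs is None:
        mafs = rng.uniform(0.05, 0.4, size=m)
    G = np.column_stack([
        ((rng.random(n) < f).astype(float) + (rng.random(n) < f).astype(float))
        for f in mafs])
    maf = np.minimum(G.mean(axis=0) / 2, 1 - G.mean(axis=0) / 2)
    return GeneMarkerSet(gene=name, variant_ids=[f"v{j}" for j in range(m)],
                         dosage=G, maf=maf)


def _null_y(rng, n=200):
    y = (rng.random(n) < 0.5).astype(float)
    while len(np.unique(y)) < 2:
        y = (rng.random(n) < 0.5).astype(float)
    return y


class TestBurden:
    def test_single_marker_equals_score_test(self, rng):
        gms = _marker_set(rng, m=1)
        y = _null_y(rng)
        res = burden_test(gms, y, None, "add")
        assert res.p == pytest.approx(
            score_test_p(y, gms.dosage[:, 0]), abs=1e-12)

    def test_perfect_ld_equals_double_weight(self, rng):
        """Two identical markers give the same burden p as one marker at
        double weight (score linearity)."""
        g = ((rng.random(300) < 0.3).astype(float)
             + (rng.random(300) < 0.3).astype(float))
        y = _null_y(rng, 300)
        two = GeneMarkerSet("A", ["v1", "v2"], np.column_stack([g, g]),
                            np.array([0.3, 0.3]))
        res2 = burden_test(two, y, None, "add")
        p_double = score_test_p(y, 2 * g)
        assert res2.p == pytest.approx(p_double, abs=1e-12)

    @pytest.mark.parametrize("scheme", ["add", "zeggini", "fp"])
    def test_null_rejection_rate_in_band(self, scheme):
        """Type-I error at 0.05 within the 99% binomial band over 1,000
        independent null genes."""
        r = np.random.default_rng(555)
        n = 1000
        y = _null_y(r, n)
        null = NullLogistic(y, None)
        rej = 0
        n_genes = 1000
        for _ in range(n_genes):
            gms = _marker_set(r, n=n, m=5)
            res = burden_test(gms, y, None, scheme, null=null)
            if np.isfinite(res.p) and res.p < 0.05:
                rej += 1
        lo, hi = stats.binom.ppf([0.005, 0.995], n_genes, 0.05)
        assert lo <= rej <= hi

    def test_zero_burden_flagged(self, rng):
        y = _null_y(rng, 50)
        gms = GeneMarkerSet("Z", ["v"], np.zeros((50, 1)), np.array([0.0]))
        res = burden_test(gms, y, None, "add")
        assert res.flag == "constant_burden" and np.isnan(res.p)


def _perm_oracle_quadratic(gms, y, n_perm=100_000, seed=0, rho=None,
                           weight_beta=(1.0, 25.0)):
    """Permutation p for SKAT (rho=0), burden (rho=1) or the min-p over a
    grid, with an intercept-only null (exact under exchangeability)."""
    rng = np.random.default_rng(seed)
    W = _skat_weights(gms.maf, weight_beta)
    A = gms.dosage * W[None, :]
    ybar = y.mean()
    r_obs = y - ybar
    S = A.T @ r_obs
    Yperm = rng.permuted(np.broadcast_to(y, (n_perm, y.size)).copy(), axis=1)
    Sp = (Yperm - ybar) @ A                      # n_perm x m
    if rho is None:
        return None
    q_obs = (1 - rho) * float(S @ S) + rho * float(S.sum() ** 2)
    q_perm = (1 - rho) * np.sum(Sp ** 2, axis=1) + rho * Sp.sum(axis=1) ** 2
    return (1 + np.sum(q_perm >= q_obs - 1e-12)) / (n_perm + 1)


class TestSkat:
    def test_single_marker_equals_score_test(self, rng):
        gms = _marker_set(rng, m=1)
        y = _null_y(rng)
        res = skat_test(gms, y, None)
        assert res.p == pytest.approx(
            score_test_p(y, gms.dosage[:, 0]), abs=1e-6)

    def test_against_permutation_oracle(self):
        """Asymptotic mixture-chi-square p agrees with a 100,000-draw
        phenotype permutation on a fixed n=200, 5-common-marker instance
        (flat weights, so the form is genuinely multivariate rather than
        dominated by one heavily up-weighted rare variant)."""
        r = np.random.default_rng(101)
        gms = _marker_set(r, n=200, m=5, mafs=r.uniform(0.15, 0.45, 5))
        y = _null_y(r, 200)
        res = skat_test(gms, y, None, weight_beta=(1.0, 1.0))
        p_perm = _perm_oracle_quadratic(gms, y, rho=0.0, seed=7,
                                        weight_beta=(1.0, 1.0))
        mc_sd = np.sqrt(max(p_perm * (1 - p_perm), 1e-9) / 100_000)
        assert abs(res.p - p_perm) <= max(3 * mc_sd, 0.005)

    def test_null_p_uniform(self):
        r = np.random.default_rng(808)
        n = 1000
        y = _null_y(r, n)
        null = NullLogistic(y, None)
        ps = []
        for _ in range(1000):
            gms = _marker_set(r, n=n, m=5)
            res = skat_test(gms, y, None, null=null)
            if np.isfinite(res.p):
                ps.append(res.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSkatO:
    def test_grid_of_one_collapses_to_burden(self, rng):
        gms = _marker_set(rng)
        y = _null_y(rng)
        res = skato_test(gms, y, None, rho_grid=[1.0])
        ref = burden_test(gms, y, None, "add")
        assert res.p == pytest.approx(ref.p, abs=1e-12)

    def test_grid_of_zero_collapses_to_skat(self, rng):
        gms = _marker_set(rng)
        y = _null_y(rng)
        res = skato_test(gms, y, None, rho_grid=[0.0])
        ref = skat_test(gms, y, None)
        assert res.p == pytest.approx(ref.p, abs=1e-12)

    def test_bounds_and_permutation_oracle(self):
        """SKAT-O p lies within its min-p safeguards and agrees with a
        100,000-permutation min-p oracle over the same rho grid."""
        r = np.random.default_rng(2024)
        gms = _marker_set(r, n=200, m=5, mafs=r.uniform(0.15, 0.45, 5))
        y = _null_y(r, 200)
        grid = (0.0, 0.25, 1.0)
        res = skato_test(gms, y, None, weight_beta=(1.0, 1.0),
                         rho_grid=grid)
        # the combined p is bounded by its own component p-values
        t_min = min(res.rho_pvalues)
        assert t_min - 1e-9 <= res.p <= min(1.0, len(grid) * t_min) + 1e-9
        # min-p permutation oracle: map each perm's Q_rho to its analytic
        # p via the observed mixture (fixed eigenvalues), take the min
        rng2 = np.random.default_rng(31)
        n_perm = 100_000
        from gardscan.gene_tests import _projected_Z
        from gardscan._quadform import mixture_chi2_sf
        null = NullLogistic(y, None)
        Z1, A = _projected_Z(gms, null, (1.0, 1.0))
        Sigma = Z1.T @ Z1
        m = gms.n_markers
        ybar = y.mean()
        Yperm = rng2.permuted(np.broadcast_to(y, (n_perm, y.size)).copy(),
                              axis=1)
        Sp = (Yperm - ybar) @ A
        S = A.T @ (y - ybar)
        minp_perm = np.full(n_perm, np.inf)
        minp_obs = np.inf
        for rho in grid:
            rr = min(rho, 1 - 1e-4)
            R = (1 - rr) * np.eye(m) + rr * np.ones((m, m))
            lam = np.real(np.linalg.eigvals(R @ Sigma))
            lam = lam[lam > 1e-10 * lam.max()]
            q_perm = ((1 - rr) * np.sum(Sp ** 2, axis=1)
                      + rr * Sp.sum(axis=1) ** 2)
            q_obs = (1 - rr) * float(S @ S) + rr * float(S.sum() ** 2)
            # interpolate the analytic tail on a grid (monotone in q)
            qs = np.linspace(0, max(q_perm.max(), q_obs) * 1.01, 400)
            sf = np.array([mixture_chi2_sf(q, lam) for q in qs])
            p_perm_rho = np.interp(q_perm, qs, sf)
            minp_perm = np.minimum(minp_perm, p_perm_rho)
            minp_obs = min(minp_obs, float(np.interp(q_obs, qs, sf)))
        p_oracle = (1 + np.sum(minp_perm <= minp_obs + 1e-12)) / (n_perm + 1)
        mc_sd = np.sqrt(max(p_oracle * (1 - p_oracle), 1e-9) / n_perm)
        assert abs(res.p - p_oracle) <= max(3 * mc_sd, 0.01)

class TestBurdenVsSkatPower:
    def test_power_ordering(self):
        """Same-signed common effects favour burden; mixed signs favour
        SKAT (directional check over 200 replicates)."""
        hits = {"same": {"burden": 0, "skat": 0},
                "mixed": {"burden": 0, "skat": 0}}
        for i in range(200):
            r = np.random.default_rng(40_000 + i)
            n, m = 400, 4
            gms = _marker_set(r, n=n, m=m, mafs=np.full(m, 0.25))
            for kind in ("same", "mixed"):
                b = np.full(m, 0.25)
                if kind == "mixed":
                    b[::2] *= -1
                eta = -0.1 + gms.dosage @ b
                y = (r.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
                if len(np.unique(y)) < 2:
                    continue
                pb = burden_test(gms, y, None, "add").p
                ps = skat_test(gms, y, None).p
                if np.isfinite(pb) and pb < 0.05:
                    hits[kind]["burden"] += 1
                if np.isfinite(ps) and ps < 0.05:
                    hits[kind]["skat"] += 1
        assert hits["same"]["burden"] >= hits["same"]["skat"]
        assert hits["mixed"]["skat"] >= hits["mixed"]["burden"]


class TestPermutationSetTest:
    def test_degenerate_statistic_p_one(self, rng):
        # no marker reaches the per-variant threshold: statistic 0
        n = 300
        y = _null_y(rng, n)
        g = np.zeros((n, 1))
        g[:3, 0] = 1.0              # nearly constant, chi2 tiny
        gms = GeneMarkerSet("D", ["v"], g, np.array([0.005]))
        res = permutation_set_test(gms, y, None, n_perm=200, seed=1)
        if res.statistic == 0.0:
            assert res.p == pytest.approx(1.0, abs=0.02)

    def test_seed_determinism(self, rng):
        gms = _marker_set(rng, n=200, m=3)
        y = _null_y(rng, 200)
        a = permutation_set_test(gms, y, None, n_perm=300, seed=9)
        b = permutation_set_test(gms, y, None, n_perm=300, seed=9)
        assert a.p == b.p and a.statistic == b.statistic

    def test_power_on_strong_marker(self):
        """A simulated OR=1.8 marker yields empirical p < 0.01 in nearly
        all of 100 seeded replicates."""
        hits = 0
        for i in range(100):
            r = np.random.default_rng(60_000 + i)
            n = 2000
            gms = _marker_set(r, n=n, m=3, mafs=np.array([0.3, 0.2, 0.25]))
            eta = -0.2 + np.log(1.8) * gms.dosage[:, 0]
            y = (r.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            res = permutation_set_test(gms, y, None, n_perm=499, seed=i)
            if res.p < 0.01:
                hits += 1
        assert hits >= 95

    def test_small_n_perm_rejected(self, rng):
        gms = _marker_set(rng, m=2)
        with pytest.raises(ValueError):
            permutation_set_test(gms, _null_y(rng), None, n_perm=50)


class TestBattery:
    def _assignment(self, panel):
        mapping = {}
        genes = [f"GENE{k}" for k in range(10)]
        ids = list(panel.variants["id"])
        for k, g in enumerate(genes):
            for vid in ids[3 * k: 3 * k + 3]:
                mapping.setdefault(vid, []).append((g, "body"))
        return GeneAssignment(mapping=mapping)

    def test_cardinality(self, small_cohort):
        panel = small_cohort[0]
        asn = self._assignment(panel)
        table = run_gene_battery(asn, panel, tests=("burden_add", "skat"),
                                 seed=3)
        assert len(table) == 10 * 2

    def test_order_invariance(self, small_cohort):
        panel = small_cohort[0]
        asn = self._assignment(panel)
        t1 = run_gene_battery(asn, panel,
                              tests=("burden_add", "skat", "skato"), seed=3)
        t2 = run_gene_battery(asn, panel,
                              tests=("skato", "burden_add", "skat"), seed=3)
        k1 = t1.set_index(["gene", "test"])["p"].sort_index()
        k2 = t2.set_index(["gene", "test"])["p"].sort_index()
        assert np.allclose(k1.to_numpy(), k2.to_numpy(), equal_nan=True)

    def test_monomorphic_gene_flagged_everywhere(self, small_cohort):
        panel = small_cohort[0]
        import pandas as pd
        from gardscan.panel import CohortPanel
        v = panel.variants.iloc[:2].copy()
        mono = CohortPanel(v, panel.samples,
                           np.zeros((panel.n_samples, 2)))
        mono.variants["maf"] = 0.0
        asn = GeneAssignment(mapping={v["id"].iloc[0]: [("GMONO", "body")],
                                      v["id"].iloc[1]: [("GMONO", "body")]})
        table = run_gene_battery(asn, mono, tests=("burden_add", "skat",
                                                   "skato"), seed=1)
        assert (table["flag"] == "all_monomorphic").all()
        assert table["p"].isna().all()

    def test_empty_assignment_fatal(self, small_cohort):
        with pytest.raises(ValueError):
            run_gene_battery(GeneAssignment(mapping={}), small_cohort[0])

    def test_model_results_wrapper(self, small_cohort):
        panel = small_cohort[0]
        res = GeneBattery(panel, self._assignment(panel),
                          tests=("burden_fp",)).fit()
        assert "Gene-level" in res.summary()
        assert set(res.pvalues("burden_fp")) <= set(
            res.table["gene"])
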