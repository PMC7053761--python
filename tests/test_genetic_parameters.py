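"""Heritabilities, correlations, reliabilities and their standard errors."""

import numpy as np
import pandas as pd
import pytest

from aspenqg.genetic_parameters import (
    CovarianceError,
    broad_H2,
    bv_site_correlation,
    delta_method_se,
    genetic_phenotypic_correlations,
    narrow_h2,
    reliability,
    type_b_correlation,
)
from aspenqg.mixed_model import BivariateFit, ModelSpec, VarianceComponents, bivariate_fit, reml_fit
from aspenqg.pedigree import build_pedigree
from oracles import simulate_halfsib


def _vc(additive, family=None, clone=None, residual=1.0, cov=None):
    variances = {"additive": additive}
    names = ["sigma2_additive"]
    if family is not None:
        variances["family"] = family
        names.append("sigma2_family")
    if clone is not None:
        variances["clone"] = clone
        names.append("sigma2_clone")
    names.append("sigma2_e")
    C = pd.DataFrame(np.zeros((len(names), len(names))) if cov is None else cov,
                     index=names, columns=names)
    return VarianceComponents(variances=variances, residual=residual, loglik=0.0, cov=C)


class TestHeritability:
    def test_narrow_arithmetic(self):
        h2 = narrow_h2(_vc(0.2, family=0.1, residual=0.7))
        assert h2.value == pytest.approx(0.20)

    def test_broad_arithmetic(self):
        H2 = broad_H2(_vc(0.2, family=0.1, residual=0.7))
        assert H2.value == pytest.approx(0.30)

    def test_perfect_heritability_zero_se(self):
        h2 = narrow_h2(_vc(1.0, family=0.0, residual=0.0))
        assert h2.value == pytest.approx(1.0)
        assert h2.se == pytest.approx(0.0)

    def test_no_nonadditive_broad_equals_narrow(self):
        vc = _vc(0.4, residual=0.6)
        assert broad_H2(vc).value == pytest.approx(narrow_h2(vc).value)

    def test_design_variances_excluded_from_denominator(self):
        vc = _vc(0.3, family=0.1, residual=0.6)
        vc.variances["rep"] = 5.0  # must not enter sigma_P^2
        assert narrow_h2(vc).value == pytest.approx(0.3)

    def test_zero_phenotypic_variance(self):
        with pytest.raises(ZeroDivisionError):
            narrow_h2(_vc(0.0, family=0.0, residual=0.0))

    def test_ordering_invariant(self):
        """0 <= h2 <= H2 <= 1 for random non-negative component sets."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, f, c, e = rng.uniform(0, 2, 4)
            vc = _vc(a, family=f, clone=c, residual=e + 1e-6)
            h2, H2 = narrow_h2(vc).value, broad_H2(vc).value
            assert 0 <= h2 <= H2 <= 1


class TestDeltaMethod:
    def test_zero_covariance_zero_se(self):
        assert delta_method_se(np.array([1.0, 2.0]), np.zeros((2, 2))) == 0.0

    def test_non_psd_rejected(self):
        with pytest.raises(CovarianceError):
            delta_method_se(np.ones(2), np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_h2_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(1)
        M = rng.standard_normal((4, 4))
        cov = M @ M.T / 10
        a, f, c, e = 0.3, 0.05, 0.1, 0.55

        def h2(p):
            return p[0] / (p[0] + p[1] + p[2] + p[3])

        p0 = np.array([a, f, c, e])
        eps = 1e-7
        grad_fd = np.array([
            (h2(p0 + eps * np.eye(4)[i]) - h2(p0 - eps * np.eye(4)[i])) / (2 * eps)
            for i in range(4)])
        se_fd = delta_method_se(grad_fd, cov)
        vc = _vc(a, family=f, clone=c, residual=e, cov=cov)
        assert narrow_h2(vc).se == pytest.approx(se_fd, rel=1e-6)

    def test_se_agrees_with_reml_fit_quadratic_form(self):
        rng = np.random.default_rng(5)
        df, ped = simulate_halfsib(rng, n_dams=30, n_per=10)
        spec = ModelSpec("y", "seedling",
                         include={"family": False, "rep": False, "block": False, "plot": False})
        fit = reml_fit(spec, df, ped)
        h2 = narrow_h2(fit.vc)
        assert h2.se is not None and 0 < h2.se < 1


def _clonal_bivariate_data(rng, rho, q=100, m=4, v1=1.0, v2=2.0):
    g = rng.standard_normal((q, 2)) @ np.linalg.cholesky(
        np.array([[v1, rho * np.sqrt(v1 * v2)], [rho * np.sqrt(v1 * v2), v2]])).T
    rows = []
    for i in range(q):
        for j in range(m):
            rows.append({"tree": f"t{i}_{j}", "genotype": f"c{i}", "rep": j + 1,
                         "y1": 10 + g[i, 0] + rng.standard_normal(),
                         "y2": 20 + g[i, 1] + 1.2 * rng.standard_normal()})
    return pd.DataFrame(rows)


class TestCorrelations:
    def test_duplicated_trait_correlation_one(self):
        """A trait paired with a re-measurement of itself (tiny measurement
        jitter keeps the likelihood bounded) has genetic correlation 1."""
        rng = np.random.default_rng(2)
        df = _clonal_bivariate_data(rng, 0.5)
        df["y2"] = df["y1"] + 0.3 * rng.standard_normal(len(df))
        bf = bivariate_fit(("y1", "y2"), df, genetic_kind="genotypic")
        rg, rp = genetic_phenotypic_correlations(bf)
        assert rg.value == pytest.approx(1.0, abs=0.01)
        # the phenotypic correlation is diluted by the measurement jitter
        assert rp.value > 0.95

    def test_zero_genetic_covariance_gives_zero_rg(self):
        G = np.array([[0.5, 0.0], [0.0, 0.8]])
        R = np.array([[1.0, 0.3], [0.3, 1.2]])
        bf = BivariateFit(("a", "b"), G, R, (0.1, 0.1), 0.0,
                          pd.DataFrame(), "genotypic", 100)
        rg, rp = genetic_phenotypic_correlations(bf)
        assert rg.value == pytest.approx(0.0)
        assert -1 <= rp.value <= 1

    def test_boundary_genetic_variance_no_estimate(self):
        G = np.array([[0.0, 0.0], [0.0, 0.8]])
        bf = BivariateFit(("a", "b"), G, np.eye(2), (0.1, 0.1), 0.0,
                          pd.DataFrame(), "genotypic", 100, boundary=True)
        rg, _ = genetic_phenotypic_correlations(bf)
        assert rg.no_estimate

    def test_independent_traits_rg_near_zero(self):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(6):
            df = _clonal_bivariate_data(rng, 0.0, q=150, m=4)
            bf = bivariate_fit(("y1", "y2"), df, genetic_kind="genotypic")
            rg, _ = genetic_phenotypic_correlations(bf)
            vals.append(rg.value)
        # per-replicate sampling sd is ~0.1 at this size
        assert abs(np.mean(vals)) < 0.12

    def test_rg_recovery_at_0p7(self):
        rng = np.random.default_rng(4)
        vals = []
        for _ in range(6):
            df = _clonal_bivariate_data(rng, 0.7, q=150, m=3)
            bf = bivariate_fit(("y1", "y2"), df, genetic_kind="genotypic")
            rg, _ = genetic_phenotypic_correlations(bf)
            vals.append(rg.value)
        mc_se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.7) < 2 * mc_se + 0.02


class TestReliability:
    def _fit(self, rng, n_dams=25, spread=True):
        df, ped = simulate_halfsib(rng, n_dams=n_dams, n_per=10)
        if spread:
            # unbalance family sizes: families keep 2..10 offspring
            keep = []
            for f, sub in df.groupby("family", sort=False):
                k = int(rng.integers(2, 11))
                keep += list(sub.index[:k])
            df = df.loc[keep]
        spec = ModelSpec("y", "seedling",
                         include={"family": False, "rep": False, "block": False, "plot": False})
        return reml_fit(spec, df, ped), ped, df

    def test_limits(self):
        rng = np.random.default_rng(6)
        fit, ped, df = self._fit(rng, spread=False)
        rel = reliability(fit)
        assert ((rel.reliability >= 0) & (rel.reliability <= 1)).all()
        # parents with no own record and many offspring have 0 < R < 1
        dams = rel.loc[[i for i in rel.index if i.startswith("D")]]
        assert (dams.reliability > 0).all()

    def test_more_offspring_more_reliable(self):
        """Across random unbalanced designs, parent reliability increases
        with offspring count."""
        rng = np.random.default_rng(7)
        agree = 0
        for _ in range(5):
            fit, ped, df = self._fit(rng)
            counts = df.family.value_counts()
            rel = reliability(fit, ids=list(counts.index))
            r = np.corrcoef(counts.to_numpy(),
                            rel.loc[counts.index, "reliability"].to_numpy())[0, 1]
            agree += r > 0
        assert agree >= 4

    def test_zero_additive_variance_undefined(self):
        vcf = _vc(0.0, residual=1.0)
        from aspenqg.mixed_model import MixedModelFit
        fit = MixedModelFit(ModelSpec("y"), vcf, np.zeros(1),
                            {"additive": pd.Series(dtype=float)},
                            {"additive": pd.Series(dtype=float)}, 0)
        with pytest.raises(ZeroDivisionError):
            reliability(fit)


class TestTypeB:
    def _two_site_frames(self, rng, rho, n_fam=30, n_per=6):
        """Full-sib families split across two sites; each genotype carries a
        site-A/site-B additive value pair with correlation rho, gene-dropped
        (mid-parent plus half-variance Mendelian deviation)."""
        L = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]) + 1e-9 * np.eye(2))
        recs = [(f"P{i}", None, None) for i in range(2 * n_fam)]
        bv = {r[0]: L @ rng.standard_normal(2) for r in recs}
        frames = {"A": [], "B": []}
        for f in range(n_fam):
            s, d = f"P{2*f}", f"P{2*f+1}"
            for site in ("A", "B"):
                for j in range(n_per):
                    g = f"{site}G{f}_{j}"
                    recs.append((g, s, d))
                    bv[g] = 0.5 * (bv[s] + bv[d]) + np.sqrt(0.5) * (L @ rng.standard_normal(2))
                    val = bv[g][0 if site == "A" else 1]
                    frames[site].append({
                        "tree": g, "genotype": g, "rep": 1 + j % 2,
                        "y": 5 + val + rng.standard_normal() * 0.8})
        ped = build_pedigree(recs)
        return pd.DataFrame(frames["A"]), pd.DataFrame(frames["B"]), ped

    def test_identical_phenotypes_cloned_to_pseudo_sites(self):
        """Clonal phenotypes duplicated as a second pseudo-site give
        r_GB = 1 up to the correlation clamp (within-clone replication keeps
        the residual variance positive)."""
        rng = np.random.default_rng(8)
        n_par, n_clone, m = 10, 40, 3
        recs = [(f"P{i}", None, None) for i in range(n_par)]
        g_eff = {}
        for c in range(n_clone):
            s, d = c % n_par, (c + 1) % n_par
            recs.append((f"C{c}", f"P{s}", f"P{d}"))
            g_eff[f"C{c}"] = rng.standard_normal()
        ped = build_pedigree(recs)
        rows = [{"tree": f"t{c}_{j}", "genotype": f"C{c}", "rep": j + 1,
                 "y": 3 + g_eff[f"C{c}"] + 0.8 * rng.standard_normal()}
                for c in range(n_clone) for j in range(m)]
        da = pd.DataFrame(rows)
        db = da.copy()
        db["tree"] = "copy_" + db["tree"]  # same genotypes, same values
        est, fit = type_b_correlation("y", da, db, ped)
        assert est.value == pytest.approx(1.0, abs=0.01)

    def test_independent_sites_near_zero(self):
        rng = np.random.default_rng(9)
        vals = []
        for _ in range(4):
            da, db, ped = self._two_site_frames(rng, 0.0)
            est, _ = type_b_correlation("y", da, db, ped)
            if est.value is not None:
                vals.append(est.value)
        assert abs(np.mean(vals)) < 0.25

    def test_recovery_0p7(self):
        rng = np.random.default_rng(10)
        vals = []
        for _ in range(5):
            da, db, ped = self._two_site_frames(rng, 0.7, n_fam=40)
            est, _ = type_b_correlation("y", da, db, ped)
            vals.append(est.value)
        mc_se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.7) < 2 * mc_se + 0.05


class TestBVSiteCorrelation:
    def test_identical_is_one(self):
        bv = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        est = bv_site_correlation(bv, bv)
        assert est.value == pytest.approx(1.0)

    def test_insufficient_overlap(self):
        a = pd.Series([1.0, 2.0], index=["x", "y"])
        with pytest.raises(ValueError):
            bv_site_correlation(a, a)

    def test_independent_within_bootstrap_ci(self):
        rng = np.random.default_rng(11)
        idx = [f"f{i}" for i in range(40)]
        a = pd.Series(rng.standard_normal(40), index=idx)
        b = pd.Series(rng.standard_normal(40), index=idx)
        est = bv_site_correlation(a, b, bootstrap=400, seed=1)
        lo, hi = est.ci
        assert lo < 0 < hi or abs(est.value) < 0.35

    def test_correlated_survival_means_recovered(self):
        """Family-mean survival vs senescence BV correlation ~0.65 falls in
        its own bootstrap CI."""
        rng = np.random.default_rng(12)
        n = 60
        z = rng.standard_normal((n, 2)) @ np.linalg.cholesky(
            np.array([[1.0, 0.65], [0.65, 1.0]])).T
        idx = [f"f{i}" for i in range(n)]
        a = pd.Series(z[:, 0], index=idx)
        b = pd.Series(z[:, 1], index=idx)
        est = bv_site_correlation(a, b, bootstrap=500, seed=2)
        assert est.ci[0] <= 0.65 <= est.ci[1] or abs(est.value - 0.65) < 0.15
        assert est.se is not None and est.se > 0
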