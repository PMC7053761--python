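"""Design assembly, MME solutions and REML estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from aspenqg.mixed_model import (
    AliasingError,
    ModelSpec,
    RandomTerm,
    _Engine,
    assemble_mme,
    build_design,
    reml_fit,
    solve_mme,
)
from aspenqg.pedigree import CloneMap, additive_relationship, build_pedigree
from conftest import balanced_oneway, random_pedigree
from oracles import (
    anova_halfsib_sigma_a,
    dense_reml_loglik,
    gls_solution,
    simulate_halfsib,
)


def _clonal_frame(rng, n_clones=15, n_ramets=4, n_parents=6):
    """Clones from several crosses so additive and clone variances are
    jointly identifiable through the family relatedness in A."""
    recs = [(f"P{k}", None, None) for k in range(n_parents)]
    fam_of = {}
    for i in range(n_clones):
        s, d = (2 * i) % n_parents, (2 * i + 1) % n_parents
        recs.append((f"C{i}", f"P{s}", f"P{d}"))
        fam_of[f"C{i}"] = f"fam{s}_{d}"
    ped = build_pedigree(recs)
    rows = []
    for i in range(n_clones):
        for j in range(n_ramets):
            rows.append({"tree": f"t{i}_{j}", "family": fam_of[f"C{i}"],
                         "rep": j + 1, "block": 1 + (i % 3), "plot": i,
                         "y": float(rng.standard_normal())})
    cm = CloneMap({f"t{i}_{j}": f"C{i}" for i in range(n_clones) for j in range(n_ramets)})
    return pd.DataFrame(rows), ped, cm


class TestBuildDesign:
    def test_distinct_genotypes_Z1_permutation(self):
        ped = build_pedigree([(f"G{i}", None, None) for i in range(4)])
        df = pd.DataFrame({"tree": [f"G{i}" for i in (2, 0, 3, 1)],
                           "family": "f", "rep": 1, "block": 1, "plot": [1, 2, 3, 4],
                           "y": [1.0, 2.0, 3.0, 4.0]})
        d = build_design(ModelSpec("y", "seedling", include={"family": False}), df, ped)
        Z1 = next(t for t in d.terms if t.name == "additive").Z.toarray()
        assert (Z1.sum(axis=0) <= 1).all() and (Z1.sum(axis=1) == 1).all()

    def test_ramets_share_Z1_column(self):
        rng = np.random.default_rng(0)
        df, ped, cm = _clonal_frame(rng)
        d = build_design(ModelSpec("y", "clonal"), df, ped, cm)
        Z1 = next(t for t in d.terms if t.name == "additive").Z
        r0 = Z1[df.index[df.tree == "t0_0"][0]].toarray()
        r1 = Z1[df.index[df.tree == "t0_1"][0]].toarray()
        assert np.array_equal(r0, r1)

    def test_column_counts_match_levels(self):
        rng = np.random.default_rng(1)
        df, ped, cm = _clonal_frame(rng)
        d = build_design(ModelSpec("y", "clonal", include={"family": False}), df, ped, cm)
        by = {t.name: t for t in d.terms}
        assert by["clone"].ncol == df.tree.str.split("_").str[0].nunique()
        assert by["rep"].ncol == df.rep.nunique()
        assert by["additive"].ncol == len(ped)

    def test_clone_all_singletons_aliased_with_residual(self):
        ped = build_pedigree([(f"G{i}", None, None) for i in range(6)])
        df = pd.DataFrame({"tree": [f"G{i}" for i in range(6)], "family": "f",
                           "rep": [1, 1, 1, 2, 2, 2], "block": 1, "plot": range(6),
                           "y": np.arange(6.0)})
        with pytest.raises(AliasingError):
            build_design(ModelSpec("y", "clonal", include={"family": False}), df, ped)

    def test_identical_incidence_terms_aliased(self):
        rng = np.random.default_rng(2)
        df, ped, cm = _clonal_frame(rng, n_clones=6, n_ramets=3)
        df["block"] = df["rep"]  # block grouping identical to rep
        with pytest.raises(AliasingError):
            build_design(ModelSpec("y", "clonal", include={"family": False}), df, ped, cm)


class TestMMESolutions:
    def test_balanced_oneway_shrinkage_formula(self):
        rng = np.random.default_rng(5)
        df, _ = balanced_oneway(rng, n_groups=10, n_per=6)
        codes, levels = pd.factorize(df.group)
        n = len(df)
        Z = sparse.csr_matrix((np.ones(n), (np.arange(n), codes)))
        term = RandomTerm("group", Z, tuple(levels))
        from aspenqg.mixed_model import DesignMatrices
        d = DesignMatrices(y=df.y.to_numpy(), X=sparse.csr_matrix(np.ones((n, 1))),
                           terms=[term], data_index=df.index.to_numpy())
        s_u, s_e = 0.8, 1.3
        beta, blups = solve_mme(d, {"group": s_u}, s_e)
        lam = 6 * s_u / (6 * s_u + s_e)
        gm = df.y.mean()
        expected = lam * (df.groupby("group", sort=False).y.mean().loc[list(levels)] - gm)
        assert beta[0] == pytest.approx(gm, abs=1e-10)
        assert np.allclose(blups["group"], expected.to_numpy(), atol=1e-10)

    def test_vanishing_variance_shrinks_blups_to_zero(self):
        rng = np.random.default_rng(6)
        df, ped, cm = _clonal_frame(rng)
        d = build_design(ModelSpec("y", "clonal", include={"family": False}), df, ped, cm)
        _, blups = solve_mme(d, {t.name: (1e-10 if t.name == "additive" else 0.5)
                                 for t in d.terms}, 1.0)
        assert np.abs(blups["additive"]).max() < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_mme_equals_dense_gls(self, seed):
        """MME solution matches the dense GLS oracle on random instances."""
        rng = np.random.default_rng(seed)
        recs = random_pedigree(rng, n_founders=10, n_gen1=10, n_gen2=8)
        ped = build_pedigree(recs)
        genos = [r[0] for r in recs]
        n = 120
        pick = rng.choice(genos, size=n)
        df = pd.DataFrame({
            "tree": [f"t{i}" for i in range(n)], "genotype": pick,
            "family": rng.choice(["f1", "f2", "f3", "f4"], n),
            "rep": rng.integers(1, 4, n), "block": rng.integers(1, 3, n),
            "plot": rng.integers(1, 3, n), "y": rng.standard_normal(n) * 2 + 7,
        })
        d = build_design(ModelSpec("y", "clonal"), df, ped)
        variances = {t.name: float(v) for t, v in
                     zip(d.terms, rng.uniform(0.2, 1.5, len(d.terms)))}
        se2 = 0.9
        beta, blups = solve_mme(d, variances, se2)
        A = additive_relationship(ped)
        beta_o, blups_o = gls_solution(d.y, d.X, d.terms, variances, se2, A_dense=A)
        assert np.abs(beta - beta_o).max() < 1e-6
        for t in d.terms:
            assert np.abs(blups[t.name] - blups_o[t.name]).max() < 1e-6, t.name

    def test_zero_residual_rejected(self):
        rng = np.random.default_rng(8)
        df, ped, cm = _clonal_frame(rng)
        d = build_design(ModelSpec("y", "clonal", include={"family": False}), df, ped, cm)
        with pytest.raises(ValueError):
            assemble_mme(d, {t.name: 1.0 for t in d.terms}, 0.0)


class TestEngine:
    def test_loglik_matches_dense_oracle(self):
        rng = np.random.default_rng(9)
        df, ped, cm = _clonal_frame(rng, n_clones=12, n_ramets=3)
        d = build_design(ModelSpec("y", "clonal", include={"family": False}), df, ped, cm)
        eng = _Engine(d.y, d.X, d.terms)
        theta = np.array([0.4, 0.3, 0.2, 0.25, 0.8])  # additive, clone, rep, block, resid
        assert len(theta) == len(d.terms) + 1
        st = eng._state(theta)
        variances = {t.name: v for t, v in zip(d.terms, theta[:-1])}
        oracle = dense_reml_loglik(d.y, d.X, d.terms, variances, theta[-1],
                                   A_dense=additive_relationship(ped))
        assert st["logl"] == pytest.approx(oracle, abs=1e-8)

    def test_em_steps_monotone_loglik(self):
        rng = np.random.default_rng(10)
        df, ped, cm = _clonal_frame(rng, n_clones=20, n_ramets=3)
        d = build_design(ModelSpec("y", "clonal", include={"family": False}), df, ped, cm)
        eng = _Engine(d.y, d.X, d.terms)
        st = eng._state(eng.start_values())
        last = st["logl"]
        for _ in range(25):
            st = eng._state(eng._clamp(eng._em_step(st)))
            assert st["logl"] >= last - 1e-9
            last = st["logl"]

    def test_ai_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(12)
        df, ped, cm = _clonal_frame(rng, n_clones=10, n_ramets=3)
        d = build_design(ModelSpec("y", "clonal", include={"family": False}), df, ped, cm)
        eng = _Engine(d.y, d.X, d.terms)
        theta = np.array([0.5, 0.4, 0.2, 0.3, 0.9])
        st = eng._state(theta)
        g, _ = eng._grad_and_workvecs(st)
        eps = 1e-6
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (eng._state(tp)["logl"] - eng._state(tm)["logl"]) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestREMLFit:
    def test_balanced_halfsib_equals_anova(self):
        """Animal-model REML equals the dam-variance ANOVA estimator
        (sigma_A^2 = 4 sigma_dam^2) under balance when interior."""
        rng = np.random.default_rng(21)
        df, ped = simulate_halfsib(rng, n_dams=40, n_per=12)
        spec = ModelSpec("y", "seedling",
                         include={"family": False, "rep": False, "block": False, "plot": False})
        fit = reml_fit(spec, df, ped, tol=1e-12)
        sa_anova, _ = anova_halfsib_sigma_a(df.y.to_numpy(), df.family.to_numpy())
        assert sa_anova > 0
        assert fit.vc.variances["additive"] == pytest.approx(sa_anova, rel=1e-4)

    def test_zero_additive_pinned_at_boundary(self):
        rng = np.random.default_rng(22)
        df, ped = simulate_halfsib(rng, n_dams=25, n_per=8, sigma_a=0.0, sigma_e=1.0)
        spec = ModelSpec("y", "seedling",
                         include={"family": False, "rep": False, "block": False, "plot": False})
        fit = reml_fit(spec, df, ped)
        assert fit.vc.variances["additive"] == 0.0
        assert "additive" in fit.vc.boundary

    def test_row_order_and_relabel_invariance(self):
        rng = np.random.default_rng(23)
        df, ped, cm = _clonal_frame(rng, n_clones=18, n_ramets=4)
        spec = ModelSpec("y", "clonal", include={"family": False})
        fit1 = reml_fit(spec, df, ped, cm, tol=1e-10)
        df2 = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        df2["rep"] = df2["rep"].map(lambda r: f"R-{r}")  # relabelled levels
        fit2 = reml_fit(spec, df2, ped, cm, tol=1e-10)
        s1, s2 = fit1.vc.as_series(), fit2.vc.as_series()
        assert np.allclose(s1.sort_index(), s2.sort_index(), rtol=1e-6)

    def test_clonal_without_clone_term_reduces_to_seedling(self):
        """All-distinct genotypes: the clonal model minus clone/plot terms is
        the seedling model minus plot, so the fits coincide."""
        rng = np.random.default_rng(24)
        recs = [("S", None, None), ("D", None, None)]
        recs += [(f"G{i}", "S", "D") for i in range(60)]
        ped = build_pedigree(recs)
        df = pd.DataFrame({
            "tree": [f"G{i}" for i in range(60)],
            "family": "f1", "rep": np.repeat([1, 2, 3], 20),
            "block": np.tile([1, 2], 30), "plot": range(60),
            "y": rng.standard_normal(60) + 4,
        })
        inc = {"family": False, "plot": False}
        f_clonal = reml_fit(ModelSpec("y", "clonal", include=dict(inc, clone=False)),
                            df, ped, tol=1e-10)
        f_seed = reml_fit(ModelSpec("y", "seedling", include=inc), df, ped, tol=1e-10)
        assert np.allclose(f_clonal.vc.as_series().sort_index(),
                           f_seed.vc.as_series().sort_index(), rtol=1e-8)
        assert f_clonal.vc.loglik == pytest.approx(f_seed.vc.loglik, abs=1e-6)

    def test_pev_bounded_by_additive_variance(self):
        rng = np.random.default_rng(25)
        df, ped = simulate_halfsib(rng, n_dams=20, n_per=10)
        spec = ModelSpec("y", "seedling",
                         include={"family": False, "rep": False, "block": False, "plot": False})
        fit = reml_fit(spec, df, ped)
        sa2 = fit.vc.variances["additive"]
        diagA = np.diag(additive_relationship(ped))
        pev = fit.pev["additive"].to_numpy()
        assert (pev >= -1e-8).all()
        assert (pev <= sa2 * diagA + 1e-6).all()
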