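"""Heritabilities, genetic correlations, reliabilities and site correlations.

Narrow-sense heritability is ``h2 = sigma_A^2 / (sigma_A^2 + sigma_NA^2 +
sigma_e^2)`` and broad-sense ``H2`` replaces the numerator by the total
genetic variance; the non-additive part is the family variance in seedling
models and family plus clone variance in clonal models.  The denominator is
the phenotypic variance in this narrow sense -- design variances (replicate,
block, plot) are excluded.  Standard errors use the delta method on the
REML sampling covariance of the variance components.

Correlations: genetic and phenotypic correlations come from bivariate fits;
type-B genetic correlations treat one trait at two sites as two genetically
correlated traits with no residual covariance; between-site agreement of
breeding values is summarised by Pearson correlations over shared parents or
clones, with a nonparametric bootstrap over family/clone units for survival
proportions.  Breeding-value reliability is ``R_i = 1 - PEV_i / sigma_A^2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mixed_model import BivariateFit, MixedModelFit, VarianceComponents, bivariate_fit
from .pedigree import Pedigree, CloneMap


class CovarianceError(ValueError):
    """The supplied sampling covariance matrix is not positive semi-definite."""


@dataclass
class HeritabilityEstimate:
    kind: str              # "narrow" | "broad"
    value: float
    se: Optional[float]
    components: Dict[str, float]

    def __repr__(self):  # compact report form
        se = "no SE" if self.se is None else f"SE {self.se:.3f}"
        return f"<{self.kind}-sense heritability {self.value:.3f} ({se})>"


@dataclass
class CorrelationEstimate:
    kind: str              # "genetic" | "phenotypic" | "type_b" | "bv_pearson" | "survival_bootstrap"
    value: Optional[float]
    se: Optional[float] = None
    ci: Optional[Tuple[float, float]] = None
    n: Optional[int] = None

    @property
    def no_estimate(self) -> bool:
        return self.value is None


def delta_method_se(gradient: np.ndarray, cov: np.ndarray) -> float:
    """SE of a scalar function of estimated parameters: sqrt(g' C g).

    ``cov`` must be symmetric positive semi-definite (small negative
    eigenvalues from numerical inversion are tolerated up to a relative
    tolerance).
    """
    cov = np.asarray(cov, dtype=float)
    g = np.asarray(gradient, dtype=float)
    ev = np.linalg.eigvalsh((cov + cov.T) / 2)
    if ev.min() < -1e-8 * max(ev.max(), 1e-300):
        raise CovarianceError("sampling covariance is not PSD")
    var = float(g @ cov @ g)
    return float(np.sqrt(max(var, 0.0)))


def _nonadditive_names(vc: VarianceComponents) -> Sequence[str]:
    return [n for n in ("family", "clone") if n in vc.variances]


def _h2_from_vc(vc: VarianceComponents, broad: bool) -> HeritabilityEstimate:
    if "additive" not in vc.variances:
        raise ValueError("fit has no additive component")
    a = vc.variances["additive"]
    na_names = _nonadditive_names(vc)
    na = sum(vc.variances[n] for n in na_names)
    e = vc.residual
    P = a + na + e
    if P <= 0:
        raise ZeroDivisionError("phenotypic variance is zero; heritability undefined")
    num = a + na if broad else a
    value = num / P
    # delta-method gradient wrt (additive, non-additive..., residual)
    order = ["sigma2_additive"] + [f"sigma2_{n}" for n in na_names] + ["sigma2_e"]
    present = [n for n in order if n in vc.cov.index]
    grad = []
    for name in present:
        in_num = (name != "sigma2_e") if broad else (name == "sigma2_additive")
        grad.append((1.0 - value) / P if in_num else -value / P)
    se = None
    if present:
        C = vc.cov.loc[present, present].to_numpy()
        se = delta_method_se(np.array(grad), C)
    comps = {"additive": a, "non_additive": na, "residual": e, "phenotypic": P}
    return HeritabilityEstimate("broad" if broad else "narrow", float(value), se, comps)


def narrow_h2(vc: VarianceComponents) -> HeritabilityEstimate:
    """Narrow-sense heritability ``sigma_A^2 / (sigma_A^2+sigma_NA^2+sigma_e^2)``."""
    return _h2_from_vc(vc, broad=False)


def broad_H2(vc: VarianceComponents) -> HeritabilityEstimate:
    """Broad-sense heritability with total genetic variance in the numerator."""
    return _h2_from_vc(vc, broad=True)


def _corr_se(cov: pd.DataFrame, names: Tuple[str, str, str],
             v1: float, v12: float, v2: float, r: float) -> Optional[float]:
    """Delta-method SE of a correlation v12 / sqrt(v1 v2)."""
    if not all(n in cov.index for n in names):
        return None
    grad = np.array([-r / (2 * v1), 1.0 / np.sqrt(v1 * v2), -r / (2 * v2)])
    C = cov.loc[list(names), list(names)].to_numpy()
    return delta_method_se(grad, C)


def genetic_phenotypic_correlations(
    fit: BivariateFit,
) -> Tuple[CorrelationEstimate, CorrelationEstimate]:
    """Genetic and phenotypic correlations from a bivariate fit.

    ``r_G = sigma_G12 / (sigma_G1 sigma_G2)``; the phenotypic covariance is
    the sum of genetic and residual (co)variances, excluding the
    trait-specific replicate variances.  Returns ``(r_G, r_P)``; a genetic
    variance at the zero boundary yields a no-estimate genetic correlation,
    mirroring blank cells in reported tables.
    """
    G, R = fit.genetic_cov, fit.residual_cov
    if fit.boundary or G[0, 0] <= 0 or G[1, 1] <= 0:
        rg = CorrelationEstimate("genetic", None, n=fit.n_obs)
    else:
        r = float(G[0, 1] / np.sqrt(G[0, 0] * G[1, 1]))
        se = _corr_se(fit.cov_params, ("genetic_11", "genetic_12", "genetic_22"),
                      G[0, 0], G[0, 1], G[1, 1], r)
        rg = CorrelationEstimate("genetic", r, se, n=fit.n_obs)
    P = G + R
    rp_val = float(P[0, 1] / np.sqrt(P[0, 0] * P[1, 1]))
    # delta over the six (co)variances feeding P
    names = ["genetic_11", "genetic_12", "genetic_22", "resid_11", "resid_12", "resid_22"]
    se_p = None
    if all(n in fit.cov_params.index for n in names):
        dP = [-rp_val / (2 * P[0, 0]), 1.0 / np.sqrt(P[0, 0] * P[1, 1]), -rp_val / (2 * P[1, 1])]
        grad = np.array(dP + dP)
        C = fit.cov_params.loc[names, names].to_numpy()
        se_p = delta_method_se(grad, C)
    rp = CorrelationEstimate("phenotypic", rp_val, se_p, n=fit.n_obs)
    return rg, rp


def reliability(
    fit: MixedModelFit,
    ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Breeding-value reliability ``R_i = 1 - PEV_i / sigma_A^2`` per genotype.

    PEVs are the diagonal of the inverse mixed-model-equation coefficient
    matrix on the additive block; values are clipped to [0, 1].  Restrict to
    ``ids`` (e.g. the parents) if given.
    """
    sa2 = fit.vc.variances.get("additive", 0.0)
    if sa2 <= 0:
        raise ZeroDivisionError("additive variance is zero; reliability undefined")
    bv = fit.blups["additive"]
    pev = fit.pev["additive"]
    if ids is not None:
        bv, pev = bv.loc[list(ids)], pev.loc[list(ids)]
    rel = (1.0 - pev / sa2).clip(0.0, 1.0)
    return pd.DataFrame({"bv": bv, "pev": pev, "reliability": rel})


def type_b_correlation(
    trait: str,
    data_a: pd.DataFrame,
    data_b: pd.DataFrame,
    pedigree: Pedigree,
    clone_maps: Tuple[Optional[CloneMap], Optional[CloneMap]] = (None, None),
    columns: Optional[Mapping[str, str]] = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> Tuple[CorrelationEstimate, BivariateFit]:
    """Type-B genetic correlation of one trait between two sites.

    The trait at each site is treated as a distinct trait; the additive
    effects of the two site-traits carry an unstructured 2x2 covariance over
    the joint pedigree, and the residual covariance is zero because no tree
    grows at both sites.  ``r_GB`` near 1 indicates weak genotype-by-
    environment interaction.
    """
    cols = {"tree": "tree", "rep": "rep"}
    cols.update(columns or {})

    def site_frame(df, cm, site):
        trees = df[cols["tree"]].astype(str).to_numpy()
        geno = (np.array([cm.genotype_of(t) for t in trees]) if cm is not None
                else (df["genotype"].astype(str).to_numpy() if "genotype" in df.columns else trees))
        return pd.DataFrame({
            "tree": trees, "genotype": geno,
            "rep": site + ":" + df[cols["rep"]].astype(str).to_numpy(),
            f"{trait}_A": df[trait].to_numpy() if site == "A" else np.nan,
            f"{trait}_B": df[trait].to_numpy() if site == "B" else np.nan,
        })

    stacked = pd.concat(
        [site_frame(data_a, clone_maps[0], "A"), site_frame(data_b, clone_maps[1], "B")],
        ignore_index=True)
    fit = bivariate_fit((f"{trait}_A", f"{trait}_B"), stacked, pedigree=pedigree,
                        genetic_kind="additive", residual_cov=False,
                        tol=tol, max_iter=max_iter)
    G = fit.genetic_cov
    if fit.boundary or G[0, 0] <= 0 or G[1, 1] <= 0:
        return CorrelationEstimate("type_b", None, n=fit.n_obs), fit
    r = float(G[0, 1] / np.sqrt(G[0, 0] * G[1, 1]))
    se = _corr_se(fit.cov_params, ("genetic_11", "genetic_12", "genetic_22"),
                  G[0, 0], G[0, 1], G[1, 1], r)
    return CorrelationEstimate("type_b", r, se, n=fit.n_obs), fit


def bv_site_correlation(
    bv_a: pd.Series,
    bv_b: pd.Series,
    bootstrap: int = 0,
    seed: int = 20200303,
) -> CorrelationEstimate:
    """Pearson correlation of breeding/genetic values over shared IDs.

    With ``bootstrap > 0`` the shared units (families or clones, as indexed)
    are resampled with replacement to give a bootstrap SE and percentile 95%
    CI -- the procedure used for survival proportions, where the values are
    family- or clone-mean survival rates.
    """
    shared = bv_a.index.intersection(bv_b.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared IDs; need at least 3")
    x = bv_a.loc[shared].to_numpy(dtype=float)
    y = bv_b.loc[shared].to_numpy(dtype=float)
    r = float(np.corrcoef(x, y)[0, 1])
    if bootstrap <= 0:
        return CorrelationEstimate("bv_pearson", r, n=len(shared))
    rng = np.random.default_rng(seed)
    reps = np.empty(bootstrap)
    k = len(shared)
    for b in range(bootstrap):
        idx = rng.integers(0, k, size=k)
        xb, yb = x[idx], y[idx]
        if np.std(xb) == 0 or np.std(yb) == 0:
            reps[b] = np.nan
            continue
        reps[b] = np.corrcoef(xb, yb)[0, 1]
    reps = reps[~np.isnan(reps)]
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return CorrelationEstimate("survival_bootstrap", r, float(np.std(reps, ddof=1)),
                               ci=(float(lo), float(hi)), n=len(shared))


def parametric_bootstrap_h2(
    spec,
    data: pd.DataFrame,
    pedigree: Pedigree,
    clone_map: Optional[CloneMap] = None,
    n_boot: int = 500,
    seed: int = 0,
    tol: float = 1e-6,
) -> Tuple[float, np.ndarray]:
    """Parametric-bootstrap SE of narrow-sense heritability.

    Fits the model, then repeatedly simulates new responses from the fitted
    generative model (additive effects drawn with covariance ``A sigma_A^2``
    via a Cholesky factor, other terms i.i.d.), refits, and returns the
    standard deviation of the bootstrap h2 draws together with the draws.
    An independent check on the delta-method SE.
    """
    from scipy.linalg import cholesky as _chol

    from .mixed_model import _Engine, build_design
    from .pedigree import additive_relationship

    designs = build_design(spec, data, pedigree, clone_map)
    eng = _Engine(designs.y, designs.X, designs.terms)
    base = eng.fit(tol=tol)
    theta = base["theta"]
    names = base["names"]
    sig = dict(zip(names, theta))
    mu = float(base["state"]["sol"][0])
    La = _chol(additive_relationship(pedigree), lower=True)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        y = np.full(eng.n, mu)
        for t in designs.terms:
            s2 = sig[f"sigma2_{t.name}"]
            if t.name == "additive":
                u = np.sqrt(s2) * (La @ rng.standard_normal(t.q))
            else:
                u = np.sqrt(s2) * rng.standard_normal(t.q)
            y = y + t.Z @ u
        y = y + np.sqrt(sig["sigma2_e"]) * rng.standard_normal(eng.n)
        eb = _Engine(y, designs.X, designs.terms)
        try:
            rb = eb.fit(start=theta, tol=max(tol, 1e-6))
        except Exception:
            draws[b] = np.nan
            continue
        tb = dict(zip(names, rb["theta"]))
        a = tb["sigma2_additive"]
        na = sum(tb.get(f"sigma2_{n}", 0.0) for n in ("family", "clone"))
        draws[b] = a / (a + na + tb["sigma2_e"])
    draws = draws[~np.isnan(draws)]
    return float(np.std(draws, ddof=1)), draws


def heritability_report(
    vc: VarianceComponents, trial: str, trait: str
) -> pd.DataFrame:
    """One-row-per-parameter CSV-ready report with boundary flags."""
    rows = []
    try:
        h2 = narrow_h2(vc)
        rows.append({"trial": trial, "trait": trait, "parameter": "h2",
                     "estimate": h2.value, "se": h2.se, "no_estimate": False})
    except (ValueError, ZeroDivisionError):
        rows.append({"trial": trial, "trait": trait, "parameter": "h2",
                     "estimate": np.nan, "se": np.nan, "no_estimate": True})
    try:
        H2 = broad_H2(vc)
        rows.append({"trial": trial, "trait": trait, "parameter": "H2",
                     "estimate": H2.value, "se": H2.se, "no_estimate": False})
    except (ValueError, ZeroDivisionError):
        rows.append({"trial": trial, "trait": trait, "parameter": "H2",
                     "estimate": np.nan, "se": np.nan, "no_estimate": True})
    for name, v in list(vc.variances.items()) + [("residual", vc.residual)]:
        boundary = name in vc.boundary
        se = None
        try:
            se = vc.se(name) if not boundary else None
        except KeyError:
            se = None
        rows.append({"trial": trial, "trait": trait, "parameter": f"sigma2_{name}",
                     "estimate": v, "se": se, "no_estimate": boundary})
    return pd.DataFrame(rows)
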