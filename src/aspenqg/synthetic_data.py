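"""Synthetic progeny-trial data with the structure the estimators assume.

The generator emulates an aspen breeding program: ~122 parents crossed in a
partial factorial (each parent in one or two full-sib families) with
polymix-pollinated dams giving half-sib families; offspring planted either
as seedlings or as clonally replicated rootlings in alpha-lattice trials
(R complete blocks x B alpha blocks x T treatments x P trees per row plot,
fillers occupying surplus cells).  Phenotypes follow the generative form of
the analysis model: additive breeding values gene-dropped through the
pedigree (founder draws plus Mendelian-sampling deviations, exact for any
pedigree and independent of the tabular A construction they are used to
test), family effects (a quarter of dominance), clone effects (epistasis
plus three quarters of dominance), replicate/block/plot effects and
residual.  Multi-trait genetic effects share a configurable genetic
correlation matrix; phenology traits additionally get ordinal score
trajectories on the trial's real assessment calendar, and survival is
Bernoulli with a logistic link on genetic values.

Trial presets (02, 03, 08) use the published design geometries, trait means
and variance-component levels as their default study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pedigree import CloneMap, Pedigree, additive_relationship, build_pedigree
from .phenology import CRITICAL_SCORES, SCORE_RANGES


class DesignError(ValueError):
    """The requested mating or field design is infeasible."""


# ---------------------------------------------------------------------------
# mating design
# ---------------------------------------------------------------------------

@dataclass
class MatingDesign:
    """Partial-factorial mating design of one breeding region."""

    dams: List[str]
    sires: List[str]
    crosses: List[Tuple[str, str, str]]      # (family_id, sire, dam)
    polymix_dams: List[Tuple[str, str]]      # (family_id, dam)

    @property
    def families(self) -> pd.DataFrame:
        rows = [{"family": f, "type": "FS", "sire": s, "dam": d}
                for f, s, d in self.crosses]
        rows += [{"family": f, "type": "HS", "sire": None, "dam": d}
                 for f, d in self.polymix_dams]
        return pd.DataFrame(rows)

    def founder_records(self) -> List[Tuple[str, None, None]]:
        return [(p, None, None) for p in self.dams + self.sires]


def simulate_mating(
    n_dams: int = 61,
    n_sires: int = 61,
    n_full_sib: int = 100,
    n_half_sib: int = 60,
    max_crosses_per_parent: int = 2,
    seed: int = 0,
    prefix: str = "",
) -> MatingDesign:
    """Partial-factorial cross list plus polymix (half-sib) dam list.

    Each dam and sire appears in at most ``max_crosses_per_parent`` full-sib
    families; the first ``n_half_sib`` dams are additionally polymix
    pollinated.  Deterministic given the seed.
    """
    if n_dams < 2 or n_sires < 2:
        raise DesignError("need at least two parents per sex")
    if n_full_sib > max_crosses_per_parent * min(n_dams, n_sires):
        raise DesignError(
            f"{n_full_sib} crosses infeasible with {n_dams} dams / {n_sires} sires "
            f"at <= {max_crosses_per_parent} crosses per parent")
    if n_half_sib > n_dams:
        raise DesignError("more polymix families than dams")
    rng = np.random.default_rng(seed)
    dams = [f"{prefix}D{i + 1:03d}" for i in range(n_dams)]
    sires = [f"{prefix}S{i + 1:03d}" for i in range(n_sires)]
    dperm = list(rng.permutation(dams))
    sperm = list(rng.permutation(sires))
    crosses = []
    for k in range(n_full_sib):
        dam = dperm[k % n_dams]
        sire = sperm[(k + k // n_dams) % n_sires]
        crosses.append((f"{prefix}F{k + 1:03d}", sire, dam))
    poly = [(f"{prefix}H{i + 1:03d}", d) for i, d in enumerate(dperm[:n_half_sib])]
    return MatingDesign(dams=dams, sires=sires, crosses=crosses, polymix_dams=poly)


# ---------------------------------------------------------------------------
# field layout
# ---------------------------------------------------------------------------

def simulate_layout(
    n_reps: int,
    n_blocks: int,
    n_treat_per_block: int,
    n_trees_per_plot: int,
    treatments: Sequence[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Randomized alpha-lattice layout ``R x B x T x P``.

    Treatments (families or clones) are randomly allocated to the B x T
    cells of every replicate; surplus cells are filled with additional
    replications of randomly chosen treatments and flagged as fillers.
    Returns one row per tree position: ``tree, rep, block, plot, treatment,
    filler``.
    """
    cells = n_blocks * n_treat_per_block
    k = len(treatments)
    if k > cells:
        raise DesignError(f"{k} treatments exceed {cells} cells per replicate")
    rng = np.random.default_rng(seed)
    rows = []
    tree_no = 0
    treatments = list(treatments)
    for r in range(1, n_reps + 1):
        alloc = list(rng.permutation(treatments))
        filler = [False] * k
        extra = cells - k
        if extra:
            alloc += list(rng.choice(treatments, size=extra, replace=True))
            filler += [True] * extra
        order = rng.permutation(cells)
        alloc = [alloc[i] for i in order]
        filler = [filler[i] for i in order]
        for cell in range(cells):
            b = cell // n_treat_per_block + 1
            for p in range(n_trees_per_plot):
                tree_no += 1
                rows.append({
                    "tree": f"T{tree_no:06d}", "rep": r, "block": b,
                    "plot": cell + 1, "treatment": alloc[cell],
                    "filler": filler[cell],
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TraitConfig:
    """Generative variance components (absolute units) for one trait."""

    name: str
    mean: float
    additive: float
    family: float = 0.0
    clone: float = 0.0
    rep: float = 0.0
    block: float = 0.0
    plot: float = 0.0
    residual: float = 1.0

    @property
    def phenotypic(self) -> float:
        """Phenotypic variance in the heritability sense (design terms excluded)."""
        return self.additive + self.family + self.clone + self.residual

    @property
    def h2(self) -> float:
        return self.additive / self.phenotypic

    @property
    def H2(self) -> float:
        return (self.additive + self.family + self.clone) / self.phenotypic


@dataclass
class TrialConfig:
    """One trial: design geometry, family/clone structure, trait conditions."""

    trial: str
    kind: str                       # "seedling" | "clonal"
    n_reps: int
    n_blocks: int
    n_treat_per_block: int
    n_trees_per_plot: int
    n_half_sib: int
    n_full_sib: int
    n_clones: Optional[int]
    traits: Dict[str, TraitConfig]
    genetic_corr: Optional[np.ndarray] = None        # over list(traits)
    residual_corr: Optional[np.ndarray] = None
    assessment_doys: Dict[str, List[int]] = field(default_factory=dict)
    score_rates: Dict[str, float] = field(default_factory=dict)
    survival_base: float = 0.7
    survival_slopes: Dict[str, float] = field(default_factory=dict)


def _corr(mat: Sequence[Sequence[float]]) -> np.ndarray:
    m = np.asarray(mat, dtype=float)
    ev = np.linalg.eigvalsh(m)
    if ev.min() < -1e-10:
        raise ValueError("correlation matrix is not PSD")
    return m


def residual_corr_from_phenotypic(
    traits: Sequence[TraitConfig],
    genetic_corr: np.ndarray,
    phenotypic_corr: np.ndarray,
) -> np.ndarray:
    """Residual correlation matrix that realises target phenotypic correlations.

    Given the genetic correlation shared by all genetic strata and target
    phenotypic correlations, solves ``cov_P = cov_G + cov_E`` pairwise;
    infeasible entries are clipped to +-0.95.
    """
    k = len(traits)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            gi = traits[i].additive + traits[i].family + traits[i].clone
            gj = traits[j].additive + traits[j].family + traits[j].clone
            cov_g = genetic_corr[i, j] * np.sqrt(gi * gj)
            cov_p = phenotypic_corr[i, j] * np.sqrt(traits[i].phenotypic * traits[j].phenotypic)
            r_e = (cov_p - cov_g) / np.sqrt(traits[i].residual * traits[j].residual)
            out[i, j] = out[j, i] = float(np.clip(r_e, -0.95, 0.95))
    return out


def _preset(trial: str) -> TrialConfig:
    bud_P, sen_P = 2.8 ** 2, 7.0 ** 2
    if trial == "02":
        # seedling trial, 6x10x9x3 = 1,620 trees
        traits = {
            "height": TraitConfig("height", 3.27, additive=0.08 * 0.64, family=0.02 * 0.64,
                                  rep=0.03, block=0.03, plot=0.03, residual=0.90 * 0.64),
            "budbreak": TraitConfig("budbreak", 128.0, additive=0.46 * bud_P, family=0.03 * bud_P,
                                    rep=0.04 * bud_P, block=0.04 * bud_P, plot=0.04 * bud_P,
                                    residual=0.51 * bud_P),
            "senescence": TraitConfig("senescence", 267.0, additive=0.33 * sen_P, family=0.02 * sen_P,
                                      rep=0.04 * sen_P, block=0.04 * sen_P, plot=0.04 * sen_P,
                                      residual=0.65 * sen_P),
        }
        g = _corr([[1.0, -0.30, 0.83], [-0.30, 1.0, -0.08], [0.83, -0.08, 1.0]])
        p = _corr([[1.0, -0.23, 0.57], [-0.23, 1.0, -0.05], [0.57, -0.05, 1.0]])
        cfg = TrialConfig(
            trial="02", kind="seedling", n_reps=6, n_blocks=10,
            n_treat_per_block=9, n_trees_per_plot=3,
            n_half_sib=33, n_full_sib=50, n_clones=None, traits=traits,
            genetic_corr=g,
            assessment_doys={"budbreak": [102, 110, 112, 114, 116, 121, 123, 129, 131, 133, 135, 137, 139],
                             "senescence": [244, 250, 264, 272, 278, 293]},
            survival_base=0.69,
        )
    elif trial == "03":
        # clonal trial, 9x24x24x1 = 5,184 trees, 560 clones
        traits = {
            "height": TraitConfig("height", 1.36, additive=0.20 * 0.1225, family=0.025 * 0.1225,
                                  clone=0.075 * 0.1225, rep=0.006, block=0.006,
                                  residual=0.70 * 0.1225),
            "budbreak": TraitConfig("budbreak", 135.0, additive=0.37 * bud_P, family=0.03 * bud_P,
                                    clone=0.06 * bud_P, rep=0.04 * bud_P, block=0.04 * bud_P,
                                    residual=0.54 * bud_P),
            "senescence": TraitConfig("senescence", 268.0, additive=0.42 * sen_P, family=0.02 * sen_P,
                                      clone=0.02 * sen_P, rep=0.04 * sen_P, block=0.04 * sen_P,
                                      residual=0.54 * sen_P),
        }
        g = _corr([[1.0, -0.19, 0.58], [-0.19, 1.0, 0.15], [0.58, 0.15, 1.0]])
        p = _corr([[1.0, -0.25, 0.37], [-0.25, 1.0, 0.00], [0.37, 0.00, 1.0]])
        cfg = TrialConfig(
            trial="03", kind="clonal", n_reps=9, n_blocks=24,
            n_treat_per_block=24, n_trees_per_plot=1,
            n_half_sib=37, n_full_sib=83, n_clones=560, traits=traits,
            genetic_corr=g,
            assessment_doys={"budbreak": [108, 111, 115, 117, 122, 130, 132, 134, 136, 138, 140],
                             "senescence": [244, 249, 266, 273, 279, 294]},
            survival_base=0.70,
        )
    elif trial == "08":
        # small clonal trial, 9x8x6x1 = 432 trees, 47 clones
        traits = {
            "height": TraitConfig("height", 0.70, additive=0.01 * 0.09, clone=0.02 * 0.09,
                                  rep=0.005, block=0.005, residual=0.97 * 0.09),
            "budbreak": TraitConfig("budbreak", 135.0, additive=0.36 * bud_P,
                                    rep=0.04 * bud_P, block=0.04 * bud_P,
                                    residual=0.64 * bud_P),
            "senescence": TraitConfig("senescence", 273.0, additive=0.0, clone=0.05 * sen_P,
                                      rep=0.04 * sen_P, block=0.04 * sen_P,
                                      residual=0.95 * sen_P),
        }
        g = _corr([[1.0, -0.2, 0.3], [-0.2, 1.0, -0.1], [0.3, -0.1, 1.0]])
        p = _corr([[1.0, -0.42, 0.28], [-0.42, 1.0, -0.20], [0.28, -0.20, 1.0]])
        cfg = TrialConfig(
            trial="08", kind="clonal", n_reps=9, n_blocks=8,
            n_treat_per_block=6, n_trees_per_plot=1,
            n_half_sib=2, n_full_sib=28, n_clones=47, traits=traits,
            genetic_corr=g,
            assessment_doys={"budbreak": [101, 108, 113, 116, 123, 129, 130, 133, 135, 137, 139, 141],
                             "senescence": [243, 250, 264, 272, 293]},
            survival_base=0.71,
        )
    else:
        raise KeyError(f"no preset for trial {trial!r}")
    cfg.residual_corr = residual_corr_from_phenotypic(
        [cfg.traits[t] for t in cfg.traits], cfg.genetic_corr, p)
    # budbreak develops ~0.7 stages/day, senescence ~0.25: the exact-score
    # window (one stage / rate) then stays within one assessment interval
    cfg.score_rates = {"budbreak": 0.7, "senescence": 0.25}
    cfg.survival_slopes = {"senescence": 0.5, "budbreak": -0.15, "height": 0.4}
    return cfg


def implied_total_genetic_corr(cfg: TrialConfig, trait_a: str, trait_b: str) -> float:
    """Total-genetic correlation implied by a per-stratum correlation.

    The additive, family and clone strata each carry the configured
    correlation; mixing strata with different variance proportions shrinks
    the correlation of the summed genetic values (Cauchy-Schwarz), so the
    realised clone-level correlation is ``r * sum_s sqrt(v_as v_bs) /
    sqrt(G_a G_b)``.
    """
    names = list(cfg.traits)
    i, j = names.index(trait_a), names.index(trait_b)
    r = float(cfg.genetic_corr[i, j])
    ta, tb = cfg.traits[trait_a], cfg.traits[trait_b]
    num = sum(np.sqrt(getattr(ta, s) * getattr(tb, s))
              for s in ("additive", "family", "clone"))
    ga = ta.additive + ta.family + ta.clone
    gb = tb.additive + tb.family + tb.clone
    return r * num / np.sqrt(ga * gb)


def recovery_config(r_g: float = 0.6, h2: float = 0.2, H2: float = 0.3) -> TrialConfig:
    """Two-trait clonal config with exactly known total-genetic correlation.

    Height and leaf-senescence DoY are given the same additive:family:clone
    proportions, so the total-genetic correlation between the traits equals
    the per-stratum correlation ``r_g`` exactly (with unequal proportions it
    would be shrunk toward zero by the geometric-mean mixing of strata).
    Geometry and trait scales follow the large clonal trial preset.
    """
    base = _preset("03")
    fa, fc = (H2 - h2) * 0.25, (H2 - h2) * 0.75
    def tc(name, mean, P):
        return TraitConfig(name, mean, additive=h2 * P, family=fa * P, clone=fc * P,
                           rep=0.04 * P, block=0.04 * P, residual=(1 - H2) * P)
    traits = {"height": tc("height", 1.36, 0.1225),
              "senescence": tc("senescence", 268.0, 49.0)}
    g = _corr([[1.0, r_g], [r_g, 1.0]])
    return TrialConfig(
        trial="03R", kind="clonal", n_reps=base.n_reps, n_blocks=base.n_blocks,
        n_treat_per_block=base.n_treat_per_block, n_trees_per_plot=1,
        n_half_sib=base.n_half_sib, n_full_sib=base.n_full_sib,
        n_clones=base.n_clones, traits=traits, genetic_corr=g,
        residual_corr=np.eye(2), survival_base=0.7,
    )


TRIAL_PRESETS: Dict[str, TrialConfig] = {}


def trial_preset(trial: str) -> TrialConfig:
    return _preset(trial)


for _t in ("02", "03", "08"):
    TRIAL_PRESETS[_t] = _preset(_t)


# ---------------------------------------------------------------------------
# phenotype simulation
# ---------------------------------------------------------------------------

def _chol_corr(corr: Optional[np.ndarray], k: int) -> np.ndarray:
    if corr is None:
        return np.eye(k)
    return np.linalg.cholesky(corr + 1e-12 * np.eye(k))


def gene_drop(
    pedigree: Pedigree,
    sd_per_trait: np.ndarray,
    genetic_corr: Optional[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Breeding values (n_individuals x n_traits) by gene dropping.

    Founders draw from ``N(0, S C S)`` (S the diagonal of per-trait additive
    SDs, C the genetic correlation); non-founders are the mid-parent value
    plus a Mendelian-sampling deviation with variance scale
    ``1 - (a_ss + a_dd)/4`` (unknown parents contribute zero), reproducing
    ``Var(bv) = A sigma_A^2`` exactly.
    """
    k = len(sd_per_trait)
    L = np.diag(sd_per_trait) @ _chol_corr(genetic_corr, k)
    n = len(pedigree)
    diagA = np.diag(additive_relationship(pedigree))
    bv = np.zeros((n, k))
    z = rng.standard_normal((n, k))
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        mid = np.zeros(k)
        scale = diagA[i]
        for p in (s, d):
            if p >= 0:
                mid += 0.5 * bv[p]
                scale -= 0.25 * diagA[p]
        bv[i] = mid + np.sqrt(scale) * (z[i] @ L.T)
    return bv


def simulate_phenotypes(
    pedigree: Pedigree,
    clone_map: CloneMap,
    layout: pd.DataFrame,
    traits: Sequence[TraitConfig],
    genetic_corr: Optional[np.ndarray] = None,
    residual_corr: Optional[np.ndarray] = None,
    family_of_genotype: Optional[Mapping[str, str]] = None,
    seed: int = 0,
) -> Tuple[pd.DataFrame, Dict[str, np.ndarray]]:
    """Simulate trait values for every tree of a layout.

    ``layout`` must carry a ``genotype`` column (clonal: the treatment;
    seedling: one genotype per tree).  Ramets of a clone share all genetic
    effects.  Returns the phenotype table (one row per tree, one column per
    trait) and a truth dict with the per-genotype breeding values, total
    genetic values and the per-trait configs.
    """
    k = len(traits)
    rng = np.random.default_rng(seed)
    sd_a = np.array([np.sqrt(t.additive) for t in traits])
    bv = gene_drop(pedigree, sd_a, genetic_corr, rng)

    Lc = _chol_corr(genetic_corr, k)
    genos = layout["genotype"].astype(str).to_numpy()
    geno_pos = pedigree.subset_positions(genos)

    fam_of = family_of_genotype or {}
    fams = np.array([fam_of.get(g, f"fam_of_{g}") for g in genos])
    fam_levels, fam_codes = np.unique(fams, return_inverse=True)
    sd_f = np.array([np.sqrt(t.family) for t in traits])
    fam_eff = (rng.standard_normal((len(fam_levels), k)) @ Lc.T) * sd_f

    uniq_g, g_codes = np.unique(genos, return_inverse=True)
    sd_c = np.array([np.sqrt(t.clone) for t in traits])
    clone_eff = (rng.standard_normal((len(uniq_g), k)) @ Lc.T) * sd_c

    n = len(layout)
    Le = _chol_corr(residual_corr, k)
    sd_e = np.array([np.sqrt(t.residual) for t in traits])
    resid = (rng.standard_normal((n, k)) @ Le.T) * sd_e

    def design_effect(keys, sd):
        # deviation coding: design effects are deviations around the trial
        # mean, so the drawn effects are centred within the trial
        lv, codes = np.unique(keys, return_inverse=True)
        eff = rng.standard_normal(len(lv)) * sd
        eff -= eff.mean()
        return eff[codes]

    values = np.zeros((n, k))
    rep_k = layout["rep"].to_numpy()
    blk_k = np.char.add(np.char.add(rep_k.astype(str), "/"), layout["block"].astype(str).to_numpy())
    plot_k = np.char.add(np.char.add(blk_k, "/"), layout["plot"].astype(str).to_numpy())
    for j, t in enumerate(traits):
        v = (t.mean + bv[geno_pos, j] + fam_eff[fam_codes, j] + clone_eff[g_codes, j]
             + resid[:, j])
        if t.rep > 0:
            v = v + design_effect(rep_k, np.sqrt(t.rep))
        if t.block > 0:
            v = v + design_effect(blk_k, np.sqrt(t.block))
        if t.plot > 0:
            v = v + design_effect(plot_k, np.sqrt(t.plot))
        values[:, j] = v

    out = layout.copy()
    for j, t in enumerate(traits):
        out[t.name] = values[:, j]
    total = bv[pedigree.subset_positions(uniq_g)] + clone_eff
    fam_of_uniq = np.array([fam_of.get(g, f"fam_of_{g}") for g in uniq_g])
    fmap = {f: i for i, f in enumerate(fam_levels)}
    total = total + fam_eff[[fmap[f] for f in fam_of_uniq]]
    truth = {
        "bv": pd.DataFrame(bv, index=list(pedigree.ids),
                           columns=[t.name for t in traits]),
        "total_genetic": pd.DataFrame(total, index=list(uniq_g),
                                      columns=[t.name for t in traits]),
        "traits": {t.name: t for t in traits},
    }
    return out, truth


def expected_measured_doy(
    latent_mean: float,
    latent_sd: float,
    assessment_doys: Sequence[int],
    trait: str,
    rate: float,
    n_grid: int = 1201,
) -> float:
    """Expected DoY measurement for a normal latent-event distribution.

    Integrates the published first-record/interpolation rule applied to the
    generator's score trajectories over ``N(latent_mean, latent_sd^2)``,
    conditioning on the event being observable within the assessment window.
    Used to place the latent mean so that the *measured* trial mean matches
    a target: ordinal scoring on a coarse calendar shifts and truncates the
    measured distribution slightly, and this quadrature quantifies it.
    """
    from .phenology import score_table_to_doy

    grid = np.linspace(latent_mean - 5 * latent_sd, latent_mean + 5 * latent_sd, n_grid)
    scores, _ = simulate_phenology_scores(
        pd.Series(grid), assessment_doys, trait, rate=rate)
    est = score_table_to_doy(scores, trait).to_numpy()
    w = np.exp(-0.5 * ((grid - latent_mean) / latent_sd) ** 2)
    ok = ~np.isnan(est)
    return float(np.sum(w[ok] * est[ok]) / np.sum(w[ok]))


def calibrated_latent_mean(
    target_mean: float,
    latent_sd: float,
    assessment_doys: Sequence[int],
    trait: str,
    rate: float,
    n_iter: int = 3,
) -> float:
    """Latent mean whose expected measured trial mean equals ``target_mean``."""
    mu = float(target_mean)
    for _ in range(n_iter):
        mu -= expected_measured_doy(mu, latent_sd, assessment_doys, trait, rate) - target_mean
    return mu


def simulate_phenology_scores(
    latent_doy: pd.Series,
    assessment_doys: Sequence[int],
    trait: str,
    rate: float = 0.5,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Ordinal score trajectories crossing the critical score at the latent DoY.

    The continuous development of a tree is ``critical + rate * (d - D)``
    stages; the recorded score is the nearest stage on the trait's scale.
    Returns a wide table (one ``d<DoY>`` column per assessment) plus a
    boolean truncation flag for trees whose latent DoY falls outside the
    assessment window (their event cannot be recovered).
    """
    lo, hi = SCORE_RANGES[trait]
    critical = CRITICAL_SCORES[trait]
    doys = np.asarray(sorted(assessment_doys))
    D = latent_doy.to_numpy(dtype=float)
    cont = critical + rate * (doys[None, :] - D[:, None])
    scores = np.clip(np.rint(cont), lo, hi).astype(int)
    out = pd.DataFrame(scores, index=latent_doy.index,
                       columns=[f"d{d}" for d in doys])
    truncated = pd.Series((D < doys[0]) | (D > doys[-1]),
                          index=latent_doy.index, name="truncated")
    return out, truncated


def simulate_survival(
    genetic_values: pd.DataFrame,
    base_probability: float,
    slopes: Mapping[str, float],
    tree_genotypes: Sequence[str],
    seed: int = 0,
) -> np.ndarray:
    """Bernoulli survival per tree with a logistic link on genetic values.

    ``slopes`` are per unit genetic SD of each named trait; positive slope on
    senescence DoY means late-senescing genotypes survive better.
    """
    if not (0 < base_probability <= 1):
        raise ValueError("base survival probability must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if base_probability == 1.0:
        return np.ones(len(tree_genotypes), dtype=int)
    eta = np.full(len(tree_genotypes), np.log(base_probability / (1 - base_probability)))
    for tr, slope in slopes.items():
        if tr not in genetic_values.columns or slope == 0:
            continue
        g = genetic_values[tr]
        sd = g.std() if g.std() > 0 else 1.0
        z = (g / sd).reindex(tree_genotypes).to_numpy()
        eta = eta + slope * np.nan_to_num(z)
    p = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(len(p)) < p).astype(int)


# ---------------------------------------------------------------------------
# whole-trial orchestration
# ---------------------------------------------------------------------------

@dataclass
class TrialDataset:
    """A simulated trial: pedigree, layout, phenotypes, scores and the truth."""

    trial: str
    config: TrialConfig
    pedigree: Pedigree
    pedigree_records: List[Tuple[str, Optional[str], Optional[str]]]
    clone_map: CloneMap
    phenotypes: pd.DataFrame
    scores: pd.DataFrame          # long: tree x trait rows, wide date columns
    truth: Dict[str, object]


def simulate_trial(
    config_or_trial,
    seed: int = 0,
    mating: Optional[MatingDesign] = None,
) -> TrialDataset:
    """Generate one complete trial dataset from a preset code or config.

    Deterministic given the seed: the mating design, family subsets, clone
    assignment, layout randomisation and all effect draws derive from one
    seed sequence.
    """
    cfg = trial_preset(config_or_trial) if isinstance(config_or_trial, str) else config_or_trial
    rng = np.random.default_rng(seed)
    if mating is None:
        mating = simulate_mating(seed=int(rng.integers(2 ** 31)))
    fams = mating.families
    fs = fams[fams.type == "FS"]
    hs = fams[fams.type == "HS"]
    if cfg.n_full_sib > len(fs) or cfg.n_half_sib > len(hs):
        raise DesignError("trial requests more families than the mating design provides")
    fs_pick = fs.iloc[np.sort(rng.choice(len(fs), cfg.n_full_sib, replace=False))]
    hs_pick = hs.iloc[np.sort(rng.choice(len(hs), cfg.n_half_sib, replace=False))]
    fam_tab = pd.concat([fs_pick, hs_pick], ignore_index=True)

    records: List[Tuple[str, Optional[str], Optional[str]]] = list(mating.founder_records())
    fam_of_geno: Dict[str, str] = {}

    if cfg.kind == "clonal":
        # distribute clones round-robin over the trial's families
        genos = []
        for i in range(cfg.n_clones):
            fam = fam_tab.iloc[i % len(fam_tab)]
            g = f"{cfg.trial}C{i + 1:04d}"
            records.append((g, fam.sire, fam.dam))
            fam_of_geno[g] = fam.family
            genos.append(g)
        layout = simulate_layout(cfg.n_reps, cfg.n_blocks, cfg.n_treat_per_block,
                                 cfg.n_trees_per_plot, genos,
                                 seed=int(rng.integers(2 ** 31)))
        layout["genotype"] = layout["treatment"]
    else:
        # treatments are families; every planted tree is a fresh offspring
        layout = simulate_layout(cfg.n_reps, cfg.n_blocks, cfg.n_treat_per_block,
                                 cfg.n_trees_per_plot, list(fam_tab.family),
                                 seed=int(rng.integers(2 ** 31)))
        fam_idx = fam_tab.set_index("family")
        genos = []
        for i, row in enumerate(layout.itertuples()):
            fam = fam_idx.loc[row.treatment]
            g = f"{cfg.trial}G{i + 1:05d}"
            records.append((g, fam.sire, fam.dam))
            fam_of_geno[g] = row.treatment
            genos.append(g)
        layout["genotype"] = genos

    pedigree = build_pedigree(records)
    clone_map = CloneMap(dict(zip(layout["tree"], layout["genotype"])))
    layout["family"] = [fam_of_geno[g] for g in layout["genotype"]]

    trait_names = list(cfg.traits)
    sim_traits = []
    for t in trait_names:
        tc = cfg.traits[t]
        if t in cfg.assessment_doys:
            # the configured mean is the target *measured* trial mean; place
            # the latent mean so scoring/truncation reproduces it
            sd_tot = float(np.sqrt(tc.phenotypic + tc.rep + tc.block + tc.plot))
            mu = calibrated_latent_mean(tc.mean, sd_tot, cfg.assessment_doys[t],
                                        t, cfg.score_rates.get(t, 0.5))
            tc = replace(tc, mean=mu)
        sim_traits.append(tc)
    phenos, truth = simulate_phenotypes(
        pedigree, clone_map, layout, sim_traits,
        genetic_corr=cfg.genetic_corr, residual_corr=cfg.residual_corr,
        family_of_genotype=fam_of_geno, seed=int(rng.integers(2 ** 31)))
    truth["config"] = cfg
    truth["latent"] = {}

    score_frames = []
    for tr in trait_names:
        if tr not in cfg.assessment_doys:
            continue
        latent = pd.Series(phenos[tr].to_numpy(), index=phenos["tree"], name=tr)
        truth["latent"][tr] = latent
        wide, trunc = simulate_phenology_scores(
            latent, cfg.assessment_doys[tr], tr, rate=cfg.score_rates.get(tr, 0.5))
        wide = wide.reset_index().rename(columns={"index": "tree"})
        wide.insert(0, "trial", cfg.trial)
        wide.insert(2, "family", phenos["family"].to_numpy())
        wide.insert(3, "clone", phenos["genotype"].to_numpy())
        wide.insert(4, "trait", tr)
        wide["truncated"] = trunc.to_numpy()
        score_frames.append(wide)
        # the analysed phenotype is the DoY, not the latent value; keep the
        # latent under truth and drop the direct column from the phenotypes
        phenos = phenos.rename(columns={tr: f"{tr}_latent"})
    scores = (pd.concat(score_frames, ignore_index=True)
              if score_frames else pd.DataFrame())

    surv = simulate_survival(
        truth["total_genetic"], cfg.survival_base, cfg.survival_slopes,
        phenos["genotype"].to_numpy(), seed=int(rng.integers(2 ** 31)))
    phenos["survival"] = surv

    return TrialDataset(trial=cfg.trial, config=cfg, pedigree=pedigree,
                        pedigree_records=records, clone_map=clone_map,
                        phenotypes=phenos, scores=scores, truth=truth)
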