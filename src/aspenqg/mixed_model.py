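"""Henderson mixed-model equations and REML variance components.

The analysis model for a seedling progeny trial is the individual-tree
("animal") model

    y = X b + Z1 a + Z2 f + Z3 r + Z4 b + Z5 p + e

with additive genetic effects ``a ~ N(0, A sigma_A^2)`` (A the numerator
relationship matrix), full-sib family effects ``f`` (one quarter of the
dominance variance), replicate, incomplete-block and row-plot effects, and
residual ``e``.  For clonally replicated trials the plot term is dropped and
a clone-within-family term ``c`` (epistasis plus three quarters of the
dominance) is added; ramets of a clone share one column of Z1 and of the
clone incidence.  The only fixed effect is the overall mean.

Variance components are estimated by REML using average-information (AI)
updates with expectation-maximisation (EM) fallback steps; EM guarantees a
monotone restricted likelihood while AI converges quadratically near the
optimum and yields the information matrix used for delta-method standard
errors.  BLUE/BLUP solutions and prediction-error variances come from the
(variance-scale) mixed-model equations

    C = [X'R^-1 X, X'R^-1 Z; Z'R^-1 X, Z'R^-1 Z + G^-1]

whose inverse gives ``Var(u_hat - u)`` directly.  A bivariate variant with
an unstructured 2x2 genetic covariance and 2x2 residual covariance supports
genetic/phenotypic correlations and type-B (between-site) correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotri

from .pedigree import CloneMap, Pedigree, additive_relationship_inverse, logdet_A


class AliasingError(ValueError):
    """Two random terms (or a term and the residual) have identical incidence."""


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the likelihood trajectory."""

    def __init__(self, message: str, trace: Optional[List[float]] = None):
        super().__init__(message)
        self.trace = trace or []


class MappingError(KeyError):
    """A tree could not be resolved to a genotype or design factor."""


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------

SEEDLING_TERMS = ("additive", "family", "rep", "block", "plot")
CLONAL_TERMS = ("additive", "family", "clone", "rep", "block")


@dataclass
class ModelSpec:
    """Random-term structure of the univariate trial model.

    ``model`` selects the seedling layout (additive, family, replicate,
    block, plot) or the clonal layout (additive, family, clone, replicate,
    block).  The additive term always carries the pedigree covariance; all
    other terms are i.i.d.  ``include`` can switch individual terms off,
    e.g. ``{"family": False}``.
    """

    trait: str
    model: str = "clonal"
    include: Dict[str, bool] = field(default_factory=dict)

    def term_names(self) -> List[str]:
        base = SEEDLING_TERMS if self.model == "seedling" else CLONAL_TERMS
        if self.model not in ("seedling", "clonal"):
            raise ValueError(f"unknown model kind {self.model!r}")
        return [t for t in base if self.include.get(t, True)]


@dataclass
class RandomTerm:
    """One random term of the mixed model.

    ``Z`` is the n x (n_traits * q) incidence matrix; columns are ordered
    trait-major for multi-trait terms.  ``K_inv`` is the inverse covariance
    structure over the q levels (``None`` means identity) and ``logdet_K``
    its log-determinant (of K, not K^-1).
    """

    name: str
    Z: sparse.csr_matrix
    levels: Tuple
    K_inv: Optional[sparse.spmatrix] = None
    logdet_K: float = 0.0
    n_traits: int = 1

    @property
    def q(self) -> int:
        return len(self.levels)

    @property
    def ncol(self) -> int:
        return self.q * self.n_traits

    def n_params(self) -> int:
        return 1 if self.n_traits == 1 else 3


@dataclass
class DesignMatrices:
    """Response, fixed-effect and random-term incidence matrices for one fit."""

    y: np.ndarray
    X: sparse.csr_matrix
    terms: List[RandomTerm]
    data_index: np.ndarray
    spec: Optional[ModelSpec] = None


def _factor_Z(codes: np.ndarray, q: int) -> sparse.csr_matrix:
    n = len(codes)
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, q)
    )


def _grouping_signature(codes: np.ndarray) -> Tuple[int, ...]:
    """Canonical relabel-invariant signature of a factor grouping."""
    _, first = np.unique(codes, return_index=True)
    order = {c: r for r, c in enumerate(codes[np.sort(first)])}
    return tuple(order[c] for c in codes)


def build_design(
    spec: ModelSpec,
    data: pd.DataFrame,
    pedigree: Pedigree,
    clone_map: Optional[CloneMap] = None,
    columns: Optional[Mapping[str, str]] = None,
) -> DesignMatrices:
    """Assemble sparse design matrices for one trial and trait.

    ``data`` holds one row per tree with the trait column plus design factor
    columns (``tree, family, rep, block, plot``; block is nested in rep and
    plot in block).  Trees resolve to genotypes through ``clone_map`` (or a
    ``genotype`` column); ramets of one clone share the same column of the
    additive and clone incidences.  Rows with a missing trait value are
    dropped.
    """
    cols = {"tree": "tree", "family": "family", "rep": "rep", "block": "block",
            "plot": "plot", "genotype": "genotype"}
    cols.update(columns or {})
    if spec.trait not in data.columns:
        raise MappingError(f"trait column {spec.trait!r} not in data")
    sub = data.loc[data[spec.trait].notna()].copy()
    if len(sub) == 0:
        raise ValueError(f"no observations for trait {spec.trait!r}")
    y = sub[spec.trait].to_numpy(dtype=float)
    n = len(sub)
    X = sparse.csr_matrix(np.ones((n, 1)))

    trees = sub[cols["tree"]].astype(str).to_numpy()
    if clone_map is not None:
        try:
            genos = np.array([clone_map.genotype_of(t) for t in trees])
        except KeyError as e:  # pragma: no cover - message clarity
            raise MappingError(f"tree {e} has no genotype in the clone map") from e
    elif cols["genotype"] in sub.columns:
        genos = sub[cols["genotype"]].astype(str).to_numpy()
    else:
        genos = trees  # seedling data: each tree is its own genotype
    try:
        geno_idx = pedigree.subset_positions(genos)
    except KeyError as e:
        raise MappingError(f"genotype {e} not in pedigree") from e

    terms: List[RandomTerm] = []
    identity_groupings: Dict[str, np.ndarray] = {}
    for name in spec.term_names():
        if name == "additive":
            Z = _factor_Z(geno_idx, len(pedigree))
            terms.append(
                RandomTerm("additive", Z, tuple(pedigree.ids),
                           K_inv=additive_relationship_inverse(pedigree),
                           logdet_K=logdet_A(pedigree))
            )
            continue
        if name == "clone":
            keys = pd.Series(genos)
        elif name == "family":
            keys = sub[cols["family"]].astype(str)
        elif name == "rep":
            keys = sub[cols["rep"]].astype(str)
        elif name == "block":
            keys = sub[cols["rep"]].astype(str) + "/" + sub[cols["block"]].astype(str)
        elif name == "plot":
            keys = (sub[cols["rep"]].astype(str) + "/" + sub[cols["block"]].astype(str)
                    + "/" + sub[cols["plot"]].astype(str))
        else:  # pragma: no cover
            raise ValueError(f"unknown term {name}")
        codes, levels = pd.factorize(keys.to_numpy())
        if len(levels) < 2:
            continue  # a factor with one level is absorbed by the mean
        identity_groupings[name] = codes
        terms.append(RandomTerm(name, _factor_Z(codes, len(levels)), tuple(levels)))

    sigs = {}
    for name, codes in identity_groupings.items():
        sig = _grouping_signature(codes)
        if sig in sigs:
            raise AliasingError(f"terms {sigs[sig]!r} and {name!r} have identical incidence")
        sigs[sig] = name
        if name == "clone" and len(np.unique(codes)) == n:
            raise AliasingError("clone term has one ramet per genotype; "
                                "it is confounded with the residual")
    return DesignMatrices(y=y, X=X, terms=terms, data_index=sub.index.to_numpy(), spec=spec)


# ---------------------------------------------------------------------------
# mixed-model equations (public, lambda form)
# ---------------------------------------------------------------------------

def assemble_mme(
    designs: DesignMatrices,
    variances: Mapping[str, float],
    resid_variance: float,
) -> Tuple[sparse.csr_matrix, np.ndarray]:
    """Coefficient matrix and right-hand side of the MME in ratio form.

    The coefficient matrix is ``W'W`` with ``K^-1 * lambda_t`` added on each
    random-term diagonal block, ``lambda_t = sigma_e^2 / sigma_t^2`` (the
    additive block receives ``A^-1 lambda_A``); the right-hand side is
    ``W'y``.  Terms with variance at the zero boundary must be dropped
    before assembly.
    """
    if resid_variance <= 0:
        raise ValueError("zero residual variance makes the MME ill-posed")
    for t in designs.terms:
        if t.n_traits != 1:
            raise ValueError("assemble_mme handles univariate terms only")
        if variances[t.name] <= 0:
            raise ValueError(f"non-positive variance for term {t.name!r}; drop it instead")
    W = sparse.hstack([designs.X] + [t.Z for t in designs.terms], format="csr")
    C = (W.T @ W).tolil()
    rhs = W.T @ designs.y
    off = designs.X.shape[1]
    for t in designs.terms:
        lam = resid_variance / variances[t.name]
        blk = slice(off, off + t.ncol)
        if t.K_inv is None:
            C[blk, blk] = C[blk, blk] + sparse.identity(t.ncol) * lam
        else:
            C[blk, blk] = C[blk, blk] + t.K_inv * lam
        off += t.ncol
    return C.tocsr(), rhs


def solve_mme(
    designs: DesignMatrices,
    variances: Mapping[str, float],
    resid_variance: float,
) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
    """Solve the MME at fixed variance components; returns (beta, BLUPs)."""
    C, rhs = assemble_mme(designs, variances, resid_variance)
    sol = sparse.linalg.spsolve(C.tocsc(), rhs)
    p = designs.X.shape[1]
    beta = np.atleast_1d(sol[:p])
    blups: Dict[str, np.ndarray] = {}
    off = p
    for t in designs.terms:
        blups[t.name] = sol[off:off + t.ncol]
        off += t.ncol
    return beta, blups


# ---------------------------------------------------------------------------
# REML engine
# ---------------------------------------------------------------------------

_E2 = [np.array([[1.0, 0.0], [0.0, 0.0]]),
       np.array([[0.0, 1.0], [1.0, 0.0]]),
       np.array([[0.0, 0.0], [0.0, 1.0]])]


class _Engine:
    """AI-REML with EM fallback on the variance-scale MME.

    Handles scalar-variance terms (identity or pedigree structure) and 2x2
    unstructured multi-trait terms, with a scalar residual or a 2x2 residual
    covariance over observation pairs sharing a tree.
    """

    def __init__(self, y, X, terms: List[RandomTerm],
                 obs_trait: Optional[np.ndarray] = None,
                 partner: Optional[np.ndarray] = None):
        self.y = np.asarray(y, dtype=float)
        self.X = sparse.csr_matrix(X)
        self.terms = terms
        self.n = len(self.y)
        self.p = self.X.shape[1]
        self.W = sparse.hstack([self.X] + [t.Z for t in terms], format="csr")
        self.m = self.W.shape[1]
        self.blocks: List[slice] = []
        off = self.p
        for t in terms:
            self.blocks.append(slice(off, off + t.ncol))
            off += t.ncol
        self.scalar_resid = obs_trait is None
        if self.scalar_resid:
            self.M = (self.W.T @ self.W).tocsr()
            self.Wty = self.W.T @ self.y
            self.yty = float(self.y @ self.y)
        else:
            self.obs_trait = np.asarray(obs_trait)
            self.partner = np.asarray(partner)
            ispair = (self.partner >= 0)
            first = ispair & (np.arange(self.n) < self.partner)
            self.pair_i = np.nonzero(first & (self.obs_trait == 0))[0]
            self.pair_j = self.partner[self.pair_i]
            self.single0 = np.nonzero(~ispair & (self.obs_trait == 0))[0]
            self.single1 = np.nonzero(~ispair & (self.obs_trait == 1))[0]
        self.vary = float(np.var(self.y)) if self.scalar_resid else float(
            np.mean([np.var(self.y[self.obs_trait == t]) for t in (0, 1)]))
        self.floor = 1e-10 * self.vary
        self.boundary_tol = 1e-8 * self.vary

    # -- parameter vector helpers ------------------------------------------

    def n_params(self) -> int:
        k = sum(t.n_params() for t in self.terms)
        return k + (1 if self.scalar_resid else 3)

    def param_names(self) -> List[str]:
        names: List[str] = []
        for t in self.terms:
            if t.n_traits == 1:
                names.append(f"sigma2_{t.name}")
            else:
                names += [f"{t.name}_11", f"{t.name}_12", f"{t.name}_22"]
        names += ["sigma2_e"] if self.scalar_resid else ["resid_11", "resid_12", "resid_22"]
        return names

    def start_values(self) -> np.ndarray:
        k = len(self.terms)
        theta: List[float] = []
        if self.scalar_resid:
            share = self.vary / (k + 1)
            for t in self.terms:
                theta.append(share)
            theta.append(share)
        else:
            v0 = float(np.var(self.y[self.obs_trait == 0]))
            v1 = float(np.var(self.y[self.obs_trait == 1]))
            for t in self.terms:
                if t.n_traits == 1:
                    theta.append(self.vary / (k + 1))
                else:
                    theta += [v0 / (k + 1), 0.0, v1 / (k + 1)]
            theta += [v0 / (k + 1), 0.0, v1 / (k + 1)]
        return np.array(theta)

    def _split(self, theta: np.ndarray):
        out = []
        off = 0
        for t in self.terms:
            if t.n_traits == 1:
                out.append(theta[off]); off += 1
            else:
                out.append(np.array([[theta[off], theta[off + 1]],
                                     [theta[off + 1], theta[off + 2]]]))
                off += 3
        resid = theta[off] if self.scalar_resid else np.array(
            [[theta[off], theta[off + 1]], [theta[off + 1], theta[off + 2]]])
        return out, resid

    def feasible(self, theta: np.ndarray) -> bool:
        tvals, resid = self._split(theta)
        for t, v in zip(self.terms, tvals):
            if t.n_traits == 1:
                if v < self.floor:
                    return False
            else:
                if v[0, 0] < self.floor or v[1, 1] < self.floor:
                    return False
                if np.linalg.det(v) < self.floor ** 2 * 1e-4:
                    return False
        if self.scalar_resid:
            if resid < self.floor:
                return False
        else:
            if resid[0, 0] < self.floor or resid[1, 1] < self.floor:
                return False
            if np.linalg.det(resid) < self.floor ** 2 * 1e-4:
                return False
        return True

    # -- per-iteration state ------------------------------------------------

    def _rinv(self, resid):
        """Sparse R^-1 plus (logdet R, per-pair R^-1 blocks)."""
        n = self.n
        if self.scalar_resid:
            return None, n * np.log(resid), None
        r11, r12, r22 = resid[0, 0], resid[0, 1], resid[1, 1]
        det = r11 * r22 - r12 ** 2
        rows, cols, vals = [], [], []
        pi, pj = self.pair_i, self.pair_j
        rows += [pi, pj, pi, pj]
        cols += [pi, pj, pj, pi]
        vals += [np.full(len(pi), r22 / det), np.full(len(pi), r11 / det),
                 np.full(len(pi), -r12 / det), np.full(len(pi), -r12 / det)]
        rows += [self.single0, self.single1]
        cols += [self.single0, self.single1]
        vals += [np.full(len(self.single0), 1.0 / r11),
                 np.full(len(self.single1), 1.0 / r22)]
        Rinv = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n)).tocsr()
        logdet = (len(pi) * np.log(det) + len(self.single0) * np.log(r11)
                  + len(self.single1) * np.log(r22))
        Rb = np.array([[r22 / det, -r12 / det], [-r12 / det, r11 / det]])
        return Rinv, logdet, Rb

    def _state(self, theta: np.ndarray) -> dict:
        """Factorize the MME at theta; return solutions, inverse and logL."""
        tvals, resid = self._split(theta)
        if self.scalar_resid:
            C = (self.M / resid).toarray()
            rhs = self.Wty / resid
            yRy = self.yty / resid
            Rinv, logdetR, Rb = None, self.n * np.log(resid), None
        else:
            Rinv, logdetR, Rb = self._rinv(resid)
            WtR = self.W.T @ Rinv
            C = (WtR @ self.W).toarray()
            rhs = WtR @ self.y
            yRy = float(self.y @ (Rinv @ self.y))
        logdetG = 0.0
        for t, blk, v in zip(self.terms, self.blocks, tvals):
            if t.n_traits == 1:
                logdetG += t.q * np.log(v) + t.logdet_K
                if t.K_inv is None:
                    idx = np.arange(blk.start, blk.stop)
                    C[idx, idx] += 1.0 / v
                else:
                    C[blk, blk] += (t.K_inv / v).toarray()
            else:
                logdetG += t.q * np.log(np.linalg.det(v)) + 2.0 * t.logdet_K
                Vinv = np.linalg.inv(v)
                for a in range(2):
                    for b in range(2):
                        ia = np.arange(blk.start + a * t.q, blk.start + (a + 1) * t.q)
                        ib = np.arange(blk.start + b * t.q, blk.start + (b + 1) * t.q)
                        if t.K_inv is None:
                            C[ia, ib] += Vinv[a, b]
                        else:
                            C[ia[0]:ia[-1] + 1, ib[0]:ib[-1] + 1] += (t.K_inv * Vinv[a, b]).toarray()
        cf = cho_factor(C, lower=True, check_finite=False)
        sol = cho_solve(cf, rhs, check_finite=False)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        yPy = yRy - float(sol @ rhs)
        logl = -0.5 * (logdetR + logdetG + logdetC + yPy)
        ehat = self.y - self.W @ sol
        Py = ehat / resid if self.scalar_resid else Rinv @ ehat
        return dict(theta=theta.copy(), tvals=tvals, resid=resid, sol=sol,
                    cf=cf, Cinv=None, logl=logl, yPy=yPy, ehat=ehat, Py=Py,
                    Rinv=Rinv, Rb=Rb)

    def _ensure_inv(self, st: dict) -> np.ndarray:
        """Dense inverse of the MME coefficient matrix, computed lazily."""
        if st["Cinv"] is None:
            inv, info = dpotri(st["cf"][0], lower=1)
            if info != 0:  # pragma: no cover
                raise np.linalg.LinAlgError("dpotri failed")
            st["Cinv"] = np.tril(inv) + np.tril(inv, -1).T
        return st["Cinv"]

    # -- gradient / AI ------------------------------------------------------

    def _block_trace(self, t: RandomTerm, Cinv, blk, a=0, b=0) -> float:
        sa = slice(blk.start + a * t.q, blk.start + (a + 1) * t.q)
        sb = slice(blk.start + b * t.q, blk.start + (b + 1) * t.q)
        sub = Cinv[sa, sb]
        if t.K_inv is None:
            return float(np.trace(sub))
        return float(t.K_inv.multiply(sub).sum())

    def _grad_and_workvecs(self, st: dict):
        """Score vector and AI working vectors F (n x k) at the state."""
        Py = st["Py"]
        Cinv = self._ensure_inv(st)
        grads: List[float] = []
        fvecs: List[np.ndarray] = []
        for t, blk, v in zip(self.terms, self.blocks, st["tvals"]):
            u = st["sol"][blk]
            if t.n_traits == 1:
                uKu = float(u @ u) if t.K_inv is None else float(u @ (t.K_inv @ u))
                tr = self._block_trace(t, Cinv, blk)
                ydot = uKu / v ** 2
                trPV = t.q / v - tr / v ** 2
                grads.append(0.5 * (ydot - trPV))
                fvecs.append(t.Z @ (u / v))
            else:
                U = u.reshape(2, t.q)
                Vinv = np.linalg.inv(v)
                if t.K_inv is None:
                    M2 = U @ U.T
                else:
                    KU = np.column_stack([t.K_inv @ U[0], t.K_inv @ U[1]])
                    M2 = U @ KU
                T2 = np.array([[self._block_trace(t, Cinv, blk, a, b)
                                for b in range(2)] for a in range(2)])
                for E in _E2:
                    H = Vinv @ E @ Vinv
                    ydot = float(np.sum(H * M2))
                    trPV = t.q * float(np.trace(Vinv @ E)) - float(np.sum(H * T2))
                    grads.append(0.5 * (ydot - trPV))
                    fvecs.append(t.Z @ (E @ Vinv @ U).ravel())
        if self.scalar_resid:
            v = st["resid"]
            ydot = float(st["ehat"] @ st["ehat"]) / v ** 2
            trCW = float(self.M.multiply(Cinv).sum())
            trPV = self.n / v - trCW / v ** 2
            grads.append(0.5 * (ydot - trPV))
            fvecs.append(Py.copy())
        else:
            Rb = st["Rb"]
            pi, pj = self.pair_i, self.pair_j
            for k, E in enumerate(_E2):
                # dR/dtheta applied blockwise
                f = np.zeros(self.n)
                if k == 0:
                    idx0 = np.concatenate([pi, self.single0])
                    f[idx0] = Py[idx0]
                    ydot = float(Py[idx0] @ Py[idx0])
                    trR = len(pi) * Rb[0, 0] + len(self.single0) * (1.0 / st["resid"][0, 0])
                elif k == 2:
                    idx1 = np.concatenate([pj, self.single1])
                    f[idx1] = Py[idx1]
                    ydot = float(Py[idx1] @ Py[idx1])
                    trR = len(pi) * Rb[1, 1] + len(self.single1) * (1.0 / st["resid"][1, 1])
                else:
                    f[pi] = Py[pj]
                    f[pj] = Py[pi]
                    ydot = 2.0 * float(Py[pi] @ Py[pj])
                    trR = 2.0 * len(pi) * Rb[0, 1]
                Dk = self._resid_sandwich(k, st)
                Sk = (self.W.T @ (Dk @ self.W)).toarray()
                trPV = trR - float(np.sum(Sk * Cinv))
                grads.append(0.5 * (ydot - trPV))
                fvecs.append(f)
        return np.array(grads), np.column_stack(fvecs)

    def _resid_sandwich(self, k: int, st: dict) -> sparse.csr_matrix:
        """Sparse R^-1 (dR/dtheta_k) R^-1 for the 2x2 residual."""
        Rb = st["Rb"]
        D = Rb @ _E2[k] @ Rb
        pi, pj = self.pair_i, self.pair_j
        rows = [pi, pj, pi, pj]
        cols = [pi, pj, pj, pi]
        vals = [np.full(len(pi), D[0, 0]), np.full(len(pi), D[1, 1]),
                np.full(len(pi), D[0, 1]), np.full(len(pi), D[1, 0])]
        r11, r22 = st["resid"][0, 0], st["resid"][1, 1]
        if k == 0:
            rows.append(self.single0); cols.append(self.single0)
            vals.append(np.full(len(self.single0), 1.0 / r11 ** 2))
        elif k == 2:
            rows.append(self.single1); cols.append(self.single1)
            vals.append(np.full(len(self.single1), 1.0 / r22 ** 2))
        return sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n)).tocsr()

    def _ai_matrix(self, st: dict, F: np.ndarray) -> np.ndarray:
        """Average-information matrix 0.5 * F' P F via one multi-RHS solve."""
        if self.scalar_resid:
            RF = F / st["resid"]
        else:
            RF = st["Rinv"] @ F
        WtRF = self.W.T @ RF
        proj = cho_solve(st["cf"], WtRF, check_finite=False)
        FPF = F.T @ RF - WtRF.T @ proj
        return 0.5 * FPF

    # -- EM steps -----------------------------------------------------------

    def _em_step(self, st: dict) -> np.ndarray:
        Cinv = self._ensure_inv(st)
        theta_new: List[float] = []
        for t, blk, v in zip(self.terms, self.blocks, st["tvals"]):
            u = st["sol"][blk]
            if t.n_traits == 1:
                uKu = float(u @ u) if t.K_inv is None else float(u @ (t.K_inv @ u))
                tr = self._block_trace(t, Cinv, blk)
                theta_new.append((uKu + tr) / t.q)
            else:
                U = u.reshape(2, t.q)
                if t.K_inv is None:
                    M2 = U @ U.T
                else:
                    KU = np.column_stack([t.K_inv @ U[0], t.K_inv @ U[1]])
                    M2 = U @ KU
                T2 = np.array([[self._block_trace(t, Cinv, blk, a, b)
                                for b in range(2)] for a in range(2)])
                G0 = (M2 + T2) / t.q
                theta_new += [G0[0, 0], G0[0, 1], G0[1, 1]]
        if self.scalar_resid:
            theta_new.append(st["resid"] * st["yPy"] / (self.n - self.p))
        else:
            eh = st["ehat"]
            Q = np.asarray((self.W @ Cinv))
            wcw_diag = np.asarray(self.W.multiply(Q).sum(axis=1)).ravel()
            pi, pj = self.pair_i, self.pair_j
            Wj = self.W[pj]
            wcw_cross = np.asarray(Wj.multiply(Q[pi]).sum(axis=1)).ravel()
            idx0 = np.concatenate([pi, self.single0])
            idx1 = np.concatenate([pj, self.single1])
            r11 = float(np.sum(eh[idx0] ** 2 + wcw_diag[idx0])) / len(idx0)
            r22 = float(np.sum(eh[idx1] ** 2 + wcw_diag[idx1])) / len(idx1)
            r12 = float(np.sum(eh[pi] * eh[pj] + wcw_cross)) / max(len(pi), 1)
            theta_new += [r11, r12, r22]
        return np.array(theta_new)

    # -- driver -------------------------------------------------------------

    def fit(self, start: Optional[np.ndarray] = None, tol: float = 1e-6,
            max_iter: int = 200, n_em_warmup: int = 2):
        theta = self.start_values() if start is None else np.asarray(start, dtype=float)
        theta = np.maximum(theta, np.where(self._scalarish_mask(), self.floor, -np.inf))
        mask = self._scalarish_mask()
        st = self._state(theta)
        trace = [st["logl"]]
        pinned: set = set()
        converged = False
        for it in range(max_iter):
            use_em = it < n_em_warmup
            if use_em:
                st_new = self._safe_state_toward(theta, self._clamp(self._em_step(st)))
                at_floor = set()
            else:
                g, F = self._grad_and_workvecs(st)
                AI = self._ai_matrix(st, F)
                # active-set handling of the zero boundary: a variance at the
                # floor stays frozen only while its gradient points outward
                at_floor = {i for i, v in enumerate(theta)
                            if mask[i] and v <= self.boundary_tol}
                frozen = {i for i in at_floor if g[i] <= 0}
                for j in self._clamped_cov_indices(theta):
                    if g[j] * np.sign(theta[j]) > 0:  # pushing outward
                        frozen.add(j)
                free = np.array([i not in frozen for i in range(len(g))])
                AIf = AI[np.ix_(free, free)]
                st_new = None
                # AI is only an approximation of the information matrix and
                # can be indefinite away from the optimum; damp it toward a
                # scaled gradient step until an ascent step is accepted
                for lam in (0.0, 1e-2, 1.0, 1e2):
                    M = AIf + lam * np.diag(np.abs(np.diag(AIf))) \
                        + 1e-12 * np.eye(int(free.sum()))
                    try:
                        sf = np.linalg.solve(M, g[free])
                    except np.linalg.LinAlgError:
                        sf = np.linalg.lstsq(M, g[free], rcond=None)[0]
                    step = np.zeros(len(g))
                    step[free] = sf
                    frac = 1.0
                    for _ in range(8):
                        cand = self._clamp(theta + frac * step)
                        if self.feasible(cand) and not np.allclose(cand, theta):
                            try:
                                s_try = self._state(cand)
                            except np.linalg.LinAlgError:
                                frac *= 0.5
                                continue  # numerically indefinite: reject step
                            if s_try["logl"] >= st["logl"] - 1e-9 * (1 + abs(st["logl"])):
                                st_new = s_try
                                break
                        frac *= 0.5
                    if st_new is not None:
                        break
                if st_new is None:
                    st_new = self._safe_state_toward(theta, self._clamp(self._em_step(st)))
            d_logl = st_new["logl"] - st["logl"]
            theta, st = st_new["theta"], st_new
            trace.append(st["logl"])
            if use_em or abs(d_logl) >= tol * (1 + abs(st["logl"])):
                continue
            # flat step: declare convergence when the Newton decrement over
            # the interior parameters is negligible and no boundary-pinned
            # parameter could buy a non-trivial likelihood gain by moving in
            g, F = self._grad_and_workvecs(st)
            pinned = {i for i, v in enumerate(theta)
                      if mask[i] and v <= self.boundary_tol}
            scale = 1 + abs(st["logl"])
            AI = self._ai_matrix(st, F)
            gain_tol = max(1e-2, 10 * tol * scale)
            ok = True
            for i in pinned:
                if g[i] > 0 and g[i] ** 2 / (2 * max(AI[i, i], 1e-300)) > gain_tol:
                    ok = False  # releasing this variance would still pay
                    break
            if not ok:
                continue
            excluded = pinned | self._clamped_cov_indices(theta)
            freeidx = np.array([i not in excluded for i in range(len(g))])
            nd = 0.0
            if freeidx.any():
                AIf = AI[np.ix_(freeidx, freeidx)]
                try:
                    nd = float(g[freeidx] @ np.linalg.solve(
                        AIf + 1e-12 * np.eye(int(freeidx.sum())), g[freeidx]))
                except np.linalg.LinAlgError:
                    nd = float(g[freeidx] @ np.linalg.lstsq(AIf, g[freeidx], rcond=None)[0])
            if abs(nd) < 2 * tol * scale:
                converged = True
                break
        if not converged and not pinned:
            raise ConvergenceError(
                f"REML did not converge in {max_iter} iterations", trace)
        g, F = self._grad_and_workvecs(st)
        AI = self._ai_matrix(st, F)
        try:
            cov = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(AI)
        return dict(theta=theta, state=st, cov=cov, trace=trace,
                    pinned=sorted(pinned), names=self.param_names(),
                    n_iter=len(trace) - 1, converged=converged)

    def _clamped_cov_indices(self, theta: np.ndarray) -> set:
        """Indices of 2x2-term covariance parameters sitting at the PSD clamp."""
        out = set()
        off = 0
        groups = [t.n_params() for t in self.terms] + [1 if self.scalar_resid else 3]
        for npar in groups:
            if npar == 3:
                v11, v12, v22 = theta[off], theta[off + 1], theta[off + 2]
                lim = 0.999 * np.sqrt(max(v11 * v22, 0.0))
                if abs(v12) >= 0.998 * lim:
                    out.add(off + 1)
            off += npar
        return out

    def _safe_state_toward(self, theta_old: np.ndarray, cand: np.ndarray) -> dict:
        """Evaluate a candidate, backing off toward the previous point when
        the coefficient matrix is numerically indefinite."""
        for _ in range(8):
            try:
                return self._state(cand)
            except np.linalg.LinAlgError:
                cand = self._clamp(0.5 * (cand + theta_old))
        return self._state(theta_old)

    def _scalarish_mask(self) -> np.ndarray:
        """True for parameters constrained to be non-negative (variances)."""
        mask: List[bool] = []
        for t in self.terms:
            mask += [True] if t.n_traits == 1 else [True, False, True]
        mask += [True] if self.scalar_resid else [True, False, True]
        return np.array(mask)

    def _clamp(self, theta: np.ndarray) -> np.ndarray:
        out = theta.copy()
        mask = self._scalarish_mask()
        out[mask] = np.maximum(out[mask], self.floor)
        # shrink covariances into the PSD region if needed
        tvals, resid = self._split(out)
        off = 0
        for t in self.terms:
            if t.n_traits == 1:
                off += 1
                continue
            v11, v12, v22 = out[off], out[off + 1], out[off + 2]
            lim = 0.999 * np.sqrt(max(v11 * v22, 0.0))
            out[off + 1] = np.clip(v12, -lim, lim)
            off += 3
        if not self.scalar_resid:
            v11, v12, v22 = out[off], out[off + 1], out[off + 2]
            lim = 0.999 * np.sqrt(max(v11 * v22, 0.0))
            out[off + 1] = np.clip(v12, -lim, lim)
        return out


# ---------------------------------------------------------------------------
# public fit results
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """REML variance-component estimates with their sampling covariance."""

    variances: Dict[str, float]
    residual: float
    loglik: float
    cov: pd.DataFrame            # sampling covariance of the sigma^2 estimates
    boundary: List[str] = field(default_factory=list)
    n_iter: int = 0
    trace: List[float] = field(default_factory=list)

    def se(self, name: str) -> float:
        key = "sigma2_e" if name in ("residual", "e") else f"sigma2_{name}"
        return float(np.sqrt(self.cov.loc[key, key]))

    def as_series(self) -> pd.Series:
        d = dict(self.variances)
        d["residual"] = self.residual
        return pd.Series(d)


@dataclass
class MixedModelFit:
    """BLUE/BLUP solution of one univariate trial fit."""

    spec: ModelSpec
    vc: VarianceComponents
    beta: np.ndarray
    blups: Dict[str, pd.Series]
    pev: Dict[str, pd.Series]
    n_obs: int

    @property
    def intercept(self) -> float:
        return float(self.beta[0])


def reml_fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    pedigree: Pedigree,
    clone_map: Optional[CloneMap] = None,
    start: Optional[Mapping[str, float]] = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    columns: Optional[Mapping[str, str]] = None,
) -> MixedModelFit:
    """REML fit of the univariate trial model.

    Starting values default to an equal partition of the phenotypic variance
    across terms.  A component pinned at the zero boundary (below
    ``1e-8 * var(y)``) is fixed at zero, the term dropped, and the model
    refit; such terms are listed in ``vc.boundary`` with a zero variance and
    no standard error ("no estimate").
    """
    designs = build_design(spec, data, pedigree, clone_map, columns)
    dropped: List[str] = []
    terms = list(designs.terms)
    while True:
        eng = _Engine(designs.y, designs.X, terms)
        if start is not None and not dropped:
            s0 = np.array([start.get(t.name, eng.vary / (len(terms) + 1)) for t in terms]
                          + [start.get("residual", eng.vary / (len(terms) + 1))])
        else:
            s0 = None
        res = eng.fit(start=s0, tol=tol, max_iter=max_iter)
        if not res["pinned"]:
            break
        # residual pinned -> ill-posed; term pinned -> drop and refit
        names = res["names"]
        pinned_names = [names[i] for i in res["pinned"]]
        if "sigma2_e" in pinned_names:
            raise ConvergenceError("residual variance pinned at zero", res["trace"])
        for pn in pinned_names:
            tname = pn.replace("sigma2_", "")
            dropped.append(tname)
            terms = [t for t in terms if t.name != tname]
        # an empty term list is legitimate: the refit estimates the
        # residual variance alone and every dropped term reports zero

    theta = res["theta"]
    variances = {t.name: float(v) for t, v in zip(terms, theta[:-1])}
    for name in dropped:
        variances[name] = 0.0
    cov = pd.DataFrame(res["cov"], index=res["names"], columns=res["names"])
    vc = VarianceComponents(
        variances=variances, residual=float(theta[-1]),
        loglik=float(res["state"]["logl"]), cov=cov, boundary=dropped,
        n_iter=res["n_iter"], trace=res["trace"],
    )
    st = res["state"]
    p = 1
    blups: Dict[str, pd.Series] = {}
    pev: Dict[str, pd.Series] = {}
    eng_terms = terms
    off = p
    for t in eng_terms:
        sol = st["sol"][off:off + t.ncol]
        d = np.diag(st["Cinv"])[off:off + t.ncol]
        blups[t.name] = pd.Series(sol, index=list(t.levels))
        pev[t.name] = pd.Series(d, index=list(t.levels))
        off += t.ncol
    return MixedModelFit(spec=spec, vc=vc, beta=np.atleast_1d(st["sol"][:1]),
                         blups=blups, pev=pev, n_obs=len(designs.y))


# ---------------------------------------------------------------------------
# bivariate fit
# ---------------------------------------------------------------------------

@dataclass
class BivariateFit:
    """Two-trait fit: unstructured genetic and residual 2x2 covariances.

    ``genetic_cov``/``residual_cov`` are the 2x2 covariance matrices; in
    seedling data the genetic effect is additive (pedigree structure), in
    clonal data it is the total genotypic effect (independent clones).
    ``cov_params`` is the AI-based sampling covariance over the parameter
    vector named in its index.
    """

    traits: Tuple[str, str]
    genetic_cov: np.ndarray
    residual_cov: np.ndarray
    rep_variances: Tuple[float, float]
    loglik: float
    cov_params: pd.DataFrame
    genetic_kind: str  # "additive" | "genotypic"
    n_obs: int
    boundary: bool = False
    blups: Optional[pd.DataFrame] = None


def _stack_bivariate(
    data: pd.DataFrame, traits: Tuple[str, str],
    tree_col: str, rep_col: str, geno: np.ndarray,
) -> pd.DataFrame:
    rows = []
    for k, tr in enumerate(traits):
        ok = data[tr].notna().to_numpy()
        rows.append(pd.DataFrame({
            "tree": data[tree_col].astype(str).to_numpy()[ok],
            "trait_idx": k,
            "value": data[tr].to_numpy(dtype=float)[ok],
            "rep": data[rep_col].astype(str).to_numpy()[ok],
            "genotype": geno[ok],
        }))
    return pd.concat(rows, ignore_index=True)


def bivariate_fit(
    traits: Tuple[str, str],
    data: pd.DataFrame,
    pedigree: Optional[Pedigree] = None,
    clone_map: Optional[CloneMap] = None,
    genetic_kind: str = "genotypic",
    columns: Optional[Mapping[str, str]] = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    residual_cov: bool = True,
) -> BivariateFit:
    """Bivariate individual-tree/clone model for two traits on one site.

    Fixed effects are the two trait means; random effects are a replicate
    effect per trait, a genetic effect with unstructured 2x2 covariance
    between traits (``genetic_kind="additive"`` uses the pedigree structure
    over genotypes, ``"genotypic"`` treats clones as independent), and a 2x2
    residual covariance across the two observations of one tree (set
    ``residual_cov=False`` for cross-site data where no tree carries both
    traits).
    """
    cols = {"tree": "tree", "rep": "rep", "genotype": "genotype"}
    cols.update(columns or {})
    trees = data[cols["tree"]].astype(str).to_numpy()
    if clone_map is not None:
        geno = np.array([clone_map.genotype_of(t) for t in trees])
    elif cols["genotype"] in data.columns:
        geno = data[cols["genotype"]].astype(str).to_numpy()
    else:
        geno = trees
    obs = _stack_bivariate(data, traits, cols["tree"], cols["rep"], geno)
    both = set(obs.loc[obs.trait_idx == 0, "tree"]) & set(obs.loc[obs.trait_idx == 1, "tree"])
    if genetic_kind == "additive":
        g0 = set(obs.loc[obs.trait_idx == 0, "genotype"])
        g1 = set(obs.loc[obs.trait_idx == 1, "genotype"])
        overlap = bool(g0 & g1) or pedigree is not None
    else:
        overlap = bool(both)
    if not both and residual_cov:
        residual_cov = False
    n = len(obs)
    trait_idx = obs["trait_idx"].to_numpy()
    y = obs["value"].to_numpy()
    X = _factor_Z(trait_idx, 2)

    # replicate-within-trait: one scalar term per trait
    terms: List[RandomTerm] = []
    for k in range(2):
        lv = pd.unique(obs.loc[trait_idx == k, "rep"])
        lmap = {v: i for i, v in enumerate(lv)}
        rows = np.nonzero(trait_idx == k)[0]
        codes_k = np.array([lmap[v] for v in obs.loc[trait_idx == k, "rep"]])
        Z = sparse.csr_matrix((np.ones(len(rows)), (rows, codes_k)), shape=(n, len(lv)))
        terms.append(RandomTerm(f"rep_{traits[k]}", Z, tuple(lv)))

    if genetic_kind == "additive":
        if pedigree is None:
            raise ValueError("additive genetic kind requires a pedigree")
        q = len(pedigree)
        gidx = pedigree.subset_positions(obs["genotype"].to_numpy())
        rows = np.arange(n)
        Zg = sparse.csr_matrix(
            (np.ones(n), (rows, trait_idx * q + gidx)), shape=(n, 2 * q))
        gterm = RandomTerm("genetic", Zg, tuple(pedigree.ids),
                           K_inv=additive_relationship_inverse(pedigree),
                           logdet_K=logdet_A(pedigree), n_traits=2)
    else:
        codes, levels = pd.factorize(obs["genotype"].to_numpy())
        q = len(levels)
        Zg = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), trait_idx * q + codes)), shape=(n, 2 * q))
        gterm = RandomTerm("genetic", Zg, tuple(levels), n_traits=2)
    terms.append(gterm)

    if residual_cov:
        tree_trait = {}
        partner = np.full(n, -1)
        tree_arr = obs["tree"].to_numpy()
        for i in range(n):
            key = tree_arr[i]
            if key in tree_trait:
                j = tree_trait[key]
                partner[i], partner[j] = j, i
            else:
                tree_trait[key] = i
    else:
        partner = np.full(n, -1)
    if not overlap:
        raise ValueError("traits share no genetic material; correlation not estimable")

    eng = _Engine(y, X, terms, obs_trait=trait_idx, partner=partner)
    res = eng.fit(tol=tol, max_iter=max_iter)
    theta = res["theta"]
    k0 = 2  # two rep variances first
    G0 = np.array([[theta[k0], theta[k0 + 1]], [theta[k0 + 1], theta[k0 + 2]]])
    R0 = np.array([[theta[k0 + 3], theta[k0 + 4]], [theta[k0 + 4], theta[k0 + 5]]])
    names = res["names"]
    cov = pd.DataFrame(res["cov"], index=names, columns=names)
    boundary = any(names[i].startswith("genetic") for i in res["pinned"])
    st = res["state"]
    # BLUPs of the genetic effects per trait
    off = 2 + sum(t.ncol for t in terms[:2])
    gq = gterm.q
    bl = pd.DataFrame({
        traits[0]: st["sol"][off:off + gq],
        traits[1]: st["sol"][off + gq:off + 2 * gq],
    }, index=list(gterm.levels))
    return BivariateFit(
        traits=traits, genetic_cov=G0, residual_cov=R0,
        rep_variances=(float(theta[0]), float(theta[1])),
        loglik=float(st["logl"]), cov_params=cov, genetic_kind=genetic_kind,
        n_obs=n, boundary=boundary, blups=bl,
    )
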