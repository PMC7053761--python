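"""Independent dense oracles used to validate the sparse MME/REML path.

These deliberately avoid the mixed-model equations: everything is computed
from the dense phenotypic covariance matrix V (generalised least squares and
the closed-form BLUP projection), or from classical ANOVA expected mean
squares, so agreement with the package is a genuine cross-check.
"""

import numpy as np

from aspenqg.pedigree import additive_relationship


def dense_V(terms, variances, resid_variance, n, A_dense=None):
    """V = sum sigma_t^2 Z_t K_t Z_t' + sigma_e^2 I, fully dense."""
    V = resid_variance * np.eye(n)
    for t in terms:
        Z = t.Z.toarray()
        K = A_dense if t.K_inv is not None else np.eye(t.q)
        V += variances[t.name] * (Z @ K @ Z.T)
    return V


def gls_solution(y, X, terms, variances, resid_variance, A_dense=None):
    """beta = (X'V^-1X)^-1 X'V^-1 y and u_t = s2 K Z'V^-1 (y - X beta)."""
    n = len(y)
    Xd = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
    V = dense_V(terms, variances, resid_variance, n, A_dense)
    Vi = np.linalg.inv(V)
    XVX = Xd.T @ Vi @ Xd
    beta = np.linalg.solve(XVX, Xd.T @ Vi @ y)
    r = Vi @ (y - Xd @ beta)
    blups = {}
    for t in terms:
        K = A_dense if t.K_inv is not None else np.eye(t.q)
        blups[t.name] = variances[t.name] * (K @ (t.Z.toarray().T @ r))
    return beta, blups


def dense_reml_loglik(y, X, terms, variances, resid_variance, A_dense=None):
    """-0.5 (log|V| + log|X'V^-1X| + y'Py), the REML log-likelihood kernel."""
    n = len(y)
    Xd = X.toarray() if hasattr(X, "toarray") else np.asarray(X)
    V = dense_V(terms, variances, resid_variance, n, A_dense)
    Vi = np.linalg.inv(V)
    XVX = Xd.T @ Vi @ Xd
    beta = np.linalg.solve(XVX, Xd.T @ Vi @ y)
    yPy = (y - Xd @ beta) @ Vi @ y
    return -0.5 * (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XVX)[1] + yPy)


def anova_halfsib_sigma_a(y, groups):
    """Method-of-moments additive variance from a balanced dam (half-sib)
    one-way ANOVA: sigma_A^2 = 4 (MSB - MSW) / n_per."""
    groups = np.asarray(groups)
    levels = np.unique(groups)
    k = len(levels)
    n_per = len(y) // k
    means = np.array([y[groups == g].mean() for g in levels])
    grand = y.mean()
    msb = n_per * ((means - grand) ** 2).sum() / (k - 1)
    msw = sum(((y[groups == g] - means[i]) ** 2).sum()
              for i, g in enumerate(levels)) / (k * (n_per - 1))
    sigma_dam = (msb - msw) / n_per
    return 4.0 * sigma_dam, msw


def simulate_halfsib(rng, n_dams=60, n_per=20, mu=10.0, sigma_a=0.4, sigma_e=0.6):
    """Balanced polymix half-sib families from known dams (animal-model truth)."""
    import pandas as pd

    from aspenqg.pedigree import build_pedigree

    recs = [(f"D{i}", None, None) for i in range(n_dams)]
    recs += [(f"O{i}_{j}", None, f"D{i}") for i in range(n_dams) for j in range(n_per)]
    ped = build_pedigree(recs)
    A = additive_relationship(ped)
    L = np.linalg.cholesky(A + 1e-10 * np.eye(len(ped)))
    bv = np.sqrt(sigma_a) * (L @ rng.standard_normal(len(ped)))
    rows = []
    for i in range(n_dams):
        for j in range(n_per):
            g = f"O{i}_{j}"
            rows.append({
                "tree": g, "genotype": g, "family": f"D{i}", "rep": 1,
                "block": 1, "plot": 1,
                "y": mu + bv[ped.index(g)] + np.sqrt(sigma_e) * rng.standard_normal(),
            })
    return pd.DataFrame(rows), ped
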