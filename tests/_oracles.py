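"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's computational paths: the
neighborhood oracle is a naive double loop, the mixed-model oracle is
tensor Gauss-Hermite integration over every random effect, and the
signed-rank oracle enumerates all sign assignments.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.special import logsumexp, roots_hermite
from scipy.stats import rankdata

from treemort.stages import STAGE_ORDER


def naive_stratified_ni(df, focal_idx, radius):
    """O(n^2) neighborhood index of one focal tree, all nine strata."""
    out = {s: 0.0 for s in
           ("CON", "HET", "EaCON", "SaCON", "LaCON", "EaHET", "SaHET", "LaHET", "ALL")}
    fx = df["x"].loc[focal_idx]
    fy = df["y"].loc[focal_idx]
    for j in df.index:
        if j == focal_idx:
            continue
        d = float(np.hypot(df["x"].loc[j] - fx, df["y"].loc[j] - fy))
        if d == 0 or d > radius:
            continue
        w = (df["dbh"].loc[j] / 2.0) ** 2 * np.pi / d
        con = "CON" if df["species"].loc[j] == df["species"].loc[focal_idx] else "HET"
        rel = int(np.sign(STAGE_ORDER[df["stage"].loc[j]] - STAGE_ORDER[df["stage"].loc[focal_idx]]))
        pre = {-1: "Ea", 0: "Sa", 1: "La"}[rel]
        out[con] += w
        out[pre + con] += w
        out["ALL"] += w
    return out


def gauss_hermite_loglik(y, X, species, grid, alpha, beta, sigma_s, sigma_g, n_nodes=10):
    """Marginal Bernoulli log-likelihood by full tensor Gauss-Hermite
    integration over every crossed random intercept (small q only)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float) if X is not None else np.empty((len(y), 0))
    beta = np.asarray(beta, float)
    sp = np.asarray(species)
    gr = np.asarray(grid)
    sp_codes = np.unique(sp, return_inverse=True)[1]
    gr_codes = np.unique(gr, return_inverse=True)[1]
    qs, qg = sp_codes.max() + 1, gr_codes.max() + 1
    q = qs + qg
    nodes, weights = roots_hermite(n_nodes)
    logw = np.log(weights / np.sqrt(np.pi))

    base = alpha + (X @ beta if X.size else 0.0)
    grids = np.meshgrid(*([nodes] * q), indexing="ij")
    combos = np.stack([g.ravel() for g in grids], axis=1)  # (C, q)
    wgrids = np.meshgrid(*([logw] * q), indexing="ij")
    logw_c = np.stack([g.ravel() for g in wgrids], axis=1).sum(axis=1)

    terms = []
    for lo in range(0, len(combos), 20_000):  # chunked to bound memory
        c = combos[lo : lo + 20_000]
        u_s = np.sqrt(2.0) * sigma_s * c[:, :qs]
        u_g = np.sqrt(2.0) * sigma_g * c[:, qs:]
        eta = base[None, :] + u_s[:, sp_codes] + u_g[:, gr_codes]  # (C, n)
        ll = (y[None, :] * eta - np.logaddexp(0.0, eta)).sum(axis=1)
        terms.append(ll + logw_c[lo : lo + 20_000])
    return float(logsumexp(np.concatenate(terms)))


def signed_rank_exact(d):
    """Exact two-sided signed-rank test by enumerating all 2^n sign
    assignments of the observed absolute differences (no zeros/ties)."""
    d = np.asarray(d, float)
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    m = n * (n + 1) / 2.0
    dev_obs = abs(w_obs - m / 2.0)
    count = 0
    for signs in product((0, 1), repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if abs(w - m / 2.0) >= dev_obs - 1e-12:
            count += 1
    return w_obs, count / 2.0**n


def irls_logistic(y, X, tol=1e-12, max_iter=100):
    """Plain logistic regression by iteratively reweighted least squares."""
    y = np.asarray(y, float)
    X1 = np.column_stack([np.ones(len(y)), np.asarray(X, float)])
    b = np.zeros(X1.shape[1])
    for _ in range(max_iter):
        eta = X1 @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / np.clip(w, 1e-12, None)
        bw = np.linalg.solve((X1 * w[:, None]).T @ X1, (X1 * w[:, None]).T @ z)
        if np.abs(bw - b).max() < tol:
            b = bw
            break
        b = bw
    return b
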