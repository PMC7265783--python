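"""Collapsed Gibbs sampler for node-wise spike-and-slab regression.

Each node (protein) is regressed on the remaining pathway proteins under a
Bernoulli(pi) inclusion prior, a conjugate normal slab ``beta ~ N(0, tau2 *
sigma2)`` per included coefficient and ``sigma2 ~ Inverse-Gamma(a, b)``.
Because the slab and noise variance are conjugate, the coefficients and
variance integrate out in closed form and the sampler walks over inclusion
bitmasks only; marginal likelihoods are memoised per visited subset, so the
chain's stationary distribution is exactly the enumerated posterior.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit, types
from numba.typed import Dict

__all__ = ["gibbs_node", "log_marginal_likelihood"]


@njit(cache=True)
def _subset_quantities(G, g, yty, tau2, mask, p):
    """log det(I + tau2*G_SS) and residual quadratic form q for subset ``mask``.

    Also returns the tau2-ridge posterior-mean coefficients embedded in a
    length-p vector (zeros off the subset).
    """
    k = 0
    for j in range(p):
        if mask & (1 << j):
            k += 1
    beta = np.zeros(p)
    if k == 0:
        return 0.0, yty, beta
    idx = np.empty(k, np.int64)
    t = 0
    for j in range(p):
        if mask & (1 << j):
            idx[t] = j
            t += 1
    A = np.empty((k, k))
    for r in range(k):
        for c in range(k):
            A[r, c] = tau2 * G[idx[r], idx[c]]
        A[r, r] += 1.0
    L = np.linalg.cholesky(A)
    logdet = 0.0
    for r in range(k):
        logdet += 2.0 * math.log(L[r, r])
    gs = np.empty(k)
    for r in range(k):
        gs[r] = g[idx[r]]
    w = np.linalg.solve(A, gs)
    q = yty
    for r in range(k):
        q -= tau2 * gs[r] * w[r]
    if q < 1e-12:
        q = 1e-12
    for r in range(k):
        beta[idx[r]] = tau2 * w[r]
    return logdet, q, beta


@njit(cache=True)
def _log_ml(logdet, q, n, a, b):
    # constants shared across subsets of the same node are dropped
    return -0.5 * logdet - (a + 0.5 * n) * math.log(b + 0.5 * q)


@njit(cache=True)
def gibbs_node(G, g, yty, n, tau2, a, b, prior_pi, n_iter, burn, seed):
    """Run the collapsed Gibbs chain for one node.

    Parameters
    ----------
    G : (p, p) Gram matrix X'X of the candidate predictors.
    g : (p,) X'y.
    yty : y'y.
    n : number of samples.
    tau2, a, b, prior_pi : prior hyperparameters.
    n_iter, burn : total sweeps and discarded initial sweeps.
    seed : RNG seed (chain is fully deterministic given it).

    Returns
    -------
    ppi : (p,) posterior inclusion frequency per candidate predictor.
    coef : (p,) posterior-mean regression coefficients (zero when excluded).
    sigma2 : posterior-mean noise variance.
    """
    p = g.shape[0]
    np.random.seed(seed)
    ml_cache = Dict.empty(types.int64, types.float64)
    q_cache = Dict.empty(types.int64, types.float64)
    beta_cache = Dict.empty(types.int64, types.float64[:])

    mask = 0
    logdet, q, beta = _subset_quantities(G, g, yty, tau2, mask, p)
    cur_ml = _log_ml(logdet, q, n, a, b)
    ml_cache[0] = cur_ml
    q_cache[0] = q
    beta_cache[0] = beta

    lpo = math.log(prior_pi) - math.log(1.0 - prior_pi)
    ppi = np.zeros(p)
    coef = np.zeros(p)
    sigma2 = 0.0
    kept = 0
    half_n = 0.5 * n

    for it in range(n_iter):
        for k in range(p):
            bit = np.int64(1) << k
            mask_in = mask | bit
            mask_out = mask & ~bit
            if mask_in not in ml_cache:
                ld, qq, bb = _subset_quantities(G, g, yty, tau2, mask_in, p)
                ml_cache[mask_in] = _log_ml(ld, qq, n, a, b)
                q_cache[mask_in] = qq
                beta_cache[mask_in] = bb
            if mask_out not in ml_cache:
                ld, qq, bb = _subset_quantities(G, g, yty, tau2, mask_out, p)
                ml_cache[mask_out] = _log_ml(ld, qq, n, a, b)
                q_cache[mask_out] = qq
                beta_cache[mask_out] = bb
            logit = ml_cache[mask_in] - ml_cache[mask_out] + lpo
            if logit > 35.0:
                pr = 1.0
            elif logit < -35.0:
                pr = 0.0
            else:
                pr = 1.0 / (1.0 + math.exp(-logit))
            if np.random.random() < pr:
                mask = mask_in
            else:
                mask = mask_out
        if it >= burn:
            kept += 1
            for k in range(p):
                if mask & (np.int64(1) << k):
                    ppi[k] += 1.0
            bcur = beta_cache[mask]
            for k in range(p):
                coef[k] += bcur[k]
            sigma2 += (b + 0.5 * q_cache[mask]) / (a + half_n - 1.0)
    inv = 1.0 / kept
    for k in range(p):
        ppi[k] *= inv
        coef[k] *= inv
    sigma2 *= inv
    return ppi, coef, sigma2


def log_marginal_likelihood(
    X: np.ndarray,
    y: np.ndarray,
    subset: np.ndarray,
    tau2: float,
    a: float,
    b: float,
) -> float:
    """Exact (unnormalised) log marginal likelihood of one predictor subset.

    Pure NumPy counterpart of the cached quantity used inside the Gibbs chain;
    exposed for the enumeration oracle. ``subset`` is a boolean mask over the
    columns of ``X``.
    """
    n = len(y)
    yty = float(y @ y)
    Xs = X[:, subset]
    k = Xs.shape[1]
    if k == 0:
        logdet, q = 0.0, yty
    else:
        A = np.eye(k) + tau2 * (Xs.T @ Xs)
        L = np.linalg.cholesky(A)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        gs = Xs.T @ y
        w = np.linalg.solve(A, gs)
        q = max(yty - tau2 * float(gs @ w), 1e-12)
    return -0.5 * logdet - (a + 0.5 * n) * math.log(b + 0.5 * q)
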