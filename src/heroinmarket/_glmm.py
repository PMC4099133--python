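"""Maximum-likelihood random-intercept logistic regression.

The marginal likelihood of a logistic regression with a Gaussian random
intercept per group,

    logit P(y_ij = 1) = b0 + b1 * x_ij + u_j,   u_j ~ N(0, sigma^2),

has no closed form; the per-group integral over u_j is evaluated with
Gauss-Hermite quadrature and the likelihood is maximized over
(b0, b1, log sigma) with L-BFGS-B.  Twenty-five nodes are ample for the
random-effect scales seen here (sigma ~ 1).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_expit


def _group_index(groups: np.ndarray) -> tuple[np.ndarray, int]:
    _, idx = np.unique(groups, return_inverse=True)
    return idx, int(idx.max()) + 1


def _negloglik(params: np.ndarray, x: np.ndarray, y: np.ndarray,
               gidx: np.ndarray, n_groups: int,
               nodes: np.ndarray, logw: np.ndarray) -> float:
    b0, b1, log_sigma = params
    sigma = np.exp(log_sigma)
    eta = b0 + b1 * x                                     # (n,)
    u = np.sqrt(2.0) * sigma * nodes                      # (k,)
    # log Bernoulli likelihood per observation per node: (k, n)
    sign = 2.0 * y - 1.0
    ll_obs = log_expit(sign[None, :] * (eta[None, :] + u[:, None]))
    # sum within groups -> (k, n_groups)
    ll_grp = np.empty((len(nodes), n_groups))
    for k in range(len(nodes)):
        ll_grp[k] = np.bincount(gidx, weights=ll_obs[k], minlength=n_groups)
    # log integral per group via log-sum-exp over nodes
    a = ll_grp + logw[:, None]
    amax = a.max(axis=0)
    log_int = amax + np.log(np.exp(a - amax).sum(axis=0))
    return -float(log_int.sum())


def fit_random_intercept_logistic(groups, x, y, start=None, n_nodes: int = 25):
    """Return (beta0, beta1, sigma2, converged)."""
    groups = np.asarray(groups)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gidx, n_groups = _group_index(groups)
    # sort by group so np.add.at is cache friendly (optional micro-opt)
    order = np.argsort(gidx, kind="stable")
    gidx, x, y = gidx[order], x[order], y[order]

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    logw = np.log(weights) - 0.5 * np.log(np.pi)

    if start is None:
        start = (0.0, 0.0)
    x0 = np.array([start[0], start[1], np.log(0.5)])
    scale = max(1.0, float(np.std(x)) or 1.0)
    xs = x / scale

    def obj(p):
        return _negloglik(p, xs, y, gidx, n_groups, nodes, logw)

    res = minimize(obj, np.array([x0[0], x0[1] * scale, x0[2]]),
                   method="L-BFGS-B",
                   bounds=[(-60, 60), (-60, 60), (np.log(1e-4), np.log(50.0))])
    b0, b1s, log_sigma = res.x
    sigma2 = float(np.exp(log_sigma) ** 2)
    return float(b0), float(b1s / scale), sigma2, bool(res.success)
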