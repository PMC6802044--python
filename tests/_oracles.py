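"""Independent oracles used by the test suite.

These deliberately avoid the package's own numerical paths: the marginal
likelihood oracle integrates by Gauss-Hermite quadrature group by group, the
mode oracle is a derivative-free simplex search on an independently written
penalized log-likelihood, and the NPV oracle is the closed-form annuity
factor.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def gh_marginal_loglik(beta: np.ndarray, sigma: float, X: np.ndarray,
                       y: np.ndarray, groups: np.ndarray, n_nodes: int = 51) -> float:
    """Single-factor binomial-GLMM marginal log-likelihood by per-group
    Gauss-Hermite quadrature (the integral factors over groups)."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    u = np.sqrt(2.0) * sigma * nodes
    w = weights / np.sqrt(np.pi)
    eta = X @ beta
    ll = 0.0
    for g in np.unique(groups):
        m = groups == g
        e = eta[m][:, None] + u[None, :]
        contrib = y[m][:, None] * e - np.logaddexp(0.0, e)
        ll += np.log(w @ np.exp(contrib.sum(axis=0)))
    return float(ll)


def penalized_loglik_dense(u: np.ndarray, beta: np.ndarray, sigmas, X, y,
                           v_idx, t_idx) -> float:
    """Penalized log-likelihood written independently of the package (no
    Gaussian normalization constants; they do not move the mode)."""
    sv, st = sigmas
    nv = int(v_idx.max()) + 1
    uv, ut = u[:nv], u[nv:]
    eta = X @ beta + uv[v_idx] + ut[t_idx]
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return ll - 0.5 * float(uv @ uv) / sv**2 - 0.5 * float(ut @ ut) / st**2


def mode_by_simplex(beta, sigmas, X, y, v_idx, t_idx) -> np.ndarray:
    """Derivative-free search for the random-effect mode."""
    nv, nt = int(v_idx.max()) + 1, int(t_idx.max()) + 1
    res = minimize(
        lambda u: -penalized_loglik_dense(u, beta, sigmas, X, y, v_idx, t_idx),
        np.zeros(nv + nt), method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000})
    assert res.success
    return res.x


def npv_by_annuity(investment_cost: float, cash_flow: float, rate: float, t: int) -> float:
    """Closed-form NPV via the annuity factor a_t = (1 - (1+r)^-t) / r."""
    if rate == 0.0:
        return cash_flow * t - investment_cost
    a_t = (1.0 - (1.0 + rate) ** (-t)) / rate
    return -investment_cost + cash_flow * a_t
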