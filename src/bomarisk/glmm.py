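"""Binomial logistic models with two crossed Gaussian random intercepts.

The marginal likelihood of a logistic model with crossed random intercepts
(here: village and survey year) does not factor over groups, so it is
approximated by the Laplace method: for random effects ``u`` with penalized
log-likelihood

    h(u) = sum_i [ y_i eta_i - log(1 + exp(eta_i)) ] + log N(u_v; 0, s_v^2 I)
           + log N(u_t; 0, s_t^2 I),        eta_i = x_i' beta + u_{v(i)} + u_{t(i)}

the approximate marginal log-likelihood is

    l(beta, s) ~= h(u_hat) + (q/2) log(2 pi) - (1/2) log det H(u_hat)

where ``u_hat`` is the mode of ``h`` (found by Newton iteration), ``H`` the
negated Hessian of ``h`` at the mode, and ``q`` the number of random effects.
As both standard deviations tend to zero the value converges to the ordinary
logistic log-likelihood.

Estimation maximizes the Laplace log-likelihood over ``(beta, log s_v,
log s_t)`` with a quasi-Newton outer optimizer; standard errors come from the
inverse of a numerically differentiated outer Hessian (fixed-effects block).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import norm

from .study_io import BomaRecord, VisitRecord
from .synthetic import CONTINUOUS_TERMS, DEFAULT_WET_MONTHS, TERMS, CovariateVector, _COV_ATTR

log = logging.getLogger(__name__)

RESPONSES = ("attempt", "success")

#: Standard deviations estimated below this are reported as exactly zero.
SIGMA_BOUNDARY = 1e-4


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One candidate fixed-effects structure (random factors are always the
    crossed pair village x year)."""

    response: str
    fixed_terms: tuple[str, ...]
    random_factors: tuple[str, str] = ("village", "year")

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")
        if "intercept" not in self.fixed_terms:
            raise ValueError("intercept must be included")
        if len(set(self.fixed_terms)) != len(self.fixed_terms):
            raise ValueError("fixed terms must be unique")
        unknown = set(self.fixed_terms) - set(TERMS)
        if unknown:
            raise ValueError(f"unknown term(s): {sorted(unknown)}")

    @property
    def k(self) -> int:
        """Parameter count: fixed effects (incl. intercept) + 2 variance components."""
        return len(self.fixed_terms) + 2


@dataclasses.dataclass
class GlmmFit:
    """A fitted crossed-random-intercepts binomial model."""

    spec: ModelSpec
    terms: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    sigma_village: float
    sigma_year: float
    loglik: float
    n_obs: int
    k: int
    converged: bool
    u_hat: dict[str, dict]
    scaling: dict[str, tuple[float, float]]  # term -> (mean, sd) used to z-score

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def coef_se(self, term: str) -> float:
        return float(self.se[self.terms.index(term)])

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "terms": list(self.terms),
            "beta": [float(b) for b in self.beta],
            "se": [float(s) for s in self.se],
            "sigma_village": self.sigma_village,
            "sigma_year": self.sigma_year,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "k": self.k,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# Model table
# ---------------------------------------------------------------------------

def binarize_response(visits: Sequence[VisitRecord],
                      bomas: Sequence[BomaRecord],
                      covariates: Mapping[str, CovariateVector],
                      response: str = "attempt",
                      wet_months: frozenset[int] = DEFAULT_WET_MONTHS) -> pd.DataFrame:
    """Build the boma-month model table for the spotted-hyena response.

    ``y`` is 1 if the window recorded any spotted-hyena raid attempt
    (``response="attempt"``) or any successful spotted-hyena raid
    (``response="success"``), else 0. The analysis is restricted to spotted
    hyena, the species with enough events for spatiotemporal modelling.
    """
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}")
    info = {b.boma_id: b for b in bomas}
    rows = []
    for v in visits:
        b = info.get(v.boma_id)
        if b is None:
            raise ValueError(f"visit references unknown boma {v.boma_id!r}")
        counts = v.attempts if response == "attempt" else v.successes
        cov = covariates[b.boma_id]
        rows.append({
            "boma_id": b.boma_id,
            "village": b.village,
            "year": v.visit_date.year,
            "season": int(v.visit_date.month in wet_months),
            "boma_type": int(b.arm == "experimental"),
            **{t: getattr(cov, _COV_ATTR[t]) for t in CONTINUOUS_TERMS},
            "y": int(counts.get("spotted_hyena", 0) > 0),
        })
    return pd.DataFrame(rows)


def design_matrix(table: pd.DataFrame, fixed_terms: Sequence[str],
                  scaling: Mapping[str, tuple[float, float]] | None = None
                  ) -> tuple[np.ndarray, dict[str, tuple[float, float]]]:
    """Design matrix for the fixed effects, z-scoring continuous covariates.

    Returns the matrix and the (mean, sd) pairs used, so that fits on new data
    can reuse the training scaling.
    """
    n = len(table)
    cols, used = [], {}
    for t in fixed_terms:
        if t == "intercept":
            cols.append(np.ones(n))
        elif t in CONTINUOUS_TERMS:
            x = table[t].to_numpy(float)
            if scaling is not None and t in scaling:
                mu, sd = scaling[t]
            else:
                mu, sd = float(x.mean()), float(x.std())
            sd = sd if sd > 0 else 1.0
            used[t] = (mu, sd)
            cols.append((x - mu) / sd)
        else:
            cols.append(table[t].to_numpy(float))
    return np.column_stack(cols), used


def _group_codes(table: pd.DataFrame) -> tuple[np.ndarray, list, np.ndarray, list]:
    v_levels, v_idx = np.unique(table["village"].to_numpy(), return_inverse=True)
    t_levels, t_idx = np.unique(table["year"].to_numpy(), return_inverse=True)
    return v_idx, list(v_levels), t_idx, list(t_levels)


# ---------------------------------------------------------------------------
# Laplace machinery
# ---------------------------------------------------------------------------

_LOG_2PI = float(np.log(2.0 * np.pi))


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


@dataclasses.dataclass
class ModeResult:
    u_village: np.ndarray
    u_year: np.ndarray
    hessian: np.ndarray  # negated penalized Hessian over active effects
    penalized_loglik: float
    converged: bool
    n_iter: int


def penalized_loglik_mode(beta: np.ndarray,
                          sigmas: tuple[float, float],
                          X: np.ndarray,
                          y: np.ndarray,
                          v_idx: np.ndarray,
                          t_idx: np.ndarray,
                          u0: np.ndarray | None = None,
                          tol: float = 1e-8,
                          max_iter: int = 100) -> ModeResult:
    """Newton maximization of the penalized log-likelihood over the random
    effects, returning the conditional modes and the negated Hessian there.

    A factor with standard deviation exactly 0 is pinned at ``u = 0``
    (infinite penalty) and dropped from the active set.
    """
    sv, st = sigmas
    if sv < 0 or st < 0:
        raise ValueError("sigmas must be >= 0")
    nv = int(v_idx.max()) + 1 if len(v_idx) else 0
    nt = int(t_idx.max()) + 1 if len(t_idx) else 0
    active_v, active_t = sv > 0.0, st > 0.0
    q = (nv if active_v else 0) + (nt if active_t else 0)
    xb = X @ beta

    def unpack(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        uv = u[:nv] if active_v else np.zeros(nv)
        ut = u[nv:] if active_v else u
        ut = ut if active_t else np.zeros(nt)
        return uv, (ut if active_t else np.zeros(nt))

    def pen_ll(u: np.ndarray) -> float:
        uv, ut = unpack(u)
        ll = _bernoulli_loglik(xb + uv[v_idx] + ut[t_idx], y)
        if active_v:
            ll += -0.5 * float(uv @ uv) / sv**2 - nv * (np.log(sv) + 0.5 * _LOG_2PI)
        if active_t:
            ll += -0.5 * float(ut @ ut) / st**2 - nt * (np.log(st) + 0.5 * _LOG_2PI)
        return ll

    if q == 0:
        eta = xb
        return ModeResult(np.zeros(nv), np.zeros(nt), np.empty((0, 0)),
                          _bernoulli_loglik(eta, y), True, 0)

    u = np.zeros(q) if u0 is None or len(u0) != q else u0.copy()
    converged = False
    H = np.empty((q, q))
    for it in range(1, max_iter + 1):
        uv, ut = unpack(u)
        eta = xb + uv[v_idx] + ut[t_idx]
        p = expit(eta)
        w = p * (1.0 - p)
        grads = []
        if active_v:
            grads.append(np.bincount(v_idx, weights=y - p, minlength=nv) - uv / sv**2)
        if active_t:
            grads.append(np.bincount(t_idx, weights=y - p, minlength=nt) - ut / st**2)
        g = np.concatenate(grads)

        # Negated penalized Hessian (positive definite).
        blocks = []
        if active_v:
            Hv = np.diag(np.bincount(v_idx, weights=w, minlength=nv) + 1.0 / sv**2)
            blocks.append(Hv)
        if active_t:
            Ht = np.diag(np.bincount(t_idx, weights=w, minlength=nt) + 1.0 / st**2)
            blocks.append(Ht)
        if active_v and active_t:
            M = np.zeros((nv, nt))
            np.add.at(M, (v_idx, t_idx), w)
            H = np.block([[blocks[0], M], [M.T, blocks[1]]])
        else:
            H = blocks[0]

        if np.max(np.abs(g)) < tol:
            converged = True
            break
        step = np.linalg.solve(H, g)
        # Newton decrement: quadratic-model improvement left; at machine
        # precision of the objective further iterations cannot help.
        if 0.5 * float(g @ step) < 1e-12 * (1.0 + abs(pen_ll(u))):
            converged = True
            break
        # Backtracking line search on the penalized log-likelihood.
        f0, alpha = pen_ll(u), 1.0
        for _ in range(30):
            if pen_ll(u + alpha * step) >= f0 - 1e-12:
                break
            alpha *= 0.5
        u = u + alpha * step

    if not converged:
        log.warning("random-effect mode search did not reach tolerance in %d iterations", max_iter)
    uv, ut = unpack(u)
    return ModeResult(uv, ut, H, pen_ll(u), converged, it)


def laplace_loglik(beta: np.ndarray,
                   sigmas: tuple[float, float],
                   X: np.ndarray,
                   y: np.ndarray,
                   v_idx: np.ndarray,
                   t_idx: np.ndarray,
                   u0: np.ndarray | None = None,
                   mode: ModeResult | None = None) -> float:
    """Laplace-approximated marginal log-likelihood (see module docstring)."""
    if mode is None:
        mode = penalized_loglik_mode(beta, sigmas, X, y, v_idx, t_idx, u0=u0)
    q = mode.hessian.shape[0]
    if q == 0:
        return mode.penalized_loglik
    sign, logdet = np.linalg.slogdet(mode.hessian)
    if sign <= 0:
        raise np.linalg.LinAlgError(
            "singular penalized Hessian: a village or year level is degenerate")
    return mode.penalized_loglik + 0.5 * q * _LOG_2PI - 0.5 * logdet


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_LOG_SIGMA_MIN, _LOG_SIGMA_MAX = np.log(1e-6), np.log(50.0)


def fit(spec: ModelSpec, table: pd.DataFrame,
        scaling: Mapping[str, tuple[float, float]] | None = None,
        fixed_sigmas: tuple[float, float] | None = None,
        max_iter: int = 500) -> GlmmFit:
    """Maximum Laplace likelihood fit of ``spec`` on a boma-month table.

    Deterministic given the input: optimization starts at ``beta = 0`` and
    ``sigma = 1`` for both factors. Variance components estimated below
    ``SIGMA_BOUNDARY`` are reported as zero. ``fixed_sigmas`` pins the two
    standard deviations (e.g. ``(0, 0)`` collapses the model to plain
    logistic regression) and optimizes the fixed effects only.
    """
    if table.empty:
        raise ValueError("model table is empty")
    y = table["y"].to_numpy(float)
    X, used_scaling = design_matrix(table, spec.fixed_terms, scaling)
    v_idx, v_levels, t_idx, t_levels = _group_codes(table)
    p = X.shape[1]

    def sigmas_of(theta: np.ndarray) -> tuple[float, float]:
        if fixed_sigmas is not None:
            return fixed_sigmas
        sv, st = np.exp(np.clip(theta[p:], _LOG_SIGMA_MIN, _LOG_SIGMA_MAX))
        return float(sv), float(st)

    # The inner Newton always cold-starts at u = 0 so the objective is a pure
    # function of theta; warm-starting across evaluations corrupts the outer
    # finite-difference gradients.
    def negll(theta: np.ndarray) -> float:
        beta = theta[:p]
        sig = sigmas_of(theta)
        mode = penalized_loglik_mode(beta, sig, X, y, v_idx, t_idx)
        return -laplace_loglik(beta, sig, X, y, v_idx, t_idx, mode=mode)

    n_free = p if fixed_sigmas is not None else p + 2
    theta0 = np.zeros(n_free)  # beta = 0, sigma = 1
    bounds = [(None, None)] * p + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)] * (n_free - p)
    res = optimize.minimize(negll, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7})
    theta = res.x
    beta = theta[:p]
    sv, st = sigmas_of(theta)
    loglik = -negll(theta)
    converged = bool(res.success)
    if np.max(np.abs(beta)) > 15.0:
        warnings.warn("extreme coefficient magnitude: possible complete separation",
                      RuntimeWarning, stacklevel=2)
        converged = False

    # Outer observed information by central finite differences; the inverse
    # fixed-effects block gives the Wald covariance.
    H = _numerical_hessian(negll, theta)
    cov_all = np.linalg.pinv(H)
    vcov = cov_all[:p, :p]
    diag = np.diag(vcov).copy()
    se = np.sqrt(np.where(diag > 0, diag, np.nan))
    if np.any(~np.isfinite(se)):
        log.warning("undefined standard error for term(s): %s",
                    [t for t, s in zip(spec.fixed_terms, se) if not np.isfinite(s)])

    mode = penalized_loglik_mode(beta, (sv, st), X, y, v_idx, t_idx)
    sv_out = 0.0 if sv < SIGMA_BOUNDARY else float(sv)
    st_out = 0.0 if st < SIGMA_BOUNDARY else float(st)
    u_hat = {
        "village": {lvl: float(u) for lvl, u in zip(v_levels, mode.u_village)},
        "year": {int(lvl): float(u) for lvl, u in zip(t_levels, mode.u_year)},
    }
    return GlmmFit(
        spec=spec,
        terms=tuple(spec.fixed_terms),
        beta=beta.copy(),
        se=se,
        vcov=vcov,
        sigma_village=sv_out,
        sigma_year=st_out,
        loglik=float(loglik),
        n_obs=len(table),
        k=spec.k,
        converged=converged and mode.converged,
        u_hat=u_hat,
        scaling=dict(used_scaling),
    )


def _numerical_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        fpp = f(x + ei); fmm = f(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# Wald inference
# ---------------------------------------------------------------------------

def wald_table(fit_result: GlmmFit) -> pd.DataFrame:
    """Wald summary per fixed effect: z, two-sided p, 95% CI, odds ratio.

    The odds ratio is ``exp(estimate)``; the intercept row leaves it blank
    (baseline odds, not a comparison).
    """
    rows = []
    for i, term in enumerate(fit_result.terms):
        est = float(fit_result.beta[i])
        se = float(fit_result.se[i])
        if np.isfinite(se) and se > 0:
            z = est / se
            pval = 2.0 * norm.sf(abs(z))
            lo, hi = est - 1.96 * se, est + 1.96 * se
        else:
            z = pval = lo = hi = np.nan
            log.warning("wald_table: undefined SE for term %r", term)
        rows.append({
            "term": term,
            "estimate": est,
            "se": se,
            "z": z,
            "p": pval,
            "ci_low": lo,
            "ci_high": hi,
            "odds_ratio": np.nan if term == "intercept" else float(np.exp(est)),
        })
    return pd.DataFrame(rows)
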