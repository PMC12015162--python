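"""Generalized linear mixed models with two crossed random intercepts.

Fits models of the form

    g(E[y_i]) = x_i' beta + u_{p(i)} + v_{r(i)},
    u_j ~ N(0, sigma_p^2),  v_k ~ N(0, sigma_r^2)  (independent, crossed)

for a gamma outcome (links: inverse, identity; shape parameter estimated)
or a Bernoulli outcome (links: logit, probit), by Laplace approximation:

* **inner problem** — for fixed variance/shape parameters theta, the joint
  penalized log-likelihood is maximized over (beta, u, v) with Fisher-scoring
  Newton steps (the lme4 ``nAGQ = 0`` flavour, where the fixed effects are
  profiled together with the random effects);
* **outer problem** — the Laplace log-likelihood
  ``l_pen(mode) - sum(log sigma) * q - 0.5 * logdet(H)`` is maximized over
  theta with Nelder–Mead.

The (p+P+R) Hessian is handled by block elimination of the diagonal
response-index block, so cost scales with the number of participants, not
with the number of response-index levels. AIC is computed from the same
Laplace likelihood for every family/link so model grids are internally
comparable. Wald standard errors come from the (beta, u, v) block of the
inverse Hessian at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, sparse, special, stats

_LOG2PI = np.log(2.0 * np.pi)
_SIGMA_FLOOR = 1e-4


class GlmmError(ValueError):
    pass


# ----------------------------------------------------------------- families

class _Family:
    """Gradient s = dl/deta and Fisher weight w = E[-d2l/deta2] per point."""
    n_extra_params = 0

    def check_eta(self, eta: np.ndarray) -> bool:
        return True


class Binomial(_Family):
    name = "binomial"

    def __init__(self, link: str = "logit"):
        if link not in ("logit", "probit"):
            raise GlmmError(f"unsupported binomial link {link!r}")
        self.link = link

    def mean(self, eta):
        if self.link == "logit":
            return special.expit(eta)
        return stats.norm.cdf(eta)

    def loglik(self, y, eta, extra):
        p = np.clip(self.mean(eta), 1e-12, 1 - 1e-12)
        return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))

    def grad_weight(self, y, eta, extra):
        if self.link == "logit":
            p = special.expit(eta)
            return y - p, np.maximum(p * (1 - p), 1e-10)
        p = np.clip(stats.norm.cdf(eta), 1e-12, 1 - 1e-12)
        phi = stats.norm.pdf(eta)
        return (y - p) * phi / (p * (1 - p)), np.maximum(phi ** 2 / (p * (1 - p)), 1e-10)

    def init_eta(self, y):
        p = np.clip((y + 0.5) / 2.0, 0.02, 0.98)
        return special.logit(p) if self.link == "logit" else stats.norm.ppf(p)


class Gamma(_Family):
    """Gamma with mean mu and shape k: Var(y) = mu^2 / k."""
    name = "gamma"
    n_extra_params = 1  # log k

    def __init__(self, link: str = "inverse"):
        if link not in ("inverse", "identity"):
            raise GlmmError(f"unsupported gamma link {link!r}")
        self.link = link

    def check_eta(self, eta):
        # both links require a strictly positive mean
        return bool(np.all(eta > 1e-10))

    def mean(self, eta):
        return 1.0 / eta if self.link == "inverse" else eta

    def loglik(self, y, eta, extra):
        k = np.exp(extra[0])
        mu = self.mean(eta)
        return float(np.sum(k * np.log(k) - special.gammaln(k) + (k - 1) * np.log(y)
                            - k * np.log(mu) - k * y / mu))

    def grad_weight(self, y, eta, extra):
        k = np.exp(extra[0])
        mu = self.mean(eta)
        if self.link == "inverse":
            return -k * (y - mu), k * mu ** 2
        return k * (y - mu) / mu ** 2, k / mu ** 2

    def init_eta(self, y):
        mu = np.maximum(y, np.mean(y) * 0.05)
        return 1.0 / mu if self.link == "inverse" else mu


def make_family(family: str, link: str) -> _Family:
    if family == "binomial":
        return Binomial(link)
    if family == "gamma":
        return Gamma(link)
    raise GlmmError(f"unsupported family {family!r}")


# ------------------------------------------------------------------ results

@dataclass
class GlmmResult:
    converged: bool
    family: str
    link: str
    coef_names: list
    coefficients: np.ndarray = field(default_factory=lambda: np.array([]))
    std_errors: np.ndarray = field(default_factory=lambda: np.array([]))
    sigma_participant: float = np.nan
    sigma_response_index: float = np.nan
    shape: Optional[float] = None       # gamma only
    loglik: float = np.nan
    aic: float = np.nan
    n_obs: int = 0
    n_params: int = 0
    df_resid: int = 0
    random_effects: dict = field(default_factory=dict)
    vcov: Optional[np.ndarray] = None
    theta: Optional[np.ndarray] = None  # outer parameters at the optimum
    message: str = ""

    @property
    def test_statistics(self) -> np.ndarray:
        return self.coefficients / self.std_errors

    @property
    def p_values(self) -> np.ndarray:
        z = self.test_statistics
        if self.family == "gamma":
            return 2 * stats.t.sf(np.abs(z), df=max(self.df_resid, 1))
        return 2 * stats.norm.sf(np.abs(z))

    def coef_table(self):
        import pandas as pd
        return pd.DataFrame({
            "estimate": self.coefficients,
            "std_error": self.std_errors,
            "statistic": self.test_statistics,
            "p_value": self.p_values,
        }, index=self.coef_names)


# -------------------------------------------------------------------- fitter

class _Workspace:
    """Per-dataset precomputation shared across outer evaluations."""

    def __init__(self, X, y, part_idx, resp_idx):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.pi = np.asarray(part_idx, dtype=np.intp)
        self.ri = np.asarray(resp_idx, dtype=np.intp)
        self.n, self.p = self.X.shape
        self.P = int(self.pi.max()) + 1 if self.n else 0
        self.R = int(self.ri.max()) + 1 if self.n else 0

    def eta(self, beta, u, v):
        return self.X @ beta + u[self.pi] + v[self.ri]


def _inner_mode(ws: _Workspace, fam: _Family, extra, sig_p, sig_r,
                start=None, max_iter=50, tol=1e-8):
    """Fisher-scoring mode of the joint penalized log-likelihood.

    Returns (beta, u, v, penalized loglik, logdet H, ok).
    The dense block is (beta, u); the response-index block is diagonal and
    eliminated by a Schur complement.
    """
    n, p, P, R = ws.n, ws.p, ws.P, ws.R
    inv_sp2 = 1.0 / sig_p ** 2
    inv_sr2 = 1.0 / sig_r ** 2
    if start is None:
        beta = np.zeros(p)
        u = np.zeros(P)
        v = np.zeros(R)
        eta0 = fam.init_eta(ws.y)
        # crude start: intercept-only least squares on the link scale
        beta, *_ = np.linalg.lstsq(ws.X, eta0, rcond=None)
    else:
        beta, u, v = (a.copy() for a in start)

    def pen_ll(beta, u, v):
        eta = ws.eta(beta, u, v)
        if not fam.check_eta(eta):
            return -np.inf, eta
        return (fam.loglik(ws.y, eta, extra)
                - 0.5 * inv_sp2 * float(u @ u)
                - 0.5 * inv_sr2 * float(v @ v)), eta

    ll, eta = pen_ll(beta, u, v)
    if not np.isfinite(ll):
        # fall back to a feasible start
        beta = np.zeros(p)
        u = np.zeros(P)
        v = np.zeros(R)
        if p:
            mu0 = float(np.mean(ws.y))
            if isinstance(fam, Gamma):
                beta[0] = 1.0 / mu0 if fam.link == "inverse" else mu0
        ll, eta = pen_ll(beta, u, v)
        if not np.isfinite(ll):
            return beta, u, v, -np.inf, np.nan, False

    logdet = np.nan
    for _ in range(max_iter):
        s, w = fam.grad_weight(ws.y, eta, extra)
        # gradient
        g_beta = ws.X.T @ s
        g_u = np.bincount(ws.pi, weights=s, minlength=P) - inv_sp2 * u
        g_v = np.bincount(ws.ri, weights=s, minlength=R) - inv_sr2 * v
        # Hessian blocks (Fisher weights)
        WX = ws.X * w[:, None]
        A = ws.X.T @ WX                                            # p x p
        Bup = np.zeros((p, P))
        for j in range(p):
            Bup[j] = np.bincount(ws.pi, weights=WX[:, j], minlength=P)
        Du = np.bincount(ws.pi, weights=w, minlength=P) + inv_sp2   # diag P
        Dv = np.bincount(ws.ri, weights=w, minlength=R) + inv_sr2   # diag R
        Brv = np.zeros((p, R))
        for j in range(p):
            Brv[j] = np.bincount(ws.ri, weights=WX[:, j], minlength=R)
        C = sparse.coo_matrix((w, (ws.pi, ws.ri)), shape=(P, R)).toarray()

        d = p + P
        M = np.empty((d, d))
        M[:p, :p] = A
        M[:p, p:] = Bup
        M[p:, :p] = Bup.T
        M[p:, p:] = np.diag(Du)
        M[p:, p:] += 0.0
        Bv = np.vstack([Brv, C])                                   # d x R
        # Schur complement of the diagonal v-block
        Bv_scaled = Bv / Dv[None, :]
        S = M - Bv_scaled @ Bv.T
        g_d = np.concatenate([g_beta, g_u])
        rhs = g_d - Bv_scaled @ g_v
        try:
            cf = np.linalg.cholesky(S + 1e-10 * np.eye(d))
        except np.linalg.LinAlgError:
            return beta, u, v, -np.inf, np.nan, False
        step_d = _chol_solve(cf, rhs)
        step_v = (g_v - Bv.T @ step_d) / Dv
        # Laplace volume: logdet of the (u, v) random-effects block only
        # (fixed effects are profiled, not integrated)
        Suv = np.diag(Du) - (C / Dv[None, :]) @ C.T
        try:
            cf_uv = np.linalg.cholesky(Suv + 1e-10 * np.eye(P))
        except np.linalg.LinAlgError:
            return beta, u, v, -np.inf, np.nan, False
        logdet_uv = 2.0 * float(np.sum(np.log(np.diag(cf_uv)))) + float(np.sum(np.log(Dv)))
        # step halving on the penalized log-likelihood
        t = 1.0
        for _ in range(30):
            nb = beta + t * step_d[:p]
            nu = u + t * step_d[p:]
            nv = v + t * step_v
            ll_new, eta_new = pen_ll(nb, nu, nv)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        else:
            break
        delta = ll_new - ll
        beta, u, v, ll, eta = nb, nu, nv, ll_new, eta_new
        logdet = logdet_uv
        if abs(delta) < tol * (abs(ll) + 1.0):
            return beta, u, v, ll, logdet, True
    return beta, u, v, ll, logdet, np.isfinite(logdet)


def _chol_solve(cf, b):
    y = np.linalg.solve(cf, b)
    return np.linalg.solve(cf.T, y)


def fit_glmm_raw(X, y, part_idx, resp_idx, *, family: str, link: str,
                 coef_names=None, theta0=None) -> GlmmResult:
    """Fit the crossed random-intercept GLMM.

    Parameters
    ----------
    X : (n, p) fixed-effects design matrix (include the intercept column).
    y : outcome (binary 0/1 or positive continuous).
    part_idx, resp_idx : integer grouping codes (0-based) for the
        participant and response-index random intercepts.
    """
    fam = make_family(family, link)
    ws = _Workspace(X, y, part_idx, resp_idx)
    if ws.n == 0:
        raise GlmmError("empty data")
    if ws.n <= ws.p:
        raise GlmmError("more fixed-effect columns than observations")
    for j in range(ws.p):
        col = ws.X[:, j]
        if j > 0 and np.all(col == col[0]):
            raise GlmmError(f"fixed-effect column {j} is constant (single-level predictor)")
    if coef_names is None:
        coef_names = [f"b{j}" for j in range(ws.p)]
    q = ws.P + ws.R
    npar = ws.p + 2 + fam.n_extra_params

    if family == "gamma" and np.any(ws.y <= 0):
        raise GlmmError("gamma outcome must be positive")
    if theta0 is None:
        if family == "gamma":
            k0 = max(0.5, (np.mean(ws.y) / np.std(ws.y)) ** 2
                     if np.std(ws.y) > 0 else 1.0)
            theta0 = np.array([np.log(0.2), np.log(0.2), np.log(k0)])
        else:
            theta0 = np.array([np.log(0.5), np.log(0.5)])
    else:
        theta0 = np.asarray(theta0, dtype=float)
        if len(theta0) != 2 + fam.n_extra_params:
            raise GlmmError("theta0 has the wrong length for this family")

    cache = {"start": None}

    def neg_laplace(theta):
        sig_p = max(np.exp(theta[0]), _SIGMA_FLOOR)
        sig_r = max(np.exp(theta[1]), _SIGMA_FLOOR)
        extra = theta[2:]
        beta, u, v, ll_pen, logdet, ok = _inner_mode(
            ws, fam, extra, sig_p, sig_r, start=cache["start"])
        if not ok or not np.isfinite(ll_pen):
            cache["start"] = None
            return 1e12
        cache["start"] = (beta, u, v)
        cache["mode"] = (beta, u, v, sig_p, sig_r, extra, logdet)
        # log integral over (u, v); the 2*pi factors of prior and Laplace
        # volume cancel except through logdet
        ll = (ll_pen - ws.P * np.log(sig_p) - ws.R * np.log(sig_r)
              - 0.5 * logdet + 0.5 * (ws.P + ws.R) * 0.0)
        return -ll

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            neg_laplace, theta0, method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 400})
    if not np.isfinite(res.fun) or res.fun >= 1e11 or "mode" not in cache:
        return GlmmResult(converged=False, family=family, link=link,
                          coef_names=list(coef_names), n_obs=ws.n,
                          message="outer optimization failed")
    # re-evaluate at the optimum so the cached mode matches res.x
    neg_ll = neg_laplace(res.x)
    if neg_ll >= 1e11:
        return GlmmResult(converged=False, family=family, link=link,
                          coef_names=list(coef_names), n_obs=ws.n,
                          message="mode evaluation failed at optimum")
    beta, u, v, sig_p, sig_r, extra, _ = cache["mode"]

    # Wald covariance: (beta, u) block of the inverse joint Hessian
    eta = ws.eta(beta, u, v)
    s, w = fam.grad_weight(ws.y, eta, extra)
    vcov = _joint_vcov(ws, w, sig_p, sig_r)
    se = np.sqrt(np.maximum(np.diag(vcov)[:ws.p], 0.0))

    ll = -neg_ll
    df_resid = ws.n - npar
    return GlmmResult(
        converged=True, family=family, link=link, coef_names=list(coef_names),
        coefficients=beta, std_errors=se,
        sigma_participant=sig_p, sigma_response_index=sig_r,
        shape=float(np.exp(extra[0])) if fam.n_extra_params else None,
        loglik=ll, aic=-2.0 * ll + 2.0 * npar,
        n_obs=ws.n, n_params=npar, df_resid=df_resid,
        random_effects={"participant": u, "response_index": v},
        vcov=vcov[:ws.p, :ws.p], theta=np.asarray(res.x),
        message=res.message if res.message else "ok")


def _joint_vcov(ws: _Workspace, w, sig_p, sig_r):
    p, P, R = ws.p, ws.P, ws.R
    WX = ws.X * w[:, None]
    A = ws.X.T @ WX
    Bup = np.zeros((p, P))
    Brv = np.zeros((p, R))
    for j in range(p):
        Bup[j] = np.bincount(ws.pi, weights=WX[:, j], minlength=P)
        Brv[j] = np.bincount(ws.ri, weights=WX[:, j], minlength=R)
    Du = np.bincount(ws.pi, weights=w, minlength=P) + 1.0 / sig_p ** 2
    Dv = np.bincount(ws.ri, weights=w, minlength=R) + 1.0 / sig_r ** 2
    C = sparse.coo_matrix((w, (ws.pi, ws.ri)), shape=(P, R)).toarray()
    d = p + P
    M = np.empty((d, d))
    M[:p, :p] = A
    M[:p, p:] = Bup
    M[p:, :p] = Bup.T
    M[p:, p:] = np.diag(Du)
    Bv = np.vstack([Brv, C])
    S = M - (Bv / Dv[None, :]) @ Bv.T
    return np.linalg.inv(S + 1e-10 * np.eye(d))
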