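"""Restricted maximum likelihood for Gaussian mixed models.

The engine fits models of the form

    y = X b + sum_r Z_r u_r,   u_r ~ N(0, C_r(theta_r))

where each covariance contribution ``C_r`` is one of

* ``Iid`` / ``ScaledKnown``  -- sigma^2 I or sigma^2 K for a known K;
* ``DiagGroups``             -- heterogeneous variances by group;
* ``FixedKnown``             -- a fully known covariance entering V with
  coefficient exactly 1 (used for the Stage-1 estimation errors);
* ``Kron(K, inner)``         -- separable K (x) Gamma with Gamma following a
  second-order factor-analytic (FA2), unstructured, or rank-one
  (correlation fixed at 1) model.

The restricted log-likelihood is

    l_R = -1/2 [ log|V| + log|X'V^-1 X| + y'Py + (n - p) log 2*pi ]

maximized over unconstrained transforms (log variances, log-Cholesky
factors) with analytic gradients via L-BFGS-B; Nelder-Mead is the fallback.
AIC = -2 l_R + 2 k where k counts only the free (co)variance parameters, so
fixed-known terms contribute nothing -- required for meaningful comparisons
of models with and without the Stage-1 error term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

__all__ = [
    "Iid", "ScaledKnown", "FixedKnown", "DiagGroups", "Kron",
    "FA2Inner", "UnstructuredInner", "RankOneInner",
    "RandomTerm", "RemlFit", "reml_fit", "fa2_rotate", "compare_aic",
]

_LOG2PI = np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# covariance structures

class Iid:
    """sigma^2 * I_q."""

    def __init__(self, q):
        self.q = q
        self.n_params = 1

    def init_params(self, scale):
        return np.array([np.log(scale)])

    def cov(self, th):
        return np.exp(th[0]) * np.eye(self.q)

    def grads(self, th):
        return [np.exp(th[0]) * np.eye(self.q)]

    def variances(self, th):
        return np.exp(th[:1])

    def describe(self, th):
        return {"variance": float(np.exp(th[0]))}


class ScaledKnown:
    """sigma^2 * K for a known symmetric K."""

    def __init__(self, K):
        self.K = np.asarray(K, float)
        self.n_params = 1

    def init_params(self, scale):
        d = np.mean(np.diag(self.K))
        return np.array([np.log(scale / max(d, 1e-12))])

    def cov(self, th):
        return np.exp(th[0]) * self.K

    def grads(self, th):
        return [np.exp(th[0]) * self.K]

    def variances(self, th):
        return np.exp(th[:1])

    def describe(self, th):
        return {"variance": float(np.exp(th[0]))}


class FixedKnown:
    """Known covariance with no free parameters (coefficient exactly 1)."""

    n_params = 0

    def __init__(self, V0, name="fixed"):
        self.V0 = np.asarray(V0, float)
        w = la.eigvalsh(self.V0, subset_by_index=[0, 0])[0] if self.V0.size else 0.0
        if w < -1e-6 * max(1.0, np.abs(self.V0).max()):
            raise ValueError(f"fixed covariance '{name}' is not PSD (min eig {w:.3g})")

    def init_params(self, scale):
        return np.empty(0)

    def cov(self, th):
        return self.V0

    def grads(self, th):
        return []

    def variances(self, th):
        return np.empty(0)

    def describe(self, th):
        return {"fixed": True}


class DiagGroups:
    """Diagonal covariance with one variance per group (heterogeneous)."""

    def __init__(self, codes, n_groups):
        self.codes = np.asarray(codes, int)
        self.g = n_groups
        self.n_params = n_groups

    def init_params(self, scale):
        return np.full(self.g, np.log(scale))

    def cov(self, th):
        return np.diag(np.exp(th)[self.codes])

    def grads(self, th):
        out = []
        v = np.exp(th)
        for k in range(self.g):
            d = np.zeros(len(self.codes))
            d[self.codes == k] = v[k]
            out.append(np.diag(d))
        return out

    def variances(self, th):
        return np.exp(th)

    def describe(self, th):
        return {"variances": np.exp(th)}


class FA2Inner:
    """Gamma = Lambda Lambda' + diag(psi), Lambda s x 2 with Lambda[0,1] = 0."""

    def __init__(self, s):
        if s < 3:
            raise ValueError("FA2 requires >= 3 levels; use UnstructuredInner")
        self.s = s
        self.n_params = 3 * s - 1  # s + (s-1) loadings + s log psi

    def _unpack(self, th):
        s = self.s
        lam = np.zeros((s, 2))
        lam[:, 0] = th[:s]
        lam[1:, 1] = th[s:2 * s - 1]
        psi = np.exp(th[2 * s - 1:])
        return lam, psi

    def init_params(self, scale):
        s = self.s
        th = np.zeros(self.n_params)
        th[:s] = np.sqrt(scale / 2.0)
        th[s:2 * s - 1] = 0.1 * np.sqrt(scale / 2.0)
        th[2 * s - 1:] = np.log(scale / 2.0)
        return th

    def cov(self, th):
        lam, psi = self._unpack(th)
        return lam @ lam.T + np.diag(psi)

    def grads(self, th):
        s = self.s
        lam, psi = self._unpack(th)
        out = []
        for i in range(s):  # d/d lam[i,0]
            d = np.zeros((s, s))
            d[i, :] += lam[:, 0]
            d[:, i] += lam[:, 0]
            out.append(d)
        for i in range(1, s):  # d/d lam[i,1]
            d = np.zeros((s, s))
            d[i, :] += lam[:, 1]
            d[:, i] += lam[:, 1]
            out.append(d)
        for i in range(s):  # d/d log psi_i
            d = np.zeros((s, s))
            d[i, i] = psi[i]
            out.append(d)
        return out

    def variances(self, th):
        return np.diag(self.cov(th))

    def describe(self, th):
        lam, psi = self._unpack(th)
        return {"loadings": lam, "psi": psi, "gamma": self.cov(th)}


class UnstructuredInner:
    """Unstructured PSD Gamma via log-Cholesky (row-wise lower triangle)."""

    def __init__(self, t):
        self.t = t
        self.n_params = t * (t + 1) // 2

    def _L(self, th):
        t = self.t
        L = np.zeros((t, t))
        k = 0
        for i in range(t):
            for j in range(i + 1):
                L[i, j] = np.exp(th[k]) if i == j else th[k]
                k += 1
        return L

    def init_params(self, scale):
        th = np.zeros(self.n_params)
        k = 0
        for i in range(self.t):
            for j in range(i + 1):
                if i == j:
                    th[k] = 0.5 * np.log(scale)
                k += 1
        return th

    def cov(self, th):
        L = self._L(th)
        return L @ L.T

    def grads(self, th):
        t = self.t
        L = self._L(th)
        out = []
        k = 0
        for i in range(t):
            for j in range(i + 1):
                dL = np.zeros((t, t))
                dL[i, j] = L[i, j] if i == j else 1.0
                d = dL @ L.T
                out.append(d + d.T)
                k += 1
        return out

    def variances(self, th):
        return np.diag(self.cov(th))

    def describe(self, th):
        return {"gamma": self.cov(th)}


class RankOneInner:
    """Gamma = s s' (correlations all fixed at 1), s_j > 0."""

    def __init__(self, t):
        self.t = t
        self.n_params = t

    def init_params(self, scale):
        return np.full(self.t, 0.5 * np.log(scale))

    def cov(self, th):
        s = np.exp(th)
        return np.outer(s, s)

    def grads(self, th):
        s = np.exp(th)
        out = []
        for i in range(self.t):
            # d Gamma / d th_i = s_i * (e_i s' + s e_i')
            d = np.zeros((self.t, self.t))
            d[i, :] = s[i] * s
            d[:, i] += s[i] * s
            out.append(d)
        return out

    def variances(self, th):
        return np.exp(2 * np.asarray(th))

    def describe(self, th):
        return {"gamma": self.cov(th)}


class Kron:
    """Separable covariance K (x) Gamma(theta) with K known."""

    def __init__(self, K, inner):
        self.K = np.asarray(K, float)
        self.inner = inner
        self.n_params = inner.n_params

    def init_params(self, scale):
        d = np.mean(np.diag(self.K))
        return self.inner.init_params(scale / max(d, 1e-12))

    def cov(self, th):
        return np.kron(self.K, self.inner.cov(th))

    def grads(self, th):
        return [np.kron(self.K, dG) for dG in self.inner.grads(th)]

    def variances(self, th):
        return self.inner.variances(th)

    def describe(self, th):
        return self.inner.describe(th)


# ---------------------------------------------------------------------------

@dataclass
class RandomTerm:
    """One random-effect term: Z (n_obs x q, or None for identity) + structure."""

    name: str
    struct: object
    Z: np.ndarray | None = None


@dataclass
class RemlFit:
    """Result of a restricted-likelihood fit."""

    loglik: float
    aic: float
    n_free_params: int
    params: dict            # term name -> raw parameter vector
    components: dict        # term name -> structure-specific description
    beta: np.ndarray
    beta_cov: np.ndarray
    converged: bool
    boundary: dict          # term name -> bool array of variances at boundary
    n_iter: int
    y: np.ndarray = field(repr=False, default=None)
    X: np.ndarray = field(repr=False, default=None)
    terms: list = field(repr=False, default=None)
    V: np.ndarray = field(repr=False, default=None)

    def variance_table(self):
        import pandas as pd
        rows = []
        for name, desc in self.components.items():
            if "variance" in desc:
                rows.append({"term": name, "variance": desc["variance"]})
            elif "variances" in desc:
                for i, v in enumerate(np.atleast_1d(desc["variances"])):
                    rows.append({"term": f"{name}[{i}]", "variance": float(v)})
            elif "gamma" in desc:
                g = desc["gamma"]
                for i in range(g.shape[0]):
                    rows.append({"term": f"{name}[{i},{i}]", "variance": float(g[i, i])})
        return pd.DataFrame(rows)


def _split(theta, terms):
    out, k = [], 0
    for t in terms:
        out.append(theta[k:k + t.struct.n_params])
        k += t.struct.n_params
    return out


def _build_V(terms, thetas, n):
    V = np.zeros((n, n))
    for t, th in zip(terms, thetas):
        C = t.struct.cov(th)
        V += C if t.Z is None else t.Z @ C @ t.Z.T
    return V


def _neg_ll(theta, y, X, terms, n, p, want_grad):
    thetas = _split(theta, terms)
    V = _build_V(terms, thetas, n)
    try:
        cf = la.cho_factor(V, lower=True, check_finite=False)
    except la.LinAlgError:
        return (np.inf, np.zeros_like(theta)) if want_grad else np.inf
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ViX = la.cho_solve(cf, X, check_finite=False)
    Viy = la.cho_solve(cf, y, check_finite=False)
    XtViX = X.T @ ViX
    try:
        cfx = la.cho_factor(XtViX, lower=True, check_finite=False)
    except la.LinAlgError:
        return (np.inf, np.zeros_like(theta)) if want_grad else np.inf
    logdetX = 2.0 * np.sum(np.log(np.diag(cfx[0])))
    beta = la.cho_solve(cfx, X.T @ Viy, check_finite=False)
    Py = Viy - ViX @ beta
    quad = float(y @ Py)
    nll = 0.5 * (logdetV + logdetX + quad + (n - p) * _LOG2PI)
    if not want_grad:
        return nll
    # P = Vi - ViX (X'ViX)^-1 ViX'
    Vi = la.cho_solve(cf, np.eye(n), check_finite=False)
    P = Vi - ViX @ la.cho_solve(cfx, ViX.T, check_finite=False)
    grad = np.zeros_like(theta)
    k = 0
    for t, th in zip(terms, thetas):
        if t.struct.n_params == 0:
            continue
        if t.Z is None:
            M = P
            v = Py
        else:
            PZ = P @ t.Z
            M = t.Z.T @ PZ
            v = t.Z.T @ Py
        for dC in t.struct.grads(th):
            g = 0.5 * (np.sum(M * dC) - v @ dC @ v)
            grad[k] = g
            k += 1
    return nll, grad


def reml_fit(y, X, terms, maxiter: int = 300, tol: float = 1e-9) -> RemlFit:
    """Fit a Gaussian mixed model by REML.

    Parameters
    ----------
    y : array (n,)
    X : array (n, p), full column rank fixed-effect design.
    terms : list of RandomTerm
        Together they must yield a positive-definite V; typically the last
        term is an i.i.d. residual.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    n = len(y)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design X is rank deficient")
    # deterministic start: half the phenotypic variance split across terms
    b0, *_ = np.linalg.lstsq(X, y, rcond=None)
    vy = max(float(np.var(y - X @ b0, ddof=min(p, n - 1))), 1e-10)
    n_free = sum(t.struct.n_params for t in terms)
    if n_free == 0:
        raise ValueError("model has no free variance parameters")
    nv = sum(1 for t in terms if t.struct.n_params > 0)
    theta0 = np.concatenate([
        t.struct.init_params(vy / (2.0 * nv)) if t.struct.n_params else np.empty(0)
        for t in terms
    ])
    ll0 = -_neg_ll(theta0, y, X, terms, n, p, False)

    res = minimize(_neg_ll, theta0, args=(y, X, terms, n, p, True),
                   jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7})
    ok = res.success and np.isfinite(res.fun)
    if (not ok) or (-res.fun < ll0 - 1e-6):
        logger.info("reml_fit: gradient path failed (%s); Nelder-Mead restart",
                    getattr(res, "message", ""))
        start = res.x if np.isfinite(res.fun) and -res.fun >= ll0 else theta0
        res2 = minimize(_neg_ll, start, args=(y, X, terms, n, p, False),
                        method="Nelder-Mead",
                        options={"maxiter": 200 * n_free, "xatol": 1e-6,
                                 "fatol": 1e-8})
        if np.isfinite(res2.fun) and res2.fun <= res.fun:
            res = res2
        ok = np.isfinite(res.fun)
    if not ok:
        raise RuntimeError(f"REML did not converge: {res.message}")

    theta = res.x
    thetas = _split(theta, terms)
    # final quantities at the optimum
    V = _build_V(terms, thetas, n)
    cf = la.cho_factor(V, lower=True, check_finite=False)
    ViX = la.cho_solve(cf, X, check_finite=False)
    XtViX = X.T @ ViX
    beta_cov = la.inv(XtViX)
    beta = beta_cov @ (X.T @ la.cho_solve(cf, y, check_finite=False))

    boundary = {}
    params = {}
    comps = {}
    floor = 1e-8 * vy
    for t, th in zip(terms, thetas):
        params[t.name] = th.copy()
        comps[t.name] = t.struct.describe(th)
        v = np.atleast_1d(t.struct.variances(th))
        if v.size:
            b = v < floor
            if b.any():
                logger.info("reml_fit: term '%s' variance at boundary (B)", t.name)
            boundary[t.name] = b

    ll = -res.fun
    fit = RemlFit(
        loglik=float(ll), aic=float(-2 * ll + 2 * n_free),
        n_free_params=n_free, params=params, components=comps,
        beta=beta, beta_cov=beta_cov, converged=True, boundary=boundary,
        n_iter=int(getattr(res, "nit", -1)),
        y=y, X=X, terms=terms, V=V,
    )
    return fit


def fa2_rotate(Lambda, Psi):
    """Rotate FA2 loadings (varimax) and return uniplot coordinates.

    Returns a dict with rotated loadings, per-level coordinates
    ``Lambda_i / sqrt(Gamma_ii)`` and squared radii (the proportion of
    genetic variance explained by the two latent factors, in [0, 1]).
    Levels with Gamma_ii = 0 are flagged and get NaN coordinates.
    """
    from statsmodels.multivariate.factor_rotation import rotate_factors

    Lambda = np.asarray(Lambda, float)
    Psi = np.asarray(Psi, float)
    if np.allclose(Lambda, 0):
        L = Lambda.copy()
    else:
        L, _ = rotate_factors(Lambda, "varimax")
    for j in range(L.shape[1]):  # sign convention: non-negative column mean
        if L[:, j].mean() < 0:
            L[:, j] = -L[:, j]
    gam = np.sum(L ** 2, axis=1) + Psi
    ok = gam > 0
    coords = np.full_like(L, np.nan)
    coords[ok] = L[ok] / np.sqrt(gam[ok, None])
    r2 = np.full(L.shape[0], np.nan)
    r2[ok] = np.sum(coords[ok] ** 2, axis=1)
    return {"loadings": L, "coords": coords, "squared_radius": r2,
            "excluded": ~ok}


def compare_aic(fit_a: RemlFit, fit_b: RemlFit) -> float:
    """Delta AIC = AIC_a - AIC_b for fits of the same response/fixed design."""
    if fit_a.y is None or fit_b.y is None or len(fit_a.y) != len(fit_b.y) \
            or not np.allclose(fit_a.y, fit_b.y):
        raise ValueError("fits use different response vectors")
    return float(fit_a.aic - fit_b.aic)
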