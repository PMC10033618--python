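"""Multi-trait selection response and restricted indices.

Under truncation selection with intensity i on a linear index c'b_hat, the
expected multi-trait response is x = i B c / sigma(c'b_hat), where
B = var_n(b_hat) is the covariance of the predicted breeding values over
the n candidates.  Imposing var(c'b_hat) = 1 turns the attainable set of
responses into the ellipsoid x' B^-1 x <= i^2, so the maximum-gain response
solves the convex program

    max_x  c'x   subject to  x' B^-1 x <= 1

with per-trait equality or inequality constraints added for a restricted
index (restricted traits leave the objective).  The index coefficients are
recovered as c = B^-1 x at intensity 1 and reported for standardized traits
with unit norm.  After whitening the quadratic form the feasible set is the
unit ball cut by halfspaces, so the program is solved exactly by
enumerating active sets of the (few) linear constraints; the
one-equality-constraint Kempthorne-Nordskog solution is the analytic
special case used to validate it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .blup import BlupState, gamma_for

logger = logging.getLogger(__name__)

__all__ = ["ResponseModel", "GainResult", "response_matrix", "gain",
           "ellipse_slice"]


@dataclass
class ResponseModel:
    """B = var_n(b_hat) with the per-trait genetic SDs used for scaling."""

    B: np.ndarray
    Delta: np.ndarray  # per-trait sigma_b = sqrt(s2_A + gamma^2 s2_D)
    gamma: float
    dims: list


@dataclass
class GainResult:
    """Optimal response and index coefficients from the gain program."""

    response: np.ndarray          # trait scale, at the requested intensity
    response_std: np.ndarray      # units of genetic SD
    coefficients: np.ndarray      # standardized-trait index, unit norm
    merit_gain: float
    intensity: float
    dims: list
    restrictions: dict


def response_matrix(state: BlupState, what: str = "BV") -> ResponseModel:
    """B matrix: population covariance of predicted merit components.

    For traits j, k:  B_jk = mean diag(L) - mean(L) + cov of the fixed
    means, with L = [I gI] cov(u_hat_j, u_hat_k) [I gI]' and
    mu_j = [W gF] delta_j (fixed markers + heterosis), g the dominance
    weight gamma.
    """
    fit = state.fit
    t = state.t_add
    gamma = gamma_for(what, fit.ploidy)
    n = state.n
    na = n * t
    B = np.zeros((t, t))
    M = np.zeros((t, n))  # fixed-effect means per trait
    if fit.W_fix is not None and fit.marker_cols:
        for (mk, dim), _ in fit.marker_cols.items():
            try:
                est, _ = state.fixed_effect(f"marker[{mk}]", dim if t > 1 else None)
            except KeyError:
                continue
            j = list(fit.spec.fixed_markers).index(mk)
            kd = state.dims.index(dim) if dim in state.dims else 0
            M[kd] += fit.W_fix[:, j] * est
    if fit.f_cols and fit.F is not None:
        Fc = -(fit.F - fit.F_mean)
        for dim, _ in fit.f_cols.items():
            try:
                est, _ = state.fixed_effect("heterosis", dim if t > 1 else None)
            except KeyError:
                continue
            kd = state.dims.index(dim) if dim in state.dims else 0
            M[kd] += gamma * Fc * est

    def block(mat, j, k, which):
        if which == "a":
            idx_j = np.arange(n) * t + j
            idx_k = np.arange(n) * t + k
        else:
            td = state.t_dom
            jj = j if td == t else 0
            kk = k if td == t else 0
            idx_j = na + np.arange(n) * td + jj
            idx_k = na + np.arange(n) * td + kk
        return mat[np.ix_(idx_j, idx_k)]

    V = state.var_u_hat
    for j in range(t):
        for k in range(j, t):
            L = block(V, j, k, "a")
            if state.t_dom:
                td = state.t_dom
                jj = j if td == t else 0
                kk = k if td == t else 0
                ia_j = np.arange(n) * t + j
                ia_k = np.arange(n) * t + k
                id_j = na + np.arange(n) * td + jj
                id_k = na + np.arange(n) * td + kk
                L = (V[np.ix_(ia_j, ia_k)]
                     + gamma * V[np.ix_(ia_j, id_k)]
                     + gamma * V[np.ix_(id_j, ia_k)]
                     + gamma ** 2 * V[np.ix_(id_j, id_k)])
            val = float(np.mean(np.diag(L)) - np.mean(L))
            val += float(np.mean(M[j] * M[k]) - np.mean(M[j]) * np.mean(M[k]))
            B[j, k] = B[k, j] = val
    sA = np.diag(fit.gamma_A)
    sD = np.diag(fit.gamma_D) if fit.gamma_D is not None else np.zeros(t)
    if len(sD) < t:
        sD = np.repeat(sD[0], t)
    Delta = np.sqrt(sA + gamma ** 2 * sD)
    return ResponseModel(B=B, Delta=Delta, gamma=gamma, dims=list(state.dims))


def _max_on_ball(c, eqs, ineqs, tol=1e-9):
    """Maximize c'z over the unit ball with linear constraints, exactly.

    The objective is linear, the feasible set is the intersection of the
    ball with halfspaces/hyperplanes, so the optimum has some active set of
    inequality constraints; with few restricted traits the active sets can
    be enumerated and each equality-constrained subproblem solved in closed
    form (project onto the constraint flat, spend the remaining radius
    along the projected gradient).
    """
    from itertools import combinations

    t = len(c)
    best, best_val = None, -np.inf
    m = len(ineqs)
    for r in range(m + 1):
        for active in combinations(range(m), r):
            A = [row for row, _v in eqs] + [ineqs[k][0] for k in active]
            b = [v for _row, v in eqs] + [ineqs[k][1] for k in active]
            if A:
                A = np.asarray(A, float)
                b = np.asarray(b, float)
                Ap = np.linalg.pinv(A)
                zp = Ap @ b                      # min-norm point on the flat
                if np.abs(A @ zp - b).max() > 1e-7:
                    continue                     # inconsistent constraints
                r2 = 1.0 - float(zp @ zp)
                if r2 < -tol:
                    continue                     # flat misses the ball
                # orthonormal basis of the nullspace of A
                _u, s, vt = np.linalg.svd(A)
                rank = int((s > s.max() * max(A.shape) * 1e-12).sum()) if s.size else 0
                N = vt[rank:].T
            else:
                zp = np.zeros(t)
                r2 = 1.0
                N = np.eye(t)
            g = N.T @ c if N.size else np.zeros(0)
            ng = np.linalg.norm(g)
            z = zp.copy()
            if ng > 0 and r2 > tol:
                z = zp + N @ (np.sqrt(r2) * g / ng)
            ok = all(
                (sgn * (row @ z) <= sgn * v + 1e-7)
                for row, v, sgn in ineqs)
            if ok and float(z @ z) <= 1 + 1e-7:
                val = float(c @ z)
                if val > best_val + 1e-12:
                    best_val, best = val, z
    return best


def _pinv_with_report(B):
    w = np.linalg.eigvalsh(B)
    if w.min() < 1e-10 * max(w.max(), 1e-300):
        rank = int((w > 1e-10 * w.max()).sum())
        logger.warning("B is singular (rank %d of %d); using pseudo-inverse",
                       rank, B.shape[0])
        return np.linalg.pinv(B, rcond=1e-10)
    return np.linalg.inv(B)


def gain(B, merit_weights, restrictions=None, intensity: float = 1.0,
         Delta=None, dims=None) -> GainResult:
    """Maximum-gain (possibly restricted) selection response.

    Parameters
    ----------
    B : t x t PSD response covariance (or a ResponseModel).
    merit_weights : relative weights for standardized traits; restricted
        traits are removed from the objective regardless of their weight.
    restrictions : dict trait -> ("=", v) | ("<=", v) | (">=", v), with
        trait given by name (if dims known) or index; v on the trait scale.
    intensity : selection intensity i for the reported response.
    Delta : per-trait genetic SDs for standardized reporting (default 1).
    """
    if isinstance(B, ResponseModel):
        Delta = B.Delta if Delta is None else Delta
        dims = B.dims if dims is None else dims
        B = B.B
    B = np.asarray(B, float)
    t = B.shape[0]
    Delta = np.ones(t) if Delta is None else np.asarray(Delta, float)
    dims = list(range(t)) if dims is None else list(dims)
    w = np.asarray(merit_weights, float)
    restrictions = dict(restrictions or {})
    ridx = {}
    for key, val in restrictions.items():
        k = dims.index(key) if key in dims else int(key)
        ridx[k] = val if isinstance(val, tuple) else ("=", float(val))
    c_obj = w / Delta
    for k in ridx:
        c_obj[k] = 0.0
    if not np.any(c_obj):
        raise ValueError("no unrestricted trait with nonzero weight")
    Binv = _pinv_with_report(B)

    # whitened coordinates z = L^-1 x with B = L L': the quadratic
    # constraint becomes the unit ball, which SLSQP handles robustly
    w_eig, U = np.linalg.eigh(B)
    w_eig = np.clip(w_eig, 0.0, None)
    L = U @ np.diag(np.sqrt(w_eig))
    cz = L.T @ c_obj  # objective c'x = cz'z

    eqs, ineqs = [], []
    for k, (op, v) in ridx.items():
        if op == "=":
            eqs.append((L[k], v))
        elif op == "<=":
            ineqs.append((L[k], v, +1))   # row@z <= v
        elif op == ">=":
            ineqs.append((L[k], v, -1))   # row@z >= v
        else:
            raise ValueError(f"unknown restriction operator '{op}'")
    z = _max_on_ball(cz, eqs, ineqs)
    if z is None:
        binding = [f"{dims[k]} {op} {v}" for k, (op, v) in ridx.items()]
        raise RuntimeError(
            f"restricted-gain program is infeasible; constraints: {binding}")
    x = L @ z
    cvec = Binv @ x  # Eq for coefficients at intensity 1
    coeff = cvec * Delta
    nrm = np.linalg.norm(coeff)
    if nrm > 0:
        coeff = coeff / nrm
    return GainResult(
        response=intensity * x,
        response_std=intensity * x / Delta,
        coefficients=coeff,
        merit_gain=float(intensity * c_obj @ x),
        intensity=intensity,
        dims=dims,
        restrictions={dims[k]: v for k, v in ridx.items()},
    )


@dataclass
class EllipseSlice:
    center: np.ndarray
    axes: np.ndarray        # columns = principal directions
    semi_axes: np.ndarray
    points: np.ndarray      # boundary points (2, npts)
    degenerate: bool
    traits: tuple


def ellipse_slice(B, Delta=None, traits=(0, 1), intensity: float = 1.0,
                  x_rest=None, npts: int = 200, dims=None) -> EllipseSlice:
    """2D slice of the standardized response ellipsoid x' M x = i^2,
    M = Delta B^-1 Delta.

    Non-displayed traits are fixed at ``x_rest`` (standardized scale;
    default their optimal-response value is 0, i.e. the central slice).
    """
    if isinstance(B, ResponseModel):
        Delta = B.Delta if Delta is None else Delta
        dims = B.dims if dims is None else dims
        B = B.B
    B = np.asarray(B, float)
    t = B.shape[0]
    Delta = np.ones(t) if Delta is None else np.asarray(Delta, float)
    dims = list(range(t)) if dims is None else list(dims)
    sel = tuple(dims.index(tr) if tr in dims else int(tr) for tr in traits)
    M = np.diag(Delta) @ _pinv_with_report(B) @ np.diag(Delta)
    others = [k for k in range(t) if k not in sel]
    xr = np.zeros(len(others)) if x_rest is None else np.asarray(x_rest, float)
    M11 = M[np.ix_(sel, sel)]
    level = intensity ** 2
    center = np.zeros(2)
    if others:
        M12 = M[np.ix_(sel, others)]
        M22 = M[np.ix_(others, others)]
        center = -np.linalg.solve(M11, M12 @ xr)
        level = intensity ** 2 - float(xr @ M22 @ xr) + float(center @ M11 @ center)
    wvals, wvecs = np.linalg.eigh(M11)
    degenerate = level <= 0 or wvals.min() <= 0
    if degenerate:
        semi = np.zeros(2)
        pts = np.tile(center[:, None], (1, npts))
    else:
        semi = np.sqrt(level / wvals)
        th = np.linspace(0, 2 * np.pi, npts)
        pts = center[:, None] + wvecs @ (semi[:, None] * np.vstack([np.cos(th), np.sin(th)]))
    return EllipseSlice(center=center, axes=wvecs, semi_axes=semi,
                        points=pts, degenerate=degenerate,
                        traits=tuple(traits))
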