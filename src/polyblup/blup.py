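"""Empirical BLUP, genetic merit, and reliability.

Conditional on the Stage-2 variance estimates, the model is rewritten in
standard form y = X d + Z u + e, where u stacks the additive values (one
per genotype x trait/location cell) and the non-additive values, and e
collects the GxE residual plus the Stage-1 errors (known covariance).  The
predictor is computed by whichever route is cheaper:

* MME route (len(y) > len(u)): invert the Henderson coefficient matrix;
  var(u_hat) = var(u) - C22 with C22 from the partitioned inverse.
* V route: u_hat = var(u) Z'Py with P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1
  and var(u_hat) = var(u) (Z'PZ) var(u).

Both exploit the BLUP identity cov(u, u_hat) = var(u_hat), which gives the
reliability of a merit index c with dominance weight gamma as

    r2_i = lam' var(u_hat_i) lam / lam' var(u_i) lam,  lam = [1 gamma]' (x) c.

Genetic merit follows the index formulation: user weights are divided by
the per-trait breeding-value SD sqrt(s2_A + gamma^2 s2_D) and rescaled to
unit norm; environment effects are excluded while fixed-marker and
heterosis contributions are included with weight gamma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la

from .stage2 import Stage2Fit

logger = logging.getLogger(__name__)

__all__ = ["BlupState", "blup_prep", "predict_merit", "index_coefficients",
           "mas_reliability", "gamma_for"]


def gamma_for(what: str, ploidy: int) -> float:
    """Dominance weight gamma: 0 (additive), 1 (total), or the
    breeding-value weight (phi/2 - 1)/(phi - 1)."""
    what = what.upper()
    if what == "AV":
        return 0.0
    if what == "GV":
        return 1.0
    if what == "BV":
        return (ploidy / 2.0 - 1.0) / (ploidy - 1.0)
    raise ValueError("what must be one of AV, BV, GV")


@dataclass
class BlupState:
    """Predicted random effects with their covariance, ready for iterative
    merit / reliability / GWAS queries under arbitrary index vectors."""

    fit: Stage2Fit = field(repr=False)
    ids: list
    dims: list
    t_add: int                      # additive dims per individual
    t_dom: int                      # non-additive dims per individual (0 if none)
    u_hat: np.ndarray = field(repr=False, default=None)
    var_u_hat: np.ndarray = field(repr=False, default=None)
    var_u: np.ndarray = field(repr=False, default=None)
    delta: np.ndarray = None        # fixed effects on the retained columns
    delta_cov: np.ndarray = field(repr=False, default=None)
    kept_xcols: list = None
    method: str = "MME"
    mask: list = None
    n_records: int = 0

    @property
    def n(self):
        return len(self.ids)

    def a_hat(self) -> np.ndarray:
        """Predicted additive values, (n, t_add)."""
        na = self.n * self.t_add
        return self.u_hat[:na].reshape(self.n, self.t_add)

    def d_hat(self) -> np.ndarray | None:
        """Predicted non-additive (d0) values, (n, t_dom)."""
        if self.t_dom == 0:
            return None
        na = self.n * self.t_add
        return self.u_hat[na:].reshape(self.n, self.t_dom)

    def var_a_hat(self) -> np.ndarray:
        na = self.n * self.t_add
        return self.var_u_hat[:na, :na]

    def var_d_hat(self) -> np.ndarray | None:
        if self.t_dom == 0:
            return None
        na = self.n * self.t_add
        return self.var_u_hat[na:, na:]

    def fixed_effect(self, name_contains: str, dim=None):
        """Estimate and SE of a retained fixed-effect column by name."""
        for j, nm in enumerate(self.kept_xcols):
            if name_contains in nm and (dim is None or f"[{dim}]" in nm or nm.endswith(str(dim))):
                return float(self.delta[j]), float(np.sqrt(self.delta_cov[j, j]))
        raise KeyError(name_contains)


def _mask_keep(obs: pd.DataFrame, mask) -> np.ndarray:
    keep = np.ones(len(obs), bool)
    if mask is None:
        return keep
    pairs = set()
    singles = set()
    for item in mask:
        if isinstance(item, (tuple, list)) and len(item) >= 2:
            pairs.add((str(item[0]), str(item[1])))
        else:
            singles.add(str(item))
    for k, r in enumerate(obs.itertuples()):
        if str(r.id) in singles or (str(r.id), str(r.env)) in pairs \
                or (str(r.id), str(r.dim)) in pairs:
            keep[k] = False
    return keep


def blup_prep(fit: Stage2Fit, mask=None, method: str | None = None) -> BlupState:
    """Solve for u_hat and var(u_hat), optionally masking records.

    ``mask`` is an iterable of ids, (id, env) pairs, or (id, trait) pairs
    whose Stage-1 BLUEs are removed before solving -- the device for
    cross-validation-style reliability studies (MAS vs MBS).  ``method``
    forces 'MME' or 'Vinv'; default picks whichever inversion is smaller.
    """
    obs = fit.obs
    keep = _mask_keep(obs, mask)
    if not keep.any():
        raise ValueError("mask removes every record")
    n = len(fit.geno_ids)
    t = fit.t
    gpos = {g: i for i, g in enumerate(fit.geno_ids)}
    obs_g = obs["id"].map(gpos).to_numpy()
    dpos = {d: k for k, d in enumerate(fit.dims)}
    obs_d = obs["dim"].map(dpos).to_numpy()

    # random-effect structure
    t_add = t
    var_blocks = []
    Zs = []
    if t == 1:
        Za = np.zeros((len(obs), n))
        Za[np.arange(len(obs)), obs_g] = 1.0
        var_blocks.append(fit.K_A * float(fit.gamma_A[0, 0]))
    else:
        Za = np.zeros((len(obs), n * t))
        Za[np.arange(len(obs)), obs_g * t + obs_d] = 1.0
        var_blocks.append(np.kron(fit.K_A, fit.gamma_A))
    Zs.append(Za)
    t_dom = 0
    if fit.K_D is not None and fit.gamma_D is not None:
        if t == 1 or fit.dom_shared:
            t_dom = 1
            Zd = np.zeros((len(obs), n))
            Zd[np.arange(len(obs)), obs_g] = 1.0
            var_blocks.append(fit.K_D * float(fit.gamma_D[0, 0]))
        else:
            t_dom = t
            Zd = np.zeros((len(obs), n * t))
            Zd[np.arange(len(obs)), obs_g * t + obs_d] = 1.0
            var_blocks.append(np.kron(fit.K_D, fit.gamma_D))
        Zs.append(Zd)
    Gu = la.block_diag(*var_blocks)
    Zu = np.hstack(Zs)

    # residual covariance R = gE + Stage-1 error, blockwise per environment
    R = la.block_diag(*fit.gE_cov_blocks)
    if fit.V0_blocks is not None:
        R = R + la.block_diag(*fit.V0_blocks)

    y = obs["y"].to_numpy(float)[keep]
    X = fit.X[keep]
    Zu_m = Zu[keep]
    R_m = R[np.ix_(keep, keep)]
    # drop empty/aliased fixed-effect columns after masking
    nz = np.abs(X).sum(axis=0) > 0
    X = X[:, nz]
    kept_names = [nm for nm, ok in zip(fit.xnames, nz) if ok]
    q, r, piv = la.qr(X, mode="economic", pivoting=True)
    dr = np.abs(np.diag(r))
    rank = int((dr > dr.max() * max(X.shape) * np.finfo(float).eps).sum())
    if rank < X.shape[1]:
        keep_cols = np.sort(piv[:rank])
        dropped = [kept_names[j] for j in piv[rank:]]
        logger.warning("dropping aliased fixed-effect columns after masking: %s", dropped)
        X = X[:, keep_cols]
        kept_names = [kept_names[j] for j in keep_cols]

    ny, nu = len(y), Zu.shape[1]
    if method is None:
        method = "MME" if ny >= nu else "Vinv"
    if method == "MME":
        # the MME route needs var(u)^-1; a VanRaden G built from centered
        # dosages is singular (G 1 = 0), in which case fall back to the
        # V-inversion route, which never inverts var(u)
        wmin = la.eigvalsh(Gu, subset_by_index=[0, 0])[0]
        if wmin < 1e-8 * np.mean(np.diag(Gu)):
            logger.info("var(u) singular (min eig %.3g); switching to the "
                        "V-inversion route", wmin)
            method = "Vinv"
    if method == "MME":
        Rf = la.cho_factor(R_m, lower=True, check_finite=False)
        RiX = la.cho_solve(Rf, X, check_finite=False)
        RiZ = la.cho_solve(Rf, Zu_m, check_finite=False)
        Riy = la.cho_solve(Rf, y, check_finite=False)
        Gui = la.inv(Gu)
        p = X.shape[1]
        C = np.block([[X.T @ RiX, X.T @ RiZ],
                      [Zu_m.T @ RiX, Zu_m.T @ RiZ + Gui]])
        rhs = np.concatenate([X.T @ Riy, Zu_m.T @ Riy])
        Cinv = la.inv(C)
        sol = Cinv @ rhs
        delta, u_hat = sol[:p], sol[p:]
        C22 = Cinv[p:, p:]
        var_u_hat = Gu - C22
        delta_cov = Cinv[:p, :p]
    elif method == "Vinv":
        V = Zu_m @ Gu @ Zu_m.T + R_m
        try:
            Vf = la.cho_factor(V, lower=True, check_finite=False)
        except la.LinAlgError as e:
            raise la.LinAlgError(
                f"V is singular (cond ~ {np.linalg.cond(V):.3g}); "
                "check Stage-1 vcov blocks") from e
        ViX = la.cho_solve(Vf, X, check_finite=False)
        XtViX = X.T @ ViX
        delta_cov = la.inv(XtViX)
        delta = delta_cov @ (X.T @ la.cho_solve(Vf, y, check_finite=False))
        Py = la.cho_solve(Vf, y, check_finite=False) - ViX @ delta
        ViZ = la.cho_solve(Vf, Zu_m, check_finite=False)
        PZ = ViZ - ViX @ (delta_cov @ (X.T @ ViZ))
        u_hat = Gu @ (Zu_m.T @ Py)
        var_u_hat = Gu @ (Zu_m.T @ PZ) @ Gu
    else:
        raise ValueError("method must be 'MME' or 'Vinv'")

    return BlupState(
        fit=fit, ids=list(fit.geno_ids), dims=list(fit.dims),
        t_add=t_add, t_dom=t_dom, u_hat=u_hat, var_u_hat=var_u_hat,
        var_u=Gu, delta=delta, delta_cov=delta_cov, kept_xcols=kept_names,
        method=method, mask=list(mask) if mask is not None else None,
        n_records=ny,
    )


def index_coefficients(weights, sds) -> np.ndarray:
    """Index vector c: user weights / breeding-value SDs, unit norm."""
    w = np.asarray(weights, float)
    if not np.any(w):
        raise ValueError("index weights are all zero")
    sds = np.asarray(sds, float)
    c = w / np.where(sds > 0, sds, 1.0)
    return c / np.linalg.norm(c)


def _lambda_blocks(state: BlupState, c, gamma):
    """Per-individual index vector over that individual's u-block."""
    lam_a = np.asarray(c, float)
    if state.t_dom == 0:
        return lam_a, None
    lam_d = gamma * (np.asarray(c, float) if state.t_dom == state.t_add
                     else np.array([np.sum(c)]))
    return lam_a, lam_d


def predict_merit(state: BlupState, weights=None, what: str = "BV") -> pd.DataFrame:
    """Predicted genetic merit and reliability for every individual.

    weights : per-trait (or per-location) index weights; default all ones.
    what : 'AV' (gamma=0), 'BV' (breeding value), 'GV' (total value).
    """
    fit = state.fit
    t = state.t_add
    gamma = gamma_for(what, fit.ploidy)
    if weights is None:
        weights = np.ones(t)
    w = np.asarray(weights, float)
    if w.shape != (t,):
        raise ValueError(f"need {t} weights")
    sA = np.diag(fit.gamma_A)
    sD = np.diag(fit.gamma_D) if fit.gamma_D is not None else np.zeros(t)
    if len(sD) < t:
        sD = np.repeat(sD[0], t)
    sds = np.sqrt(sA + gamma ** 2 * sD)
    c = index_coefficients(w, sds)
    lam_a, lam_d = _lambda_blocks(state, c, gamma)

    a = state.a_hat()
    merit = a @ lam_a
    d = state.d_hat()
    if d is not None:
        merit = merit + d @ lam_d
    # fixed-effect contributions: markers (weight 1) and heterosis (weight gamma)
    if fit.marker_cols and fit.W_fix is not None:
        for (mk, dim), _ in fit.marker_cols.items():
            try:
                est, _se = state.fixed_effect(f"marker[{mk}]", dim if t > 1 else None)
            except KeyError:
                continue
            j = list(fit.spec.fixed_markers).index(mk)
            kd = state.dims.index(dim) if dim in state.dims else 0
            merit = merit + c[kd] * fit.W_fix[:, j] * est
    if fit.f_cols and fit.F is not None:
        Fc = -(fit.F - fit.F_mean)  # the design column; coefficient is b
        for dim, _col in fit.f_cols.items():
            try:
                est, _se = state.fixed_effect("heterosis", dim if t > 1 else None)
            except KeyError:
                continue
            kd = state.dims.index(dim) if dim in state.dims else 0
            merit = merit + gamma * c[kd] * Fc * est

    # reliability
    n = state.n
    na = n * state.t_add
    r2 = np.zeros(n)
    for i in range(n):
        ia = np.arange(i * state.t_add, (i + 1) * state.t_add)
        idx = ia
        lam = lam_a
        if state.t_dom:
            idd = na + np.arange(i * state.t_dom, (i + 1) * state.t_dom)
            idx = np.concatenate([ia, idd])
            lam = np.concatenate([lam_a, lam_d])
        num = float(lam @ state.var_u_hat[np.ix_(idx, idx)] @ lam)
        den = float(lam @ state.var_u[np.ix_(idx, idx)] @ lam)
        r2[i] = 0.0 if den <= 0 else min(max(num / den, 0.0), 1.0)
    return pd.DataFrame({"id": state.ids, "value": merit, "r2": r2})


def mas_reliability(h2: float, rB2: float) -> float:
    """Index-theory link between marker-based (MBS) and marker-assisted
    (MAS) selection reliability:

        r2_A = r2_B + h2 (1 - r2_B)^2 / (1 - h2 r2_B)
    """
    if not (0 <= h2 <= 1 and 0 <= rB2 <= 1):
        raise ValueError("h2 and rB2 must lie in [0, 1]")
    if h2 * rB2 >= 1.0:
        return 1.0
    return rB2 + h2 * (1 - rB2) ** 2 / (1 - h2 * rB2)
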