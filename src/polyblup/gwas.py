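"""Marker effects backsolved from genomic predictions, and GWAS scores.

By the linearity of BLUP, the predicted index of additive marker effects is

    (I_m (x) c') alpha_hat = (W' G^-1 (x) c') a_hat / (phi sum_k p_k q_k)

with the dominance analog using Q, D and the digenic-substitution scaling;
the fixed heterosis regression is folded into the predicted dominance
values and therefore represented in the backsolved effects.  Standard
errors come from var(a_hat), giving standardized BLUPs that are
asymptotically standard normal; two-sided p-values are reported as
-log10(p).  The discovery threshold divides the genome-wide significance
level by the effective number of markers, computed per chromosome from the
dosage correlation matrix (Moskvina-Schmidt-style adjacency bound, with
the Li-Ji eigenvalue method as an alternative).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.linalg as la
from scipy.stats import norm

from .blup import BlupState, gamma_for, index_coefficients

logger = logging.getLogger(__name__)

__all__ = ["marker_effects", "gwas_scores", "effective_markers"]


def _inv_with_ridge(K, name):
    # centered dosages make G (and D) rank-deficient by one; the predicted
    # values lie in the range space, so the pseudo-inverse is exact there
    cond = np.linalg.cond(K)
    if cond > 1e8:
        logger.info("%s rank-deficient (cond %.3g); using pseudo-inverse "
                    "for the backsolve", name, cond)
        return np.linalg.pinv(K, rcond=1e-10)
    return la.inv(K)


def marker_effects(state: BlupState, weights=None, what: str = "BV",
                   dominance: bool | None = None) -> pd.DataFrame:
    """Backsolve additive (and digenic dominance) index effects per marker.

    Requires a fit with a pure genomic additive matrix (omega = 0); blended
    H matrices break the W W' ~ G identity the backsolve relies on.
    """
    fit = state.fit
    if fit.ms is None:
        raise ValueError("marker effects require a marker-based Stage-2 fit")
    if fit.K_A_kind == "H":
        raise ValueError("backsolve requires the G matrix; refit with omega=0")
    t = state.t_add
    gamma = gamma_for(what, fit.ploidy)
    if weights is None:
        weights = np.ones(t)
    sA = np.diag(fit.gamma_A)
    sD = np.diag(fit.gamma_D) if fit.gamma_D is not None else np.zeros(t)
    if len(sD) < t:
        sD = np.repeat(sD[0], t)
    c = index_coefficients(weights, np.sqrt(sA + gamma ** 2 * sD))

    ms = fit.ms
    p = ms.p
    keep = (p > 0) & (p < 1) & (ms.W.std(axis=0) > 0)
    W = ms.W[:, keep]
    denomA = ms.ploidy * float(np.sum(p[keep] * (1 - p[keep])))
    Ginv = _inv_with_ridge(fit.K_A, "G")
    a = state.a_hat()            # n x t
    ahat_c = a @ c               # n
    add_eff = (W.T @ (Ginv @ ahat_c)) / denomA

    out = pd.DataFrame({
        "marker": np.asarray(ms.marker_ids)[keep],
        "chrom": ms.chrom[keep],
        "position": ms.position[keep],
        "additive": add_eff,
    })
    do_dom = dominance if dominance is not None else (
        fit.spec.model == "additive-dominance")
    if do_dom:
        if fit.dom is None:
            raise ValueError("dominance effects require an additive-dominance fit")
        Q = fit.dom.Q[:, : keep.sum()] if fit.dom.Q.shape[1] == keep.sum() \
            else fit.dom.Q
        Dinv = _inv_with_ridge(fit.K_D, "D")
        d0 = state.d_hat()       # n x t_dom
        bvec = fit.b if fit.b is not None else np.zeros(t)
        # full dominance value includes the fixed heterosis part
        Fc = fit.F - fit.F_mean
        if state.t_dom == t:
            dfull = d0 - np.outer(Fc, bvec[:t])
            dhat_c = dfull @ c
        else:
            dfull = d0[:, 0] - Fc * float(np.mean(bvec))
            dhat_c = dfull * float(np.sum(c))
        out["dominance"] = (Q.T @ (Dinv @ dhat_c)) / fit.dom.denomD
    return out


def _se_from_var(W, Kinv, var_block, cvec, t, denom):
    """SE of (w_k' K^-1 (x) c') u_hat / denom for every marker column."""
    n = W.shape[0]
    if t == 1:
        Vc = var_block
    else:
        # contract the trait dimension with c on both sides
        V4 = var_block.reshape(n, t, n, t)
        Vc = np.einsum("itjs,t,s->ij", V4, cvec, cvec)
    M = Kinv @ Vc @ Kinv
    q = np.einsum("ki,ij,jk->k", W.T, M, W)
    return np.sqrt(np.maximum(q, 0.0)) / denom


def gwas_scores(effects: pd.DataFrame, state: BlupState, weights=None,
                what: str = "BV", level: float = 0.05,
                method: str = "ms") -> tuple[pd.DataFrame, float]:
    """Attach -log10 p scores and the multiple-testing threshold.

    Returns ``(table, threshold)`` with threshold = -log10(level / m_eff).
    Markers whose SE is zero (orthogonal to the data) get NaN scores and
    are flagged.
    """
    fit = state.fit
    ms = fit.ms
    t = state.t_add
    gamma = gamma_for(what, fit.ploidy)
    if weights is None:
        weights = np.ones(t)
    sA = np.diag(fit.gamma_A)
    sD = np.diag(fit.gamma_D) if fit.gamma_D is not None else np.zeros(t)
    if len(sD) < t:
        sD = np.repeat(sD[0], t)
    c = index_coefficients(weights, np.sqrt(sA + gamma ** 2 * sD))

    p = ms.p
    keep = (p > 0) & (p < 1) & (ms.W.std(axis=0) > 0)
    W = ms.W[:, keep]
    denomA = ms.ploidy * float(np.sum(p[keep] * (1 - p[keep])))
    Ginv = _inv_with_ridge(fit.K_A, "G")
    se_a = _se_from_var(W, Ginv, state.var_a_hat(), c, t, denomA)

    tab = effects.copy()
    tab["se_additive"] = se_a
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_a > 0, tab["additive"] / se_a, np.nan)
    pval = 2 * norm.sf(np.abs(z))
    tab["score"] = -np.log10(pval)
    tab["flagged"] = se_a <= 0
    if "dominance" in tab:
        Dinv = _inv_with_ridge(fit.K_D, "D")
        vd = state.var_d_hat()
        cd = c if state.t_dom == t else np.array([np.sum(c)])
        Q = fit.dom.Q
        se_d = _se_from_var(Q, Dinv, vd, cd, state.t_dom, fit.dom.denomD)
        tab["se_dominance"] = se_d
        with np.errstate(divide="ignore", invalid="ignore"):
            zd = np.where(se_d > 0, tab["dominance"] / se_d, np.nan)
        tab["score_dominance"] = -np.log10(2 * norm.sf(np.abs(zd)))
    m_eff = effective_markers(W, tab["chrom"].to_numpy(), method=method)
    threshold = -np.log10(level / m_eff)
    tab["significant"] = tab["score"] >= threshold
    return tab, threshold


def effective_markers(W, chrom, method: str = "ms") -> float:
    """Effective number of independent markers, summed over chromosomes.

    method 'ms': adjacency-style bound 1 + sum_j sqrt(1 - max_{k<j} r2_kj)
    from the dosage correlation matrix; method 'liji': Li-Ji eigenvalue
    count sum_i [1(lam_i >= 1) + frac(lam_i)].
    """
    W = np.asarray(W, float)
    chrom = np.asarray(chrom)
    total = 0.0
    for ch in pd.unique(chrom):
        sub = W[:, chrom == ch]
        m = sub.shape[1]
        if m == 1:
            total += 1.0
            continue
        R = np.corrcoef(sub, rowvar=False)
        R = np.nan_to_num(R, nan=0.0)
        if method == "ms":
            r2 = R ** 2
            keff = 1.0
            for j in range(1, m):
                keff += np.sqrt(max(0.0, 1.0 - r2[j, :j].max()))
            total += keff
        elif method == "liji":
            lam = np.linalg.eigvalsh(R)
            # round before floor: eigenvalues at integer values (exact
            # duplicates) would otherwise straddle the discontinuity
            lam = np.round(np.clip(lam, 0, None), 8)
            total += float(np.sum((lam >= 1) + (lam - np.floor(lam))))
        else:
            raise ValueError("method must be 'ms' or 'liji'")
    return total
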