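"""Stage 2: genomic mixed model on the Stage-1 BLUEs.

The single-trait model is

    BLUE[g_ij] = E_j + g_i + gE_ij + s_ij

with environment fixed effects, genotype effects g_i decomposed (when
markers are available) into additive values ~ N(0, G s2_A) plus either
i.i.d. genetic residuals or directional dominance -b F + d0 with
d0 ~ N(0, D s2_D), i.i.d. GxE (the model residual), and the Stage-1
estimation errors s_ij entering as a random term whose covariance -- the
direct sum of the Stage-1 vcov blocks -- is fully known (no free
parameter).

Multi-location models replace g_i by genotype-within-location with a
separable G (x) Gamma covariance where Gamma is second-order
factor-analytic (unstructured when fewer than 3 locations); the
non-additive correlation between locations is fixed at 1; GxE variances are
heterogeneous by location.  Multi-trait models use unstructured trait
covariances for both additive and non-additive effects and an unstructured
trait covariance for the GxE residual.

Variance explained (PVE) follows Legarra's expected-variance accounting:
for an effect with covariance K and mean mu on the gE basis,

    E[V] = [mean diag(K) - mean(K)] + [mean mu^2 - (mean mu)^2]

with weighted averages (weights = number of environments per genotype) for
genotype-indexed effects; environment main effects are excluded and rows
are normalized to sum to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MarkerSet, RelMatrix, blend_H, compute_G, compute_dominance
from .reml import (DiagGroups, FA2Inner, FixedKnown, Iid, Kron, RandomTerm,
                   RankOneInner, RemlFit, ScaledKnown, UnstructuredInner,
                   fa2_rotate, reml_fit)
from .stage1 import Stage1Fit

logger = logging.getLogger(__name__)

__all__ = ["Stage2Spec", "Stage2Fit", "fit_stage2", "pve_summary",
           "optimize_blend", "legarra_variance"]


@dataclass
class Stage2Spec:
    """Model choices for Stage 2.

    model : 'no-markers' | 'additive-residual' | 'additive-dominance'
    multi : None (single trait/location), 'loc', or 'trait'
    omega : blend weight for H = (1-omega) G + omega A (0 = pure genomic)
    fixed_markers : marker ids entered as fixed additive covariates
    """

    model: str = "additive-residual"
    multi: str | None = None
    omega: float = 0.0
    fixed_markers: tuple = ()
    trait: str | None = None  # which trait when single-trait s1 has several

    def __post_init__(self):
        if self.model not in ("no-markers", "additive-residual",
                              "additive-dominance"):
            raise ValueError(f"unknown model '{self.model}'")
        if self.multi not in (None, "loc", "trait"):
            raise ValueError(f"unknown multi '{self.multi}'")


@dataclass
class Stage2Fit:
    """Fitted Stage-2 model plus everything BLUP and GWAS need."""

    reml: RemlFit
    spec: Stage2Spec
    dims: list                      # trait names, location names, or [trait]
    geno_ids: list                  # individuals in the model (order of K rows)
    obs: pd.DataFrame               # env, id, dim, y  (one row per response)
    X: np.ndarray = field(repr=False, default=None)
    xnames: list = None
    K_A: np.ndarray = field(repr=False, default=None)
    K_A_kind: str = "iid"
    K_D: np.ndarray = field(repr=False, default=None)  # D, I, or None
    gamma_A: np.ndarray = None      # t x t additive covariance across dims
    gamma_D: np.ndarray = None      # t x t non-additive covariance (or None)
    dom_shared: bool = False        # non-additive shared across dims (multi=loc)
    sigma2_gE: np.ndarray = None    # per-dim (loc) or t x t (trait) or scalar
    V0_blocks: list = field(repr=False, default=None)   # per-env Stage-1 vcov
    gE_cov_blocks: list = field(repr=False, default=None)  # per-env gE cov
    b: np.ndarray = None            # heterosis coefficient per dim
    b_se: np.ndarray = None
    F: np.ndarray = None            # genomic inbreeding (centered covariate basis)
    F_mean: float = 0.0
    W_fix: np.ndarray = field(repr=False, default=None)  # centered fixed-marker dosages
    marker_effects: pd.DataFrame = None
    marker_cols: dict = None        # (marker, dim) -> X column
    f_cols: dict = None             # dim -> X column
    loadings: dict = None           # multi=loc FA2 rotation output
    ms: MarkerSet = field(repr=False, default=None)  # subset to geno_ids
    dom: object = field(repr=False, default=None)    # DomCoeffs on subset
    ploidy: int = 2
    pve: pd.DataFrame = None

    @property
    def aic(self):
        return self.reml.aic

    @property
    def loglik(self):
        return self.reml.loglik

    @property
    def t(self):
        return len(self.dims)

    def additive_correlation(self) -> pd.DataFrame:
        """Additive correlation matrix across traits/locations."""
        g = self.gamma_A
        d = np.sqrt(np.diag(g))
        c = g / np.outer(d, d)
        return pd.DataFrame(c, index=self.dims, columns=self.dims)


def legarra_variance(K=None, mu=None, weights=None, t=None):
    """Expected variance of a random vector on the observation basis.

    E[V] = [wmean diag(K) - wmean K] + [wmean mu^2 - (wmean mu)^2], with
    weights defaulting to 1 and t (the observation count) to sum(weights).
    """
    if weights is None:
        q = len(mu) if mu is not None else K.shape[0]
        weights = np.ones(q)
    w = np.asarray(weights, float)
    t = float(w.sum()) if t is None else float(t)
    out = 0.0
    if K is not None:
        out += float(w @ np.diag(K)) / t - float(w @ K @ w) / t ** 2
    if mu is not None:
        mu = np.asarray(mu, float)
        out += float(w @ mu ** 2) / t - (float(w @ mu) / t) ** 2
    return out


def _incidence(codes, q):
    Z = np.zeros((len(codes), q))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _assemble(s1: Stage1Fit, spec: Stage2Spec, geno, A):
    """Build response, design, terms, and caches. Returns a dict."""
    multi = spec.multi
    if multi == "trait":
        dims = list(s1.traits)
        if len(dims) < 2:
            logger.info("multi='trait' with one trait reduces to single-trait")
    else:
        tr = spec.trait or s1.traits[0]
        if tr not in s1.traits:
            raise ValueError(f"trait '{tr}' not in Stage1Fit")
        dims = [tr]
        kt = s1.traits.index(tr)
    if multi == "loc":
        if not s1.loc:
            raise ValueError("multi='loc' requires location labels in Stage 1")
        dims = list(dict.fromkeys(s1.loc[e] for e in s1.envs))
    if len(s1.envs) < 2:
        raise ValueError("Stage 2 requires >= 2 environments")

    use_markers = spec.model != "no-markers"
    if use_markers and geno is None:
        raise ValueError(f"model '{spec.model}' requires marker data")

    # individuals: union over envs, intersect marker data if present
    all_ids = list(dict.fromkeys(g for e in s1.envs for g in s1.ids[e]))
    if geno is not None:
        gset = set(geno.ids)
        dropped = [g for g in all_ids if g not in gset]
        if dropped:
            logger.warning("dropping %d phenotyped ids without marker data", len(dropped))
        all_ids = [g for g in all_ids if g in gset]
    if len(all_ids) < 2:
        raise ValueError("fewer than 2 individuals remain after id alignment")
    n = len(all_ids)
    gpos = {g: i for i, g in enumerate(all_ids)}

    ms = geno.subset(all_ids) if geno is not None else None
    K_A_kind = "iid"
    K_A = None
    K_D = None
    dom = None
    F = None
    if use_markers:
        G = compute_G(ms)
        if spec.omega > 0:
            if A is None:
                raise ValueError("omega > 0 requires a pedigree A matrix")
            K = blend_H(G, A, spec.omega)
        else:
            K = G
        K_A, K_A_kind = K.values, K.kind
        if spec.model == "additive-dominance":
            dom, Dm = compute_dominance(ms)
            K_D = Dm.values
            F = dom.F
        else:
            K_D = np.eye(n)

    # observation rows
    rows = []
    v0_blocks = []
    t = len(dims)
    st1 = s1.t
    for e in s1.envs:
        keep = [i for i, g in enumerate(s1.ids[e]) if g in gpos]
        if not keep:
            continue
        ids_e = [s1.ids[e][i] for i in keep]
        if multi == "trait":
            sel = np.array([i * st1 + k for i in keep for k in range(st1)])
            for i in keep:
                for k, trn in enumerate(dims):
                    rows.append({"env": e, "id": s1.ids[e][i], "dim": trn,
                                 "y": s1.blue[e][i, k]})
        else:
            kk = kt if multi != "loc" else (s1.traits.index(spec.trait) if spec.trait else 0)
            sel = np.array([i * st1 + kk for i in keep])
            d = s1.loc[e] if multi == "loc" else dims[0]
            for i in keep:
                rows.append({"env": e, "id": s1.ids[e][i], "dim": d,
                             "y": s1.blue[e][i, kk]})
        v0_blocks.append(s1.vcov[e][np.ix_(sel, sel)])
    obs = pd.DataFrame(rows)
    n_obs = len(obs)
    y = obs["y"].to_numpy(float)
    dpos = {d: k for k, d in enumerate(dims)}
    obs_g = obs["id"].map(gpos).to_numpy()
    obs_d = obs["dim"].map(dpos).to_numpy()

    # fixed-effect design
    envs = list(dict.fromkeys(obs["env"]))
    epos = {e: j for j, e in enumerate(envs)}
    obs_e = obs["env"].map(epos).to_numpy()
    xcols, xnames = [], []
    if multi == "trait" and t > 1:
        for e in envs:
            for d in dims:
                xcols.append(((obs_e == epos[e]) & (obs_d == dpos[d])).astype(float))
                xnames.append(f"env[{e}]:{d}")
    else:
        for e in envs:
            xcols.append((obs_e == epos[e]).astype(float))
            xnames.append(f"env[{e}]")
    marker_cols, f_cols = {}, {}
    W_fix = None
    if spec.fixed_markers:
        mpos = {mk: k for k, mk in enumerate(ms.marker_ids)}
        missing = [mk for mk in spec.fixed_markers if mk not in mpos]
        if missing:
            raise KeyError(f"fixed markers not found: {missing}")
        W_fix = ms.W[:, [mpos[mk] for mk in spec.fixed_markers]]
        for j, mk in enumerate(spec.fixed_markers):
            wcol = W_fix[obs_g, j]
            for d in dims:
                marker_cols[(mk, d)] = len(xcols)
                xcols.append(wcol * (obs_d == dpos[d]) if t > 1 else wcol)
                xnames.append(f"marker[{mk}]:{d}" if t > 1 else f"marker[{mk}]")
                if t == 1:
                    break
    F_mean = 0.0
    if spec.model == "additive-dominance":
        F_mean = float(F.mean())
        fc = -(F - F_mean)
        for d in dims:
            f_cols[d] = len(xcols)
            xcols.append(fc[obs_g] * (obs_d == dpos[d]) if t > 1 else fc[obs_g])
            xnames.append(f"heterosis[{d}]" if t > 1 else "heterosis")
            if t == 1:
                break
    X = np.column_stack(xcols)

    # random terms
    terms = []
    Z_g = _incidence(obs_g, n)
    if t > 1:
        Z_cell = _incidence(obs_g * t + obs_d, n * t)
    else:
        Z_cell = Z_g
    if use_markers:
        if t == 1:
            terms.append(RandomTerm("additive", ScaledKnown(K_A), Z_g))
        elif multi == "loc":
            inner = FA2Inner(t) if t >= 3 else UnstructuredInner(t)
            if t < 3:
                logger.info("fewer than 3 locations: FA2 replaced by unstructured")
            terms.append(RandomTerm("additive", Kron(K_A, inner), Z_cell))
        else:
            terms.append(RandomTerm("additive", Kron(K_A, UnstructuredInner(t)), Z_cell))
        nname = "dominance" if spec.model == "additive-dominance" else "genetic-residual"
        if multi == "trait" and t > 1:
            terms.append(RandomTerm(nname, Kron(K_D, UnstructuredInner(t)), Z_cell))
            dom_shared = False
        else:
            # single dim, or correlation fixed at 1 across locations:
            # one non-additive value per genotype
            terms.append(RandomTerm(nname, ScaledKnown(K_D), Z_g))
            dom_shared = multi == "loc"
    else:
        if t == 1:
            terms.append(RandomTerm("genotype", Iid(n), Z_g))
        elif multi == "loc":
            inner = FA2Inner(t) if t >= 3 else UnstructuredInner(t)
            terms.append(RandomTerm("genotype", Kron(np.eye(n), inner), Z_cell))
        else:
            terms.append(RandomTerm("genotype", Kron(np.eye(n), UnstructuredInner(t)), Z_cell))
        dom_shared = False
    if multi == "loc":
        loccodes = obs_d
        terms.append(RandomTerm("gxe", DiagGroups(loccodes, t)))
    elif multi == "trait" and t > 1:
        # unstructured t x t residual per (env, genotype) cell
        cell_codes, cells = pd.factorize(
            obs["env"].astype(str) + "\x1f" + obs["id"].astype(str))
        if not np.array_equal(cell_codes, np.repeat(np.arange(len(cells)), t)):
            raise ValueError("multi-trait Stage 2 expects complete trait records per cell")
        terms.append(RandomTerm("gxe", Kron(np.eye(len(cells)), UnstructuredInner(t))))
    else:
        terms.append(RandomTerm("gxe", Iid(n_obs)))
    return {
        "dims": dims, "geno_ids": all_ids, "obs": obs, "y": y, "X": X,
        "xnames": xnames, "terms": terms, "v0_blocks": v0_blocks,
        "K_A": K_A, "K_A_kind": K_A_kind, "K_D": K_D, "dom": dom, "F": F,
        "F_mean": F_mean, "W_fix": W_fix, "marker_cols": marker_cols,
        "f_cols": f_cols, "ms": ms, "dom_shared": dom_shared,
        "obs_g": obs_g, "obs_d": obs_d,
    }


def fit_stage2(s1: Stage1Fit, spec: Stage2Spec | None = None,
               geno: MarkerSet | None = None, A: RelMatrix | None = None,
               include_s_term: bool = True) -> Stage2Fit:
    """Fit the Stage-2 mixed model by REML.

    Parameters
    ----------
    s1 : Stage-1 output (or equivalent external BLUE + vcov input).
    spec : model choices; defaults to additive + genetic residual.
    geno : marker data (required unless model='no-markers').
    A : pedigree relationship for H-blending (omega > 0).
    include_s_term : include the Stage-1 error term with its known
        covariance (the fully efficient analysis); False reproduces the
        naive analysis that ignores Stage-1 uncertainty.
    """
    spec = spec or Stage2Spec()
    parts = _assemble(s1, spec, geno, A)
    terms = list(parts["terms"])
    if include_s_term:
        import scipy.linalg as la
        V0 = la.block_diag(*parts["v0_blocks"])
        terms.append(RandomTerm("stage1-error", FixedKnown(V0, "stage1-error")))
    fit = reml_fit(parts["y"], parts["X"], terms)
    t = len(parts["dims"])
    dims = parts["dims"]

    def gam(name):
        if name not in fit.components:
            return None
        d = fit.components[name]
        if "variance" in d:
            return np.array([[d["variance"]]])
        return np.asarray(d["gamma"])

    nname = ("dominance" if spec.model == "additive-dominance"
             else "genetic-residual" if spec.model == "additive-residual"
             else None)
    gamma_A = gam("additive") if "additive" in fit.components else gam("genotype")
    gd = gam(nname) if nname else None
    if gd is not None and parts["dom_shared"]:
        gd = np.full((t, t), float(gd[0, 0]))  # correlation fixed at 1
    elif gd is not None and gd.shape[0] == 1 and t > 1:
        gd = np.full((t, t), float(gd[0, 0]))
    if gamma_A is not None and gamma_A.shape[0] == 1 and t > 1 and spec.multi == "loc":
        pass  # cannot happen: loc model uses t x t structure
    # gE variances
    ge = fit.components["gxe"]
    if "variance" in ge:
        sigma2_gE = np.full(t, ge["variance"]) if spec.multi == "loc" else np.array([ge["variance"]])
    elif "variances" in ge:
        sigma2_gE = np.asarray(ge["variances"])
    else:
        sigma2_gE = np.asarray(ge["gamma"])

    b = b_se = None
    if parts["f_cols"]:
        idx = [parts["f_cols"][d] if d in parts["f_cols"] else parts["f_cols"][dims[0]]
               for d in (dims if len(parts["f_cols"]) > 1 else dims[:1])]
        b = fit.beta[idx]
        b_se = np.sqrt(np.diag(fit.beta_cov)[idx])
        if len(b) == 1 and t > 1:
            b = np.repeat(b, t)
            b_se = np.repeat(b_se, t)
    mrows = []
    for (mk, d), j in parts["marker_cols"].items():
        mrows.append({"marker": mk, "dim": d, "effect": fit.beta[j],
                      "se": float(np.sqrt(fit.beta_cov[j, j]))})
    marker_effects = pd.DataFrame(mrows) if mrows else None

    loadings = None
    if spec.multi == "loc" and "additive" in fit.components \
            and "loadings" in fit.components["additive"]:
        c = fit.components["additive"]
        loadings = fa2_rotate(c["loadings"], c["psi"])
        loadings["locations"] = dims

    # per-env gE covariance blocks (for the BLUP residual)
    gE_cov_blocks = []
    for e in list(dict.fromkeys(parts["obs"]["env"])):
        m = (parts["obs"]["env"] == e).to_numpy()
        d_e = parts["obs_d"][m]
        if spec.multi == "trait" and t > 1:
            ncell = int(m.sum()) // t
            gE_cov_blocks.append(np.kron(np.eye(ncell), sigma2_gE))
        elif spec.multi == "loc":
            gE_cov_blocks.append(np.diag(sigma2_gE[d_e]))
        else:
            gE_cov_blocks.append(np.eye(int(m.sum())) * float(sigma2_gE[0]))

    out = Stage2Fit(
        reml=fit, spec=spec, dims=dims, geno_ids=parts["geno_ids"],
        obs=parts["obs"], X=parts["X"], xnames=parts["xnames"],
        K_A=parts["K_A"] if parts["K_A"] is not None else np.eye(len(parts["geno_ids"])),
        K_A_kind=parts["K_A_kind"], K_D=parts["K_D"],
        gamma_A=gamma_A, gamma_D=gd, dom_shared=parts["dom_shared"],
        sigma2_gE=sigma2_gE,
        V0_blocks=parts["v0_blocks"] if include_s_term else None,
        gE_cov_blocks=gE_cov_blocks,
        b=b, b_se=b_se, F=parts["F"], F_mean=parts["F_mean"],
        W_fix=parts["W_fix"], marker_effects=marker_effects,
        marker_cols=parts["marker_cols"], f_cols=parts["f_cols"],
        loadings=loadings, ms=parts["ms"], dom=parts["dom"],
        ploidy=parts["ms"].ploidy if parts["ms"] is not None else 2,
    )
    out.pve = pve_summary(out)
    return out


def pve_summary(fit: Stage2Fit) -> pd.DataFrame:
    """Proportion of variance explained by each Stage-2 effect.

    Expected variances on the gE basis with weights = number of
    observations per genotype (per trait for multi-trait); environment main
    effects excluded; columns normalized to sum to 1.
    """
    obs = fit.obs
    dims = fit.dims
    gpos = {g: i for i, g in enumerate(fit.geno_ids)}
    n = len(fit.geno_ids)
    nname = ("dominance" if fit.spec.model == "additive-dominance"
             else "genetic residual")

    def s1_error(d):
        diag_sum = all_sum = t_d = 0.0
        for blk, e in zip(fit.V0_blocks, list(dict.fromkeys(obs["env"]))):
            sube = obs[obs["env"] == e]
            if d is not None and len(dims) > 1:
                sel = np.flatnonzero((sube["dim"] == d).to_numpy())
                B = blk[np.ix_(sel, sel)]
            else:
                B = blk
            diag_sum += float(np.trace(B))
            all_sum += float(B.sum())
            t_d += B.shape[0]
        return diag_sum / t_d - all_sum / t_d ** 2

    if fit.spec.multi == "loc":
        # one global column: additive main + g x loc from G (x) Gamma (Eqs for
        # the balanced case extended with weighted averages of G)
        t = len(obs)
        s = len(dims)
        w = np.zeros(n)
        for g in obs["id"]:
            w[gpos[g]] += 1
        Wm = np.zeros((n, s))
        dmap = {dd: k for k, dd in enumerate(dims)}
        for g, dd in zip(obs["id"], obs["dim"]):
            Wm[gpos[g], dmap[dd]] += 1
        gam = fit.gamma_A
        G = fit.K_A
        total = float(np.einsum("ik,i,k->", Wm, np.diag(G), np.diag(gam))) / t \
            - float(np.sum((Wm.T @ G @ Wm) * gam)) / t ** 2
        offmean = (gam.sum() - np.trace(gam)) / (s * (s - 1)) if s > 1 else gam[0, 0]
        vg = legarra_variance(K=G, weights=w, t=t) * offmean
        rows = {"additive": max(vg, 0.0), "g x loc": max(total - vg, 0.0)}
        if fit.gamma_D is not None and fit.K_D is not None:
            rows[nname] = legarra_variance(K=fit.K_D * float(fit.gamma_D[0, 0]),
                                           weights=w, t=t)
        if fit.b is not None:
            # per-location heterosis coefficients: mu varies by (i, loc)
            bvec = np.array([fit.b[min(dmap[dd], len(fit.b) - 1)] for dd in obs["dim"]])
            Fv = fit.F[[gpos[g] for g in obs["id"]]]
            rows["heterosis"] = legarra_variance(mu=-bvec * Fv)
        if fit.marker_effects is not None and fit.W_fix is not None:
            me = fit.marker_effects
            mu = np.zeros(len(obs))
            for k, (g, dd) in enumerate(zip(obs["id"], obs["dim"])):
                delta = me[me["dim"] == dd]["effect"].to_numpy()
                mu[k] = fit.W_fix[gpos[g]] @ delta
            rows["fixed markers"] = legarra_variance(mu=mu)
        dcodes = obs["dim"].map(dmap).to_numpy()
        v = fit.sigma2_gE[dcodes]
        rows["g x env"] = float(v.mean()) - float(v.sum()) / t ** 2
        if fit.V0_blocks is not None:
            rows["stage1 error"] = s1_error(None)
        tot = sum(rows.values())
        df = pd.DataFrame({"PVE": {k: v / tot if tot > 0 else 0.0
                                   for k, v in rows.items()}})
        df.index.name = "component"
        return df

    out = {}
    for kd, d in enumerate(dims):
        sub = obs[obs["dim"] == d] if len(dims) > 1 else obs
        t = len(sub)
        w = np.zeros(n)
        for g in sub["id"]:
            w[gpos[g]] += 1
        rows = {}
        sA = float(fit.gamma_A[kd, kd]) if fit.gamma_A.shape[0] > kd \
            else float(fit.gamma_A[0, 0])
        rows["additive"] = legarra_variance(K=fit.K_A * sA, weights=w, t=t)
        if fit.gamma_D is not None and fit.K_D is not None:
            sD = float(fit.gamma_D[min(kd, fit.gamma_D.shape[0] - 1),
                                   min(kd, fit.gamma_D.shape[0] - 1)])
            rows[nname] = legarra_variance(K=fit.K_D * sD, weights=w, t=t)
        if fit.b is not None:
            bk = fit.b[min(kd, len(fit.b) - 1)]
            rows["heterosis"] = legarra_variance(mu=-bk * fit.F, weights=w, t=t)
        if fit.marker_effects is not None and fit.W_fix is not None:
            me = fit.marker_effects
            sel = me[me["dim"] == d]
            delta = sel["effect"].to_numpy()
            rows["fixed markers"] = legarra_variance(mu=fit.W_fix @ delta,
                                                     weights=w, t=t)
        if fit.spec.multi == "trait" and len(dims) > 1:
            rows["g x env"] = float(fit.sigma2_gE[kd, kd]) * (1 - 1 / t)
        else:
            rows["g x env"] = float(fit.sigma2_gE[0]) * (1 - 1 / t)
        if fit.V0_blocks is not None:
            rows["stage1 error"] = s1_error(d)
        tot = sum(rows.values())
        out[d] = {k: (v / tot if tot > 0 else 0.0) for k, v in rows.items()}
    df = pd.DataFrame(out)
    df.index.name = "component"
    if len(dims) == 1:
        df.columns = ["PVE"]
    return df


def optimize_blend(s1: Stage1Fit, spec: Stage2Spec, geno: MarkerSet,
                   A: RelMatrix, omega_grid=None, include_s_term: bool = True):
    """AIC search over H = (1-omega) G + omega A blending weights.

    Returns ``(omega_star, table)`` where the table has one row per omega
    with AIC and the additive/non-additive PVE traces.
    """
    if omega_grid is None:
        omega_grid = np.round(np.arange(0.0, 1.0001, 0.1), 10)
    omega_grid = np.asarray(omega_grid, float)
    if omega_grid.min() < 0 or omega_grid.max() > 1:
        raise ValueError("omega grid must lie in [0, 1]")
    rows = []
    fits = []
    from dataclasses import replace
    for w in omega_grid:
        f = fit_stage2(s1, replace(spec, omega=float(w)), geno=geno, A=A,
                       include_s_term=include_s_term)
        pa = float(f.pve.loc["additive"].iloc[0]) if "additive" in f.pve.index else np.nan
        nname = ("dominance" if spec.model == "additive-dominance"
                 else "genetic residual")
        pd_ = float(f.pve.loc[nname].iloc[0]) if nname in f.pve.index else np.nan
        rows.append({"omega": float(w), "AIC": f.aic, "pve_additive": pa,
                     "pve_nonadditive": pd_})
        fits.append(f)
    tab = pd.DataFrame(rows)
    omega_star = float(tab.loc[tab["AIC"].idxmin(), "omega"])
    return omega_star, tab
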