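"""Stage 1: per-environment genotype means (BLUEs) and their covariance.

Each environment is analyzed separately with genotype as a fixed effect.
The returned BLUEs are full genotype means on the observation scale (the
intercept is absorbed and all other covariates are evaluated at their
average level), so Stage 2 can include environment main effects.  The full
variance-covariance matrix of the BLUEs is kept per environment; their
direct sum is the known covariance of the Stage-1 estimation errors carried
into Stage 2 -- the essence of a fully efficient two-stage analysis.

Plot-basis broad-sense heritability per environment comes from a companion
fit with genotype as an i.i.d. random effect: H^2 = s2_g / (s2_g + s2_e).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la

from .reml import Iid, RandomTerm, reml_fit

logger = logging.getLogger(__name__)

__all__ = ["Stage1Fit", "fit_stage1", "h2_table"]


@dataclass
class Stage1Fit:
    """Genotype BLUEs with full vcov blocks, one block per environment.

    Attributes
    ----------
    traits : list of trait names (t >= 1).
    envs : environment labels in block order.
    ids : dict env -> list of genotype ids present in that env.
    blue : dict env -> array (n_j, t) of BLUEs.
    vcov : dict env -> array (n_j*t, n_j*t), trait nested within genotype.
    h2 : DataFrame (env, trait, H2) or None.
    loc : dict env -> location label, or None.
    resid : dict env -> residual variance info.
    """

    traits: list
    envs: list
    ids: dict
    blue: dict
    vcov: dict
    h2: pd.DataFrame | None = None
    loc: dict | None = None
    resid: dict = field(default_factory=dict)

    @property
    def t(self) -> int:
        return len(self.traits)

    def blues_frame(self) -> pd.DataFrame:
        rows = []
        for env in self.envs:
            for i, g in enumerate(self.ids[env]):
                for k, tr in enumerate(self.traits):
                    rows.append({"id": g, "env": env, "trait": tr,
                                 "value": self.blue[env][i, k]})
        return pd.DataFrame(rows)

    def to_csv(self, blue_path, vcov_path):
        self.blues_frame().to_csv(blue_path, index=False)
        rows = []
        for env in self.envs:
            ids, t = self.ids[env], self.t
            V = self.vcov[env]
            for a in range(len(ids) * t):
                for b in range(a, len(ids) * t):
                    if V[a, b] == 0.0 and a != b:
                        continue
                    rows.append({
                        "env": env,
                        "id1": ids[a // t], "trait1": self.traits[a % t],
                        "id2": ids[b // t], "trait2": self.traits[b % t],
                        "value": V[a, b],
                    })
        pd.DataFrame(rows).to_csv(vcov_path, index=False)

    @classmethod
    def from_csv(cls, blue_path, vcov_path, loc=None):
        blues = pd.read_csv(blue_path, dtype={"id": str, "env": str})
        traits = list(pd.unique(blues["trait"]))
        envs = list(pd.unique(blues["env"]))
        t = len(traits)
        tpos = {tr: k for k, tr in enumerate(traits)}
        ids, blue = {}, {}
        for env in envs:
            sub = blues[blues["env"] == env]
            ids[env] = list(pd.unique(sub["id"]))
            gpos = {g: i for i, g in enumerate(ids[env])}
            B = np.full((len(ids[env]), t), np.nan)
            for r in sub.itertuples():
                B[gpos[r.id], tpos[r.trait]] = r.value
            blue[env] = B
        vc = pd.read_csv(vcov_path, dtype={"env": str, "id1": str, "id2": str})
        vcov = {}
        for env in envs:
            gpos = {g: i for i, g in enumerate(ids[env])}
            q = len(ids[env]) * t
            V = np.zeros((q, q))
            for r in vc[vc["env"] == env].itertuples():
                a = gpos[r.id1] * t + tpos[r.trait1]
                b = gpos[r.id2] * t + tpos[r.trait2]
                V[a, b] = V[b, a] = r.value
            vcov[env] = V
        return cls(traits, envs, ids, blue, vcov, loc=loc)


def _sum_contrasts(series: pd.Series):
    """Sum-to-zero coding: L-1 columns; effects average to zero over levels."""
    levels = list(pd.unique(series))
    n = len(series)
    cols, names = [], []
    codes = series.map({l: i for i, l in enumerate(levels)}).to_numpy()
    for j, lev in enumerate(levels[:-1]):
        x = np.where(codes == j, 1.0, 0.0) - np.where(codes == len(levels) - 1, 1.0, 0.0)
        cols.append(x)
        names.append(f"{series.name}[{lev}]")
    return cols, names


def _design(sub: pd.DataFrame, genotype: str, fixed: list):
    g = sub[genotype].astype(str)
    glevels = list(pd.unique(g))
    gpos = {l: i for i, l in enumerate(glevels)}
    Xg = np.zeros((len(sub), len(glevels)))
    Xg[np.arange(len(sub)), g.map(gpos).to_numpy()] = 1.0
    cols, names = [Xg], [f"{genotype}[{l}]" for l in glevels]
    for c in fixed:
        s = sub[c]
        if pd.api.types.is_numeric_dtype(s):
            cols.append((s - s.mean()).to_numpy(float)[:, None])
            names.append(c)
        else:
            cc, nn = _sum_contrasts(s)
            if cc:
                cols.append(np.column_stack(cc))
                names.extend(nn)
    X = np.column_stack([np.atleast_2d(c.T).T for c in cols])
    return X, glevels, names


def _check_rank(X, names):
    q, r, piv = la.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps
    rank = int((d > tol).sum())
    if rank < X.shape[1]:
        aliased = [names[j] for j in piv[rank:]]
        raise ValueError(f"singular design; aliased columns: {aliased}")


def _parse_terms(spec):
    if spec is None:
        return []
    if isinstance(spec, str):
        return [s.strip() for s in spec.split("+") if s.strip()]
    return list(spec)


def fit_stage1(pheno: pd.DataFrame, traits, genotype: str = "id",
               env: str = "env", loc: str | None = None,
               fixed=None, random=None) -> Stage1Fit:
    """Per-environment fixed-effect analysis of a long-format phenotype table.

    Parameters
    ----------
    pheno : DataFrame with columns ``genotype``, ``env``, trait columns and
        any design covariates.
    traits : list of trait column names (multi-trait uses a separable
        residual covariance and requires ``random`` to be empty).
    fixed : covariate names (or "a+b" string); factors get sum-to-zero
        coding, numeric covariates are centered, so the genotype BLUEs are
        means at the average covariate level.
    random : names of i.i.d. random terms (single trait only); variance
        components by REML, BLUEs by GLS.
    """
    traits = [traits] if isinstance(traits, str) else list(traits)
    fixed = _parse_terms(fixed)
    random = _parse_terms(random)
    if len(traits) > 1 and random:
        raise NotImplementedError("random terms are supported for single-trait Stage 1 only")
    envs_all = list(pd.unique(pheno[env].astype(str)))
    out_ids, out_blue, out_vcov, resid = {}, {}, {}, {}
    h2rows = []
    envs, locmap = [], ({} if loc else None)
    for e in envs_all:
        sub = pheno[pheno[env].astype(str) == e].dropna(subset=traits).copy()
        if sub[genotype].nunique() < 2:
            logger.warning("environment '%s' has <2 genotypes; skipped", e)
            continue
        X, glevels, names = _design(sub, genotype, fixed)
        _check_rank(X, names)
        t = len(traits)
        Y = sub[list(traits)].to_numpy(float)
        n, pcol = X.shape
        if t == 1 and random:
            zterms = []
            for rname in random:
                s = sub[rname].astype(str)
                lv = list(pd.unique(s))
                Z = np.zeros((n, len(lv)))
                Z[np.arange(n), s.map({l: i for i, l in enumerate(lv)}).to_numpy()] = 1.0
                zterms.append(RandomTerm(rname, Iid(len(lv)), Z))
            zterms.append(RandomTerm("residual", Iid(n)))
            fit = reml_fit(Y[:, 0], X, zterms)
            beta, bcov = fit.beta, fit.beta_cov
            s2e = fit.components["residual"]["variance"]
        else:
            XtX = X.T @ X
            beta = la.solve(XtX, X.T @ Y, assume_a="pos")
            R = Y - X @ beta
            dfres = max(n - pcol, 1)
            Sig = (R.T @ R) / dfres  # t x t residual covariance (separable)
            XtXi = la.inv(XtX)
            beta, bcov, s2e = beta, (XtXi, Sig), Sig
        ng = len(glevels)
        if t == 1 and random:
            B = beta[:ng][:, None]
            V = bcov[:ng, :ng]
        else:
            B = beta[:ng, :]
            XtXi, Sig = bcov
            V = np.kron(XtXi[:ng, :ng], Sig)  # trait within genotype
        envs.append(e)
        out_ids[e] = glevels
        out_blue[e] = B
        out_vcov[e] = V
        resid[e] = s2e
        if locmap is not None:
            locmap[e] = str(sub[loc].iloc[0])
        # companion random-genotype fit for plot-basis H2
        X0cols = [np.ones((n, 1))]
        for c in fixed:
            s = sub[c]
            if pd.api.types.is_numeric_dtype(s):
                X0cols.append((s - s.mean()).to_numpy(float)[:, None])
            else:
                cc, _ = _sum_contrasts(s)
                if cc:
                    X0cols.append(np.column_stack(cc))
        X0 = np.column_stack(X0cols)
        gidx = sub[genotype].astype(str).map({l: i for i, l in enumerate(glevels)}).to_numpy()
        Zg = np.zeros((n, ng))
        Zg[np.arange(n), gidx] = 1.0
        for k, tr in enumerate(traits):
            hfit = reml_fit(Y[:, k], X0,
                            [RandomTerm("g", Iid(ng), Zg),
                             RandomTerm("residual", Iid(n))])
            s2g = hfit.components["g"]["variance"]
            s2r = hfit.components["residual"]["variance"]
            bflag = bool(hfit.boundary.get("g", np.zeros(1, bool)).any())
            h2 = 0.0 if bflag else s2g / (s2g + s2r)
            h2rows.append({"env": e, "trait": tr, "H2": h2, "boundary": bflag})
    if not envs:
        raise ValueError("no environment had >=2 genotypes")
    return Stage1Fit(traits, envs, out_ids, out_blue, out_vcov,
                     h2=pd.DataFrame(h2rows), loc=locmap, resid=resid)


def h2_table(fit: Stage1Fit) -> pd.DataFrame:
    """Plot-basis broad-sense heritability per environment and trait."""
    if fit.h2 is None:
        raise ValueError("Stage1Fit has no companion H2 fits")
    return fit.h2[["env", "trait", "H2"]].copy()
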