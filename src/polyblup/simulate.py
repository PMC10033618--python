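"""Synthetic marker/phenotype generator matching the pipeline's assumptions.

The stated world: a panmictic population of even-ploidy individuals with
independent bi-allelic markers (dosage ~ Binomial(phi, p_k)); genetic value
built from random allele-substitution effects alpha_k ~ N(0, s2_alpha) and
digenic substitution effects beta_k ~ N(mu_beta, s2_beta) through the
centered dosage matrix W and the dominance-coefficient matrix Q; a non-zero
mu_beta induces directional dominance with heterosis coefficient
b = mu_beta * C(phi,2) * sum_k 2 p_k q_k.  Phenotypes add environment
effects, i.i.d. GxE, and either plot-level errors or exact Stage-1-style
BLUEs with heterogeneous known error variances (default scales spanning
0.5-2.0, the spread used for REML recovery checks).

Defaults mirror the reference scenario used throughout the tests:
n=300 tetraploid individuals, m=1000 markers, 4 environments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import comb

from .markers import MarkerSet, compute_dominance
from .stage1 import Stage1Fit

__all__ = ["SimTruth", "sim_population", "sim_progeny", "sim_genetic_values",
           "sim_phenotypes"]


@dataclass
class SimTruth:
    """Ground truth of a simulated population."""

    alpha: np.ndarray        # additive substitution effects per marker
    beta: np.ndarray         # digenic substitution effects per marker
    additive: np.ndarray     # W alpha, per individual
    dominance: np.ndarray    # Q beta, per individual
    b: float                 # heterosis regression coefficient (implied by mu_beta)
    sigma2_A: float
    sigma2_D: float
    sigma2_gE: float
    F: np.ndarray            # genomic inbreeding coefficients

    @property
    def genetic(self) -> np.ndarray:
        return self.additive + self.dominance


def sim_population(n: int, m: int, ploidy: int = 4, freq=(0.1, 0.9),
                   seed=None, rng=None) -> MarkerSet:
    """Panmictic population: dosages ~ Binomial(phi, p_k), independent loci.

    ``freq`` is either a (lo, hi) tuple for uniform allele frequencies or an
    array of length m.
    """
    if ploidy < 2 or ploidy % 2:
        raise ValueError("ploidy must be an even integer >= 2")
    rng = np.random.default_rng(seed) if rng is None else rng
    if isinstance(freq, tuple):
        p = rng.uniform(freq[0], freq[1], m)
    else:
        p = np.broadcast_to(np.asarray(freq, float), (m,)).copy()
    X = rng.binomial(ploidy, p[None, :], size=(n, m)).astype(float)
    ids = [f"G{i+1:04d}" for i in range(n)]
    mk = [f"M{k+1:05d}" for k in range(m)]
    nchr = max(1, min(10, m // 100))
    chrom = np.array([f"chr{k % nchr + 1:02d}" for k in range(m)])
    pos = np.arange(m, dtype=float) * 1e5
    return MarkerSet(ids, mk, X, ploidy, chrom, pos)


def sim_progeny(parents: MarkerSet, crosses, n_each: int, seed=None,
                rng=None) -> MarkerSet:
    """Offspring under random bivalent pairing, no double reduction.

    Each parent transmits phi/2 alleles drawn without replacement from its
    dosage (hypergeometric per locus).  ``crosses`` is a list of
    (mother_id, father_id) tuples.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    phi = parents.ploidy
    half = phi // 2
    pos = {g: i for i, g in enumerate(parents.ids)}
    rows, ids = [], []
    for ci, (mo, fa) in enumerate(crosses):
        Xm = parents.dosage[pos[mo]]
        Xf = parents.dosage[pos[fa]]
        for j in range(n_each):
            gm = rng.hypergeometric(Xm.astype(int), phi - Xm.astype(int), half)
            gf = rng.hypergeometric(Xf.astype(int), phi - Xf.astype(int), half)
            rows.append(gm + gf)
            ids.append(f"X{ci+1:03d}_{j+1:03d}")
    return MarkerSet(ids, list(parents.marker_ids),
                     np.array(rows, float), phi,
                     parents.chrom.copy(), parents.position.copy())


def sim_genetic_values(ms: MarkerSet, sigma2_A: float = 1.0,
                       sigma2_D: float = 0.3, mu_beta: float = 0.0,
                       sigma2_gE: float = 0.5, seed=None, rng=None) -> SimTruth:
    """Draw substitution effects and build true additive/dominance values.

    Effect variances are scaled so the expected population variances equal
    the targets: s2_alpha = sigma2_A / (phi sum pq) and
    s2_beta = sigma2_D / (C(phi,2) sum 4 p^2 q^2).
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    p = ms.p
    q = 1 - p
    phi = ms.ploidy
    c2 = comb(phi, 2, exact=True)
    poly = (p > 0) & (p < 1)
    denomA = phi * float(np.sum(p[poly] * q[poly]))
    dom, _ = compute_dominance(ms)
    alpha = np.zeros(ms.m)
    beta = np.zeros(ms.m)
    alpha[poly] = rng.normal(0.0, np.sqrt(sigma2_A / denomA), int(poly.sum()))
    beta[poly] = rng.normal(mu_beta, np.sqrt(sigma2_D / dom.denomD),
                            int(poly.sum()))
    additive = ms.W @ alpha
    dominance = dom.Q @ beta[poly]
    b = mu_beta * dom.denomF
    return SimTruth(alpha, beta, additive, dominance, b,
                    sigma2_A, sigma2_D, sigma2_gE, dom.F)


def sim_phenotypes(ms: MarkerSet, truth: SimTruth, n_envs: int = 4,
                   reps: int = 2, env_sd: float = 1.0,
                   error_scales=(0.5, 2.0), plot_error: float = 1.0,
                   seed=None, rng=None):
    """Plot-level phenotypes plus exact Stage-1-style BLUEs.

    Returns ``(pheno, s1)``: a long-format plot table (id, env, block, y)
    and a :class:`Stage1Fit` whose BLUEs are the true cell values plus
    heterogeneous Gaussian errors with *known* variance blocks -- the ideal
    input for testing Stage 2 directly.  Per-environment error variances are
    evenly spaced across ``error_scales``.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    n = ms.n
    g = truth.genetic
    envs = [f"env{j+1}" for j in range(n_envs)]
    Ej = rng.normal(0.0, env_sd, n_envs)
    gE = rng.normal(0.0, np.sqrt(truth.sigma2_gE), (n, n_envs))
    scales = np.linspace(error_scales[0], error_scales[1], n_envs)
    rows = []
    ids_d, blue_d, vcov_d, resid_d = {}, {}, {}, {}
    for j, env in enumerate(envs):
        cell = Ej[j] + g + gE[:, j]
        for r in range(reps):
            e = rng.normal(0.0, np.sqrt(plot_error * scales[j]), n)
            for i in range(n):
                rows.append({"id": ms.ids[i], "env": env, "block": f"b{r+1}",
                             "y": cell[i] + e[i]})
        v = scales[j] * plot_error / reps
        s = rng.normal(0.0, np.sqrt(v), n)
        ids_d[env] = list(ms.ids)
        blue_d[env] = (cell + s)[:, None]
        vcov_d[env] = np.eye(n) * v
        resid_d[env] = plot_error * scales[j]
    pheno = pd.DataFrame(rows)
    s1 = Stage1Fit(["y"], envs, ids_d, blue_d, vcov_d, resid=resid_d)
    return pheno, s1
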