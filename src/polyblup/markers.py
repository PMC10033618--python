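"""Marker data and relationship matrices for even-ploidy populations.

The additive genomic relationship matrix ``G`` follows VanRaden's method 1
generalized to arbitrary even ploidy: with ``W`` the column-centered dosage
matrix and ``p_k`` the observed allele frequencies,

    G = W W' / (phi * sum_k p_k q_k)

Digenic dominance is handled through the per-locus dominance coefficient

    Q = -2 * C(phi,2) * p^2 + 2 p (phi - 1) X - X (X - 1)

whose cross-product gives the dominance relationship ``D`` and whose row sum
scales to the genomic inbreeding coefficient ``F``.  Allele frequencies are
the observed frequencies of the supplied population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import comb

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerSet",
    "RelMatrix",
    "DomCoeffs",
    "read_geno",
    "compute_G",
    "compute_dominance",
    "inbreeding_from_diag",
    "read_pedigree",
    "pedigree_A",
    "blend_H",
]


@dataclass
class MarkerSet:
    """Bi-allelic dosage data for ``n`` individuals at ``m`` markers.

    Parameters
    ----------
    ids : list of str
        Individual identifiers (rows of ``dosage``).
    marker_ids : list of str
        Marker names (columns of ``dosage``).
    dosage : ndarray, shape (n, m)
        Allele dosages in ``[0, ploidy]``; fractional values allowed.
    ploidy : int
        Even ploidy (2 = diploid, 4 = tetraploid, ...).
    chrom, position : arrays, optional
        Genetic map, one entry per marker.
    """

    ids: list
    marker_ids: list
    dosage: np.ndarray
    ploidy: int
    chrom: np.ndarray | None = None
    position: np.ndarray | None = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.ploidy < 2 or self.ploidy % 2 != 0:
            raise ValueError(f"ploidy must be an even integer >= 2, got {self.ploidy}")
        n, m = self.dosage.shape
        if n != len(self.ids) or m != len(self.marker_ids):
            raise ValueError("dosage shape does not match ids/marker_ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        bad = np.argwhere((self.dosage < 0) | (self.dosage > self.ploidy))
        if bad.size:
            i, k = bad[0]
            raise ValueError(
                f"dosage out of [0, {self.ploidy}] for individual "
                f"'{self.ids[i]}' at marker '{self.marker_ids[k]}'"
            )
        if self.chrom is None:
            self.chrom = np.array(["0"] * m)
        if self.position is None:
            self.position = np.arange(m, dtype=float)

    @property
    def n(self) -> int:
        return self.dosage.shape[0]

    @property
    def m(self) -> int:
        return self.dosage.shape[1]

    @property
    def p(self) -> np.ndarray:
        """Observed frequency of allele 1 per marker."""
        return self.dosage.mean(axis=0) / self.ploidy

    @property
    def W(self) -> np.ndarray:
        """Column-centered dosage matrix."""
        return self.dosage - self.ploidy * self.p

    def subset(self, ids) -> "MarkerSet":
        """Row-subset (and reorder) to the requested individuals."""
        pos = {g: i for i, g in enumerate(self.ids)}
        missing = [g for g in ids if g not in pos]
        if missing:
            raise KeyError(f"ids not in MarkerSet: {missing[:5]}")
        idx = [pos[g] for g in ids]
        return MarkerSet(
            list(ids), list(self.marker_ids), self.dosage[idx], self.ploidy,
            self.chrom.copy(), self.position.copy(),
        )


@dataclass
class RelMatrix:
    """Named symmetric relationship matrix over individual ids."""

    ids: list
    values: np.ndarray
    kind: str  # one of {"G", "D", "A", "H"}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")

    def align(self, ids) -> "RelMatrix":
        """Subset/reorder to ``ids``; error if any are absent."""
        pos = {g: i for i, g in enumerate(self.ids)}
        missing = [g for g in ids if g not in pos]
        if missing:
            raise KeyError(
                f"{self.kind} matrix is missing individuals: {missing[:5]}"
            )
        idx = np.array([pos[g] for g in ids])
        return RelMatrix(list(ids), self.values[np.ix_(idx, idx)], self.kind)

    def to_csv(self, path):
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, kind):
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float), kind)


@dataclass
class DomCoeffs:
    """Dominance coefficients Q, genomic inbreeding F and their scalings."""

    Q: np.ndarray       # n x m
    F: np.ndarray       # length n
    denomD: float       # C(phi,2) * sum_k 4 p^2 q^2
    denomF: float       # C(phi,2) * sum_k 2 p q


def _filter_and_impute(dosage, marker_ids, chrom, position, ploidy,
                       min_maf, max_missing):
    miss_frac = np.isnan(dosage).mean(axis=0)
    keep = miss_frac <= max_missing
    n_miss = int((~keep).sum())
    dosage, out = dosage[:, keep], keep
    col_mean = np.nanmean(np.where(np.isnan(dosage), np.nan, dosage), axis=0) \
        if dosage.size else np.array([])
    if dosage.size:
        nan_idx = np.isnan(dosage)
        dosage = np.where(nan_idx, col_mean[None, :], dosage)
    p = dosage.mean(axis=0) / ploidy if dosage.size else np.array([])
    maf = np.minimum(p, 1 - p)
    poly = (maf >= max(min_maf, 1e-12)) & (p > 0) & (p < 1)
    n_maf = int((~poly).sum())
    logger.info(
        "read_geno: dropped %d markers for missingness > %.3g, "
        "%d monomorphic/MAF < %.3g; %d retained",
        n_miss, max_missing, n_maf, min_maf, int(poly.sum()),
    )
    sel = np.flatnonzero(out)
    sel = sel[poly]
    return dosage[:, poly], sel


def read_geno(path, ploidy: int, min_maf: float = 0.0,
              max_missing: float = 1.0) -> MarkerSet:
    """Read a marker-rows dosage CSV into a :class:`MarkerSet`.

    Expected header: ``marker,chrom,position,<id1>,<id2>,...`` with one row
    per marker.  Markers failing the MAF or missingness filters (including
    monomorphic markers) are dropped; remaining missing dosages are imputed
    with the marker mean.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 4:
        raise ValueError("dosage CSV needs marker,chrom,position + >=1 individual")
    marker_ids = df.iloc[:, 0].astype(str).to_list()
    chrom = df.iloc[:, 1].astype(str).to_numpy()
    position = df.iloc[:, 2].to_numpy(float)
    ids = [str(c) for c in df.columns[3:]]
    dosage = df.iloc[:, 3:].to_numpy(float).T  # n x m
    finite = dosage[np.isfinite(dosage)]
    if finite.size and (finite.min() < 0 or finite.max() > ploidy):
        bad = np.argwhere((dosage < 0) | (dosage > ploidy))
        i, k = bad[0]
        raise ValueError(
            f"dosage out of [0, {ploidy}] for individual '{ids[i]}' "
            f"at marker '{marker_ids[k]}'"
        )
    dosage, sel = _filter_and_impute(dosage, marker_ids, chrom, position,
                                     ploidy, min_maf, max_missing)
    if dosage.shape[1] == 0:
        raise ValueError("no markers survived the MAF/missingness filters")
    return MarkerSet(
        ids, [marker_ids[k] for k in sel], dosage, ploidy,
        chrom[sel], position[sel],
    )


def compute_G(ms: MarkerSet) -> RelMatrix:
    """Additive genomic relationship, VanRaden method 1 for ploidy ``phi``."""
    p = ms.p
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers are monomorphic; G undefined")
    W = ms.W[:, poly]
    denom = ms.ploidy * float(np.sum(p[poly] * (1 - p[poly])))
    return RelMatrix(list(ms.ids), W @ W.T / denom, "G")


def dominance_coeff(X: np.ndarray, p: np.ndarray, ploidy: int) -> np.ndarray:
    """Per-locus dominance coefficient Q(X) for dosage X and frequency p."""
    c2 = comb(ploidy, 2, exact=True)
    return -2.0 * c2 * p ** 2 + 2.0 * p * (ploidy - 1) * X - X * (X - 1.0)


def compute_dominance(ms: MarkerSet) -> tuple[DomCoeffs, RelMatrix]:
    """Dominance coefficients Q, relationship D = QQ'/denomD, inbreeding F."""
    p = ms.p
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers are monomorphic; D undefined")
    X = ms.dosage[:, poly]
    p = p[poly]
    q = 1 - p
    c2 = comb(ms.ploidy, 2, exact=True)
    Q = dominance_coeff(X, p[None, :], ms.ploidy)
    denomD = c2 * float(np.sum(4 * p ** 2 * q ** 2))
    denomF = c2 * float(np.sum(2 * p * q))
    D = Q @ Q.T / denomD
    F = -Q.sum(axis=1) / denomF
    return DomCoeffs(Q, F, denomD, denomF), RelMatrix(list(ms.ids), D, "D")


def inbreeding_from_diag(K: RelMatrix, ploidy: int) -> np.ndarray:
    """Inbreeding coefficients from an additive relationship diagonal.

    F_i = (K_ii - 1) / (phi - 1), valid for G, A or H.
    """
    if K.kind == "D":
        raise ValueError("inbreeding_from_diag expects an additive matrix (G/A/H)")
    if ploidy <= 1:
        raise ValueError("ploidy must exceed 1")
    return (np.diag(K.values) - 1.0) / (ploidy - 1.0)


def read_pedigree(path) -> pd.DataFrame:
    """3-column pedigree CSV (id, parent1, parent2); blank/NA = founder."""
    ped = pd.read_csv(path, dtype=str).iloc[:, :3]
    ped.columns = ["id", "parent1", "parent2"]
    for c in ("parent1", "parent2"):
        ped[c] = ped[c].replace({"": None, "NA": None, "0": None})
        ped[c] = ped[c].where(ped[c].notna(), None)
    return ped


def _toposort(ped: pd.DataFrame) -> list:
    parents = {r.id: [p for p in (r.parent1, r.parent2)] for r in ped.itertuples()}
    # implicit founders: parents never listed as ids
    for pl in list(parents.values()):
        for p in pl:
            if p is not None and p not in parents:
                parents[p] = [None, None]
    order, state = [], {}

    def visit(v, stack):
        if state.get(v) == 2:
            return
        if state.get(v) == 1:
            raise ValueError(f"pedigree cycle involving '{v}'")
        state[v] = 1
        for p in parents[v]:
            if p is not None:
                visit(p, stack)
        state[v] = 2
        order.append(v)

    for v in parents:
        visit(v, [])
    return order, parents


def pedigree_A(ped: pd.DataFrame, ploidy: int) -> RelMatrix:
    """Pedigree additive relationship by the tabular (recursive) method.

    Diploid: standard Wright/Henderson recursion.  Tetraploid: random
    bivalent pairing without double reduction; each parent transmits two
    distinct alleles, so for offspring y of (s, d)

        F_y = (F_s + F_d)/6 + (2/3) f(s, d)

    with f the kinship coefficient.  A = phi * f, so non-inbred individuals
    have diagonal 1 and inbred ones 1 + (phi - 1) F.
    """
    if ploidy not in (2, 4):
        raise ValueError("pedigree_A supports ploidy 2 and 4 only")
    order, parents = _toposort(ped)
    n = len(order)
    pos = {g: i for i, g in enumerate(order)}
    f = np.zeros((n, n))
    Finb = np.zeros(n)
    for y in order:
        iy = pos[y]
        s, d = parents[y]
        is_, id_ = (pos[s] if s else None), (pos[d] if d else None)
        fsd = f[is_, id_] if (s and d) else 0.0
        Fs = Finb[is_] if s else 0.0
        Fd = Finb[id_] if d else 0.0
        if ploidy == 2:
            Finb[iy] = fsd
            f[iy, iy] = 0.5 * (1 + Finb[iy])
        else:
            Finb[iy] = (Fs + Fd) / 6.0 + (2.0 / 3.0) * fsd
            f[iy, iy] = 0.25 * (1 + 3 * Finb[iy])
        for x in order[: order.index(y)]:
            ix = pos[x]
            val = 0.0
            if s:
                val += 0.5 * f[ix, is_]
            if d:
                val += 0.5 * f[ix, id_]
            f[iy, ix] = f[ix, iy] = val
    A = ploidy * f
    # order rows by the input pedigree order (ids first, implicit founders kept)
    listed = list(dict.fromkeys(ped["id"].tolist() + [g for g in order if g not in set(ped["id"])]))
    idx = [pos[g] for g in listed]
    return RelMatrix(listed, A[np.ix_(idx, idx)], "A")


def blend_H(G: RelMatrix, A: RelMatrix, omega: float) -> RelMatrix:
    """H = (1 - omega) G + omega A, with A aligned to G's ids."""
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must be in [0, 1]")
    A = A.align(G.ids)
    return RelMatrix(list(G.ids), (1 - omega) * G.values + omega * A.values, "H")
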