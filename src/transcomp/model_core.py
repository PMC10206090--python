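"""The probabilistic model of trans-contact sub-compartmentalization.

Each genomic bin i resides in one of M nuclear sub-compartments per cell,
with population probability P_ik (rows sum to 1). Two loci on different
chromosomes interact only when co-located in the same sub-compartment, so
the expected trans contact count between bins i and j is

    F_ij = R_ij * sum_k C_ik C_jk,        C_ik = B_i P_ik,

where B_i is a per-bin bias factor (mappability, accessibility, ligation
and PCR efficiency) and R_ij = 1 + alpha*r_i*r_j + beta*(r_i+r_j)*r_i*r_j
is a two-parameter correction for the Rabl configuration (centromeres
cluster with centromeres, telomeres with telomeres), with r the relative
arm position in [-0.5, 0.5]. Observed counts N_ij are Poisson(F_ij), giving
the log-likelihood (constant terms in N dropped)

    L = sum_{trans pairs ij} [ N_ij ln F_ij - F_ij ].

The -F_ij term summed over all O(n^2) trans pairs is evaluated in closed
form from per-chromosome column sums (see :class:`PairSums`), so zero-count
pairs are never materialized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome_io import ContactTable, ExclusionSet, GenomeBinning

__all__ = [
    "CompartmentModel",
    "rabl_term",
    "expected_contacts",
    "log_likelihood",
    "decompose",
    "PairSums",
    "eligible_entries",
    "group_cross_pairs",
]


@dataclass
class CompartmentModel:
    """Nonnegative score matrix C (n x M) plus Rabl coefficients.

    C_ik = B_i * P_ik carries units of sqrt(expected read counts); the bias
    B_i = sum_k C_ik and the probabilities P_ik = C_ik / B_i are derived via
    :func:`decompose`. Blacklisted bins keep all-zero rows.
    """

    C: np.ndarray
    alpha: float = 0.0
    beta: float = 0.0
    n_nonempty: int = 0

    def __post_init__(self):
        self.C = np.asarray(self.C, dtype=np.float64)
        if self.C.ndim != 2:
            raise ValueError("C must be 2-D (n_bins x M)")
        if np.any(self.C < 0):
            raise ValueError("C must be nonnegative")

    @property
    def M(self) -> int:
        return int(self.C.shape[1])

    @property
    def n_bins(self) -> int:
        return int(self.C.shape[0])


def rabl_term(r_i, r_j, alpha: float, beta: float):
    """Rabl interaction factor R_ij = 1 + a*ri*rj + b*(ri+rj)*ri*rj.

    Symmetric in (i, j); identically 1 when alpha = beta = 0. alpha sets the
    strength of like-end clustering, beta skews it toward the centromeric
    (beta < 0 effect at r = -0.5) or telomeric side. Values <= 0 indicate
    Rabl parameters invalid for these coordinates; callers must keep R
    positive wherever a contact can occur.
    """
    r_i = np.asarray(r_i, dtype=np.float64)
    r_j = np.asarray(r_j, dtype=np.float64)
    p = r_i * r_j
    return 1.0 + alpha * p + beta * (r_i + r_j) * p


def expected_contacts(C_i, C_j, R_ij):
    """Poisson rate F_ij = R_ij * sum_k C_ik C_jk for one bin pair."""
    return R_ij * float(np.dot(np.asarray(C_i, float), np.asarray(C_j, float)))


def decompose(model: CompartmentModel):
    """Split C into per-bin bias B and probability rows P.

    Returns (B, P, present): P rows sum to 1 where B > 0; bins with B = 0
    (blacklisted or without trans reads) get all-zero P rows and
    present=False.
    """
    B = model.C.sum(axis=1)
    present = B > 0
    P = np.zeros_like(model.C)
    P[present] = model.C[present] / B[present, None]
    return B, P, present


def group_cross_pairs(exclusions: ExclusionSet | None, binning: GenomeBinning):
    """All cross-chromosome unordered bin pairs within any region group.

    These pairs are excluded from every sum over trans pairs. Returns two
    int arrays (gi, gj), possibly empty.
    """
    if exclusions is None or not exclusions.region_groups:
        e = np.empty(0, dtype=np.int64)
        return e, e
    cid = binning.chrom_ids
    gis, gjs = [], []
    for g in exclusions.region_groups:
        g = np.asarray(g, dtype=np.int64)
        for a_idx in range(len(g) - 1):
            a = g[a_idx]
            rest = g[a_idx + 1 :]
            rest = rest[cid[rest] != cid[a]]
            gis.append(np.full(rest.size, a, dtype=np.int64))
            gjs.append(rest)
    if not gis:
        e = np.empty(0, dtype=np.int64)
        return e, e
    return np.concatenate(gis), np.concatenate(gjs)


def eligible_entries(table: ContactTable, exclusions: ExclusionSet | None):
    """Contact entries surviving blacklist and region-group exclusion.

    Returns (i, j, N) arrays. Tables built by ``load_pairs`` are already
    filtered; this makes the exclusion idempotent for programmatic tables.
    """
    i, j, N = table.row, table.col, table.count.astype(np.float64)
    if exclusions is None:
        return i, j, N
    n = table.binning.n_total
    bl = exclusions.blacklist_mask(n)
    gid = exclusions.group_id(n)
    keep = ~(bl[i] | bl[j]) & ~((gid[i] >= 0) & (gid[i] == gid[j]))
    return i[keep], j[keep], N[keep]


class PairSums:
    """Closed-form sums over all eligible trans bin pairs.

    For column k let S_k = sum_i C_ik, T_k = sum_i r_i C_ik and
    U_k = sum_i r_i^2 C_ik, with per-chromosome counterparts S_ck, T_ck,
    U_ck. Over unordered trans pairs (same-chromosome pairs removed, region
    group pairs subtracted explicitly):

        Q_k  = sum_{i<j} C_ik C_jk            = (S_k^2 - sum_c S_ck^2)/2
        A_k  = sum_{i<j} r_i r_j C_ik C_jk    = (T_k^2 - sum_c T_ck^2)/2
        Bt_k = sum_{i<j} (r_i+r_j) r_i r_j C_ik C_jk
             = U_k T_k - sum_c U_ck T_ck

    so the total expected count is sum_k Q_k + alpha*A_k + beta*Bt_k, and
    A, Bt are also the alpha/beta derivatives of that total. The per-locus
    linear term w_k(i) = sum_j R_ij C_jk over eligible partners follows from
    the same cached sums.
    """

    def __init__(self, C, binning: GenomeBinning, group_pairs=None):
        if binning.r is None:
            raise ValueError("binning has no relative positions r; "
                             "call compute_relative_positions first")
        self.binning = binning
        n_ch = binning.n_chroms
        r = binning.r
        off = binning.chrom_offsets
        self.S = C.sum(axis=0)
        rc = C * r[:, None]
        r2c = C * (r * r)[:, None]
        self.T = rc.sum(axis=0)
        self.U = r2c.sum(axis=0)
        self.Sc = np.add.reduceat(C, off[:-1], axis=0)
        self.Tc = np.add.reduceat(rc, off[:-1], axis=0)
        self.Uc = np.add.reduceat(r2c, off[:-1], axis=0)
        # empty chromosomes would confuse reduceat only if a chrom had 0 bins,
        # impossible by construction (length >= 1 implies >= 1 bin)

        self._C = C
        gi, gj = group_pairs if group_pairs is not None else (
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
        )
        self.gi, self.gj = gi, gj
        if gi.size:
            p = r[gi] * r[gj]
            s = r[gi] + r[gj]
            cc = C[gi] * C[gj]
            self.Qg = cc.sum(axis=0)
            self.Ag = (p[:, None] * cc).sum(axis=0)
            self.Btg = ((s * p)[:, None] * cc).sum(axis=0)
        else:
            self.Qg = np.zeros_like(self.S)
            self.Ag = np.zeros_like(self.S)
            self.Btg = np.zeros_like(self.S)

        self.Q = 0.5 * (self.S**2 - (self.Sc**2).sum(axis=0)) - self.Qg
        self.A = 0.5 * (self.T**2 - (self.Tc**2).sum(axis=0)) - self.Ag
        self.Bt = self.U * self.T - (self.Uc * self.Tc).sum(axis=0) - self.Btg

    def total_expected(self, alpha: float, beta: float) -> float:
        """sum over eligible trans pairs of F_ij (the -F likelihood term)."""
        return float(self.Q.sum() + alpha * self.A.sum() + beta * self.Bt.sum())

    def dF_dalpha(self) -> float:
        return float(self.A.sum())

    def dF_dbeta(self) -> float:
        return float(self.Bt.sum())

    def w_for_chrom(self, c: int, alpha: float, beta: float) -> np.ndarray:
        """Linear coefficients w_k(i) = sum_j R_ij C_jk for bins of chrom c.

        Partners j run over all other chromosomes; same-region-group
        partners are subtracted by the caller (they need pairwise terms).
        """
        b = self.binning
        lo, hi = b.chrom_offsets[c], b.chrom_offsets[c + 1]
        ri = b.r[lo:hi]
        S_rest = self.S - self.Sc[c]
        T_rest = self.T - self.Tc[c]
        U_rest = self.U - self.Uc[c]
        w = (
            S_rest[None, :]
            + (alpha * ri + beta * ri * ri)[:, None] * T_rest[None, :]
            + (beta * ri)[:, None] * U_rest[None, :]
        )
        return w


def log_likelihood(
    table: ContactTable,
    model: CompartmentModel,
    exclusions: ExclusionSet | None = None,
) -> float:
    """Poisson log-likelihood sum_ij [N_ij ln F_ij - F_ij] over trans pairs.

    Pairs with N_ij = 0 contribute only -F_ij (handled in closed form);
    a pair with N_ij > 0 but F_ij = 0 yields -inf, reported with a warning
    rather than clamped. Constant -ln(N!) terms are omitted.
    """
    binning = table.binning
    if model.C.shape[0] != binning.n_total:
        raise ValueError(
            f"model has {model.C.shape[0]} rows, binning has {binning.n_total} bins"
        )
    C = model.C
    if exclusions is not None and exclusions.blacklisted_bins.size:
        C = C.copy()
        C[exclusions.blacklisted_bins] = 0.0
    i, j, N = eligible_entries(table, exclusions)
    gp = group_cross_pairs(exclusions, binning)
    ps = PairSums(C, binning, group_pairs=gp)
    ftot = ps.total_expected(model.alpha, model.beta)
    if i.size == 0:
        return -ftot
    R = rabl_term(binning.r[i], binning.r[j], model.alpha, model.beta)
    rate = R * np.einsum("ek,ek->e", C[i], C[j])
    bad = rate <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} observed pairs have zero/negative expected rate; "
            "log-likelihood is -inf",
            stacklevel=2,
        )
        return -np.inf
    return float(np.dot(N, np.log(rate)) - ftot)
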