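"""Genomic file formats, binning, and per-bin relative arm positions.

The model operates on fixed-width genomic windows ("bins") tiling each
chromosome, and on inter-chromosomal (trans) contact counts between bins.
This module defines the binning, reads the standard text formats
(UCSC chrom.sizes, 4DN ``.pairs``, BED), and writes the score tables and
bedGraph tracks produced by a fitted model.

Coordinate conventions: bins are 0-based half-open internally; ``.pairs``
input positions are treated as 1-based (4DN convention) and converted on
read.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GenomeBinning",
    "ContactTable",
    "ExclusionSet",
    "load_chrom_sizes",
    "compute_relative_positions",
    "load_pairs",
    "load_blacklist_bed",
    "load_region_groups_bed",
    "load_centromeres",
    "write_scores",
    "read_scores",
    "write_pairs",
]


@dataclass
class GenomeBinning:
    """Fixed-width windows tiling a genome, with optional Rabl coordinates.

    Attributes
    ----------
    chrom_names : list of str
        Chromosome identifiers in input order.
    chrom_lengths : ndarray of int
        Length of each chromosome in base pairs.
    bin_size : int
        Window width in base pairs (the last bin of a chromosome may be
        shorter).
    centromere_pos : dict or None
        Optional centromere coordinate per chromosome name.
    r : ndarray of float or None
        Per-bin relative arm position in [-0.5, 0.5]; -0.5 at the
        centromere, approaching +0.5 at the telomeric end of each arm.
        Populated by :func:`compute_relative_positions`.
    """

    chrom_names: list
    chrom_lengths: np.ndarray
    bin_size: int
    centromere_pos: dict | None = None
    r: np.ndarray | None = None
    # derived, filled in __post_init__
    n_bins_per_chrom: np.ndarray = field(init=False, repr=False)
    chrom_offsets: np.ndarray = field(init=False, repr=False)
    chrom_ids: np.ndarray = field(init=False, repr=False)
    starts: np.ndarray = field(init=False, repr=False)
    ends: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.chrom_lengths = np.asarray(self.chrom_lengths, dtype=np.int64)
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths length mismatch")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome name")
        if len(self.chrom_names) == 0:
            raise ValueError("empty genome")
        if np.any(self.chrom_lengths <= 0):
            raise ValueError("non-positive chromosome length")
        nb = -(-self.chrom_lengths // self.bin_size)  # ceil division
        self.n_bins_per_chrom = nb.astype(np.int64)
        self.chrom_offsets = np.concatenate([[0], np.cumsum(nb)]).astype(np.int64)
        self.chrom_ids = np.repeat(
            np.arange(len(self.chrom_names), dtype=np.int64), nb
        )
        starts = []
        for c, n in enumerate(nb):
            s = np.arange(n, dtype=np.int64) * self.bin_size
            starts.append(s)
        self.starts = np.concatenate(starts)
        self.ends = np.minimum(
            self.starts + self.bin_size, self.chrom_lengths[self.chrom_ids]
        )
        self._chrom_index = {name: i for i, name in enumerate(self.chrom_names)}

    @property
    def n_total(self) -> int:
        return int(self.chrom_offsets[-1])

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    def chrom_ordinal(self, name: str) -> int:
        return self._chrom_index[name]

    def bin_index(self, chrom: str, pos0: int) -> int:
        """Global bin index of 0-based position ``pos0`` on ``chrom``."""
        c = self._chrom_index[chrom]
        if pos0 < 0 or pos0 >= self.chrom_lengths[c]:
            raise ValueError(
                f"position {pos0} outside chromosome {chrom} "
                f"(length {self.chrom_lengths[c]}); assembly mismatch?"
            )
        return int(self.chrom_offsets[c] + pos0 // self.bin_size)

    def bins_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of bins overlapping [start, end) on ``chrom``."""
        c = self._chrom_index[chrom]
        length = int(self.chrom_lengths[c])
        start = max(0, int(start))
        end = min(length, int(end))
        if end <= start:
            return np.empty(0, dtype=np.int64)
        b0 = start // self.bin_size
        b1 = (end - 1) // self.bin_size
        return np.arange(
            self.chrom_offsets[c] + b0, self.chrom_offsets[c] + b1 + 1, dtype=np.int64
        )


@dataclass
class ExclusionSet:
    """Bins removed from the likelihood.

    ``blacklisted_bins`` are dropped entirely (their score rows stay zero);
    ``region_groups`` are disjoint sets of bins (e.g. the partners of a
    translocation) whose *within-group* trans pairs are excluded because
    their contact counts reflect cis proximity, not compartmentalization.
    """

    blacklisted_bins: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )
    region_groups: list = field(default_factory=list)

    def __post_init__(self):
        self.blacklisted_bins = np.unique(
            np.asarray(self.blacklisted_bins, dtype=np.int64)
        )
        self.region_groups = [
            np.unique(np.asarray(g, dtype=np.int64)) for g in self.region_groups
        ]
        seen = set()
        for g in self.region_groups:
            for b in g:
                if int(b) in seen:
                    raise ValueError(f"bin {b} appears in more than one region group")
                seen.add(int(b))

    def blacklist_mask(self, n_total: int) -> np.ndarray:
        m = np.zeros(n_total, dtype=bool)
        m[self.blacklisted_bins] = True
        return m

    def group_id(self, n_total: int) -> np.ndarray:
        """Per-bin group id, -1 when not in any group."""
        gid = np.full(n_total, -1, dtype=np.int64)
        for g_idx, g in enumerate(self.region_groups):
            gid[g] = g_idx
        return gid


@dataclass
class ContactTable:
    """Sparse symmetric table of trans-only bin-pair read counts.

    Entries are stored once with ``row < col`` and ``chrom(row) != chrom(col)``.
    ``stats`` carries the read-filtering accounting from :func:`load_pairs`
    (empty for tables built programmatically).
    """

    binning: GenomeBinning
    row: np.ndarray
    col: np.ndarray
    count: np.ndarray
    stats: dict = field(default_factory=dict)

    def __post_init__(self):
        self.row = np.asarray(self.row, dtype=np.int64)
        self.col = np.asarray(self.col, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=np.int64)
        if np.any(self.count < 0):
            raise ValueError("negative contact count")
        cid = self.binning.chrom_ids
        if self.row.size and np.any(cid[self.row] == cid[self.col]):
            raise ValueError("cis pair stored in ContactTable")

    @classmethod
    def from_coo(cls, binning, i, j, count, stats=None):
        """Build from unordered (possibly duplicated) bin pairs, aggregating."""
        i = np.asarray(i, dtype=np.int64)
        j = np.asarray(j, dtype=np.int64)
        count = np.asarray(count, dtype=np.int64)
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        n = binning.n_total
        m = sp.coo_matrix((count, (lo, hi)), shape=(n, n)).tocsr()
        m.sum_duplicates()
        m.eliminate_zeros()
        coo = m.tocoo()
        return cls(
            binning,
            coo.row.astype(np.int64),
            coo.col.astype(np.int64),
            coo.data.astype(np.int64),
            stats=stats or {},
        )

    @property
    def n_entries(self) -> int:
        return int(self.row.size)

    @property
    def total_trans(self) -> int:
        return int(self.count.sum())

    def get(self, i: int, j: int) -> int:
        """Symmetric access N(i, j) = N(j, i); zero when absent."""
        lo, hi = (i, j) if i < j else (j, i)
        mask = (self.row == lo) & (self.col == hi)
        return int(self.count[mask].sum())

    def bin_totals(self) -> np.ndarray:
        """Total trans read-ends per bin."""
        t = np.zeros(self.binning.n_total, dtype=np.int64)
        np.add.at(t, self.row, self.count)
        np.add.at(t, self.col, self.count)
        return t

    def to_symmetric_csr(self) -> sp.csr_matrix:
        """Symmetric CSR adjacency (both (i,j) and (j,i)), float64 data."""
        n = self.binning.n_total
        a = sp.coo_matrix(
            (self.count.astype(np.float64), (self.row, self.col)), shape=(n, n)
        )
        return (a + a.T).tocsr()


def load_chrom_sizes(path, bin_size: int) -> GenomeBinning:
    """Read a UCSC-style chrom.sizes file into a :class:`GenomeBinning`.

    Two whitespace-delimited columns: chromosome name and length in bp.
    Global bin indexing follows file order, then position.
    """
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#", names=["chrom", "length"]
    )
    if df.empty:
        raise ValueError(f"empty chrom.sizes file: {path}")
    names = df["chrom"].astype(str).tolist()
    lengths = df["length"].to_numpy()
    if not np.issubdtype(lengths.dtype, np.integer):
        raise ValueError("chromosome lengths must be integers")
    return GenomeBinning(names, lengths, bin_size)


def load_centromeres(path) -> dict:
    """Read a two-column (chrom, position) centromere coordinate file."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", names=["chrom", "pos"])
    return {str(c): int(p) for c, p in zip(df["chrom"], df["pos"])}


def compute_relative_positions(
    binning: GenomeBinning, centromeres: dict | None = None
) -> GenomeBinning:
    """Attach per-bin relative arm positions r in [-0.5, 0.5].

    For a bin whose midpoint lies at arm-distance d from the centromere on
    an arm of length A, r = d/A - 0.5: -0.5 at the centromere, approaching
    +0.5 at the telomere. Chromosomes without a supplied centromere use the
    acrocentric convention (centromere at coordinate 0), which reduces to
    r = midpoint/length - 0.5. The bin containing the centromere gets
    exactly -0.5.
    """
    centromeres = centromeres or {}
    r = np.empty(binning.n_total, dtype=np.float64)
    mid = (binning.starts + binning.ends) / 2.0
    for c, name in enumerate(binning.chrom_names):
        lo, hi = binning.chrom_offsets[c], binning.chrom_offsets[c + 1]
        length = float(binning.chrom_lengths[c])
        cen = float(centromeres.get(name, 0))
        if cen < 0 or cen > length:
            raise ValueError(
                f"centromere at {cen} outside chromosome {name} (length {length})"
            )
        m = mid[lo:hi]
        d = np.abs(m - cen)
        arm = np.where(m < cen, cen, length - cen)
        # degenerate arm (centromere at an end): the other arm covers all bins
        arm = np.maximum(arm, binning.bin_size * 0.5)
        rc = d / arm - 0.5
        # the bin containing the centromere sits at the centromeric extreme
        contains = (binning.starts[lo:hi] <= cen) & (cen < binning.ends[lo:hi])
        rc[contains] = -0.5
        r[lo:hi] = np.clip(rc, -0.5, 0.5)
    return GenomeBinning(
        binning.chrom_names,
        binning.chrom_lengths,
        binning.bin_size,
        centromere_pos=dict(centromeres) if centromeres else None,
        r=r,
    )


def load_blacklist_bed(path, binning: GenomeBinning) -> np.ndarray:
    """Global indices of bins overlapping any interval of a BED blacklist."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    bins = []
    for _, rowv in df.iterrows():
        chrom = str(rowv[0])
        if chrom not in binning._chrom_index:
            continue
        bins.append(binning.bins_overlapping(chrom, int(rowv[1]), int(rowv[2])))
    if not bins:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(bins))


def load_region_groups_bed(path, binning: GenomeBinning) -> list:
    """Region groups from a BED file; the name column (4th) is the group id."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("region-group BED requires a name column (group id)")
    groups = {}
    for _, rowv in df.iterrows():
        chrom = str(rowv[0])
        if chrom not in binning._chrom_index:
            continue
        b = binning.bins_overlapping(chrom, int(rowv[1]), int(rowv[2]))
        groups.setdefault(str(rowv[3]), []).append(b)
    return [np.unique(np.concatenate(v)) for _, v in sorted(groups.items())]


def _parse_pairs_dataframe(path):
    """Read a pairs file, returning (chrom1, pos1, chrom2, pos2) columns.

    Accepts the 4DN dialect (readID chrom1 pos1 chrom2 pos2 [strand1
    strand2], '#' header lines) and a headerless 4-column dialect
    (chrom1 pos1 chrom2 pos2). Strand columns are read and ignored.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.empty:
        raise ValueError(f"no data lines in pairs file: {path}")
    ncol = df.shape[1]
    if ncol == 4:
        c1, p1, c2, p2 = 0, 1, 2, 3
    elif ncol >= 5:
        c1, p1, c2, p2 = 1, 2, 3, 4
    else:
        raise ValueError(f"malformed pairs file ({ncol} columns): {path}")
    try:
        pos1 = df[p1].to_numpy(dtype=np.int64)
        pos2 = df[p2].to_numpy(dtype=np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-integer position in pairs file {path}: {exc}") from exc
    return (
        df[c1].to_numpy(dtype=object),
        pos1,
        df[c2].to_numpy(dtype=object),
        pos2,
    )


def load_pairs(
    path, binning: GenomeBinning, exclusions: ExclusionSet | None = None
) -> ContactTable:
    """Aggregate a pairs file into trans-only bin-pair counts.

    Cis pairs, pairs touching blacklisted bins, and pairs with both ends in
    the same region group are discarded; the exact accounting is kept in
    ``ContactTable.stats`` (pairs_in = cis + blacklisted + grouped +
    unknown_chrom + kept).

    Input positions are 1-based (4DN convention); reads beyond the
    chromosome length are rejected as an assembly mismatch.
    """
    exclusions = exclusions or ExclusionSet()
    chrom1, pos1, chrom2, pos2 = _parse_pairs_dataframe(path)
    n_in = len(pos1)

    cmap = binning._chrom_index
    cid1 = np.array([cmap.get(c, -1) for c in chrom1], dtype=np.int64)
    cid2 = np.array([cmap.get(c, -1) for c in chrom2], dtype=np.int64)
    known = (cid1 >= 0) & (cid2 >= 0)
    n_unknown = int((~known).sum())
    if n_unknown:
        import warnings

        warnings.warn(
            f"{n_unknown} pairs with unknown chromosome skipped", stacklevel=2
        )

    cid1, cid2 = cid1[known], cid2[known]
    p1, p2 = pos1[known] - 1, pos2[known] - 1  # to 0-based
    if np.any(p1 < 0) or np.any(p2 < 0):
        raise ValueError("non-positive 1-based position in pairs file")
    if np.any(p1 >= binning.chrom_lengths[cid1]) or np.any(
        p2 >= binning.chrom_lengths[cid2]
    ):
        raise ValueError(
            "read position beyond chromosome length; assembly mismatch?"
        )

    gi = binning.chrom_offsets[cid1] + p1 // binning.bin_size
    gj = binning.chrom_offsets[cid2] + p2 // binning.bin_size

    cis = cid1 == cid2
    n_cis = int(cis.sum())
    gi, gj = gi[~cis], gj[~cis]

    bl = exclusions.blacklist_mask(binning.n_total)
    hit_bl = bl[gi] | bl[gj]
    n_black = int(hit_bl.sum())
    gi, gj = gi[~hit_bl], gj[~hit_bl]

    gid = exclusions.group_id(binning.n_total)
    same_group = (gid[gi] >= 0) & (gid[gi] == gid[gj])
    n_grouped = int(same_group.sum())
    gi, gj = gi[~same_group], gj[~same_group]

    stats = {
        "pairs_in": n_in,
        "pairs_unknown_chrom": n_unknown,
        "pairs_cis": n_cis,
        "pairs_blacklisted": n_black,
        "pairs_grouped": n_grouped,
        "pairs_kept": int(gi.size),
    }
    return ContactTable.from_coo(
        binning, gi, gj, np.ones(gi.size, dtype=np.int64), stats=stats
    )


def write_pairs(table: ContactTable, path, comment: str | None = None):
    """Write a ContactTable as 4DN-dialect text pairs, one read per count.

    Reads are placed at bin midpoints (1-based), closing the I/O loop with
    :func:`load_pairs` at the same bin size.
    """
    b = table.binning
    mid1 = ((b.starts[table.row] + b.ends[table.row]) // 2 + 1).astype(np.int64)
    mid2 = ((b.starts[table.col] + b.ends[table.col]) // 2 + 1).astype(np.int64)
    with open(path, "w") as fh:
        fh.write("## pairs format v1.0\n")
        if comment:
            fh.write(f"# {comment}\n")
        for c, ln in zip(b.chrom_names, b.chrom_lengths):
            fh.write(f"#chromsize: {c} {ln}\n")
        fh.write("#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2\n")
        rid = 0
        for e in range(table.n_entries):
            c1 = b.chrom_names[b.chrom_ids[table.row[e]]]
            c2 = b.chrom_names[b.chrom_ids[table.col[e]]]
            for _ in range(int(table.count[e])):
                fh.write(f"read{rid}\t{c1}\t{mid1[e]}\t{c2}\t{mid2[e]}\t+\t+\n")
                rid += 1


def write_scores(model, binning: GenomeBinning, outdir, seed=None, extra=None):
    """Write a fitted model: score TSV, per-compartment bedGraphs, summary JSON.

    The TSV has columns chrom, start, end, P_1..P_M, B, status (0-based
    half-open intervals); bins with zero bias (blacklisted or no trans
    reads) have all-zero score rows and status ``missing``.
    """
    from .model_core import decompose

    os.makedirs(outdir, exist_ok=True)
    B, P, present = decompose(model)
    M = model.M
    chroms = [binning.chrom_names[c] for c in binning.chrom_ids]

    cols = {"chrom": chroms, "start": binning.starts, "end": binning.ends}
    for k in range(M):
        cols[f"P_{k + 1}"] = np.round(P[:, k], 6)
    cols["B"] = np.round(B, 6)
    cols["status"] = np.where(present, "ok", "missing")
    df = pd.DataFrame(cols)
    tsv_path = os.path.join(outdir, "scores.tsv")
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.6f")

    for k in range(M):
        bg = os.path.join(outdir, f"subcompartment_{k + 1}.bedgraph")
        with open(bg, "w") as fh:
            fh.write(f'track type=bedGraph name="subcompartment_{k + 1}"\n')
            for t in range(binning.n_total):
                fh.write(
                    f"{chroms[t]}\t{binning.starts[t]}\t{binning.ends[t]}"
                    f"\t{P[t, k]:.6f}\n"
                )

    summary = {
        "M": int(M),
        "alpha": float(model.alpha),
        "beta": float(model.beta),
        "n_nonempty": int(model.n_nonempty),
        "seed": seed,
    }
    if extra:
        summary.update(extra)
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return tsv_path


def read_scores(path):
    """Read back a score TSV written by :func:`write_scores`.

    Returns (DataFrame, P matrix, B vector).
    """
    df = pd.read_csv(path, sep="\t")
    pcols = [c for c in df.columns if c.startswith("P_")]
    P = df[pcols].to_numpy(dtype=np.float64)
    B = df["B"].to_numpy(dtype=np.float64)
    return df, P, B
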