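"""Binned contact-matrix containers, I/O, balancing, and expected profiles.

The central object is :class:`ContactMap`: a genome-wide symmetric matrix of
raw contact counts over a uniform :class:`BinTable`, stored as an
upper-triangular sparse matrix, plus optional per-bin balancing weights
(NaN marks bins excluded from all downstream averages).  Balanced signal is
always ``weights[i] * weights[j] * counts[i, j]``.

Two on-disk dialects are supported: a .cool-style HDF5 layout
(``chroms``/``bins``/``pixels`` tables, upper-triangle pixels) and a plain
TSV triplet text with a ``#`` header declaring chromosomes and bin size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "BinTable",
    "ContactMap",
    "ExpectedProfile",
    "read_contact_map",
    "write_cool",
    "write_triplet",
    "balance_ic",
    "expected",
    "obs_over_exp",
]


class MatrixIOError(ValueError):
    """Malformed contact-matrix file or inconsistent bin table."""


class BalanceError(RuntimeError):
    """Iterative correction failed (non-convergence or no usable bins)."""


@dataclass(frozen=True)
class BinTable:
    """Uniform genomic bin grid: chromosomes tiled contiguously in order.

    Coordinates are 0-based, half-open (BED semantics).  Every bin has
    ``end - start == bin_size`` except possibly the last bin per chromosome.
    """

    chromsizes: tuple[tuple[str, int], ...]
    bin_size: int

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if isinstance(self.chromsizes, Mapping):
            object.__setattr__(self, "chromsizes", tuple(self.chromsizes.items()))
        else:
            object.__setattr__(self, "chromsizes", tuple(map(tuple, self.chromsizes)))
        for name, length in self.chromsizes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    # -- derived geometry -------------------------------------------------
    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromsizes]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromsizes)

    def n_bins_chrom(self, chrom: str) -> int:
        length = self.chrom_lengths[chrom]
        return -(-length // self.bin_size)

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_chrom(c) for c in self.chrom_names)

    @property
    def chrom_offsets(self) -> dict[str, int]:
        offs, total = {}, 0
        for c in self.chrom_names:
            offs[c] = total
            total += self.n_bins_chrom(c)
        return offs

    def chrom_slice(self, chrom: str) -> slice:
        off = self.chrom_offsets[chrom]
        return slice(off, off + self.n_bins_chrom(chrom))

    def bins(self) -> pd.DataFrame:
        """(chrom, start, end) triple per bin, genome order."""
        rows = []
        for chrom, length in self.chromsizes:
            starts = np.arange(0, length, self.bin_size)
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def bin_id(self, chrom: str, pos: int) -> int:
        if not 0 <= pos < self.chrom_lengths[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self.chrom_offsets[chrom] + pos // self.bin_size

    def coarsen(self, resolution: int) -> "BinTable":
        if resolution % self.bin_size:
            raise MatrixIOError(
                f"resolution {resolution} is not a multiple of base {self.bin_size}"
            )
        return BinTable(self.chromsizes, resolution)


@dataclass
class ContactMap:
    """Symmetric binned contact matrix with optional balancing weights.

    ``counts`` is upper-triangular (i <= j) CSR over genome-wide bin ids;
    symmetry is implicit.  ``weights`` is a per-bin float vector, NaN for
    invalid bins, or None when unbalanced.
    """

    bin_table: BinTable
    counts: sp.csr_matrix
    weights: np.ndarray | None = None

    def __post_init__(self):
        n = self.bin_table.n_bins
        if self.counts.shape != (n, n):
            raise MatrixIOError("counts shape inconsistent with bin table")
        coo = self.counts.tocoo()
        if np.any(coo.row > coo.col):
            raise MatrixIOError("counts must be stored upper-triangular (i <= j)")
        if np.any(coo.data < 0):
            raise MatrixIOError("negative contact counts")

    # -- basic properties --------------------------------------------------
    @property
    def is_balanced(self) -> bool:
        return self.weights is not None

    def total_counts(self) -> float:
        return float(self.counts.sum())

    def valid_mask(self) -> np.ndarray:
        if self.weights is None:
            return np.ones(self.bin_table.n_bins, dtype=bool)
        return np.isfinite(self.weights)

    def _require_balanced(self):
        if self.weights is None:
            raise ValueError("operation requires a balanced map (run balance_ic)")

    # -- views -------------------------------------------------------------
    def balanced_coo(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle (row, col, balanced value) with invalid bins dropped."""
        self._require_balanced()
        coo = self.counts.tocoo()
        w = self.weights
        val = coo.data * w[coo.row] * w[coo.col]
        keep = np.isfinite(val)
        return coo.row[keep], coo.col[keep], val[keep]

    def dense(self, rows: slice, cols: slice, balanced: bool = True) -> np.ndarray:
        """Dense symmetric sub-block; invalid bins become NaN when balanced."""
        sym = self.counts.tocsr()
        block = (
            sym[rows, cols]
            + sym.T.tocsr()[rows, cols]
        ).toarray().astype(float)
        # diagonal pixels were added twice when the two slices overlap
        r = np.arange(rows.start, rows.stop)
        c = np.arange(cols.start, cols.stop)
        inter = np.intersect1d(r, c)
        if inter.size:
            ri = inter - rows.start
            ci = inter - cols.start
            block[ri, ci] -= np.asarray(sym[inter, inter]).ravel()
        if balanced:
            self._require_balanced()
            w = self.weights
            block = block * np.outer(w[rows], w[cols])
        return block

    def chrom_dense(self, chrom: str, balanced: bool = True) -> np.ndarray:
        s = self.bin_table.chrom_slice(chrom)
        return self.dense(s, s, balanced=balanced)

    def trans_block(self, chrom_a: str, chrom_b: str, balanced: bool = True) -> np.ndarray:
        return self.dense(
            self.bin_table.chrom_slice(chrom_a),
            self.bin_table.chrom_slice(chrom_b),
            balanced=balanced,
        )

    # -- resolution --------------------------------------------------------
    def coarsen(self, resolution: int) -> "ContactMap":
        """Sum counts into a coarser grid.  Weights are dropped (re-balance)."""
        bt = self.bin_table
        if resolution == bt.bin_size:
            return ContactMap(bt, self.counts.copy(), None)
        new_bt = bt.coarsen(resolution)
        factor = resolution // bt.bin_size
        # map old bin id -> new bin id, per chromosome
        mapping = np.empty(bt.n_bins, dtype=np.int64)
        for chrom in bt.chrom_names:
            old = bt.chrom_slice(chrom)
            new_off = new_bt.chrom_offsets[chrom]
            local = np.arange(old.stop - old.start) // factor
            mapping[old] = new_off + local
        coo = self.counts.tocoo()
        r = mapping[coo.row]
        c = mapping[coo.col]
        lo, hi = np.minimum(r, c), np.maximum(r, c)
        m = new_bt.n_bins
        new = sp.coo_matrix((coo.data, (lo, hi)), shape=(m, m)).tocsr()
        new.sum_duplicates()
        return ContactMap(new_bt, new, None)


@dataclass
class ExpectedProfile:
    """Distance-expected cis signal per chromosome + scalar trans expected.

    ``cis[chrom][d]`` is the mean balanced value over all valid intra-
    chromosomal bin pairs at bin-distance d (NaN where no valid pair);
    ``trans[(a, b)]`` is the mean balanced value over all valid a x b pairs.
    """

    cis: dict[str, np.ndarray] = field(default_factory=dict)
    cis_n_pairs: dict[str, np.ndarray] = field(default_factory=dict)
    trans: dict[tuple[str, str], float] = field(default_factory=dict)

    def trans_value(self, a: str, b: str) -> float:
        if (a, b) in self.trans:
            return self.trans[(a, b)]
        return self.trans[(b, a)]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cool(path: str | Path, cmap: ContactMap) -> None:
    """Write a .cool-style HDF5 file (chroms/bins/pixels, upper triangle)."""
    bt = cmap.bin_table
    bins = bt.bins()
    coo = sp.triu(cmap.counts).tocoo()
    order = np.lexsort((coo.col, coo.row))
    with h5py.File(path, "w") as h5:
        h5.attrs["bin-size"] = bt.bin_size
        h5.attrs["format"] = "HDF5::Cooler"
        g = h5.create_group("chroms")
        g.create_dataset("name", data=np.array(bt.chrom_names, dtype="S64"))
        g.create_dataset("length", data=np.array([l for _, l in bt.chromsizes], dtype=np.int64))
        g = h5.create_group("bins")
        chrom_idx = {c: i for i, c in enumerate(bt.chrom_names)}
        g.create_dataset("chrom", data=bins["chrom"].map(chrom_idx).to_numpy(np.int32))
        g.create_dataset("start", data=bins["start"].to_numpy(np.int64))
        g.create_dataset("end", data=bins["end"].to_numpy(np.int64))
        if cmap.weights is not None:
            g.create_dataset("weight", data=cmap.weights.astype(np.float64))
        g = h5.create_group("pixels")
        g.create_dataset("bin1_id", data=coo.row[order].astype(np.int64))
        g.create_dataset("bin2_id", data=coo.col[order].astype(np.int64))
        g.create_dataset("count", data=coo.data[order].astype(np.float64))


def write_triplet(path: str | Path, cmap: ContactMap) -> None:
    """Write the plain TSV triplet dialect (upper triangle, '#' header)."""
    bt = cmap.bin_table
    coo = sp.triu(cmap.counts).tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        fh.write(f"#binsize\t{bt.bin_size}\n")
        for name, length in bt.chromsizes:
            fh.write(f"#chromsize\t{name}\t{length}\n")
        for r, c, v in zip(coo.row[order], coo.col[order], coo.data[order]):
            fh.write(f"{r}\t{c}\t{v:.10g}\n")


def _read_cool(path: Path) -> ContactMap:
    with h5py.File(path, "r") as h5:
        for key in ("chroms", "bins", "pixels"):
            if key not in h5:
                raise MatrixIOError(f"unknown dialect: missing HDF5 group {key!r}")
        names = [n.decode() for n in h5["chroms/name"][:]]
        lengths = h5["chroms/length"][:]
        bin_size = int(h5.attrs["bin-size"])
        bt = BinTable(tuple(zip(names, map(int, lengths))), bin_size)
        starts = h5["bins/start"][:]
        if len(starts) != bt.n_bins:
            raise MatrixIOError("bin table inconsistent with declared chromosome lengths")
        r = h5["pixels/bin1_id"][:]
        c = h5["pixels/bin2_id"][:]
        v = h5["pixels/count"][:].astype(float)
        weights = None
        if "weight" in h5["bins"]:
            weights = h5["bins/weight"][:].astype(float)
    if np.any(r > c):
        raise MatrixIOError("pixels must be upper-triangular")
    n = bt.n_bins
    counts = sp.coo_matrix((v, (r, c)), shape=(n, n)).tocsr()
    return ContactMap(bt, counts, weights)


def _read_triplet(path: Path) -> ContactMap:
    bin_size = None
    chromsizes: list[tuple[str, int]] = []
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                if parts[0] == "binsize":
                    bin_size = int(parts[1])
                elif parts[0] == "chromsize":
                    chromsizes.append((parts[1], int(parts[2])))
                else:
                    raise MatrixIOError(f"unknown header key {parts[0]!r} (line {lineno})")
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise MatrixIOError(f"malformed triplet on line {lineno}")
            rows.append(int(parts[0]))
            cols.append(int(parts[1]))
            vals.append(float(parts[2]))
    if bin_size is None or not chromsizes:
        raise MatrixIOError("triplet header must declare #binsize and #chromsize lines")
    bt = BinTable(tuple(chromsizes), bin_size)
    r = np.asarray(rows, dtype=np.int64)
    c = np.asarray(cols, dtype=np.int64)
    v = np.asarray(vals, dtype=float)
    if r.size and (r.min() < 0 or max(r.max(), c.max() if c.size else 0) >= bt.n_bins):
        raise MatrixIOError("bin id outside the declared bin table")
    lo, hi = np.minimum(r, c), np.maximum(r, c)
    key = lo * bt.n_bins + hi
    uniq, counts_per_key = np.unique(key, return_counts=True)
    if np.any(counts_per_key > 1):
        dup = uniq[counts_per_key > 1][0]
        i, j = divmod(int(dup), bt.n_bins)
        # distinguish symmetric duplicates (i,j) + (j,i) from plain repeats
        mask = key == dup
        if i != j and len(set(zip(r[mask], c[mask]))) > 1:
            raise MatrixIOError(f"asymmetric duplicate records for bin pair ({i}, {j})")
        raise MatrixIOError(f"duplicate records for bin pair ({i}, {j})")
    counts = sp.coo_matrix((v, (lo, hi)), shape=(bt.n_bins, bt.n_bins)).tocsr()
    return ContactMap(bt, counts, None)


def read_contact_map(path: str | Path, resolution: int | None = None) -> ContactMap:
    """Read a contact map; optionally coarsen to ``resolution``.

    Coarsening sums counts into the coarser grid and drops any stored
    weights (the coarse map must be re-balanced).
    """
    path = Path(path)
    if h5py.is_hdf5(path):
        cmap = _read_cool(path)
    else:
        cmap = _read_triplet(path)
    if resolution is not None and resolution != cmap.bin_table.bin_size:
        cmap = cmap.coarsen(resolution)
    return cmap


# ---------------------------------------------------------------------------
# Balancing (iterative correction)
# ---------------------------------------------------------------------------

def balance_ic(
    cmap: ContactMap,
    tol: float = 1e-5,
    max_iter: int = 500,
    min_coverage_quantile: float = 0.02,
) -> ContactMap:
    """Iterative-correction balancing: equalize valid-bin marginals to 1.

    Bins with zero raw marginal, or whose nonzero marginal falls below the
    ``min_coverage_quantile`` quantile, are flagged invalid (NaN weight) and
    excluded from all downstream averages.
    """
    n = cmap.bin_table.n_bins
    upper = cmap.counts.tocsr()
    lower = sp.triu(upper, k=1).T.tocsr()
    ones = np.ones(n)
    raw_marg = upper @ ones + lower @ ones
    valid = raw_marg > 0
    nz = raw_marg[valid]
    if nz.size:
        cut = np.quantile(nz, min_coverage_quantile)
        valid &= raw_marg >= cut
    if valid.sum() < 2:
        raise BalanceError("all bins invalid (insufficient coverage)")

    w = np.where(valid, 1.0, 0.0)
    residual = np.inf
    for _ in range(max_iter):
        # marginal of the currently-scaled matrix
        m = w * (upper @ w + lower @ w)
        if np.any(m[valid] == 0):
            # a bin can lose all its partners to the invalid set
            valid &= m > 0
            if valid.sum() < 2:
                raise BalanceError("all bins invalid (insufficient coverage)")
            w = np.where(valid, w, 0.0)
            m = w * (upper @ w + lower @ w)
        mv = m[valid]
        mean = mv.mean()
        residual = float(np.abs(mv / mean - 1.0).max()) if mean > 0 else np.inf
        if residual <= tol:
            break
        scale = np.ones(n)
        scale[valid] = np.sqrt(mv / mean)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(valid, w / scale, 0.0)
    else:
        raise BalanceError(
            f"iterative correction did not converge in {max_iter} iterations "
            f"(last residual {residual:.3g})"
        )
    # normalize so each valid marginal equals 1 (not just equal)
    m = w * (upper @ w + lower @ w)
    w[valid] /= np.sqrt(m[valid].mean())
    weights = np.where(valid, w, np.nan)
    return ContactMap(cmap.bin_table, cmap.counts, weights)


# ---------------------------------------------------------------------------
# Expected profiles and observed/expected views
# ---------------------------------------------------------------------------

def _valid_pairs_per_distance(valid: np.ndarray) -> np.ndarray:
    """Number of valid (i, i+d) pairs for d = 0..n-1 (autocorrelation)."""
    v = valid.astype(float)
    n = len(v)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(v, nfft)
    corr = np.fft.irfft(f * np.conj(f), nfft)[:n]
    return np.rint(corr).astype(np.int64)


def expected(cmap: ContactMap) -> ExpectedProfile:
    """Per-chromosome distance-expected (cis) and per-pair scalar (trans).

    cis[d] = mean balanced value over all valid intra-chromosomal pairs at
    bin-distance d; zeros count (the mean is over all valid pairs, not only
    nonzero pixels).
    """
    cmap._require_balanced()
    bt = cmap.bin_table
    w = cmap.weights
    valid = np.isfinite(w)
    row, col, val = cmap.balanced_coo()
    prof = ExpectedProfile()

    offsets = bt.chrom_offsets
    chrom_of = np.empty(bt.n_bins, dtype=np.int32)
    for k, chrom in enumerate(bt.chrom_names):
        chrom_of[bt.chrom_slice(chrom)] = k

    same = chrom_of[row] == chrom_of[col]
    any_pairs = False
    for k, chrom in enumerate(bt.chrom_names):
        s = bt.chrom_slice(chrom)
        nb = s.stop - s.start
        sel = same & (chrom_of[row] == k)
        d = col[sel] - row[sel]
        sums = np.bincount(d, weights=val[sel], minlength=nb)
        npairs = _valid_pairs_per_distance(valid[s])
        with np.errstate(invalid="ignore", divide="ignore"):
            cis = np.where(npairs > 0, sums / npairs, np.nan)
        prof.cis[chrom] = cis
        prof.cis_n_pairs[chrom] = npairs
        if npairs.sum() > 0:
            any_pairs = True

    names = bt.chrom_names
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            si, sj = bt.chrom_slice(names[i]), bt.chrom_slice(names[j])
            sel = (chrom_of[row] == i) & (chrom_of[col] == j)
            n_valid = int(valid[si].sum()) * int(valid[sj].sum())
            if n_valid == 0:
                prof.trans[(names[i], names[j])] = np.nan
                continue
            prof.trans[(names[i], names[j])] = float(val[sel].sum()) / n_valid
            any_pairs = True
    if not any_pairs:
        warnings.warn("no valid pairs at any distance; expected profile is empty")
    return prof


def obs_over_exp(
    cmap: ContactMap,
    region_a: tuple[str, int, int],
    region_b: tuple[str, int, int],
    profile: ExpectedProfile,
) -> np.ndarray:
    """Element-wise balanced / expected for a region pair.

    Regions are (chrom, start, end) on the bin grid.  Invalid bins and
    zero-expected distances yield NaN (never infinity).
    """
    bt = cmap.bin_table
    sl = []
    for chrom, start, end in (region_a, region_b):
        if start % bt.bin_size or (end % bt.bin_size and end != bt.chrom_lengths[chrom]):
            raise ValueError(f"region ({chrom}, {start}, {end}) off the bin grid")
        off = bt.chrom_offsets[chrom]
        sl.append(slice(off + start // bt.bin_size, off + -(-end // bt.bin_size)))
    sa, sb = sl
    block = cmap.dense(sa, sb, balanced=True)
    chrom_a, chrom_b = region_a[0], region_b[0]
    if chrom_a == chrom_b:
        cis = profile.cis[chrom_a]
        i = np.arange(sa.start, sa.stop)[:, None]
        j = np.arange(sb.start, sb.stop)[None, :]
        d = np.abs(i - j)
        exp = cis[d]
    else:
        exp = np.full(block.shape, profile.trans_value(chrom_a, chrom_b))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where((exp > 0) & np.isfinite(exp), block / exp, np.nan)
    return out
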