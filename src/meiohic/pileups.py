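"""Aggregate (pileup) Hi-C signal around site sets.

Pairwise pileups average obs/exp sub-matrices centered on same-chromosome
site pairs within a separation band, optionally normalized by randomly
shifted control pairs (shifts preserve separation and chromosome).  Local
pileups average on-diagonal obs/exp windows centered at single sites;
window quantifications sum balanced signal over the full window or along
the center line through the site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrixio import ContactMap, ExpectedProfile

__all__ = [
    "PileupResult",
    "pairwise_pileup",
    "local_pileup",
    "quantify_windows",
    "sites_to_bins",
]


@dataclass
class PileupResult:
    """Mean obs/exp window (odd side), pair/site count, optional control."""

    matrix: np.ndarray
    n_windows: int
    control: np.ndarray | None = None

    @property
    def normalized(self) -> np.ndarray:
        if self.control is None:
            raise ValueError("no shifted control was requested")
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.control > 0, self.matrix / self.control, np.nan)


def sites_to_bins(bt, sites: pd.DataFrame) -> dict[str, np.ndarray]:
    """Snap intervals to the bin containing their midpoint, per chromosome."""
    out: dict[str, list[int]] = {c: [] for c in bt.chrom_names}
    for _, iv in sites.iterrows():
        mid = (int(iv["start"]) + int(iv["end"])) // 2
        if iv["chrom"] in out and 0 <= mid < bt.chrom_lengths[iv["chrom"]]:
            out[iv["chrom"]].append(mid // bt.bin_size)
    return {c: np.unique(np.asarray(v, dtype=int)) for c, v in out.items() if v}


def _oe_chrom(cmap: ContactMap, profile: ExpectedProfile, chrom: str) -> np.ndarray:
    block = cmap.chrom_dense(chrom, balanced=True)
    cis = profile.cis[chrom]
    nb = block.shape[0]
    d = np.abs(np.arange(nb)[:, None] - np.arange(nb)[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(cis[d] > 0, block / cis[d], np.nan)


def _accumulate(oe: np.ndarray, pairs: list[tuple[int, int]], fw: int,
                total: np.ndarray, count: np.ndarray) -> int:
    nb = oe.shape[0]
    used = 0
    for i, j in pairs:
        if i - fw < 0 or j - fw < 0 or i + fw >= nb or j + fw >= nb:
            continue
        win = oe[i - fw: i + fw + 1, j - fw: j + fw + 1]
        fin = np.isfinite(win)
        total += np.where(fin, win, 0.0)
        count += fin
        used += 1
    return used


def pairwise_pileup(cmap: ContactMap, sites: pd.DataFrame,
                    profile: ExpectedProfile,
                    min_sep: int = 500_000, max_sep: int = 2_000_000,
                    flank: int = 500_000, n_controls: int = 10,
                    seed: int = 0) -> PileupResult:
    """Average obs/exp around same-chromosome site pairs in [min_sep, max_sep].

    The control matrix repeats the averaging over ``n_controls`` randomly
    shifted pairs per eligible pair; a shift is uniform in +-[flank,
    10*flank], applied to both anchors (preserving separation and
    chromosome), rejection-sampled to stay on the chromosome.
    """
    bt = cmap.bin_table
    fw = flank // bt.bin_size
    side = 2 * fw + 1
    rng = np.random.default_rng(seed)
    total = np.zeros((side, side))
    count = np.zeros((side, side))
    ctl_total = np.zeros((side, side)) if n_controls else None
    ctl_count = np.zeros((side, side)) if n_controls else None
    bins_by_chrom = sites_to_bins(bt, sites)
    n_pairs = 0
    for chrom, bins in bins_by_chrom.items():
        lo_d = -(-min_sep // bt.bin_size)
        hi_d = max_sep // bt.bin_size
        pairs = [
            (int(bins[a]), int(bins[b]))
            for a in range(len(bins))
            for b in range(a + 1, len(bins))
            if lo_d <= bins[b] - bins[a] <= hi_d
        ]
        if not pairs:
            continue
        oe = _oe_chrom(cmap, profile, chrom)
        nb = oe.shape[0]
        n_pairs += _accumulate(oe, pairs, fw, total, count)
        if n_controls:
            shift_lo, shift_hi = fw, 10 * fw
            for i, j in pairs:
                placed = 0
                attempts = 0
                while placed < n_controls and attempts < 100 * n_controls:
                    attempts += 1
                    mag = rng.integers(shift_lo, shift_hi + 1)
                    sgn = 1 if rng.random() < 0.5 else -1
                    ii, jj = i + sgn * mag, j + sgn * mag
                    if ii - fw < 0 or jj + fw >= nb:
                        continue
                    win = oe[ii - fw: ii + fw + 1, jj - fw: jj + fw + 1]
                    fin = np.isfinite(win)
                    ctl_total += np.where(fin, win, 0.0)
                    ctl_count += fin
                    placed += 1
    if n_pairs == 0:
        raise ValueError("no eligible site pairs in the separation band")
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = np.where(count > 0, total / count, np.nan)
        control = None
        if n_controls:
            control = np.where(ctl_count > 0, ctl_total / ctl_count, np.nan)
    return PileupResult(matrix=matrix, n_windows=n_pairs, control=control)


def local_pileup(cmap: ContactMap, sites: pd.DataFrame,
                 profile: ExpectedProfile, flank: int = 1_000_000
                 ) -> PileupResult:
    """Mean obs/exp over windows centered at each site's diagonal position."""
    bt = cmap.bin_table
    fw = flank // bt.bin_size
    side = 2 * fw + 1
    total = np.zeros((side, side))
    count = np.zeros((side, side))
    n_sites = 0
    for chrom, bins in sites_to_bins(bt, sites).items():
        oe = _oe_chrom(cmap, profile, chrom)
        n_sites += _accumulate(oe, [(int(b), int(b)) for b in bins], fw,
                               total, count)
    if n_sites == 0:
        raise ValueError("all sites are too close to chromosome ends")
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = np.where(count > 0, total / count, np.nan)
    return PileupResult(matrix=matrix, n_windows=n_sites)


def quantify_windows(cmap: ContactMap, sites: pd.DataFrame, flank: int,
                     mode: str = "total") -> pd.DataFrame:
    """Per-site balanced-signal sums over (2*flank)^2 windows.

    mode 'total': sum of balanced signal in the square window around the
    site's diagonal position.  mode 'centerline': sum of balanced signal
    between the site's single bin and every bin within +-flank — each
    (site, other) pair counted once, i.e. the single row through the site
    (by symmetry identical to the single column; center pixel once).
    """
    if mode not in {"total", "centerline"}:
        raise ValueError("mode must be 'total' or 'centerline'")
    bt = cmap.bin_table
    fw = flank // bt.bin_size
    valid = cmap.valid_mask()
    rows = []
    for chrom, bins in sites_to_bins(bt, sites).items():
        block = cmap.chrom_dense(chrom, balanced=True)
        nb = block.shape[0]
        off = bt.chrom_offsets[chrom]
        for b in bins:
            b = int(b)
            if b - fw < 0 or b + fw >= nb:
                continue
            if not valid[off + b]:
                raise ValueError(f"site bin {chrom}:{b} is invalid (unbalanced)")
            win = block[b - fw: b + fw + 1, b - fw: b + fw + 1]
            if mode == "total":
                value = np.nansum(win)
            else:
                value = np.nansum(win[fw, :])
            rows.append((chrom, b * bt.bin_size,
                         min((b + 1) * bt.bin_size, bt.chrom_lengths[chrom]), value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
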