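"""Diamond insulation index, TAD-boundary calling, and track utilities.

The insulation index of bin i is the log2 of the mean balanced signal in
the off-diagonal square spanning the w bins upstream x w bins downstream of
i, normalized by the chromosome's mean square signal.  Minima of the track
mark contact-insulating loci; boundaries are local minima whose prominence
exceeds a noise threshold (default 0.1, the threshold used to retain only
the most prominent boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .matrixio import ContactMap

__all__ = [
    "InsulationTrack",
    "BoundarySet",
    "insulation_track",
    "call_boundaries",
    "score_at_intervals",
    "track_correlation",
]


@dataclass
class InsulationTrack:
    """Per-bin insulation index (log2 ratio); NaN for flank/invalid bins."""

    bin_table: object
    values: np.ndarray
    window: int

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.bin_table.chrom_slice(chrom)]

    def to_bedgraph(self, path) -> None:
        bins = self.bin_table.bins()
        ok = np.isfinite(self.values)
        out = bins.loc[ok].copy()
        out["value"] = self.values[ok]
        out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class BoundarySet:
    """Boundary bins (global ids) with prominence-based strength > 0."""

    bins: np.ndarray
    strength: np.ndarray

    def to_frame(self, bin_table) -> pd.DataFrame:
        tbl = bin_table.bins().iloc[self.bins].copy()
        tbl["score"] = self.strength
        return tbl.reset_index(drop=True)


def _square_stats(row: np.ndarray, col: np.ndarray, val: np.ndarray,
                  valid: np.ndarray, nb: int, w: int):
    """Sum of balanced values and valid-pixel count of every insulation square.

    Square for bin t: rows [t-w, t), cols [t, t+w).  A pixel (r, c) with
    r < c contributes to all t in [max(r+1, c-w+1), min(r+w, c)]; the range
    update is accumulated with a difference array.
    """
    sel = row < col
    r, c, v = row[sel], col[sel], val[sel]
    lo = np.maximum(r + 1, c - w + 1)
    hi = np.minimum(r + w, c)
    keep = hi >= lo
    lo, hi, v = lo[keep], hi[keep], v[keep]
    diff = np.zeros(nb + 1)
    np.add.at(diff, lo, v)
    np.add.at(diff, hi + 1, -v)
    sums = np.cumsum(diff)[:nb]

    cv = np.concatenate(([0], np.cumsum(valid.astype(np.int64))))
    t = np.arange(nb)
    n_rows = np.where(t >= w, cv[t] - cv[np.maximum(t - w, 0)], 0)
    n_cols = np.where(t + w <= nb, cv[np.minimum(t + w, nb)] - cv[t], 0)
    return sums, n_rows * n_cols


def insulation_track(cmap: ContactMap, window: int = 500_000,
                     max_invalid_frac: float = 0.5) -> InsulationTrack:
    """Windowed-square insulation index per bin, log2-normalized per chromosome.

    Defined only for bins a full window away from both chromosome ends;
    squares with more than ``max_invalid_frac`` invalid pixels are missing.
    """
    bt = cmap.bin_table
    if window % bt.bin_size:
        raise ValueError("window must be a multiple of the bin size")
    w = window // bt.bin_size
    values = np.full(bt.n_bins, np.nan)
    row, col, val = cmap.balanced_coo()
    valid = cmap.valid_mask()
    for chrom in bt.chrom_names:
        sl = bt.chrom_slice(chrom)
        nb = sl.stop - sl.start
        if 2 * w >= nb:
            raise ValueError(f"window larger than chromosome {chrom}")
        on = (row >= sl.start) & (col < sl.stop)
        sums, npix = _square_stats(row[on] - sl.start, col[on] - sl.start,
                                   val[on], valid[sl], nb, w)
        t = np.arange(nb)
        eligible = (t >= w) & (t + w <= nb) & (npix > (1 - max_invalid_frac) * w * w)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(eligible, sums / np.maximum(npix, 1), np.nan)
        chrom_mean = np.nanmean(means) if np.any(eligible) else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            values[sl] = np.log2(means / chrom_mean)
    return InsulationTrack(bin_table=bt, values=values, window=window)


def call_boundaries(track: InsulationTrack, noise_threshold: float = 0.1
                    ) -> BoundarySet:
    """Local minima of the insulation track with prominence >= threshold."""
    bins_all, strength_all = [], []
    bt = track.bin_table
    for chrom in bt.chrom_names:
        sl = bt.chrom_slice(chrom)
        v = track.values[sl]
        finite = np.isfinite(v)
        # process each finite run independently (gaps break minima search)
        idx = np.flatnonzero(finite)
        if idx.size < 3:
            continue
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            if run.size < 3:
                continue
            seg = v[run]
            peaks, props = find_peaks(-seg, prominence=noise_threshold)
            if peaks.size:
                bins_all.append(sl.start + run[peaks])
                strength_all.append(props["prominences"])
    if not bins_all:
        return BoundarySet(np.array([], dtype=int), np.array([]))
    return BoundarySet(np.concatenate(bins_all), np.concatenate(strength_all))


def score_at_intervals(track: InsulationTrack, sets: dict[str, pd.DataFrame],
                       complement_label: str | None = None,
                       n_complement: int | None = None,
                       seed: int = 0) -> dict[str, np.ndarray]:
    """Insulation values of the bins containing each labeled interval set.

    Intervals are snapped to the bin containing their midpoint.  When
    ``complement_label`` is given, a seeded sample of defined bins covered
    by no input interval is added as the non-peak control.
    """
    bt = track.bin_table
    out: dict[str, np.ndarray] = {}
    occupied = np.zeros(bt.n_bins, dtype=bool)
    for label, frame in sets.items():
        if len(frame) == 0:
            raise ValueError(f"empty interval label {label!r}")
        ids = []
        for _, iv in frame.iterrows():
            mid = (int(iv["start"]) + int(iv["end"])) // 2
            ids.append(bt.bin_id(iv["chrom"], mid))
        ids = np.asarray(ids, dtype=int)
        occupied[ids] = True
        vals = track.values[ids]
        out[label] = vals[np.isfinite(vals)]
    if complement_label is not None:
        pool = np.flatnonzero(~occupied & np.isfinite(track.values))
        rng = np.random.default_rng(seed)
        k = n_complement or min(pool.size, max(len(v) for v in out.values()))
        pick = rng.choice(pool, size=min(k, pool.size), replace=False)
        out[complement_label] = track.values[np.sort(pick)]
    return out


def track_correlation(a: np.ndarray, b: np.ndarray, min_overlap: int = 10) -> float:
    """Pearson r over pairwise-complete bins of two same-grid tracks."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tracks must share one bin grid")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < min_overlap:
        raise ValueError(f"fewer than {min_overlap} pairwise-complete bins")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])
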