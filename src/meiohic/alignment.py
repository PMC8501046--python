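"""Trans-chromosomal end-alignment analytics and inter-homolog scores.

Mouse chromosomes are acrocentric: the centromere-proximal (CEN) end is
chromosome coordinate 0 and the centromere-distal (TEL) end is the far end.
Sub-telomeric statistics average balanced trans signal over 5 Mb windows at
each end for every autosome pair; the polarity
Pi = (CEN-CEN + TEL-TEL) / (2 * CEN-TEL) quantifies bouquet-like end
coalescence.  Averaged trans obs/exp maps (every pair rescaled to a common
500 x 500 grid, CEN->TEL on both axes) expose the diagonal alignment tracts
whose fractional extent is estimated from the 21 x 21-windowed diagonal
profile.  The same windowed-diagonal construction, normalized by the
block's per-bin mean, yields the inter-homolog alignment score.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .matrixio import ContactMap, ExpectedProfile

__all__ = [
    "SubTelomericStats",
    "TransAlignmentProfile",
    "autosome_pairs",
    "subtelomeric_stats",
    "polarity",
    "rescale_bilinear",
    "averaged_trans_map",
    "diagonal_profile",
    "tract_extent",
    "homolog_alignment_score",
    "scores_by_class",
]


@dataclass
class SubTelomericStats:
    """Per-pair mean balanced signal per bin for CEN-CEN/TEL-TEL/CEN-TEL."""

    frame: pd.DataFrame  # chrom_a, chrom_b, cen_cen, tel_tel, cen_tel

    def __len__(self):
        return len(self.frame)


@dataclass
class TransAlignmentProfile:
    """Averaged rescaled trans obs/exp matrix and diagonal-tract readouts."""

    matrix: np.ndarray                # n x n averaged obs/exp
    raw_profile: np.ndarray | None = None
    smoothed_profile: np.ndarray | None = None
    extent_cen: float | None = None
    extent_tel: float | None = None


def autosome_pairs(chrom_names) -> list[tuple[str, str]]:
    """All unordered pairs of distinct autosomes (19 autosomes -> 171)."""
    return list(combinations(list(chrom_names), 2))


def subtelomeric_stats(cmap: ContactMap, window: int = 5_000_000,
                       pairs=None) -> SubTelomericStats:
    """Mean balanced trans signal per bin over 5 Mb end-window pairs.

    CEN = chromosome start.  The CEN-TEL category pools both cross
    orientations (A-CEN x B-TEL and A-TEL x B-CEN).  Means are per valid
    bin pair; NaN pixels (invalid bins) are excluded.
    """
    bt = cmap.bin_table
    wb = window // bt.bin_size
    if pairs is None:
        pairs = autosome_pairs(bt.chrom_names)
    rows = []
    for ca, cb in pairs:
        for c in (ca, cb):
            if bt.chrom_lengths[c] < 2 * window:
                raise ValueError(f"chromosome {c} shorter than twice the window")
        block = cmap.trans_block(ca, cb, balanced=True)
        cen_a, tel_a = slice(0, wb), slice(block.shape[0] - wb, block.shape[0])
        cen_b, tel_b = slice(0, wb), slice(block.shape[1] - wb, block.shape[1])
        cc = np.nanmean(block[cen_a, cen_b])
        tt = np.nanmean(block[tel_a, tel_b])
        ct = np.nanmean(np.concatenate([
            block[cen_a, tel_b].ravel(), block[tel_a, cen_b].ravel()]))
        rows.append((ca, cb, cc, tt, ct))
    return SubTelomericStats(pd.DataFrame(
        rows, columns=["chrom_a", "chrom_b", "cen_cen", "tel_tel", "cen_tel"]))


def polarity(stats: SubTelomericStats) -> pd.Series:
    """Pi = (CEN-CEN + TEL-TEL) / (2 * CEN-TEL) per chromosome pair."""
    f = stats.frame
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = (f["cen_cen"] + f["tel_tel"]) / (2.0 * f["cen_tel"])
    return pi.where(f["cen_tel"] > 0)


def rescale_bilinear(matrix: np.ndarray, n: int) -> np.ndarray:
    """Bilinear rescaling of a matrix to n x n (cell-center convention).

    Source and target cells are placed by their centers on [0, 1]; target
    positions outside the source center range clamp to the edge rows/cols.
    NaNs propagate into the cells they touch.
    """
    src = np.asarray(matrix, dtype=float)
    out_rows = _interp_axis(src, n, axis=0)
    return _interp_axis(out_rows, n, axis=1)


def _interp_axis(a: np.ndarray, n: int, axis: int) -> np.ndarray:
    m = a.shape[axis]
    pos = (np.arange(n) + 0.5) / n * m - 0.5
    lo = np.clip(np.floor(pos).astype(int), 0, m - 1)
    hi = np.clip(lo + 1, 0, m - 1)
    frac = np.clip(pos - lo, 0.0, 1.0)
    a_lo = np.take(a, lo, axis=axis)
    a_hi = np.take(a, hi, axis=axis)
    shape = [1, 1]
    shape[axis] = n
    f = frac.reshape(shape)
    return a_lo * (1 - f) + a_hi * f


def averaged_trans_map(cmap: ContactMap, profile: ExpectedProfile,
                       pairs=None, n: int = 500) -> TransAlignmentProfile:
    """Average the rescaled trans obs/exp blocks of all chromosome pairs.

    Every pair's balanced block is divided by its scalar trans expected,
    oriented CEN->TEL on both axes, bilinearly rescaled to n x n, and
    averaged with equal pair weight; missing pixels are excluded per-pixel.
    """
    bt = cmap.bin_table
    if pairs is None:
        pairs = autosome_pairs(bt.chrom_names)
    if not pairs:
        raise ValueError("empty chromosome-pair list")
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for ca, cb in pairs:
        block = cmap.trans_block(ca, cb, balanced=True)
        exp = profile.trans_value(ca, cb)
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = block / exp if exp > 0 else np.full_like(block, np.nan)
        scaled = rescale_bilinear(oe, n)
        fin = np.isfinite(scaled)
        total += np.where(fin, scaled, 0.0)
        count += fin
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = np.where(count > 0, total / count, np.nan)
    return TransAlignmentProfile(matrix=avg)


def _windowed_diagonal_means(matrix: np.ndarray, half_window: int) -> np.ndarray:
    """Mean of the (2h+1)^2 square centered at each diagonal bin, edge-truncated."""
    n = matrix.shape[0]
    fin = np.isfinite(matrix)
    vals = np.where(fin, matrix, 0.0)
    cs = np.zeros((n + 1, n + 1))
    cs[1:, 1:] = np.cumsum(np.cumsum(vals, axis=0), axis=1)
    cn = np.zeros((n + 1, n + 1))
    cn[1:, 1:] = np.cumsum(np.cumsum(fin, axis=0), axis=1)

    def box(c, r0, r1, c0, c1):
        return c[r1, c1] - c[r0, c1] - c[r1, c0] + c[r0, c0]

    out = np.full(n, np.nan)
    for t in range(n):
        r0, r1 = max(0, t - half_window), min(n, t + half_window + 1)
        s = box(cs, r0, r1, r0, r1)
        m = box(cn, r0, r1, r0, r1)
        if m > 0:
            out[t] = s / m
    return out


def diagonal_profile(profile: TransAlignmentProfile, half_window: int = 10,
                     span: float = 1.0 / 20.0) -> TransAlignmentProfile:
    """21 x 21 sliding-square diagonal means, then loess smoothing.

    The raw profile assigns to each diagonal index the mean of the square
    centered there (truncated at matrix edges); the smoothed profile is the
    loess fit at the given span evaluated on the same grid.
    """
    raw = _windowed_diagonal_means(profile.matrix, half_window)
    x = np.arange(raw.size, dtype=float)
    ok = np.isfinite(raw)
    smooth = np.full_like(raw, np.nan)
    if ok.sum() >= 3:
        smooth[ok] = sm.nonparametric.lowess(
            raw[ok], x[ok], frac=span, it=0, return_sorted=False)
    profile.raw_profile = raw
    profile.smoothed_profile = smooth
    return profile


def tract_extent(smoothed: np.ndarray, baseline_central_frac: float = 0.2,
                 peak_outer_frac: float = 0.05) -> tuple[float, float]:
    """Per-end alignment-tract extent from the smoothed diagonal profile.

    Baseline b = median over the central ``baseline_central_frac`` of
    indices; end peak p = max over the outer ``peak_outer_frac`` of that
    end; threshold = b + (p - b)/2.  The extent is the largest fraction x
    such that the profile exceeds the threshold at every index within x of
    that end; 0 when p <= b.
    """
    v = np.asarray(smoothed, dtype=float)
    n = v.size
    if n < 50:
        raise ValueError("profile too short for tract-extent estimation")
    c0 = int(np.floor(n * (0.5 - baseline_central_frac / 2)))
    c1 = int(np.ceil(n * (0.5 + baseline_central_frac / 2)))
    b = float(np.nanmedian(v[c0:c1]))
    k = max(1, int(round(n * peak_outer_frac)))

    def one_end(seq: np.ndarray) -> float:
        p = float(np.nanmax(seq[:k]))
        if not np.isfinite(p) or p <= b:
            return 0.0
        theta = b + (p - b) / 2.0
        above = seq > theta
        if not above[0]:
            return 0.0
        stop = int(np.argmin(above)) if not above.all() else n
        return stop / n

    return one_end(v), one_end(v[::-1])


def homolog_alignment_score(block: np.ndarray, half_window: int = 10,
                            mode: str = "window") -> np.ndarray:
    """Per-bin inter-homolog alignment score for one homolog pair block.

    mode 'window' (default): mean signal in the (2h+1)^2 square centered at
    each diagonal bin, normalized per chromosome pair so the mean of the
    defined scores is 1.  mode 'band100k' (variant): per-bin total signal to
    partner bins within ``half_window`` bins of the diagonal, normalized the
    same way.
    """
    block = np.asarray(block, dtype=float)
    if not np.isfinite(np.nanmean(block)) or np.nanmean(block) == 0:
        raise ValueError("zero or undefined block mean; cannot normalize")
    if mode == "window":
        raw = _windowed_diagonal_means(block, half_window)
    elif mode == "band100k":
        n = block.shape[0]
        raw = np.full(n, np.nan)
        for t in range(n):
            lo, hi = max(0, t - half_window), min(n, t + half_window + 1)
            raw[t] = np.nansum(block[t, lo:hi])
    else:
        raise ValueError("mode must be 'window' or 'band100k'")
    return raw / np.nanmean(raw)


def scores_by_class(scores: np.ndarray, labels: np.ndarray,
                    n_position_bins: int | None = None,
                    interior_margin: int = 0
                    ) -> dict[object, np.ndarray] | pd.DataFrame:
    """Group per-bin scores by class label, optionally by chromosome position.

    Without ``n_position_bins``: dict class -> score vector (NaN dropped).
    With it: per-class mean score in each of ``n_position_bins`` equal
    CEN->TEL position bins, as a tidy frame.  ``interior_margin`` > 0 drops
    bins within that many bins of a class boundary — for windowed scores
    this isolates the per-class signal from boundary-straddling windows
    (set it to the score's window half-width to recover planted class
    enrichment ratios).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must share the bin grid")
    if interior_margin > 0:
        interior = np.ones(labels.size, dtype=bool)
        change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
        for b in change:
            interior[max(0, b - interior_margin): b + interior_margin] = False
        scores = np.where(interior, scores, np.nan)
    classes = [c for c in pd.unique(labels)]
    if n_position_bins is None:
        out = {}
        for c in classes:
            v = scores[labels == c]
            out[c] = v[np.isfinite(v)]
            if out[c].size == 0:
                raise ValueError(f"class {c!r} has no defined scores")
        return out
    pos = np.arange(scores.size) / scores.size
    pos_bin = np.minimum((pos * n_position_bins).astype(int), n_position_bins - 1)
    rows = []
    for c in classes:
        for pb in range(n_position_bins):
            sel = (labels == c) & (pos_bin == pb)
            v = scores[sel]
            v = v[np.isfinite(v)]
            rows.append((c, pb, v.mean() if v.size else np.nan, v.size))
    return pd.DataFrame(rows, columns=["cls", "position_bin", "mean_score", "n"])
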