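"""Contact-probability scaling curves P(s), log-log slopes, and loop sizes.

P(s) is computed on geometrically spaced distance bins (spacing factor 1.12)
by averaging balanced contact values over all valid bin pairs in each
distance bin.  The log-space derivative of P(s), loess-smoothed, peaks at
the average chromatin-loop size: meiotic loop arrays produce a shallow
(slope ~ -0.6) regime below the loop scale and a steep drop beyond it, so
the slope curve has an interior maximum at the loop scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .matrixio import ContactMap, _valid_pairs_per_distance

__all__ = [
    "ScalingCurve",
    "SlopeCurve",
    "LoopSizeEstimate",
    "contact_frequency_curve",
    "slope_curve",
    "estimate_loop_size",
    "fit_powerlaw_slope",
    "LOG_FACTOR",
]

LOG_FACTOR = 1.12


@dataclass
class ScalingCurve:
    """P(s) on log-spaced distance bins.

    ``edges`` are the bin edges in bp (strictly increasing, ratio 1.12);
    ``s`` the geometric midpoints; ``P`` the mean balanced contact value per
    bin (NaN where no pair contributes); ``n_pairs`` the number of valid bin
    pairs per distance bin.
    """

    edges: np.ndarray
    s: np.ndarray
    P: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"s": self.s, "P": self.P, "n_pairs": self.n_pairs})


@dataclass
class SlopeCurve:
    """d log P / d log s on the log grid, loess-smoothed."""

    log_s: np.ndarray
    slope: np.ndarray
    span: float

    @property
    def s(self) -> np.ndarray:
        return np.exp(self.log_s)


@dataclass
class LoopSizeEstimate:
    """Distance of the slope-curve maximum within a search window."""

    loop_size: float
    window: tuple[float, float]
    peak_slope: float
    no_peak: bool


def log_bin_edges(s_min: float, s_max: float, factor: float = LOG_FACTOR) -> np.ndarray:
    """Geometric edges s_min, s_min*factor, ... covering (s_min, s_max]."""
    n = int(np.ceil(np.log(s_max / s_min) / np.log(factor))) + 1
    return s_min * factor ** np.arange(n + 1)


def _per_chrom_diag_stats(cmap: ContactMap, chrom: str,
                          regions: pd.DataFrame | None):
    """(sum of balanced values, n valid pairs) per bin-distance for one chrom.

    With ``regions``, only pairs whose two bins fall inside one and the same
    region contribute (the in-region restriction used for compartment-class
    P(s) curves).
    """
    bt = cmap.bin_table
    sl = bt.chrom_slice(chrom)
    nb = sl.stop - sl.start
    valid = cmap.valid_mask()[sl]
    row, col, val = cmap.balanced_coo()
    on = (row >= sl.start) & (col < sl.stop) & (row < sl.stop) & (col >= sl.start)
    r, c, v = row[on] - sl.start, col[on] - sl.start, val[on]

    if regions is None:
        sums = np.bincount(c - r, weights=v, minlength=nb)
        npairs = _valid_pairs_per_distance(valid)
        return sums, npairs

    sums = np.zeros(nb)
    npairs = np.zeros(nb, dtype=np.int64)
    sub = regions[regions["chrom"] == chrom]
    for _, reg in sub.iterrows():
        lo = int(reg["start"]) // bt.bin_size
        hi = -(-int(reg["end"]) // bt.bin_size)
        lo, hi = max(lo, 0), min(hi, nb)
        if hi - lo < 2:
            continue
        inside = (r >= lo) & (c < hi)
        sums[: hi - lo] += np.bincount(c[inside] - r[inside],
                                       weights=v[inside], minlength=hi - lo)
        npairs[: hi - lo] += _valid_pairs_per_distance(valid[lo:hi])
    return sums, npairs


def contact_frequency_curve(cmap: ContactMap,
                            regions: pd.DataFrame | None = None,
                            chroms: list[str] | None = None) -> ScalingCurve:
    """Genome P(s): mean balanced value per x1.12 log-spaced distance bin.

    Per-chromosome diagonal statistics are pooled weighted by valid-pair
    counts.  ``regions`` (chrom/start/end frame) restricts to pairs with
    both anchors inside a single region; ``chroms`` restricts chromosomes
    (e.g. autosomes only).
    """
    bt = cmap.bin_table
    if regions is not None and len(regions) == 0:
        raise ValueError("empty region set")
    if chroms is None:
        chroms = bt.chrom_names
    n_max = max(bt.n_bins_chrom(c) for c in chroms)
    sums = np.zeros(n_max)
    npairs = np.zeros(n_max, dtype=np.int64)
    for chrom in chroms:
        s_c, n_c = _per_chrom_diag_stats(cmap, chrom, regions)
        sums[: s_c.size] += s_c
        npairs[: n_c.size] += n_c
    # drop d = 0 (self pairs are not part of P(s))
    d = np.arange(1, n_max)
    dist = d * float(bt.bin_size)
    edges = log_bin_edges(bt.bin_size, n_max * bt.bin_size)
    idx = np.searchsorted(edges, dist, side="left") - 1
    idx = np.clip(idx, 0, len(edges) - 2)
    nb = len(edges) - 1
    bin_sum = np.bincount(idx, weights=sums[1:], minlength=nb)
    bin_n = np.bincount(idx, weights=npairs[1:].astype(float), minlength=nb)
    bin_sd = np.bincount(idx, weights=npairs[1:].astype(float) * dist, minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(bin_n > 0, bin_sum / bin_n, np.nan)
        # pair-weighted mean separation; geometric midpoint for empty bins
        s_mid = np.where(bin_n > 0, bin_sd / bin_n, np.sqrt(edges[:-1] * edges[1:]))
    return ScalingCurve(edges=edges, s=s_mid, P=P, n_pairs=bin_n.astype(np.int64))


def slope_curve(curve: ScalingCurve, span: float = 0.3) -> SlopeCurve:
    """Centered finite differences of log P vs log s, then loess smoothing.

    The derivative is taken on the log-binned grid itself (no resampling);
    loess is local-linear with tricube weights at fraction ``span``.
    """
    ok = np.isfinite(curve.P) & (curve.P > 0)
    if ok.sum() < 5:
        raise ValueError("need at least 5 non-missing P(s) bins")
    x = np.log(curve.s[ok])
    y = np.log(curve.P[ok])
    slope = np.gradient(y, x)
    if span >= 1.0:
        frac = 1.0
    else:
        frac = span
    sm_ = sm.nonparametric.lowess(slope, x, frac=frac, it=0, return_sorted=False)
    return SlopeCurve(log_s=x, slope=sm_, span=span)


def estimate_loop_size(slope: SlopeCurve,
                       window: tuple[float, float] = (100_000.0, 5_000_000.0),
                       min_prominence: float = 0.02) -> LoopSizeEstimate:
    """Loop size = distance of the slope maximum inside the search window.

    The no-peak flag is set when the maximum sits on a window edge or the
    in-window slope is monotone / flat: the maximum must rise by at least
    ``min_prominence`` above both window-edge slope values, which keeps
    numeric wobble on a pure power law from registering as a loop hump.
    """
    lo, hi = window
    sel = (slope.s >= lo) & (slope.s <= hi) & np.isfinite(slope.slope)
    if not np.any(sel):
        raise ValueError("search window contains no defined slope values")
    xs = slope.log_s[sel]
    ys = slope.slope[sel]
    k = int(np.argmax(ys))
    no_peak = (
        k == 0
        or k == len(ys) - 1
        or (ys[k] - ys[0] < min_prominence)
        or (ys[k] - ys[-1] < min_prominence)
    )
    return LoopSizeEstimate(
        loop_size=float(np.exp(xs[k])),
        window=window,
        peak_slope=float(ys[k]),
        no_peak=bool(no_peak),
    )


def fit_powerlaw_slope(curve: ScalingCurve, s_min: float, s_max: float) -> float:
    """Least-squares slope of log P on log s over [s_min, s_max]."""
    ok = np.isfinite(curve.P) & (curve.P > 0) & (curve.s >= s_min) & (curve.s <= s_max)
    if ok.sum() < 3:
        raise ValueError("need at least 3 P(s) bins in the fitting window")
    coef = np.polyfit(np.log(curve.s[ok]), np.log(curve.P[ok]), 1)
    return float(coef[0])
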