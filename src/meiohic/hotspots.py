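"""Interval-set logic for meiotic recombination analysis.

DSB hotspots (DMC1-derived, consumed as BED-like frames) are classified
against CO hotspots into CO-DSBs (DSB bin contains a CO), NCO-DSBs (nearest
CO more than 100 kb away) and excluded bins (in between); shuffled controls,
overlap counts, per-region densities, CO/DSB ratios and Mann-Whitney rank
tests support the downstream compartment-region comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, norm

from .matrixio import BinTable

__all__ = [
    "HotspotClassification",
    "classify_dsb",
    "shuffle_intervals",
    "interval_overlap",
    "region_stats",
    "rank_test",
    "read_bed",
    "write_bed",
]

CO_DSB, NCO_DSB, EXCLUDED = "CO-DSB", "NCO-DSB", "excluded"


def read_bed(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    frame = frame.iloc[:, :4] if frame.shape[1] >= 4 else frame.iloc[:, :3]
    frame.columns = ["chrom", "start", "end", "name"][: frame.shape[1]]
    return frame


def write_bed(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class HotspotClassification:
    """10 kb DSB bins labeled CO-DSB / NCO-DSB / excluded (a partition)."""

    bins: pd.DataFrame  # chrom, start, end, label

    def counts(self) -> dict[str, int]:
        return self.bins["label"].value_counts().to_dict()

    def of(self, label: str) -> pd.DataFrame:
        return self.bins[self.bins["label"] == label]


def classify_dsb(dsb: pd.DataFrame, co: pd.DataFrame,
                 bin_size: int = 10_000,
                 distance_cut: int = 100_000) -> HotspotClassification:
    """Classify DSB-containing bins by their distance to CO hotspot midpoints.

    A DSB bin containing at least one CO midpoint is a CO-DSB; a bin whose
    nearest CO midpoint (midpoint-to-midpoint distance) is more than
    ``distance_cut`` away is an NCO-DSB; anything in between is excluded.
    """
    if len(dsb) == 0:
        raise ValueError("empty DSB set")
    rows = []
    co_mid = {
        chrom: np.sort(((grp["start"] + grp["end"]) // 2).to_numpy())
        for chrom, grp in co.groupby("chrom")
    }
    for chrom, grp in dsb.groupby("chrom"):
        mids = (grp["start"] + grp["end"]) // 2
        bins = np.unique(mids // bin_size)
        mids_co = co_mid.get(chrom, np.array([], dtype=int))
        for b in bins:
            lo, hi = b * bin_size, (b + 1) * bin_size
            if mids_co.size:
                inside = np.searchsorted(mids_co, hi) - np.searchsorted(mids_co, lo)
                if inside > 0:
                    rows.append((chrom, lo, hi, CO_DSB))
                    continue
                center = lo + bin_size // 2
                k = np.searchsorted(mids_co, center)
                cand = []
                if k > 0:
                    cand.append(abs(center - mids_co[k - 1]))
                if k < mids_co.size:
                    cand.append(abs(center - mids_co[k]))
                dist = min(cand)
            else:
                dist = np.inf
            rows.append((chrom, lo, hi, NCO_DSB if dist > distance_cut else EXCLUDED))
    return HotspotClassification(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def shuffle_intervals(intervals: pd.DataFrame, genome: BinTable, seed: int = 0,
                      max_tries: int = 1000) -> pd.DataFrame:
    """Randomize interval positions per chromosome, preserving lengths.

    Placement is uniform over the valid start range on the same chromosome;
    overlaps among shuffled intervals are rejected and re-drawn (bounded
    retries), matching bedtools-shuffle -chrom -noOverlapping semantics.
    """
    rng = np.random.default_rng(seed)
    lengths = genome.chrom_lengths
    rows = []
    for chrom, grp in intervals.groupby("chrom", sort=False):
        L = lengths[chrom]
        placed: list[tuple[int, int]] = []
        for _, iv in grp.iterrows():
            size = int(iv["end"]) - int(iv["start"])
            if size > L:
                raise ValueError(f"interval longer than chromosome {chrom}")
            for _ in range(max_tries):
                start = int(rng.integers(0, L - size + 1))
                end = start + size
                if all(end <= s or start >= e for s, e in placed):
                    placed.append((start, end))
                    rows.append((chrom, start, end))
                    break
            else:
                raise RuntimeError(
                    f"could not place shuffled interval on {chrom} without overlap")
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def interval_overlap(a: pd.DataFrame, b: pd.DataFrame) -> tuple[int, int, int]:
    """(count of a overlapping b, a-only count, b-only count).

    An interval overlaps when it intersects at least one interval of the
    other set by >= 1 bp.
    """
    def hits(x: pd.DataFrame, y: pd.DataFrame) -> int:
        n = 0
        y_by_chrom = {
            chrom: (grp["start"].to_numpy(), np.sort(grp["end"].to_numpy()),
                    np.sort(grp["start"].to_numpy()))
            for chrom, grp in y.groupby("chrom")
        }
        for chrom, grp in x.groupby("chrom"):
            if chrom not in y_by_chrom:
                continue
            _, ends_sorted, starts_sorted = y_by_chrom[chrom]
            for _, iv in grp.iterrows():
                s, e = int(iv["start"]), int(iv["end"])
                # overlap exists iff some y has start < e and end > s
                n_start_lt_e = np.searchsorted(starts_sorted, e, side="left")
                n_end_le_s = np.searchsorted(ends_sorted, s, side="right")
                if n_start_lt_e - n_end_le_s > 0:
                    n += 1
        return n

    a_hit = hits(a, b)
    b_hit = hits(b, a)
    return a_hit, len(a) - a_hit, len(b) - b_hit


def region_stats(regions: pd.DataFrame, dsb: pd.DataFrame, co: pd.DataFrame
                 ) -> pd.DataFrame:
    """Per-region DSB/CO densities (midpoint containment) and CO/DSB ratio.

    Densities are hotspot midpoints per Mb; the ratio is missing (NaN), not
    zero, for regions without DSBs.
    """
    def mids(frame):
        return {
            chrom: np.sort(((g["start"] + g["end"]) // 2).to_numpy())
            for chrom, g in frame.groupby("chrom")
        }

    dsb_m, co_m = mids(dsb), mids(co)
    rows = []
    for _, reg in regions.iterrows():
        chrom, s, e = reg["chrom"], int(reg["start"]), int(reg["end"])
        mb = (e - s) / 1e6
        def count(table):
            m = table.get(chrom)
            if m is None:
                return 0
            return int(np.searchsorted(m, e) - np.searchsorted(m, s))
        nd, nc = count(dsb_m), count(co_m)
        ratio = nc / nd if nd > 0 else np.nan
        row = {"chrom": chrom, "start": s, "end": e,
               "dsb_density": nd / mb, "co_density": nc / mb,
               "co_dsb_ratio": ratio}
        if "cls" in reg.index:
            row["cls"] = reg["cls"]
        if "subclass" in reg.index:
            row["subclass"] = reg["subclass"]
        rows.append(row)
    return pd.DataFrame(rows)


def _exact_tail_counts(pooled_ranks: np.ndarray, nx: int, u_obs: float):
    """Exact null distribution of U_x by enumeration of group assignments."""
    n = len(pooled_ranks)
    idx = range(n)
    rank_sum_all = pooled_ranks.sum()
    n_le = n_ge = total = 0
    for comb in combinations(idx, nx):
        rx = pooled_ranks[list(comb)].sum()
        u = rx - nx * (nx + 1) / 2.0
        total += 1
        if u <= u_obs + 1e-12:
            n_le += 1
        if u >= u_obs - 1e-12:
            n_ge += 1
    return n_le / total, n_ge / total


def rank_test(x, y, alternative: str = "two-sided",
              exact_limit: int = 20) -> tuple[float, float]:
    """Mann-Whitney U test with midrank ties.

    Returns (U of x, p).  Exact p by full enumeration of group assignments
    when the combined sample size is at most ``exact_limit``; otherwise the
    normal approximation with tie and continuity correction.  ``alternative``
    'greater'/'less' refer to x relative to y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    if nx + ny <= exact_limit:
        p_le, p_ge = _exact_tail_counts(ranks, nx, u_x)
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2.0 * min(p_le, p_ge))
        return u_x, float(p)

    mu = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / ((nx + ny) * (nx + ny - 1.0))
    sigma = np.sqrt(nx * ny / 12.0 * ((nx + ny + 1.0) - tie_term))
    if sigma == 0:
        return u_x, 1.0
    if alternative == "greater":
        z = (u_x - mu - 0.5) / sigma
        p = norm.sf(z)
    elif alternative == "less":
        z = (u_x - mu + 0.5) / sigma
        p = norm.cdf(z)
    else:
        z = (abs(u_x - mu) - 0.5) / sigma
        p = 2.0 * norm.sf(z)
    return u_x, float(min(1.0, p))
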