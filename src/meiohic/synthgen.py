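"""Synthetic contact maps, tracks, and interval sets with known planted truth.

The generator emulates the statistical structure of meiotic-prophase Hi-C
maps: a power-law cis decay carrying a log-normal "loop hump" whose scale can
differ between A and B compartment classes, checkerboard (plaid)
compartmentalization, trans maps with end-proximal alignment tracts of
controllable fractional extent, inter-homolog blocks with compartment-
modulated diagonal enrichment, and DSB/CO hotspot sets with class-dependent
densities.  Counts are drawn as independent Poisson pixels at a controllable
sequencing depth — an estimator test-bed, not a polymer model.

Truth values (e.g. the loop size implied by a kernel) are always derived
numerically from the analytic kernel, independent of any estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrixio import BinTable, ContactMap

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "make_genome",
    "simulate_cis",
    "simulate_trans",
    "assemble_trans_map",
    "simulate_homolog",
    "simulate_tad_map",
    "cis_kernel",
    "kernel_loop_size",
    "loop_scale_for_truth",
]

A, B = 0, 1  # compartment class codes


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition parameters for the synthetic genome and maps.

    Defaults describe a leptotene/zygotene-like regime: shallow sub-loop
    contact decay, ~500 kb loops (A compartments shorter than B), moderate
    plaid, wild-type end-alignment tracts over 20% of chromosome length.
    """

    chrom_lengths: tuple[int, ...] = (60_000_000, 60_000_000, 60_000_000)
    bin_size: int = 50_000
    # cis decay: k_c(s) = s^alpha * (1 + A * exp(-(ln s - ln L_c)^2 / 2 sigma^2))
    # With the default hump shape the log-log slope sits near -0.6 below the
    # loop scale (loop-array regime) and the slope maximum — the loop-size
    # truth — falls at ~0.45 L_c; the default hump centers plant slope-peak
    # loop sizes of ~560 kb (A) and ~730 kb (B), the leptotene regime.
    alpha: float = -1.2
    loop_scale_a: float = 1_253_000.0
    loop_scale_b: float = 1_633_000.0
    hump_amplitude: float = 2.0
    hump_log_width: float = 0.6
    # compartments
    segment_mean_length: float = 3_000_000.0
    plaid_strength: float = 0.3
    # trans end alignment
    trans_mu: float = 1.0
    align_amplitude: float = 2.0
    align_diag_width: float = 0.05
    tract_extent: float = 0.20
    # inter-homolog diagonal enrichment
    homolog_rho_a: float = 2.0
    homolog_rho_b: float = 1.0
    homolog_base: float = 0.01
    homolog_decay_bp: float = 100_000.0
    # hotspots (per Mb) and CO conversion probability per DSB
    dsb_density_a: float = 6.0
    dsb_density_b: float = 2.0
    co_prob_a: float = 0.12
    co_prob_b: float = 0.05
    # sampling
    depth: float = 1e7
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "chrom_lengths", tuple(self.chrom_lengths))
        if self.alpha >= 0:
            raise ValueError("cis exponent alpha must be negative")
        if not (0.0 < self.tract_extent <= 0.5):
            raise ValueError("tract extent must lie in (0, 0.5]")
        for name in ("loop_scale_a", "loop_scale_b", "hump_log_width",
                     "segment_mean_length", "bin_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")

    def with_(self, **kwargs) -> "SyntheticSpec":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth derived analytically from the generator kernels."""

    loop_size: dict[str, float]          # class -> numeric argmax of dlogk/dlogs
    labels: np.ndarray                   # per-bin class code (0=A, 1=B)
    tract_extent: float
    dsb: pd.DataFrame = field(default_factory=pd.DataFrame)
    co: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# analytic cis kernel and its numeric loop-size truth
# ---------------------------------------------------------------------------

def cis_kernel(s, alpha: float, loop_scale: float, amplitude: float,
               log_width: float) -> np.ndarray:
    """k(s) = s^alpha * (1 + A exp(-(ln s - ln L)^2 / (2 sigma^2)))."""
    s = np.asarray(s, dtype=float)
    hump = amplitude * np.exp(-((np.log(s) - np.log(loop_scale)) ** 2)
                              / (2.0 * log_width ** 2))
    return s ** alpha * (1.0 + hump)


def kernel_loop_size(alpha: float, loop_scale: float, amplitude: float,
                     log_width: float, s_min: float = 1e4, s_max: float = 1e7,
                     n_grid: int = 400) -> float:
    """Loop-size truth: argmax of d log k / d log s on a dense log grid.

    Evaluated on a 10 kb - 10 Mb grid of 400 points by default; this numeric
    argmax, not the hump center L itself, is the reference for recovery
    tests (the two differ slightly because of the power-law background).
    """
    x = np.linspace(np.log(s_min), np.log(s_max), n_grid)
    logk = np.log(cis_kernel(np.exp(x), alpha, loop_scale, amplitude, log_width))
    slope = np.gradient(logk, x)
    return float(np.exp(x[np.argmax(slope)]))


def loop_scale_for_truth(target: float, alpha: float = -1.2,
                         amplitude: float = 2.0, log_width: float = 0.6) -> float:
    """Hump center L_c whose slope-argmax truth equals ``target`` bp.

    The kernel is scale-invariant up to the power-law factor, so
    argmax = r * L_c with r depending only on (alpha, amplitude, log_width);
    the ratio is measured once on a reference kernel and inverted.
    """
    ref = 1e6
    r = kernel_loop_size(alpha, ref, amplitude, log_width,
                         s_min=ref / 100, s_max=ref * 100, n_grid=4000) / ref
    return target / r


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

def make_genome(spec: SyntheticSpec):
    """Alternating A/B genome with class-dependent DSB/CO hotspot sets.

    Returns (bin_table, labels, dsb_intervals, co_intervals, truth).
    Segment lengths are exponential with the configured mean (rounded to the
    bin grid, minimum one bin); DSB midpoints are a per-class Poisson process;
    each DSB independently becomes a CO with class-dependent probability.
    """
    rng = np.random.default_rng(spec.seed)
    names = [f"chr{i + 1}" for i in range(len(spec.chrom_lengths))]
    bt = BinTable(tuple(zip(names, spec.chrom_lengths)), spec.bin_size)

    labels = np.empty(bt.n_bins, dtype=np.int8)
    for chrom in bt.chrom_names:
        s = bt.chrom_slice(chrom)
        nb = s.stop - s.start
        pos = 0
        cls = rng.integers(0, 2)
        while pos < nb:
            seg_bins = max(1, int(round(rng.exponential(spec.segment_mean_length)
                                        / spec.bin_size)))
            if seg_bins > nb:
                seg_bins = nb
            labels[s.start + pos: s.start + min(pos + seg_bins, nb)] = cls
            pos += seg_bins
            cls = 1 - cls

    dsb_rows, co_rows = [], []
    density = {A: spec.dsb_density_a / 1e6, B: spec.dsb_density_b / 1e6}
    co_prob = {A: spec.co_prob_a, B: spec.co_prob_b}
    for chrom in bt.chrom_names:
        s = bt.chrom_slice(chrom)
        for i in range(s.start, s.stop):
            cls = int(labels[i])
            start = (i - s.start) * spec.bin_size
            width = min(spec.bin_size, bt.chrom_lengths[chrom] - start)
            k = rng.poisson(density[cls] * width)
            for _ in range(k):
                mid = start + rng.integers(0, width)
                dsb_rows.append((chrom, int(mid), int(mid) + 1, cls))
                if rng.random() < co_prob[cls]:
                    co_rows.append((chrom, int(mid), int(mid) + 1, cls))
    cols = ["chrom", "start", "end", "cls"]
    dsb = pd.DataFrame(dsb_rows, columns=cols)
    co = pd.DataFrame(co_rows, columns=cols)

    truth = SyntheticTruth(
        loop_size={
            "A": kernel_loop_size(spec.alpha, spec.loop_scale_a,
                                  spec.hump_amplitude, spec.hump_log_width),
            "B": kernel_loop_size(spec.alpha, spec.loop_scale_b,
                                  spec.hump_amplitude, spec.hump_log_width),
        },
        labels=labels,
        tract_extent=spec.tract_extent,
        dsb=dsb,
        co=co,
    )
    return bt, labels, dsb, co, truth


# ---------------------------------------------------------------------------
# cis simulation
# ---------------------------------------------------------------------------

def simulate_cis(spec: SyntheticSpec, bin_table: BinTable, labels: np.ndarray,
                 seed: int | None = None, sample: bool = True) -> ContactMap:
    """Sample a genome-wide cis map from the class-dependent kernels.

    Expected pixel value is proportional to g_ci(s) * g_cj(s) * plaid(i, j)
    with g_c = sqrt(k_c), so same-class pairs see their class kernel and
    mixed pairs the geometric mean.  The plaid factor multiplies same-class
    pairs by (1 + eps) and cross-class pairs by (1 - eps).  Expected counts
    per chromosome are scaled to ``spec.depth``; ``sample=False`` returns the
    expectation itself (no Poisson noise).
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    eps = spec.plaid_strength
    n_total = bin_table.n_bins
    rows_all, cols_all, vals_all = [], [], []

    for chrom in bin_table.chrom_names:
        sl = bin_table.chrom_slice(chrom)
        nb = sl.stop - sl.start
        lab = labels[sl]
        d = np.arange(1, nb)
        s = d * float(bin_table.bin_size)
        g = np.empty((2, nb), dtype=float)  # sqrt-kernels per class per distance
        g[A, 1:] = np.sqrt(cis_kernel(s, spec.alpha, spec.loop_scale_a,
                                      spec.hump_amplitude, spec.hump_log_width))
        g[B, 1:] = np.sqrt(cis_kernel(s, spec.alpha, spec.loop_scale_b,
                                      spec.hump_amplitude, spec.hump_log_width))
        # expected value per diagonal
        lam_diags = []
        total = 0.0
        for dd in range(1, nb):
            li, lj = lab[:-dd], lab[dd:]
            lam = g[li, dd] * g[lj, dd]
            if eps != 0.0:
                lam = lam * np.where(li == lj, 1.0 + eps, 1.0 - eps)
            lam_diags.append(lam)
            total += lam.sum()
        scale = spec.depth / total if total > 0 else 0.0
        if sample and scale > 0 and lam_diags and scale * lam_diags[0].max() < 1.0:
            warnings.warn(f"depth too low to populate the diagonal of {chrom}")
        rs, cs, vs = [], [], []
        for dd in range(1, nb):
            lam = lam_diags[dd - 1] * scale
            if sample:
                cnt = rng.poisson(lam)
                nz = np.nonzero(cnt)[0]
                vals = cnt[nz].astype(float)
            else:
                nz = np.arange(lam.size)
                vals = lam
            rs.append(sl.start + nz)
            cs.append(sl.start + nz + dd)
            vs.append(vals)
        rows_all.append(np.concatenate(rs))
        cols_all.append(np.concatenate(cs))
        vals_all.append(np.concatenate(vs))

    counts = sp.coo_matrix(
        (np.concatenate(vals_all),
         (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n_total, n_total),
    ).tocsr()
    return ContactMap(bin_table, counts, None)


# ---------------------------------------------------------------------------
# trans simulation (end-proximal alignment tracts)
# ---------------------------------------------------------------------------

def _end_gate(x: np.ndarray, f: float, soft: float = 0.02) -> np.ndarray:
    """g_f(x): 1 within the tract (x <= f), exponential shoulder beyond."""
    return np.where(x <= f, 1.0, np.exp(-(x - f) / soft))


def trans_kernel(u: np.ndarray, v: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Expected trans signal at normalized CEN->TEL positions (u, v)."""
    uu, vv = np.meshgrid(u, v, indexing="ij")
    diag = np.exp(-np.abs(uu - vv) / spec.align_diag_width)
    near = _end_gate(np.minimum(uu, vv), spec.tract_extent)
    far = _end_gate(np.minimum(1.0 - uu, 1.0 - vv), spec.tract_extent)
    return spec.trans_mu * (1.0 + spec.align_amplitude * diag * (near + far))


def simulate_trans(spec: SyntheticSpec, bin_table: BinTable, chrom_a: str,
                   chrom_b: str, seed: int | None = None,
                   sample: bool = True) -> np.ndarray:
    """Sample one trans block (chrom_a x chrom_b) as a dense count matrix.

    CEN is coordinate 0 on every chromosome (acrocentric convention); the
    block is oriented CEN->TEL on both axes.  Total expected counts equal
    ``spec.depth``.  With ``sample=False`` the Poisson expectation is
    returned directly.
    """
    if chrom_a == chrom_b:
        raise ValueError("trans simulation needs two distinct chromosomes")
    if seed is None:
        seed = spec.seed
    na = bin_table.n_bins_chrom(chrom_a)
    nb = bin_table.n_bins_chrom(chrom_b)
    u = (np.arange(na) + 0.5) / na
    v = (np.arange(nb) + 0.5) / nb
    lam = trans_kernel(u, v, spec)
    lam *= spec.depth / lam.sum()
    if not sample:
        return lam
    rng = np.random.default_rng(seed)
    return rng.poisson(lam).astype(float)


def assemble_trans_map(spec: SyntheticSpec, bin_table: BinTable,
                       pairs=None, seed: int | None = None,
                       sample: bool = True) -> ContactMap:
    """Genome-wide ContactMap holding the trans blocks of the given pairs.

    Blocks are simulated independently (each at ``spec.depth`` expected
    counts); weights are set to 1 everywhere, so the map is ready for
    trans expected / obs-over-exp computation without re-balancing.
    """
    if pairs is None:
        names = bin_table.chrom_names
        pairs = [(names[i], names[j]) for i in range(len(names))
                 for j in range(i + 1, len(names))]
    if seed is None:
        seed = spec.seed
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(len(pairs)) % (2 ** 31)
    rows, cols, vals = [], [], []
    order = {c: k for k, c in enumerate(bin_table.chrom_names)}
    for k, (ca, cb) in enumerate(pairs):
        if order[ca] > order[cb]:
            ca, cb = cb, ca
        block = simulate_trans(spec, bin_table, ca, cb,
                               seed=int(child[k]), sample=sample)
        r, c = np.nonzero(block if sample else np.ones_like(block, dtype=bool))
        v = block[r, c]
        nz = v != 0
        sa, sb = bin_table.chrom_slice(ca), bin_table.chrom_slice(cb)
        rows.append(sa.start + r[nz])
        cols.append(sb.start + c[nz])
        vals.append(v[nz])
    n = bin_table.n_bins
    counts = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n)).tocsr()
    return ContactMap(bin_table, counts, np.ones(n))


# ---------------------------------------------------------------------------
# inter-homolog simulation
# ---------------------------------------------------------------------------

def simulate_homolog(spec: SyntheticSpec, bin_table: BinTable, chrom: str,
                     labels: np.ndarray, seed: int | None = None,
                     sample: bool = True) -> np.ndarray:
    """Inter-homolog block for one chromosome duplicated as homologs.

    Expected signal = base + rho_class(i) * exp(-|i - j| * bin / decay),
    i.e. the enrichment follows the class of the row bin (homolog-1
    coordinate); an inter-homolog block relates two distinct molecules, so
    it need not be symmetric.  Scaled to ``spec.depth`` expected counts.
    """
    if seed is None:
        seed = spec.seed
    sl = bin_table.chrom_slice(chrom)
    lab = labels[sl]
    nb = lab.size
    rho = np.where(lab == A, spec.homolog_rho_a, spec.homolog_rho_b)
    i = np.arange(nb)
    dist = np.abs(i[:, None] - i[None, :]) * float(bin_table.bin_size)
    lam = spec.homolog_base + rho[:, None] * np.exp(-dist / spec.homolog_decay_bp)
    total = lam.sum()
    if total == 0 or spec.depth == 0:
        return np.zeros((nb, nb))
    lam *= spec.depth / total
    if not sample:
        return lam
    rng = np.random.default_rng(seed)
    return rng.poisson(lam).astype(float)


# ---------------------------------------------------------------------------
# planted-boundary (TAD-like) maps for insulation benchmarking
# ---------------------------------------------------------------------------

def simulate_tad_map(bin_table: BinTable, boundary_spacing: int,
                     depletion: float = 0.4, alpha: float = -1.0,
                     depth: float = 5e6, seed: int = 0,
                     sample: bool = True) -> tuple[ContactMap, dict[str, np.ndarray]]:
    """Block-diagonal domain map with boundaries every ``boundary_spacing`` bins.

    Pairs whose bins fall in different domains are depleted by the factor
    ``depletion`` relative to the power-law background s^alpha.  Returns the
    sampled map and the planted boundary bin indices per chromosome.
    """
    rng = np.random.default_rng(seed)
    n_total = bin_table.n_bins
    rows_all, cols_all, vals_all = [], [], []
    truth: dict[str, np.ndarray] = {}
    for chrom in bin_table.chrom_names:
        sl = bin_table.chrom_slice(chrom)
        nb = sl.stop - sl.start
        domain = np.arange(nb) // boundary_spacing
        truth[chrom] = np.arange(boundary_spacing, nb, boundary_spacing)
        lam_diags, total = [], 0.0
        for dd in range(1, nb):
            lam = (dd * bin_table.bin_size) ** alpha * np.ones(nb - dd)
            cross = domain[:-dd] != domain[dd:]
            lam[cross] *= depletion
            lam_diags.append(lam)
            total += lam.sum()
        scale = depth / total
        rs, cs, vs = [], [], []
        for dd in range(1, nb):
            lam = lam_diags[dd - 1] * scale
            if sample:
                cnt = rng.poisson(lam)
                nz = np.nonzero(cnt)[0]
                vals = cnt[nz].astype(float)
            else:
                nz = np.arange(lam.size)
                vals = lam
            rs.append(sl.start + nz)
            cs.append(sl.start + nz + dd)
            vs.append(vals)
        rows_all.append(np.concatenate(rs))
        cols_all.append(np.concatenate(cs))
        vals_all.append(np.concatenate(vs))
    counts = sp.coo_matrix(
        (np.concatenate(vals_all),
         (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(n_total, n_total),
    ).tocsr()
    return ContactMap(bin_table, counts, None), truth
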