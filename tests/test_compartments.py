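"""Eigenvector compartment calls, segments, saddles, and A1-A3 stratification."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from meiohic.matrixio import BinTable, ContactMap, balance_ic, expected
from meiohic.compartments import (
    EigenTrack,
    eigentrack,
    saddle,
    segment_compartments,
    stratify_A_regions,
    switch_and_fraction,
)
from meiohic.synthgen import SyntheticSpec, make_genome, simulate_cis


def plaid_fixture(eps=0.3, seed=19, depth=2e6):
    spec = SyntheticSpec(chrom_lengths=(20_000_000,) * 2, bin_size=50_000,
                         depth=depth, seed=seed, plaid_strength=eps)
    bt, labels, *_ = make_genome(spec)
    cmap = balance_ic(simulate_cis(spec, bt, labels, seed=seed + 1))
    return bt, labels, cmap


def track_of(signs, bin_size=10_000):
    values = np.asarray(signs, dtype=float)
    bt = BinTable((("chr1", values.size * bin_size),), bin_size)
    return EigenTrack(bin_table=bt, values=values)


class TestEigentrack:
    def test_planted_plaid_recovered(self):
        bt, labels, cmap = plaid_fixture()
        orient = np.where(labels == 0, 1.0, -1.0)
        e1 = eigentrack(cmap, orient)
        cls = e1.classes()
        ok = np.isfinite(e1.values)
        agree = np.mean((cls[ok] > 0) == (labels[ok] == 0))
        assert agree >= 0.95

    def test_orientation_negation_flips_track(self):
        bt, labels, cmap = plaid_fixture(seed=23)
        orient = np.where(labels == 0, 1.0, -1.0)
        e1 = eigentrack(cmap, orient)
        e1_neg = eigentrack(cmap, -orient)
        np.testing.assert_allclose(e1.values, -e1_neg.values, equal_nan=True)

    def test_constant_matrix_degenerate(self):
        n = 30
        bt = BinTable((("chr1", n * 10_000),), 10_000)
        dense = np.triu(np.ones((n, n)))
        cmap = ContactMap(bt, sp.csr_matrix(dense), np.ones(n))
        e1 = eigentrack(cmap, np.ones(n))
        assert "chr1" in e1.degenerate
        assert np.all(np.isnan(e1.values))

    def test_rescaling_invariance_up_to_sign(self):
        bt, labels, cmap = plaid_fixture(seed=29)
        orient = np.where(labels == 0, 1.0, -1.0)
        e1 = eigentrack(cmap, orient)
        scaled = ContactMap(bt, cmap.counts * 4.0, cmap.weights)
        e2 = eigentrack(scaled, orient)
        np.testing.assert_allclose(e1.values, e2.values, atol=1e-8,
                                   equal_nan=True)


class TestSegments:
    def test_basic_runs(self):
        segs = segment_compartments(track_of([1, 1, -1, -1, 1]))
        want = [("chr1", 0, 20_000, "A"), ("chr1", 20_000, 40_000, "B"),
                ("chr1", 40_000, 50_000, "A")]
        assert [tuple(r) for r in segs.frame.to_numpy()] == want

    def test_min_length_strict(self):
        signs = np.r_[np.ones(99), -np.ones(101), np.ones(10)]
        segs = segment_compartments(track_of(signs), min_length=1_000_000)
        # 990 kb A run dropped, 1.01 Mb B run kept
        assert list(segs.frame["cls"]) == ["B"]

    def test_roundtrip_reconstruction(self):
        rng = np.random.default_rng(31)
        signs = rng.choice([-1.0, 1.0], size=200)
        segs = segment_compartments(track_of(signs))
        rebuilt = np.zeros(200)
        for _, r in segs.frame.iterrows():
            rebuilt[r["start"] // 10_000: r["end"] // 10_000] = (
                1.0 if r["cls"] == "A" else -1.0)
        np.testing.assert_array_equal(rebuilt, signs)

    def test_missing_bins_break_runs(self):
        signs = np.array([1, 1, np.nan, 1, 1])
        segs = segment_compartments(track_of(signs))
        assert len(segs.frame) == 2


class TestSwitchFraction:
    def test_identical_and_negated(self):
        t = track_of([1, -1, 1, -1, 1])
        assert switch_and_fraction(t, t)[0] == 0.0
        neg = track_of([-1, 1, -1, 1, -1])
        assert switch_and_fraction(t, neg)[0] == 1.0

    def test_hand_counts(self):
        a = track_of([1, 1, 1, -1, -1, -1, 1, -1, 1, 1])
        b = track_of([1, -1, 1, -1, 1, -1, 1, -1, -1, 1])
        switch, fa, fb = switch_and_fraction(a, b)
        assert np.isclose(switch, 3 / 10)
        assert np.isclose(fa, 6 / 10)
        assert np.isclose(fb, 5 / 10)


class TestSaddle:
    def test_flat_obs_exp_is_one(self):
        n = 50
        bt = BinTable((("chr1", n * 10_000),), 10_000)
        dense = np.zeros((n, n))
        for d in range(1, n):
            dense[np.arange(n - d), np.arange(n - d) + d] = 1.0 / d
        cmap = ContactMap(bt, sp.csr_matrix(dense), np.ones(n))
        e1 = EigenTrack(bin_table=bt, values=np.linspace(-1, 1, n))
        sad, corner = saddle(cmap, e1, n_quantiles=5)
        off_diag_defined = np.isfinite(sad)
        np.testing.assert_allclose(sad[off_diag_defined], 1.0, rtol=1e-10)
        assert np.isclose(corner, 1.0)

    def test_plaid_corners_exceed_cross(self):
        bt, labels, cmap = plaid_fixture(seed=37)
        orient = np.where(labels == 0, 1.0, -1.0)
        e1 = eigentrack(cmap, orient)
        sad, corner = saddle(cmap, e1, n_quantiles=5)
        assert sad[0, 0] > sad[0, -1]
        assert sad[-1, -1] > sad[-1, 0]
        assert corner > 1.0

    def test_matches_bruteforce_group_means(self):
        rng = np.random.default_rng(41)
        n = 50
        bt = BinTable((("chr1", n * 10_000),), 10_000)
        upper = np.triu(rng.poisson(8.0, (n, n)).astype(float))
        cmap = ContactMap(bt, sp.csr_matrix(upper), np.ones(n))
        e1 = EigenTrack(bin_table=bt, values=rng.normal(size=n))
        nq = 5
        sad, _ = saddle(cmap, e1, n_quantiles=nq)
        # brute force
        prof = expected(cmap)
        full = upper + np.triu(upper, k=1).T
        cis = prof.cis["chr1"]
        oe = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(n):
                e = cis[abs(i - j)]
                if e > 0:
                    oe[i, j] = full[i, j] / e
        order = np.argsort(e1.values, kind="stable")
        q = np.empty(n, dtype=int)
        q[order] = np.minimum(np.arange(n) * nq // n, nq - 1)
        want = np.full((nq, nq), np.nan)
        for p in range(nq):
            for r in range(nq):
                block = oe[np.ix_(q == p, q == r)]
                if np.isfinite(block).any():
                    want[p, r] = np.nanmean(block)
        np.testing.assert_allclose(sad, want, rtol=1e-10, equal_nan=True)

    def test_too_many_quantiles(self):
        bt = BinTable((("chr1", 100_000),), 10_000)
        e1 = EigenTrack(bin_table=bt, values=np.arange(10.0))
        dense = np.triu(np.ones((10, 10)))
        cmap = ContactMap(bt, sp.csr_matrix(dense), np.ones(10))
        with pytest.raises(ValueError):
            saddle(cmap, e1, n_quantiles=11)


class TestStratify:
    def _segments_and_map(self, n_segs, seed=43):
        # one chromosome; segments of 1.2 Mb separated by 0.4 Mb B gaps
        bin_size = 50_000
        seg_bins, gap_bins = 24, 8
        n = n_segs * (seg_bins + gap_bins)
        bt = BinTable((("chr1", n * bin_size),), bin_size)
        rng = np.random.default_rng(seed)
        dense = np.zeros((n, n))
        d = 500_000 // bin_size
        level = rng.permutation(n_segs) + 1.0
        rows = []
        for k in range(n_segs):
            lo = k * (seg_bins + gap_bins)
            hi = lo + seg_bins
            rows.append(("chr1", lo * bin_size, hi * bin_size, "A"))
            for i in range(lo, hi - d):
                dense[i, i + d] = level[k]
        cmap = ContactMap(bt, sp.csr_matrix(np.triu(dense)), np.ones(n))
        from meiohic.compartments import CompartmentSegments
        segs = CompartmentSegments(pd.DataFrame(
            rows, columns=["chrom", "start", "end", "cls"]))
        return segs, cmap, level

    @pytest.mark.parametrize("n_segs,sizes", [(9, (3, 3, 3)), (10, (4, 3, 3)),
                                              (11, (4, 4, 3))])
    def test_group_sizes(self, n_segs, sizes):
        segs, cmap, _ = self._segments_and_map(n_segs)
        out = stratify_A_regions(segs, cmap)
        counts = out.frame["subclass"].value_counts()
        assert tuple(counts[f"A{i}"] for i in (1, 2, 3)) == sizes
        assert max(sizes) - min(sizes) <= 1

    def test_ranking_by_500kb_value(self):
        segs, cmap, level = self._segments_and_map(9)
        out = stratify_A_regions(segs, cmap)
        sub = out.frame
        a1 = sub[sub["subclass"] == "A1"]["value_at_sep"]
        a3 = sub[sub["subclass"] == "A3"]["value_at_sep"]
        assert a1.min() > a3.max()

    def test_too_few_segments(self):
        segs, cmap, _ = self._segments_and_map(9)
        from meiohic.compartments import CompartmentSegments
        small = CompartmentSegments(segs.frame.iloc[:2])
        with pytest.raises(ValueError):
            stratify_A_regions(small, cmap)
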