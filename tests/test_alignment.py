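"""Trans end-alignment statistics and inter-homolog alignment scores."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from meiohic.matrixio import BinTable, ContactMap, ExpectedProfile, expected
from meiohic.alignment import (
    SubTelomericStats,
    TransAlignmentProfile,
    autosome_pairs,
    averaged_trans_map,
    diagonal_profile,
    homolog_alignment_score,
    polarity,
    rescale_bilinear,
    scores_by_class,
    subtelomeric_stats,
    tract_extent,
)
from meiohic.synthgen import SyntheticSpec, assemble_trans_map, make_genome


def stats_frame(cc, tt, ct):
    return SubTelomericStats(pd.DataFrame(
        [("chr1", "chr2", cc, tt, ct)],
        columns=["chrom_a", "chrom_b", "cen_cen", "tel_tel", "cen_tel"]))


class TestSubtelomeric:
    def test_autosome_pair_count(self):
        assert len(autosome_pairs([f"chr{i}" for i in range(1, 20)])) == 171

    def test_uniform_block_polarity_one(self):
        bt = BinTable((("chr1", 12_000_000), ("chr2", 12_000_000)), 50_000)
        n = bt.n_bins
        block = np.full((240, 240), 0.7)
        counts = sp.lil_matrix((n, n))
        counts[0:240, 240:480] = block
        cmap = ContactMap(bt, counts.tocsr(), np.ones(n))
        stats = subtelomeric_stats(cmap, window=5_000_000,
                                   pairs=[("chr1", "chr2")])
        pi = polarity(stats)
        assert abs(pi.iloc[0] - 1.0) < 1e-9

    def test_hand_polarity_formula(self):
        assert np.isclose(polarity(stats_frame(2.0, 2.0, 1.0)).iloc[0], 2.0)
        assert np.isnan(polarity(stats_frame(1.0, 1.0, 0.0)).iloc[0])

    def test_matches_bruteforce_window_means(self):
        rng = np.random.default_rng(61)
        bt = BinTable((("chr1", 12_000_000), ("chr2", 15_000_000)), 50_000)
        na, nb = 240, 300
        block = rng.poisson(3.0, (na, nb)).astype(float)
        counts = sp.lil_matrix((bt.n_bins, bt.n_bins))
        counts[0:na, na:na + nb] = block
        cmap = ContactMap(bt, counts.tocsr(), np.ones(bt.n_bins))
        stats = subtelomeric_stats(cmap, window=5_000_000,
                                   pairs=[("chr1", "chr2")]).frame
        w = 100
        assert np.isclose(stats["cen_cen"][0], block[:w, :w].mean())
        assert np.isclose(stats["tel_tel"][0], block[-w:, -w:].mean())
        want_ct = np.concatenate([block[:w, -w:].ravel(),
                                  block[-w:, :w].ravel()]).mean()
        assert np.isclose(stats["cen_tel"][0], want_ct)

    def test_short_chromosome_rejected(self):
        bt = BinTable((("chr1", 8_000_000), ("chr2", 12_000_000)), 50_000)
        cmap = ContactMap(bt, sp.csr_matrix((bt.n_bins, bt.n_bins)),
                          np.ones(bt.n_bins))
        with pytest.raises(ValueError):
            subtelomeric_stats(cmap, window=5_000_000,
                               pairs=[("chr1", "chr2")])


class TestRescale:
    def test_constant_idempotent(self):
        m = np.full((7, 9), 3.0)
        np.testing.assert_allclose(rescale_bilinear(m, 20), 3.0)

    def test_matches_hand_bilinear_on_toy(self):
        rng = np.random.default_rng(63)
        src = rng.random((7, 9))
        n = 13
        got = rescale_bilinear(src, n)

        def axis_pos(k, m):
            p = (k + 0.5) / n * m - 0.5
            lo = int(np.clip(np.floor(p), 0, m - 1))
            hi = min(lo + 1, m - 1)
            f = min(max(p - lo, 0.0), 1.0)
            return lo, hi, f

        want = np.empty((n, n))
        for a in range(n):
            r0, r1, fr = axis_pos(a, 7)
            for b in range(n):
                c0, c1, fc = axis_pos(b, 9)
                top = src[r0, c0] * (1 - fc) + src[r0, c1] * fc
                bot = src[r1, c0] * (1 - fc) + src[r1, c1] * fc
                want[a, b] = top * (1 - fr) + bot * fr
        np.testing.assert_allclose(got, want, rtol=1e-12)


class TestAveragedMap:
    def _map(self, seed=65, n_chroms=3):
        spec = SyntheticSpec(chrom_lengths=(12_000_000,) * n_chroms,
                             bin_size=50_000, depth=3e5, seed=seed)
        bt = BinTable(tuple((f"chr{i+1}", 12_000_000) for i in range(n_chroms)),
                      50_000)
        return assemble_trans_map(spec, bt, seed=seed), bt

    def test_uniform_blocks_average_to_one(self):
        bt = BinTable((("chr1", 10_000_000), ("chr2", 10_000_000),
                       ("chr3", 10_000_000)), 50_000)
        counts = sp.lil_matrix((bt.n_bins, bt.n_bins))
        for a, b in [(0, 1), (0, 2), (1, 2)]:
            counts[a * 200:(a + 1) * 200, b * 200:(b + 1) * 200] = 0.5
        cmap = ContactMap(bt, counts.tocsr(), np.ones(bt.n_bins))
        prof = expected(cmap)
        res = averaged_trans_map(cmap, prof, n=50)
        np.testing.assert_allclose(res.matrix, 1.0, rtol=1e-9)

    def test_pair_list_permutation_and_duplication_invariance(self):
        cmap, bt = self._map()
        prof = expected(cmap)
        pairs = autosome_pairs(bt.chrom_names)
        m1 = averaged_trans_map(cmap, prof, pairs=pairs, n=60).matrix
        m2 = averaged_trans_map(cmap, prof, pairs=pairs[::-1], n=60).matrix
        m3 = averaged_trans_map(cmap, prof, pairs=pairs * 2, n=60).matrix
        np.testing.assert_allclose(m1, m2, rtol=1e-12, equal_nan=True)
        np.testing.assert_allclose(m1, m3, rtol=1e-12, equal_nan=True)

    def test_empty_pair_list(self):
        cmap, bt = self._map()
        with pytest.raises(ValueError):
            averaged_trans_map(cmap, expected(cmap), pairs=[])


class TestDiagonalProfile:
    def test_all_ones(self):
        prof = diagonal_profile(TransAlignmentProfile(matrix=np.ones((80, 80))))
        np.testing.assert_allclose(prof.raw_profile, 1.0)
        np.testing.assert_allclose(prof.smoothed_profile, 1.0, atol=1e-9)

    def test_band_construction(self):
        n = 100
        m = np.ones((n, n))
        band = 20
        for t in range(band):
            m[t, t] += 2.0
        prof = diagonal_profile(TransAlignmentProfile(matrix=m), half_window=2)
        raw = prof.raw_profile
        assert raw[:band - 2].min() > raw[band + 5:].max()

    def test_matches_bruteforce_square_means(self):
        rng = np.random.default_rng(67)
        m = rng.random((60, 60))
        prof = diagonal_profile(TransAlignmentProfile(matrix=m), half_window=10)
        want = np.empty(60)
        for t in range(60):
            lo, hi = max(0, t - 10), min(60, t + 11)
            want[t] = m[lo:hi, lo:hi].mean()
        np.testing.assert_allclose(prof.raw_profile, want, rtol=1e-12)


class TestTractExtent:
    def test_step_profile(self):
        n = 500
        prof = np.ones(n)
        prof[: n // 5] = 2.0   # elevated for first 20%
        ec, et = tract_extent(prof)
        assert np.isclose(ec, 0.20, atol=0.01)
        assert et == 0.0

    def test_flat_profile_zero(self):
        assert tract_extent(np.ones(200)) == (0.0, 0.0)

    def test_both_ends(self):
        n = 400
        prof = np.ones(n)
        prof[:40] = 1.8
        prof[-20:] = 1.5
        ec, et = tract_extent(prof)
        assert np.isclose(ec, 0.10, atol=0.01)
        assert np.isclose(et, 0.05, atol=0.01)


class TestHomologScore:
    def test_uniform_block_scores_one(self):
        scores = homolog_alignment_score(np.full((60, 60), 3.0))
        np.testing.assert_allclose(scores, 1.0, rtol=1e-12)

    def test_normalization_mean_one(self):
        rng = np.random.default_rng(69)
        block = rng.poisson(2.0, (120, 120)).astype(float)
        scores = homolog_alignment_score(block)
        assert abs(np.nanmean(scores) - 1.0) < 1e-9

    def test_matches_bruteforce_windowed_means(self):
        rng = np.random.default_rng(71)
        block = rng.random((40, 40))
        scores = homolog_alignment_score(block, half_window=10)
        want = np.empty(40)
        for t in range(40):
            lo, hi = max(0, t - 10), min(40, t + 11)
            want[t] = block[lo:hi, lo:hi].mean()
        want /= want.mean()
        np.testing.assert_allclose(scores, want, rtol=1e-10)

    def test_zero_block_rejected(self):
        with pytest.raises(ValueError):
            homolog_alignment_score(np.zeros((30, 30)))

    def test_band_variant_runs(self):
        rng = np.random.default_rng(73)
        block = rng.random((50, 50))
        scores = homolog_alignment_score(block, half_window=2, mode="band100k")
        assert abs(np.nanmean(scores) - 1.0) < 1e-9


class TestScoresByClass:
    def test_identical_classes_identical_distributions(self):
        scores = np.arange(40, dtype=float)
        labels = np.r_[np.zeros(20), np.ones(20)]
        out = scores_by_class(scores, labels)
        assert out[0.0].size == out[1.0].size == 20

    def test_position_binning_conserves_counts(self):
        rng = np.random.default_rng(75)
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        frame = scores_by_class(scores, labels, n_position_bins=50)
        assert frame["n"].sum() == 200

    def test_empty_class_rejected(self):
        scores = np.full(10, np.nan)
        labels = np.zeros(10)
        with pytest.raises(ValueError):
            scores_by_class(scores, labels)
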