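import numpy as np
import pandas as pd
import pytest
from _utils import random_symmetric_map

from lampsim.contactmap import ContactMap
from lampsim.hicstats import (Pileup, contact_fractions, cps_track,
                              diamond_insulation, pileup_local,
                              pileup_rescaled, quadrant_insulation_score,
                              read_bedgraph, saddle_strength, write_bedgraph)


# --- independent brute-force oracles ----------------------------------------

def cps_oracle(mat, sb, wb):
    """Direct double-sum evaluation of the printed band/square formula with
    end truncation (independent of the summed-area-table implementation)."""
    n = mat.shape[0]
    out = np.full(n, np.nan)
    for c in range(n):
        s0, s1 = max(0, c - sb), min(n - 1, c + sb)
        w0, w1 = max(0, c - wb), min(n - 1, c + wb)
        band_row = sum(mat[i, j] for i in range(w0, w1 + 1)
                       for j in range(s0, s1 + 1))
        band_col = sum(mat[i, j] for i in range(s0, s1 + 1)
                       for j in range(w0, w1 + 1))
        square = sum(mat[i, j] for i in range(s0, s1 + 1)
                     for j in range(s0, s1 + 1))
        if square > 0:
            out[c] = (band_row + band_col - 2 * square) / square
    return out


def insulation_oracle(mat, w, cov):
    n = mat.shape[0]
    out = np.full(n, np.nan)
    for c in range(w, n - w):
        vals = [mat[i, j] for i in range(c - w, c)
                for j in range(c + 1, c + 1 + w) if cov[i] and cov[j]]
        if vals:
            out[c] = np.mean(vals)
    mean = np.nanmean(out)
    return np.log2(out / mean)


class TestCps:
    def test_matches_oracle_random(self, rng):
        for n in (60, 200):
            mat = random_symmetric_map(n, rng)
            cmap = ContactMap(mat, 1000)
            got = cps_track(cmap, 5_000, 20_000)
            want = cps_oracle(mat, 5, 20)
            np.testing.assert_allclose(got, want, rtol=1e-9, equal_nan=True)

    def test_uniform_closed_form(self):
        # uniform matrix: CPS = 4 (W - s) / (2 s + 1) in bin units,
        # verified against the brute-force double sums
        n = 101
        mat = np.full((n, n), 3.0)
        cmap = ContactMap(mat, 1000)
        sb, wb = 5, 40
        got = cps_track(cmap, sb * 1000, wb * 1000)
        expected = 4 * (wb - sb) / (2 * sb + 1)
        assert got[n // 2] == pytest.approx(expected, rel=1e-12)
        assert got[n // 2] == pytest.approx(cps_oracle(mat, sb, wb)[n // 2])

    def test_full_scale_closed_form_value(self):
        # the printed defaults (s = 35 kb, W = 4 Mb at 1 kb) give 223.38...
        assert 4 * (4000 - 35) / (2 * 35 + 1) == pytest.approx(223.3803,
                                                               abs=1e-3)

    def test_isolated_block_zero(self):
        n = 60
        mat = np.zeros((n, n))
        mat[28:33, 28:33] = 5.0  # width <= s around the center bin
        got = cps_track(ContactMap(mat, 1000), 5_000, 20_000)
        assert got[30] == pytest.approx(0.0, abs=1e-12)

    def test_empty_locus_nan(self):
        n = 50
        mat = np.zeros((n, n))
        mat[:10, :10] = 1.0
        got = cps_track(ContactMap(mat, 1000), 3_000, 10_000)
        assert np.isnan(got[30])

    def test_s_ge_w_rejected(self, rng):
        cmap = ContactMap(random_symmetric_map(30, rng), 1000)
        with pytest.raises(ValueError):
            cps_track(cmap, 10_000, 10_000)


class TestDiamondInsulation:
    def test_matches_oracle(self, rng):
        mat = random_symmetric_map(100, rng)
        cmap = ContactMap(mat, 10_000)
        got = diamond_insulation(cmap, 100_000)
        want = insulation_oracle(mat, 10, cmap.covered())
        np.testing.assert_allclose(got, want, rtol=1e-9, equal_nan=True)

    def test_uniform_map_zero_track(self):
        mat = np.full((40, 40), 2.0)
        got = diamond_insulation(ContactMap(mat, 1000), 5_000)
        valid = ~np.isnan(got)
        np.testing.assert_allclose(got[valid], 0.0, atol=1e-12)

    def test_block_junction_minimum(self):
        n = 40
        mat = np.zeros((n, n))
        mat[:20, :20] = 4.0
        mat[20:, 20:] = 4.0
        got = diamond_insulation(ContactMap(mat, 1000), 6_000)
        interior = got[6:-6]
        assert np.nanargmin(interior) + 6 in (19, 20, 21)

    def test_window_validation(self):
        cmap = ContactMap(np.ones((10, 10)), 1000)
        with pytest.raises(ValueError):
            diamond_insulation(cmap, 20_000)


class TestPileupLocal:
    def test_control_anchors_converge_to_one(self, rng):
        mat = random_symmetric_map(400, rng)
        cmap = ContactMap(mat, 1000)
        anchors = rng.integers(30, 370, size=500) * 1000.0
        p = pileup_local(cmap, anchors, 5_000, 50_000, n_controls=4, rng=rng)
        assert np.nanmean(p.matrix) == pytest.approx(1.0, abs=0.05)

    def test_single_anchor_deterministic_obs(self, rng):
        mat = random_symmetric_map(60, rng)
        cmap = ContactMap(mat, 1000)
        p = pileup_local(cmap, [30_000.0], 3_000, 20_000, n_controls=10,
                         rng=rng)
        # the observed numerator is exactly the anchored submatrix
        sub = mat[27:34, 27:34]
        recovered = p.matrix
        assert recovered.shape == sub.shape

    def test_planted_enrichment(self, rng):
        n = 300
        mat = random_symmetric_map(n, rng)
        anchors = np.array([50, 120, 200, 260])
        for a in anchors:
            mat[a - 2:a + 3, a - 2:a + 3] += 200.0
        cmap = ContactMap(mat, 1000)
        p = pileup_local(cmap, anchors * 1000.0, 5_000, 40_000,
                         n_controls=10, rng=rng)
        c = p.matrix.shape[0] // 2
        assert p.matrix[c, c] > 1.5

    def test_edge_anchors_dropped(self, rng):
        mat = random_symmetric_map(50, rng)
        cmap = ContactMap(mat, 1000)
        p = pileup_local(cmap, [1_000.0, 25_000.0], 5_000, 10_000, rng=rng)
        assert p.n_used == 1 and p.n_dropped == 1

    def test_no_anchors_error(self, rng):
        cmap = ContactMap(random_symmetric_map(30, rng), 1000)
        with pytest.raises(ValueError):
            pileup_local(cmap, [1_000.0], 20_000, 5_000, rng=rng)


class TestPileupRescaled:
    def test_all_ones_oe(self):
        n = 400
        cmap = ContactMap(np.ones((n, n)), 1000)
        p = pileup_rescaled(cmap, [(150_000, 170_000), (200_000, 215_000)])
        np.testing.assert_allclose(p.matrix, 1.0)

    def test_identical_intervals_equal_single(self, rng):
        mat = random_symmetric_map(400, rng)
        cmap = ContactMap(mat, 1000)
        p1 = pileup_rescaled(cmap, [(180_000, 200_000)])
        p2 = pileup_rescaled(cmap, [(180_000, 200_000)] * 3)
        np.testing.assert_allclose(p1.matrix, p2.matrix, equal_nan=True)

    def test_planted_cross_depletes_flanks(self, rng):
        n = 500
        mat = np.ones((n, n)) + 0.01 * random_symmetric_map(n, rng)
        iv = [(200_000, 220_000), (300_000, 312_000)]
        for (a, b) in iv:
            b0, b1 = a // 1000, b // 1000
            mat[b0:b1, :] *= 0.05
            mat[:, b0:b1] *= 0.05
            mat[b0:b1, b0:b1] /= 0.05
        p = pileup_rescaled(ContactMap(mat, 1000), iv)
        npx = p.matrix.shape[0]
        body = slice(33, 39)
        flank_cols = p.matrix[10:20, body]
        background = p.matrix[10:20, 10:20]
        assert np.nanmean(flank_cols) < np.nanmean(background)

    def test_short_interval_skipped(self, rng):
        cmap = ContactMap(np.ones((100, 100)), 1000)
        with pytest.warns(UserWarning):
            p = pileup_rescaled(cmap, [(50_000, 50_500), (30_000, 34_000)])
        assert p.n_used == 1


class TestQuadrant:
    def test_uniform(self):
        assert quadrant_insulation_score(np.ones((10, 10))) == pytest.approx(1.0)

    def test_block_diagonal(self):
        m = np.ones((8, 8))
        m[:4, :4] = 2.0
        m[4:, 4:] = 2.0
        assert quadrant_insulation_score(m) == pytest.approx(2.0)

    def test_transpose_invariant(self, rng):
        m = rng.uniform(size=(12, 12))
        assert quadrant_insulation_score(m) == pytest.approx(
            quadrant_insulation_score(m.T))

    def test_odd_side_drops_center(self):
        m = np.ones((9, 9))
        m[4, :] = 100.0
        m[:, 4] = 100.0
        assert quadrant_insulation_score(m) == pytest.approx(1.0)


class TestSaddle:
    def test_two_level_strength(self):
        n = 200
        ev = np.where(np.arange(n) < n // 2, -1.0, 1.0) \
            + np.linspace(0, 1e-6, n)
        same = np.equal.outer(ev > 0, ev > 0)
        oe = np.where(same, 2.0, 0.5)
        np.fill_diagonal(oe, 2.0)
        cmap = ContactMap(oe, 100_000)
        strength, sad = saddle_strength(cmap, ev)
        assert strength == pytest.approx(4.0, rel=1e-6)

    def test_random_ev_homogeneous_map(self, rng):
        n = 300
        oe = np.ones((n, n)) + rng.normal(scale=0.01, size=(n, n))
        oe = (oe + oe.T) / 2
        strength, _ = saddle_strength(ContactMap(oe, 100_000),
                                      rng.normal(size=n))
        assert strength == pytest.approx(1.0, abs=0.02)

    def test_relabel_invariance(self, rng):
        n = 120
        ev = rng.normal(size=n)
        mat = random_symmetric_map(n, rng) + 1.0
        cmap = ContactMap(mat, 100_000)
        s1, _ = saddle_strength(cmap, ev)
        perm = rng.permutation(n)
        cmap2 = ContactMap(mat[np.ix_(perm, perm)], 100_000)
        s2, _ = saddle_strength(cmap2, ev[perm])
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_all_nan_rejected(self):
        cmap = ContactMap(np.ones((10, 10)), 100_000)
        with pytest.raises(ValueError):
            saddle_strength(cmap, np.full(10, np.nan))


class TestContactFractions:
    def _df(self, rows):
        return pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2"])

    def test_trans_fraction(self):
        rows = [("c1", 100, "c1", 200)] * 99 + [("c1", 100, "c2", 500)]
        rep = contact_fractions(self._df(rows))
        assert rep["trans_fraction"] == pytest.approx(0.01)

    def test_all_within_one_domain(self):
        rows = [("c1", 100, "c1", 900)] * 5
        rep = contact_fractions(self._df(rows),
                                domains=[("c1", 0, 1000), ("c1", 1000, 2000)])
        assert rep["neighboring_domain_fraction"] == 0.0

    def test_adjacent_domains_counted(self):
        rows = [("c1", 100, "c1", 1500), ("c1", 100, "c1", 900)]
        rep = contact_fractions(self._df(rows),
                                domains=[("c1", 0, 1000), ("c1", 1000, 2000)])
        assert rep["neighboring_domain_fraction"] == pytest.approx(0.5)

    def test_qc_flags_one_site(self):
        rows = [("c1", 0, "c1", (k + 1) * 10) for k in range(9)]
        rep = contact_fractions(self._df(rows))
        assert rep["n_sites_over_cap"] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            contact_fractions(self._df([]))


class TestBedgraph:
    def test_roundtrip(self, tmp_path):
        vals = np.array([1.0, np.nan, 3.5, 2.0])
        path = tmp_path / "t.bedgraph"
        write_bedgraph(path, vals, 100, "chrS")
        back = read_bedgraph(path, 100, 400)
        np.testing.assert_allclose(back, vals, equal_nan=True)
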