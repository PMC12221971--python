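"""Tile DMR machinery: tiling, exact test vs enumeration oracle, FDR, annotation."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methdev import dmr as mdmr
from conftest import make_calls


def fisher_two_sided_bruteforce(a, b, c, d):
    """Exact-rational enumeration of the two-sided Fisher p over fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    denom = comb(n, c1)
    obs = comb(r1, a) * comb(r2, c1 - a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= obs:
            total += Fraction(w, denom)
    return float(total)


class TestTiling:
    def test_tile_bounds_cover_partial_final_window(self):
        tb = mdmr.tile_bounds(250, 100)
        assert tb.tolist() == [[0, 100], [100, 200], [200, 250]]

    def test_retention_requires_reads_in_both_conditions(self):
        a = make_calls([("chr1", 50, "+", 2, 1)], destranded=True)   # covA = 3
        b = make_calls([("chr1", 50, "+", 1, 1)], destranded=True)   # covB = 2
        assert len(mdmr.tile_counts(a, b, min_reads=3)) == 0
        b2 = make_calls([("chr1", 50, "+", 2, 1)], destranded=True)
        tiles = mdmr.tile_counts(a, b2, min_reads=3)
        assert len(tiles) == 1 and tiles.iloc[0]["n_cpg"] == 1

    def test_every_cpg_maps_to_exactly_one_tile(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 2000), 300, replace=False))
        a = make_calls([("chr1", int(p), "+", 5, 5) for p in pos], destranded=True)
        tiles = mdmr.tile_counts(a, a, min_reads=0, min_cpg=0)
        assert tiles["n_cpg"].sum() == len(pos)
        assert (tiles["start"] // 100 == tiles["end"].sub(1) // 100).all()

    def test_rejects_nonpositive_tile(self):
        a = make_calls([("chr1", 50, "+", 2, 1)], destranded=True)
        with pytest.raises(ValueError):
            mdmr.tile_counts(a, a, tile_bp=0)


class TestExactTest:
    def test_printed_examples(self):
        # margins 2/2: hypergeometric point masses {1/6, 4/6, 1/6}
        assert mdmr.exact_test(2, 0, 0, 2) == pytest.approx(1 / 3, abs=1e-12)
        assert mdmr.exact_test(5, 5, 5, 5) == pytest.approx(1.0)

    def test_zero_margin_convention(self):
        assert mdmr.exact_test(0, 0, 3, 4) == 1.0
        assert mdmr.exact_test(0, 5, 0, 7) == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 9, size=4))
        assert mdmr.exact_test(a, b, c, d) == pytest.approx(
            fisher_two_sided_bruteforce(a, b, c, d), abs=1e-12
        )


class TestFDR:
    def test_hand_computed_step_up(self):
        q = mdmr.adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])
        assert mdmr.adjust_fdr([0.2]) == pytest.approx([0.2])
        assert mdmr.adjust_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_nan_propagates_and_is_excluded_from_m(self):
        q = mdmr.adjust_fdr([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert q[[0, 2]] == pytest.approx(mdmr.adjust_fdr([0.01, 0.02]))

    def test_rank_monotone_and_permutation_invariant(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        q = mdmr.adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        perm = rng.permutation(50)
        assert mdmr.adjust_fdr(p[perm]) == pytest.approx(q[perm])


class TestCallDMRs:
    def _tiles(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "diff", "q"])
        df["p"] = df["q"]
        return df

    def test_threshold_logic(self):
        tiles = self._tiles([("chr1", 0, 100, 85.0, 0.001),
                             ("chr1", 100, 200, 85.0, 0.02),
                             ("chr1", 200, 300, -90.0, 0.001),
                             ("chr1", 300, 400, 60.0, 0.0001)])
        out = mdmr.call_dmrs(tiles, difference=80, qvalue=0.01,
                             label_a="sperm", label_b="oocyte")
        assert list(out["label"]) == ["sperm_specific", "oocyte_specific"]

    def test_thresholds_monotone_and_permissive_limit(self):
        rng = np.random.default_rng(1)
        tiles = self._tiles([
            ("chr1", i * 100, (i + 1) * 100, float(rng.uniform(-100, 100)),
             float(rng.uniform(0, 1))) for i in range(200)
        ])
        assert len(mdmr.call_dmrs(tiles, difference=0, qvalue=1.0000001)) == len(tiles)
        prev = None
        for diff in (0, 20, 50, 80, 100):
            got = set(map(tuple, mdmr.call_dmrs(tiles, difference=diff, qvalue=0.5)[
                ["chrom", "start"]].to_numpy()))
            if prev is not None:
                assert got <= prev
            prev = got


class TestAnnotate:
    def _ann(self):
        bed = lambda rows: pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                                       "score", "strand"])
        return {
            "genes": bed([("chr1", 1000, 9000, "g1", 0, "+")]),
            "promoters": bed([("chr1", 0, 1000, "g1", 0, "+")]),
            "cgis": bed([("chr1", 2000, 2600, "cgi1", 0, "+")]),
        }

    def test_precedence_and_intergenic(self):
        dmrs = pd.DataFrame(
            [("chr1", 2100, 2200), ("chr1", 5000, 5100), ("chr1", 500, 600),
             ("chr1", 20000, 20100)],
            columns=["chrom", "start", "end"],
        )
        out = mdmr.annotate_dmrs(dmrs, self._ann())
        assert list(out["feature_class"]) == ["cgi", "intragenic", "promoter", "intergenic"]

    def test_recovers_planted_class_distribution(self):
        # 70% of DMRs placed inside genes, the rest in open space
        rng = np.random.default_rng(2)
        genes = pd.DataFrame([("chr1", i * 20000, i * 20000 + 10000, f"g{i}", 0, "+")
                              for i in range(50)],
                             columns=["chrom", "start", "end", "name", "score", "strand"])
        rows = []
        for i in range(200):
            g = int(rng.integers(0, 50))
            if i < 140:
                s = int(rng.integers(g * 20000, g * 20000 + 9900))
            else:
                s = int(rng.integers(g * 20000 + 10000, g * 20000 + 19900))
            rows.append(("chr1", s, s + 100))
        dmrs = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        out = mdmr.annotate_dmrs(dmrs, {"genes": genes})
        frac = (out["feature_class"] == "intragenic").mean()
        assert abs(frac - 0.7) <= 0.05


class TestDiffSites:
    def test_identical_tables_fully_stable(self):
        tab = make_calls([("chr1", p, "+", 5, 5) for p in range(10, 200, 10)],
                         destranded=True)
        _, stable = mdmr.diff_sites(tab, tab, alpha=0.05, min_cov=5)
        assert stable == 1.0

    def test_no_shared_sites_is_an_error(self):
        a = make_calls([("chr1", 10, "+", 5, 5)], destranded=True)
        b = make_calls([("chr2", 10, "+", 5, 5)], destranded=True)
        with pytest.raises(ValueError, match="shared"):
            mdmr.diff_sites(a, b)


class TestMetaProfile:
    def test_flat_methylation_gives_flat_profile(self):
        tab = make_calls([("chr1", p, "+", 7, 3) for p in range(5, 8000, 20)],
                         destranded=True)
        iv = pd.DataFrame([("chr1", 3000, 5000, "+")],
                          columns=["chrom", "start", "end", "strand"])
        prof = mdmr.meta_profile(tab, iv)
        assert np.nanmax(np.abs(prof - 0.7)) < 1e-9

    def test_hypomethylated_body_gives_u_shape(self):
        rows = []
        for p in range(5, 8000, 20):
            level = (1, 9) if 3000 <= p < 5000 else (8, 2)
            rows.append(("chr1", p, "+", level[0], level[1]))
        tab = make_calls(rows, destranded=True)
        iv = pd.DataFrame([("chr1", 3000, 5000, "+")],
                          columns=["chrom", "start", "end", "strand"])
        prof = mdmr.meta_profile(tab, iv, body_bins=10)
        n_flank = 1000 // 50
        assert np.nanmean(prof[n_flank:n_flank + 10]) < 0.2
        assert np.nanmean(prof[:n_flank]) > 0.7

    def test_minus_strand_interval_is_reversed(self):
        rows = [("chr1", p, "+", (9, 1)[0], 1) if p < 4000 else ("chr1", p, "+", 0, 10)
                for p in range(2005, 6000, 20)]
        tab = make_calls(rows, destranded=True)
        plus = pd.DataFrame([("chr1", 3000, 5000, "+")],
                            columns=["chrom", "start", "end", "strand"])
        minus = plus.assign(strand="-")
        p1 = mdmr.meta_profile(tab, plus, body_bins=10, flank=500)
        p2 = mdmr.meta_profile(tab, minus, body_bins=10, flank=500)
        np.testing.assert_allclose(p1, p2[::-1], equal_nan=True)

    def test_zero_intervals_rejected(self):
        tab = make_calls([("chr1", 10, "+", 1, 1)], destranded=True)
        with pytest.raises(ValueError, match="zero intervals"):
            mdmr.meta_profile(tab, pd.DataFrame(columns=["chrom", "start", "end", "strand"]))
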