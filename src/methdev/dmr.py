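"""Tile-based differential methylation between two pooled conditions.

The genome is cut into fixed non-overlapping tiles (default 100 bp) laid from
coordinate 0, the final partial tile at each chromosome end included.  Counts
are pooled per tile and condition; a tile is retained if it holds at least one
CpG and at least ``min_reads`` summed reads in *both* conditions.  Each retained
tile is tested with a two-sided Fisher exact test on the pooled 2x2 count table
and adjusted with Benjamini-Hochberg FDR.  Gamete DMRs are the tiles passing
the |difference| and q-value thresholds (defaults 80 percentage points and
0.01), labelled by the sign of the difference.

Also provided: per-site paired testing (site-level stability), annotation of
DMRs against genomic feature classes, and scale-regions meta-profiles.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from . import calls as _calls
from .intervals import IntervalSet

log = logging.getLogger("methdev.dmr")

# relative tolerance on the point-probability comparison of the two-sided test
_REL_TOL = 1e-12


def tile_bounds(chrom_length: int, tile_bp: int = 100) -> np.ndarray:
    """(start, end) pairs of the fixed-window tiling of one chromosome."""
    if tile_bp <= 0:
        raise ValueError("tile_bp must be positive")
    starts = np.arange(0, chrom_length, tile_bp, dtype=np.int64)
    ends = np.minimum(starts + tile_bp, chrom_length)
    return np.column_stack([starts, ends])


def tile_counts(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    tile_bp: int = 100,
    min_reads: int = 3,
    min_cpg: int = 1,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Pool two destranded call tables into per-tile counts.

    Returns one row per retained tile with per-condition summed counts,
    methylation percentages and their difference (condition A minus B, in
    percentage points).  ``n_cpg`` counts CpG sites over the union of both
    conditions' site sets.
    """
    if tile_bp <= 0:
        raise ValueError("tile_bp must be positive")
    for t in (calls_a, calls_b):
        if not _calls.is_destranded(t):
            raise ValueError("tile_counts requires destranded/pooled inputs")
    a = calls_a[["chrom", "pos", "n_meth", "n_unmeth"]].rename(
        columns={"n_meth": "a_meth", "n_unmeth": "a_unmeth"}
    )
    b = calls_b[["chrom", "pos", "n_meth", "n_unmeth"]].rename(
        columns={"n_meth": "b_meth", "n_unmeth": "b_unmeth"}
    )
    m = a.merge(b, on=["chrom", "pos"], how="outer")
    for col in ("a_meth", "a_unmeth", "b_meth", "b_unmeth"):
        m[col] = m[col].fillna(0).astype(np.int64)
    m["tile"] = (m["pos"] - 1) // tile_bp
    g = m.groupby(["chrom", "tile"], sort=True, as_index=False).agg(
        n_cpg=("pos", "size"),
        a_meth=("a_meth", "sum"),
        a_unmeth=("a_unmeth", "sum"),
        b_meth=("b_meth", "sum"),
        b_unmeth=("b_unmeth", "sum"),
    )
    g["cov_a"] = g["a_meth"] + g["a_unmeth"]
    g["cov_b"] = g["b_meth"] + g["b_unmeth"]
    g = g[(g["cov_a"] >= min_reads) & (g["cov_b"] >= min_reads) & (g["n_cpg"] >= min_cpg)]
    g = g.copy()
    g["start"] = g["tile"] * tile_bp
    g["end"] = g["start"] + tile_bp
    if chrom_lengths is not None:
        lens = g["chrom"].map(chrom_lengths)
        g["end"] = np.minimum(g["end"], lens.fillna(g["end"]).astype(np.int64))
    with np.errstate(invalid="ignore", divide="ignore"):
        g["meth_a"] = 100.0 * g["a_meth"] / g["cov_a"]
        g["meth_b"] = 100.0 * g["b_meth"] / g["cov_b"]
    g["diff"] = g["meth_a"] - g["meth_b"]
    out = g[
        ["chrom", "start", "end", "n_cpg", "a_meth", "a_unmeth", "b_meth",
         "b_unmeth", "cov_a", "cov_b", "meth_a", "meth_b", "diff"]
    ].reset_index(drop=True)
    out.attrs.update({"tile_bp": tile_bp, "min_reads": min_reads, "min_cpg": min_cpg})
    return out


@lru_cache(maxsize=1 << 20)
def _exact_test_cached(a: int, b: int, c: int, d: int) -> float:
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        log.debug("exact_test: zero margin for table (%d,%d,%d,%d); p=1 by convention",
                  a, b, c, d)
        return 1.0
    kmin = max(0, c1 - r2)
    kmax = min(c1, r1)
    support = np.arange(kmin, kmax + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * (1.0 + _REL_TOL)].sum())
    return min(1.0, p)


def exact_test(a_meth: int, a_unmeth: int, b_meth: int, b_unmeth: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a_meth, a_unmeth], [b_meth, b_unmeth]].

    The p-value sums hypergeometric probabilities (margins fixed) of all tables
    whose point probability does not exceed that of the observed table, with a
    1e-12 relative tolerance on the comparison.  A zero margin yields p = 1 by
    convention (flagged in the debug log).
    """
    for v in (a_meth, a_unmeth, b_meth, b_unmeth):
        if v < 0:
            raise ValueError("counts must be non-negative")
    return _exact_test_cached(int(a_meth), int(a_unmeth), int(b_meth), int(b_unmeth))


def exact_test_many(a_meth, a_unmeth, b_meth, b_unmeth) -> np.ndarray:
    cols = [np.asarray(x, dtype=np.int64) for x in (a_meth, a_unmeth, b_meth, b_unmeth)]
    return np.array([_exact_test_cached(*map(int, row)) for row in zip(*cols)])


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values propagate and are excluded from m."""
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        if np.any((p[mask] < 0) | (p[mask] > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def test_tiles(tiles: pd.DataFrame) -> pd.DataFrame:
    """Add exact-test p and BH q columns to a tile-count table."""
    out = tiles.copy()
    out["p"] = exact_test_many(out["a_meth"], out["a_unmeth"], out["b_meth"], out["b_unmeth"])
    out["q"] = adjust_fdr(out["p"].to_numpy())
    out.attrs.update(tiles.attrs)
    out.attrs["fdr_method"] = "benjamini-hochberg"
    return out


def diff_tiles(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    tile_bp: int = 100,
    min_reads: int = 3,
    min_cpg: int = 1,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Convenience: tile_counts -> exact test -> FDR adjustment."""
    return test_tiles(
        tile_counts(calls_a, calls_b, tile_bp=tile_bp, min_reads=min_reads,
                    min_cpg=min_cpg, chrom_lengths=chrom_lengths)
    )


def call_dmrs(
    tiles: pd.DataFrame,
    difference: float = 80.0,
    qvalue: float = 0.01,
    label_a: str = "sperm",
    label_b: str = "oocyte",
) -> pd.DataFrame:
    """Tiles with |diff| >= difference and q < qvalue, labelled by the sign of diff.

    ``diff`` is condition A minus condition B; with the gamete convention
    A = sperm, a positive difference yields a sperm_specific (paternal) DMR and
    a negative one an oocyte_specific (maternal) DMR.
    """
    if "q" not in tiles.columns:
        raise ValueError("tiles must be tested and adjusted first (see test_tiles)")
    hit = tiles[(tiles["diff"].abs() >= difference) & (tiles["q"] < qvalue)].copy()
    hit["label"] = np.where(hit["diff"] > 0, f"{label_a}_specific", f"{label_b}_specific")
    hit.reset_index(drop=True, inplace=True)
    hit.attrs.update(tiles.attrs)
    hit.attrs.update({"difference": difference, "qvalue": qvalue,
                      "label_a": label_a, "label_b": label_b})
    return hit


_FEATURE_PRECEDENCE = ("cgi", "promoter", "intragenic")


def annotate_dmrs(dmrs: pd.DataFrame, annotations: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Assign one feature class per DMR by precedence CGI > promoter > intragenic > intergenic.

    ``annotations`` maps "cgis", "promoters" and "genes" to BED-like frames.
    Overlap is half-open with a 1 bp minimum.
    """
    key_map = {"cgi": "cgis", "promoter": "promoters", "intragenic": "genes"}
    index: dict[str, dict[str, IntervalSet]] = {}
    for cls in _FEATURE_PRECEDENCE:
        tab = annotations.get(key_map[cls])
        per_chrom: dict[str, IntervalSet] = {}
        if tab is not None and len(tab):
            for chrom, grp in tab.groupby("chrom", sort=False):
                per_chrom[chrom] = IntervalSet(grp["start"].to_numpy(), grp["end"].to_numpy())
        index[cls] = per_chrom
    out = dmrs.copy()
    classes = []
    for row in out.itertuples(index=False):
        assigned = "intergenic"
        for cls in _FEATURE_PRECEDENCE:
            iset = index[cls].get(row.chrom)
            if iset is not None and iset.overlaps(row.start, row.end):
                assigned = cls
                break
        classes.append(assigned)
    out["feature_class"] = classes
    return out


def diff_sites(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    alpha: float = 0.05,
    min_cov: int = 5,
) -> tuple[pd.DataFrame, float]:
    """Per-site exact test over shared CpG sites plus the fraction of stable sites.

    Both tables are filtered at ``min_cov`` first; a site is *stable* when its
    BH-adjusted q-value is >= alpha.  Returns (per-site table, fraction_stable).
    """
    a = _calls.filter_coverage(calls_a, min_cov)
    b = _calls.filter_coverage(calls_b, min_cov)
    m = a[["chrom", "pos", "n_meth", "n_unmeth"]].merge(
        b[["chrom", "pos", "n_meth", "n_unmeth"]],
        on=["chrom", "pos"],
        suffixes=("_a", "_b"),
    )
    if len(m) == 0:
        raise ValueError("diff_sites: no shared sites after coverage filtering")
    m["p"] = exact_test_many(m["n_meth_a"], m["n_unmeth_a"], m["n_meth_b"], m["n_unmeth_b"])
    m["q"] = adjust_fdr(m["p"].to_numpy())
    fraction_stable = float((m["q"] >= alpha).mean())
    return m, fraction_stable


def meta_profile(
    calls: pd.DataFrame,
    intervals: pd.DataFrame,
    body_bins: int = 20,
    flank: int = 1000,
    bin_bp: int = 50,
) -> np.ndarray:
    """Scale-regions methylation meta-profile over a set of stranded intervals.

    Each interval body is rescaled to ``body_bins`` bins; flanks are tiled in
    fixed ``bin_bp`` windows.  A bin's value is the mean of the per-site
    methylation fractions of the CpGs falling in it; minus-strand intervals are
    reversed; the profile is the cross-interval mean per bin (NaN-aware).
    """
    if len(intervals) == 0:
        raise ValueError("meta_profile: zero intervals")
    if not _calls.is_destranded(calls):
        raise ValueError("meta_profile requires destranded calls")
    n_flank = flank // bin_bp
    n_bins = 2 * n_flank + body_bins
    cov = _calls.coverage(calls)
    covered = calls[cov > 0].sort_values(["chrom", "pos"]).reset_index(drop=True)
    ccov = (covered["n_meth"] + covered["n_unmeth"]).to_numpy()
    frac = covered["n_meth"].to_numpy() / ccov
    pos0 = covered["pos"].to_numpy() - 1
    by_chrom = {
        chrom: (pos0[list(idx)], frac[list(idx)])
        for chrom, idx in covered.groupby("chrom", sort=False).groups.items()
    }
    acc = np.zeros(n_bins)
    cnt = np.zeros(n_bins, dtype=np.int64)
    for row in intervals.itertuples(index=False):
        got = by_chrom.get(row.chrom)
        if got is None:
            continue
        cpos, cfrac = got
        lo, hi = row.start - flank, row.end + flank
        i0, i1 = np.searchsorted(cpos, [lo, hi])
        if i1 <= i0:
            continue
        p = cpos[i0:i1]
        f = cfrac[i0:i1]
        body_len = max(row.end - row.start, 1)
        binidx = np.empty(len(p), dtype=np.int64)
        up = p < row.start
        dn = p >= row.end
        body = ~up & ~dn
        binidx[up] = (p[up] - (row.start - flank)) // bin_bp
        binidx[body] = n_flank + np.minimum(
            (p[body] - row.start) * body_bins // body_len, body_bins - 1
        )
        binidx[dn] = n_flank + body_bins + np.minimum((p[dn] - row.end) // bin_bp, n_flank - 1)
        strand = getattr(row, "strand", "+")
        if strand == "-":
            binidx = n_bins - 1 - binidx
        per_bin = np.zeros(n_bins)
        per_cnt = np.zeros(n_bins, dtype=np.int64)
        np.add.at(per_bin, binidx, f)
        np.add.at(per_cnt, binidx, 1)
        with np.errstate(invalid="ignore"):
            mean_bin = per_bin / per_cnt
        hit = per_cnt > 0
        acc[hit] += mean_bin[hit]
        cnt[hit] += 1
    with np.errstate(invalid="ignore"):
        profile = acc / cnt
    return profile
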