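"""Methylome segmentation and partially-methylated-domain (PMD) flagging.

The per-site methylation sequence of each chromosome is cut into contiguous
segments of similar methylation by greedy recursive binary splitting: at each
step the candidate change point minimising the within-segment sum of squared
error (SSE) is evaluated, and the split is accepted only if both children hold
at least ``min_seg`` CpGs and the SSE reduction passes a BIC criterion under
Gaussian noise.  Segment mean-methylation values are then clustered into at
most ``max_classes`` methylation classes with a 1-D Gaussian mixture (class
count chosen by BIC), and adjacent same-class segments are merged.

A PMD candidate is a long segment (default >= 100 kb) of intermediate mean
methylation (default 0.3-0.7): the signature of the disordered, partially
methylated blocks typical of trophectoderm/placenta.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from . import calls as _calls

log = logging.getLogger("methdev.segment")

_SSE_FLOOR = 1e-10

SEGMENT_COLUMNS = ["chrom", "start", "end", "n_cpg", "mean_meth", "seg_class", "short"]


def _sse(prefix_s: np.ndarray, prefix_s2: np.ndarray, i: int, j: int) -> float:
    """SSE of values[i:j] from inclusive prefix sums (prefix arrays have a leading 0)."""
    n = j - i
    s = prefix_s[j] - prefix_s[i]
    s2 = prefix_s2[j] - prefix_s2[i]
    return max(s2 - s * s / n, 0.0)


def _split_points(values: np.ndarray, min_seg: int, penalty: float = 6.0) -> list[int]:
    """Boundaries (indices into values) from greedy binary splitting with BIC acceptance."""
    n = len(values)
    ps = np.concatenate([[0.0], np.cumsum(values)])
    ps2 = np.concatenate([[0.0], np.cumsum(values * values)])
    bounds: list[int] = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        m = j - i
        if m < 2 * min_seg:
            continue
        ks = np.arange(i + min_seg, j - min_seg + 1)
        nl = ks - i
        nr = j - ks
        sl = ps[ks] - ps[i]
        s2l = ps2[ks] - ps2[i]
        sr = ps[j] - ps[ks]
        s2r = ps2[j] - ps2[ks]
        sse_l = np.maximum(s2l - sl * sl / nl, 0.0)
        sse_r = np.maximum(s2r - sr * sr / nr, 0.0)
        tot = sse_l + sse_r
        best = int(np.argmin(tot))
        sse0 = _sse(ps, ps2, i, j)
        sse1 = float(tot[best])
        # Gaussian log-likelihood gain vs a BIC-style penalty for one extra mean
        # plus a free breakpoint; the factor sits above the extreme-value ceiling
        # of pure-noise SSE reductions so flat stretches stay unsplit
        gain = m * np.log(max(sse0, m * _SSE_FLOOR) / max(sse1, m * _SSE_FLOOR))
        if gain > penalty * np.log(m):
            k = int(ks[best])
            bounds.append(k)
            stack.append((i, k))
            stack.append((k, j))
    return sorted(bounds)


def classify_segment_means(
    means: np.ndarray,
    n_classes: int | None = None,
    max_classes: int = 3,
    random_state: int = 0,
) -> tuple[np.ndarray, int]:
    """Cluster segment means into 1..max_classes classes (1-D GMM, BIC-selected).

    Returns (class labels in 1..G ordered by increasing class mean, G).
    """
    means = np.asarray(means, dtype=float)
    x = means.reshape(-1, 1)
    n_unique = len(np.unique(means))
    if n_classes is not None:
        candidates = [min(n_classes, n_unique)]
    else:
        candidates = list(range(1, min(max_classes, n_unique) + 1))
    best = None
    for g in candidates:
        if g == 1:
            labels = np.zeros(len(means), dtype=int)
            sse = float(((means - means.mean()) ** 2).sum()) if len(means) else 0.0
            var = max(sse / max(len(means), 1), 1e-8)
            ll = -0.5 * len(means) * (np.log(2 * np.pi * var) + 1)
            bic = -2 * ll + 2 * np.log(max(len(means), 1))
            model = None
        else:
            model = GaussianMixture(
                n_components=g, n_init=5, random_state=random_state, reg_covar=1e-4
            ).fit(x)
            bic = model.bic(x)
            labels = model.predict(x)
        if best is None or bic < best[0] - 1e-9:
            best = (bic, g, labels, model)
    _, g, labels, model = best
    if model is not None:
        order = np.argsort(model.means_.ravel())
        rank = np.empty(g, dtype=int)
        rank[order] = np.arange(1, g + 1)
        classes = rank[labels]
    else:
        classes = labels + 1
    return classes, g


def segment(
    calls: pd.DataFrame,
    min_cov: int = 5,
    min_seg: int = 5,
    max_classes: int = 3,
    n_classes: int | None = None,
    max_gap: int | None = None,
    random_state: int = 0,
) -> pd.DataFrame:
    """Segment a destranded single-sample call table into methylation classes.

    Segment bounds run from the first to the last CpG of the segment plus one
    (0-based half-open).  A chromosome with fewer than ``min_seg`` covered
    sites yields a single segment flagged ``short``.  ``max_gap``, when set,
    imposes additional splits at inter-CpG gaps larger than the given bp
    (off by default; 10 kb is a reasonable choice when enabled) -- the setting
    is recorded in the output metadata.
    """
    if not _calls.is_destranded(calls):
        raise ValueError("segment requires a destranded call table")
    filt = _calls.filter_coverage(calls, min_cov)
    filt = filt.sort_values(["chrom", "pos"]).reset_index(drop=True)
    rows = []
    for chrom, grp in filt.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        cov = (grp["n_meth"] + grp["n_unmeth"]).to_numpy()
        frac = grp["n_meth"].to_numpy() / cov
        n = len(pos)
        if n == 0:
            continue
        blocks: list[tuple[int, int]] = []
        if max_gap is not None and n > 1:
            cut = np.flatnonzero(np.diff(pos) > max_gap) + 1
            edges = np.concatenate([[0], cut, [n]])
        else:
            edges = np.array([0, n])
        for b0, b1 in zip(edges[:-1], edges[1:]):
            blocks.append((int(b0), int(b1)))
        for block_id, (b0, b1) in enumerate(blocks):
            vals = frac[b0:b1]
            m = b1 - b0
            if m < min_seg:
                rows.append((chrom, pos[b0] - 1, pos[b1 - 1], m, float(vals.mean()),
                             True, block_id))
                continue
            bounds = [0] + _split_points(vals, min_seg) + [m]
            for i, j in zip(bounds[:-1], bounds[1:]):
                rows.append(
                    (chrom, pos[b0 + i] - 1, pos[b0 + j - 1], j - i,
                     float(vals[i:j].mean()), False, block_id)
                )
    seg = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_cpg", "mean_meth",
                                      "short", "block_id"])
    seg["end"] = seg["end"].astype(np.int64)  # last CpG pos (1-based) == half-open end past the C
    if len(seg):
        classes, g = classify_segment_means(
            seg["mean_meth"].to_numpy(), n_classes=n_classes,
            max_classes=max_classes, random_state=random_state,
        )
        seg["seg_class"] = classes
        seg = _join_neighbours(seg)
    else:
        seg["seg_class"] = pd.Series(dtype=int)
        seg = seg.drop(columns=["block_id"])
        g = 0
    seg.attrs.update({
        "min_cov": min_cov, "min_seg": min_seg, "max_classes": max_classes,
        "n_classes_used": int(g), "max_gap": max_gap,
    })
    log.info("segment: %d segment(s), %d class(es), max_gap=%s", len(seg), g, max_gap)
    return seg


def _join_neighbours(seg: pd.DataFrame) -> pd.DataFrame:
    """Merge adjacent same-class segments within each chromosome (count-weighted mean).

    Segments separated by an imposed max-gap split (different ``block_id``) are
    never merged.
    """
    out = []
    for chrom, grp in seg.groupby("chrom", sort=True):
        grp = grp.sort_values("start").reset_index(drop=True)
        cur = None
        for row in grp.itertuples(index=False):
            if (cur is not None and row.seg_class == cur["seg_class"]
                    and getattr(row, "block_id", 0) == cur["block_id"]
                    and not row.short and not cur["short"]):
                w = cur["n_cpg"] + row.n_cpg
                cur["mean_meth"] = (cur["mean_meth"] * cur["n_cpg"] + row.mean_meth * row.n_cpg) / w
                cur["n_cpg"] = w
                cur["end"] = row.end
            else:
                if cur is not None:
                    out.append(cur)
                cur = {"chrom": chrom, "start": row.start, "end": row.end,
                       "n_cpg": row.n_cpg, "mean_meth": row.mean_meth,
                       "seg_class": row.seg_class, "short": row.short,
                       "block_id": getattr(row, "block_id", 0)}
        if cur is not None:
            out.append(cur)
    res = pd.DataFrame(out, columns=["chrom", "start", "end", "n_cpg", "mean_meth",
                                     "seg_class", "short"])
    return res


def flag_pmds(
    segments: pd.DataFrame,
    min_len_bp: int = 100_000,
    mid_lo: float = 0.3,
    mid_hi: float = 0.7,
) -> pd.DataFrame:
    """Flag PMD candidates: segments >= min_len_bp with intermediate mean methylation."""
    out = segments.copy()
    length = out["end"] - out["start"]
    out["is_pmd"] = (
        (length >= min_len_bp) & (out["mean_meth"] >= mid_lo) & (out["mean_meth"] <= mid_hi)
    )
    out.attrs.update(segments.attrs)
    out.attrs.update({"pmd_min_len_bp": min_len_bp, "pmd_lo": mid_lo, "pmd_hi": mid_hi})
    return out


def segment_compare(segments_a: pd.DataFrame, segments_b: pd.DataFrame) -> dict:
    """Length/methylation summaries of two segmentations run with identical parameters."""
    keys = ("min_cov", "min_seg", "max_classes", "max_gap")
    pa = {k: segments_a.attrs.get(k) for k in keys}
    pb = {k: segments_b.attrs.get(k) for k in keys}
    if pa != pb:
        raise ValueError(f"segmentation parameter mismatch: {pa} vs {pb}")

    def one(seg: pd.DataFrame) -> dict:
        length = (seg["end"] - seg["start"]).to_numpy()
        covered = float(length.sum()) if len(seg) else 0.0
        pmd_bp = float(length[seg["is_pmd"].to_numpy()].sum()) if "is_pmd" in seg else 0.0
        return {
            "length": length,
            "mean_meth": seg["mean_meth"].to_numpy(),
            "seg_class": seg["seg_class"].to_numpy() if "seg_class" in seg else None,
            "pmd_genome_fraction": (pmd_bp / covered) if covered else 0.0,
            "n_segments": int(len(seg)),
        }

    return {"a": one(segments_a), "b": one(segments_b)}
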