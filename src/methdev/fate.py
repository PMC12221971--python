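"""Fate of gamete DMRs through development: transient, lineage-specific, life-long.

A gamete DMR carries a parental methylation asymmetry (maternal origin =
oocyte-methylated, paternal = sperm-methylated).  In balanced diploid tissue a
retained one-allele mark shows *intermediate* methylation (default 40-60%,
inclusive bounds).  The classifier follows the DMR through an ordered series of
stages -- cleavage embryo (E3.5), E7.5 embryonic disc (ED) and trophectoderm
(TE), and adult brain, liver and spleen -- and assigns exactly one fate:

    not_established      E3.5 not intermediate
    lifelong             intermediate at E3.5, ED and all three adult tissues
                         (candidate imprinted locus)
    ED_retained          intermediate at E3.5 and ED (but not life-long)
    TE_retained          intermediate at E3.5 and TE (but not at ED)
    transient_embryonic  intermediate at E3.5 only

A stage whose pooled DMR coverage falls below ``stage_min_reads`` is missing,
and any clause it gates evaluates false.  Sex-mixed embryo pools preclude
X-linked analysis, so DMRs on the X (and Y) are excluded by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import calls as _calls
from .intervals import interval_gap

log = logging.getLogger("methdev.fate")

ADULT_STAGES = ("brain", "liver", "spleen")
FATE_LABELS = ("not_established", "transient_embryonic", "ED_retained",
               "TE_retained", "lifelong")


@dataclass
class FateConfig:
    stages: Mapping[str, pd.DataFrame]
    intermediate_lo: float = 40.0
    intermediate_hi: float = 60.0
    stage_min_reads: int = 3
    exclude_chroms: tuple[str, ...] = ("chrX", "chrY")

    def __post_init__(self):
        if not self.intermediate_lo < self.intermediate_hi:
            raise ValueError("intermediate_lo must be below intermediate_hi")
        missing = [s for s in ("E3.5",) if s not in self.stages]
        if missing:
            raise ValueError(f"required stage table(s) missing: {missing}")


def dmr_methylation_by_stage(dmrs: pd.DataFrame, config: FateConfig) -> pd.DataFrame:
    """Pooled-count methylation percentage per DMR per stage; NaN when under-covered."""
    out = pd.DataFrame(index=dmrs.index)
    for stage, table in config.stages.items():
        if table is None or len(table) == 0:
            log.warning("stage %s: empty call table, all DMRs missing", stage)
            out[stage] = np.nan
            continue
        if not _calls.is_destranded(table):
            raise ValueError(f"stage {stage}: call table must be destranded/pooled")
        col = np.full(len(dmrs), np.nan)
        by_chrom = {
            chrom: grp.sort_values("pos")
            for chrom, grp in table.groupby("chrom", sort=False)
        }
        for i, row in enumerate(dmrs.itertuples(index=False)):
            grp = by_chrom.get(row.chrom)
            if grp is None:
                continue
            pos = grp["pos"].to_numpy()
            i0, i1 = np.searchsorted(pos, [row.start + 1, row.end + 1])
            if i1 <= i0:
                continue
            m = int(grp["n_meth"].to_numpy()[i0:i1].sum())
            u = int(grp["n_unmeth"].to_numpy()[i0:i1].sum())
            if m + u >= config.stage_min_reads:
                col[i] = 100.0 * m / (m + u)
        out[stage] = col
    return out


def classify_fate(meth_by_stage: Mapping[str, float], lo: float = 40.0,
                  hi: float = 60.0) -> str:
    """One fate label from a DMR's per-stage methylation percentages.

    Missing stages (absent key or NaN) make the clause they gate false.
    Bounds are inclusive on both sides.
    """
    def inter(stage: str) -> bool:
        v = meth_by_stage.get(stage)
        return v is not None and not (isinstance(v, float) and math.isnan(v)) and lo <= v <= hi

    if not inter("E3.5"):
        return "not_established"
    if inter("E7.5_ED") and all(inter(s) for s in ADULT_STAGES):
        return "lifelong"
    if inter("E7.5_ED"):
        return "ED_retained"
    if inter("E7.5_TE"):
        return "TE_retained"
    return "transient_embryonic"


def nearest_gene(chrom: str, start: int, end: int,
                 genes: pd.DataFrame) -> tuple[str | None, float]:
    """Nearest gene by half-open interval gap; overlap gives distance 0.

    Ties break on the smaller gene start, then lexicographic id.  Only
    same-chromosome genes are considered; (None, nan) flags no assignment.
    """
    cand = genes[genes["chrom"] == chrom]
    if len(cand) == 0:
        return None, float("nan")
    best: tuple[int, int, str] | None = None
    for g in cand.itertuples(index=False):
        gap = interval_gap(start, end, g.start, g.end)
        key = (gap, g.start, g.name)
        if best is None or key < best:
            best = key
    return best[2], float(best[0])


def track_fates(dmrs: pd.DataFrame, config: FateConfig,
                genes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Full fate records for a set of gamete DMRs.

    ``dmrs`` needs chrom/start/end plus either an ``origin`` column
    (maternal/paternal) or the ``label`` column produced by
    :func:`methdev.dmr.call_dmrs` (oocyte_specific -> maternal).  The fate
    tracker is agnostic to DMR provenance: any BED-like interval frame works.
    """
    keep = ~dmrs["chrom"].isin(config.exclude_chroms)
    if (~keep).any():
        log.info("track_fates: excluding %d DMR(s) on %s", int((~keep).sum()),
                 ",".join(config.exclude_chroms))
    dmrs = dmrs[keep].reset_index(drop=True)
    if "origin" in dmrs.columns:
        origin = dmrs["origin"].astype(str)
    elif "label" in dmrs.columns:
        origin = dmrs["label"].map(
            lambda s: "maternal" if "oocyte" in s else ("paternal" if "sperm" in s else "unknown")
        )
    else:
        origin = pd.Series(["unknown"] * len(dmrs))
    stages = dmr_methylation_by_stage(dmrs, config)
    lo, hi = config.intermediate_lo, config.intermediate_hi
    # stage labels like "E3.5" are not identifiers; build plain dicts per row
    fates = [
        classify_fate(dict(zip(stages.columns, vals)), lo=lo, hi=hi)
        for vals in stages.to_numpy()
    ]

    def _inter(v):
        return not (isinstance(v, float) and math.isnan(v)) and lo <= v <= hi

    both = [
        _inter(d.get("E7.5_ED", float("nan"))) and _inter(d.get("E7.5_TE", float("nan")))
        for d in (dict(zip(stages.columns, vals)) for vals in stages.to_numpy())
    ]
    rec = pd.concat(
        [dmrs[["chrom", "start", "end"]].reset_index(drop=True), stages.reset_index(drop=True)],
        axis=1,
    )
    rec["origin"] = origin.to_numpy()
    rec["fate"] = fates
    rec["both_e75_retained"] = both
    if genes is not None:
        names, dists = [], []
        for row in rec.itertuples(index=False):
            name, dist = nearest_gene(row.chrom, row.start, row.end, genes)
            names.append(name)
            dists.append(dist)
        rec["nearest_gene"] = names
        rec["distance_bp"] = dists
    return rec


def fate_report(records: pd.DataFrame) -> dict:
    """Contingency counts per fate x origin, plus the maternal share of life-long DMRs."""
    if len(records) == 0:
        return {"n": 0, "counts": {}, "lifelong_maternal_fraction": None}
    counts: dict[str, dict[str, int]] = {}
    tab = records.groupby(["fate", "origin"]).size()
    for (f, o), n in tab.items():
        counts.setdefault(f, {})[o] = int(n)
    lifelong = records[records["fate"] == "lifelong"]
    frac = float((lifelong["origin"] == "maternal").mean()) if len(lifelong) else None
    return {"n": int(len(records)), "counts": counts, "lifelong_maternal_fraction": frac}
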