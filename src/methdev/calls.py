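"""Per-CpG bisulfite call tables: reading, writing, destranding, pooling.

A *call table* is a pandas DataFrame with one row per cytosine (or per CpG
dinucleotide after destranding) and columns

    chrom    chromosome identifier (str)
    pos      1-based cytosine position (int)
    strand   "+" or "-" ("+" uniformly after destranding)
    n_meth   methylated read count (int, >= 0)
    n_unmeth unmethylated read count (int, >= 0)
    context  "CpG" | "CHG" | "CHH"

Two standard text dialects are supported: the Bismark-style *cytosine report*
(one row per strand per cytosine, with a trailing trinucleotide column) and the
destranded *coverage* dialect (chrom, 1-based start, 1-based end, %methylation,
methylated count, unmethylated count).  Destranding merges the minus-strand
record of a CpG dinucleotide into the plus-strand record one base upstream;
pooling sums counts per site across libraries of the same condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("methdev.calls")

CALL_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]

_REPORT_NAMES = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "trinucleotide"]
_COVERAGE_NAMES = ["chrom", "start", "end", "pct", "n_meth", "n_unmeth"]


def empty_calls(destranded: bool = False) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "n_meth": pd.Series(dtype=np.int64),
            "n_unmeth": pd.Series(dtype=np.int64),
            "context": pd.Series(dtype=str),
        }
    )
    df.attrs["destranded"] = destranded
    return df


def _finalize(df: pd.DataFrame, destranded: bool) -> pd.DataFrame:
    df = df[CALL_COLUMNS].copy()
    df["pos"] = df["pos"].astype(np.int64)
    df["n_meth"] = df["n_meth"].astype(np.int64)
    df["n_unmeth"] = df["n_unmeth"].astype(np.int64)
    df.reset_index(drop=True, inplace=True)
    df.attrs["destranded"] = destranded
    return df


def is_destranded(calls: pd.DataFrame) -> bool:
    """A table counts as destranded if flagged so, or if no minus-strand row exists."""
    if calls.attrs.get("destranded", False):
        return True
    return bool((calls["strand"] == "+").all()) if len(calls) else True


def coverage(calls: pd.DataFrame) -> pd.Series:
    return calls["n_meth"] + calls["n_unmeth"]


def _require(cond: pd.Series, path, message: str) -> None:
    """Raise on the first failing row, reporting its 1-based line number."""
    bad = ~cond.to_numpy()
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 1
        raise ValueError(f"{path}: {message} at line {line}")


def read_calls(path, dialect: str = "cytosine_report", context: str | None = "CpG") -> pd.DataFrame:
    """Read a call table from one of the two supported dialects.

    ``context`` restricts cytosine-report rows to the given context (pass None
    to keep all).  Coverage-dialect rows are treated as already destranded.
    """
    if dialect not in ("cytosine_report", "coverage"):
        raise ValueError(f"unknown dialect {dialect!r}")
    names = _REPORT_NAMES if dialect == "cytosine_report" else _COVERAGE_NAMES
    try:
        raw = pd.read_csv(path, sep="\t", header=None, names=names, dtype=str)
    except pd.errors.EmptyDataError:
        return empty_calls(destranded=dialect == "coverage")
    if raw.isna().any(axis=None):
        _require(~raw.isna().any(axis=1), path, "malformed row")

    for col in ("pos", "start", "end", "n_meth", "n_unmeth"):
        if col in raw.columns:
            parsed = pd.to_numeric(raw[col], errors="coerce")
            _require(parsed.notna() & (np.mod(parsed.fillna(0.5), 1) == 0), path,
                     f"non-integer {col}")
            _require(parsed >= 0, path, f"negative {col}")
            raw[col] = parsed.astype(np.int64)

    if dialect == "cytosine_report":
        _require(raw["strand"].isin(["+", "-"]), path, "unknown strand symbol")
        df = raw
        if context is not None:
            df = df[df["context"] == context]
        return _finalize(df, destranded=False)

    df = raw.rename(columns={"start": "pos"})
    df["strand"] = "+"
    df["context"] = "CpG"
    return _finalize(df, destranded=True)


def write_cytosine_report(calls: pd.DataFrame, path) -> None:
    """Write the Bismark-dialect cytosine report (one row per strand per cytosine)."""
    out = calls.copy()
    if "trinucleotide" not in out.columns:
        out["trinucleotide"] = np.where(out["strand"] == "+", "CGG", "CGA")
    out[_REPORT_NAMES].to_csv(path, sep="\t", header=False, index=False)


def write_coverage(calls: pd.DataFrame, path) -> None:
    """Write the destranded coverage dialect; zero-coverage sites are omitted."""
    if not is_destranded(calls):
        raise ValueError("coverage dialect requires a destranded table")
    cov = coverage(calls)
    out = calls[cov > 0].copy()
    cov = cov[cov > 0]
    out["start"] = out["pos"]
    out["end"] = out["pos"]
    out["pct"] = (100.0 * out["n_meth"] / cov).map(lambda v: format(v, ".6g"))
    out[_COVERAGE_NAMES].to_csv(path, sep="\t", header=False, index=False)


def destrand(calls: pd.DataFrame, cpg_map: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Merge minus-strand calls into the plus-strand CpG record one base upstream.

    The destranded coordinate is the plus-strand C position (1-based).  Orphan
    single-strand records are kept at the canonical plus coordinate; a
    minus-strand record at position <= 1 has no admissible partner and is kept
    in place (flagged in the log).  Total counts are conserved exactly.
    """
    if is_destranded(calls):
        out = calls.copy()
        out["strand"] = "+"
        out.attrs["destranded"] = True
        return out
    df = calls[calls["context"] == "CpG"].copy()
    pos = df["pos"].to_numpy(dtype=np.int64, copy=True)
    minus = (df["strand"] == "-").to_numpy()
    stuck = minus & (pos <= 1)
    if stuck.any():
        log.warning("destrand: %d minus-strand record(s) at pos<=1 kept in place", stuck.sum())
    pos[minus & ~stuck] -= 1
    df["pos"] = pos
    if cpg_map is not None:
        for chrom, grp in df[minus & ~stuck].groupby("chrom", sort=False):
            known = cpg_map.get(chrom, np.empty(0, dtype=np.int64))
            miss = ~np.isin(grp["pos"].to_numpy(), known)
            if miss.any():
                log.warning("destrand: %d minus-strand record(s) on %s without a mapped CpG partner",
                            int(miss.sum()), chrom)
    g = (
        df.groupby(["chrom", "pos"], sort=True, as_index=False)[["n_meth", "n_unmeth"]]
        .sum()
    )
    g["strand"] = "+"
    g["context"] = "CpG"
    return _finalize(g, destranded=True)


def pool(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Sum counts per (chrom, pos) across destranded tables; site set is the union."""
    if not tables:
        return empty_calls(destranded=True)
    for t in tables:
        if not is_destranded(t):
            raise ValueError("pool: all inputs must be destranded")
    cat = pd.concat([t[CALL_COLUMNS] for t in tables], ignore_index=True)
    g = (
        cat.groupby(["chrom", "pos"], sort=True, as_index=False)[["n_meth", "n_unmeth"]]
        .sum()
    )
    g["strand"] = "+"
    g["context"] = "CpG"
    return _finalize(g, destranded=True)


def filter_coverage(calls: pd.DataFrame, min_cov: int) -> pd.DataFrame:
    """Retain sites with n_meth + n_unmeth >= min_cov."""
    keep = coverage(calls) >= min_cov
    n_removed = int((~keep).sum())
    log.info("filter_coverage: min_cov=%d removed %d of %d sites", min_cov, n_removed, len(calls))
    out = calls[keep].copy()
    out.attrs["destranded"] = calls.attrs.get("destranded", is_destranded(calls))
    out.reset_index(drop=True, inplace=True)
    return out


@dataclass
class SampleSummary:
    """Per-sample methylome summary: site count, per-site mean, histogram, capture."""

    sample: str
    n_sites: int
    mean_meth: float
    hist: np.ndarray = field(default_factory=lambda: np.zeros(10, dtype=np.int64))
    capture: dict[int, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "sample": self.sample,
            "n_sites": self.n_sites,
            "mean_meth": None if np.isnan(self.mean_meth) else float(self.mean_meth),
            "hist": [int(x) for x in self.hist],
        }
        if self.capture is not None:
            d["capture"] = {str(k): float(v) for k, v in self.capture.items()}
        return d


def summarize(calls: pd.DataFrame, genome_cpg_total: int | None = None,
              sample: str = "") -> SampleSummary:
    """Summarize a destranded, filtered table.

    ``mean_meth`` is the unweighted mean over covered sites of n_meth/coverage
    (per-site, not read-weighted).  The histogram uses 10-percentage-point bins,
    right-open except the last, so fully methylated sites land in the top bin.
    Capture fractions (share of genome CpGs at >=1x and >=5x) are reported when
    the genome total is supplied.
    """
    cov = coverage(calls)
    covered = calls[cov > 0]
    cov_pos = cov[cov > 0]
    n_sites = int(len(covered))
    if n_sites == 0:
        log.warning("summarize: empty table, mean methylation undefined")
        mean = float("nan")
        hist = np.zeros(10, dtype=np.int64)
    else:
        frac = covered["n_meth"].to_numpy() / cov_pos.to_numpy()
        mean = float(frac.mean())
        hist, _ = np.histogram(frac * 100.0, bins=10, range=(0.0, 100.0))
    capture = None
    if genome_cpg_total is not None:
        capture = {
            1: float((cov >= 1).sum() / genome_cpg_total),
            5: float((cov >= 5).sum() / genome_cpg_total),
        }
    return SampleSummary(sample=sample, n_sites=n_sites, mean_meth=mean,
                         hist=hist, capture=capture)


# ---------------------------------------------------------------------------
# BED / GTF annotation I/O

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read BED6 (0-based half-open); intervals with end <= start are rejected."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED_COLUMNS)
    df = df.iloc[:, : len(BED_COLUMNS)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in df.columns:
            df[col] = default
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    _require(df["end"] > df["start"], path, "interval with end <= start")
    return df[BED_COLUMNS]


def write_bed(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in out.columns:
            out[col] = default
    out[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def write_genes_gtf(genes: pd.DataFrame, path, source: str = "methdev") -> None:
    """Write gene intervals as a minimal GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            attrs = f'gene_id "{row.name}";'
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start + 1}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )
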