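"""Chromosome-level and expression-linked methylation analyses.

Covers embryo sexing from X/pseudo-Y read counts, X-vs-autosome methylation
distributions (the female X runs at roughly the midpoint of the two alleles
because the imprinted inactive X is hypomethylated), allele-specific Xi
hypomethylation, escape-gene methylation, oocyte active/inactive gene-body
methylation, and X/A expression ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calls as _calls

log = logging.getLogger("methdev.chromx")

SEX_CHROMS = ("chrX", "chrY")


@dataclass
class SexCall:
    sample: str
    x_reads: int
    y_reads: int
    total_reads: int
    y_cpm: float
    sex_call: str  # male | female | ambiguous


def infer_sex(
    x_reads: int,
    y_reads: int,
    total_reads: int,
    tau_cpm: float = 1.0,
    guard: float = 0.2,
    sample: str = "",
) -> SexCall:
    """Sex call from pseudo-Y reads per million total reads.

    male iff y_cpm >= tau*(1+guard); female iff y_cpm <= tau*(1-guard);
    anything inside the guard band is ambiguous.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    y_cpm = 1e6 * y_reads / total_reads
    if y_cpm >= tau_cpm * (1.0 + guard):
        call = "male"
    elif y_cpm <= tau_cpm * (1.0 - guard):
        call = "female"
    else:
        call = "ambiguous"
    return SexCall(sample, int(x_reads), int(y_reads), int(total_reads), y_cpm, call)


def estimate_tau(y_cpm_values, default: float = 1.0) -> float:
    """Midpoint of the bimodal split (largest gap) of a batch's y_cpm values.

    Falls back to ``default`` with fewer than 4 samples or no usable gap.
    """
    v = np.sort(np.asarray(y_cpm_values, dtype=float))
    if len(v) < 4:
        return default
    gaps = np.diff(v)
    i = int(np.argmax(gaps))
    if gaps[i] <= 0:
        return default
    return float((v[i] + v[i + 1]) / 2.0)


def infer_sex_batch(
    counts: pd.DataFrame,
    tau_cpm: float | None = None,
    guard: float = 0.2,
) -> list[SexCall]:
    """Sex calls for a batch; tau is estimated from the batch bimodality when not given.

    ``counts`` needs columns sample, x_reads, y_reads, total_reads and may carry
    a boolean ``pooled`` column: sex-mixed pools are flagged ambiguous, never
    classified.
    """
    y_cpm = 1e6 * counts["y_reads"] / counts["total_reads"]
    if tau_cpm is None:
        pooled = counts["pooled"] if "pooled" in counts else pd.Series(False, index=counts.index)
        tau_cpm = estimate_tau(y_cpm[~pooled.astype(bool)].to_numpy())
    out = []
    for i, row in counts.reset_index(drop=True).iterrows():
        call = infer_sex(row["x_reads"], row["y_reads"], row["total_reads"],
                         tau_cpm=tau_cpm, guard=guard, sample=str(row["sample"]))
        if bool(row.get("pooled", False)):
            call.sex_call = "ambiguous"
        out.append(call)
    return out


def chrom_distributions(
    calls: pd.DataFrame,
    chrom_groups: dict[str, list[str] | None] | None = None,
) -> dict[str, dict]:
    """Per-group per-site methylation histograms (10-point bins) and means.

    The default grouping is autosomes (everything but chrX/chrY) versus chrX.
    A group with zero covered sites is flagged with n_sites = 0 and NaN mean.
    """
    if chrom_groups is None:
        chrom_groups = {"autosomes": None, "chrX": ["chrX"]}
    out = {}
    for name, chroms in chrom_groups.items():
        if chroms is None:
            sub = calls[~calls["chrom"].isin(SEX_CHROMS)]
        else:
            sub = calls[calls["chrom"].isin(chroms)]
        summ = _calls.summarize(sub, sample=name)
        if summ.n_sites == 0:
            log.warning("chrom_distributions: group %s has zero covered sites", name)
        out[name] = {"n_sites": summ.n_sites, "mean": summ.mean_meth,
                     "hist": summ.hist}
    return out


def x_female_male_ratio(calls_female: pd.DataFrame, calls_male: pd.DataFrame) -> float:
    """Female-to-male ratio of mean X-chromosome methylation (paired samples)."""
    f = chrom_distributions(calls_female)["chrX"]["mean"]
    m = chrom_distributions(calls_male)["chrX"]["mean"]
    return float(f / m)


def allele_compare(
    calls_maternal: pd.DataFrame,
    calls_paternal: pd.DataFrame,
    chroms: list[str] | None = None,
    min_cov: int = 5,
) -> dict:
    """Per-allele methylation distributions and mean(paternal) - mean(maternal).

    Each allele table is filtered at ``min_cov`` independently, then restricted
    to the shared site set so both alleles are measured at the same CpGs.
    The X chromosome is typically analysed separately from the autosomes
    (pass ``chroms=['chrX']``) because of its coverage asymmetry across sexes.
    """
    if len(calls_maternal) == 0 or len(calls_paternal) == 0:
        raise ValueError("allele_compare: empty allele table")
    mat = _calls.filter_coverage(calls_maternal, min_cov)
    pat = _calls.filter_coverage(calls_paternal, min_cov)
    if chroms is not None:
        mat = mat[mat["chrom"].isin(chroms)]
        pat = pat[pat["chrom"].isin(chroms)]
    m = mat[["chrom", "pos", "n_meth", "n_unmeth"]].merge(
        pat[["chrom", "pos", "n_meth", "n_unmeth"]],
        on=["chrom", "pos"], suffixes=("_mat", "_pat"),
    )
    if len(m) == 0:
        raise ValueError("allele_compare: no shared sites after filtering")
    frac_m = m["n_meth_mat"] / (m["n_meth_mat"] + m["n_unmeth_mat"])
    frac_p = m["n_meth_pat"] / (m["n_meth_pat"] + m["n_unmeth_pat"])
    return {
        "n_sites": int(len(m)),
        "mean_maternal": float(frac_m.mean()),
        "mean_paternal": float(frac_p.mean()),
        "mean_difference": float(frac_p.mean() - frac_m.mean()),
        "hist_maternal": np.histogram(frac_m * 100, bins=10, range=(0, 100))[0],
        "hist_paternal": np.histogram(frac_p * 100, bins=10, range=(0, 100))[0],
    }


def classify_gene_activity(
    expression: dict[str, float],
    active_gt: float = 5.0,
    inactive_le: float = 1.0,
) -> dict[str, str]:
    """Active (TPM > 5) / inactive (TPM <= 1) gene classes; the gap in between is excluded."""
    out = {}
    for gene, tpm in expression.items():
        if tpm < 0:
            raise ValueError(f"negative TPM for {gene}")
        if tpm > active_gt:
            out[gene] = "active"
        elif tpm <= inactive_le:
            out[gene] = "inactive"
    return out


def gene_region_methylation(
    calls: pd.DataFrame,
    regions: pd.DataFrame,
    min_cov: int = 3,
) -> pd.DataFrame:
    """Pooled-count methylation percentage per region (gene body, promoter, ...).

    Sites are filtered at ``min_cov`` reads first; a region with no surviving
    CpG gets a missing value.  ``regions`` is BED-like (chrom/start/end/name).
    """
    filt = _calls.filter_coverage(calls, min_cov)
    filt = filt.sort_values(["chrom", "pos"]).reset_index(drop=True)
    by_chrom = {c: g for c, g in filt.groupby("chrom", sort=False)}
    rows = []
    for r in regions.itertuples(index=False):
        grp = by_chrom.get(r.chrom)
        n_cpg, pct = 0, np.nan
        if grp is not None:
            pos = grp["pos"].to_numpy()
            i0, i1 = np.searchsorted(pos, [r.start + 1, r.end + 1])
            if i1 > i0:
                mm = int(grp["n_meth"].to_numpy()[i0:i1].sum())
                uu = int(grp["n_unmeth"].to_numpy()[i0:i1].sum())
                n_cpg = i1 - i0
                pct = 100.0 * mm / (mm + uu)
        rows.append((getattr(r, "name", "."), r.chrom, n_cpg, pct))
    return pd.DataFrame(rows, columns=["name", "chrom", "n_cpg", "meth_pct"])


def escapee_methylation(
    gene_meth: pd.DataFrame,
    escape_list: list[str],
    expression: dict[str, float],
    fpkm_gt: float = 1.0,
) -> pd.DataFrame:
    """Per-allele methylation of expressed X genes grouped escapee vs subject-to-XCI.

    ``gene_meth`` needs columns name, allele, meth_pct (one row per gene x
    allele).  Only genes with FPKM above ``fpkm_gt`` enter; escape/subject
    labels come from the supplied published list.  Labels for unknown genes are
    skipped with a warning; an empty escape list yields a single 'subject'
    group with a warning.
    """
    known = set(gene_meth["name"])
    unknown = [g for g in escape_list if g not in known]
    if unknown:
        log.warning("escapee_methylation: %d escape label(s) for unknown genes skipped",
                    len(unknown))
    if not escape_list:
        log.warning("escapee_methylation: empty escape list; all genes grouped as subject")
    escape = set(escape_list) & known
    expressed = {g for g, v in expression.items() if v > fpkm_gt}
    sub = gene_meth[gene_meth["name"].isin(expressed)].copy()
    sub["category"] = np.where(sub["name"].isin(escape), "escapee", "subject")
    return (
        sub.groupby(["category", "allele"], as_index=False)
        .agg(mean_meth_pct=("meth_pct", "mean"), n_genes=("name", "nunique"))
    )


def xa_ratio(
    expression: dict[str, float],
    gene_chrom: dict[str, str],
    tpm_ge: float = 1.0,
    x_chrom: str = "chrX",
) -> float:
    """median(X-linked TPM) / median(autosomal TPM) over genes with TPM >= tpm_ge."""
    x_vals, a_vals = [], []
    for gene, tpm in expression.items():
        if tpm < tpm_ge:
            continue
        chrom = gene_chrom.get(gene)
        if chrom is None or chrom == "chrY":
            continue
        (x_vals if chrom == x_chrom else a_vals).append(tpm)
    if not x_vals:
        raise ValueError("xa_ratio: no X-linked genes pass the expression filter")
    if not a_vals:
        raise ValueError("xa_ratio: no autosomal genes pass the expression filter")
    return float(np.median(x_vals) / np.median(a_vals))
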