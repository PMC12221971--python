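"""Synthetic methylome generator with a fully known planted-feature truth ledger.

The generator stands in for a deep-sequencing developmental methylome study:
it builds a toy genome (geometric inter-CpG gaps, densified CpG-island blocks,
uniformly placed genes with 1 kb promoters, a pseudo-Y gene set), plants
features with exact intervals and per-sample effects -- gamete DMRs with
transient / lineage-specific / life-long fates, partially methylated domains,
an inactive-X hypomethylation block with escape-gene holes, hypomethylated
CGIs -- and then samples per-CpG bisulfite calls per sample:

    latent p ~ Beta centred on the regional target (feature override, else the
               sample's bulk level; CGIs forced low), concentration
               ``beta_dispersion``
    p'       = p + (1 - p) * conversion_error   (non-conversion folded in)
    coverage ~ Poisson(coverage_mean), split equally across two alleles in
               diploid samples
    n_meth   ~ Binomial(coverage, p'); counts split across strands ~ Binomial

Diploid embryo/adult samples see retained gamete DMRs as the balanced mixture
of the two parental allele effects (~mid-level methylation, the diploid
signature of an imprint).  Female samples carry a hypomethylated paternal
(inactive) X; allele-labelled tables are emitted separately.  Everything is
driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import calls as _calls

log = logging.getLogger("methdev.simulate")

DEFAULT_SEED = 1729
TRUTH_VERSION = "methdev-truth v1"

GAMETE_SAMPLES = ("sperm", "oocyte")
# stages at which a DMR keeps its one-allele mark, per fate
FATE_STAGES = {
    "transient_embryonic": ("E3.5",),
    "ED_retained": ("E3.5", "E7.5_ED"),
    "TE_retained": ("E3.5", "E7.5_TE"),
    "lifelong": ("E3.5", "E7.5_ED", "E7.5_TE", "brain", "liver", "spleen"),
}


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class GenomeSpec:
    """Toy genome layout: chromosome sizes, CpG spacing, CGI/gene placement."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 3_000_000, "chr2": 1_500_000, "chrX": 400_000, "chrY": 60_000,
        }
    )
    cpg_spacing_mean: float = 100.0
    cgi_count: int = 150
    cgi_length_bp: int = 600
    cgi_density_factor: float = 10.0  # CGI CpG spacing = spacing_mean / factor
    gene_count: int = 80
    gene_length_bp: int = 8_000
    promoter_bp: int = 1_000
    pseudo_y_genes: int = 19
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must not be empty")
        for chrom, length in self.chrom_lengths.items():
            if length < 2 * self.cgi_length_bp:
                raise ValueError(
                    f"chromosome {chrom} ({length} bp) shorter than "
                    f"2 x cgi_length_bp ({2 * self.cgi_length_bp} bp)"
                )
        if self.cpg_spacing_mean < 2:
            raise ValueError("cpg_spacing_mean must be >= 2")
        if self.cgi_count and self.cgi_density_factor < 5:
            raise ValueError("CGI CpG density must be >= 5x background")

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chrom_lengths if c not in ("chrX", "chrY")]


@dataclass(frozen=True)
class SampleSpec:
    """One library/condition: bulk methylation target, depth, dispersion, sex."""

    name: str
    global_meth_mean: float
    coverage_mean: float = 10.0
    beta_dispersion: float = 50.0
    sex: str = "pooled"  # male | female | pooled
    conversion_error: float = 0.005

    def validate(self) -> None:
        if not 0.0 <= self.global_meth_mean <= 1.0:
            raise ValueError(f"{self.name}: global_meth_mean outside [0, 1]")
        if self.coverage_mean <= 0:
            raise ValueError(f"{self.name}: coverage_mean must be positive")
        if not 0.0 <= self.conversion_error < 0.05:
            raise ValueError(f"{self.name}: conversion_error outside [0, 0.05)")
        if self.sex not in ("male", "female", "pooled"):
            raise ValueError(f"{self.name}: unknown sex {self.sex!r}")


@dataclass
class PlantedFeature:
    kind: str          # gamete_dmr | pmd | xi_block | cgi
    chrom: str
    start: int         # 0-based half-open
    end: int
    origin: str = "none"      # maternal | paternal | none
    fate: str = "none"        # transient_embryonic | ED_retained | TE_retained | lifelong | none
    effect: dict = field(default_factory=dict)
    stages: tuple[str, ...] = ()


@dataclass
class SimTruth:
    """The planted-feature ledger every downstream stage is validated against."""

    features: list[PlantedFeature]
    sample_sexes: dict[str, str]
    xy_read_counts: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    escape_genes: list[str] = field(default_factory=list)
    seed: int = DEFAULT_SEED

    def features_frame(self) -> pd.DataFrame:
        rows = [
            (f.kind, f.chrom, f.start, f.end, f.origin, f.fate,
             json.dumps(f.effect, sort_keys=True), ",".join(f.stages))
            for f in self.features
        ]
        return pd.DataFrame(rows, columns=["kind", "chrom", "start", "end",
                                           "origin", "fate", "effect", "stages"])

    def features_of(self, kind: str) -> list[PlantedFeature]:
        return [f for f in self.features if f.kind == kind]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#{TRUTH_VERSION}\n#seed\t{self.seed}\n")
            fh.write("#sample_sexes\t" + json.dumps(self.sample_sexes, sort_keys=True) + "\n")
            fh.write("#escape_genes\t" + ",".join(self.escape_genes) + "\n")
            self.features_frame().to_csv(fh, sep="\t", index=False)


@dataclass
class SampleCalls:
    """Simulated calls for one sample: stranded table plus allele-labelled tables."""

    name: str
    sex: str
    calls: pd.DataFrame
    allele_calls: dict[str, pd.DataFrame] | None = None


# ---------------------------------------------------------------------------
# genome


def _geometric_positions(rng: np.random.Generator, lo: int, hi: int,
                         spacing_mean: float) -> np.ndarray:
    """1-based positions in [lo, hi] with gaps 1 + Geometric (mean spacing, min gap 2)."""
    if hi < lo:
        return np.empty(0, dtype=np.int64)
    mean_gap = max(spacing_mean - 1.0, 1.0)
    out = []
    pos = lo - 1
    span = hi - lo + 1
    while pos < hi:
        n = max(int(1.3 * span / spacing_mean) + 16, 16)
        gaps = 1 + rng.geometric(1.0 / mean_gap, size=n)
        steps = pos + np.cumsum(gaps)
        out.append(steps[steps <= hi])
        pos = int(steps[-1])
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def _place_nonoverlapping(rng: np.random.Generator, chrom: str, chrom_len: int,
                          n: int, lengths, occupied: list[tuple[int, int]],
                          max_tries: int | None = None) -> list[tuple[int, int]]:
    """Uniform non-overlapping intervals (0-based half-open); error when saturated."""
    lengths = np.broadcast_to(np.asarray(lengths, dtype=np.int64), (n,))
    placed: list[tuple[int, int]] = []
    taken = list(occupied)
    tries = 0
    budget = max_tries if max_tries is not None else 200 * max(n, 1)
    for L in lengths:
        L = int(L)
        if L >= chrom_len - 2:
            raise ValueError(f"cannot place a {L} bp feature on {chrom} ({chrom_len} bp)")
        while True:
            tries += 1
            if tries > budget:
                raise ValueError(
                    f"cannot place all features without overlap: chromosome {chrom} saturated"
                )
            s = int(rng.integers(1, chrom_len - L - 1))
            e = s + L
            if all(e <= a or s >= b for a, b in taken):
                placed.append((s, e))
                taken.append((s, e))
                break
    return placed


def simulate_genome(
    spec: GenomeSpec,
    cgi_exclude: dict[str, list[tuple[int, int]]] | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, pd.DataFrame]]:
    """Generate CpG positions and toy annotations (genes, promoters, CGIs, pseudo-Y).

    CpG positions are 1-based plus-strand C coordinates, strictly increasing,
    within [1, length - 1].  CGI blocks carry >= 5x the background CpG density.
    Promoters are 1 kb upstream of the TSS, strand-aware.  ``cgi_exclude``
    reserves intervals (e.g. future PMDs, which are CGI-poor in real genomes)
    that CGI placement must avoid.
    """
    spec.validate()
    cgi_exclude = cgi_exclude or {}
    rng = np.random.default_rng(spec.seed)
    chroms = list(spec.chrom_lengths)
    non_y = [c for c in chroms if c != "chrY"]
    weights = np.array([spec.chrom_lengths[c] for c in non_y], dtype=float)
    weights /= weights.sum()

    cgi_alloc = rng.multinomial(spec.cgi_count, weights) if spec.cgi_count else np.zeros(len(non_y), int)
    gene_alloc = rng.multinomial(spec.gene_count, weights) if spec.gene_count else np.zeros(len(non_y), int)

    cgi_rows, gene_rows, prom_rows, py_rows = [], [], [], []
    cpg_map: dict[str, np.ndarray] = {}
    for chrom in chroms:
        L = spec.chrom_lengths[chrom]
        cgis: list[tuple[int, int]] = []
        if chrom != "chrY":
            i = non_y.index(chrom)
            cgis = _place_nonoverlapping(rng, chrom, L, int(cgi_alloc[i]),
                                         spec.cgi_length_bp,
                                         list(cgi_exclude.get(chrom, [])))
            for k, (s, e) in enumerate(cgis):
                cgi_rows.append((chrom, s, e, f"cgi_{chrom}_{k:04d}", 0, "+"))
            genes = _place_nonoverlapping(rng, chrom, L, int(gene_alloc[i]),
                                          rng.integers(spec.gene_length_bp // 2,
                                                       spec.gene_length_bp * 3 // 2,
                                                       size=int(gene_alloc[i]))
                                          if gene_alloc[i] else [], [])
            for k, (s, e) in enumerate(genes):
                strand = "+" if rng.random() < 0.5 else "-"
                name = f"gene_{chrom}_{k:04d}"
                gene_rows.append((chrom, s, e, name, 0, strand))
                if strand == "+":
                    ps, pe = max(s - spec.promoter_bp, 0), s
                else:
                    ps, pe = e, min(e + spec.promoter_bp, L)
                if pe > ps:
                    prom_rows.append((chrom, ps, pe, name, 0, strand))
        else:
            py = _place_nonoverlapping(rng, chrom, L, spec.pseudo_y_genes, 1000, [])
            for k, (s, e) in enumerate(py):
                py_rows.append((chrom, s, e, f"ygene_{k:02d}", 0, "+"))

        background = _geometric_positions(rng, 1, L - 1, spec.cpg_spacing_mean)
        dense = [
            _geometric_positions(rng, s + 1, min(e, L - 1),
                                 spec.cpg_spacing_mean / spec.cgi_density_factor)
            for s, e in cgis
        ]
        pos = np.unique(np.concatenate([background, *dense])) if dense else np.unique(background)
        if len(pos) > 1:  # a CpG occupies i, i+1: drop positions 1 bp apart
            pos = pos[np.concatenate([[True], np.diff(pos) >= 2])]
        cpg_map[chrom] = pos.astype(np.int64)

    bedcols = ["chrom", "start", "end", "name", "score", "strand"]
    annotations = {
        "genes": pd.DataFrame(gene_rows, columns=bedcols),
        "promoters": pd.DataFrame(prom_rows, columns=bedcols),
        "cgis": pd.DataFrame(cgi_rows, columns=bedcols),
        "pseudo_y": pd.DataFrame(py_rows, columns=bedcols),
    }
    return cpg_map, annotations


# ---------------------------------------------------------------------------
# planted features


def _allocate_fates(n: int, proportions: dict[str, float],
                    rng: np.random.Generator) -> list[str]:
    """Largest-remainder allocation of n DMRs to fates, in shuffled order."""
    labels = list(proportions)
    weights = np.array([proportions[k] for k in labels], dtype=float)
    weights /= weights.sum()
    counts = np.floor(weights * n).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(weights * n - counts), kind="stable")
    for i in range(rem):
        counts[order[i % len(labels)]] += 1
    out = [lab for lab, c in zip(labels, counts) for _ in range(c)]
    return [out[i] for i in rng.permutation(n)]


def plant_features(
    cpg_map: dict[str, np.ndarray],
    annotations: dict[str, pd.DataFrame],
    dmr_n: int = 50,
    pmd_n: int = 3,
    xi_fraction: float = 1.0,
    *,
    sample_sexes: dict[str, str] | None = None,
    fate_proportions: dict[str, float] | None = None,
    dmr_effect: tuple[float, float] = (0.85, 0.05),
    pmd_level: float = 0.45,
    pmd_length_bp: int = 200_000,
    pmd_stages: tuple[str, ...] = ("E7.5_TE",),
    xi_level: float = 0.35,
    cgi_level: float = 0.08,
    escape_gene_count: int = 2,
    pmd_intervals: list[tuple[str, int, int]] | None = None,
    seed: int = DEFAULT_SEED,
) -> SimTruth:
    """Plant gamete DMRs (``dmr_n`` per parental origin), PMDs, Xi blocks and CGIs.

    Gamete DMRs occupy CpG-island intervals (where real maternal imprints sit
    and where the tile test has CpG density to work with); fates are allocated
    per ``fate_proportions`` (default: equal quarters).  PMDs are placed on the
    largest autosome.  The Xi block covers ``xi_fraction`` of chrX minus the
    bodies of ``escape_gene_count`` X-linked escape genes.  Every feature is
    checked to contain at least one simulated CpG.
    """
    rng = np.random.default_rng(seed)
    hi, lo = dmr_effect
    if fate_proportions is None:
        fate_proportions = {k: 0.25 for k in FATE_STAGES}
    features: list[PlantedFeature] = []

    cgis = annotations["cgis"]
    for row in cgis.itertuples(index=False):
        features.append(PlantedFeature("cgi", row.chrom, int(row.start), int(row.end),
                                       effect={"level": cgi_level}))

    auto_cgis = cgis[~cgis["chrom"].isin(["chrX", "chrY"])].reset_index(drop=True)
    need = 2 * dmr_n
    if need > len(auto_cgis):
        busiest = auto_cgis["chrom"].mode()
        name = busiest.iloc[0] if len(busiest) else "autosomes"
        raise ValueError(
            f"cannot place {need} gamete DMRs without overlap: only {len(auto_cgis)} "
            f"CGI intervals available (chromosome {name} saturated)"
        )
    pick = rng.permutation(len(auto_cgis))[:need]
    fates = _allocate_fates(dmr_n, fate_proportions, rng) + \
        _allocate_fates(dmr_n, fate_proportions, rng)
    for j, idx in enumerate(pick):
        row = auto_cgis.iloc[int(idx)]
        origin = "maternal" if j < dmr_n else "paternal"
        fate = fates[j]
        effect = {"oocyte": hi, "sperm": lo} if origin == "maternal" else {"oocyte": lo, "sperm": hi}
        features.append(PlantedFeature(
            "gamete_dmr", row["chrom"], int(row["start"]), int(row["end"]),
            origin=origin, fate=fate, effect=effect, stages=FATE_STAGES[fate],
        ))

    if pmd_intervals is not None:
        for chrom, s, e in pmd_intervals:
            features.append(PlantedFeature("pmd", chrom, int(s), int(e),
                                           effect={"level": pmd_level}, stages=pmd_stages))
    elif pmd_n:
        autosomes = sorted(
            (c for c in cpg_map if c not in ("chrX", "chrY")),
            key=lambda c: -(cpg_map[c][-1] if len(cpg_map[c]) else 0),
        )
        if not autosomes:
            raise ValueError("cannot place PMDs: no autosome in the genome")
        target = autosomes[0]
        chrom_len = int(cpg_map[target][-1]) + 2 if len(cpg_map[target]) else 0
        for _ in range(50):
            spans = _place_nonoverlapping(rng, target, chrom_len, pmd_n, pmd_length_bp, [])
            if all(_count_cpgs(cpg_map, target, s, e) > 0 for s, e in spans):
                break
        else:
            raise ValueError(f"cannot place PMDs containing CpGs on {target}")
        for s, e in spans:
            features.append(PlantedFeature("pmd", target, s, e,
                                           effect={"level": pmd_level}, stages=pmd_stages))

    escape_genes: list[str] = []
    if xi_fraction > 0 and "chrX" in cpg_map:
        x_len = int(cpg_map["chrX"][-1]) + 2 if len(cpg_map["chrX"]) else 0
        block_end = int(round(x_len * xi_fraction))
        genes = annotations["genes"]
        x_genes = genes[genes["chrom"] == "chrX"].reset_index(drop=True)
        holes: list[tuple[int, int]] = []
        if escape_gene_count and len(x_genes):
            take = rng.permutation(len(x_genes))[:escape_gene_count]
            for idx in sorted(int(i) for i in take):
                g = x_genes.iloc[idx]
                escape_genes.append(g["name"])
                holes.append((int(g["start"]), int(g["end"])))
        holes.sort()
        cursor = 0
        blocks: list[tuple[int, int]] = []
        for hs, he in holes:
            if hs > cursor:
                blocks.append((cursor, min(hs, block_end)))
            cursor = max(cursor, he)
            if cursor >= block_end:
                break
        if cursor < block_end:
            blocks.append((cursor, block_end))
        for s, e in blocks:
            if e > s and _count_cpgs(cpg_map, "chrX", s, e) > 0:
                features.append(PlantedFeature("xi_block", "chrX", s, e,
                                               effect={"level": xi_level}))

    for f in features:
        if _count_cpgs(cpg_map, f.chrom, f.start, f.end) == 0 and f.kind != "cgi":
            raise ValueError(f"planted {f.kind} at {f.chrom}:{f.start}-{f.end} contains no CpG")

    return SimTruth(features=features, sample_sexes=dict(sample_sexes or {}),
                    escape_genes=escape_genes, seed=seed)


def _count_cpgs(cpg_map, chrom, start, end) -> int:
    pos = cpg_map.get(chrom)
    if pos is None or len(pos) == 0:
        return 0
    i0, i1 = np.searchsorted(pos, [start + 1, end + 1])
    return int(i1 - i0)


# ---------------------------------------------------------------------------
# per-sample call sampling


def _apply_interval(target: np.ndarray, pos: np.ndarray, start: int, end: int,
                    level: float) -> None:
    i0, i1 = np.searchsorted(pos, [start + 1, end + 1])
    target[i0:i1] = level


def _allele_targets(cpg_map, truth: SimTruth, sample: SampleSpec,
                    chrom: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-CpG latent methylation targets for the maternal and paternal allele."""
    pos = cpg_map[chrom]
    mat = np.full(len(pos), sample.global_meth_mean)
    pat = mat.copy()
    sex = truth.sample_sexes.get(sample.name, sample.sex)
    for kind in ("pmd", "xi_block", "cgi", "gamete_dmr"):
        for f in truth.features:
            if f.kind != kind or f.chrom != chrom:
                continue
            if kind == "pmd":
                if sample.name in f.stages:
                    _apply_interval(mat, pos, f.start, f.end, f.effect["level"])
                    _apply_interval(pat, pos, f.start, f.end, f.effect["level"])
            elif kind == "xi_block":
                if sex == "female":  # imprinted XCI: the paternal X is silenced
                    _apply_interval(pat, pos, f.start, f.end, f.effect["level"])
            elif kind == "cgi":
                _apply_interval(mat, pos, f.start, f.end, f.effect["level"])
                _apply_interval(pat, pos, f.start, f.end, f.effect["level"])
            else:  # gamete_dmr
                if sample.name in f.effect:  # a gamete: haploid effect on both slots
                    _apply_interval(mat, pos, f.start, f.end, f.effect[sample.name])
                    _apply_interval(pat, pos, f.start, f.end, f.effect[sample.name])
                elif sample.name in f.stages:
                    _apply_interval(mat, pos, f.start, f.end, f.effect["oocyte"])
                    _apply_interval(pat, pos, f.start, f.end, f.effect["sperm"])
    return mat, pat


def _beta_latent(rng: np.random.Generator, target: np.ndarray, k: float) -> np.ndarray:
    p = np.asarray(target, dtype=float).copy()
    mid = (p > 0) & (p < 1)
    if k > 0 and mid.any():
        p[mid] = rng.beta(p[mid] * k, (1.0 - p[mid]) * k)
    return p


def _allele_lambdas(chrom: str, sex: str, sample: SampleSpec) -> tuple[float, float]:
    lam = sample.coverage_mean / 2.0
    haploid = sample.name in GAMETE_SAMPLES
    if haploid:
        return (sample.coverage_mean, 0.0) if chrom != "chrY" or sample.name == "sperm" else (0.0, 0.0)
    if chrom == "chrX":
        if sex == "male":
            return lam, 0.0
        return lam, lam
    if chrom == "chrY":
        if sex == "male":
            return 0.0, lam
        if sex == "pooled":
            return 0.0, lam / 2.0
        return 0.0, 0.0
    return lam, lam


def simulate_sample(
    cpg_map: dict[str, np.ndarray],
    truth: SimTruth,
    sample: SampleSpec,
    seed: int | None = None,
    latent_seed: int | None = None,
) -> SampleCalls:
    """Simulate one sample's stranded call table (plus allele tables when diploid).

    ``latent_seed`` controls the RNG for the latent per-CpG beta draws only;
    two samples simulated with the same targets and latent seed share the same
    latent methylation state while read sampling stays independent -- the null
    condition for type-I-error calibration of the differential tests.
    """
    sample.validate()
    if sample.name not in truth.sample_sexes:
        raise ValueError(f"sample {sample.name!r} not present in truth.sample_sexes")
    sex = truth.sample_sexes[sample.name]
    if seed is None:
        seed = (truth.seed * 100003 + zlib.crc32(sample.name.encode())) % (2**31)
    rng = np.random.default_rng(seed)
    rng_latent = np.random.default_rng(latent_seed if latent_seed is not None
                                       else seed + 2**31)

    frames = []
    allele_frames: dict[str, list[pd.DataFrame]] = {"maternal": [], "paternal": []}
    for chrom in cpg_map:
        pos = cpg_map[chrom]
        if len(pos) == 0:
            continue
        t_mat, t_pat = _allele_targets(cpg_map, truth, sample, chrom)
        p_mat = _beta_latent(rng_latent, t_mat, sample.beta_dispersion)
        p_pat = _beta_latent(rng_latent, t_pat, sample.beta_dispersion)
        eps = sample.conversion_error
        p_mat = p_mat + (1.0 - p_mat) * eps
        p_pat = p_pat + (1.0 - p_pat) * eps

        lam_mat, lam_pat = _allele_lambdas(chrom, sex, sample)
        cov_mat = rng.poisson(lam_mat, size=len(pos)) if lam_mat > 0 else np.zeros(len(pos), np.int64)
        cov_pat = rng.poisson(lam_pat, size=len(pos)) if lam_pat > 0 else np.zeros(len(pos), np.int64)
        m_mat = rng.binomial(cov_mat, p_mat)
        m_pat = rng.binomial(cov_pat, p_pat)

        cov = cov_mat + cov_pat
        meth = m_mat + m_pat
        unmeth = cov - meth
        plus_m = rng.binomial(meth, 0.5)
        plus_u = rng.binomial(unmeth, 0.5)

        plus = pd.DataFrame({
            "chrom": chrom, "pos": pos, "strand": "+",
            "n_meth": plus_m, "n_unmeth": plus_u, "context": "CpG",
        })
        minus = pd.DataFrame({
            "chrom": chrom, "pos": pos + 1, "strand": "-",
            "n_meth": meth - plus_m, "n_unmeth": unmeth - plus_u, "context": "CpG",
        })
        both = pd.concat([plus, minus], ignore_index=True).sort_values(
            ["pos", "strand"], kind="stable"
        )
        frames.append(both)

        if sample.name not in GAMETE_SAMPLES:
            for allele, c, m in (("maternal", cov_mat, m_mat), ("paternal", cov_pat, m_pat)):
                keep = c > 0
                allele_frames[allele].append(pd.DataFrame({
                    "chrom": chrom, "pos": pos[keep], "strand": "+",
                    "n_meth": m[keep], "n_unmeth": (c - m)[keep], "context": "CpG",
                }))

    stranded = _calls._finalize(pd.concat(frames, ignore_index=True), destranded=False)
    allele_calls = None
    if sample.name not in GAMETE_SAMPLES:
        allele_calls = {
            allele: _calls._finalize(pd.concat(lst, ignore_index=True), destranded=True)
            for allele, lst in allele_frames.items()
        }
    return SampleCalls(name=sample.name, sex=sex, calls=stranded, allele_calls=allele_calls)


def simulate_xy_counts(
    truth: SimTruth,
    sample: str,
    seed: int | None = None,
    lambda_x: float = 5_000.0,
    lambda_y: float = 500.0,
    noise_factor: float = 0.01,
    total_reads: int = 1_000_000,
) -> tuple[int, int, int]:
    """X-mapping and pseudo-Y-mapping read counts for one sample.

    Males draw y ~ Poisson(lambda_y); females draw y ~ Poisson(noise_factor x
    lambda_y), modelling mismapping; a sex-mixed pool sits in between.  The
    result is recorded in ``truth.xy_read_counts``.
    """
    sex = truth.sample_sexes[sample]
    if seed is None:
        seed = (truth.seed * 99991 + zlib.crc32(("xy:" + sample).encode())) % (2**31)
    rng = np.random.default_rng(seed)
    if sex == "male":
        lx, ly = lambda_x, lambda_y
    elif sex == "female":
        lx, ly = 2.0 * lambda_x, noise_factor * lambda_y
    else:
        lx, ly = 1.5 * lambda_x, lambda_y / 2.0
    x = int(rng.poisson(lx)) if lx > 0 else 0
    y = int(rng.poisson(ly)) if ly > 0 else 0
    truth.xy_read_counts[sample] = (x, y, total_reads)
    return x, y, total_reads


# ---------------------------------------------------------------------------
# packaged study


@dataclass(frozen=True)
class StudyConfig:
    """The full synthetic study: genome, sample series, planted-feature plan."""

    genome: GenomeSpec = field(default_factory=GenomeSpec)
    samples: tuple[SampleSpec, ...] = ()
    dmr_n: int = 50
    pmd_n: int = 3
    pmd_length_bp: int = 200_000
    xi_fraction: float = 1.0
    fate_proportions: dict[str, float] | None = None
    dmr_effect: tuple[float, float] = (0.85, 0.05)
    pmd_level: float = 0.45
    xi_level: float = 0.35
    cgi_level: float = 0.08
    escape_gene_count: int = 2


def default_samples(coverage_mean: float = 10.0) -> tuple[SampleSpec, ...]:
    """The packaged developmental series: gametes, embryo stages, adult tissues.

    Bulk (non-CGI, non-feature) methylation targets follow the study's stage
    trajectory for gametes, cleavage embryo and adult tissues; the E7.5
    lineages use a hypermethylated bulk so that planted trophectoderm PMDs are
    the only intermediate blocks (see docs/methods.md).
    """
    mk = lambda name, mean, sex: SampleSpec(name, mean, coverage_mean=coverage_mean, sex=sex)
    return (
        mk("sperm", 0.77, "male"),
        mk("oocyte", 0.65, "female"),
        mk("E3.5", 0.63, "pooled"),
        mk("E7.5_ED", 0.75, "pooled"),
        mk("E7.5_TE", 0.75, "pooled"),
        mk("brain", 0.72, "male"),
        mk("liver", 0.69, "male"),
        mk("spleen", 0.55, "male"),
    )


def default_study(coverage_mean: float = 10.0, **overrides) -> StudyConfig:
    return StudyConfig(samples=default_samples(coverage_mean), **overrides)


def demo_study(coverage_mean: float = 8.0) -> StudyConfig:
    """A scaled-down study (1.5 Mb genome) for demos and end-to-end runs."""
    genome = GenomeSpec(
        chrom_lengths={"chr1": 800_000, "chr2": 400_000, "chrX": 200_000, "chrY": 60_000},
        cgi_count=60, gene_count=40,
    )
    return StudyConfig(genome=genome, samples=default_samples(coverage_mean),
                       dmr_n=20, pmd_n=1, pmd_length_bp=120_000)


@dataclass
class StudyResult:
    config: StudyConfig
    cpg_map: dict[str, np.ndarray]
    annotations: dict[str, pd.DataFrame]
    truth: SimTruth
    samples: dict[str, SampleCalls]


def simulate_study(config: StudyConfig | None = None, seed: int = DEFAULT_SEED,
                   outdir=None) -> StudyResult:
    """Run the full generator: genome, truth ledger, one call set per sample.

    With ``outdir`` set, writes cytosine reports, destranded coverage files,
    allele-labelled coverage files, BED annotations, X/pseudo-Y counts and the
    truth ledger; identical (config, seed) pairs produce byte-identical trees.
    """
    if config is None:
        config = default_study()
    if not config.samples:
        raise ValueError("study config lists no samples")
    ss = np.random.SeedSequence(seed)
    subseeds = [int(s.generate_state(1)[0] % (2**31))
                for s in ss.spawn(3 + 2 * len(config.samples))]
    genome = replace(config.genome, seed=subseeds[0])

    # PMDs are CGI-poor in real genomes: reserve their intervals first so CGI
    # placement avoids them, keeping planted domains contiguous for the caller.
    pmd_intervals: list[tuple[str, int, int]] = []
    if config.pmd_n:
        rng_pmd = np.random.default_rng(subseeds[2])
        target = max(genome.autosomes, key=lambda c: genome.chrom_lengths[c])
        spans = _place_nonoverlapping(rng_pmd, target, genome.chrom_lengths[target],
                                      config.pmd_n, config.pmd_length_bp, [])
        pmd_intervals = [(target, s, e) for s, e in spans]
    cgi_exclude: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in pmd_intervals:
        cgi_exclude.setdefault(chrom, []).append((s, e))

    cpg_map, annotations = simulate_genome(genome, cgi_exclude=cgi_exclude)
    sexes = {s.name: s.sex for s in config.samples}
    truth = plant_features(
        cpg_map, annotations,
        dmr_n=config.dmr_n, pmd_n=config.pmd_n, xi_fraction=config.xi_fraction,
        sample_sexes=sexes, fate_proportions=config.fate_proportions,
        dmr_effect=config.dmr_effect, pmd_level=config.pmd_level,
        pmd_length_bp=config.pmd_length_bp, xi_level=config.xi_level,
        cgi_level=config.cgi_level, escape_gene_count=config.escape_gene_count,
        pmd_intervals=pmd_intervals or None,
        seed=subseeds[1],
    )
    samples: dict[str, SampleCalls] = {}
    for i, spec in enumerate(config.samples):
        sc = simulate_sample(cpg_map, truth, spec, seed=subseeds[3 + i])
        simulate_xy_counts(truth, spec.name, seed=subseeds[3 + len(config.samples) + i])
        samples[spec.name] = sc
    log.info("simulate_study: seed=%d, %d samples, %d planted features",
             seed, len(samples), len(truth.features))

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key, tab in annotations.items():
            _calls.write_bed(tab, outdir / f"{key}.bed")
        _calls.write_genes_gtf(annotations["genes"], outdir / "genes.gtf")
        truth.write(outdir / "truth.tsv")
        with open(outdir / "xy_counts.tsv", "w") as fh:
            fh.write("sample\tx_reads\ty_reads\ttotal_reads\tsex\n")
            for name in samples:
                x, y, t = truth.xy_read_counts[name]
                fh.write(f"{name}\t{x}\t{y}\t{t}\t{truth.sample_sexes[name]}\n")
        for name, sc in samples.items():
            _calls.write_cytosine_report(sc.calls, outdir / f"{name}.CpG_report.txt")
            _calls.write_coverage(_calls.destrand(sc.calls), outdir / f"{name}.cov")
            if sc.allele_calls:
                for allele, tab in sc.allele_calls.items():
                    _calls.write_coverage(tab, outdir / f"{name}.{allele}.cov")
    return StudyResult(config=config, cpg_map=cpg_map, annotations=annotations,
                       truth=truth, samples=samples)
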