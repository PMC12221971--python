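# Methods

This note documents the models, defaults and numerical choices behind
`methdev`, and what the synthetic-data validation does and does not show.

## Call-table substrate (`methdev.calls`)

A call table holds one row per cytosine with methylated/unmethylated read
counts. Destranding merges the minus-strand record of a CpG dinucleotide
(position i+1) into the plus-strand record at position i; the destranded
coordinate is always the 1-based plus-strand C, which keeps joins against a
CpG position map trivial. Orphan single-strand records are kept at the
canonical plus coordinate; a minus record at position ≤ 1 has no admissible
partner and is kept in place with a log flag. Destranding and pooling
conserve total counts exactly (integer arithmetic throughout).

Pooling by condition happens before coverage filtering, matching the
processing order low-input studies use to retain maximum read depth. The
per-sample mean methylation is the **unweighted per-site mean** of
n_meth/coverage, not the read-weighted mean; the two differ when coverage
correlates with methylation, and the per-site convention matches the
percentage-matrix semantics of tile/region operations elsewhere in the
package. The choice is configurable in effect: read-weighted means are
recoverable from the same table by pooling counts first. Histogram bins are
10-percentage-point, right-open except the last, so fully methylated sites
land in one bin (the convention that makes bimodal methylome histograms look
bimodal rather than leaking the 100% spike into an 11th bin).

## Tile-based DMR calling (`methdev.dmr`)

Tiles are fixed 100-bp windows laid from coordinate 0, the final partial
window at each chromosome end retained. A tile enters testing with ≥ 1 CpG
and ≥ 3 summed reads in **both** conditions. The test is a two-sided Fisher
exact test on the pooled 2×2 table — the appropriate exact choice for a
two-condition comparison without replicates. The two-sided p sums
hypergeometric point probabilities ≤ that of the observed table; the
comparison uses a 1e-12 **relative** tolerance so that ties produced by
floating-point noise in the pmf are counted as ties (scipy's implementation
uses a much looser 1e-7 gamma, which is why the test is implemented directly
on `scipy.stats.hypergeom`). A zero margin returns p = 1 by convention and is
flagged. Tables are memoized, which makes per-site testing over tens of
thousands of sites cheap because count patterns repeat.

Multiple testing uses Benjamini–Hochberg step-up, chosen over smoothing-based
q-value estimators for exact reproducibility; the method name is recorded in
the output metadata. NaN p-values propagate and are excluded from m. DMR
thresholds default to |difference| ≥ 80 percentage points on pooled
proportions and q < 0.01. The difference sign is condition A − condition B
with A = first argument; under the gamete convention A = sperm, positive
differences are sperm-specific (paternal) and negative oocyte-specific
(maternal) DMRs.

Feature-class annotation assigns one class per DMR with precedence
CGI > promoter > intragenic > intergenic, ≥ 1 bp half-open overlap. When only
gene intervals are available, promoters are defined as 1 kb upstream of the
TSS, strand-aware.

Site-level stability testing (`diff_sites`) applies the same exact test per
shared CpG after a 5× coverage filter and reports the fraction of sites with
q ≥ α (default 0.05) — the "fraction stable" statistic. Because the exact
test is conservative, its type-I error on null data sits below nominal; the
acceptance suite verifies ≤ 6% raw p < 0.05 on a shared-latent null.

Meta-profiles follow scale-regions semantics: interval bodies rescaled to a
fixed bin count (default 20), 1-kb flanks in fixed 50-bp bins, per-bin value
the mean of per-site fractions, minus-strand intervals reversed, and the
profile the NaN-aware cross-interval mean.

## Imprint-fate tracking (`methdev.fate`)

A retained one-allele mark in balanced diploid tissue shows intermediate
methylation; the band is 40–60% **inclusive** on both ends (the permissive
reading of a printed range). Per DMR per stage the methylation percentage is
computed from pooled counts over the DMR's CpGs; a stage with fewer than 3
reads is missing, and any clause a missing stage gates evaluates false rather
than erroring — low-input embryo pools drop out of individual regions
routinely and the classifier must tolerate that. The 3-read minimum reuses
the tile threshold; it is a config field.

Classification precedence: not intermediate at E3.5 → `not_established`;
else intermediate at E7.5 ED **and** all of brain/liver/spleen → `lifelong`;
else intermediate at ED → `ED_retained`; else at TE → `TE_retained`; else
`transient_embryonic`. Labels are a partition by construction. ED/TE
retention is not exclusive — a DMR intermediate in both is labelled by the
precedence order, and both-tissue retention is reported in its own column
(`both_e75_retained`). DMRs on chrX/chrY are excluded by default because
sex-mixed embryo pools confound X methylation; the exclusion list is a
config field. The tracker accepts any BED-like interval frame, not only
tiles produced by the DMR caller.

Nearest-gene assignment minimises the half-open interval gap on the same
chromosome (overlap ⇒ 0); ties break on smaller gene start, then
lexicographic id; a chromosome without genes yields an explicit
no-assignment flag.

## Segmentation and PMDs (`methdev.segment`)

The engine is greedy recursive binary splitting of each chromosome's
per-site methylation sequence: the candidate change point minimising total
within-segment SSE is found by vectorised prefix sums, and the split is
accepted when both children have ≥ minSeg (= 5) CpGs and the Gaussian
log-likelihood gain `n·log(SSE₀/SSE₁)` exceeds `penalty·log(n)`. The penalty
is 6: the extreme-value ceiling of SSE reductions obtainable from pure noise
grows like ~2·log n plus a slowly varying term, so a factor of 6 leaves flat
stretches unsplit across the sequence lengths used here, while genuine level
shifts (≥ 0.1 over ≥ 5 sites at the noise levels of 10× data) carry gains an
order of magnitude above the bar. SSE values are floored at n·1e-10 to keep
the ratio finite on constant sequences. On sequences with ≤ 2 change points
and clear levels the greedy boundaries coincide with exhaustive SSE search;
the acceptance suite asserts this exactly.

Segment means are clustered by a 1-D Gaussian mixture with G chosen in 1..3
by BIC (G = 1 scored in closed form), components ranked by mean so class
indices are ordered. Adjacent same-class segments are then joined
(count-weighted mean). Segment bounds run from the first to the last CpG of
the segment plus one, 0-based half-open; an optional `max_gap` parameter
(off by default; 10 kb is a sensible value when enabled) imposes splits at
larger inter-CpG gaps, and joined neighbours never cross such a split.

A PMD candidate is a segment ≥ 100 kb with mean methylation in [0.3, 0.7].
Both thresholds are package decisions (the qualitative definition is "long"
and "intermediate") and are parameters. Note one consequence of the
first-to-last-CpG bounds: a domain whose true extent is exactly 100 kb
yields a segment a few dozen bp shorter and may miss the length cutoff;
domains meaningfully longer than the cutoff are unaffected.

## Chromosome-level analyses (`methdev.chromx`)

Embryo sexing uses pseudo-Y reads per million total (y_cpm) rather than a
raw X:Y ratio, making it invariant to library size. The male/female
threshold τ is estimated per batch as the midpoint of the largest gap in the
sorted y_cpm values when ≥ 4 samples are available (the statistic is
strongly bimodal), else a fixed default; calls inside a guard band
(default ±20%) are ambiguous, and sex-mixed pools are always flagged
ambiguous, never classified.

Allele-specific comparison filters each allele table at 5× independently,
restricts to the shared site set, and reports per-allele distributions and
mean(paternal) − mean(maternal). The X is analysed separately from autosomes
because male samples carry no paternal X coverage. With imprinted X
inactivation the paternal allele is the inactive X; planting Xi at 0.35
against a 0.70 background yields a female X mean near the allele midpoint
(≈ 0.52) and a female/male X ratio near 0.75 — deepening the Xi effect
toward 0 drives the ratio toward one half.

Expression-linked operations follow the standard thresholds: oocyte gene
classes active (TPM > 5) / inactive (TPM ≤ 1) with the gap excluded;
escape-gene analysis keeps genes with FPKM > 1 and takes escape/subject
labels as input (they come from published work, not from this package); the
X/A ratio is median X-linked TPM over median autosomal TPM among genes with
TPM ≥ 1, invariant to global rescaling.

## Synthetic-methylome generator (`methdev.simulate`)

**Genome.** Inter-CpG gaps are 1 + Geometric (memoryless, minimum gap 2 so
CpGs cannot overlap), mean spacing 100 bp. CGIs are dense blocks (10× the
background CpG density, 600 bp) placed uniformly without overlap; genes are
uniform intervals with 1-kb strand-aware promoters; a 19-gene pseudo-Y set
sits on chrY. Real dinucleotide structure is not modelled.

**Sampling model.** Per CpG and allele, a latent methylation level p is drawn
from a Beta centred on the regional target with concentration
`beta_dispersion` (default 50 — per-site latent s.d. ≈ 0.06 at p = 0.7,
a plausible biological-noise scale); bisulfite non-conversion is folded into
the success probability as p′ = p + (1−p)·ε with ε = 0.005; coverage is
Poisson (split equally over two alleles in diploid samples); methylated
counts are Binomial(coverage, p′) and counts split across strands
Binomial(·, ½). Gametes are haploid. Males carry one X at half autosomal
depth; pooled samples get a diploid X without an Xi effect (mirroring why
sex-mixed pools preclude X analysis). A `latent_seed` lets two samples share
the same latent state with independent read sampling — the proper null for
type-I-error calibration of the count tests.

**Planted features.** Gamete DMRs occupy CGI intervals (where maternal
imprints sit in real genomes, and where tiles have the CpG density the count
test needs), 0.85 vs 0.05 between the methylated and unmethylated gamete;
fates are allocated by largest-remainder from configurable proportions, and
each fate defines the stages at which the one-allele mark persists — embryo
and adult samples then see the balanced mixture of the two parental allele
effects (≈ 45%) at retained stages and revert to the CGI-low level
elsewhere. Effect precedence per site is pmd < xi_block < cgi < gamete_dmr:
CGIs stay hypomethylated on both alleles inside Xi blocks (the generator
does not model the real Xi-vs-Xa CGI contrast), and DMR effects override the
CGI baseline. PMD intervals are reserved **before** CGI placement (PMDs are
CGI-poor, gene-poor domains in real genomes), which keeps planted domains
contiguous for the segmentation contract. The Xi block covers a configurable
fraction of chrX minus escape-gene bodies, at level 0.35 on the paternal
allele of female samples.

**Stage trajectory.** Bulk (non-CGI, non-feature) targets: sperm 0.77,
oocyte 0.65, E3.5 0.63, brain 0.72, liver 0.69, spleen 0.55 — the printed
developmental series. The E7.5 ED/TE bulk is set to 0.75 rather than the
genome-wide 63%/47% figures: those are mixtures over CGIs and (for TE) PMDs,
and the PMD flag band [0.3, 0.7] is only meaningful when the non-PMD
background sits above it. The observed genome-wide means of simulated
samples accordingly run below the bulk targets by the CGI/PMD pull (e.g.
sperm ≈ 70% with 15% of sites in CGIs).

**Determinism.** A single integer seed drives everything through
`numpy.random.SeedSequence` spawning; identical (config, seed) pairs write
byte-identical file trees. The truth ledger (`truth.tsv`, versioned header)
records every planted interval, per-sample effects and sample sexes; call
files stay strictly in the Bismark dialects.

## What the validation shows — and does not

Passing the planted-truth suite shows the *pipeline* recovers known signals
at realistic depths (10×) and calibrates correctly on nulls. It does not
certify performance on real data, where the generator omits: sequence-driven
CpG density structure, mapping artefacts and coverage biases, non-CpG
contexts beyond a constant background, replicate-level biological variation
(the gamete comparison is deliberately unreplicated), partial bisulfite
conversion heterogeneity, and chromosome-scale features such as repeats.
Feature counts observed in deep whole-genome datasets are properties of real
data and are **not** simulation targets; the synthetic studies use tens to
hundreds of planted features at desk scale (≈ 1.5–5 Mb genomes, 8–20×
depth), sizes chosen so the full suite runs in seconds while leaving every
statistical contract testable.
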