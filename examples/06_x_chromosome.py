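"""X-chromosome analyses: embryo sexing, Xi hypomethylation, X/A expression.

Sexing uses pseudo-Y reads per million with a batch-estimated threshold.
In females the paternal X is imprinted-inactive and globally hypomethylated,
so the female X mean runs near the midpoint of the two alleles while male X
matches the autosomes.
"""

import numpy as np
import pandas as pd

from methdev import calls, chromx, simulate as sim

# A male/female adult pair on a CGI-free genome with the inactive X at 0.35
genome = sim.GenomeSpec(
    chrom_lengths={"chr1": 1_000_000, "chrX": 600_000, "chrY": 60_000},
    cgi_count=0, gene_count=40, seed=99,
)
cpg, ann = sim.simulate_genome(genome)
truth = sim.plant_features(cpg, ann, dmr_n=0, pmd_n=0, xi_fraction=1.0,
                           xi_level=0.35, escape_gene_count=0,
                           sample_sexes={"brain_f": "female", "brain_m": "male"},
                           seed=99)
female = sim.simulate_sample(cpg, truth, sim.SampleSpec("brain_f", 0.70, 20.0, sex="female"))
male = sim.simulate_sample(cpg, truth, sim.SampleSpec("brain_m", 0.70, 20.0, sex="male"))

fd = calls.filter_coverage(calls.destrand(female.calls), 5)
md = calls.filter_coverage(calls.destrand(male.calls), 5)
for label, d in (("female", chromx.chrom_distributions(fd)),
                 ("male", chromx.chrom_distributions(md))):
    print(f"{label}: autosome mean {d['autosomes']['mean']:.3f}, "
          f"chrX mean {d['chrX']['mean']:.3f}")
print(f"female/male X ratio: {chromx.x_female_male_ratio(fd, md):.3f} "
      "(midpoint mixture of Xa=0.70 and Xi=0.35 alleles)")

comp = chromx.allele_compare(female.allele_calls["maternal"],
                             female.allele_calls["paternal"], chroms=["chrX"])
print(f"paternal - maternal X methylation: {comp['mean_difference']:.3f} "
      f"over {comp['n_sites']} shared sites")

# Sexing a batch from X/pseudo-Y read counts
rows = []
for i, (name, sex) in enumerate(truth.sample_sexes.items()):
    x, y, t = sim.simulate_xy_counts(truth, name, seed=200 + i)
    rows.append({"sample": name, "x_reads": x, "y_reads": y, "total_reads": t})
for call in chromx.infer_sex_batch(pd.DataFrame(rows), tau_cpm=100.0):
    print(f"sex call for {call.sample}: {call.sex_call} (y_cpm={call.y_cpm:.1f})")

# X/A expression ratio: median X TPM over median autosomal TPM
rng = np.random.default_rng(1)
expr = {f"a{i}": float(v) for i, v in enumerate(rng.lognormal(2, 1, 300))}
expr |= {f"x{i}": float(v) for i, v in enumerate(0.8 * rng.lognormal(2, 1, 100))}
chrom_map = {g: ("chrX" if g.startswith("x") else "chr1") for g in expr}
print(f"X/A ratio with a planted 20% X down-shift: "
      f"{chromx.xa_ratio(expr, chrom_map):.3f}")
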