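"""Generate a synthetic developmental methylome study with known planted truth.

Builds the packaged demo genome (1.5 Mb over chr1/chr2/chrX/chrY), plants
gamete DMRs with allocated fates, a trophectoderm PMD and an inactive-X block,
then simulates bisulfite calls for gametes, embryo stages and adult tissues.
"""

from pathlib import Path

from methdev import simulate as sim

outdir = Path("scratch/demo_study")
res = sim.simulate_study(sim.demo_study(), seed=1729, outdir=outdir)

print(f"wrote {len(list(outdir.iterdir()))} files to {outdir}/")
print(f"CpG sites per chromosome: {({c: len(p) for c, p in res.cpg_map.items()})}")
for kind in ("gamete_dmr", "pmd", "xi_block", "cgi"):
    print(f"planted {kind:>10}: {len(res.truth.features_of(kind))}")
print(f"samples: {', '.join(res.samples)}")
# Every planted interval is recorded in truth.tsv; downstream examples
# validate the analysis stages against this ledger.
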