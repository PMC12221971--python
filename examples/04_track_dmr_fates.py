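"""Track gamete DMRs through development and flag candidate imprinted loci.

A retained one-allele mark shows intermediate (40-60%) methylation in diploid
tissue.  DMRs intermediate at E3.5 and then at E7.5 embryonic disc plus all
three adult tissues are life-long -- candidate imprints -- and get a nearest
gene; others are transient or lineage-specific.
"""

import pandas as pd

from methdev import calls, fate, simulate as sim

res = sim.simulate_study(sim.demo_study(), seed=1729)
planted = res.truth.features_of("gamete_dmr")
dmrs = pd.DataFrame([(f.chrom, f.start, f.end, f.origin) for f in planted],
                    columns=["chrom", "start", "end", "origin"])

stage_names = ["E3.5", "E7.5_ED", "E7.5_TE", "brain", "liver", "spleen"]
config = fate.FateConfig(
    stages={n: calls.destrand(res.samples[n].calls) for n in stage_names}
)
records = fate.track_fates(dmrs, config, genes=res.annotations["genes"])
report = fate.fate_report(records)

print("fate counts by parental origin:")
for f, by_origin in sorted(report["counts"].items()):
    print(f"  {f:>20}: {by_origin}")
print(f"maternal share of life-long DMRs: {report['lifelong_maternal_fraction']}")
lifelong = records[records["fate"] == "lifelong"]
print("life-long DMRs and their nearest genes (candidate imprinted loci):")
print(lifelong[["chrom", "start", "end", "origin", "nearest_gene", "distance_bp"]]
      .to_string(index=False))
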