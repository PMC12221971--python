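"""Call sperm/oocyte DMRs with 100-bp tiles, Fisher exact test and BH FDR.

A tile enters the test if it holds >= 1 CpG and >= 3 reads in both gametes;
a DMR is a tile with |methylation difference| >= 80 percentage points and
q < 0.01.  Recovery is checked against the generator's planted truth.
"""

from methdev import calls, dmr, simulate as sim

res = sim.simulate_study(sim.demo_study(), seed=1729)
sperm = calls.destrand(res.samples["sperm"].calls)
oocyte = calls.destrand(res.samples["oocyte"].calls)

tiles = dmr.diff_tiles(sperm, oocyte, tile_bp=100, min_reads=3)
called = dmr.call_dmrs(tiles, difference=80, qvalue=0.01,
                       label_a="sperm", label_b="oocyte")
called = dmr.annotate_dmrs(called, res.annotations)

print(f"tested tiles: {len(tiles)};  DMR tiles: {len(called)}")
print(called["label"].value_counts().to_string())
print(called["feature_class"].value_counts().to_string())

planted = res.truth.features_of("gamete_dmr")
hit = sum(((called["chrom"] == f.chrom) & (called["start"] < f.end)
           & (called["end"] > f.start)).any() for f in planted)
print(f"planted DMRs recovered: {hit}/{len(planted)}")
# sperm_specific = paternal origin (sperm-methylated); oocyte_specific =
# maternal.  Planted DMRs sit on CpG islands, hence the CGI feature class.
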