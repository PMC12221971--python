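"""Destrand, pool, filter and summarize per-CpG call tables per stage.

Prints each sample's per-site mean methylation (unweighted over sites at
>= 5x coverage) and the 10-bin methylation histogram -- the bimodal shape
typical of vertebrate methylomes, with a hypomethylated CGI peak at the left.
"""

from methdev import calls, simulate as sim

res = sim.simulate_study(sim.demo_study(), seed=1729)
total_cpgs = sum(len(p) for p in res.cpg_map.values())

print(f"{'sample':>8}  {'sites':>6}  {'mean%':>6}  histogram (0-100% in 10 bins)")
for name, sc in res.samples.items():
    destranded = calls.destrand(sc.calls)           # merge the two strands of each CpG
    filtered = calls.filter_coverage(destranded, 5)  # >= 5 reads, as for real libraries
    s = calls.summarize(filtered, genome_cpg_total=total_cpgs, sample=name)
    bars = " ".join(f"{int(x):>4}" for x in s.hist)
    print(f"{name:>8}  {s.n_sites:>6}  {100 * s.mean_meth:>6.1f}  {bars}")
# The mean tracks each stage's configured bulk level minus the pull of the
# hypomethylated CpG islands; capture fractions are in s.capture.
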