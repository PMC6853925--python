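"""Pooled-heterozygosity (ZHp) sliding-window sweep scan.

Runs the 150 kb / 50%-overlap Hp scan on the sweep fixture, Z-transforms
the windows genome-wide, and shows that the most negative ZHp window
overlaps the injected sweep.
"""

from selsweep import SimParams, SweepParams, simulate_sweep_panel, zhp_scan

panel, truth = simulate_sweep_panel(SimParams(sweep=SweepParams(), seed=0))
table = zhp_scan(panel, "JH")

best = table.loc[table["zhp"].idxmin()]
print(f"{len(table)} retained windows; ZHp range "
      f"[{table['zhp'].min():.2f}, {table['zhp'].max():.2f}]")
print(f"most negative window: {best['contig']}:{int(best['start'])}-{int(best['end'])} "
      f"(Hp {best['hp']:.3f}, ZHp {best['zhp']:.2f}, {int(best['n_snps'])} SNPs)")
print(f"sweep truth interval:  {truth.contig}:{truth.start}-{truth.end}")
overlap = best["start"] < truth.end and best["end"] > truth.start
print("minimum-ZHp window overlaps the sweep:", overlap)
# Low Hp means one allele dominates at most SNPs in the window — the
# footprint a sweep leaves; deeply negative ZHp flags the genome-wide
# extreme tail of that footprint.
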