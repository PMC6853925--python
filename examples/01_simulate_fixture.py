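"""Simulate a two-population panel with a hard sweep and export it.

Builds the default fixture — 12 "JH" + 10 "TB" diploids on a 2 Mb contig,
with 90% of JH haplotypes carrying a shared 150 kb-halo haplotype — and
writes VCF, population map, truth BED, synthetic gene BED and a manifest.
"""

from pathlib import Path

from selsweep import SimParams, SweepParams, export_fixture, simulate_sweep_panel

params = SimParams(sweep=SweepParams(), seed=0)
panel, truth = simulate_sweep_panel(params)
files = export_fixture(panel, truth, Path("scratch/fixture"), params)

print(f"simulated {panel.n_sites} SNPs for {panel.n_samples} samples "
      f"({', '.join(panel.populations)})")
print(f"sweep truth interval: {truth.contig}:{truth.start}-{truth.end} "
      f"in {truth.population} ({len(truth.carrier_haplotypes)}/24 carrier haplotypes)")
print("wrote:", ", ".join(str(p) for p in files.values()))
# The truth interval is the ground-truth target the ZHp and XP-EHH scans
# are expected to recover; everything is deterministic given the seed.
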