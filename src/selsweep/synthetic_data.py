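"""Two-population synthetic genotype panels with an optional hard sweep.

A small forward-in-time Wright–Fisher simulator: founder haplotypes
accumulate mutations (Poisson per genome per generation, finite sites) and
recombine with a single uniform crossover per meiosis, evolving through a
shared burn-in phase and then as two independent populations, which
creates divergence, realistic allele-frequency spectra and linkage
structure.  A hard sweep is injected afterwards by copying one donor
haplotype over a halo interval into a chosen fraction of one population's
haplotypes — a long, high-frequency shared haplotype with locally
depressed heterozygosity, and an exact truth interval for benchmarking
the scans.

Default parameters mirror the study design the scans target: 12 + 10
diploid samples (populations "JH" and "TB"), a 2 Mb contig, sweep carrier
frequency 0.9 and a 150 kb halo.  The per-bp mutation rate is scaled up
(3e-6) so that a desk-sized contig reaches a usable SNP density
(roughly one SNP per kb); this is a deliberate surrogate, not an equine
parameter set.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import write_vcf
from .panel import SITE_COLUMNS, GenotypePanel

log = logging.getLogger(__name__)

_BASES = np.array(["A", "C", "G", "T"])
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class SweepParams:
    core_pos: int = 1_000_000
    carrier_freq: float = 0.9
    halo_bp: int = 150_000
    #: recombination during a sweep truncates the shared haplotype at
    #: increasing distance from the core; each carrier's copied extent per
    #: side is Uniform((1 - taper) * halo, halo).  0 = sharp-edged copy.
    taper_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.carrier_freq <= 1.0:
            raise ValueError("carrier_freq must be in (0, 1]")
        if not 0.0 <= self.taper_fraction <= 1.0:
            raise ValueError("taper_fraction must be in [0, 1]")


@dataclass
class SimParams:
    n_samples: dict[str, int] = field(default_factory=lambda: {"JH": 12, "TB": 10})
    contig: str = "1"
    contig_length: int = 2_000_000
    founder_haplotypes: int = 60
    burn_in_generations: int = 150
    n_generations: int = 100          # per population, after the split
    mutation_rate: float = 3e-6       # per bp per generation (scaled-up surrogate)
    recombination_rate: float = 5e-7  # per bp per generation; one crossover/meiosis at 2 Mb
    missing_rate: float = 0.0
    contaminate: bool = False         # plant filter-failing INFO values on ~2% of sites
    sweep: SweepParams | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.sweep is not None and not 0 <= self.sweep.core_pos < self.contig_length:
            raise ValueError("sweep core_pos outside the contig")


@dataclass
class SimTruth:
    """Ground truth for an injected sweep (0-based half-open interval)."""

    contig: str
    start: int
    end: int
    population: str
    carrier_haplotypes: list[int]


def _one_generation(rng, pops, pos, length, mu, rec):
    """Advance every population one generation on the shared site registry."""
    p_cross = min(1.0, rec * length)
    new_pops = []
    new_cols: dict[int, list[tuple[int, int]]] = {}  # pos -> [(pop_idx, hap_idx)]
    for pi, haps in enumerate(pops):
        n_hap, _ = haps.shape
        p1 = rng.integers(0, n_hap, n_hap)
        p2 = rng.integers(0, n_hap, n_hap)
        cross = rng.random(n_hap) < p_cross
        xpos = rng.integers(1, length, n_hap)
        children = haps[p1].copy()
        for i in np.flatnonzero(cross):
            right = pos >= xpos[i]
            children[i, right] = haps[p2[i], right]
        n_mut = rng.poisson(mu * length * n_hap)
        who = rng.integers(0, n_hap, n_mut)
        where = rng.integers(1, length + 1, n_mut)
        hit = np.searchsorted(pos, where)
        for m in range(n_mut):
            k = hit[m]
            if k < pos.size and pos[k] == where[m]:
                children[who[m], k] ^= 1
            else:
                new_cols.setdefault(int(where[m]), []).append((pi, int(who[m])))
        new_pops.append(children)
    if new_cols:
        add_pos = np.array(sorted(new_cols), dtype=np.int64)
        blocks = []
        for pi, haps in enumerate(new_pops):
            block = np.zeros((haps.shape[0], add_pos.size), dtype=np.int8)
            blocks.append(block)
        for c, p in enumerate(add_pos):
            for pi, hi in new_cols[int(p)]:
                blocks[pi][hi, c] ^= 1
        pos = np.concatenate([pos, add_pos])
        order = np.argsort(pos, kind="mergesort")
        pos = pos[order]
        new_pops = [np.concatenate([h, b], axis=1)[:, order] for h, b in zip(new_pops, blocks)]
    # prune sites lost everywhere or fixed everywhere
    total = sum(int(h.shape[0]) for h in new_pops)
    counts = sum(h.sum(axis=0, dtype=np.int64) for h in new_pops)
    keep = (counts > 0) & (counts < total)
    return [h[:, keep] for h in new_pops], pos[keep]


def simulate_neutral_panel(params: SimParams | None = None) -> GenotypePanel:
    """Forward-simulate a neutral two-population phased diploid panel.

    A single founder population evolves for ``burn_in_generations``; its
    final haplotype pool seeds each population (2 * n_samples haplotypes,
    drawn with replacement — a founder bottleneck), which then evolve
    independently for ``n_generations``.  Site INFO metrics (QUAL, QD,
    MQ, FS) are synthesized in hard-filter-passing ranges unless
    ``contaminate`` plants failing values on a small fraction of sites.
    """
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)
    length, mu, rec = params.contig_length, params.mutation_rate, params.recombination_rate

    pops = [np.zeros((params.founder_haplotypes, 0), dtype=np.int8)]
    pos = np.empty(0, dtype=np.int64)
    for _ in range(params.burn_in_generations):
        pops, pos = _one_generation(rng, pops, pos, length, mu, rec)

    founder = pops[0]
    pop_names = list(params.n_samples)
    pops = [
        founder[rng.integers(0, founder.shape[0], 2 * params.n_samples[p])].copy()
        for p in pop_names
    ]
    for _ in range(params.n_generations):
        pops, pos = _one_generation(rng, pops, pos, length, mu, rec)

    if pos.size == 0:
        raise ValueError(
            "simulation produced zero segregating sites; increase "
            "mutation_rate or the number of generations"
        )

    haplotypes = np.concatenate(pops, axis=0)
    genotypes = (haplotypes[0::2] + haplotypes[1::2]).astype(np.int8)
    n_sites = pos.size

    ref = _BASES[rng.integers(0, 4, n_sites)]
    alt = np.array(
        [
            _TRANSITION[r] if rng.random() < 2.0 / 3.0
            else _TRANSVERSIONS[r][rng.integers(0, 2)]
            for r in ref
        ]
    )
    qual = np.round(rng.uniform(50, 900, n_sites), 1)
    qd = np.round(rng.uniform(15, 35, n_sites), 1)
    mq = np.round(rng.uniform(50, 60, n_sites), 1)
    fs = np.round(rng.uniform(0, 20, n_sites), 1)
    if params.contaminate:
        bad = rng.random(n_sites) < 0.02
        which = rng.integers(0, 4, n_sites)
        qual[bad & (which == 0)] = np.round(rng.uniform(1, 29, int((bad & (which == 0)).sum())), 1)
        qd[bad & (which == 1)] = np.round(rng.uniform(0.1, 4.9, int((bad & (which == 1)).sum())), 1)
        mq[bad & (which == 2)] = np.round(rng.uniform(10, 39, int((bad & (which == 2)).sum())), 1)
        fs[bad & (which == 3)] = np.round(rng.uniform(201, 400, int((bad & (which == 3)).sum())), 1)

    if params.missing_rate > 0:
        miss = rng.random(genotypes.shape) < params.missing_rate
        genotypes[miss] = -1
        haplotypes[0::2][miss] = -1
        haplotypes[1::2][miss] = -1

    sites = pd.DataFrame(
        {
            "contig": params.contig, "pos": pos,  # registry is 1-based
            "ref": ref, "alt": alt, "qual": qual, "qd": qd, "mq": mq, "fs": fs,
        },
        columns=SITE_COLUMNS,
    )
    sample_ids = [f"{p}_{i:02d}" for p in pop_names for i in range(params.n_samples[p])]
    panel = GenotypePanel(
        sites=sites,
        genotypes=genotypes,
        sample_ids=sample_ids,
        pop_map={s: s.split("_")[0] for s in sample_ids},
        contig_lengths={params.contig: length},
        haplotypes=haplotypes,
    )
    panel.validate()
    return panel


def inject_sweep(
    panel: GenotypePanel,
    population: str,
    sweep: SweepParams,
    seed: int = 0,
) -> tuple[GenotypePanel, SimTruth]:
    """Copy one donor haplotype over the sweep halo into carrier haplotypes.

    A fraction ``carrier_freq`` of the population's haplotypes (seeded
    choice; the donor is always a carrier) receives the donor's alleles
    around ``core_pos``.  Each carrier's copied extent per side is drawn
    Uniform((1 - taper_fraction) * halo, halo), emulating the truncation
    of the swept haplotype by recombination at increasing distance from
    the core; with ``taper_fraction`` 0 every carrier gets the full
    ``[core_pos - halo, core_pos + halo)`` block.  The truth interval is
    the full halo, clipped to the contig.
    """
    if not panel.phased:
        raise ValueError("sweep injection needs a phased panel")
    rng = np.random.default_rng(seed)
    contig = panel.sites["contig"].iloc[0]
    length = panel.contig_lengths[contig]
    start = max(0, sweep.core_pos - sweep.halo_bp)
    end = min(length, sweep.core_pos + sweep.halo_bp)
    if start > sweep.core_pos - sweep.halo_bp or end < sweep.core_pos + sweep.halo_bp:
        log.info("sweep halo clipped to contig: [%d, %d)", start, end)

    rows = panel.haplotype_indices(population)
    n_carriers = max(1, int(round(sweep.carrier_freq * rows.size)))
    carriers = rng.choice(rows, size=n_carriers, replace=False)
    donor = carriers[0]

    pos0 = panel.sites["pos"].to_numpy() - 1
    on_contig = panel.sites["contig"].to_numpy() == contig
    out = panel.take_sites(np.ones(panel.n_sites, dtype=bool))
    lo = sweep.halo_bp * (1.0 - sweep.taper_fraction)
    for c in carriers:
        ext_l = sweep.halo_bp if c == donor else rng.uniform(lo, sweep.halo_bp)
        ext_r = sweep.halo_bp if c == donor else rng.uniform(lo, sweep.halo_bp)
        c_start = max(start, sweep.core_pos - ext_l)
        c_end = min(end, sweep.core_pos + ext_r)
        cols = np.flatnonzero(on_contig & (pos0 >= c_start) & (pos0 < c_end))
        out.haplotypes[c, cols] = panel.haplotypes[donor, cols]
    out.genotypes = np.where(
        (out.haplotypes[0::2] == -1) | (out.haplotypes[1::2] == -1),
        -1,
        out.haplotypes[0::2] + out.haplotypes[1::2],
    ).astype(np.int8)
    out.validate()
    truth = SimTruth(
        contig=contig, start=int(start), end=int(end),
        population=population, carrier_haplotypes=sorted(int(c) for c in carriers),
    )
    return out, truth


def simulate_sweep_panel(params: SimParams | None = None) -> tuple[GenotypePanel, SimTruth]:
    """Neutral panel plus an injected sweep (default fixture conditions)."""
    params = params or SimParams(sweep=SweepParams())
    if params.sweep is None:
        raise ValueError("params.sweep must be set")
    panel = simulate_neutral_panel(params)
    sweep_pop = next(iter(params.n_samples))
    return inject_sweep(panel, sweep_pop, params.sweep, seed=(params.seed + 1) % 2**31)


def export_fixture(
    panel: GenotypePanel,
    truth: SimTruth | None,
    out_dir: str | Path,
    params: SimParams | None = None,
    gene_tile_bp: int = 50_000,
) -> dict[str, Path]:
    """Write VCF, population map, truth BED, synthetic genes BED and manifest.

    Synthetic genes tile the contig every ``gene_tile_bp`` (one 30 kb gene
    per tile) so region/gene annotation is exercisable without downloads.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "vcf": out / "panel.vcf",
        "popmap": out / "popmap.txt",
        "truth": out / "truth.bed",
        "genes": out / "genes.bed",
        "manifest": out / "manifest.json",
    }
    write_vcf(panel, files["vcf"])
    files["popmap"].write_text(
        "".join(f"{s}\t{panel.pop_map[s]}\n" for s in panel.sample_ids)
    )
    if truth is not None:
        files["truth"].write_text(
            f"{truth.contig}\t{truth.start}\t{truth.end}\tsweep_{truth.population}\n"
        )
    else:
        files["truth"].write_text("")
    gene_lines = []
    for contig, length in panel.contig_lengths.items():
        for k, start in enumerate(range(0, length, gene_tile_bp)):
            g_start = start + 10_000
            g_end = min(start + 40_000, length)
            if g_end > g_start:
                gene_lines.append(f"{contig}\t{g_start}\t{g_end}\tSYNGENE_{contig}_{k}\t0\t+\n")
    files["genes"].write_text("".join(gene_lines))
    manifest = {"params": asdict(params) if params else None,
                "truth": asdict(truth) if truth else None}
    files["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return files
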