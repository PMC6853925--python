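import numpy as np
import pandas as pd
import pytest

from selsweep.panel import SITE_COLUMNS, GenotypePanel
from selsweep.synthetic_data import SimParams, SweepParams, simulate_sweep_panel
from selsweep.xpehh_scan import xpehh_scores


def panel_from_haplotypes(
    haps,
    positions,
    pop_labels,
    contig="1",
    contig_length=None,
    ref=None,
    alt=None,
    qual=None,
    qd=None,
    mq=None,
    fs=None,
    phased=True,
):
    """Build a small GenotypePanel directly from a haplotype matrix.

    ``haps`` is (2*N, S) with alleles in {0, 1, -1}; ``pop_labels`` has one
    label per diploid sample.  INFO metrics default to NaN (treated as
    passing by the filters).
    """
    haps = np.asarray(haps, dtype=np.int8)
    positions = np.asarray(positions, dtype=np.int64)
    n_hap, n_sites = haps.shape
    assert n_hap == 2 * len(pop_labels)
    genotypes = np.where(
        (haps[0::2] == -1) | (haps[1::2] == -1), -1, haps[0::2] + haps[1::2]
    ).astype(np.int8)

    def col(values, default):
        if values is None:
            return np.full(n_sites, default)
        return np.asarray(values)

    sites = pd.DataFrame(
        {
            "contig": contig,
            "pos": positions,
            "ref": col(ref, "A"),
            "alt": col(alt, "G"),
            "qual": col(qual, np.nan),
            "qd": col(qd, np.nan),
            "mq": col(mq, np.nan),
            "fs": col(fs, np.nan),
        },
        columns=SITE_COLUMNS,
    )
    sample_ids = [f"s{i}" for i in range(len(pop_labels))]
    length = contig_length if contig_length is not None else int(positions.max()) + 1000
    panel = GenotypePanel(
        sites=sites,
        genotypes=genotypes,
        sample_ids=sample_ids,
        pop_map=dict(zip(sample_ids, pop_labels)),
        contig_lengths={contig: length},
        haplotypes=haps if phased else None,
    )
    panel.validate()
    return panel


def random_panel(rng, n_samples=10, n_sites=20, pops=("A", "B"), length=100_000,
                 missing_rate=0.0):
    """Random phased panel with uniform allele frequencies (for oracles)."""
    haps = (rng.random((2 * n_samples, n_sites)) < rng.uniform(0.1, 0.9, n_sites)).astype(np.int8)
    if missing_rate:
        # missingness applies per genotype: blank both haplotypes together
        miss = rng.random((n_samples, n_sites)) < missing_rate
        haps[0::2][miss] = -1
        haps[1::2][miss] = -1
    positions = np.sort(rng.choice(np.arange(1, length), size=n_sites, replace=False))
    labels = [pops[i % len(pops)] for i in range(n_samples)]
    return panel_from_haplotypes(haps, positions, labels, contig_length=length)


@pytest.fixture(scope="session")
def sweep_fixture():
    """The packaged 2 Mb sweep fixture: 12 + 10 diploids, carrier freq 0.9,
    150 kb halo, fixed seed (the SimParams defaults)."""
    return simulate_sweep_panel(SimParams(sweep=SweepParams()))


@pytest.fixture(scope="session")
def sweep_scores(sweep_fixture):
    panel, _ = sweep_fixture
    return xpehh_scores(panel, "JH", "TB")
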