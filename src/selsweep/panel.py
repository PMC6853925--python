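"""Genotype panel container shared by every analysis module.

A :class:`GenotypePanel` holds biallelic SNP sites for a set of diploid
samples split into populations.  Genotypes are stored as alt-allele dosages
(0/1/2, -1 = missing); when the source data are phased the individual
haplotypes (rows ``2*s`` and ``2*s+1`` for sample ``s``) are kept as well,
which the haplotype-based scans require.

Positions are 1-based (VCF convention) in ``sites``; all window arithmetic
elsewhere in the package uses 0-based half-open intervals and converts at
the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

#: columns of the per-site table, in storage order
SITE_COLUMNS = ["contig", "pos", "ref", "alt", "qual", "qd", "mq", "fs"]


@dataclass
class GenotypePanel:
    """Biallelic SNP genotypes for N diploid samples with a population map.

    Parameters
    ----------
    sites
        DataFrame with columns ``contig, pos, ref, alt, qual, qd, mq, fs``
        (``qd/mq/fs`` are NaN when the INFO key was absent).
    genotypes
        ``(n_samples, n_sites)`` int8 array of alt-allele dosages,
        ``-1`` for missing calls.
    sample_ids
        Sample names, in genotype row order.
    pop_map
        ``sample_id -> population label``; must cover every sample.
    contig_lengths
        ``contig -> length in bp``.
    haplotypes
        Optional ``(2 * n_samples, n_sites)`` int8 array of phased alleles
        (0 = ref, 1 = alt, -1 = missing).
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    sample_ids: list[str]
    pop_map: dict[str, str]
    contig_lengths: dict[str, int] = field(default_factory=dict)
    haplotypes: np.ndarray | None = None

    # -- basic shape ------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def phased(self) -> bool:
        return self.haplotypes is not None

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.pop_map[s], None)
        return list(seen)

    # -- population views -------------------------------------------------
    def sample_indices(self, population: str) -> np.ndarray:
        """Row indices (into ``genotypes``) of the samples of one population."""
        idx = np.array(
            [i for i, s in enumerate(self.sample_ids) if self.pop_map[s] == population],
            dtype=np.intp,
        )
        if idx.size == 0:
            raise ValueError(f"population {population!r} has no samples")
        return idx

    def haplotype_indices(self, population: str) -> np.ndarray:
        """Row indices into ``haplotypes`` for one population."""
        s = self.sample_indices(population)
        return np.sort(np.concatenate([2 * s, 2 * s + 1]))

    def pop_genotypes(self, population: str) -> np.ndarray:
        return self.genotypes[self.sample_indices(population)]

    def pop_haplotypes(self, population: str) -> np.ndarray:
        if self.haplotypes is None:
            raise ValueError(
                "panel is unphased: haplotype-based statistics need phased GTs "
                "(enable pseudo-phasing to proceed on unphased data)"
            )
        return self.haplotypes[self.haplotype_indices(population)]

    # -- manipulation ------------------------------------------------------
    def take_sites(self, mask_or_index) -> "GenotypePanel":
        """Return a panel restricted to the given site mask / index array."""
        arr = np.asarray(mask_or_index)
        if arr.dtype == bool:
            arr = np.flatnonzero(arr)
        return replace(
            self,
            sites=self.sites.iloc[arr].reset_index(drop=True),
            genotypes=self.genotypes[:, arr],
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, arr],
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on the first failure."""
        if list(self.sites.columns) != SITE_COLUMNS:
            raise ValueError(f"sites columns must be {SITE_COLUMNS}")
        if self.genotypes.shape != (self.n_samples, self.n_sites):
            raise ValueError("genotype matrix shape does not match samples × sites")
        for s in self.sample_ids:
            if s not in self.pop_map:
                raise ValueError(f"sample {s!r} missing from population map")
        ref = self.sites["ref"].to_numpy()
        alt = self.sites["alt"].to_numpy()
        bases = {"A", "C", "G", "T"}
        for r, a in zip(ref, alt):
            if r == a or r not in bases or a not in bases:
                raise ValueError(f"non-biallelic-SNP alleles {r!r}/{a!r}")
        for contig, grp in self.sites.groupby("contig", sort=False):
            p = grp["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on contig {contig}")
        g = self.genotypes
        if g.size and (g.min() < MISSING or g.max() > 2):
            raise ValueError("genotype dosages must be in {-1, 0, 1, 2}")
        if self.haplotypes is not None:
            h = self.haplotypes
            if h.shape != (2 * self.n_samples, self.n_sites):
                raise ValueError("haplotype matrix shape must be 2·samples × sites")
            dos = np.where(
                (h[0::2] == MISSING) | (h[1::2] == MISSING),
                MISSING,
                h[0::2] + h[1::2],
            )
            called = g != MISSING
            if not np.array_equal(dos[called], g[called]):
                raise ValueError("haplotypes do not sum to genotype dosages")


def call_rate(panel: GenotypePanel) -> np.ndarray:
    """Fraction of samples with a called genotype, per site."""
    return (panel.genotypes != MISSING).mean(axis=0)


def pooled_maf(panel: GenotypePanel) -> np.ndarray:
    """Minor-allele frequency per site over all samples pooled.

    Missing genotypes are excluded from the denominator; an all-missing
    site gets MAF 0.
    """
    g = panel.genotypes
    called = g != MISSING
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
    return np.minimum(p, 1.0 - p)
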