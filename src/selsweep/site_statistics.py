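"""Per-population allele-count summaries.

Covers the descriptive statistics reported for each breed panel: Ts/Tv
ratio, het/hom tallies, fixed non-reference sites, shared/unique SNP sets
between populations, and 10 kb windowed nucleotide diversity (pi).

All counts are taken over non-missing genotypes of the requested
population only.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel

log = logging.getLogger(__name__)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def allele_count_table(panel: GenotypePanel, population: str) -> pd.DataFrame:
    """Per-site allele and genotype counts for one population.

    Returns a DataFrame aligned with ``panel.sites`` with columns
    ``n_ref, n_alt, n_maj, n_min, n_het, n_hom_ref, n_hom_alt``.
    The major allele on a ref/alt tie is the reference allele; the Hp
    statistic downstream is symmetric, so the tie-break cannot affect it.
    """
    g = panel.pop_genotypes(population)
    called = g != MISSING
    n_called = called.sum(axis=0)
    n_alt = np.where(called, g, 0).sum(axis=0)
    n_ref = 2 * n_called - n_alt
    out = pd.DataFrame(
        {
            "n_ref": n_ref,
            "n_alt": n_alt,
            "n_maj": np.maximum(n_ref, n_alt),
            "n_min": np.minimum(n_ref, n_alt),
            "n_het": (g == 1).sum(axis=0),
            "n_hom_ref": (g == 0).sum(axis=0),
            "n_hom_alt": (g == 2).sum(axis=0),
        }
    )
    return out


def tstv_ratio(panel_or_counts) -> tuple[int, int, float]:
    """Transition/transversion tally and ratio.

    Accepts either a :class:`GenotypePanel` (classifies each site's
    ref/alt pair) or a pre-computed ``(n_transitions, n_transversions)``
    pair.  Transitions are A<->G and C<->T; every other base pair is a
    transversion.  With zero transversions the ratio is NaN (undefined),
    never +inf.
    """
    if isinstance(panel_or_counts, GenotypePanel):
        pairs = zip(panel_or_counts.sites["ref"], panel_or_counts.sites["alt"])
        ts = sum(1 for p in pairs if p in TRANSITIONS)
        tv = panel_or_counts.n_sites - ts
    else:
        ts, tv = (int(x) for x in panel_or_counts)
    ratio = ts / tv if tv > 0 else float("nan")
    return ts, tv, ratio


def is_transition(ref: str, alt: str) -> bool:
    return (ref, alt) in TRANSITIONS


def detect_fixed_sites(panel: GenotypePanel, population: str) -> np.ndarray:
    """Boolean mask of sites fixed for the non-reference allele in a population.

    Fixed means: every sample of the population has a called genotype and
    all are homozygous alternate.  Sites with any missing genotype are not
    fixed under this strict complete-case rule.
    """
    g = panel.pop_genotypes(population)
    fixed = (g == 2).all(axis=0)
    n_partial = int(((g == 2) | (g == MISSING)).all(axis=0).sum() - fixed.sum())
    if n_partial:
        log.info(
            "detect_fixed_sites(%s): %d sites hom-alt in all called samples "
            "but excluded for missing genotypes", population, n_partial,
        )
    return fixed


def allele_freq_from_genotypes(genotype_freqs: dict[str, float], allele: str) -> float:
    """Allele frequency from genotype frequencies: f(hom) + f(het)/2.

    ``genotype_freqs`` maps two-character genotype strings (e.g. ``"TT"``,
    ``"CT"``) to population fractions.  Fractions must sum to 1 within
    +-0.02 (published tables are rounded).
    """
    total = sum(genotype_freqs.values())
    if abs(total - 1.0) > 0.02:
        raise ValueError(f"genotype fractions sum to {total:.3f}, outside 1 +- 0.02")
    freq = 0.0
    for gt, frac in genotype_freqs.items():
        if len(gt) != 2:
            raise ValueError(f"genotype {gt!r} is not a two-allele string")
        freq += frac * sum(1 for a in gt if a == allele) / 2.0
    return freq


def population_snp_sets(
    panel: GenotypePanel, populations: list[str] | None = None
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Segregating-site masks per population and pairwise shared/unique tallies.

    A site belongs to a population iff its alt-allele count there is > 0.
    The tally table has one row per population pair with ``a_only``,
    ``b_only`` and ``shared`` counts.
    """
    populations = populations or panel.populations
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    masks = {
        pop: allele_count_table(panel, pop)["n_alt"].to_numpy() > 0
        for pop in populations
    }
    rows = []
    for a, b in itertools.combinations(populations, 2):
        rows.append(
            {
                "pop_a": a,
                "pop_b": b,
                "a_only": int((masks[a] & ~masks[b]).sum()),
                "b_only": int((masks[b] & ~masks[a]).sum()),
                "shared": int((masks[a] & masks[b]).sum()),
            }
        )
    return masks, pd.DataFrame(rows)


def per_site_pi(counts: pd.DataFrame) -> np.ndarray:
    """Unbiased per-site nucleotide diversity 2*n_ref*n_alt / (n*(n-1)).

    Equals the fraction of allele pairs that differ; sites with fewer than
    two called alleles contribute 0.
    """
    n_ref = counts["n_ref"].to_numpy(float)
    n_alt = counts["n_alt"].to_numpy(float)
    n = n_ref + n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, 2.0 * n_ref * n_alt / (n * (n - 1.0)), 0.0)
    return pi


def windowed_pi(
    panel: GenotypePanel, population: str, window_bp: int = 10_000
) -> pd.DataFrame:
    """Nucleotide diversity in non-overlapping windows (default 10 kb).

    Window pi is the sum of per-site pi over SNPs in the window divided by
    the full window length in bp (monomorphic positions count in the
    denominator, the convention of the standard VCF tooling).  Returns a
    DataFrame ``contig, start, end, n_snps, pi`` with 0-based half-open
    windows tiling each contig of known length.
    """
    if not panel.contig_lengths:
        raise ValueError("windowed_pi needs contig_lengths")
    counts = allele_count_table(panel, population)
    pi_site = per_site_pi(counts)
    rows = []
    for contig, length in panel.contig_lengths.items():
        on = panel.sites["contig"].to_numpy() == contig
        pos0 = panel.sites["pos"].to_numpy()[on] - 1  # 0-based
        pis = pi_site[on]
        for start in range(0, length, window_bp):
            end = min(start + window_bp, length)
            in_w = (pos0 >= start) & (pos0 < end)
            rows.append(
                {
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "n_snps": int(in_w.sum()),
                    "pi": float(pis[in_w].sum()) / (end - start),
                }
            )
    return pd.DataFrame(rows)


def mean_pi(windows: pd.DataFrame) -> float:
    """Mean diversity over windows, weighted by window length."""
    lengths = (windows["end"] - windows["start"]).to_numpy(float)
    return float((windows["pi"].to_numpy() * lengths).sum() / lengths.sum())


def population_summary(panel: GenotypePanel, population: str) -> dict[str, float]:
    """One-row summary: SNP count, Ts/Tv, het/hom tallies, fixed sites."""
    counts = allele_count_table(panel, population)
    seg = counts["n_alt"].to_numpy() > 0
    sub = panel.take_sites(seg)
    ts, tv, ratio = tstv_ratio(sub)
    return {
        "population": population,
        "n_snps": int(seg.sum()),
        "ts": ts,
        "tv": tv,
        "tstv": round(ratio, 2) if np.isfinite(ratio) else float("nan"),
        "n_het_genotypes": int(counts["n_het"].sum()),
        "n_hom_alt_genotypes": int(counts["n_hom_alt"].sum()),
        "n_fixed": int(detect_fixed_sites(panel, population).sum()),
    }
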