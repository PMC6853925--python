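"""Read, filter and write variant panels and auxiliary files.

Reading goes through cyvcf2; writing emits minimal VCF 4.2 text (GT format,
QD/MQ/FS INFO) so that write → read → write is byte-identical.  The module
also houses the hard site filters used upstream of every statistic
(QD ≥ 5, MQ ≥ 40, FS ≤ 200, QUAL ≥ 30, call rate ≥ 0.9, MAF > 0.01) and
the known/novel classification against a dbSNP-style site list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import MISSING, SITE_COLUMNS, GenotypePanel, call_rate, pooled_maf

log = logging.getLogger(__name__)

_BASES = {"A", "C", "G", "T"}


@dataclass
class FilterConfig:
    """Hard-filter thresholds applied per site (GATK-style annotations).

    A site is kept only if it passes every sub-filter.  Missing INFO
    metrics pass their sub-filter: an uncalled annotation is not evidence
    of failure.
    """

    qd_min: float = 5.0
    mq_min: float = 40.0
    fs_max: float = 200.0
    qual_min: float = 30.0
    call_rate_min: float = 0.9
    maf_min_exclusive: float = 0.01  # sites with MAF <= this are removed
    per_population: str | None = None  # compute call rate/MAF within one population

    def __post_init__(self) -> None:
        for name in ("qd_min", "mq_min", "fs_max", "qual_min"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("call_rate_min", "maf_min_exclusive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")


def read_pop_map(path: str | Path) -> dict[str, str]:
    """Two-column whitespace-delimited text: sample, population."""
    pop_map: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'sample population'")
        pop_map[parts[0]] = parts[1]
    return pop_map


def read_known_sites(path: str | Path) -> set[tuple[str, int]]:
    """Known-site keys from two-column text (contig, 1-based pos) or a VCF."""
    path = Path(path)
    if path.suffix in {".vcf", ".bcf"} or str(path).endswith(".vcf.gz"):
        return {(v.CHROM, v.POS) for v in VCF(str(path))}
    known: set[tuple[str, int]] = set()
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        contig, pos = line.split()[:2]
        known.add((contig, int(pos)))
    return known


def read_vcf(path: str | Path, pop_map_path: str | Path) -> GenotypePanel:
    """Load biallelic SNPs from a VCF 4.x file into a :class:`GenotypePanel`.

    Multiallelic and non-SNP records are dropped (count logged).  If every
    genotype in the file is phased the haplotype matrix is populated,
    otherwise ``haplotypes`` is ``None``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pop_map = read_pop_map(pop_map_path)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in pop_map:
            raise ValueError(f"sample {s!r} in VCF is absent from population map")

    contig_lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}

    rows: list[tuple] = []
    geno_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    all_phased = True
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1 \
                or v.REF not in _BASES or v.ALT[0] not in _BASES:
            n_dropped += 1
            continue
        info = v.INFO
        rows.append(
            (v.CHROM, v.POS, v.REF, v.ALT[0],
             float(v.QUAL) if v.QUAL is not None else np.nan,
             _info_float(info, "QD"), _info_float(info, "MQ"), _info_float(info, "FS"))
        )
        g = np.empty(len(samples), dtype=np.int8)
        h = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            a, b = gt[0], gt[1]
            if a < -1 or b < -1 or a > 1 or b > 1:
                raise ValueError(f"malformed GT at {v.CHROM}:{v.POS} sample {samples[i]}")
            h[2 * i], h[2 * i + 1] = a, b
            g[i] = MISSING if (a < 0 or b < 0) else a + b
            if not gt[2] and not (a < 0 and b < 0):
                all_phased = False
        geno_cols.append(g)
        hap_cols.append(h)
    if n_dropped:
        log.info("read_vcf(%s): dropped %d multiallelic/non-SNP records", path, n_dropped)

    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    genotypes = (
        np.column_stack(geno_cols) if geno_cols
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    haplotypes = None
    if all_phased and hap_cols:
        haplotypes = np.column_stack(hap_cols)
    panel = GenotypePanel(
        sites=sites,
        genotypes=genotypes,
        sample_ids=samples,
        pop_map={s: pop_map[s] for s in samples},
        contig_lengths=contig_lengths,
        haplotypes=haplotypes,
    )
    panel.validate()
    return panel


def _info_float(info, key: str) -> float:
    v = info.get(key)
    return float(v) if v is not None else np.nan


def _fmt(x: float) -> str:
    """Stable float formatting shared by writer and round-trip tests."""
    if np.isnan(x):
        return "."
    return f"{x:g}"


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel as VCF 4.2 with GT FORMAT and QD/MQ/FS INFO."""
    lines = ["##fileformat=VCFv4.2"]
    for contig, length in panel.contig_lengths.items():
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines += [
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.sample_ids),
    ]
    sep = "|" if panel.phased else "/"
    sites = panel.sites
    for j in range(panel.n_sites):
        info_parts = [
            f"{key}={_fmt(sites.iloc[j][col])}"
            for key, col in (("QD", "qd"), ("MQ", "mq"), ("FS", "fs"))
            if not np.isnan(sites.iloc[j][col])
        ]
        gts = []
        for i in range(panel.n_samples):
            if panel.haplotypes is not None:
                a, b = panel.haplotypes[2 * i, j], panel.haplotypes[2 * i + 1, j]
                gts.append(f"{'.' if a < 0 else a}{sep}{'.' if b < 0 else b}")
            else:
                d = panel.genotypes[i, j]
                gts.append("./." if d == MISSING else ("0/0", "0/1", "1/1")[d])
        lines.append(
            "\t".join(
                [
                    str(sites.iloc[j]["contig"]), str(sites.iloc[j]["pos"]), ".",
                    sites.iloc[j]["ref"], sites.iloc[j]["alt"],
                    _fmt(sites.iloc[j]["qual"]), "PASS",
                    ";".join(info_parts) if info_parts else ".", "GT",
                ]
                + gts
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a report table as TSV with a header line."""
    rows.to_csv(path, sep="\t", index=False)


def filter_mask(
    panel: GenotypePanel, config: FilterConfig | None = None
) -> tuple[np.ndarray, dict[str, int]]:
    """Boolean keep-mask for the hard filters plus per-filter removal counts.

    Each count is the number of sites failing that sub-filter alone
    (a site may fail several).  Missing QD/MQ/FS pass their sub-filter.
    """
    config = config or FilterConfig()
    s = panel.sites
    if config.per_population is not None:
        g = panel.genotypes[panel.sample_indices(config.per_population)]
        called = g != MISSING
        cr = called.mean(axis=0)
        n_alleles = 2 * called.sum(axis=0)
        p = np.where(n_alleles > 0,
                     np.where(called, g, 0).sum(axis=0) / np.maximum(n_alleles, 1), 0.0)
        maf = np.minimum(p, 1.0 - p)
    else:
        cr, maf = call_rate(panel), pooled_maf(panel)

    def _pass(values: np.ndarray, ok) -> np.ndarray:
        v = values.astype(float)
        return np.where(np.isnan(v), True, ok(v))

    checks = {
        "qd": _pass(s["qd"].to_numpy(), lambda v: v >= config.qd_min),
        "mq": _pass(s["mq"].to_numpy(), lambda v: v >= config.mq_min),
        "fs": _pass(s["fs"].to_numpy(), lambda v: v <= config.fs_max),
        "qual": _pass(s["qual"].to_numpy(), lambda v: v >= config.qual_min),
        "call_rate": cr >= config.call_rate_min,
        "maf": maf > config.maf_min_exclusive,
    }
    keep = np.ones(panel.n_sites, dtype=bool)
    counts: dict[str, int] = {}
    for name, ok in checks.items():
        counts[name] = int((~ok).sum())
        keep &= ok
    n_missing_info = int(s[["qd", "mq", "fs"]].isna().any(axis=1).sum())
    if n_missing_info:
        log.info("filter: %d sites with missing INFO metric passed that sub-filter", n_missing_info)
    return keep, counts


def apply_site_filters(panel: GenotypePanel, config: FilterConfig | None = None) -> GenotypePanel:
    """Return the panel restricted to sites passing all hard filters."""
    if panel.n_sites == 0:
        raise ValueError("cannot filter an empty panel")
    keep, counts = filter_mask(panel, config)
    log.info(
        "apply_site_filters: %d/%d sites kept (failures per filter: %s)",
        int(keep.sum()), panel.n_sites, counts,
    )
    return panel.take_sites(keep)


def novel_summary(known_count: int, novel_count: int) -> dict[str, float]:
    """Known/novel tally summary; novel_fraction = novel/total to 4 decimals."""
    total = known_count + novel_count
    if total == 0:
        raise ValueError("no sites to summarise")
    return {
        "known_count": int(known_count),
        "novel_count": int(novel_count),
        "novel_fraction": round(novel_count / total, 4),
    }


def classify_known_novel(
    panel: GenotypePanel, known_sites: set[tuple[str, int]]
) -> tuple[np.ndarray, dict[str, float]]:
    """Flag each site as known (present in the reference site list) or novel.

    Returns the per-site known-flags and a summary with ``known_count``,
    ``novel_count`` and ``novel_fraction`` (novel/total, 4 decimals).
    """
    if panel.n_sites == 0:
        raise ValueError("empty panel")
    keys = list(zip(panel.sites["contig"], panel.sites["pos"]))
    known = np.fromiter(((c, int(p)) in known_sites for c, p in keys), bool, panel.n_sites)
    n_known = int(known.sum())
    return known, novel_summary(n_known, panel.n_sites - n_known)
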