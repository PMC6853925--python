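"""Candidate-region calling: merge significant windows, annotate genes,
and intersect gene sets across scan methods.

Windows surviving either scan are merged (overlapping or book-ended
windows coalesce) into candidate regions under selection; genes
overlapping a region by at least 1 bp are attached, and the gene sets of
the two methods are intersected.  All intervals are 0-based half-open
internally; GFF3 (1-based inclusive) is converted on read.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

REGION_COLUMNS = ["contig", "start", "end", "method", "n_windows", "best_stat"]


def read_bed_genes(path: str | Path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open; name from column 4)."""
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        rows.append(
            {"contig": f[0], "start": int(f[1]), "end": int(f[2]),
             "gene_id": f[3] if len(f) > 3 else f"gene_{i}",
             "strand": f[5] if len(f) > 5 else "."}
        )
    return pd.DataFrame(rows, columns=["contig", "start", "end", "gene_id", "strand"])


def read_gff3_genes(path: str | Path, feature_types: tuple[str, ...] = ("gene",)) -> pd.DataFrame:
    """Gene intervals from GFF3, converted to 0-based half-open.

    ``gene_id`` comes from the ``ID=`` or ``gene_id=`` attribute key.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 9 or f[2] not in feature_types:
            continue
        attrs = dict(
            kv.split("=", 1) for kv in f[8].strip().split(";") if "=" in kv
        )
        gene_id = attrs.get("ID") or attrs.get("gene_id")
        if gene_id is None:
            raise ValueError(f"GFF3 record without ID/gene_id attribute: {line[:80]}")
        rows.append(
            {"contig": f[0], "start": int(f[3]) - 1, "end": int(f[4]),
             "gene_id": gene_id, "strand": f[6]}
        )
    return pd.DataFrame(rows, columns=["contig", "start", "end", "gene_id", "strand"])


def read_genes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return read_gff3_genes(path)
    return read_bed_genes(path)


def merge_regions(significant_windows: pd.DataFrame, method: str, stat_column: str) -> pd.DataFrame:
    """Merge overlapping or book-ended windows into candidate regions.

    The best statistic carried per region is the minimum for ZHp-style
    columns (named ``zhp``) and the maximum otherwise.  The result is
    sorted and non-overlapping; merging is idempotent and independent of
    input order.
    """
    if len(significant_windows) == 0:
        return pd.DataFrame(columns=REGION_COLUMNS)
    take_min = stat_column == "zhp"
    w = significant_windows.sort_values(["contig", "start", "end"], kind="mergesort")
    rows: list[dict] = []
    cur: dict | None = None
    for rec in w.itertuples():
        stat = float(getattr(rec, stat_column))
        if cur is not None and rec.contig == cur["contig"] and rec.start <= cur["end"]:
            cur["end"] = max(cur["end"], rec.end)
            cur["n_windows"] += 1
            cur["best_stat"] = min(cur["best_stat"], stat) if take_min else max(cur["best_stat"], stat)
        else:
            if cur is not None:
                rows.append(cur)
            cur = {"contig": rec.contig, "start": int(rec.start), "end": int(rec.end),
                   "method": method, "n_windows": 1, "best_stat": stat}
    rows.append(cur)
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def genes_in_regions(
    regions: pd.DataFrame, gene_intervals: pd.DataFrame
) -> tuple[pd.DataFrame, set[str]]:
    """Genes overlapping each region by >= 1 bp, plus the unique gene set.

    Book-ended gene/region pairs do not overlap.  A region contig missing
    from the annotation logs a warning and yields zero genes.
    """
    trees: dict[str, IntervalTree] = {}
    for g in gene_intervals.itertuples():
        trees.setdefault(g.contig, IntervalTree()).addi(g.start, g.end, g.gene_id)
    rows = []
    unique: set[str] = set()
    for r in regions.itertuples():
        tree = trees.get(r.contig)
        if tree is None:
            log.warning("genes_in_regions: contig %s absent from annotation", r.contig)
            genes: list[str] = []
        else:
            genes = sorted({iv.data for iv in tree.overlap(r.start, r.end)})
        unique.update(genes)
        rows.append(
            {"contig": r.contig, "start": r.start, "end": r.end,
             "method": r.method, "n_genes": len(genes), "genes": ",".join(genes)}
        )
    return pd.DataFrame(rows, columns=["contig", "start", "end", "method", "n_genes", "genes"]), unique


def method_overlap(genes_a: set[str], genes_b: set[str]) -> dict[str, set[str]]:
    """Gene-level intersection and per-method unique sets."""
    return {
        "shared": genes_a & genes_b,
        "only_a": genes_a - genes_b,
        "only_b": genes_b - genes_a,
    }


def regions_bp_intersection(regions_a: pd.DataFrame, regions_b: pd.DataFrame) -> int:
    """Total bp shared between two merged region sets (for completeness)."""
    trees: dict[str, IntervalTree] = {}
    for r in regions_a.itertuples():
        trees.setdefault(r.contig, IntervalTree()).addi(r.start, r.end)
    total = 0
    for r in regions_b.itertuples():
        for iv in trees.get(r.contig, IntervalTree()).overlap(r.start, r.end):
            total += min(iv.end, r.end) - max(iv.begin, r.start)
    return total
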