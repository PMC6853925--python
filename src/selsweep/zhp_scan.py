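"""Pooled-heterozygosity (Hp) sliding-window scan with Z-transformation.

For each 150 kb window (50% overlap) the numbers of major and minor
alleles at every SNP are summed and

    Hp = 2 * sum(nMAJ) * sum(nMIN) / (sum(nMAJ) + sum(nMIN))**2

Windows with fewer than ``min_snps`` SNPs are dropped; sites with minor
allele frequency below ``maf_min`` are removed before windowing.  Hp is
Z-transformed genome-wide (ZHp) and windows below the threshold (default
ZHp < -3.5, strict) are candidate sweeps: excess homozygosity drives Hp
towards 0 and ZHp deeply negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel
from .site_statistics import allele_count_table


@dataclass
class ZHpParams:
    window_bp: int = 150_000
    overlap_fraction: float = 0.5
    min_snps: int = 10
    maf_min: float = 0.05       # sites with MAF < this removed before Hp
    zhp_threshold: float = -3.5  # candidate windows have zhp strictly below

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")


def make_sliding_windows(
    contig_lengths: dict[str, int], window_bp: int, overlap_fraction: float = 0.5
) -> pd.DataFrame:
    """Sliding windows per contig, 0-based half-open, anchored at 0.

    Step is ``window_bp * (1 - overlap_fraction)``.  A final truncated
    window is added when a full window no longer fits but uncovered
    sequence remains; a contig shorter than one window yields a single
    truncated window.
    """
    step = int(round(window_bp * (1.0 - overlap_fraction)))
    if step < 1:
        raise ValueError("window step must be at least 1 bp")
    rows = []
    for contig, length in contig_lengths.items():
        start = 0
        last_end = 0
        while start + window_bp <= length:
            rows.append({"contig": contig, "start": start, "end": start + window_bp})
            last_end = start + window_bp
            start += step
        if last_end < length:
            rows.append({"contig": contig, "start": start, "end": length})
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def hp_from_sums(sum_nmaj: float, sum_nmin: float) -> float:
    """The pooled-heterozygosity formula 2*SMAJ*SMIN/(SMAJ+SMIN)^2."""
    total = sum_nmaj + sum_nmin
    if total == 0:
        return float("nan")
    return 2.0 * sum_nmaj * sum_nmin / (total * total)


def window_hp(count_table: pd.DataFrame, pos0: np.ndarray, window: tuple[int, int],
              params: ZHpParams | None = None) -> dict:
    """Hp for a single window given a count table already MAF-restricted.

    ``pos0`` are the 0-based positions of the count-table rows; ``window``
    is a (start, end) half-open interval.  Windows with fewer than
    ``min_snps`` SNPs are flagged ``dropped``.
    """
    params = params or ZHpParams()
    start, end = window
    in_w = (pos0 >= start) & (pos0 < end)
    smaj = float(count_table["n_maj"].to_numpy()[in_w].sum())
    smin = float(count_table["n_min"].to_numpy()[in_w].sum())
    n = int(in_w.sum())
    return {
        "n_snps": n,
        "sum_nmaj": smaj,
        "sum_nmin": smin,
        "hp": hp_from_sums(smaj, smin) if n else float("nan"),
        "dropped": n < params.min_snps,
    }


def hp_windows(panel: GenotypePanel, population: str,
               params: ZHpParams | None = None) -> pd.DataFrame:
    """Hp in sliding windows for one population (retained windows only).

    Applies the MAF >= ``maf_min`` site filter (within the population),
    assigns each remaining SNP to every overlapping window, and drops
    windows with fewer than ``min_snps`` SNPs.
    """
    params = params or ZHpParams()
    if not panel.contig_lengths:
        raise ValueError("hp_windows needs contig_lengths")
    counts = allele_count_table(panel, population)
    n = (counts["n_maj"] + counts["n_min"]).to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(n > 0, counts["n_min"].to_numpy(float) / np.maximum(n, 1), 0.0)
    keep = maf >= params.maf_min
    counts = counts[keep].reset_index(drop=True)
    contigs = panel.sites["contig"].to_numpy()[keep]
    pos0 = panel.sites["pos"].to_numpy()[keep] - 1

    windows = make_sliding_windows(panel.contig_lengths, params.window_bp, params.overlap_fraction)
    rows = []
    for contig in windows["contig"].unique():
        on = contigs == contig
        ct, p0 = counts[on].reset_index(drop=True), pos0[on]
        for w in windows[windows["contig"] == contig].itertuples():
            res = window_hp(ct, p0, (w.start, w.end), params)
            if res["dropped"]:
                continue
            rows.append({"contig": contig, "start": w.start, "end": w.end, **res})
    out = pd.DataFrame(rows, columns=["contig", "start", "end", "n_snps",
                                      "sum_nmaj", "sum_nmin", "hp", "dropped"])
    return out.drop(columns=["dropped"])


def zhp_scores(hp_table: pd.DataFrame) -> pd.DataFrame:
    """Add the genome-wide Z-transformation: zhp = (hp - mean) / sd (ddof=1)."""
    if len(hp_table) < 2:
        raise ValueError("need at least two retained windows to Z-transform")
    hp = hp_table["hp"].to_numpy(float)
    sd = hp.std(ddof=1)
    if np.ptp(hp) == 0 or sd == 0:
        raise ValueError("all window Hp values identical: Z-transform degenerate")
    out = hp_table.copy()
    out["zhp"] = (hp - hp.mean()) / sd
    return out


def extreme_zhp_windows(hp_table: pd.DataFrame, threshold: float = -3.5) -> pd.DataFrame:
    """Windows with zhp strictly below the threshold, most extreme first."""
    if "zhp" not in hp_table:
        raise ValueError("run zhp_scores first")
    hits = hp_table[hp_table["zhp"] < threshold]
    return hits.sort_values("zhp", kind="mergesort").reset_index(drop=True)


def zhp_scan(panel: GenotypePanel, population: str,
             params: ZHpParams | None = None) -> pd.DataFrame:
    """Full scan: windows -> Hp -> ZHp, with a candidate flag column."""
    params = params or ZHpParams()
    table = zhp_scores(hp_windows(panel, population, params))
    table["candidate"] = table["zhp"] < params.zhp_threshold
    return table
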