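"""Window summaries and SNP-density-binned empirical p-values for XP-EHH.

The genome is tiled with non-overlapping 50 kb windows; each window is
summarised by the maximum normalized XP-EHH score of its SNPs.  Because
windows with more SNPs sample more extreme maxima, windows are binned by
SNP count in increments of 500 (all windows with >= 1000 SNPs pooled into
one bin) and, within each bin, the empirical p-value of window i is the
fraction of windows in the bin whose summary statistic strictly exceeds
window i's.  Windows with p below ``alpha`` (default 0.005, strict) are
the significant selection signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SignificanceParams:
    window_bp: int = 50_000
    bin_width: int = 500
    pool_from: int = 1000          # windows with >= this many SNPs share one bin
    alpha: float = 0.005
    strict: bool = True            # significant iff p < alpha (else p <= alpha)
    positive_scores_only: bool = False  # summarise max over positive z only
    rank_correction: bool = False  # optional (r+1)/(n+1) pseudo-count form


def tile_windows(contig_lengths: dict[str, int], window_bp: int = 50_000) -> pd.DataFrame:
    """Non-overlapping windows tiling each contig, 0-based half-open."""
    rows = []
    for contig, length in contig_lengths.items():
        for start in range(0, length, window_bp):
            rows.append({"contig": contig, "start": start, "end": min(start + window_bp, length)})
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def window_max_scores(
    scores: pd.DataFrame,
    contig_lengths: dict[str, int],
    params: SignificanceParams | None = None,
) -> pd.DataFrame:
    """Max normalized score and SNP count per window; empty windows dropped.

    ``scores`` needs columns ``contig, pos, z`` (1-based positions); SNPs
    with NaN z are not scored.  With ``positive_scores_only`` the maximum
    is taken over positive z only (windows without one are dropped);
    otherwise the literal maximum is used, so an all-negative window is
    summarised by its least-negative score.
    """
    params = params or SignificanceParams()
    windows = tile_windows(contig_lengths, params.window_bp)
    scored = scores[np.isfinite(scores["z"].to_numpy(float))]
    if params.positive_scores_only:
        scored = scored[scored["z"] > 0]
    rows = []
    for w in windows.itertuples():
        on = scored[
            (scored["contig"] == w.contig)
            & (scored["pos"] - 1 >= w.start)
            & (scored["pos"] - 1 < w.end)
        ]
        if len(on) == 0:
            continue
        rows.append(
            {"contig": w.contig, "start": w.start, "end": w.end,
             "n_snps": len(on), "max_score": float(on["z"].max())}
        )
    return pd.DataFrame(rows, columns=["contig", "start", "end", "n_snps", "max_score"])


def bin_windows_by_snp_count(
    windows: pd.DataFrame, bin_width: int = 500, pool_from: int = 1000
) -> pd.DataFrame:
    """Assign ``bin_id = floor(n_snps / bin_width)`` capped at the pooled bin.

    Default bins: [1, 500), [500, 1000), [1000, inf).
    """
    n = windows["n_snps"].to_numpy()
    if (n < 1).any():
        raise ValueError("windows with zero SNPs must be dropped before binning")
    out = windows.copy()
    out["bin_id"] = np.minimum(n // bin_width, pool_from // bin_width)
    return out


def binned_empirical_pvalues(windows: pd.DataFrame, rank_correction: bool = False) -> pd.DataFrame:
    """Empirical p per window: within its bin, the fraction of windows with a
    strictly greater summary statistic.

    The top window of each bin always gets p = 0 under the plain counting
    rule; ``rank_correction`` switches to (r+1)/(n+1) where r is the
    strict-dominance count.
    """
    out = windows.copy()
    p = np.empty(len(out))
    for _, idx in out.groupby("bin_id").groups.items():
        s = out.loc[idx, "max_score"].to_numpy(float)
        greater = len(s) - np.searchsorted(np.sort(s), s, side="right")
        if rank_correction:
            p[out.index.get_indexer(idx)] = (greater + 1) / (len(s) + 1)
        else:
            p[out.index.get_indexer(idx)] = greater / len(s)
    out["empirical_p"] = p
    return out


def significant_windows(windows: pd.DataFrame, alpha: float = 0.005, strict: bool = True) -> pd.DataFrame:
    """Windows below the significance level, sorted by p then score desc."""
    if "empirical_p" not in windows:
        raise ValueError("run binned_empirical_pvalues first")
    p = windows["empirical_p"].to_numpy(float)
    keep = p < alpha if strict else p <= alpha
    hits = windows[keep]
    return hits.sort_values(
        ["empirical_p", "max_score"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)


def score_windows(
    scores: pd.DataFrame,
    contig_lengths: dict[str, int],
    params: SignificanceParams | None = None,
) -> pd.DataFrame:
    """Full procedure: window maxima -> SNP-count bins -> empirical p,
    with a ``significant`` flag column."""
    params = params or SignificanceParams()
    w = window_max_scores(scores, contig_lengths, params)
    if len(w) == 0:
        w["bin_id"] = w["empirical_p"] = w["significant"] = []
        return w
    w = bin_windows_by_snp_count(w, params.bin_width, params.pool_from)
    w = binned_empirical_pvalues(w, params.rank_correction)
    p = w["empirical_p"].to_numpy(float)
    w["significant"] = p < params.alpha if params.strict else p <= params.alpha
    return w
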