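"""Extended haplotype homozygosity (EHH), integrated EHH (iHH) and
cross-population XP-EHH scores.

EHH at distance x from a core SNP is the probability that two haplotypes
drawn at random from the population are identical over every marker from
the core out to x: grouping haplotypes by their allele string over
``[core..m]``,

    EHH(m) = sum_g C(n_g, 2) / C(n, 2).

iHH is the area under EHH versus physical distance (bp), both directions
summed, integrated with the trapezoid rule out to and including the first
marker where EHH drops below ``stop_cutoff`` (0.05 by default).  For
XP-EHH the *pooled* two-population EHH sets a shared stop point for both
populations, and

    raw = ln(iHH_obs / iHH_ref),    z = (raw - mean) / sd

with the normalization taken over all non-truncated cores.  Large
positive z marks a long, high-frequency haplotype in the observed
population relative to the reference, i.e. near-fixation by a sweep.

The scan is core-site based across all haplotypes of each population
(EHH(0) = 1 trivially); allele-stratified EHH as in iHS is not used.
Distances are physical bp throughout — no genetic map.

Two engines implement the identical walk: a numba-compiled kernel (the
default, needed for genome-sized scans) and a pure-Python reference used
to cross-check it in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .panel import GenotypePanel


@dataclass
class XPEHHParams:
    stop_cutoff: float = 0.05        # integration stops when pooled EHH < this
    min_haplotypes: int = 2          # per population
    include_truncated: bool = False  # keep contig-end-truncated cores in normalization
    engine: str = "numba"            # "numba" | "python"
    pseudo_phase_seed: int | None = None  # set to pseudo-phase unphased input


@dataclass
class EHHCurve:
    """EHH decay from a core SNP in one direction.

    ``positions``/``distances``/``ehh`` include the core itself as the
    first point (distance 0, EHH 1.0).  ``truncated`` is True when the
    walk hit the end of the data before EHH fell below the cutoff.
    """

    core_index: int
    direction: int  # -1 left, +1 right
    positions: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    distances: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    ehh: np.ndarray = field(default_factory=lambda: np.empty(0, float))
    truncated: bool = False


def _pair_fraction(labels: np.ndarray) -> float:
    """Fraction of identical pairs given group labels (n >= 2)."""
    _, counts = np.unique(labels, return_counts=True)
    n = labels.size
    return float((counts * (counts - 1)).sum()) / (n * (n - 1))


def ehh_curve(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core_index: int,
    direction: int,
    stop_cutoff: float = 0.05,
) -> EHHCurve:
    """EHH decay from ``core_index`` walking left (-1) or right (+1).

    Haplotypes are grouped by their allele string over ``[core..m]``;
    the walk stops after the first marker whose EHH is below
    ``stop_cutoff`` (that marker is kept in the curve) or at the end of
    the matrix, in which case ``truncated`` is set.
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be -1 or +1")
    h = np.asarray(haplotypes)
    if h.shape[0] < 2:
        raise ValueError("EHH needs at least two haplotypes")
    n_sites = h.shape[1]
    pos = np.asarray(positions)
    out_pos = [int(pos[core_index])]
    out_ehh = [1.0]
    # haplotypes are grouped over [core..m]: the core allele splits groups too
    labels = (h[:, core_index].astype(np.int64) + 1)
    j = core_index + direction
    truncated = True
    while 0 <= j < n_sites:
        _, labels = np.unique(
            labels * 3 + (h[:, j].astype(np.int64) + 1), return_inverse=True
        )
        e = _pair_fraction(labels)
        out_pos.append(int(pos[j]))
        out_ehh.append(e)
        if e < stop_cutoff:
            truncated = False
            break
        j += direction
    p = np.array(out_pos)
    return EHHCurve(
        core_index=core_index,
        direction=direction,
        positions=p,
        distances=np.abs(p - p[0]),
        ehh=np.array(out_ehh),
        truncated=truncated,
    )


def _curve_area(curve: EHHCurve, cutoff: float) -> float:
    """Trapezoid area under one side, through the first sub-cutoff marker."""
    area = 0.0
    d, e = curve.distances, curve.ehh
    for k in range(1, len(e)):
        area += 0.5 * (e[k - 1] + e[k]) * (d[k] - d[k - 1])
        if e[k] < cutoff:
            break
    return area


def integrate_ihh(
    left_curve: EHHCurve, right_curve: EHHCurve, cutoff: float = 0.05
) -> tuple[float, bool]:
    """Integrated EHH: trapezoid areas of both sides summed.

    Each side is integrated out to and including the first marker where
    EHH < ``cutoff``; a side whose curve ran off the data before dropping
    below the cutoff marks the result truncated.  An empty side (core at
    the edge) contributes zero area.
    """
    area = _curve_area(left_curve, cutoff) + _curve_area(right_curve, cutoff)
    return area, bool(left_curve.truncated or right_curve.truncated)


# ---------------------------------------------------------------------------
# pooled-bound per-core scan (the XP-EHH inner loop), two engines
# ---------------------------------------------------------------------------

@njit(cache=True)
def _scan_core_numba(haps, pos, core, obs_mask, cutoff):  # pragma: no cover
    H, S = haps.shape
    n_obs = 0
    for i in range(H):
        if obs_mask[i]:
            n_obs += 1
    n_ref = H - n_obs
    ihh = np.zeros(2)
    truncated = False
    labels = np.empty(H, dtype=np.int64)
    key = np.empty(H, dtype=np.int64)
    cnt_o = np.empty(H + 1, dtype=np.int64)
    cnt_r = np.empty(H + 1, dtype=np.int64)
    for direction in (-1, 1):
        for i in range(H):
            labels[i] = haps[i, core] + 1
        prev_d = 0.0
        prev_eo = 1.0
        prev_er = 1.0
        j = core + direction
        stopped = False
        while 0 <= j < S:
            for i in range(H):
                key[i] = labels[i] * 3 + haps[i, j] + 1
            order = np.argsort(key)
            c = 0
            prev_key = key[order[0]]
            for k in range(H):
                if key[order[k]] != prev_key:
                    c += 1
                    prev_key = key[order[k]]
                labels[order[k]] = c
            for g in range(c + 1):
                cnt_o[g] = 0
                cnt_r[g] = 0
            for i in range(H):
                if obs_mask[i]:
                    cnt_o[labels[i]] += 1
                else:
                    cnt_r[labels[i]] += 1
            so = 0
            sr = 0
            sp = 0
            for g in range(c + 1):
                so += cnt_o[g] * (cnt_o[g] - 1)
                sr += cnt_r[g] * (cnt_r[g] - 1)
                tot = cnt_o[g] + cnt_r[g]
                sp += tot * (tot - 1)
            eo = so / (n_obs * (n_obs - 1))
            er = sr / (n_ref * (n_ref - 1))
            ep = sp / (H * (H - 1))
            d = abs(pos[j] - pos[core])
            ihh[0] += 0.5 * (prev_eo + eo) * (d - prev_d)
            ihh[1] += 0.5 * (prev_er + er) * (d - prev_d)
            prev_d, prev_eo, prev_er = d, eo, er
            if ep < cutoff:
                stopped = True
                break
            j += direction
        if not stopped:
            truncated = True
    return ihh[0], ihh[1], truncated


def _scan_core_python(haps, pos, core, obs_mask, cutoff):
    """Reference implementation of the pooled-bound per-core walk."""
    H, S = haps.shape
    n_obs = int(obs_mask.sum())
    n_ref = H - n_obs
    ihh = [0.0, 0.0]
    truncated = False
    for direction in (-1, 1):
        labels = haps[:, core].astype(np.int64) + 1
        prev_d, prev_eo, prev_er = 0.0, 1.0, 1.0
        j = core + direction
        stopped = False
        while 0 <= j < S:
            _, labels = np.unique(
                labels * 3 + (haps[:, j].astype(np.int64) + 1), return_inverse=True
            )
            n_groups = int(labels.max()) + 1
            co = np.bincount(labels[obs_mask], minlength=n_groups)
            ct = np.bincount(labels, minlength=n_groups)
            cr = ct - co
            eo = float((co * (co - 1)).sum()) / (n_obs * (n_obs - 1))
            er = float((cr * (cr - 1)).sum()) / (n_ref * (n_ref - 1))
            ep = float((ct * (ct - 1)).sum()) / (H * (H - 1))
            d = abs(float(pos[j] - pos[core]))
            ihh[0] += 0.5 * (prev_eo + eo) * (d - prev_d)
            ihh[1] += 0.5 * (prev_er + er) * (d - prev_d)
            prev_d, prev_eo, prev_er = d, eo, er
            if ep < cutoff:
                stopped = True
                break
            j += direction
        if not stopped:
            truncated = True
    return ihh[0], ihh[1], truncated


def pseudo_phase(panel: GenotypePanel, seed: int) -> GenotypePanel:
    """Deterministic random phasing of an unphased panel.

    Heterozygote alleles are assigned to the two haplotype rows by a
    seeded coin flip; homozygous and missing genotypes phase trivially.
    Only for statistics robust to phase noise — no LD model is used.
    """
    rng = np.random.default_rng(seed)
    g = panel.genotypes
    n, s = g.shape
    h = np.zeros((2 * n, s), dtype=np.int8)
    first = rng.integers(0, 2, size=g.shape).astype(np.int8)
    h[0::2] = np.where(g == 1, first, np.where(g == 2, 1, np.where(g == 0, 0, -1)))
    h[1::2] = np.where(g == 1, 1 - first, np.where(g == 2, 1, np.where(g == 0, 0, -1)))
    out = panel.take_sites(np.ones(s, dtype=bool))
    out.haplotypes = h
    out.validate()
    return out


def xpehh_scores(
    panel: GenotypePanel,
    obs_pop: str,
    ref_pop: str,
    params: XPEHHParams | None = None,
) -> pd.DataFrame:
    """XP-EHH per core SNP for the observed vs the reference population.

    EHH is computed separately per population over all of its haplotypes;
    the integration stop point per side is where the pooled
    two-population EHH drops below ``stop_cutoff`` (shared bounds).
    Cores whose integration runs off a contig end are flagged truncated
    and excluded from the z-normalization unless ``include_truncated``.

    Returns ``contig, pos, ihh_obs, ihh_ref, raw, z, truncated``; ``raw``
    and ``z`` are NaN where either iHH is zero.
    """
    params = params or XPEHHParams()
    if not panel.phased:
        if params.pseudo_phase_seed is None:
            raise ValueError(
                "panel is unphased: set XPEHHParams.pseudo_phase_seed to "
                "enable deterministic pseudo-phasing"
            )
        panel = pseudo_phase(panel, params.pseudo_phase_seed)

    obs_rows = panel.haplotype_indices(obs_pop)
    ref_rows = panel.haplotype_indices(ref_pop)
    if obs_rows.size < params.min_haplotypes or ref_rows.size < params.min_haplotypes:
        raise ValueError("too few haplotypes in one of the populations")
    scan = _scan_core_numba if params.engine == "numba" else _scan_core_python

    rows = []
    contigs = panel.sites["contig"].to_numpy()
    for contig in dict.fromkeys(contigs):
        on = np.flatnonzero(contigs == contig)
        haps = np.ascontiguousarray(
            panel.haplotypes[np.concatenate([obs_rows, ref_rows])][:, on]
        )
        obs_mask = np.zeros(haps.shape[0], dtype=np.bool_)
        obs_mask[: obs_rows.size] = True
        pos = panel.sites["pos"].to_numpy()[on].astype(np.float64)
        # cores: polymorphic in the pooled two-population sample
        alt = (haps == 1).sum(axis=0)
        poly = np.flatnonzero((alt > 0) & (alt < haps.shape[0]))
        for core in poly:
            ihh_o, ihh_r, trunc = scan(haps, pos, core, obs_mask, params.stop_cutoff)
            raw = math.log(ihh_o / ihh_r) if ihh_o > 0 and ihh_r > 0 else float("nan")
            rows.append(
                {"contig": contig, "pos": int(pos[core]), "ihh_obs": ihh_o,
                 "ihh_ref": ihh_r, "raw": raw, "truncated": bool(trunc)}
            )
    out = pd.DataFrame(rows, columns=["contig", "pos", "ihh_obs", "ihh_ref", "raw", "truncated"])
    use = np.isfinite(out["raw"].to_numpy(float))
    if not params.include_truncated:
        use &= ~out["truncated"].to_numpy()
    raws = out["raw"].to_numpy(float)[use]
    out["z"] = np.nan
    if raws.size >= 2 and raws.std(ddof=1) > 0:
        out.loc[use, "z"] = (out.loc[use, "raw"] - raws.mean()) / raws.std(ddof=1)
    return out[["contig", "pos", "ihh_obs", "ihh_ref", "raw", "z", "truncated"]]
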