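"""End-to-end orchestration: filter -> site statistics -> ZHp -> XP-EHH ->
window significance -> candidate regions, with TSV/BED/JSON reports.

Every stage logs its parameters and counts; the run summary JSON records
counts at each stage so they can be cross-checked (sites out of filtering
equal sites into statistics, and so on).  A stage failure aborts the run
with the stage name; outputs written so far keep a ``.partial`` marker.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotype_io, region_calling, site_statistics, window_significance, zhp_scan
from .genotype_io import FilterConfig
from .panel import GenotypePanel
from .window_significance import SignificanceParams
from .xpehh_scan import XPEHHParams, xpehh_scores
from .zhp_scan import ZHpParams

log = logging.getLogger(__name__)

STAGES = ["read", "filter", "stats", "zhp", "xpehh", "windows", "regions", "summary"]


class ConfigError(Exception):
    """Bad or missing configuration / input paths."""


class DataError(Exception):
    """Input data violate a precondition."""


class StageError(Exception):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    vcf: str
    popmap: str
    out_dir: str
    known_sites: str | None = None
    genes: str | None = None
    obs_pop: str | None = None   # population scanned for sweeps (default: first)
    ref_pop: str | None = None   # XP-EHH reference population (default: second)
    seed: int = 0
    filters: FilterConfig = field(default_factory=FilterConfig)
    zhp: ZHpParams = field(default_factory=ZHpParams)
    xpehh: XPEHHParams = field(default_factory=XPEHHParams)
    significance: SignificanceParams = field(default_factory=SignificanceParams)
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("vcf", "popmap", "known_sites", "genes"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} file not found: {p}")


def _resolve_pops(config: RunConfig, panel: GenotypePanel) -> tuple[str, str]:
    pops = panel.populations
    if len(pops) < 2:
        raise DataError("pipeline needs at least two populations")
    obs = config.obs_pop or pops[0]
    ref = config.ref_pop or next(p for p in pops if p != obs)
    for p in (obs, ref):
        if p not in pops:
            raise DataError(f"population {p!r} not present in the panel")
    return obs, ref


def run_pipeline(config: RunConfig) -> dict:
    """Run the full scan and write the report bundle into ``out_dir``.

    Returns the run summary dict (also written as ``run_summary.json``).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}
    stage = "read"
    try:
        panel = genotype_io.read_vcf(config.vcf, config.popmap)
        obs_pop, ref_pop = _resolve_pops(config, panel)
        summary["obs_pop"], summary["ref_pop"] = obs_pop, ref_pop
        summary["stages"]["read"] = {"sites_in": panel.n_sites, "samples": panel.n_samples}

        stage = "filter"
        keep, fail_counts = genotype_io.filter_mask(panel, config.filters)
        filtered = panel.take_sites(keep)
        genotype_io.write_vcf(filtered, out / "filtered.vcf")
        summary["stages"]["filter"] = {
            "sites_in": panel.n_sites,
            "sites_out": filtered.n_sites,
            "failures_per_filter": fail_counts,
        }
        log.info("filter: %d -> %d sites", panel.n_sites, filtered.n_sites)

        stage = "stats"
        pop_rows = [site_statistics.population_summary(filtered, p) for p in filtered.populations]
        genotype_io.write_table(pd.DataFrame(pop_rows), out / "population_summary.tsv")
        _, pair_table = site_statistics.population_snp_sets(filtered)
        genotype_io.write_table(pair_table, out / "snp_set_tallies.tsv")
        pi_frames = []
        for p in filtered.populations:
            pw = site_statistics.windowed_pi(filtered, p)
            pw.insert(0, "population", p)
            pi_frames.append(pw)
        genotype_io.write_table(pd.concat(pi_frames), out / "pi_windows.tsv")
        stats_stage = {
            "sites_in": filtered.n_sites,
            "mean_pi": {
                p: site_statistics.mean_pi(f.drop(columns="population"))
                for p, f in zip(filtered.populations, pi_frames)
            },
        }
        if config.known_sites:
            known = genotype_io.read_known_sites(config.known_sites)
            _, ks = genotype_io.classify_known_novel(filtered, known)
            stats_stage["known_novel"] = ks
        summary["stages"]["stats"] = stats_stage

        stage = "zhp"
        zhp_table = zhp_scan.zhp_scan(filtered, obs_pop, config.zhp)
        genotype_io.write_table(zhp_table, out / "zhp_windows.tsv")
        summary["stages"]["zhp"] = {
            "windows_retained": len(zhp_table),
            "candidates": int(zhp_table["candidate"].sum()),
            "zhp_min": float(zhp_table["zhp"].min()),
        }

        stage = "xpehh"
        scores = xpehh_scores(filtered, obs_pop, ref_pop, config.xpehh)
        genotype_io.write_table(scores, out / "xpehh_scores.tsv")
        summary["stages"]["xpehh"] = {
            "cores_scored": int(np.isfinite(scores["z"].to_numpy(float)).sum()),
            "cores_truncated": int(scores["truncated"].sum()),
        }

        stage = "windows"
        sig = window_significance.score_windows(
            scores, filtered.contig_lengths, config.significance
        )
        genotype_io.write_table(sig, out / "xpehh_windows.tsv")
        summary["stages"]["windows"] = {
            "windows_scored": len(sig),
            "significant": int(sig["significant"].sum()) if len(sig) else 0,
        }

        stage = "regions"
        zhp_regions = region_calling.merge_regions(
            zhp_table[zhp_table["candidate"]], "zhp", "zhp"
        )
        xp_regions = region_calling.merge_regions(
            sig[sig["significant"]], "xpehh", "max_score"
        )
        non_empty = [r for r in (zhp_regions, xp_regions) if len(r)]
        regions = (
            pd.concat(non_empty, ignore_index=True)
            if non_empty
            else pd.DataFrame(columns=region_calling.REGION_COLUMNS)
        )
        bed_lines = [
            f"{r.contig}\t{r.start}\t{r.end}\t{r.method}\t{r.best_stat:.4f}\n"
            for r in regions.itertuples()
        ]
        (out / "candidate_regions.bed").write_text("".join(bed_lines))
        regions_stage = {
            "zhp_regions": len(zhp_regions),
            "xpehh_regions": len(xp_regions),
        }
        if config.genes:
            genes = region_calling.read_genes(config.genes)
            zhp_rep, zhp_genes = region_calling.genes_in_regions(zhp_regions, genes)
            xp_rep, xp_genes = region_calling.genes_in_regions(xp_regions, genes)
            genotype_io.write_table(
                pd.concat([zhp_rep, xp_rep], ignore_index=True), out / "region_genes.tsv"
            )
            ov = region_calling.method_overlap(zhp_genes, xp_genes)
            regions_stage.update(
                genes_zhp=len(zhp_genes),
                genes_xpehh=len(xp_genes),
                genes_shared=len(ov["shared"]),
            )
        summary["stages"]["regions"] = regions_stage

        stage = "summary"
        manhattan = _manhattan_table(zhp_table, sig)
        genotype_io.write_table(manhattan, out / "manhattan.tsv")
        (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    except (ConfigError, DataError):
        raise
    except Exception as exc:  # noqa: BLE001 - abort with the failing stage named
        (out / f"{stage}.partial").write_text("")
        raise StageError(stage, exc) from exc
    return summary


def _manhattan_table(zhp_table: pd.DataFrame, sig: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready rows: window midpoints with statistic and -log10 p (XP-EHH)."""
    rows = []
    for r in zhp_table.itertuples():
        rows.append({"method": "zhp", "contig": r.contig,
                     "mid": (r.start + r.end) // 2, "statistic": r.zhp,
                     "neg_log10_p": np.nan})
    for r in sig.itertuples():
        p = r.empirical_p
        rows.append({"method": "xpehh", "contig": r.contig,
                     "mid": (r.start + r.end) // 2, "statistic": r.max_score,
                     "neg_log10_p": -np.log10(p) if p > 0 else np.nan})
    return pd.DataFrame(rows, columns=["method", "contig", "mid", "statistic", "neg_log10_p"])


def config_from_yaml(path: str | Path, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file; keyword overrides win."""
    import yaml

    data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    for key, cls in (("filters", FilterConfig), ("zhp", ZHpParams),
                     ("xpehh", XPEHHParams), ("significance", SignificanceParams)):
        if key in data and isinstance(data[key], dict):
            data[key] = cls(**data[key])
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(config: RunConfig) -> dict:
    return asdict(config)
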