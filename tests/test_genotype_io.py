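import numpy as np
import pandas as pd
import pytest

from selsweep import (
    FilterConfig,
    apply_site_filters,
    classify_known_novel,
    novel_summary,
    read_pop_map,
    read_vcf,
    write_vcf,
)
from selsweep.genotype_io import filter_mask

from conftest import panel_from_haplotypes, random_panel

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1,length=100000>
##INFO=<ID=QD,Number=1,Type=Float,Description="qd">
##INFO=<ID=MQ,Number=1,Type=Float,Description="mq">
##INFO=<ID=FS,Number=1,Type=Float,Description="fs">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsA\tsB
"""


def write_popmap(tmp_path, samples={"sA": "P1", "sB": "P2"}):
    p = tmp_path / "popmap.txt"
    p.write_text("".join(f"{s}\t{pop}\n" for s, pop in samples.items()))
    return p


def test_read_vcf_phased_snps(tmp_path):
    """Three phased SNP records parse into a 3-site panel with haplotypes."""
    vcf = tmp_path / "a.vcf"
    vcf.write_text(
        VCF_HEADER
        + "1\t100\t.\tA\tG\t50\tPASS\tQD=20;MQ=55;FS=1\tGT\t0|1\t1|1\n"
        + "1\t200\t.\tC\tT\t60\tPASS\tQD=25;MQ=50;FS=2\tGT\t0|0\t0|1\n"
        + "1\t300\t.\tG\tA\t70\tPASS\tQD=30;MQ=58;FS=0\tGT\t1|0\t0|0\n"
    )
    panel = read_vcf(vcf, write_popmap(tmp_path))
    assert panel.n_sites == 3 and panel.n_samples == 2
    assert panel.phased
    assert panel.haplotypes[:, 0].tolist() == [0, 1, 1, 1]
    assert panel.genotypes[:, 0].tolist() == [1, 2]
    assert panel.contig_lengths == {"1": 100000}


def test_read_vcf_drops_non_snp_records(tmp_path):
    """An indel among 5 SNPs is dropped; the panel keeps the 5 SNPs."""
    body = [f"1\t{100 * (i + 1)}\t.\tA\tG\t50\tPASS\tQD=20\tGT\t0|1\t1|1" for i in range(5)]
    body.insert(2, "1\t250\t.\tAT\tA\t50\tPASS\tQD=20\tGT\t0|1\t1|1")
    vcf = tmp_path / "a.vcf"
    vcf.write_text(VCF_HEADER + "\n".join(body) + "\n")
    panel = read_vcf(vcf, write_popmap(tmp_path))
    assert panel.n_sites == 5
    assert panel.sites["pos"].tolist() == [100, 200, 300, 400, 500]


def test_read_vcf_unknown_sample_errors(tmp_path):
    vcf = tmp_path / "a.vcf"
    vcf.write_text(VCF_HEADER + "1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0|1\t1|1\n")
    pm = write_popmap(tmp_path, {"sA": "P1"})
    with pytest.raises(ValueError, match="sB"):
        read_vcf(vcf, pm)


def test_vcf_round_trip_and_idempotence(tmp_path):
    """write(read(f)) preserves the panel; write-read-write is byte-identical."""
    rng = np.random.default_rng(7)
    panel = random_panel(rng, n_samples=6, n_sites=15, missing_rate=0.1)
    panel.sites["qual"] = np.round(rng.uniform(30, 900, panel.n_sites), 1)
    panel.sites["qd"] = np.round(rng.uniform(5, 35, panel.n_sites), 1)
    f1, f2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
    write_vcf(panel, f1)
    pm = write_popmap(tmp_path, {s: panel.pop_map[s] for s in panel.sample_ids})
    back = read_vcf(f1, pm)
    assert back.sample_ids == panel.sample_ids
    pd.testing.assert_frame_equal(back.sites, panel.sites, check_dtype=False)
    assert np.array_equal(back.genotypes, panel.genotypes)
    assert np.array_equal(back.haplotypes, panel.haplotypes)
    write_vcf(back, f2)
    assert f1.read_bytes() == f2.read_bytes()


def test_read_pop_map_skips_comments(tmp_path):
    p = tmp_path / "pm.txt"
    p.write_text("# header\nsA P1\n\nsB\tP2\n")
    assert read_pop_map(p) == {"sA": "P1", "sB": "P2"}


class TestSiteFilters:
    def _panel(self, **info):
        # 2 sites x 41 samples; site 0 carries the INFO values under test
        n = 41
        haps = np.zeros((2 * n, 2), dtype=np.int8)
        haps[:20, 0] = 1  # MAF well above threshold at site 0
        haps[:20, 1] = 1
        qual = [info.get("qual", 50.0), 50.0]
        qd = [info.get("qd", 20.0), 20.0]
        mq = [info.get("mq", 55.0), 55.0]
        fs = [info.get("fs", 1.0), 1.0]
        return panel_from_haplotypes(
            haps, [100, 200], ["P"] * n, qual=qual, qd=qd, mq=mq, fs=fs
        )

    def test_boundary_values_pass(self):
        """QD=5, MQ=40, FS=200, QUAL=30 are all inclusive boundaries."""
        panel = self._panel(qd=5.0, mq=40.0, fs=200.0, qual=30.0)
        assert apply_site_filters(panel).n_sites == 2

    @pytest.mark.parametrize(
        "info", [{"qd": 4.9}, {"mq": 39.9}, {"fs": 200.1}, {"qual": 29.9}]
    )
    def test_failing_metric_removes_site(self, info):
        panel = self._panel(**info)
        filtered = apply_site_filters(panel)
        assert filtered.n_sites == 1
        assert filtered.sites["pos"].tolist() == [200]

    def test_missing_info_metric_passes(self):
        panel = self._panel()
        panel.sites.loc[0, ["qd", "mq", "fs"]] = np.nan
        assert apply_site_filters(panel).n_sites == 2

    def test_maf_threshold_on_82_alleles(self):
        """41 diploids: one minor allele gives MAF 1/82 > 0.01 (kept);
        a monomorphic site has MAF 0 <= 0.01 (removed)."""
        n = 41
        haps = np.zeros((2 * n, 2), dtype=np.int8)
        haps[0, 0] = 1  # singleton at site 0; site 1 monomorphic
        panel = panel_from_haplotypes(
            haps, [100, 200], ["P"] * n, qual=[50.0] * 2, qd=[20.0] * 2,
            mq=[55.0] * 2, fs=[1.0] * 2,
        )
        filtered = apply_site_filters(panel)
        assert filtered.sites["pos"].tolist() == [100]

    def test_call_rate_filter(self):
        n = 41
        haps = np.zeros((2 * n, 2), dtype=np.int8)
        haps[:20, :] = 1
        haps[0:10, 0] = -1  # 5 samples missing at site 0 -> call rate 36/41 < 0.9
        panel = panel_from_haplotypes(
            haps, [100, 200], ["P"] * n, qual=[50.0] * 2, qd=[20.0] * 2,
            mq=[55.0] * 2, fs=[1.0] * 2,
        )
        assert apply_site_filters(panel).sites["pos"].tolist() == [200]

    def test_filtering_idempotent_and_conjunctive(self):
        """Filtering twice equals once, and the kept set is the AND of
        the individual sub-filter masks."""
        rng = np.random.default_rng(11)
        panel = random_panel(rng, n_samples=12, n_sites=40, missing_rate=0.05)
        panel.sites["qd"] = rng.uniform(0, 40, panel.n_sites).round(1)
        panel.sites["mq"] = rng.uniform(20, 70, panel.n_sites).round(1)
        panel.sites["qual"] = rng.uniform(0, 200, panel.n_sites).round(1)
        once = apply_site_filters(panel)
        twice = apply_site_filters(once)
        pd.testing.assert_frame_equal(once.sites, twice.sites)
        keep, _ = filter_mask(panel)
        single_masks = []
        base = FilterConfig(qd_min=-1e9, mq_min=-1e9, fs_max=1e9, qual_min=-1e9,
                            call_rate_min=0.0, maf_min_exclusive=0.0)
        for attr, val in [("qd_min", 5.0), ("mq_min", 40.0), ("fs_max", 200.0),
                          ("qual_min", 30.0), ("call_rate_min", 0.9),
                          ("maf_min_exclusive", 0.01)]:
            cfg = FilterConfig(**{**base.__dict__, attr: val})
            m, _ = filter_mask(panel, cfg)
            single_masks.append(m)
        assert np.array_equal(keep, np.logical_and.reduce(single_masks))


class TestKnownNovel:
    def test_counts_partition_sites(self):
        rng = np.random.default_rng(3)
        panel = random_panel(rng, n_samples=4, n_sites=30)
        known = {("1", int(p)) for p in panel.sites["pos"][::3]}
        flags, summary = classify_known_novel(panel, known)
        assert summary["known_count"] + summary["novel_count"] == panel.n_sites
        assert summary["known_count"] == int(flags.sum()) == 10

    def test_empty_known_set_all_novel(self):
        panel = random_panel(np.random.default_rng(4), n_samples=3, n_sites=10)
        _, summary = classify_known_novel(panel, set())
        assert summary["novel_fraction"] == 1.0

    def test_full_known_set_no_novel(self):
        panel = random_panel(np.random.default_rng(5), n_samples=3, n_sites=10)
        known = {("1", int(p)) for p in panel.sites["pos"]}
        _, summary = classify_known_novel(panel, known)
        assert summary["novel_fraction"] == 0.0

    def test_empty_panel_errors(self):
        panel = random_panel(np.random.default_rng(6), n_samples=3, n_sites=5)
        empty = panel.take_sites(np.zeros(5, dtype=bool))
        with pytest.raises(ValueError):
            classify_known_novel(empty, set())

    def test_novel_summary_rounding(self):
        assert novel_summary(3, 1)["novel_fraction"] == 0.25
        with pytest.raises(ValueError):
            novel_summary(0, 0)
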