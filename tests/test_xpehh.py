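import itertools

import numpy as np
import pytest

from selsweep import XPEHHParams, ehh_curve, integrate_ihh, pseudo_phase, xpehh_scores
from selsweep.xpehh_scan import EHHCurve

from conftest import panel_from_haplotypes, random_panel


def brute_force_ehh(haps, core, marker, direction):
    """Fraction of haplotype pairs identical over [core..marker], by
    exhaustive pair enumeration."""
    lo, hi = (marker, core) if direction < 0 else (core, marker)
    segs = [tuple(h[lo : hi + 1]) for h in haps]
    pairs = list(itertools.combinations(segs, 2))
    return sum(1 for a, b in pairs if a == b) / len(pairs)


class TestEhhCurve:
    def test_identical_haplotypes_stay_at_one(self):
        haps = np.tile([0, 1, 0, 1, 1], (6, 1)).astype(np.int8)
        pos = np.array([10, 20, 30, 40, 50])
        c = ehh_curve(haps, pos, 2, +1)
        assert c.ehh.tolist() == [1.0, 1.0, 1.0]
        assert c.truncated  # ran off the matrix with EHH above the cutoff

    def test_two_identical_pairs_give_one_third(self):
        """4 haplotypes forming two identical pairs at the flanking marker:
        EHH = (1+1)/C(4,2) = 1/3."""
        haps = np.array([[0, 0], [0, 0], [0, 1], [0, 1]], dtype=np.int8)
        c = ehh_curve(haps, np.array([100, 200]), 0, +1)
        assert c.ehh[1] == pytest.approx(1 / 3)

    def test_all_distinct_drops_to_zero(self):
        haps = np.array([[0, 0, 0], [0, 1, 0], [1, 0, 0], [1, 1, 0]], dtype=np.int8)
        c = ehh_curve(haps, np.array([1, 2, 3]), 0, +1)
        # core + first flanking marker already separates all four haplotypes
        assert c.ehh[1] == 0.0
        assert len(c.ehh) == 2  # walk stops once below the cutoff

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(8)
        haps = (rng.random((10, 30)) < 0.5).astype(np.int8)
        pos = np.arange(1, 31) * 100
        for direction in (-1, 1):
            c = ehh_curve(haps, pos, 15, direction, stop_cutoff=0.0)
            assert (np.diff(c.ehh) <= 1e-12).all()
            assert c.ehh[0] == 1.0

    def test_matches_pair_enumeration_oracle(self):
        """Grouping-formula EHH equals brute-force identical-pair fractions
        on panels of <= 12 haplotypes."""
        rng = np.random.default_rng(17)
        for trial in range(5):
            haps = (rng.random((12, 15)) < rng.uniform(0.2, 0.8)).astype(np.int8)
            pos = np.sort(rng.choice(np.arange(1, 5000), 15, replace=False))
            core = int(rng.integers(3, 12))
            for direction in (-1, 1):
                c = ehh_curve(haps, pos, core, direction, stop_cutoff=0.0)
                for k, p in enumerate(c.positions[1:], 1):
                    marker = int(np.flatnonzero(pos == p)[0])
                    assert c.ehh[k] == pytest.approx(
                        brute_force_ehh(haps, core, marker, direction)
                    )

    def test_too_few_haplotypes_error(self):
        with pytest.raises(ValueError):
            ehh_curve(np.zeros((1, 3), dtype=np.int8), np.array([1, 2, 3]), 1, 1)


class TestIntegrateIhh:
    def _curve(self, distances, ehh, truncated=False):
        d = np.asarray(distances)
        return EHHCurve(core_index=0, direction=1, positions=d, distances=d,
                        ehh=np.asarray(ehh, float), truncated=truncated)

    def test_rectangle_area(self):
        """EHH = 1 over 1000 bp each side: area 2 * 1000."""
        left = self._curve([0, 500, 1000], [1, 1, 1], truncated=True)
        right = self._curve([0, 500, 1000], [1, 1, 1], truncated=True)
        ihh, truncated = integrate_ihh(left, right)
        assert ihh == pytest.approx(2000.0)
        assert truncated

    def test_triangle_area(self):
        """EHH falling linearly 1 -> 0 over 1000 bp per side: area 2 * 500."""
        side = self._curve([0, 250, 500, 750, 1000], [1, 0.75, 0.5, 0.25, 0.0])
        ihh, truncated = integrate_ihh(side, side)
        assert ihh == pytest.approx(1000.0)
        assert not truncated

    def test_integration_stops_at_cutoff_marker(self):
        side = self._curve([0, 100, 200, 300], [1.0, 0.04, 0.9, 0.9])
        empty = self._curve([0], [1.0])
        ihh, _ = integrate_ihh(side, empty)
        assert ihh == pytest.approx(0.5 * (1.0 + 0.04) * 100)

    def test_empty_side_contributes_zero(self):
        side = self._curve([0, 1000], [1.0, 0.0])
        empty = self._curve([0], [1.0], truncated=True)
        ihh, truncated = integrate_ihh(side, empty)
        assert ihh == pytest.approx(500.0)
        assert truncated


class TestXpehhScores:
    def _two_pop_panel(self, rng, n_sites=40, distinct=False):
        half = (rng.random((12, n_sites)) < 0.5).astype(np.int8)
        other = (rng.random((12, n_sites)) < 0.5).astype(np.int8) if distinct else half.copy()
        haps = np.vstack([half, other])
        keep = (haps.sum(axis=0) > 0) & (haps.sum(axis=0) < 24)
        haps = haps[:, keep]
        pos = np.sort(rng.choice(np.arange(1, 100_000), haps.shape[1], replace=False))
        return panel_from_haplotypes(haps, pos, ["A"] * 6 + ["B"] * 6, contig_length=120_000)

    def test_identical_populations_raw_zero(self):
        panel = self._two_pop_panel(np.random.default_rng(3))
        scores = xpehh_scores(panel, "A", "B", XPEHHParams(engine="python"))
        raws = scores["raw"].to_numpy(float)
        assert np.allclose(raws[np.isfinite(raws)], 0.0)

    def test_swapping_populations_negates_raw(self):
        panel = self._two_pop_panel(np.random.default_rng(4), distinct=True)
        p = XPEHHParams(engine="python")
        ab = xpehh_scores(panel, "A", "B", p)["raw"].to_numpy(float)
        ba = xpehh_scores(panel, "B", "A", p)["raw"].to_numpy(float)
        finite = np.isfinite(ab) & np.isfinite(ba)
        assert np.allclose(ab[finite], -ba[finite])

    def test_engines_agree(self):
        panel = self._two_pop_panel(np.random.default_rng(5), distinct=True)
        a = xpehh_scores(panel, "A", "B", XPEHHParams(engine="numba"))
        b = xpehh_scores(panel, "A", "B", XPEHHParams(engine="python"))
        assert np.allclose(a["ihh_obs"], b["ihh_obs"])
        assert np.allclose(a["ihh_ref"], b["ihh_ref"])
        assert (a["truncated"] == b["truncated"]).all()

    def test_monomorphic_marker_cannot_split_groups(self):
        """A monomorphic marker leaves the EHH value at every real marker
        unchanged (the curve gains a knot but no new haplotype groups)."""
        rng = np.random.default_rng(6)
        haps = (rng.random((8, 11)) < 0.5).astype(np.int8)
        haps = haps[:, (haps.sum(axis=0) > 0) & (haps.sum(axis=0) < 8)]
        n = haps.shape[1]
        pos = np.arange(1, n + 1) * 500
        core = n // 2
        base = ehh_curve(haps, pos, core, +1, stop_cutoff=0.0)
        with_mono = np.insert(haps, core + 1, 0, axis=1)
        pos2 = np.insert(pos, core + 1, pos[core] + 250)
        aug = ehh_curve(with_mono, pos2, core, +1, stop_cutoff=0.0)
        by_pos = dict(zip(aug.positions.tolist(), aug.ehh.tolist()))
        for p, e in zip(base.positions.tolist(), base.ehh.tolist()):
            assert by_pos[p] == pytest.approx(e)
        assert len(aug.ehh) == len(base.ehh) + 1

    def test_normalized_scores_standardized(self, sweep_scores):
        z = sweep_scores.loc[~sweep_scores["truncated"], "z"].to_numpy(float)
        z = z[np.isfinite(z)]
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9

    def test_unphased_panel_requires_pseudo_phasing(self):
        panel = self._two_pop_panel(np.random.default_rng(7))
        panel.haplotypes = None
        with pytest.raises(ValueError, match="pseudo-phasing"):
            xpehh_scores(panel, "A", "B")
        phased = pseudo_phase(panel, seed=1)
        assert phased.phased
        scores = xpehh_scores(phased, "A", "B", XPEHHParams(engine="python"))
        assert len(scores) > 0

    def test_sweep_fixture_max_score_in_truth(self, sweep_fixture, sweep_scores):
        """The top normalized XP-EHH core lies inside the truth interval
        when the observed population carries the sweep."""
        _, truth = sweep_fixture
        top = sweep_scores.loc[sweep_scores["z"].idxmax()]
        assert truth.start <= top["pos"] - 1 < truth.end
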