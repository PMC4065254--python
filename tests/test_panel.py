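"""Marker ranking, bin selection, distances and gap detection."""

import numpy as np
import pandas as pd
import pytest

import minmod as mm
from minmod.panel import RepeatRule, assign_bins


def cand(chrom="1", pos=100, ref="A", alt="T", quality=99, flank=None,
         specificity="single-line"):
    return {
        "line_id": "g", "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "depth": 6, "genotype_quality": quality, "zygosity": "hom",
        "flank": flank if flank is not None else "ACGTACGTACGTACGTACGT",
        "specificity": specificity,
    }


class TestRanking:
    def test_transversion_preferred_over_transition(self):
        df = pd.DataFrame([
            cand(pos=1, ref="A", alt="G"),
            cand(pos=2, ref="A", alt="T"),
        ])
        ranked = mm.rank_candidates(df)
        assert list(ranked["pos"]) == [2, 1]

    def test_full_preference_order(self):
        df = pd.DataFrame([
            cand(pos=1, ref="G", alt="A"),   # group 2
            cand(pos=2, ref="C", alt="G"),   # group 3 (other)
            cand(pos=3, ref="T", alt="A"),   # group 0
            cand(pos=4, ref="T", alt="C"),   # group 1
        ])
        ranked = mm.rank_candidates(df)
        assert list(ranked["pos"]) == [3, 4, 1, 2]

    def test_related_pair_shared_outranks_single_line(self):
        df = pd.DataFrame([
            cand(pos=1, ref="A", alt="T", specificity="single-line"),
            cand(pos=2, ref="G", alt="A", specificity="related-pair-only"),
        ])
        ranked = mm.rank_candidates(df)
        assert list(ranked["pos"]) == [2, 1]

    def test_below_max_quality_excluded(self):
        df = pd.DataFrame([cand(pos=1, quality=98), cand(pos=2, quality=99)])
        ranked = mm.rank_candidates(df)
        assert list(ranked["pos"]) == [2]

    def test_homopolymer_flank_excluded(self):
        df = pd.DataFrame([
            cand(pos=1, flank="GCGT" + "A" * 10 + "TGCA"),
            cand(pos=2),
        ])
        ranked = mm.rank_candidates(df)
        assert list(ranked["pos"]) == [2]

    def test_dinucleotide_repeat_excluded(self):
        assert RepeatRule().is_repetitive("GG" + "AT" * 4 + "CC")
        assert not RepeatRule().is_repetitive("GGATATATCC")

    def test_strict_mode_drops_unpreferred_types(self):
        df = pd.DataFrame([cand(pos=1, ref="C", alt="G")])
        assert len(mm.rank_candidates(df, relax_types=False)) == 0
        assert len(mm.rank_candidates(df, relax_types=True)) == 1


class TestSelectPanel:
    sizes = mm.ChromSizes({str(i): 90_000_000 for i in range(1, 20)} | {"X": 90_000_000})

    def test_bins_are_equal_thirds(self):
        assert list(assign_bins(np.array([1, 30_000_000, 30_000_001, 90_000_000]), 90_000_000)) == [0, 0, 1, 2]

    def test_sparse_chromosome_reports_unfilled(self):
        df = mm.rank_candidates(pd.DataFrame([cand(chrom="1", pos=45_000_000)]))
        panel, unfilled = mm.select_panel(df, mm.ChromSizes({"1": 90_000_000}))
        assert len(panel) == 1
        assert panel.iloc[0]["bin"] == "middle"
        assert sorted(unfilled) == [("1", "distal"), ("1", "proximal")]

    def test_full_coverage_panel_size(self):
        rows = []
        for i, chrom in enumerate(self.sizes.autosomes):
            for pos in (10_000_000, 45_000_000, 80_000_000):
                rows.append(cand(chrom=chrom, pos=pos + i))
        panel, unfilled = mm.select_panel(mm.rank_candidates(pd.DataFrame(rows)), self.sizes)
        assert len(panel) == 57  # 3 bins x 19 autosomes
        assert unfilled == []

    def test_x_chromosome_excluded(self):
        df = mm.rank_candidates(pd.DataFrame([cand(chrom="X", pos=45_000_000)]))
        panel, _ = mm.select_panel(df, self.sizes)
        assert len(panel) == 0

    def test_equal_rank_tie_broken_by_bin_midpoint(self):
        # middle bin of a 90 Mb chromosome is (30, 60] Mb, midpoint 45 Mb
        df = mm.rank_candidates(pd.DataFrame([
            cand(chrom="1", pos=40_000_000),
            cand(chrom="1", pos=44_000_000),
            cand(chrom="1", pos=59_000_000),
        ]))
        panel, _ = mm.select_panel(df, mm.ChromSizes({"1": 90_000_000}))
        assert int(panel.iloc[0]["pos"]) == 44_000_000

    def test_idempotent_and_deterministic(self):
        rows = [cand(chrom="1", pos=p) for p in range(1_000_000, 90_000_000, 7_000_000)]
        ranked = mm.rank_candidates(pd.DataFrame(rows))
        p1, _ = mm.select_panel(ranked, mm.ChromSizes({"1": 90_000_000}))
        p2, _ = mm.select_panel(ranked, mm.ChromSizes({"1": 90_000_000}))
        pd.testing.assert_frame_equal(p1, p2)


class TestDistances:
    def test_simple_arithmetic(self):
        sites = pd.DataFrame({"chrom": ["1"] * 3, "pos": [100, 200, 400]})
        d = mm.intermarker_distances(sites)
        assert d["median"] == 150.0
        assert d["n"] == 2

    def test_equally_spaced_iqr_zero(self):
        sites = pd.DataFrame({"chrom": "1", "pos": np.arange(1, 50) * 1000})
        d = mm.intermarker_distances(sites)
        assert d["q75"] - d["q25"] == 0.0

    def test_order_invariant(self):
        pos = [500, 100, 900, 300]
        a = mm.intermarker_distances(pd.DataFrame({"chrom": "1", "pos": pos}))
        b = mm.intermarker_distances(pd.DataFrame({"chrom": "1", "pos": sorted(pos)}))
        assert a == b

    def test_within_chromosome_only(self):
        sites = pd.DataFrame({"chrom": ["1", "1", "2", "2"], "pos": [100, 200, 1000, 1300]})
        d = mm.intermarker_distances(sites)
        assert d["n"] == 2
        assert d["median"] == pytest.approx(200.0)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            mm.intermarker_distances(pd.DataFrame({"chrom": ["1"], "pos": [5]}))


class TestGaps:
    def test_interval_arithmetic_example(self):
        sites = pd.DataFrame({"chrom": ["1", "1"], "pos": [1_000_000, 40_000_000]})
        gaps = mm.find_gaps(sites, mm.ChromSizes({"1": 50_000_000}), min_gap=3e7)
        assert len(gaps) == 1
        g = gaps.iloc[0]
        assert g["start"] == 1_000_000
        assert g["end"] == 39_999_999
        assert g["length"] == pytest.approx(39_000_000, abs=1)

    def test_dense_sites_no_gaps(self):
        sites = pd.DataFrame({"chrom": "1", "pos": np.arange(1, 50_000_000, 1_000_000)})
        gaps = mm.find_gaps(sites, mm.ChromSizes({"1": 50_000_000}), min_gap=3e7)
        assert len(gaps) == 0

    def test_empty_chromosome_is_one_gap(self):
        gaps = mm.find_gaps(
            pd.DataFrame({"chrom": [], "pos": []}), mm.ChromSizes({"1": 50_000_000})
        )
        assert len(gaps) == 1
        assert (gaps.iloc[0]["start"], gaps.iloc[0]["end"]) == (0, 50_000_000)

    def test_agrees_with_grid_scan(self):
        """Cross-check against a brute-force 1-Mb grid scan on random
        site placements."""
        rng = np.random.default_rng(12)
        length = 150_000_000
        sizes = mm.ChromSizes({"1": length})
        for _ in range(5):
            pos = np.sort(rng.integers(1, length, size=8))
            sites = pd.DataFrame({"chrom": "1", "pos": pos})
            gaps = mm.find_gaps(sites, sizes, min_gap=3e7)
            grid = np.arange(0, length, 1_000_000)
            covered = np.zeros(len(grid), dtype=bool)
            for p in pos:
                covered |= np.abs(grid - p) < 500_000
            # a reported gap must contain a long run of uncovered grid points
            for _, g in gaps.iterrows():
                inside = (grid >= g["start"]) & (grid < g["end"])
                assert not covered[inside][1:-1].any()
                assert inside.sum() >= 28
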