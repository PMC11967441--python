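"""Interval validation, hotspot merging, QTN windows and candidate calling,
cross-checked against per-basepair brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from earphase import qtl
from oracles import oracle_candidates, oracle_flank, oracle_merge, oracle_overlap

CHROMS = {"chr1": 100_000, "chr2": 100_000}


def _qtl_frame(rows):
    return pd.DataFrame(rows, columns=["qtl_id", "study_id", "chrom", "start", "end"])


def _random_qtls(rng, n):
    rows = []
    for i in range(n):
        chrom = rng.choice(list(CHROMS))
        start = int(rng.integers(1, CHROMS[chrom] - 2000))
        rows.append((f"q{i}", f"S{rng.integers(1, 4)}", chrom, start,
                     start + int(rng.integers(50, 2000))))
    return _qtl_frame(rows)


class TestBuildIntervals:
    def test_swapped_coordinates_normalised(self):
        df = qtl.build_intervals(_qtl_frame([("q1", "S1", "chr1", 500, 100)]), CHROMS)
        assert (df.loc[0, "start"], df.loc[0, "end"]) == (100, 500)

    def test_unknown_chromosome_named_in_error(self):
        with pytest.raises(ValueError, match="chrX"):
            qtl.build_intervals(_qtl_frame([("q1", "S1", "chrX", 1, 10)]), CHROMS)

    def test_duplicates_collapsed_and_missing_dropped(self):
        df = qtl.build_intervals(
            pd.DataFrame(
                {"qtl_id": ["a", "b", "c"], "study_id": ["S1", "S1", "S2"],
                 "chrom": ["chr1", "chr1", None], "start": [10, 10, 5],
                 "end": [90, 90, 50]}
            ),
            CHROMS,
        )
        assert len(df) == 1

    def test_valid_table_passes_through(self):
        rng = np.random.default_rng(0)
        table = _random_qtls(rng, 25)
        assert len(qtl.build_intervals(table, CHROMS)) == 25


class TestMergeHotspots:
    def test_worked_single_linkage_example(self):
        table = _qtl_frame(
            [("q1", "S1", "chr1", 1, 100), ("q2", "S2", "chr1", 50, 150),
             ("q3", "S1", "chr1", 200, 300)]
        )
        hotspots = qtl.merge_hotspots(table)
        assert len(hotspots) == 1
        h = hotspots[0]
        assert (h.chrom, h.start, h.end, h.support) == ("chr1", 1, 150, 2)
        assert sorted(h.member_qtls) == ["q1", "q2"]

    def test_single_study_support_never_forms_hotspot(self):
        table = _qtl_frame(
            [("q1", "S1", "chr1", 1, 100), ("q2", "S1", "chr1", 50, 150)]
        )
        assert qtl.merge_hotspots(table) == []
        assert len(qtl.merge_hotspots(table, require_distinct_studies=False)) == 1

    def test_abutting_intervals_do_not_merge(self):
        table = _qtl_frame(
            [("q1", "S1", "chr1", 1, 100), ("q2", "S2", "chr1", 101, 200)]
        )
        assert qtl.merge_hotspots(table) == []
        # one shared basepair does merge
        table.loc[1, "start"] = 100
        assert len(qtl.merge_hotspots(table)) == 1

    def test_merging_is_idempotent(self):
        rng = np.random.default_rng(1)
        table = _random_qtls(rng, 40)
        hotspots = qtl.merge_hotspots(table, min_support=1, require_distinct_studies=False)
        as_table = _qtl_frame(
            [(h.hotspot_id, "S1", h.chrom, h.start, h.end) for h in hotspots]
        )
        again = qtl.merge_hotspots(as_table, min_support=1, require_distinct_studies=False)
        assert [(h.chrom, h.start, h.end) for h in again] == [
            (h.chrom, h.start, h.end) for h in hotspots
        ]

    def test_merging_is_order_invariant(self):
        rng = np.random.default_rng(2)
        table = _random_qtls(rng, 40)
        shuffled = table.sample(frac=1, random_state=3).reset_index(drop=True)
        a = qtl.merge_hotspots(table)
        b = qtl.merge_hotspots(shuffled)
        assert [(h.chrom, h.start, h.end, sorted(h.member_qtls)) for h in a] == [
            (h.chrom, h.start, h.end, sorted(h.member_qtls)) for h in b
        ]

    def test_emitted_hotspots_cover_members_and_never_overlap(self):
        rng = np.random.default_rng(4)
        table = _random_qtls(rng, 60)
        hotspots = qtl.merge_hotspots(table)
        for h in hotspots:
            members = table[table["qtl_id"].isin(h.member_qtls)]
            assert h.start == members["start"].min()
            assert h.end == members["end"].max()
        by_chrom: dict[str, list] = {}
        for h in hotspots:
            by_chrom.setdefault(h.chrom, []).append(h)
        for group in by_chrom.values():
            group.sort(key=lambda h: h.start)
            for a, b in zip(group, group[1:]):
                assert a.end < b.start

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_bp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = _random_qtls(rng, 30)
        hotspots = qtl.merge_hotspots(table)
        expected = oracle_merge(table)
        got = [
            {"chrom": h.chrom, "start": h.start, "end": h.end,
             "members": sorted(h.member_qtls), "support": h.support,
             "n_studies": h.n_studies}
            for h in hotspots
        ]
        assert got == expected


class TestQtnFlanks:
    def test_window_arithmetic_and_clamping(self):
        qtns = pd.DataFrame(
            {"qtn_id": ["a", "b"], "study_id": "S1", "chrom": "chr1",
             "pos": [150_000, 40_000]}
        )
        win = qtl.qtn_flanks(qtns, {"chr1": 1_000_000})
        assert tuple(win.loc[0, ["start", "end"]]) == (50_000, 250_000)
        assert tuple(win.loc[1, ["start", "end"]]) == (1, 140_000)

    def test_width_bounded_and_matches_oracle(self):
        rng = np.random.default_rng(5)
        qtns = pd.DataFrame(
            {"qtn_id": [f"t{i}" for i in range(50)], "study_id": "S1",
             "chrom": "chr1", "pos": rng.integers(1, 100_001, 50)}
        )
        win = qtl.qtn_flanks(qtns, CHROMS, flank=5_000)
        widths = win["end"] - win["start"] + 1
        assert (widths <= 2 * 5_000 + 1).all()
        for _, row in win.iterrows():
            lo, hi = oracle_flank(int(row["pos"]), 5_000, CHROMS["chr1"])
            assert (row["start"], row["end"]) == (lo, hi)

    def test_position_outside_chromosome_rejected(self):
        qtns = pd.DataFrame({"qtn_id": ["a"], "study_id": "S1", "chrom": "chr1",
                             "pos": [200_000]})
        with pytest.raises(ValueError):
            qtl.qtn_flanks(qtns, CHROMS)


class TestOverlapGenes:
    def test_shared_basepair_rule(self):
        genes = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "chrom": ["chr1", "chr2"],
             "start": [149_900, 100], "end": [151_000, 500]}
        )
        regions = pd.DataFrame(
            {"region_id": ["w1"], "chrom": ["chr1"], "start": [50_000], "end": [250_000]}
        )
        hits = qtl.overlap_genes(genes, regions)
        assert hits == {"g1": ["w1"]}

    def test_disjoint_chromosome_names_raise(self):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["1"], "start": [1], "end": [10]})
        regions = pd.DataFrame({"region_id": ["r"], "chrom": ["chr1"], "start": [1], "end": [10]})
        with pytest.raises(ValueError, match="chromosome"):
            qtl.overlap_genes(genes, regions)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_bp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(80)],
             "chrom": rng.choice(list(CHROMS), 80),
             "start": rng.integers(1, 95_000, 80)}
        )
        genes["end"] = genes["start"] + rng.integers(100, 3000, 80)
        regions = pd.DataFrame(
            {"region_id": [f"r{i}" for i in range(30)],
             "chrom": rng.choice(list(CHROMS), 30),
             "start": rng.integers(1, 90_000, 30)}
        )
        regions["end"] = regions["start"] + rng.integers(200, 8000, 30)
        assert qtl.overlap_genes(genes, regions) == oracle_overlap(genes, regions, "region_id")


class TestCallCandidates:
    def _setup(self):
        hotspots = [qtl.Hotspot("h1", "chr1", 1, 500_000, ["q1", "q2"], ["S1", "S2"])]
        qtns = pd.DataFrame(
            {"qtn_id": ["t1"], "study_id": "S3", "chrom": "chr1", "pos": [400_000]}
        )
        windows = qtl.qtn_flanks(qtns, {"chr1": 1_000_000})
        annotation = pd.DataFrame(
            {"gene_id": ["far", "near"], "chrom": "chr1",
             "start": [120_000, 310_000], "end": [121_000, 312_000]}
        )
        return hotspots, qtns, windows, annotation

    def test_common_region_requires_window_and_same_hotspot(self):
        hotspots, _, windows, annotation = self._setup()
        result = qtl.call_candidates({"far", "near"}, hotspots, windows, annotation)
        table = result.candidates.set_index("gene_id")
        assert not table.loc["far", "common_region"]     # hotspot only
        assert table.loc["near", "common_region"]        # hotspot + QTN window
        assert result.counts["n_tier1"] == 2
        assert result.counts["n_common_region"] == 1

    def test_no_qtns_means_no_common_region(self):
        hotspots, qtns, _, annotation = self._setup()
        empty = qtl.qtn_flanks(qtns.iloc[:0], {"chr1": 1_000_000})
        result = qtl.call_candidates({"far", "near"}, hotspots, empty, annotation)
        assert result.counts["n_common_region"] == 0
        assert result.counts["n_tier1"] == 2

    def test_candidates_are_subset_of_deg_set(self):
        hotspots, _, windows, annotation = self._setup()
        result = qtl.call_candidates({"near"}, hotspots, windows, annotation)
        assert set(result.candidates["gene_id"]) <= {"near"}

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_predicate(self, seed):
        rng = np.random.default_rng(seed)
        table = _random_qtls(rng, 30)
        hotspots = qtl.merge_hotspots(table)
        qtns = pd.DataFrame(
            {"qtn_id": [f"t{i}" for i in range(12)], "study_id": "S9",
             "chrom": rng.choice(list(CHROMS), 12),
             "pos": rng.integers(1, 100_001, 12)}
        )
        windows = qtl.qtn_flanks(qtns, CHROMS, flank=3_000)
        genes = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(60)],
             "chrom": rng.choice(list(CHROMS), 60),
             "start": rng.integers(1, 95_000, 60)}
        )
        genes["end"] = genes["start"] + rng.integers(100, 3000, 60)
        result = qtl.call_candidates(set(genes["gene_id"]), hotspots, windows, genes)
        expected = oracle_candidates(
            genes,
            [{"id": h.hotspot_id, "chrom": h.chrom, "start": h.start, "end": h.end}
             for h in hotspots],
            qtns, 3_000, CHROMS,
        )
        got = {
            row["gene_id"]: {
                "hotspots": sorted(filter(None, row["hotspot_ids"].split(","))),
                "windows": sorted(filter(None, row["qtn_ids"].split(","))),
                "common": bool(row["common_region"]),
            }
            for _, row in result.candidates.iterrows()
        }
        assert got == expected


class TestAnnotateTfs:
    def _candidates(self):
        return pd.DataFrame(
            {"gene_id": ["g1", "g2", "g3"], "hotspot_ids": ["h1", "", "h1"],
             "qtn_ids": ["", "t1", "t1"], "common_region": [False, False, True]}
        )

    def test_empty_table_gives_no_annotations(self):
        annotated, tally = qtl.annotate_tfs(self._candidates(), pd.DataFrame(columns=["gene_id", "family"]))
        assert (annotated["tf_family"] == "").all()
        assert tally.empty

    def test_family_attached_verbatim_and_tally_partitions(self):
        tf = pd.DataFrame({"gene_id": ["g1", "g3"], "family": ["SBP-box", "AP2/EREBP"]})
        annotated, tally = qtl.annotate_tfs(self._candidates(), tf)
        assert annotated.set_index("gene_id").loc["g1", "tf_family"] == "SBP-box"
        assert annotated.set_index("gene_id").loc["g2", "tf_family"] == ""
        assert tally["n_genes"].sum() == 2
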