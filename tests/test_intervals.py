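"""Interval model, BED/RepeatMasker I/O, and interval-algebra oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dupliconevo import (
    GenomeLandscape,
    GenomicInterval,
    RegionSet,
    RepeatAnnotation,
    allowed_space,
    flanking_unique,
    merge_intervals,
    overlap_elements,
    read_bed,
    read_repeatmasker,
)
from dupliconevo.intervals import complement, normalize_repeat_class

from conftest import brute_force_overlap_count


def intervals_to_baseset(regions):
    out = set()
    for iv in regions:
        out.update((iv.chrom, b) for b in range(iv.start, iv.end))
    return out


class TestGenomicInterval:
    def test_rejects_zero_and_negative_length(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_length(self):
        assert len(GenomicInterval("chr1", 5, 9)) == 4


class TestReadBed:
    def test_browser_style_duplicon_line(self, tmp_path):
        # a 14.5 kbp duplicon given in 1-based browser coordinates
        p = tmp_path / "dup.bed"
        p.write_text("chr4\t155451842\t155466390\tLCR16a-003\n")
        rs = read_bed(p, one_based=True)
        assert rs.n_regions == 1
        assert len(rs[0]) == 14_548 + 1  # inclusive coords span one extra base
        rs0 = read_bed(p)  # BED semantics
        assert len(rs0[0]) == 14_548

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_bed(p).n_regions == 0

    def test_zero_length_line_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t5\t10\tok\nchr1\t7\t7\tbad\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(p)

    def test_too_few_columns(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t5\n")
        with pytest.raises(ValueError, match="line 1"):
            read_bed(p)

    def test_order_and_names_preserved(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chrB\t10\t20\tx\nchrA\t5\t8\ty\n")
        rs = read_bed(p)
        assert [iv.chrom for iv in rs] == ["chrB", "chrA"]
        assert [iv.name for iv in rs] == ["x", "y"]


class TestMerge:
    def test_overlapping(self):
        rs = RegionSet([GenomicInterval("c", 10, 50), GenomicInterval("c", 40, 80)])
        merged = merge_intervals(rs)
        assert [(iv.start, iv.end) for iv in merged] == [(10, 80)]
        assert intervals_to_baseset(merged) == intervals_to_baseset(rs)

    def test_abutting_merged(self):
        rs = RegionSet([GenomicInterval("c", 10, 20), GenomicInterval("c", 20, 30)])
        assert merge_intervals(rs).n_regions == 1

    def test_disjoint_unchanged(self):
        rs = RegionSet([GenomicInterval("c", 10, 20), GenomicInterval("c", 30, 40)])
        assert merge_intervals(rs).n_regions == 2

    @given(
        st.lists(
            st.tuples(st.integers(0, 200), st.integers(1, 30)),
            min_size=1,
            max_size=20,
        )
    )
    @settings(derandomize=True, max_examples=60)
    def test_merge_matches_baseset_union_and_is_idempotent(self, raw):
        rs = RegionSet([GenomicInterval("c", s, s + l) for s, l in raw])
        merged = merge_intervals(rs)
        assert intervals_to_baseset(merged) == intervals_to_baseset(rs)
        again = merge_intervals(merged)
        assert [(iv.start, iv.end) for iv in again] == [
            (iv.start, iv.end) for iv in merged
        ]
        # nonoverlapping, non-abutting, sorted
        for a, b in zip(merged.intervals, merged.intervals[1:]):
            assert a.end < b.start


class TestAllowedSpace:
    def test_empty_mask_gives_whole_genome(self):
        land = GenomeLandscape(chrom_sizes={"c": 1000})
        out = allowed_space(land)
        assert [(iv.start, iv.end) for iv in out] == [(0, 1000)]

    def test_internal_mask_complement(self):
        land = GenomeLandscape(
            chrom_sizes={"c": 1000},
            exclusion_mask=RegionSet([GenomicInterval("c", 100, 200)]),
        )
        out = allowed_space(land)
        assert [(iv.start, iv.end) for iv in out] == [(0, 100), (200, 1000)]

    def test_fully_masked_chromosome_absent(self):
        land = GenomeLandscape(
            chrom_sizes={"a": 500, "b": 500},
            exclusion_mask=RegionSet([GenomicInterval("a", 0, 500)]),
        )
        out = allowed_space(land)
        assert {iv.chrom for iv in out} == {"b"}

    def test_whole_genome_masked_errors(self):
        land = GenomeLandscape(
            chrom_sizes={"a": 500},
            exclusion_mask=RegionSet([GenomicInterval("a", 0, 500)]),
        )
        with pytest.raises(ValueError):
            allowed_space(land)

    @given(
        st.lists(
            st.tuples(st.integers(0, 900), st.integers(1, 150)),
            max_size=10,
        )
    )
    @settings(derandomize=True, max_examples=40)
    def test_mask_and_complement_partition_chromosome(self, raw):
        ivs = [GenomicInterval("c", s, min(s + l, 1000)) for s, l in raw if s < 1000]
        mask = RegionSet(ivs)
        comp = complement(mask, {"c": 1000})
        mask_bases = intervals_to_baseset(merge_intervals(mask) if ivs else mask)
        comp_bases = intervals_to_baseset(comp)
        assert mask_bases | comp_bases == {("c", b) for b in range(1000)}
        assert not mask_bases & comp_bases


class TestFlankingUnique:
    def test_unobstructed(self):
        land = GenomeLandscape(chrom_sizes={"c": 1_000_000})
        block = GenomicInterval("c", 50_000, 60_000, name="blk")
        out = flanking_unique(block, land, flank_len=10_000)
        assert [(iv.start, iv.end) for iv in out] == [(40_000, 50_000), (60_000, 70_000)]

    def test_block_at_chrom_start_truncates_left(self):
        land = GenomeLandscape(chrom_sizes={"c": 1_000_000})
        block = GenomicInterval("c", 0, 10_000)
        out = flanking_unique(block, land, flank_len=10_000)
        assert [(iv.start, iv.end) for iv in out] == [(10_000, 20_000)]

    def test_walk_skips_duplicated_segment(self):
        # an SD abuts the block on the right: unique bases start after it
        sd = GenomicInterval("c", 60_000, 65_000)
        uniq = complement(RegionSet([sd]), {"c": 1_000_000})
        land = GenomeLandscape(chrom_sizes={"c": 1_000_000}, unique_mask=uniq)
        block = GenomicInterval("c", 50_000, 60_000)
        out = flanking_unique(block, land, flank_len=10_000)
        right = [iv for iv in out if iv.start >= 60_000]
        assert [(iv.start, iv.end) for iv in right] == [(65_000, 75_000)]

    @given(
        st.lists(st.tuples(st.integers(0, 950), st.integers(1, 60)), max_size=8),
        st.integers(200, 700),
    )
    @settings(derandomize=True, max_examples=40)
    def test_walk_matches_base_level_oracle(self, sds, block_start):
        size = 1000
        flank = 50
        block = GenomicInterval("c", block_start, block_start + 20)
        sd_set = RegionSet(
            [GenomicInterval("c", s, min(s + l, size)) for s, l in sds if s < size]
        )
        uniq = complement(sd_set, {"c": size})
        land = GenomeLandscape(chrom_sizes={"c": size}, unique_mask=uniq)
        out = flanking_unique(block, land, flank_len=flank)
        got = intervals_to_baseset(out) if len(out) else set()
        # oracle: walk base-by-base outward collecting unique bases
        uniq_bases = intervals_to_baseset(uniq)
        expect = set()
        for rng_iter, limit in (
            (range(block.start - 1, -1, -1), flank),
            (range(block.end, size), flank),
        ):
            n = 0
            for b in rng_iter:
                if ("c", b) in uniq_bases:
                    expect.add(("c", b))
                    n += 1
                    if n >= limit:
                        break
        assert got == expect
        # never intersects the SD mask, bounded total
        assert not got & intervals_to_baseset(merge_intervals(sd_set) if len(sd_set) else sd_set)
        assert len(got) <= 2 * flank


class TestOverlapElements:
    def test_empty_and_single(self):
        regions = RegionSet([GenomicInterval("c", 100, 200)])
        assert overlap_elements(regions, [], "SINE") == 0
        rep = RepeatAnnotation(GenomicInterval("c", 150, 180), "SINE", "AluS")
        assert overlap_elements(regions, [rep], "SINE") == 1
        assert overlap_elements(regions, [rep], "LINE") == 0

    def test_element_spanning_two_regions_counts_once(self):
        regions = RegionSet(
            [GenomicInterval("c", 100, 200), GenomicInterval("c", 210, 300)]
        )
        rep = RepeatAnnotation(GenomicInterval("c", 150, 250), "LINE", "L1")
        assert overlap_elements(regions, [rep], "LINE") == 1

    @given(st.data())
    @settings(derandomize=True, max_examples=40)
    def test_matches_brute_force(self, data):
        regions = RegionSet(
            [
                GenomicInterval("c", s, s + l)
                for s, l in data.draw(
                    st.lists(
                        st.tuples(st.integers(0, 500), st.integers(1, 80)),
                        min_size=1,
                        max_size=8,
                    )
                )
            ]
        )
        repeats = [
            RepeatAnnotation(GenomicInterval("c", s, s + l), "SINE", "Alu")
            for s, l in data.draw(
                st.lists(
                    st.tuples(st.integers(0, 550), st.integers(1, 40)), max_size=25
                )
            )
        ]
        assert overlap_elements(regions, repeats, "SINE") == brute_force_overlap_count(
            regions, repeats, "SINE"
        )


class TestRepeatMaskerReader:
    def test_out_style_table(self, tmp_path):
        text = (
            "   SW   perc perc perc  query     position in query\n"
            "score   div. del. ins.  sequence  begin end (left) repeat class/family\n"
            "\n"
            "  463   11.4  0.0  0.0  chr1   3000001 3000097 (195） + AluSx SINE/Alu 1 97 (215) 1\n"
            "  239   29.4  1.9  1.0  chr1   3000098 3001200 (100) C L1MC5a LINE/L1 10 20 (5) 2\n"
            "  100   10.0  0.0  0.0  chr2   500 600 (0) + MLT1 LTR/ERVL-MaLR 1 5 (0) 3\n"
            "  100   10.0  0.0  0.0  chr2   700 800 (0) + Weird Unknown 1 5 (0) 4\n"
        )
        p = tmp_path / "rm.out"
        p.write_text(text)
        reps = read_repeatmasker(p)
        assert [r.repeat_class for r in reps] == ["SINE", "LINE", "LTR", "other"]
        assert reps[0].interval.start == 3000000  # converted to 0-based
        assert reps[0].family == "AluSx"

    def test_class_normalization(self):
        assert normalize_repeat_class("SINE/Alu") == "SINE"
        assert normalize_repeat_class("line/L1") == "LINE"
        assert normalize_repeat_class("Simple_repeat") == "other"
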