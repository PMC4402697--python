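"""Segment I/O, breakpoint regions, merging and inference of new segments."""

import numpy as np
import pytest

from pigs.calibration import CalibrationParams, lod_to_probability
from pigs.graph import HaplotypeId
from pigs.segments import (
    GeneticMap,
    IBDSegment,
    SegmentFormatError,
    breakpoints,
    build_region_graphs,
    filter_segments,
    infer_new_segments,
    merge_across_regions,
    merge_segments,
    read_segments,
    write_segments,
)

H = HaplotypeId


def seg(a, b, start, end, lod=None, prob=None, chrom="1", inferred=False):
    return IBDSegment(H.parse(a), H.parse(b), chrom, start, end, lod, prob, inferred)


class TestSegmentType:
    def test_canonical_haplotype_order(self):
        s = IBDSegment(H("B", 1), H("A", 2), "1", 10, 20, lod=1.0)
        assert s.hap_a == H("A", 2)
        assert s.hap_b == H("B", 1)

    def test_rejects_inverted_interval(self):
        with pytest.raises(ValueError):
            seg("a.1", "b.1", 100, 50)

    def test_length_with_and_without_map(self):
        s = seg("a.1", "b.1", 1, 1_000_000)
        assert s.length_cm() == pytest.approx(1.0)  # 1 cM/Mb fallback
        gmap = GeneticMap({"1": (np.array([1, 1_000_000]), np.array([0.0, 2.0]))})
        assert s.length_cm(gmap) == pytest.approx(2.0)


class TestIO:
    def test_round_trip(self, tmp_path):
        segs = [
            seg("S1.1", "S2.2", 100, 5000, lod=2.5),
            seg("S3.1", "S4.1", 200, 900, prob=0.995, inferred=True),
        ]
        path = tmp_path / "x.ibd"
        write_segments(segs, path)
        back = read_segments(path)
        assert back == segs

    def test_reads_plain_eight_column_dialect(self, tmp_path):
        path = tmp_path / "y.ibd"
        path.write_text("S1\t1\tS2\t2\t7\t100\t5000\t3.2\n")
        (s,) = read_segments(path)
        assert s.hap_a == H("S1", 1) and s.hap_b == H("S2", 2)
        assert (s.chrom, s.start_bp, s.end_bp, s.lod) == ("7", 100, 5000, 3.2)

    def test_swapped_haplotypes_canonicalized(self, tmp_path):
        path = tmp_path / "y.ibd"
        path.write_text("S9\t1\tS2\t2\t1\t100\t500\t1.0\n")
        (s,) = read_segments(path)
        assert s.hap_a == H("S2", 2)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.ibd"
        path.write_text("S1\t1\tS2\t2\t1\t100\t500\t1.0\nS1\t1\tS2\n")
        with pytest.raises(SegmentFormatError, match="line 2"):
            read_segments(path)
        assert len(read_segments(path, errors="skip")) == 1

    def test_non_numeric_coordinate_is_row_error(self, tmp_path):
        path = tmp_path / "bad.ibd"
        path.write_text("S1\t1\tS2\t2\t1\tabc\t500\t1.0\n")
        with pytest.raises(SegmentFormatError, match="line 1"):
            read_segments(path)

    def test_empty_file_gives_empty_list(self, tmp_path, caplog):
        path = tmp_path / "empty.ibd"
        path.write_text("")
        with caplog.at_level("WARNING"):
            assert read_segments(path) == []
        assert "no segments" in caplog.text

    def test_probability_formatted_to_six_decimals(self, tmp_path):
        path = tmp_path / "p.ibd"
        write_segments([seg("a.1", "b.1", 1, 10, prob=0.123456789)], path)
        assert "0.123457" in path.read_text()

    def test_empty_list_writes_header_only(self, tmp_path):
        path = tmp_path / "hdr.ibd"
        write_segments([], path)
        text = path.read_text()
        assert text.startswith("#") and len(text.splitlines()) == 1


class TestGeneticMap:
    def test_reads_plink_map(self, tmp_path):
        path = tmp_path / "g.map"
        path.write_text("1 rs1 0.0 1\n1 rs2 1.5 1000000\n2 rs3 0.0 1\n2 rs4 1.0 500000\n")
        gmap = GeneticMap.read(path)
        assert gmap.cm_at("1", 500000) == pytest.approx(0.75, rel=1e-3)

    def test_reads_three_column_map(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("1\t1\t0.0\n1\t2000000\t3.0\n")
        gmap = GeneticMap.read(path)
        assert gmap.length_cm("1", 1, 1000000) == pytest.approx(1.5, rel=1e-3)

    def test_unmapped_chromosome_uses_constant_rate(self):
        gmap = GeneticMap({"1": (np.array([1, 100]), np.array([0.0, 1.0]))})
        assert gmap.length_cm("2", 1, 2_000_001) == pytest.approx(2.0)

    def test_rejects_decreasing_positions(self):
        with pytest.raises(ValueError):
            GeneticMap({"1": (np.array([100, 50]), np.array([0.0, 1.0]))})


class TestFiltering:
    def test_production_thresholds(self):
        segs = [
            seg("a.1", "b.1", 1, 2_000_000, lod=0.05),  # LOD too low
            seg("a.1", "c.1", 1, 50_000, lod=3.0),  # 0.05 cM: too short
            seg("a.1", "d.1", 1, 600_000, lod=3.0),  # keeps
        ]
        kept = filter_segments(segs, min_lod=0.1, min_cm=0.1)
        assert kept == [segs[2]]

    def test_truth_segments_without_lod_pass(self):
        s = seg("a.1", "b.1", 1, 600_000)
        assert filter_segments([s]) == [s]


class TestBreakpoints:
    def test_overlapping_pair(self):
        segs = [seg("a.1", "b.1", 100, 500), seg("a.1", "c.1", 300, 700)]
        bps = breakpoints(segs)["1"]
        assert list(bps) == [100, 300, 501, 701]

    def test_single_segment(self):
        bps = breakpoints([seg("a.1", "b.1", 10, 20)])["1"]
        assert list(bps) == [10, 21]

    def test_no_segments(self):
        assert breakpoints([]) == {}


class TestRegionGraphs:
    def test_shared_node_component_gets_epsilon_edge(self):
        calib = CalibrationParams()
        segs = [
            seg("A.1", "B.1", 100, 500, lod=2.0),
            seg("B.1", "C.1", 100, 500, lod=2.0),
        ]
        regions = build_region_graphs(segs, calib)
        assert len(regions) == 1
        (comp,) = regions[0].components
        assert set(comp.nodes) == {H("A", 1), H("B", 1), H("C", 1)}
        assert comp.probability(H("A", 1), H("C", 1)) == calib.epsilon
        assert comp.probability(H("A", 1), H("B", 1)) == pytest.approx(
            lod_to_probability(2.0, calib)
        )

    def test_single_segment_gives_two_node_graph(self):
        regions = build_region_graphs([seg("A.1", "B.1", 100, 500, lod=1.0)])
        (comp,) = regions[0].components
        assert comp.n_nodes == 2

    def test_disjoint_pairs_are_separate_components(self):
        segs = [
            seg("A.1", "B.1", 100, 500, lod=1.0),
            seg("C.1", "D.1", 100, 500, lod=1.0),
        ]
        regions = build_region_graphs(segs)
        assert len(regions[0].components) == 2

    def test_partial_overlap_creates_multiple_regions(self):
        segs = [
            seg("A.1", "B.1", 100, 500, lod=1.0),
            seg("A.1", "C.1", 300, 700, lod=1.0),
        ]
        regions = build_region_graphs(segs)
        assert [(r.start_bp, r.end_bp) for r in regions] == [
            (100, 300), (300, 501), (501, 701)
        ]
        # middle region sees both segments
        assert len(regions[1].segments) == 2

    def test_member_segments_cover_their_region(self):
        segs = [
            seg("A.1", "B.1", 100, 500, lod=1.0),
            seg("A.1", "C.1", 300, 700, lod=1.0),
            seg("B.1", "D.2", 450, 620, lod=1.0),
        ]
        for region in build_region_graphs(segs):
            for s in region.segments:
                assert s.start_bp <= region.start_bp
                assert s.end_bp + 1 >= region.end_bp


class TestMerging:
    def test_adjacent_passing_pieces_merge_with_max(self):
        pieces = [
            seg("a.1", "b.1", 100, 299, prob=0.995),
            seg("a.1", "b.1", 300, 500, prob=0.999),
        ]
        (merged,) = merge_segments(pieces, threshold=0.99)
        assert (merged.start_bp, merged.end_bp) == (100, 500)
        assert merged.prob == 0.999

    def test_sub_threshold_piece_stays_out(self):
        pieces = [
            seg("a.1", "b.1", 100, 299, prob=0.995),
            seg("a.1", "b.1", 300, 500, prob=0.95),
        ]
        merged = merge_segments(pieces, threshold=0.99)
        assert len(merged) == 2

    def test_different_pairs_never_merge(self):
        pieces = [
            seg("a.1", "b.1", 100, 299, prob=0.999),
            seg("a.1", "c.1", 300, 500, prob=0.999),
        ]
        assert len(merge_segments(pieces, threshold=0.99)) == 2

    def test_merge_never_decreases_probability(self, rng):
        pieces = [
            seg("a.1", "b.1", s, s + 99, prob=p)
            for s, p in zip(range(1, 1000, 100), rng.uniform(0.99, 1.0, 10))
        ]
        (merged,) = merge_segments(pieces, threshold=0.99)
        assert merged.prob == pytest.approx(max(p.prob for p in pieces))

    def test_merge_across_regions_interface(self):
        segs = [seg("A.1", "B.1", 100, 500, lod=3.0)]
        (region,) = build_region_graphs(segs)
        pair = (H("A", 1), H("B", 1))
        out = merge_across_regions([(region, {pair: 0.999})], threshold=0.99)
        assert out == [seg("A.1", "B.1", 100, 500, prob=0.999)]


class TestInferNewSegments:
    def _component_region(self):
        segs = [
            seg("A.1", "B.1", 100, 500, lod=2.0),
            seg("B.1", "C.1", 300, 700, lod=2.0),
        ]
        regions = build_region_graphs(segs)
        # middle region [300, 501) holds the 3-node component
        return regions[1]

    def test_new_segment_spans_member_intersection(self):
        region = self._component_region()
        pair = (H("A", 1), H("C", 1))
        (new,) = infer_new_segments(region, {pair: 0.995}, threshold=0.99)
        assert (new.start_bp, new.end_bp) == (300, 500)
        assert new.inferred and new.prob == 0.995

    def test_low_probability_pair_is_not_emitted(self):
        region = self._component_region()
        pair = (H("A", 1), H("C", 1))
        assert infer_new_segments(region, {pair: 0.5}, threshold=0.99) == []

    def test_two_node_component_has_nothing_to_infer(self):
        (region,) = build_region_graphs([seg("A.1", "B.1", 100, 500, lod=2.0)])
        pair = (H("A", 1), H("B", 1))
        assert infer_new_segments(region, {pair: 0.999}, threshold=0.99) == []
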