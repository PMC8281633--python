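"""Read classification at splice junctions, junction tallies, coverage."""

import numpy as np
import pysam
import pytest

from sefq import (
    GeneAnnotation,
    Exon,
    Intron,
    JunctionCounts,
    ReadFilterConfig,
    classify_read_at_junction,
    compute_coverage_stats,
    count_junction_reads,
    infer_introns,
)
from sefq.counting import interval_depth, read_transcript_strand

from conftest import make_header, make_read, write_bam


INTRON = Intron("chr1", 201, 300, "+", "G1", frozenset({"T1"}),
                flank_left=(101, 200), flank_right=(301, 400))
J_LOWER = INTRON.sj5   # + strand: 200|201
J_UPPER = INTRON.sj3   # 300|301


class TestClassification:
    def test_gap_matching_intron_is_split_at_both_junctions(self):
        rd = make_read([(150, 200), (301, 350)], gaps=[(201, 300)])
        assert classify_read_at_junction(rd, J_LOWER, INTRON) == "split"
        assert classify_read_at_junction(rd, J_UPPER, INTRON) == "split"

    def test_contiguous_match_over_junction_is_unsplit(self):
        rd = make_read([(190, 210)])
        assert classify_read_at_junction(rd, J_LOWER, INTRON) == "unsplit"
        assert classify_read_at_junction(rd, J_UPPER, INTRON) == "none"

    def test_read_ending_at_last_exonic_base_is_none(self):
        rd = make_read([(150, 200)])
        assert classify_read_at_junction(rd, J_LOWER, INTRON) == "none"

    def test_exon_skipping_gap_counts_as_split(self):
        # gap spans introns 1+2 and the middle exon: still split at intron 1's
        # lower junction (gap start matches), none at its upper junction
        rd = make_read([(150, 200), (501, 550)], gaps=[(201, 500)])
        assert classify_read_at_junction(rd, J_LOWER, INTRON) == "split"
        assert classify_read_at_junction(rd, J_UPPER, INTRON) == "none"

    @pytest.mark.parametrize("shift,expected", [(-1, "none"), (1, "unsplit")])
    def test_gap_boundary_off_by_one_is_never_split(self, shift, expected):
        rd = make_read([(150, 200 + shift), (301, 350)],
                       gaps=[(201 + shift, 300)])
        assert classify_read_at_junction(rd, J_LOWER, INTRON) == expected

    def test_deletion_at_junction_breaks_unsplit(self):
        rd = make_read([(190, 200), (203, 220)], deletions=[(201, 202)])
        assert classify_read_at_junction(rd, J_LOWER, INTRON) == "none"

    def test_split_takes_precedence_in_partition(self):
        # pathological read both covering the junction and carrying a
        # boundary-matching gap elsewhere: exactly one label, split wins
        rd = make_read([(190, 210), (301, 320)], gaps=[(211, 300)])
        assert classify_read_at_junction(rd, J_UPPER, INTRON) == "split"

    def test_min_overhang_enforced(self):
        rd = make_read([(199, 203)])  # 2 exonic, 3 intronic bases
        assert classify_read_at_junction(rd, J_LOWER, INTRON, min_overhang=2) == "unsplit"
        assert classify_read_at_junction(rd, J_LOWER, INTRON, min_overhang=3) == "none"

    def test_partition_is_total_on_random_reads(self, rng):
        for _ in range(200):
            start = int(rng.integers(150, 320))
            length = int(rng.integers(5, 120))
            if rng.random() < 0.5:
                rd = make_read([(start, start + length)])
            else:
                gap_len = int(rng.integers(10, 150))
                rd = make_read(
                    [(start, start + length),
                     (start + length + gap_len + 1, start + length + gap_len + 20)],
                    gaps=[(start + length + 1, start + length + gap_len)])
            for junction in (J_LOWER, J_UPPER):
                assert classify_read_at_junction(rd, junction, INTRON) in {
                    "split", "unsplit", "none"}


def _toy_annotation():
    return GeneAnnotation([
        Exon("chr1", 101, 200, "+", "G1", "T1"),
        Exon("chr1", 301, 400, "+", "G1", "T1"),
    ])


def _fixture_reads(n_split=5, n_unsplit5=2, reverse_protocol=True):
    # under the reverse protocol a '+'-transcript single-end read maps reversed
    reads = []
    for k in range(n_split):
        reads.append(make_read([(160 + k, 200), (301, 341 + k)],
                               gaps=[(201, 300)], name=f"s{k}",
                               is_reverse=reverse_protocol))
    for k in range(n_unsplit5):
        reads.append(make_read([(180 + k, 220 + k)], name=f"u{k}",
                               is_reverse=reverse_protocol))
    return reads


class TestCounting:
    def test_hand_tallied_fixture(self, tmp_path):
        introns = infer_introns(_toy_annotation())
        bam_path = write_bam(tmp_path / "t.bam", _fixture_reads())
        with pysam.AlignmentFile(bam_path) as bam:
            counts = count_junction_reads(bam, introns, ReadFilterConfig())
        assert counts[introns[0]].as_tuple() == (5, 2, 5, 0)

    def test_empty_alignment_gives_zero_counts(self, tmp_path):
        introns = infer_introns(_toy_annotation())
        bam_path = write_bam(tmp_path / "e.bam", [])
        with pysam.AlignmentFile(bam_path) as bam:
            counts = count_junction_reads(bam, introns, ReadFilterConfig())
        assert counts[introns[0]].as_tuple() == (0, 0, 0, 0)

    def test_wrong_strand_reads_all_excluded(self, tmp_path):
        introns = infer_introns(_toy_annotation())
        reads = _fixture_reads(reverse_protocol=False)  # forward-mapped reads
        bam_path = write_bam(tmp_path / "w.bam", reads)
        with pysam.AlignmentFile(bam_path) as bam:
            counts = count_junction_reads(
                bam, introns, ReadFilterConfig(protocol="reverse"))
            assert counts[introns[0]].as_tuple() == (0, 0, 0, 0)
            counts = count_junction_reads(
                bam, introns, ReadFilterConfig(protocol="unstranded"))
            assert counts[introns[0]].as_tuple() == (5, 2, 5, 0)

    def test_multimapper_and_low_mapq_excluded(self, tmp_path):
        introns = infer_introns(_toy_annotation())
        reads = [
            make_read([(190, 210)], name="multi", nh=3, is_reverse=True),
            make_read([(190, 210)], name="lowq", nh=None, mapq=5,
                      is_reverse=True),
            make_read([(190, 210)], name="ok", nh=None, mapq=45,
                      is_reverse=True),
        ]
        bam_path = write_bam(tmp_path / "m.bam", reads)
        with pysam.AlignmentFile(bam_path) as bam:
            counts = count_junction_reads(bam, introns, ReadFilterConfig())
        assert counts[introns[0]].as_tuple() == (0, 1, 0, 0)

    def test_counts_additive_over_read_partition(self, tmp_path):
        introns = infer_introns(_toy_annotation())
        reads = _fixture_reads(n_split=7, n_unsplit5=4)
        part_a = [r for i, r in enumerate(reads) if i % 2 == 0]
        part_b = [r for i, r in enumerate(reads) if i % 2 == 1]
        tallies = []
        for name, part in (("all", reads), ("a", part_a), ("b", part_b)):
            path = write_bam(tmp_path / f"{name}.bam", part)
            with pysam.AlignmentFile(path) as bam:
                tallies.append(
                    count_junction_reads(bam, introns, ReadFilterConfig())
                    [introns[0]].as_tuple())
        total, a, b = tallies
        assert total == tuple(x + y for x, y in zip(a, b))

    def test_absent_chromosome_warns_and_zeroes(self, tmp_path, caplog):
        ann = GeneAnnotation([
            Exon("chr9", 101, 200, "+", "G9", "T9"),
            Exon("chr9", 301, 400, "+", "G9", "T9"),
        ])
        introns = infer_introns(ann)
        bam_path = write_bam(tmp_path / "z.bam", [])
        with pysam.AlignmentFile(bam_path) as bam, \
                caplog.at_level("WARNING", logger="sefq"):
            counts = count_junction_reads(bam, introns, ReadFilterConfig())
        assert counts[introns[0]].as_tuple() == (0, 0, 0, 0)
        assert "absent" in caplog.text


def _tile(lo, hi, depth, chunk=50, **kw):
    reads = []
    for rep in range(depth):
        pos = lo
        while pos <= hi:
            end = min(pos + chunk - 1, hi)
            reads.append(make_read([(pos, end)], name=f"b{lo}.{rep}.{pos}", **kw))
            pos = end + 1
    return reads


class TestCoverage:
    def test_no_reads_gives_zero_medians(self, tmp_path):
        bam_path = write_bam(tmp_path / "c0.bam", [])
        with pysam.AlignmentFile(bam_path) as bam:
            stats = compute_coverage_stats(bam, INTRON,
                                           cfg=ReadFilterConfig())
        assert (stats.intron_median, stats.exon5_median,
                stats.exon3_median) == (0, 0, 0)

    def test_uniform_depth_fixture(self, tmp_path):
        reads = (_tile(101, 200, 10, is_reverse=True)
                 + _tile(301, 400, 10, is_reverse=True)
                 + _tile(201, 300, 2, is_reverse=True))
        bam_path = write_bam(tmp_path / "c1.bam", reads)
        with pysam.AlignmentFile(bam_path) as bam:
            stats = compute_coverage_stats(bam, INTRON, cfg=ReadFilterConfig())
        assert (stats.intron_median, stats.exon5_median,
                stats.exon3_median) == (2.0, 10.0, 10.0)

    def test_median_includes_zero_depth_bases(self, tmp_path):
        # depth vector (0, 0, 5, 5, 6) over a 5-base intron
        intron = Intron("chr1", 201, 205, "+", "G1", frozenset({"T1"}),
                        flank_left=(101, 200), flank_right=(206, 300))
        reads = [make_read([(203, 205)], name=f"x{k}", is_reverse=True)
                 for k in range(5)]
        reads.append(make_read([(205, 208)], name="y", is_reverse=True))
        bam_path = write_bam(tmp_path / "c2.bam", reads)
        with pysam.AlignmentFile(bam_path) as bam:
            depth = interval_depth(bam, "chr1", 201, 205,
                                   ReadFilterConfig(), strand="+")
            stats = compute_coverage_stats(bam, intron, cfg=ReadFilterConfig())
        assert depth.tolist() == [0, 0, 5, 5, 6]
        assert stats.intron_median == 5.0

    def test_agrees_with_independent_pileup(self, tmp_path, rng):
        reads = []
        for k in range(150):
            start = int(rng.integers(150, 380))
            reads.append(make_read([(start, start + int(rng.integers(5, 60)))],
                                   name=f"p{k}", is_reverse=True))
        bam_path = write_bam(tmp_path / "c3.bam", reads)
        cfg = ReadFilterConfig(protocol="unstranded")
        with pysam.AlignmentFile(bam_path) as bam:
            depth = interval_depth(bam, "chr1", 201, 300, cfg)
            expected = np.zeros(100, dtype=int)
            for col in bam.pileup("chr1", 200, 300, truncate=True,
                                  min_base_quality=0):
                expected[col.reference_pos - 200] = col.nsegments
        assert depth.tolist() == expected.tolist()

    def test_gap_contributes_no_depth(self, tmp_path):
        rd = make_read([(150, 200), (301, 350)], gaps=[(201, 300)],
                       is_reverse=True)
        bam_path = write_bam(tmp_path / "c4.bam", [rd])
        with pysam.AlignmentFile(bam_path) as bam:
            depth = interval_depth(bam, "chr1", 201, 300, ReadFilterConfig(),
                                   strand="+")
        assert depth.sum() == 0


class TestStrandInference:
    @pytest.mark.parametrize("protocol,is_reverse,is_read2,expected", [
        ("forward", False, False, "+"),
        ("forward", True, False, "-"),
        ("reverse", True, False, "+"),
        ("reverse", False, False, "-"),
        ("forward", True, True, "+"),   # mate 2 flips
        ("reverse", False, True, "+"),
        ("unstranded", False, False, None),
    ])
    def test_protocol_table(self, protocol, is_reverse, is_read2, expected):
        rd = make_read([(100, 150)], is_reverse=is_reverse,
                       is_paired=is_read2, is_read2=is_read2)
        assert read_transcript_strand(rd, protocol) == expected
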