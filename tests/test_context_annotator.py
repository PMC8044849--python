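"""Gene-context classification: intergenic placement, orientation
classes, CDS distances, strand-aware flanks, and C-rich track calls."""

import pytest

from rpqs import GenomeRecord, reverse_complement
from rpqs.context_annotator import (
    GENIC,
    HEAD_TO_HEAD,
    HEAD_TO_TAIL,
    INTERGENIC,
    TAIL_TO_TAIL,
    UNPAIRED,
    build_context_records,
    classify_location,
    classify_orientation,
    detect_crich_track,
    distance_to_cds,
    extract_flanks,
    oric_distance,
    summarize_context,
)
from rpqs.genome_io import AnnotatedGenome, GeneAnnotation
from rpqs.pqs_scanner import PqsMatch, scan_minimal_overlapping
from rpqs.repeat_finder import find_repeated_pqs

GCA_TAIL = "GCCCCCTCCCCGCA"


def gene(start1, end1, strand, tag="g", seq_id="chr"):
    return GeneAnnotation(
        seq_id=seq_id, start=start1, end=end1, strand=strand, locus_tag=tag
    )


def match(start, end, strand="+", seq_id="chr"):
    return PqsMatch(seq_id=seq_id, start=start, end=end, strand=strand)


class TestLocation:
    def test_midpoint_in_cds_is_genic(self):
        genome = GenomeRecord("chr", "A" * 2000)
        loc, left, right = classify_location(
            match(150, 170), [gene(100, 400, "+")], genome
        )
        assert loc == GENIC and left is None and right is None

    def test_intergenic_between_two_genes(self):
        genome = GenomeRecord("chr", "A" * 2000)
        genes = [gene(101, 400, "+", "L"), gene(901, 1200, "-", "R")]
        loc, left, right = classify_location(match(590, 610), genes, genome)
        assert loc == INTERGENIC
        assert left.locus_tag == "L" and right.locus_tag == "R"

    def test_circular_wrap_picks_first_gene(self):
        genome = GenomeRecord("chr", "A" * 1000, circular=True)
        genes = [gene(51, 150, "+", "first"), gene(301, 400, "+", "last")]
        loc, left, right = classify_location(match(900, 920), genes, genome)
        assert loc == INTERGENIC
        assert left.locus_tag == "last" and right.locus_tag == "first"

    def test_linear_end_leaves_gene_absent(self):
        genome = GenomeRecord("chr", "A" * 1000)
        loc, left, right = classify_location(match(900, 920), [gene(51, 150, "+")], genome)
        assert loc == INTERGENIC and right is None and left is not None


class TestOrientation:
    @pytest.mark.parametrize(
        "ls,rs,expected",
        [
            ("+", "-", TAIL_TO_TAIL),
            ("-", "+", HEAD_TO_HEAD),
            ("+", "+", HEAD_TO_TAIL),
            ("-", "-", HEAD_TO_TAIL),
        ],
    )
    def test_strand_pairs(self, ls, rs, expected):
        assert classify_orientation(gene(1, 10, ls), gene(20, 30, rs)) == expected

    def test_absent_gene_is_unpaired(self):
        assert classify_orientation(None, gene(1, 10, "+")) == UNPAIRED

    def test_invariant_under_genome_reverse_complement(self):
        # reverse-complementing the genome swaps left/right and flips
        # strands; the orientation class is preserved
        n = 2000
        for ls, rs in [("+", "-"), ("-", "+"), ("+", "+")]:
            left, right = gene(101, 400, ls, "L"), gene(901, 1200, rs, "R")
            cls = classify_orientation(left, right)
            flip = {"+": "-", "-": "+"}
            # mapped coordinates: 1-based (n-end+1, n-start+1)
            new_left = gene(n - 1200 + 1, n - 901 + 1, flip[rs], "R")
            new_right = gene(n - 400 + 1, n - 101 + 1, flip[ls], "L")
            assert classify_orientation(new_left, new_right) == cls


class TestDistance:
    def test_distance_to_plus_gene_end(self):
        # gene on the left, + strand: its CDS end faces the match
        cd = distance_to_cds(match(500, 520), gene(101, 400, "+"))
        assert (cd.distance, cd.boundary, cd.overlaps) == (100, "end", False)

    def test_distance_to_minus_gene_end_on_right(self):
        # gene on the right, - strand: its CDS end (left edge) faces the match
        cd = distance_to_cds(match(500, 520), gene(901, 1200, "-"))
        assert (cd.distance, cd.boundary) == (380, "end")

    def test_plus_gene_on_right_faces_with_start(self):
        cd = distance_to_cds(match(500, 520), gene(901, 1200, "+"))
        assert (cd.distance, cd.boundary) == (380, "start")

    def test_adjacent_gene_distance_zero(self):
        cd = distance_to_cds(match(400, 420), gene(101, 400, "+"))
        assert cd.distance == 0 and not cd.overlaps

    def test_overlap_flagged(self):
        cd = distance_to_cds(match(390, 420), gene(101, 400, "+"))
        assert cd.distance == 0 and cd.overlaps


class TestFlanks:
    def test_plus_strand_flanks_are_genomic_slices(self):
        seq = "A" * 50 + "G" * 20 + "C" * 50
        genome = GenomeRecord("chr", seq)
        f5, f3 = extract_flanks(match(50, 70), genome, window=10)
        assert f5 == "A" * 10 and f3 == "C" * 10

    def test_minus_strand_flank3_is_revcomp_of_upstream(self):
        seq = "ACGTACGTAC" + "G" * 20 + "TTTTTTTTTT"
        genome = GenomeRecord("chr", seq)
        f5, f3 = extract_flanks(match(10, 30, strand="-"), genome, window=10)
        assert f3 == reverse_complement("ACGTACGTAC")
        assert f5 == reverse_complement("TTTTTTTTTT")

    def test_truncation_at_linear_ends(self):
        genome = GenomeRecord("chr", "ACGTACGT")
        f5, f3 = extract_flanks(match(2, 4), genome, window=10)
        assert f5 == "AC" and f3 == "ACGT"

    def test_circular_wrap(self):
        genome = GenomeRecord("chr", "AACCGGTT", circular=True)
        f5, f3 = extract_flanks(match(1, 3), genome, window=3)
        assert f5 == "TTA"  # wraps past the origin
        assert f3 == "CGG"

    def test_minus_flank_roundtrip_property(self):
        genome = GenomeRecord("chr", "ACGT" * 30)
        m = match(40, 60, strand="-")
        _, f3 = extract_flanks(m, genome, window=15)
        assert f3 == reverse_complement(genome.sequence[25:40])


class TestCRichTrack:
    def test_table1_tail_direct_call(self):
        track = detect_crich_track(GCA_TAIL + "ATATATAT")
        assert track is not None
        assert track.offset == 1
        assert track.length == 10  # CCCCCTCCCC
        assert track.matches_minimal_motif
        # best 12-nt window is tail[1:13] = CCCCCTCCCCGC -> 10 C of 12
        assert track.c_fraction == pytest.approx(10 / 12)

    def test_minimal_motif_alone(self):
        track = detect_crich_track("CCCTCCC")
        assert (track.offset, track.length, track.matches_minimal_motif) == (0, 7, True)

    def test_non_t_separator_not_minimal_motif(self):
        track = detect_crich_track("CCCACCC")
        assert track is not None and not track.matches_minimal_motif

    def test_a_rich_flank_absent(self):
        assert detect_crich_track("A" * 40) is None

    def test_track_outside_search_window_not_found(self):
        assert detect_crich_track("A" * 35 + "CCCTCCC", search_window=30) is None

    def test_empty_flank_rejected(self):
        with pytest.raises(ValueError):
            detect_crich_track("")


class TestOriDistance:
    def test_zero_at_oric(self):
        genome = GenomeRecord("chr", "A" * 100)
        assert oric_distance(match(4, 6), 5, genome) == 0

    def test_circular_wrap_distance(self):
        genome = GenomeRecord("chr", "A" * 100, circular=True)
        assert oric_distance(match(94, 96), 5, genome) == 10

    def test_linear_distance(self):
        genome = GenomeRecord("chr", "A" * 100)
        assert oric_distance(match(94, 96), 5, genome) == 90


class TestSummarize:
    def _records(self, annotated):
        fams = find_repeated_pqs(annotated.genome)
        copies = [c for fam in fams for c in fam.copies]
        return build_context_records(copies, annotated)

    def test_synthetic_layout_recovered(self, small_synthetic):
        annotated, truth = small_synthetic
        records = self._records(annotated)
        summary = summarize_context(records)
        planted = [p.orientation for p in truth.planted]
        for cls in (TAIL_TO_TAIL, HEAD_TO_HEAD, HEAD_TO_TAIL):
            assert summary["orientation_fractions"][cls] == pytest.approx(
                planted.count(cls) / len(planted)
            )
        assert summary["fraction_intergenic"] == 1.0
        assert summary["fraction_crich_minimal_motif"] == 1.0
        assert summary["distance_stats"]["mean"] == 300.0

    def test_all_unpaired_reports_absent_fractions(self):
        genome = GenomeRecord("chr", "A" * 200)
        ann = AnnotatedGenome(genome=genome, genes=[])
        records = build_context_records([match(50, 70)], ann)
        summary = summarize_context(records)
        assert summary["orientation_fractions"] is None

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            summarize_context([])

    def test_planted_distances_exact(self, small_synthetic):
        annotated, _ = small_synthetic
        for r in self._records(annotated):
            dists = [
                d
                for d in (r.dist_to_nearest_cds_start, r.dist_to_nearest_cds_end)
                if d is not None
            ]
            assert dists and all(d == 300 for d in dists)

    def test_flank3_carries_planted_tail(self, small_synthetic):
        annotated, truth = small_synthetic
        records = {(r.match.start, r.match.end): r for r in self._records(annotated)}
        for p in truth.planted:
            r = records[(p.match_start, p.match_end)]
            if p.strand == "+":
                offset = p.tail_start - p.match_end
            else:
                offset = p.match_start - p.tail_end
            tail_len = p.tail_end - p.tail_start
            assert r.flank3[offset : offset + tail_len] == GCA_TAIL
            assert r.crich is not None and r.crich.matches_minimal_motif
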