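import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_dna
from naive_oracle import naive_revcomp, naive_scan
from surreg.motif_scan import (
    MotifHit,
    PatternSpecError,
    compile_pattern,
    default_patterns,
    genome_scan,
    match_at,
    resolve_nesting,
    scan_region,
    write_bed,
)
from surreg.sequence_io import GenomeRecord, reverse_complement
from surreg.synthetic_data import Plant, PromoterPlan, build_promoter

CANONICAL_LONG = "GTT" + "ACG" + "AAC" + "TTTTT" + "GTT"


def hit_tuples(hits):
    return {
        (h.region_offset, h.pattern_name, h.genomic_spacers, h.edit_cost, h.strand_label)
        for h in hits
    }


class TestCompilePattern:
    def test_short_and_long(self):
        short = compile_pattern("GTTn3AAC")
        assert (short.name, short.blocks, short.spacer_lens) == (
            "short",
            ("GTT", "AAC"),
            (3,),
        )
        long = compile_pattern("GTTn3AACn5GTT")
        assert (long.name, long.blocks, long.spacer_lens) == (
            "long",
            ("GTT", "AAC", "GTT"),
            (3, 5),
        )
        assert (short.edit_budget, long.edit_budget) == (1, 2)

    @pytest.mark.parametrize("bad", ["GTT", "", "GTTn0AAC", "gttn3aac", "GTTnAAC"])
    def test_malformed_specs(self, bad):
        with pytest.raises(PatternSpecError):
            compile_pattern(bad)


class TestMatchAt:
    def test_one_block_mismatch(self, patterns):
        short, _ = patterns
        m = match_at("ATTTTTAAC", 0, short, [3])
        assert (m.mismatch_count, m.edit_cost) == (1, 1)
        assert m.matched_blocks == ("ATT", "AAC")

    def test_canonical_long_exact(self, patterns):
        _, long = patterns
        m = match_at(CANONICAL_LONG, 0, long, [3, 5])
        assert (m.edit_cost, m.mismatch_count) == (0, 0)

    def test_double_spacer_shift(self, patterns):
        _, long = patterns
        m = match_at("GTTACAACTTTTTTGTT", 0, long, [2, 6])
        assert (m.mismatch_count, m.edit_cost) == (0, 2)
        assert m.spacer_devs == (-1, 1)

    def test_over_budget_is_no_match(self, patterns):
        short, _ = patterns
        assert match_at("ATTTTTATC", 0, short, [3]) is None  # 2 mismatches

    def test_window_must_fit(self, patterns):
        short, _ = patterns
        assert match_at("GTTAAA", 0, short, [3]) is None


class TestScanRegion:
    def test_planted_canonical_long_alone(self):
        seq, _ = build_promoter(
            PromoterPlan("t", (Plant("GTTn3AACn5GTT", 67, "forward"),), 200),
            seed=5,
        )
        (hit,) = scan_region(seq)
        assert hit.pattern_name == "long"
        assert hit.exact
        assert hit.upstream_distance == 67
        assert hit.strand_label == "forward"

    def test_empty_background_has_no_hits(self):
        seq, _ = build_promoter(PromoterPlan("empty", (), 200), seed=5)
        assert scan_region(seq) == []

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_naive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, int(rng.integers(40, 300)))
        assert hit_tuples(scan_region(seq)) == naive_scan(seq)

    def test_overlapping_distinct_start_hits_all_reported(self):
        # Sites 8 bp apart (as upstream of Mrp-Mbh1) are both kept.
        seq, _ = build_promoter(
            PromoterPlan(
                "t",
                (
                    Plant("GTTn3AATn5GTT", 139, "reverse"),
                    Plant("ATTn3AACn5GTT", 147, "forward"),
                ),
                300,
            ),
            seed=3,
        )
        hits = scan_region(seq)
        assert [h.upstream_distance for h in hits] == [139, 147]

    def test_budget_monotonicity(self, rng):
        # The match relation itself is monotone in the budgets; checked
        # pre-nesting because a long hit appearing at a looser budget can
        # newly swallow an embedded short in the nested report.
        for _ in range(15):
            seq = random_dna(rng, 250)
            def sites(**kw):
                return {
                    (h.region_offset, h.pattern_name)
                    for h in scan_region(seq, default_patterns(**kw), nesting=False)
                }
            tight = sites(short_budget=0, long_budget=0, spacer_flex=0)
            lo = sites()
            hi = sites(short_budget=2, long_budget=3)
            assert tight <= lo <= hi

    def test_strand_symmetry(self, rng):
        # At alignment level, scanning the reverse complement reflects every
        # match (with the genomic spacer vector reversed); exact short hits
        # (self-reverse-complementary) keep their two-orientation label on
        # both strands. Inexact equal-cost hits tie-break to forward on
        # either strand, so labels themselves are not compared.
        for _ in range(15):
            seq = random_dna(rng, 220)
            fwd_hits = scan_region(seq, nesting=False, collapse=False)
            rc_hits = scan_region(
                reverse_complement(seq), nesting=False, collapse=False
            )
            fwd = {
                (h.region_offset, h.pattern_name, h.genomic_spacers, h.edit_cost)
                for h in fwd_hits
            }
            mirrored = {
                (
                    len(seq) - h.region_offset - h.span,
                    h.pattern_name,
                    tuple(reversed(h.genomic_spacers)),
                    h.edit_cost,
                )
                for h in rc_hits
            }
            assert fwd == mirrored
            both = {
                len(seq) - h.region_offset - h.span
                for h in rc_hits
                if h.strand_label == "forward_and_reverse"
            }
            assert both == {
                h.region_offset
                for h in fwd_hits
                if h.strand_label == "forward_and_reverse"
            }


class TestStrandLabels:
    def test_exact_short_is_forward_and_reverse(self):
        seq, _ = build_promoter(
            PromoterPlan("t", (Plant("GTTn3AAC", 31, "forward"),), 200), seed=2
        )
        (hit,) = scan_region(seq)
        assert hit.strand_label == "forward_and_reverse"
        # palindromy: the matched window reverse-complements onto itself's
        # pattern, so both orientations are genuine
        window = seq[hit.region_offset : hit.region_offset + hit.span]
        assert naive_revcomp(window)[:3] == "GTT"

    def test_one_mismatch_short_ties_forward(self):
        seq, _ = build_promoter(
            PromoterPlan("t", (Plant("ATTn3AAC", 21, "forward"),), 200), seed=2
        )
        (hit,) = scan_region(seq)
        assert hit.strand_label == "forward"
        assert hit.edit_cost == 1

    def test_reverse_only_long_labels_reverse(self):
        seq, _ = build_promoter(
            PromoterPlan("t", (Plant("GTTn3AACn5GTT", 40, "reverse"),), 200), seed=2
        )
        (hit,) = scan_region(seq)
        assert (hit.strand_label, hit.exact) == ("reverse", True)


class TestNesting:
    def test_long_hit_suppresses_embedded_short(self):
        hits = scan_region(CANONICAL_LONG)
        assert [h.pattern_name for h in hits] == ["long"]
        unnested = {h.pattern_name for h in scan_region(CANONICAL_LONG, nesting=False)}
        assert unnested == {"short", "long"}

    def test_distant_short_retained(self):
        seq, _ = build_promoter(
            PromoterPlan(
                "t",
                (
                    Plant("GTTn3AAC", 20, "forward"),
                    Plant("GTTn3AACn5GTT", 60, "forward"),
                ),
                200,
            ),
            seed=4,
        )
        assert {h.pattern_name for h in scan_region(seq)} == {"short", "long"}

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_suppression_only_inside_long_spans(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 150)
        kept = scan_region(seq)
        all_hits = scan_region(seq, nesting=False)
        suppressed = hit_tuples(all_hits) - hit_tuples(kept)
        longs = [
            (h.region_offset, h.region_offset + h.span - 1)
            for h in all_hits
            if h.pattern_name == "long"
        ]
        for off, name, g, _cost, _label in suppressed:
            assert name == "short"
            span = 9 + sum(g) - 3  # short span for this geometry
            start, end = off, off + 6 + g[0] - 1
            assert any(ls <= start and end <= le for ls, le in longs)


class TestAnnotations:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            (CANONICAL_LONG, "Long"),
            ("GTTACGAATTTTTTGTT"[:17], "Long with mutation: GTTn3AATn5GTT"),
            ("GTTACAACTTTTTTGTT", "Long with mutation: GTTn2AACn6GTT"),
            ("GTACCCAACCCCCCTTT"[:17], "Long with mutations: GTAn3AACn5TTT"),
        ],
        ids=["exact", "one-mismatch", "spacer-shift", "two-mismatches"],
    )
    def test_rendered_like_site_tables(self, seq, expected):
        hits = [h for h in scan_region(seq) if h.pattern_name == "long"]
        assert expected in [h.annotation for h in hits]


class TestGenomeScan:
    def test_bed_coordinates_and_palindromic_strand(self, tmp_path):
        seq, _ = build_promoter(
            PromoterPlan("t", (Plant("GTTn3AAC", 81, "forward"),), 100), seed=9
        )
        genome = GenomeRecord("c1", seq)
        hits = genome_scan(genome)
        assert [(h.genome_start, h.genome_end) for h in hits] == [(11, 19)]
        bed = tmp_path / "hits.bed"
        write_bed(hits, bed)
        chrom, start, end, _name, score, strand = bed.read_text().split()
        assert (chrom, start, end, strand) == ("c1", "10", "19", ".")
        assert score == "1"  # budget 1 - cost 0

    def test_hit_free_contig_gives_empty_track(self, tmp_path):
        seq, _ = build_promoter(PromoterPlan("t", (), 150), seed=9)
        hits = genome_scan(GenomeRecord("c1", seq))
        assert hits == []
        bed = tmp_path / "empty.bed"
        write_bed(hits, bed)
        assert bed.read_text() == ""

    def test_count_matches_oracle_on_long_contig(self):
        rng = np.random.default_rng(42)
        seq = random_dna(rng, 10_000)
        hits = genome_scan(GenomeRecord("c1", seq))
        assert len(hits) == len(naive_scan(seq, nesting=False))
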