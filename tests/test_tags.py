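"""5'-tag reduction, contaminant/MAPQ filters, UMI deduplication."""
from __future__ import annotations

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from captss import io
from captss.tags import (
    UMIParseError,
    deduplicate,
    filter_biotype,
    filter_mapq,
    read_tags_tsv,
    to_tags,
    write_tags_tsv,
)

from conftest import make_tag

SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100000\n"


def sam_records(tmp_path, lines):
    p = tmp_path / "t.sam"
    p.write_text(SAM_HEADER + "".join(lines))
    return io.read_alignments(p)


class TestToTags:
    def test_plus_strand_five_prime_is_leftmost(self, tmp_path):
        recs = sam_records(
            tmp_path, ["r1_AAAACCCC\t0\tchr1\t101\t60\t75M\t*\t0\t0\t" + "A" * 75 + "\t*\n"]
        )
        tags, _ = to_tags(recs, "s1")
        assert tags[0].pos5 == 100 and tags[0].strand == "+"

    def test_minus_strand_five_prime_is_rightmost(self, tmp_path):
        recs = sam_records(
            tmp_path, ["r1_AAAACCCC\t16\tchr1\t101\t60\t75M\t*\t0\t0\t" + "A" * 75 + "\t*\n"]
        )
        tags, _ = to_tags(recs, "s1")
        assert tags[0].pos5 == 174  # rightmost base of [100, 175)

    def test_minus_strand_spliced_rightmost_across_blocks(self, tmp_path):
        # blocks [100,120) + [180,200): 20M60N20M starting at 101 (1-based)
        recs = sam_records(
            tmp_path,
            ["r1_AAAACCCC\t16\tchr1\t101\t60\t20M60N20M\t*\t0\t0\t" + "A" * 40 + "\t*\n"],
        )
        tags, _ = to_tags(recs, "s1")
        assert tags[0].blocks == ((100, 120), (180, 200))
        assert tags[0].pos5 == 199

    def test_unmapped_skipped_and_tallied(self, tmp_path):
        recs = sam_records(
            tmp_path,
            [
                "r1_AAAACCCC\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*\n",
                "r2_AAAACCCC\t0\tchr1\t11\t60\t4M\t*\t0\t0\tACGT\t*\n",
            ],
        )
        tags, n_unmapped = to_tags(recs, "s1")
        assert len(tags) == 1 and n_unmapped == 1

    def test_name_without_umi_errors(self, tmp_path):
        recs = sam_records(tmp_path, ["r1\t0\tchr1\t11\t60\t4M\t*\t0\t0\tACGT\t*\n"])
        with pytest.raises(UMIParseError):
            to_tags(recs, "s1")


class TestFilters:
    def test_tag_inside_rrna_removed(self, hand_annotation):
        t = make_tag(pos5=5100)  # inside rrna1 [5000, 5300)
        assert filter_biotype([t], hand_annotation) == []

    def test_tag_in_protein_coding_kept(self, hand_annotation):
        t = make_tag(pos5=1200)
        assert filter_biotype([t], hand_annotation) == [t]

    def test_one_bp_overlap_removed(self, hand_annotation):
        # block [4951, 5001) overlaps rrna1 [5000, 5300) by exactly one base
        t = make_tag(pos5=4951, blocks=((4951, 5001),))
        assert filter_biotype([t], hand_annotation) == []
        t2 = make_tag(pos5=4950, blocks=((4950, 5000),))
        assert filter_biotype([t2], hand_annotation) == [t2]

    def test_opposite_strand_overlap_also_removed(self, hand_annotation):
        t = make_tag(strand="-", pos5=5100, blocks=((5051, 5101),))
        assert filter_biotype([t], hand_annotation) == []

    def test_mapq_boundary(self):
        kept = filter_mapq([make_tag(mapq=10), make_tag(mapq=9)])
        assert [t.mapq for t in kept] == [10]

    def test_lowmapq_count_matches_generator_truth(self):
        from captss.simulate import generate_dataset

        ds = generate_dataset(seed=7, n_genes=10, n_clusters=20, chrom_len=50_000,
                              lowmapq_frac=0.2)
        tags = ds.tags_by_sample["cold_1"]
        n_low = sum(1 for t in tags if t.mapq < 10)
        assert n_low > 0
        assert len(filter_mapq(tags)) == len(tags) - n_low

    def test_filter_order_commutes(self, hand_annotation):
        tags = [
            make_tag(pos5=p, mapq=m, umi=u, read_id=f"r{i}")
            for i, (p, m, u) in enumerate(
                [(5100, 255, "A" * 8), (1200, 5, "A" * 8), (1200, 255, "A" * 8),
                 (1200, 255, "A" * 8), (700, 255, "C" * 8), (4951, 12, "G" * 8)]
            )
        ]
        a, _ = deduplicate(filter_mapq(filter_biotype(tags, hand_annotation)))
        b, _ = deduplicate(filter_biotype(filter_mapq(tags), hand_annotation))
        key = lambda t: (t.chrom, t.strand, t.pos5, t.umi)
        assert Counter(map(key, a)) == Counter(map(key, b))


def brute_force_dedup_keys(tags):
    return {(t.chrom, t.strand, t.pos5, t.umi) for t in tags}


class TestDeduplicate:
    def test_redundant_umi_collapsed(self):
        tags = [
            make_tag(umi="AAAAAAAA", read_id="r1"),
            make_tag(umi="AAAAAAAA", read_id="r2"),
            make_tag(umi="CCCCCCCC", read_id="r3"),
        ]
        kept, summary = deduplicate(tags)
        assert len(kept) == 2
        assert summary.duplicates_removed == 1

    def test_same_umi_different_positions_both_kept(self):
        tags = [make_tag(pos5=100), make_tag(pos5=101, read_id="r2")]
        kept, _ = deduplicate(tags)
        assert len(kept) == 2

    def test_same_position_opposite_strands_distinct(self):
        tags = [make_tag(strand="+"), make_tag(strand="-", read_id="r2")]
        kept, _ = deduplicate(tags)
        assert len(kept) == 2

    def test_idempotent(self):
        tags = [make_tag(umi="AAAAAAAA", read_id=f"r{i}") for i in range(5)]
        once, _ = deduplicate(tags)
        twice, _ = deduplicate(once)
        assert once == twice

    @given(st.data())
    @settings(deadline=None, max_examples=50)
    def test_matches_brute_force_and_order_independent(self, data):
        umis = ["AAAAAAAA", "CCCCCCCC", "GGGGGGGG", "TTTTTTTT"]
        n = data.draw(st.integers(0, 120))
        tags = [
            make_tag(
                pos5=data.draw(st.integers(0, 30)),
                strand=data.draw(st.sampled_from("+-")),
                umi=data.draw(st.sampled_from(umis)),
                read_id=f"r{i}",
            )
            for i in range(n)
        ]
        kept, summary = deduplicate(tags)
        assert brute_force_dedup_keys(kept) == brute_force_dedup_keys(tags)
        assert len(kept) == len(brute_force_dedup_keys(tags)) == summary.tags_retained
        shuffled = data.draw(st.permutations(tags))
        kept2, _ = deduplicate(shuffled)
        assert kept == kept2  # canonical sorted output


def test_tags_tsv_round_trip(tmp_path):
    tags = [make_tag(read_id=f"r{i}", pos5=100 + i) for i in range(5)]
    tags.append(make_tag(strand="-", pos5=300, read_id="rm",
                         blocks=((251, 261), (281, 301))))
    p = tmp_path / "tags.tsv"
    write_tags_tsv(tags, p)
    assert read_tags_tsv(p) == tags
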