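"""Cluster calling (proximity merge), quantification, hierarchical annotation."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from captss.clusters import Annotator, annotate_clusters, call_clusters, quantify_clusters
from captss.core import CoverageTrack, TagCluster


def union_find_clusters(positions, merge_dist):
    """Independent oracle: explicit union-find over all pairs."""
    pos = sorted(set(positions))
    parent = {p: p for p in pos}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for a in pos:
        for b in pos:
            if a < b and b - a <= merge_dist:
                parent[find(b)] = find(a)
    groups = {}
    for p in pos:
        groups.setdefault(find(p), []).append(p)
    return sorted((min(g), max(g) + 1) for g in groups.values())


class TestCallClusters:
    def test_gap_above_merge_distance_splits(self):
        out = call_clusters({("chr1", "+"): [100, 115, 140]}, 20)
        assert [(c.start, c.end) for c in out] == [(100, 116), (140, 141)]

    def test_gap_exactly_merge_distance_merges(self):
        out = call_clusters({("chr1", "+"): [100, 120, 140]}, 20)
        assert [(c.start, c.end) for c in out] == [(100, 141)]

    def test_opposite_strands_never_merge(self):
        out = call_clusters({("chr1", "+"): [100], ("chr1", "-"): [105]}, 20)
        assert len(out) == 2
        assert {c.strand for c in out} == {"+", "-"}

    @given(
        positions=st.sets(st.integers(0, 300), max_size=60),
        merge_dist=st.integers(1, 40),
    )
    @settings(deadline=None, max_examples=100)
    def test_matches_union_find_oracle(self, positions, merge_dist):
        out = call_clusters({("chr1", "+"): positions}, merge_dist)
        assert [(c.start, c.end) for c in out] == union_find_clusters(positions, merge_dist)

    @given(positions=st.sets(st.integers(0, 200), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_partition_and_monotonicity(self, positions):
        for merge_dist in (1, 5, 20):
            out = call_clusters({("chr1", "+"): positions}, merge_dist)
            covered = [p for c in out for p in positions if c.start <= p < c.end]
            assert sorted(covered) == sorted(positions)  # each position exactly once
        n = [len(call_clusters({("chr1", "+"): positions}, d)) for d in (1, 5, 20, 50)]
        assert n == sorted(n, reverse=True)


class TestQuantify:
    def _tracks(self, per_sample):
        out = {}
        for sample, counts in per_sample.items():
            out[sample] = (
                CoverageTrack(sample, "+", {("chr1", p): v for p, v in counts.items()},
                              sum(counts.values())),
                CoverageTrack(sample, "-", {}, sum(counts.values())),
            )
        return out

    def test_sums_span_including_subthreshold_positions(self):
        clusters = [TagCluster("chr1", "+", 100, 116)]
        tracks = self._tracks({"A": {100: 3, 115: 2}})
        quantify_clusters(clusters, tracks)
        assert clusters[0].counts == {"A": 5}

    def test_summit_tie_breaks_to_smallest_coordinate(self):
        clusters = [TagCluster("chr1", "+", 100, 116)]
        tracks = self._tracks({"A": {100: 4, 115: 4}})
        quantify_clusters(clusters, tracks)
        assert clusters[0].summit == 100

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(3)
        counts_a = {int(p): int(c) for p, c in zip(rng.integers(0, 100, 40),
                                                   rng.integers(1, 9, 40))}
        counts_b = {int(p): int(c) for p, c in zip(rng.integers(0, 100, 40),
                                                   rng.integers(1, 9, 40))}
        clusters = call_clusters({("chr1", "+"): set(counts_a) | set(counts_b)}, 10)
        tracks = self._tracks({"A": counts_a, "B": counts_b})
        quantify_clusters(clusters, tracks)
        for c in clusters:
            for sample, counts in (("A", counts_a), ("B", counts_b)):
                assert c.counts[sample] == sum(
                    v for p, v in counts.items() if c.start <= p < c.end
                )


class TestAnnotator:
    @pytest.mark.parametrize(
        "strand,pos,expected",
        [
            ("+", 950, "promoter"),    # within [-100, +100] of geneA TSS (1000)
            ("+", 1100, "promoter"),   # +100 boundary inclusive
            ("+", 600, "proximal"),    # 400 bp upstream, also antisense to geneB
            ("+", 1120, "utr5"),
            ("+", 1650, "exon"),
            ("+", 1950, "exon"),       # 3'UTR bases count as exonic sequence
            ("+", 1500, "intron"),
            ("-", 1500, "antisense"),  # inside geneA body on the opposite strand
            ("+", 8000, "intergenic"),
        ],
    )
    def test_category_assignment(self, hand_annotation, strand, pos, expected):
        ann = Annotator(hand_annotation)
        assert ann.category_at("chr1", strand, pos) == expected

    def test_conflicting_promoter_beats_antisense(self, hand_annotation):
        # 920 is inside geneA's promoter window AND inside minus-strand geneB
        ann = Annotator(hand_annotation)
        assert ann.category_at("chr1", "+", 920) == "promoter"

    def test_minus_strand_windows_are_mirrored(self, hand_annotation):
        ann = Annotator(hand_annotation)
        # geneB TSS = 949; promoter window covers [849, 1049] on the genome
        assert ann.category_at("chr1", "-", 1040) == "promoter"
        # 300 bp upstream (larger coordinate on minus strand) -> proximal
        assert ann.category_at("chr1", "-", 1249) == "proximal"

    def test_unknown_chromosome_errors(self, hand_annotation):
        ann = Annotator(hand_annotation)
        with pytest.raises(ValueError, match="unknown chromosome"):
            ann.category_at("chrX", "+", 100)

    def test_all_seven_categories_reachable_and_exclusive(self, hand_annotation):
        ann = Annotator(hand_annotation)
        seen = set()
        for strand in "+-":
            for pos in range(0, 10000, 1):
                seen.add(ann.category_at("chr1", strand, pos))
        assert seen == {
            "promoter", "proximal", "utr5", "exon", "intron", "antisense", "intergenic"
        }

    def test_interval_mode_pools_labels(self, hand_annotation):
        c = TagCluster("chr1", "+", 1550, 1650, summit=1550)
        ann = Annotator(hand_annotation)
        assert ann.annotate(c, mode="summit") == "intron"
        assert ann.annotate(c, mode="interval") == "exon"  # span reaches exon 2

    def test_annotate_clusters_sets_categories(self, hand_annotation):
        clusters = [
            TagCluster("chr1", "+", 940, 961, summit=950),
            TagCluster("chr1", "+", 7990, 8011, summit=8000),
        ]
        annotate_clusters(clusters, hand_annotation)
        assert [c.category for c in clusters] == ["promoter", "intergenic"]
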