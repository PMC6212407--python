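"""TSS tag-cluster calling, quantification, and hierarchical annotation.

Candidate positions (those passing the coverage filter, pooled across
samples) are merged into clusters by single-linkage proximity: two adjacent
positions on the same strand belong to one cluster iff their coordinate
difference is at most ``merge_dist`` (default 20 bp).  Each cluster is
represented by its summit — the base of maximal pooled count — and receives
one annotation category decided by a fixed priority order:

    intergenic < antisense < intron < exon < 5'UTR < proximal < promoter

Windows are oriented in the gene's direction: "promoter" is [-100, +100]
around the annotated gene TSS, "proximal" is [-500, -100) upstream of it.
"""
from __future__ import annotations

from typing import Iterable, Mapping

from intervaltree import IntervalTree

from .core import (
    CATEGORY_RANK,
    CoverageTrack,
    GenomeAnnotation,
    TagCluster,
)

DEFAULT_MERGE_DIST = 20
DEFAULT_PROXIMAL_WINDOW = (-500, -100)  # [-500, -100)
DEFAULT_PROMOTER_WINDOW = (-100, 100)  # [-100, +100] inclusive


def call_clusters(
    positions: Mapping[tuple[str, str], Iterable[int]],
    merge_dist: int = DEFAULT_MERGE_DIST,
) -> list[TagCluster]:
    """Merge candidate TSS positions into clusters per (chrom, strand).

    ``positions`` maps (chrom, strand) to candidate coordinates pooled
    across samples.  Clustering is the transitive closure of the pairwise
    "gap <= merge_dist" relation; the cluster interval spans
    [min member, max member + 1).  Counts are left unfilled.
    """
    clusters: list[TagCluster] = []
    for (chrom, strand) in sorted(positions):
        pos = sorted(set(positions[(chrom, strand)]))
        if not pos:
            continue
        start = prev = pos[0]
        for p in pos[1:]:
            if p - prev <= merge_dist:
                prev = p
            else:
                clusters.append(
                    TagCluster(chrom=chrom, strand=strand, start=start, end=prev + 1)
                )
                start = prev = p
        clusters.append(
            TagCluster(chrom=chrom, strand=strand, start=start, end=prev + 1)
        )
    return clusters


def quantify_clusters(
    clusters: list[TagCluster],
    tracks: Mapping[str, tuple[CoverageTrack, CoverageTrack]],
) -> list[TagCluster]:
    """Fill per-sample counts and the pooled summit of each cluster.

    ``tracks`` maps sample label to its raw (plus, minus) coverage pair.
    The per-sample count sums raw coverage over every base of the cluster
    span, including bases that individually failed the coverage filter.
    The summit is the position of maximal pooled count; ties break to the
    smallest coordinate.
    """
    for c in clusters:
        pooled: dict[int, float] = {}
        counts: dict[str, int] = {}
        for sample, (plus, minus) in tracks.items():
            track = plus if c.strand == "+" else minus
            s = 0
            for pos in range(c.start, c.end):
                v = track.counts.get((c.chrom, pos), 0)
                if v:
                    s += v
                    pooled[pos] = pooled.get(pos, 0) + v
            counts[sample] = int(s)
        c.counts = counts
        if pooled:
            c.summit = min(p for p in pooled if pooled[p] == max(pooled.values()))
        else:
            c.summit = c.start
        c.validate()
    return clusters


class Annotator:
    """Assigns annotation categories to genomic positions.

    Builds one interval tree per chromosome over gene bodies extended by the
    maximal window reach, then evaluates all candidate labels for a query
    point and returns the highest-priority one.
    """

    def __init__(
        self,
        annotation: GenomeAnnotation,
        proximal_window: tuple[int, int] = DEFAULT_PROXIMAL_WINDOW,
        promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
    ) -> None:
        self.annotation = annotation
        self.proximal_window = proximal_window
        self.promoter_window = promoter_window
        reach = max(
            abs(v) for v in (*proximal_window, *promoter_window)
        ) + 1
        self._trees: dict[str, IntervalTree] = {}
        for g in annotation.genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree.addi(g.start - reach, g.end + reach, g)

    def _labels_at(self, chrom: str, strand: str, pos: int) -> set[str]:
        labels = {"intergenic"}
        tree = self._trees.get(chrom)
        if tree is None:
            return labels
        for iv in tree.at(pos):
            g = iv.data
            inside = g.start <= pos < g.end
            if g.strand != strand:
                if inside:
                    labels.add("antisense")
                continue
            # relative position in gene orientation, 0 at the annotated TSS
            r = pos - g.tss if g.strand == "+" else g.tss - pos
            pmin, pmax = self.promoter_window
            if pmin <= r <= pmax:
                labels.add("promoter")
            xmin, xmax = self.proximal_window
            if xmin <= r < xmax:
                labels.add("proximal")
            if inside:
                if any(a <= pos < b for a, b in g.utr5):
                    labels.add("utr5")
                elif any(a <= pos < b for a, b in g.exons):
                    labels.add("exon")
                else:
                    labels.add("intron")
        return labels

    def category_at(self, chrom: str, strand: str, pos: int) -> str:
        """Category of a single base, resolved by the priority order."""
        if chrom not in self.annotation.chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        labels = self._labels_at(chrom, strand, pos)
        return max(labels, key=CATEGORY_RANK.__getitem__)

    def annotate(self, cluster: TagCluster, mode: str = "summit") -> str:
        """Annotate a cluster by its summit base (default) or whole interval.

        In ``interval`` mode the labels of every base in the span are pooled
        before applying the priority order.
        """
        if cluster.chrom not in self.annotation.chrom_sizes:
            raise ValueError(f"unknown chromosome {cluster.chrom!r}")
        if mode == "summit":
            pos = cluster.summit if cluster.summit is not None else cluster.start
            category = self.category_at(cluster.chrom, cluster.strand, pos)
        elif mode == "interval":
            labels: set[str] = set()
            for pos in range(cluster.start, cluster.end):
                labels |= self._labels_at(cluster.chrom, cluster.strand, pos)
            category = max(labels, key=CATEGORY_RANK.__getitem__)
        else:
            raise ValueError(f"unknown annotation mode {mode!r}")
        cluster.category = category
        return category


def annotate_clusters(
    clusters: list[TagCluster],
    annotation: GenomeAnnotation,
    proximal_window: tuple[int, int] = DEFAULT_PROXIMAL_WINDOW,
    promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
    mode: str = "summit",
) -> list[TagCluster]:
    ann = Annotator(annotation, proximal_window, promoter_window)
    for c in clusters:
        ann.annotate(c, mode=mode)
    return clusters
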