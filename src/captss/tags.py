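"""Alignment-to-tag reduction, contaminant and MAPQ filters, UMI dedup.

A TSS-seq alignment is informative only through its 5' terminus: each mapped
read becomes an :class:`~captss.core.AlignedTag` whose ``pos5`` is the
genomic base where transcription started.  Tags overlapping structural RNA
genes (rRNA/tRNA/snRNA/snoRNA) are contaminants of the capture chemistry and
are removed; so are ambiguous multimappers (MAPQ < 10).  PCR copies are
collapsed by keeping one tag per distinct UMI within each
(chrom, strand, 5' position) group.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .core import AlignedTag, GenomeAnnotation
from .preprocess import UMI_SEPARATOR

DEFAULT_EXCLUDED_BIOTYPES = frozenset({"rRNA", "tRNA", "snRNA", "snoRNA"})
DEFAULT_MIN_MAPQ = 10

_UMI_WORD = re.compile(r"^[ACGTN]+$")


class UMIParseError(ValueError):
    """Read name does not carry a UMI with the preprocess convention."""


def parse_umi_from_name(name: str, umi_len: int = 8, sep: str = UMI_SEPARATOR) -> str:
    head, _, umi = name.rpartition(sep)
    if not head or len(umi) != umi_len or not _UMI_WORD.match(umi):
        raise UMIParseError(
            f"read name {name!r} does not end in {sep!r} + {umi_len}-mer UMI; "
            f"was the FASTQ preprocessed with the same convention?"
        )
    return umi


def to_tags(
    alignments: Iterable,
    sample: str,
    umi_len: int = 8,
) -> tuple[list[AlignedTag], int]:
    """Reduce mapped alignment records to 5' tags.

    Returns ``(tags, n_unmapped_skipped)``.  The 5' position is the leftmost
    aligned base for plus-strand alignments and the rightmost aligned base
    (across all splice blocks) for minus-strand alignments.
    """
    tags: list[AlignedTag] = []
    n_unmapped = 0
    for rec in alignments:
        if rec.is_unmapped:
            n_unmapped += 1
            continue
        blocks = tuple(rec.get_blocks())
        strand = "-" if rec.is_reverse else "+"
        pos5 = blocks[0][0] if strand == "+" else blocks[-1][1] - 1
        tags.append(
            AlignedTag(
                chrom=rec.reference_name,
                strand=strand,
                pos5=pos5,
                mapq=rec.mapping_quality,
                umi=parse_umi_from_name(rec.query_name, umi_len),
                sample=sample,
                read_id=rec.query_name,
                blocks=blocks,
            )
        )
    return tags, n_unmapped


def filter_biotype(
    tags: Iterable[AlignedTag],
    annotation: GenomeAnnotation,
    excluded: frozenset[str] | set[str] = DEFAULT_EXCLUDED_BIOTYPES,
) -> list[AlignedTag]:
    """Drop tags whose aligned blocks overlap any excluded-biotype gene.

    The overlap test is strand-blind: contaminant reads map to both strands
    of the structural RNA loci, so a 1-bp overlap on either strand removes
    the tag.
    """
    trees: dict[str, IntervalTree] = {}
    for g in annotation.genes_by_biotype(excluded):
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
    kept = []
    for t in tags:
        tree = trees.get(t.chrom)
        blocks = t.blocks or ((t.pos5, t.pos5 + 1),)
        if tree is not None and any(tree.overlap(a, b) for a, b in blocks):
            continue
        kept.append(t)
    return kept


def filter_mapq(
    tags: Iterable[AlignedTag], min_mapq: int = DEFAULT_MIN_MAPQ
) -> list[AlignedTag]:
    """Keep tags with MAPQ >= ``min_mapq`` (boundary inclusive)."""
    return [t for t in tags if t.mapq >= min_mapq]


@dataclass
class DedupSummary:
    tags_in: int = 0
    tags_retained: int = 0

    @property
    def duplicates_removed(self) -> int:
        return self.tags_in - self.tags_retained


def deduplicate(tags: Sequence[AlignedTag]) -> tuple[list[AlignedTag], DedupSummary]:
    """Collapse PCR duplicates: one tag per (chrom, strand, pos5, UMI).

    UMI matching is exact.  Within a duplicate group the retained tag is the
    first by (pos5, read id) lexicographic order; which copy survives is
    irrelevant downstream, only the 5' event counts.  Idempotent and
    order-independent as a multiset.
    """
    best: dict[tuple[str, str, int, str], AlignedTag] = {}
    n_in = 0
    for t in tags:
        n_in += 1
        key = (t.chrom, t.strand, t.pos5, t.umi)
        cur = best.get(key)
        if cur is None or (t.pos5, t.read_id) < (cur.pos5, cur.read_id):
            best[key] = t
    retained = sorted(best.values(), key=lambda t: (t.chrom, t.strand, t.pos5, t.umi))
    return retained, DedupSummary(tags_in=n_in, tags_retained=len(retained))


# -- tag table I/O ---------------------------------------------------------

_TAG_COLUMNS = ["chrom", "pos5", "strand", "mapq", "umi", "sample", "read_id", "blocks"]


def _blocks_to_str(blocks: tuple) -> str:
    return ",".join(f"{a}-{b}" for a, b in blocks) or "."


def _blocks_from_str(s: str) -> tuple:
    if s == "." or not s:
        return ()
    return tuple(tuple(int(x) for x in part.split("-")) for part in s.split(","))


def write_tags_tsv(tags: Iterable[AlignedTag], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TAG_COLUMNS) + "\n")
        for t in tags:
            fh.write(
                f"{t.chrom}\t{t.pos5}\t{t.strand}\t{t.mapq}\t{t.umi}\t{t.sample}\t"
                f"{t.read_id}\t{_blocks_to_str(t.blocks)}\n"
            )


def read_tags_tsv(path: str) -> list[AlignedTag]:
    tags = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TAG_COLUMNS:
            raise ValueError(f"{path}: unexpected tag table header {header}")
        for line in fh:
            chrom, pos5, strand, mapq, umi, sample, read_id, blocks = line.rstrip(
                "\n"
            ).split("\t")
            tags.append(
                AlignedTag(
                    chrom=chrom,
                    strand=strand,
                    pos5=int(pos5),
                    mapq=int(mapq),
                    umi=umi,
                    sample=sample,
                    read_id=read_id,
                    blocks=_blocks_from_str(blocks),
                )
            )
    return tags
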