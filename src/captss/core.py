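"""Core domain records shared across pipeline stages.

All genomic coordinates are 0-based half-open throughout the package;
1-based formats (GFF3) are converted at the I/O boundary.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

Interval = tuple[int, int]

_UMI_RE = re.compile(r"^[ACGTN]+$")


@dataclass
class Read:
    """A sequencing read, optionally carrying an extracted 5' UMI."""

    id: str
    bases: str
    quals: str
    umi: str | None = None

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: bases ({len(self.bases)}) and qualities "
                f"({len(self.quals)}) differ in length"
            )
        if self.umi is not None and not _UMI_RE.match(self.umi):
            raise ValueError(f"read {self.id!r}: UMI {self.umi!r} is not a DNA word")


@dataclass(frozen=True)
class AlignedTag:
    """One aligned read reduced to its informative 5' event.

    ``pos5`` is the genomic base where the read's 5' end maps: the leftmost
    aligned base on the plus strand, the rightmost on the minus strand.
    ``blocks`` keeps the aligned genomic intervals (split across introns for
    spliced alignments) for feature-overlap filtering.
    """

    chrom: str
    strand: str
    pos5: int
    mapq: int
    umi: str
    sample: str
    read_id: str = ""
    blocks: tuple[Interval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class GeneModel:
    """A gene with merged exon structure and UTRs, 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "protein_coding"
    exons: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def tss(self) -> int:
        """The annotated transcription start site base."""
        return self.start if self.strand == "+" else self.end - 1

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.gene_id}: empty or negative interval")
        for name, ivs in (("exon", self.exons), ("utr5", self.utr5), ("utr3", self.utr3)):
            for a, b in ivs:
                if not (self.start <= a < b <= self.end):
                    raise ValueError(
                        f"{self.gene_id}: {name} [{a},{b}) outside gene "
                        f"[{self.start},{self.end})"
                    )
        for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]):
            if a2 < b1:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")


@dataclass
class GenomeAnnotation:
    chrom_sizes: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)

    def validate(self) -> None:
        for g in self.genes:
            g.validate()
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom!r}")
            if g.end > size:
                raise ValueError(
                    f"{g.gene_id}: gene end {g.end} exceeds {g.chrom} length {size}"
                )

    def genes_by_biotype(self, biotypes: frozenset[str] | set[str]) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype in biotypes]


@dataclass
class CoverageTrack:
    """Single-base 5'-tag counts for one strand of one sample.

    ``total_tags`` is the tag total over *both* strands of the sample, so a
    plus/minus pair built together shares one normalization denominator.
    Zero-count positions are never stored.
    """

    sample: str
    strand: str
    counts: dict[tuple[str, int], float] = field(default_factory=dict)
    total_tags: int = 0


#: Annotation categories, lowest to highest priority.
CATEGORY_HIERARCHY = (
    "intergenic",
    "antisense",
    "intron",
    "exon",
    "utr5",
    "proximal",
    "promoter",
)
CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORY_HIERARCHY)}


@dataclass
class TagCluster:
    """A called TSS tag cluster."""

    chrom: str
    strand: str
    start: int
    end: int
    summit: int | None = None
    counts: dict[str, int] = field(default_factory=dict)
    category: str | None = None

    @property
    def cluster_id(self) -> str:
        return f"{self.chrom}:{self.strand}:{self.start}-{self.end}"

    def validate(self) -> None:
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(f"{self.cluster_id}: summit outside interval")
        if self.category is not None and self.category not in CATEGORY_RANK:
            raise ValueError(f"{self.cluster_id}: unknown category {self.category!r}")
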