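"""Shared fixtures: a small hand-built annotation and tag helpers.

The hand annotation is designed so that every one of the seven annotation
categories is reachable and at least one position is deliberately
conflicted (inside a same-strand promoter window *and* an opposite-strand
gene body).
"""
from __future__ import annotations

import pytest

from captss.core import AlignedTag, GeneModel, GenomeAnnotation


@pytest.fixture
def hand_annotation() -> GenomeAnnotation:
    gene_a = GeneModel(
        gene_id="geneA",
        chrom="chr1",
        strand="+",
        start=1000,
        end=2000,
        biotype="protein_coding",
        exons=[(1000, 1400), (1600, 2000)],
        utr5=[(1000, 1150)],
        utr3=[(1900, 2000)],
    )
    # minus-strand gene whose body overlaps geneA's promoter window [900, 1100]
    gene_b = GeneModel(
        gene_id="geneB",
        chrom="chr1",
        strand="-",
        start=600,
        end=950,
        biotype="protein_coding",
        exons=[(600, 950)],
    )
    rrna = GeneModel(
        gene_id="rrna1", chrom="chr1", strand="+", start=5000, end=5300, biotype="rRNA"
    )
    ann = GenomeAnnotation(
        chrom_sizes={"chr1": 10000, "chr2": 8000},
        genes=[gene_a, gene_b, rrna],
    )
    ann.validate()
    return ann


def make_tag(
    chrom="chr1",
    strand="+",
    pos5=100,
    mapq=255,
    umi="AACCGGTT",
    sample="s1",
    read_id="r1",
    blocks=None,
):
    if blocks is None:
        blocks = ((pos5, pos5 + 50),) if strand == "+" else ((max(pos5 - 49, 0), pos5 + 1),)
    return AlignedTag(
        chrom=chrom, strand=strand, pos5=pos5, mapq=mapq, umi=umi,
        sample=sample, read_id=read_id, blocks=tuple(blocks),
    )
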