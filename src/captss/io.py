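"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions: everything in memory is 0-based half-open.  GFF3
(1-based inclusive) is converted on read and write; bedGraph and BED are
already 0-based half-open and pass through unchanged.
"""
from __future__ import annotations

import gzip
import warnings
from typing import IO, Iterator

import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .core import CoverageTrack, GeneModel, GenomeAnnotation, Interval, Read, TagCluster

__all__ = [
    "FastqParseError",
    "read_fastq",
    "open_maybe_gzip",
    "read_alignments",
    "read_gff",
    "write_gff",
    "read_bedgraph",
    "write_bedgraph",
    "write_bed3",
    "write_clusters_bed",
]


class FastqParseError(ValueError):
    pass


def open_maybe_gzip(path: str, mode: str = "rt") -> IO:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str) -> Iterator[Read]:
    """Yield reads from a (optionally gzipped) 4-line-per-record FASTQ file.

    Malformed records raise :class:`FastqParseError` naming the offending
    line number.
    """
    n = 0
    with open_maybe_gzip(path) as fh:
        it = FastqGeneralIterator(fh)
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as err:
                raise FastqParseError(
                    f"{path}: malformed FASTQ record near line {4 * n + 1}: {err}"
                ) from err
            n += 1
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: record near line {4 * (n - 1) + 1}: sequence and "
                    f"quality lengths differ"
                )
            yield Read(id=title.split()[0], bases=seq, quals=qual)


def write_fastq(reads, path: str) -> int:
    n = 0
    with open_maybe_gzip(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.bases}\n+\n{r.quals}\n")
            n += 1
    return n


def read_alignments(path: str) -> Iterator[pysam.AlignedSegment]:
    """Yield alignment records from a SAM/BAM file in file order.

    Unmapped records are yielded too (flagged via ``is_unmapped``); filtering
    is the caller's job.  A file without a sequence dictionary in its header
    is rejected.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as fh:
        if fh.header.nreferences == 0:
            raise ValueError(f"{path}: SAM/BAM header has no sequence dictionary")
        yield from fh.fetch(until_eof=True)


# -- GFF3 ------------------------------------------------------------------

_KNOWN_BIOTYPES = {"protein_coding", "rRNA", "tRNA", "snRNA", "snoRNA"}
_BIOTYPE_KEYS = ("biotype", "gene_biotype", "locus_type")
_CHILD_TYPES = ("exon", "five_prime_UTR", "three_prime_UTR")


def _merge_intervals(ivs: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for a, b in sorted(ivs):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def read_gff(path: str) -> GenomeAnnotation:
    """Load a GFF3 annotation into a :class:`GenomeAnnotation`.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    The gene biotype is read from the first of the ``biotype``,
    ``gene_biotype`` or ``locus_type`` attributes (default
    ``protein_coding``; unrecognized values map to ``other``).  Child
    features whose parent chain does not reach a gene are skipped with a
    warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    chrom_sizes: dict[str, int] = {}
    for d in db.directives:
        if d.startswith("sequence-region"):
            parts = d.split()
            if len(parts) >= 4:
                chrom_sizes[parts[1]] = int(parts[3])

    genes: list[GeneModel] = []
    for f in db.features_of_type("gene", order_by=("seqid", "start")):
        biotype = "protein_coding"
        for key in _BIOTYPE_KEYS:
            if key in f.attributes:
                val = f.attributes[key][0]
                biotype = val if val in _KNOWN_BIOTYPES else "other"
                break
        exons: list[Interval] = []
        utr5: list[Interval] = []
        utr3: list[Interval] = []
        for c in db.children(f.id):
            iv = (c.start - 1, c.end)
            if c.featuretype == "exon":
                exons.append(iv)
            elif c.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif c.featuretype == "three_prime_UTR":
                utr3.append(iv)
        genes.append(
            GeneModel(
                gene_id=f.id,
                chrom=f.seqid,
                strand=f.strand,
                start=f.start - 1,
                end=f.end,
                biotype=biotype,
                exons=_merge_intervals(exons),
                utr5=_merge_intervals(utr5),
                utr3=_merge_intervals(utr3),
            )
        )

    gene_ids = {g.gene_id for g in genes}
    for f in db.features_of_type(_CHILD_TYPES):
        if not any(p.id in gene_ids for p in db.parents(f, featuretype="gene")):
            warnings.warn(
                f"{path}: {f.featuretype} at {f.seqid}:{f.start}-{f.end} has no "
                f"parent gene; skipped"
            )

    if not chrom_sizes:
        for g in genes:
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)
    ann = GenomeAnnotation(chrom_sizes=chrom_sizes, genes=genes)
    ann.validate()
    return ann


def write_gff(annotation: GenomeAnnotation, path: str) -> None:
    """Write a GenomeAnnotation as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chrom_sizes):
            fh.write(f"##sequence-region {chrom} 1 {annotation.chrom_sizes[chrom]}\n")
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start)):
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            fh.write(
                f"{g.chrom}\tcaptss\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tcaptss\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for ftype, ivs in (
                ("exon", g.exons),
                ("five_prime_UTR", g.utr5),
                ("three_prime_UTR", g.utr3),
            ):
                for i, (a, b) in enumerate(ivs, 1):
                    fh.write(
                        f"{g.chrom}\tcaptss\t{ftype}\t{a + 1}\t{b}\t.\t{g.strand}\t.\t"
                        f"ID={mrna_id}.{ftype}.{i};Parent={mrna_id}\n"
                    )


# -- bedGraph / BED --------------------------------------------------------

def _fmt(value: float) -> str:
    if float(value).is_integer():
        return str(int(value))
    return repr(round(float(value), 6))


def write_bedgraph(
    track: CoverageTrack,
    path: str,
    strand_sign: int = 1,
    chrom_sizes: dict[str, int] | None = None,
    mode: str = "w",
) -> None:
    """Write a coverage track as bedGraph, merging adjacent equal-value runs.

    With ``strand_sign=-1`` values are negated, the convention used when the
    two strands of a sample are combined into one signed browser track
    (write the plus track, then append the minus track with ``mode="a"``).
    """
    if strand_sign not in (1, -1):
        raise ValueError("strand_sign must be +1 or -1")
    items = sorted(track.counts.items())
    with open(path, mode) as fh:
        run: list = []  # chrom, start, end, value
        for (chrom, pos), value in items:
            if chrom_sizes is not None and pos >= chrom_sizes.get(chrom, float("inf")):
                raise ValueError(
                    f"position {chrom}:{pos} outside chromosome length "
                    f"{chrom_sizes.get(chrom)}"
                )
            v = value * strand_sign
            if run and run[0] == chrom and run[2] == pos and run[3] == v:
                run[2] = pos + 1
            else:
                if run:
                    fh.write(f"{run[0]}\t{run[1]}\t{run[2]}\t{_fmt(run[3])}\n")
                run = [chrom, pos, pos + 1, v]
        if run:
            fh.write(f"{run[0]}\t{run[1]}\t{run[2]}\t{_fmt(run[3])}\n")


def read_bedgraph(path: str) -> dict[tuple[str, int], float]:
    """Read a bedGraph file, expanding intervals to single-base resolution."""
    counts: dict[tuple[str, int], float] = {}
    with open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")
            v = float(value)
            for pos in range(int(start), int(end)):
                counts[(chrom, pos)] = v
    return counts


def write_bed3(positions, path: str) -> None:
    """Write single-base positions as BED3 records."""
    with open(path, "w") as fh:
        for chrom, pos in sorted(positions):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\n")


def write_clusters_bed(clusters: list[TagCluster], path: str) -> None:
    """Write tag clusters as BED6 (score = pooled count capped at 1000)."""
    with open(path, "w") as fh:
        for c in sorted(clusters, key=lambda c: (c.chrom, c.start)):
            score = min(int(sum(c.counts.values())), 1000)
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_id}\t{score}\t{c.strand}\n"
            )
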