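"""FASTQ-level preprocessing: 3' adapter trimming, then 5' UMI extraction.

The protocol ligates an 8-nt random barcode (UMI) to the 5' end of each
fragment and a fixed adapter is read into the 3' end of short inserts.
Preprocessing removes the best 3'-terminal adapter occurrence, then moves
the leading UMI bases into the read name so the deduplication stage can
recover them after alignment.  The adapter is trimmed before UMI
extraction: the UMI is ligated 5' of the insert, so the adapter boundary
is defined on the untouched 3' end.
"""
from __future__ import annotations

from dataclasses import dataclass

from . import io
from .core import Read

DEFAULT_ADAPTER = "ATCTCGTATGCCG"
UMI_SEPARATOR = "_"  # dedup parses the same convention


def trim_adapter(
    read: Read,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
) -> Read:
    """Remove the best 3'-terminal adapter occurrence and everything after it.

    Candidate matches are full adapter occurrences anywhere in the read and
    partial matches where a prefix of the adapter (>= ``min_overlap`` bases)
    runs into the 3' end of the read.  Among candidates within
    ``max_error_rate`` (mismatches / overlap length), the longest overlap
    wins; ties go to the leftmost (most-trimming) position.  A read without
    a match is returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    bases = read.bases
    n, m = len(bases), len(adapter)
    best: tuple[int, int] | None = None  # (overlap, -start)
    for start in range(0, n - min_overlap + 1):
        overlap = min(m, n - start)
        if overlap < m and start + overlap != n:
            continue  # partial matches must run into the 3' end
        errors = sum(1 for i in range(overlap) if bases[start + i] != adapter[i])
        if errors <= max_error_rate * overlap:
            cand = (overlap, -start)
            if best is None or cand > best:
                best = cand
    if best is None:
        return read
    cut = -best[1]
    return Read(id=read.id, bases=bases[:cut], quals=read.quals[:cut], umi=read.umi)


def extract_umi(read: Read, umi_len: int = 8) -> Read | None:
    """Move the first ``umi_len`` bases into the UMI field and the read name.

    Returns ``None`` for reads too short to leave at least one base of
    insert; callers count those as dropped.
    """
    if len(read.bases) <= umi_len:
        return None
    umi = read.bases[:umi_len]
    return Read(
        id=f"{read.id}{UMI_SEPARATOR}{umi}",
        bases=read.bases[umi_len:],
        quals=read.quals[umi_len:],
        umi=umi,
    )


@dataclass
class PreprocessSummary:
    reads_in: int = 0
    reads_out: int = 0
    reads_dropped: int = 0
    adapter_trimmed: int = 0

    def validate(self) -> None:
        if self.reads_in != self.reads_out + self.reads_dropped:
            raise AssertionError("preprocess summary counts are inconsistent")


def preprocess_fastq(
    in_path: str,
    out_path: str,
    adapter: str = DEFAULT_ADAPTER,
    umi_len: int = 8,
    min_overlap: int = 3,
    max_error_rate: float = 0.1,
) -> PreprocessSummary:
    """Adapter-trim and UMI-extract a FASTQ file, preserving read order."""
    summary = PreprocessSummary()

    def _process():
        for read in io.read_fastq(in_path):
            summary.reads_in += 1
            trimmed = trim_adapter(read, adapter, min_overlap, max_error_rate)
            if len(trimmed.bases) < len(read.bases):
                summary.adapter_trimmed += 1
            out = extract_umi(trimmed, umi_len)
            if out is None:
                summary.reads_dropped += 1
                continue
            summary.reads_out += 1
            yield out

    io.write_fastq(_process(), out_path)
    summary.validate()
    return summary
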