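"""Stranded single-base 5'-tag coverage, CPM normalization, >=2x filter.

Raw per-sample counts feed the statistics (a count threshold on integers is
exact and the differential test needs raw counts); per-million normalization
exists for browser tracks and reporting only.
"""
from __future__ import annotations

from typing import Iterable

from .core import AlignedTag, CoverageTrack

DEFAULT_MIN_COUNT = 2


def build_coverage(tags: Iterable[AlignedTag]) -> tuple[CoverageTrack, CoverageTrack]:
    """Count deduplicated 5' tags per (chrom, position) on each strand.

    Both returned tracks share ``total_tags`` (the two-strand total of the
    sample) so normalization uses one denominator.
    """
    sample = ""
    plus: dict[tuple[str, int], float] = {}
    minus: dict[tuple[str, int], float] = {}
    total = 0
    for t in tags:
        sample = sample or t.sample
        d = plus if t.strand == "+" else minus
        key = (t.chrom, t.pos5)
        d[key] = d.get(key, 0) + 1
        total += 1
    return (
        CoverageTrack(sample=sample, strand="+", counts=plus, total_tags=total),
        CoverageTrack(sample=sample, strand="-", counts=minus, total_tags=total),
    )


def normalize_cpm(
    plus: CoverageTrack, minus: CoverageTrack
) -> tuple[CoverageTrack, CoverageTrack]:
    """Scale both strands by 1e6 / total tags (shared denominator).

    The normalized values over both strands sum to one million within
    floating-point tolerance.
    """
    total = plus.total_tags
    if total != minus.total_tags:
        raise ValueError("plus/minus tracks do not share a total; not a pair")
    if total == 0:
        raise ValueError("cannot normalize an empty sample (total_tags = 0)")
    scale = 1e6 / total
    out = []
    for track in (plus, minus):
        out.append(
            CoverageTrack(
                sample=track.sample,
                strand=track.strand,
                counts={k: v * scale for k, v in track.counts.items()},
                total_tags=track.total_tags,
            )
        )
    return out[0], out[1]


def threshold_positions(
    track: CoverageTrack, min_count: float = DEFAULT_MIN_COUNT
) -> set[tuple[str, int]]:
    """Positions whose raw count passes the coverage filter (>= min_count)."""
    return {key for key, v in track.counts.items() if v >= min_count}
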