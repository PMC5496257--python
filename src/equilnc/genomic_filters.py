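"""Filter 2 (length) and Filter 4 (proximity to protein-coding genes).

Filter 2 removes transcripts shorter than 200 bp. Filter 4 removes
candidates whose genomic span lies within 1 kb of a likely protein-coding
gene on the same strand: gene spans are extended by the flank on both
sides and a candidate is removed when its span overlaps (>= 1 bp, closed
coordinates, so abutting at distance 0 counts) any extended span on the
same chromosome and strand. Candidates of unknown strand are compared
against both strands (conservative removal).

The interval engine is backed by :mod:`intervaltree`; a brute-force
equivalence oracle lives in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .io_model import Category, TranscriptRecord

__all__ = [
    "GeneSpan",
    "apply_filter2",
    "extend_span",
    "apply_filter4",
    "interval_overlaps",
    "gene_spans_from_records",
    "read_gene_spans",
]


@dataclass(frozen=True)
class GeneSpan:
    """Genomic span of a (likely) protein-coding gene, 1-based closed."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


def apply_filter2(
    records: Sequence[TranscriptRecord],
    min_len: int = 200,
    categories: Iterable[Category] | None = None,
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Split records into (retained, removed) by spliced length.

    A transcript is retained iff ``length_bp >= min_len``. When
    ``categories`` is given, the rule is applied only to transcripts of
    those categories (others pass unconditionally) — multi-source inputs
    are sometimes pre-filtered for length upstream.
    """
    cats = set(categories) if categories is not None else None
    retained: list[TranscriptRecord] = []
    removed: list[TranscriptRecord] = []
    for r in records:
        if cats is not None and r.category not in cats:
            retained.append(r)
        elif r.length_bp >= min_len:
            retained.append(r)
        else:
            removed.append(r)
    return retained, removed


def extend_span(g: GeneSpan, flank: int = 1000) -> GeneSpan:
    """Extend a gene span by ``flank`` bp both ways, clamped at position 1."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    return replace(g, start=max(1, g.start - flank), end=g.end + flank)


def _strand_keys(strand: str) -> tuple[str, ...]:
    # unknown-strand features are indexed/queried on both strands
    return ("+", "-") if strand == "unknown" else (strand,)


def apply_filter4(
    candidates: Sequence[TranscriptRecord],
    genes: Iterable[GeneSpan],
    flank: int = 1000,
    same_strand_only: bool = True,
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Split candidates into (retained, removed) by gene proximity.

    A candidate is removed iff its genomic span (first exon start to last
    exon end — introns included) overlaps any gene span extended by
    ``flank`` on the same chromosome and, when ``same_strand_only``, the
    same strand. Unknown-strand candidates or genes match either strand.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes:
        eg = extend_span(g, flank)
        strands = _strand_keys(eg.strand) if same_strand_only else ("+", "-")
        for st in strands:
            # half-open tree coordinates: closed [s, e] -> [s, e + 1)
            trees.setdefault((eg.chrom, st), IntervalTree()).addi(eg.start, eg.end + 1, g.gene_id)

    retained: list[TranscriptRecord] = []
    removed: list[TranscriptRecord] = []
    for r in candidates:
        s, e = r.span
        hit = False
        for st in (_strand_keys(r.strand) if same_strand_only else ("+",)):
            tree = trees.get((r.chrom, st))
            if tree is not None and tree.overlap(s, e + 1):
                hit = True
                break
        (removed if hit else retained).append(r)
    return retained, removed


def interval_overlaps(
    a: Sequence[tuple[str, int, int]], b: Sequence[tuple[str, int, int]]
) -> list[tuple[int, int]]:
    """All overlapping index pairs between two 1-based closed interval sets.

    Each interval is ``(chrom, start, end)``. Returns pairs ``(i, j)`` with
    ``a[i]`` overlapping ``b[j]`` (shared chromosome and
    ``a.start <= b.end and b.start <= a.end``), sorted by (i, j).
    """
    trees: dict[str, IntervalTree] = {}
    for j, (chrom, s, e) in enumerate(b):
        if s > e:
            raise ValueError(f"b[{j}]: start > end")
        trees.setdefault(chrom, IntervalTree()).addi(s, e + 1, j)
    pairs: list[tuple[int, int]] = []
    for i, (chrom, s, e) in enumerate(a):
        if s > e:
            raise ValueError(f"a[{i}]: start > end")
        tree = trees.get(chrom)
        if tree is None:
            continue
        pairs.extend((i, iv.data) for iv in tree.overlap(s, e + 1))
    pairs.sort()
    return pairs


def gene_spans_from_records(records: Iterable[TranscriptRecord]) -> list[GeneSpan]:
    """Collapse transcript records to per-gene genomic spans.

    Used to build the Filter-4 gene set from a reference transcriptome:
    the span of a gene is the union span of its transcripts; conflicting
    strands within one gene collapse to 'unknown' (matched to both).
    """
    spans: dict[tuple[str, str], list] = {}
    for r in records:
        s, e = r.span
        key = (r.gene_id or r.transcript_id, r.chrom)
        cur = spans.get(key)
        if cur is None:
            spans[key] = [r.strand, s, e]
        else:
            if cur[0] != r.strand:
                cur[0] = "unknown"
            cur[1] = min(cur[1], s)
            cur[2] = max(cur[2], e)
    return [
        GeneSpan(gene_id=gid, chrom=chrom, strand=st, start=s, end=e)
        for (gid, chrom), (st, s, e) in sorted(spans.items())
    ]


def read_gene_spans(path) -> list[GeneSpan]:
    """Read gene spans from a GTF or a BED6 file (detected by content).

    BED coordinates (0-based half-open) are converted to the internal
    1-based closed convention; BED strand '.' becomes 'unknown'.
    """
    from pathlib import Path

    from .io_model import read_annotation

    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                first = line
                break
    n_fields = len(first.rstrip("\n").split("\t"))
    if n_fields == 9:
        return gene_spans_from_records(read_annotation(path))
    spans = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns")
            spans.append(GeneSpan(gene_id=f[3], chrom=f[0],
                                  strand=f[5] if f[5] in "+-" else "unknown",
                                  start=int(f[1]) + 1, end=int(f[2])))
    return spans
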