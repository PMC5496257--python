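"""Core transcript data model and readers/writers for GTF, FASTA, BED12 and TSV.

Coordinates are GTF-style (1-based, closed) everywhere inside the package;
BED12 output converts to 0-based half-open on the way out. Transcript
categories follow the five input groups of multi-tissue lncRNA annotation
pipelines (novel I/II/III, intergenic, previously known lncRNA) plus
``protein_coding`` for reference transcripts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("equilnc")

__all__ = [
    "Category",
    "TranscriptRecord",
    "ExpressionMatrix",
    "FilterReport",
    "AnnotationParseError",
    "read_annotation",
    "attach_sequences",
    "write_results",
    "read_expression",
    "gc_percent",
]


class Category(str, Enum):
    """Input category of a candidate transcript."""

    novel_I = "novel_I"
    novel_II = "novel_II"
    novel_III = "novel_III"
    intergenic = "intergenic"
    known_lncRNA = "known_lncRNA"
    protein_coding = "protein_coding"


def gc_percent(sequence: str) -> float:
    """GC content in percent, ignoring IUPAC ambiguity codes.

    Ambiguous bases (N and other non-ACGT letters) are excluded from both
    numerator and denominator, so gc_percent + at_percent == 100 holds on
    the unambiguous part of the sequence. Returns 0.0 for sequences with no
    unambiguous base.
    """
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    denom = gc + at
    if denom == 0:
        return 0.0
    return 100.0 * gc / denom


@dataclass(frozen=True)
class TranscriptRecord:
    """One spliced transcript with its genomic structure and sequence.

    ``exons`` are 1-based closed genomic intervals, sorted and
    non-overlapping. ``sequence`` is the spliced sense-strand sequence when
    attached; ``sequence_missing`` marks records that had no FASTA entry and
    must be excluded from sequence-dependent filters.
    """

    transcript_id: str
    gene_id: str = ""
    category: Category = Category.intergenic
    chrom: str = ""
    strand: str = "unknown"  # '+', '-' or 'unknown'
    exons: tuple[tuple[int, int], ...] = ()
    sequence: str | None = None
    sequence_missing: bool = False

    def __post_init__(self) -> None:
        ex = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        for (a, b) in ex:
            if a > b:
                raise ValueError(f"{self.transcript_id}: exon {a}-{b} has start > end")
        for (_, b0), (a1, _) in zip(ex, ex[1:]):
            if a1 <= b0:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        object.__setattr__(self, "exons", ex)

    @property
    def length_bp(self) -> int:
        if self.sequence is not None:
            return len(self.sequence)
        return sum(b - a + 1 for a, b in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span (first exon start, last exon end), 1-based closed."""
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        return self.exons[0][0], self.exons[-1][1]

    @property
    def gc_percent(self) -> float:
        if self.sequence is None:
            raise ValueError(f"{self.transcript_id}: no sequence attached")
        return gc_percent(self.sequence)

    def with_sequence(self, sequence: str) -> "TranscriptRecord":
        return replace(self, sequence=sequence, sequence_missing=False)


@dataclass
class ExpressionMatrix:
    """Transcript x tissue TPM table with per-tissue library-prep metadata.

    ``values`` is a pandas DataFrame indexed by transcript_id with one
    column per tissue. ``library_prep`` maps tissue name to one of
    ``rRNA_depleted``, ``polyA``, ``ovation`` or ``unknown``.
    """

    values: pd.DataFrame
    library_prep: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.rename(columns=str)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative values")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate tissue names")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate transcript ids")
        for t in self.values.columns:
            self.library_prep.setdefault(str(t), "unknown")

    @property
    def tissues(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    def tpm(self, transcript_id: str) -> np.ndarray:
        """TPM vector across tissues; all-zero for unknown transcripts."""
        if transcript_id in self.values.index:
            return self.values.loc[transcript_id].to_numpy(dtype=float)
        return np.zeros(len(self.values.columns))

    def mean_tpm(self, transcript_id: str) -> float:
        return float(self.tpm(transcript_id).mean()) if len(self.tissues) else 0.0

    def subset(self, transcript_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [t for t in transcript_ids if t in self.values.index]
        return ExpressionMatrix(self.values.loc[ids].copy(), dict(self.library_prep))


STAGES = ("initial", "F1", "F2", "F3", "F4", "rescued", "final")


@dataclass
class FilterReport:
    """Per-category ledger of counts and cumulative TPM removed per stage.

    ``counts`` and ``tpm_removed`` are DataFrames (category rows, stage
    columns); ``summary`` carries the final-set statistics per category:
    mean spliced length (kb), mean TPM, GC% and total bp.
    """

    counts: pd.DataFrame
    tpm_removed: pd.DataFrame
    summary: pd.DataFrame

    def validate(self) -> None:
        filt = ["initial", "F1", "F2", "F3", "F4"]
        c = self.counts[filt].to_numpy()
        if (np.diff(c, axis=1) > 0).any():
            raise ValueError("counts increase along the filter cascade")
        if not (self.counts["final"] == self.counts["F4"] + self.counts["rescued"]).all():
            raise ValueError("final != F4 + rescued")
        if (self.tpm_removed.to_numpy() < 0).any():
            raise ValueError("negative TPM removed")

    def write(self, counts_path: Path | str, summary_path: Path | str) -> None:
        merged = pd.concat(
            {"count": self.counts, "tpm_removed": self.tpm_removed}, axis=1
        )
        merged.columns = [f"{a}_{b}" for a, b in merged.columns]
        merged.to_csv(counts_path, sep="\t", index_label="category")
        self.summary.to_csv(summary_path, sep="\t", index_label="category")


class AnnotationParseError(ValueError):
    pass


_STRAND_IN = {"+": "+", "-": "-"}


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().strip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise AnnotationParseError(f"malformed attribute {chunk!r}")
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_annotation(
    gtf_path: Path | str,
    category_attribute: str = "category",
    default_category: Category = Category.intergenic,
    category_override: Category | str | None = None,
) -> list[TranscriptRecord]:
    """Read transcripts from a GTF file (Ensembl-dialect attributes).

    Records are built by grouping exon features on ``transcript_id``; a
    transcript feature line is not required. The category is taken from
    ``category_attribute`` and defaults to ``intergenic`` (logged) when the
    attribute is absent; ``category_override`` forces a category for every
    transcript in this file. Returns records sorted by transcript_id.
    """
    gtf_path = Path(gtf_path)
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict[str, str]] = {}
    n_lines = 0
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationParseError(
                    f"{gtf_path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature != "exon":
                continue
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{gtf_path}:{lineno}: non-integer coordinates"
                ) from exc
            if s > e or s < 1:
                raise AnnotationParseError(f"{gtf_path}:{lineno}: bad interval {s}-{e}")
            try:
                attrs = _parse_gtf_attributes(attr)
            except AnnotationParseError as exc:
                raise AnnotationParseError(f"{gtf_path}:{lineno}: {exc}") from exc
            tid = attrs.get("transcript_id")
            if tid is None:
                raise AnnotationParseError(
                    f"{gtf_path}:{lineno}: exon feature without transcript_id"
                )
            st = _STRAND_IN.get(strand, "unknown")
            if tid in meta:
                prev = meta[tid]
                if prev["chrom"] != chrom:
                    raise AnnotationParseError(
                        f"{gtf_path}:{lineno}: transcript {tid} on multiple chromosomes"
                    )
                if prev["strand"] != st:
                    raise AnnotationParseError(
                        f"{gtf_path}:{lineno}: transcript {tid} has conflicting strands"
                    )
            else:
                meta[tid] = {
                    "chrom": chrom,
                    "strand": st,
                    "gene_id": attrs.get("gene_id", tid),
                    "category": attrs.get(category_attribute, ""),
                }
            exons.setdefault(tid, []).append((s, e))

    if n_lines == 0:
        logger.warning("%s: empty annotation file", gtf_path)

    records: list[TranscriptRecord] = []
    for tid in sorted(exons):
        m = meta[tid]
        if category_override is not None:
            cat = Category(category_override)
        elif m["category"]:
            cat = Category(m["category"])
        else:
            logger.info("%s: no %r attribute, defaulting to %s", tid,
                        category_attribute, default_category.value)
            cat = default_category
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=m["gene_id"],
                category=cat,
                chrom=m["chrom"],
                strand=m["strand"],
                exons=tuple(exons[tid]),
            )
        )
    return records


def attach_sequences(
    records: Sequence[TranscriptRecord], fasta_path: Path | str
) -> list[TranscriptRecord]:
    """Attach spliced sequences from a FASTA keyed by transcript_id.

    Records without a FASTA entry are flagged ``sequence_missing`` (and
    logged); a length mismatch between the FASTA sequence and the exon sum
    is a warning and the FASTA length wins.
    """
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    out: list[TranscriptRecord] = []
    for r in records:
        if r.transcript_id not in seqs:
            logger.warning("%s: no sequence in %s", r.transcript_id, fasta_path)
            out.append(replace(r, sequence=None, sequence_missing=True))
            continue
        seq = seqs[r.transcript_id]
        exon_sum = sum(b - a + 1 for a, b in r.exons)
        if r.exons and len(seq) != exon_sum:
            warnings.warn(
                f"{r.transcript_id}: FASTA length {len(seq)} != exon sum {exon_sum}; "
                "using FASTA length",
                stacklevel=2,
            )
        out.append(r.with_sequence(seq))
    return out


_STRAND_OUT = {"+": "+", "-": "-", "unknown": "."}


def write_results(
    records: Sequence[TranscriptRecord],
    bed_path: Path | str | None = None,
    gtf_path: Path | str | None = None,
    fasta_path: Path | str | None = None,
) -> None:
    """Write BED12 (0-based half-open) and/or GTF (1-based closed) outputs.

    The GTF output round-trips exactly through :func:`read_annotation`.
    Records are written sorted by (chrom, span, transcript_id) for
    deterministic output; unknown strand is written as ``.``.
    """
    recs = sorted(records, key=lambda r: (r.chrom, r.span, r.transcript_id))
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for r in recs:
                chrom_start = r.exons[0][0] - 1
                chrom_end = r.exons[-1][1]
                sizes = ",".join(str(b - a + 1) for a, b in r.exons) + ","
                starts = ",".join(str(a - 1 - chrom_start) for a, _ in r.exons) + ","
                fh.write(
                    "\t".join(
                        [
                            r.chrom,
                            str(chrom_start),
                            str(chrom_end),
                            r.transcript_id,
                            "0",
                            _STRAND_OUT[r.strand],
                            str(chrom_start),
                            str(chrom_end),
                            "0",
                            str(len(r.exons)),
                            sizes,
                            starts,
                        ]
                    )
                    + "\n"
                )
    if gtf_path is not None:
        with open(gtf_path, "w") as fh:
            for r in recs:
                attrs = (
                    f'gene_id "{r.gene_id or r.transcript_id}"; '
                    f'transcript_id "{r.transcript_id}"; '
                    f'category "{r.category.value}";'
                )
                for a, b in r.exons:
                    fh.write(
                        "\t".join(
                            [
                                r.chrom,
                                "equilnc",
                                "exon",
                                str(a),
                                str(b),
                                ".",
                                _STRAND_OUT[r.strand],
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for r in recs:
                if r.sequence is not None:
                    fh.write(f">{r.transcript_id}\n{r.sequence}\n")


def read_expression(
    tsv_path: Path | str, tissue_meta: Path | str | None = None
) -> ExpressionMatrix:
    """Read a transcript x tissue TPM table and optional tissue metadata.

    The TSV has a header row of tissue names and transcript ids in the
    first column. ``tissue_meta`` is a two-column TSV (name, library_prep);
    tissues absent from it get library_prep ``unknown`` with a warning.
    """
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate transcript rows: {dups[:5]}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{tsv_path}: non-numeric expression value ({exc})") from exc
    prep: dict[str, str] = {}
    if tissue_meta is not None:
        meta = pd.read_csv(tissue_meta, sep="\t")
        prep = dict(zip(meta.iloc[:, 0].astype(str), meta.iloc[:, 1].astype(str)))
    for t in values.columns:
        if str(t) not in prep:
            if tissue_meta is not None:
                warnings.warn(f"tissue {t!r} missing from metadata; library_prep unknown",
                              stacklevel=2)
            prep[str(t)] = "unknown"
    return ExpressionMatrix(values, prep)
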