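"""Filter 3: removal of transcripts with protein-coding capability.

An open reading frame (ORF) is an ATG-initiated codon run ending at a stop
codon (or, flagged partial, at the sequence end), scanned in three frames
on both strands. Maximality: within one stop-free stretch of a frame only
the first (5'-most) ATG is reported. Codons containing ambiguous bases do
not translate and break the ORF.

A transcript is removed when it carries an ORF of at least ``min_aa``
amino acids (default 100) AND that ORF has protein-level evidence: a motif
match or a local-alignment hit against the protein database with e-value
below the cutoff (default 1e-3). Long ORFs without evidence are retained.

Protein search is Smith-Waterman (BLOSUM62, gap open 11 / extend 1) with
Karlin-Altschul e-values, E = K * m * n * exp(-lambda * S), using the
standard gapped parameters lambda = 0.267, K = 0.041; effective lengths
are raw lengths (no edge correction).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

from .io_model import TranscriptRecord

logger = logging.getLogger("equilnc")

__all__ = [
    "Orf",
    "ProteinHit",
    "KarlinAltschul",
    "BLOSUM62_GAPPED",
    "find_orfs",
    "search_protein_db",
    "match_motifs",
    "prosite_to_regex",
    "apply_filter3",
    "translate",
]

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(codons: str) -> str:
    """Translate a nucleotide string codon by codon; stops become '*'.

    Codons containing ambiguous bases raise KeyError — callers treat them
    as ORF breaks.
    """
    return "".join(_CODON_TABLE[codons[i:i + 3]] for i in range(0, len(codons) - 2, 3))


@dataclass(frozen=True)
class Orf:
    """One predicted ORF in transcript (sense-orientation) coordinates."""

    transcript_id: str
    frame: int  # 0-2, offset on the scanned strand
    strand_of_transcript: str  # 'sense' or 'antisense'
    start: int  # 1-based closed, sense orientation; includes stop codon if any
    end: int
    peptide: str
    partial: bool  # True when no stop codon before the sequence end

    def __post_init__(self) -> None:
        if not self.peptide.startswith("M") or "*" in self.peptide:
            raise ValueError("peptide must start with M and contain no stop")

    @property
    def length_aa(self) -> int:
        return len(self.peptide)

    @property
    def orf_id(self) -> str:
        return f"{self.transcript_id}|{self.strand_of_transcript}|f{self.frame}|{self.start}-{self.end}"


def _scan_strand(seq: str, min_aa: int, sense: bool, transcript_id: str) -> list[Orf]:
    n = len(seq)
    orfs: list[Orf] = []
    for frame in range(3):
        start_pos: int | None = None  # 0-based position of the ORF's ATG on this strand
        pep: list[str] = []
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            aa = _CODON_TABLE.get(codon)
            if aa is None:  # ambiguous codon: breaks the ORF
                start_pos, pep = None, []
                continue
            if aa == "*":
                if start_pos is not None and len(pep) >= min_aa:
                    orfs.append(_make_orf(transcript_id, frame, sense, n,
                                          start_pos, pos + 2, "".join(pep), False))
                start_pos, pep = None, []
                continue
            if start_pos is None:
                if codon == "ATG":
                    start_pos, pep = pos, ["M"]
            else:
                pep.append(aa)
        if start_pos is not None and len(pep) >= min_aa:
            # ran off the end without a stop: partial ORF
            last = start_pos + 3 * len(pep) - 1
            orfs.append(_make_orf(transcript_id, frame, sense, n,
                                  start_pos, last, "".join(pep), True))
    return orfs


def _make_orf(tid: str, frame: int, sense: bool, seqlen: int,
              s0: int, e0: int, pep: str, partial: bool) -> Orf:
    # s0/e0 are 0-based closed on the scanned strand; map to sense orientation
    if sense:
        start, end = s0 + 1, e0 + 1
    else:
        start, end = seqlen - e0, seqlen - s0
    return Orf(transcript_id=tid, frame=frame,
               strand_of_transcript="sense" if sense else "antisense",
               start=start, end=end, peptide=pep, partial=partial)


def find_orfs(
    seq: str,
    min_aa: int = 100,
    both_strands: bool = True,
    transcript_id: str = "",
) -> list[Orf]:
    """All maximal ATG-initiated ORFs of at least ``min_aa`` amino acids.

    Scans 3 frames of the given sequence and, when ``both_strands``, of its
    reverse complement. Returns ORFs sorted by length descending (ties by
    coordinates, sense first).
    """
    seq = seq.upper()
    orfs = _scan_strand(seq, min_aa, True, transcript_id)
    if both_strands:
        orfs += _scan_strand(revcomp(seq), min_aa, False, transcript_id)
    orfs.sort(key=lambda o: (-o.length_aa, o.strand_of_transcript != "sense", o.start, o.frame))
    return orfs


@dataclass(frozen=True)
class KarlinAltschul:
    """Karlin-Altschul statistics for a scoring scheme."""

    lam: float
    k: float

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.k * m * n * math.exp(-self.lam * score)

    def bitscore(self, score: float) -> float:
        return (self.lam * score - math.log(self.k)) / math.log(2)


BLOSUM62_GAPPED = KarlinAltschul(lam=0.267, k=0.041)


@dataclass(frozen=True)
class ProteinHit:
    """Protein-level evidence for an ORF (alignment or motif match)."""

    orf_id: str
    subject_id: str
    score: float  # bit score; 0 for motif hits
    evalue: float
    source: str  # 'protein_db' or 'motif'
    percent_identity: float | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


def _load_fasta(db: Path | str | Mapping[str, str]) -> dict[str, str]:
    if isinstance(db, Mapping):
        return {k: v.upper() for k, v in db.items()}
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(db), "fasta")}


@lru_cache(maxsize=1)
def _protein_aligner(gap_open: float, gap_extend: float):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def search_protein_db(
    peptide: str,
    db: Path | str | Mapping[str, str],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    ka: KarlinAltschul = BLOSUM62_GAPPED,
    evalue_max: float | None = None,
    orf_id: str = "",
) -> list[ProteinHit]:
    """Smith-Waterman search of one peptide against a protein FASTA/dict.

    Returns hits sorted by ascending e-value (ties by subject id);
    deterministic for fixed inputs. ``evalue_max`` limits reported hits
    (None reports all subjects). Identity is computed from the traceback
    for hits below 1e-3 or ``evalue_max``, whichever is larger.
    """
    if not peptide:
        raise ValueError("empty peptide")
    seqs = _load_fasta(db)
    if not seqs:
        logger.warning("empty protein database")
        return []
    aligner = _protein_aligner(gap_open, gap_extend)
    total_n = sum(len(s) for s in seqs.values())
    m = len(peptide)
    ident_cutoff = max(1e-3, evalue_max or 0.0)
    hits: list[ProteinHit] = []
    for sid in sorted(seqs):
        subj = seqs[sid]
        score = aligner.score(peptide, subj)
        if score <= 0:
            continue
        ev = ka.evalue(score, m, total_n)
        if evalue_max is not None and ev >= evalue_max:
            continue
        ident = None
        if ev < ident_cutoff:
            aln = aligner.align(peptide, subj)[0]
            counts = aln.counts()
            aln_len = counts.identities + counts.mismatches + counts.gaps
            ident = 100.0 * counts.identities / aln_len if aln_len else 0.0
        hits.append(ProteinHit(orf_id=orf_id, subject_id=sid, score=ka.bitscore(score),
                               evalue=ev, source="protein_db", percent_identity=ident))
    hits.sort(key=lambda h: (h.evalue, h.subject_id))
    return hits


_PROSITE_ELEM = re.compile(
    r"(?P<body><|>|x|[A-Z]|\[[A-Z]+\]|\{[A-Z]+\})(?:\((?P<lo>\d+)(?:,(?P<hi>\d+))?\))?$"
)


def prosite_to_regex(pattern: str) -> str:
    """Compile a Prosite-style pattern to a Python regex.

    Grammar: elements joined by '-'; ``x`` any residue; ``[ACD]`` choice;
    ``{ACD}`` exclusion; ``elem(n)`` / ``elem(n,m)`` repetition; leading
    ``<`` anchors at the N-terminus, trailing ``>`` at the C-terminus.
    A terminal '.' (Prosite full stop) is tolerated.
    """
    pat = pattern.strip().rstrip(".")
    if not pat:
        raise ValueError("empty motif pattern")
    parts = pat.split("-")
    out: list[str] = []
    for part in parts:
        part = part.strip()
        # anchors may be standalone elements or attached: "<M", "G>"
        prefix = suffix = ""
        if part.startswith("<") and part != "<":
            prefix, part = "^", part[1:]
        if part.endswith(">") and part != ">":
            suffix, part = "$", part[:-1]
        m = _PROSITE_ELEM.match(part)
        if m is None:
            raise ValueError(f"malformed motif element {part!r} in pattern {pattern!r}")
        body, lo, hi = m.group("body"), m.group("lo"), m.group("hi")
        if body == "<":
            out.append("^")
            continue
        if body == ">":
            out.append("$")
            continue
        if body == "x":
            rx = "."
        elif body.startswith("["):
            rx = body
        elif body.startswith("{"):
            rx = "[^" + body[1:-1] + "]"
        else:
            rx = body
        if hi is not None:
            rx += f"{{{lo},{hi}}}"
        elif lo is not None:
            rx += f"{{{lo}}}"
        out.append(prefix + rx + suffix)
    return "".join(out)


def load_motifs(path: Path | str) -> list[tuple[str, str]]:
    """Read a motif file: lines of ``name<TAB>pattern`` (or pattern only)."""
    motifs: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "\t" in line:
                name, pat = line.split("\t", 1)
            else:
                name, pat = f"motif_{i}", line
            motifs.append((name, pat))
    return motifs


def match_motifs(
    peptide: str,
    motifs: Path | str | Sequence[tuple[str, str]],
    orf_id: str = "",
) -> list[ProteinHit]:
    """Match Prosite-style patterns against a peptide.

    One hit per matching pattern (evalue 0, source 'motif'); malformed
    patterns raise ValueError naming the pattern.
    """
    if isinstance(motifs, (str, Path)):
        motifs = load_motifs(motifs)
    hits: list[ProteinHit] = []
    for name, pat in motifs:
        rx = prosite_to_regex(pat)
        if re.search(rx, peptide):
            hits.append(ProteinHit(orf_id=orf_id, subject_id=name, score=0.0,
                                   evalue=0.0, source="motif"))
    return hits


def apply_filter3(
    records: Sequence[TranscriptRecord],
    db: Path | str | Mapping[str, str] | None,
    motifs: Path | str | Sequence[tuple[str, str]] | None,
    min_aa: int = 100,
    evalue_max: float = 1e-3,
    both_strands: bool = True,
    external_hits: Mapping[str, Sequence[ProteinHit]] | None = None,
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Split records into (retained, removed) by protein-coding evidence.

    Removal requires BOTH a >= ``min_aa``-aa ORF and evidence on that ORF:
    a motif match or a database hit with evalue < ``evalue_max``. Records
    flagged ``sequence_missing`` are retained (cannot be assessed) and
    logged. ``external_hits`` (orf peptide -> hits) replaces the built-in
    search, e.g. to inject precomputed tabular results.
    """
    db_seqs = _load_fasta(db) if db is not None else {}
    motif_list: Sequence[tuple[str, str]] | None
    if motifs is None:
        motif_list = None
    elif isinstance(motifs, (str, Path)):
        motif_list = load_motifs(motifs)
    else:
        motif_list = motifs

    peptide_cache: dict[str, bool] = {}

    def peptide_has_evidence(pep: str, oid: str) -> bool:
        if pep in peptide_cache:
            return peptide_cache[pep]
        found = False
        if external_hits is not None:
            found = any(h.source == "motif" or h.evalue < evalue_max
                        for h in external_hits.get(pep, ()))
        else:
            if motif_list and match_motifs(pep, motif_list, orf_id=oid):
                found = True
            if not found and db_seqs:
                found = bool(search_protein_db(pep, db_seqs, evalue_max=evalue_max,
                                               orf_id=oid))
        peptide_cache[pep] = found
        return found

    retained: list[TranscriptRecord] = []
    removed: list[TranscriptRecord] = []
    for r in records:
        if r.sequence is None:
            logger.warning("%s: no sequence; cannot assess coding potential", r.transcript_id)
            retained.append(r)
            continue
        coding = any(
            peptide_has_evidence(o.peptide, o.orf_id)
            for o in find_orfs(r.sequence, min_aa=min_aa, both_strands=both_strands,
                               transcript_id=r.transcript_id)
        )
        (removed if coding else retained).append(r)
    return retained, removed
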