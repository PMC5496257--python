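"""Nucleotide homology: local alignment, lncRNA rescue, conservation curve.

The aligner is Smith-Waterman with blastn-style scoring (match +2,
mismatch -3, gap open 5 / extend 2), preceded by an exact shared k-mer
(default k = 13) seed requirement between query and subject — pairs with
no common word are not aligned, mirroring seeded search. E-values are
Karlin-Altschul, E = K * m * n * exp(-lambda * S) with the gapped
parameters for this scoring scheme (lambda = 0.625, K = 0.41), n summed
over the database.

Rescue reinstates transcripts removed by the coding-potential filter when
they align to a known-lncRNA database with e-value below 1e-5 and strictly
over 25% query coverage and 75% identity.

The conservation measure per query is best-hit percent identity times
percent query coverage, scaled to [0, 100]; queries without a significant
hit score 0. The conservation curve is the empirical CDF of this measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .coding_potential import KarlinAltschul, _load_fasta
from .io_model import TranscriptRecord

logger = logging.getLogger("equilnc")

__all__ = [
    "NucHit",
    "ConservationCurve",
    "BLASTN_GAPPED",
    "align_nucleotide",
    "rescue",
    "conservation_curve",
]

BLASTN_GAPPED = KarlinAltschul(lam=0.625, k=0.41)
SEED_K = 13


@dataclass(frozen=True)
class NucHit:
    """Local nucleotide alignment of a query against one database entry."""

    query_id: str
    subject_id: str
    percent_identity: float  # matches / alignment columns * 100
    percent_query_coverage: float  # aligned query bases / query length * 100
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0 <= self.percent_identity <= 100):
            raise ValueError("identity out of range")
        if not (0 <= self.percent_query_coverage <= 100):
            raise ValueError("coverage out of range")


@lru_cache(maxsize=1)
def _nuc_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # BLAST convention: a gap of length k costs open + k * extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@lru_cache(maxsize=256)
def _kmer_set(seq: str, k: int) -> frozenset[str]:
    # cached so database entries queried repeatedly are decomposed once
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def align_nucleotide(
    query: str,
    subject_db: Path | str | Mapping[str, str],
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = 5.0,
    gap_extend: float = 2.0,
    ka: KarlinAltschul = BLASTN_GAPPED,
    evalue_max: float = 10.0,
    seed_k: int = SEED_K,
    query_id: str = "",
) -> list[NucHit]:
    """Seeded Smith-Waterman search of one query against a nucleotide db.

    Subjects sharing no exact ``seed_k``-mer with the query are skipped.
    Hits with e-value below ``evalue_max`` are returned sorted by bitscore
    descending (ties: lower e-value, then subject id), deterministically.
    Queries shorter than the seed length yield an empty result (warning).
    """
    query = query.upper()
    seqs = _load_fasta(subject_db)
    if len(query) < max(20, seed_k):
        logger.warning("%s: query shorter than seed length; no alignment", query_id)
        return []
    qkmers = _kmer_set(query, seed_k)
    aligner = _nuc_aligner(match, mismatch, gap_open, gap_extend)
    total_n = sum(len(s) for s in seqs.values())
    m = len(query)
    hits: list[NucHit] = []
    for sid in sorted(seqs):
        subj = seqs[sid]
        if qkmers.isdisjoint(_kmer_set(subj, seed_k)):
            continue
        score = aligner.score(query, subj)
        if score <= 0:
            continue
        ev = ka.evalue(score, m, total_n)
        if ev >= evalue_max:
            continue
        aln = aligner.align(query, subj)[0]
        counts = aln.counts()
        aln_len = counts.identities + counts.mismatches + counts.gaps
        ident = 100.0 * counts.identities / aln_len if aln_len else 0.0
        qblocks = aln.aligned[0]
        qcov = 100.0 * sum(int(e - s) for s, e in qblocks) / m
        hits.append(NucHit(query_id=query_id, subject_id=sid,
                           percent_identity=ident,
                           percent_query_coverage=min(qcov, 100.0),
                           evalue=ev, bitscore=ka.bitscore(score)))
    hits.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
    return hits


def best_hit(hits: Sequence[NucHit]) -> NucHit | None:
    """Highest-bitscore hit; ties by lower e-value then subject id."""
    return min(hits, key=lambda h: (-h.bitscore, h.evalue, h.subject_id)) if hits else None


def rescue(
    removed_by_f3: Sequence[TranscriptRecord],
    lnc_db: Path | str | Mapping[str, str],
    evalue_max: float = 1e-5,
    min_cov: float = 25.0,
    min_ident: float = 75.0,
    external_hits: Mapping[str, Sequence[NucHit]] | None = None,
) -> list[TranscriptRecord]:
    """Reinstate coding-filter casualties with strong known-lncRNA homology.

    A transcript is rescued iff it has a hit with e-value < ``evalue_max``,
    query coverage strictly over ``min_cov`` and identity strictly over
    ``min_ident``. The result is always a subset of the input, in input
    order. ``external_hits`` (transcript_id -> hits) replaces the built-in
    aligner when provided.
    """
    seqs = _load_fasta(lnc_db) if external_hits is None else {}
    if external_hits is None and not seqs:
        logger.warning("empty lncRNA rescue database; no rescues possible")
        return []
    rescued: list[TranscriptRecord] = []
    for r in removed_by_f3:
        if external_hits is not None:
            hits = external_hits.get(r.transcript_id, ())
        elif r.sequence is None:
            continue
        else:
            hits = align_nucleotide(r.sequence, seqs, evalue_max=evalue_max,
                                    query_id=r.transcript_id)
        if any(h.evalue < evalue_max
               and h.percent_query_coverage > min_cov
               and h.percent_identity > min_ident
               for h in hits):
            rescued.append(r)
    return rescued


@dataclass
class ConservationCurve:
    """Empirical CDF of the per-query best-hit conservation measure."""

    scores: dict[str, float]  # query id -> conservation measure in [0, 100]
    no_hit_fraction: float

    @property
    def curve(self) -> list[tuple[float, float]]:
        """Sorted (score, cumulative fraction of queries <= score) pairs."""
        vals = np.sort(np.array(list(self.scores.values())))
        n = len(vals)
        out: list[tuple[float, float]] = []
        for s in np.unique(vals):
            out.append((float(s), float(np.searchsorted(vals, s, side="right")) / n))
        return out

    def cdf_at(self, score: float) -> float:
        vals = np.array(list(self.scores.values()))
        return float((vals <= score).mean()) if len(vals) else 0.0

    def write(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            fh.write("score\tcumulative_fraction\n")
            for s, f in self.curve:
                fh.write(f"{s:.6g}\t{f:.6g}\n")


def conservation_curve(
    queries: Sequence[TranscriptRecord],
    subject_db: Path | str | Mapping[str, str],
    evalue_max: float = 1e-5,
    scaled: bool = True,
) -> ConservationCurve:
    """Conservation of each query against a reference transcript database.

    Per query the best hit (highest bitscore) defines the measure
    identity% * coverage% / 100 (or the raw product when ``scaled`` is
    False); queries with no significant hit contribute 0 and count toward
    ``no_hit_fraction``.
    """
    seqs = _load_fasta(subject_db)
    scores: dict[str, float] = {}
    n_no_hit = 0
    for r in queries:
        hits = [] if r.sequence is None else align_nucleotide(
            r.sequence, seqs, evalue_max=evalue_max, query_id=r.transcript_id)
        best = best_hit(hits)
        if best is None:
            n_no_hit += 1
            scores[r.transcript_id] = 0.0
        else:
            raw = best.percent_identity * best.percent_query_coverage
            scores[r.transcript_id] = raw / 100.0 if scaled else raw
    frac = n_no_hit / len(queries) if queries else 0.0
    return ConservationCurve(scores=scores, no_hit_fraction=frac)
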