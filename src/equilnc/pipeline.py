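"""Orchestration of the four-filter cascade plus homology rescue.

Stage order is fixed: expression (F1) -> length (F2) -> coding potential
(F3) -> rescue of F3 casualties against a known-lncRNA database -> gene
proximity (F4). Rescued transcripts re-enter before F4, so a rescued
fragment sitting next to a gene can still be removed (a
``rescue_bypass_f4`` switch exempts them). The final set is the union of
F4 survivors and rescued transcripts surviving F4.

The :class:`FilterReport` ledger mirrors a per-input-category accounting:
transcript counts after each stage, cumulative TPM (summed across tissues)
removed by each stage, and final-set summary statistics (mean spliced
length in kb, mean TPM, GC%, total bp).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coding_potential import apply_filter3
from .expression_filter import Filter1Params, apply_filter1
from .genomic_filters import GeneSpan, apply_filter2, apply_filter4
from .homology import rescue as rescue_op
from .io_model import (Category, ExpressionMatrix, FilterReport, STAGES,
                       TranscriptRecord, write_results)

logger = logging.getLogger("equilnc")

__all__ = [
    "PipelineThresholds",
    "PipelineResult",
    "run_pipeline",
    "summarize_categories",
    "chromosome_distribution",
]


@dataclass(frozen=True)
class PipelineThresholds:
    """Every tunable cutoff of the cascade, with the standard defaults."""

    f1: Filter1Params = field(default_factory=Filter1Params)
    min_len: int = 200
    f2_categories: tuple[Category, ...] | None = None  # None: all categories
    min_aa: int = 100
    evalue_max: float = 1e-3
    both_strands: bool = True
    rescue_evalue: float = 1e-5
    rescue_min_cov: float = 25.0
    rescue_min_ident: float = 75.0
    flank: int = 1000
    same_strand_only: bool = True
    rescue_bypass_f4: bool = False


@dataclass
class PipelineResult:
    """Final candidate set plus the full per-stage accounting."""

    final: list[TranscriptRecord]
    report: FilterReport
    removed_by: dict[str, str]  # transcript_id -> 'F1'..'F4' (post-rescue fate)
    rescued_ids: set[str]
    thresholds: PipelineThresholds

    @property
    def final_ids(self) -> set[str]:
        return {r.transcript_id for r in self.final}

    def write(self, outdir: Path | str) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "final_bed": outdir / "final.bed",
            "final_gtf": outdir / "final.gtf",
            "filter_report": outdir / "filter_report.tsv",
            "summary": outdir / "summary.tsv",
            "removed_by": outdir / "removed_by.tsv",
        }
        write_results(self.final, bed_path=paths["final_bed"],
                      gtf_path=paths["final_gtf"])
        self.report.write(paths["filter_report"], paths["summary"])
        with open(paths["removed_by"], "w") as fh:
            fh.write("transcript_id\tremoved_by\trescued\n")
            for tid in sorted(set(self.removed_by) | self.rescued_ids):
                fh.write(f"{tid}\t{self.removed_by.get(tid, 'none')}\t"
                         f"{int(tid in self.rescued_ids)}\n")
        return paths


def _category_counts(records: Sequence[TranscriptRecord],
                     categories: Sequence[Category]) -> pd.Series:
    counts = pd.Series(0, index=[c.value for c in categories], dtype=int)
    for r in records:
        counts[r.category.value] += 1
    return counts


def _tpm_total(records: Sequence[TranscriptRecord], expr: ExpressionMatrix) -> pd.Series:
    """Per-category sum over transcripts of their TPM summed across tissues."""
    out: dict[str, float] = {}
    for r in records:
        out[r.category.value] = out.get(r.category.value, 0.0) + float(
            expr.tpm(r.transcript_id).sum())
    return pd.Series(out, dtype=float)


def summarize_categories(
    final: Sequence[TranscriptRecord],
    expr: ExpressionMatrix,
    categories: Sequence[Category] | None = None,
) -> pd.DataFrame:
    """Final-set summary per category: length, expression, GC, total bp.

    Columns: ``mean_length_kb`` (mean spliced length), ``mean_tpm`` (mean
    over transcripts of the per-transcript mean TPM across tissues),
    ``gc_percent`` (mean), ``total_bp``. Categories with no survivors get
    a row of zeros.
    """
    if categories is None:
        categories = sorted({r.category for r in final}, key=lambda c: c.value)
    rows = {}
    for cat in categories:
        recs = [r for r in final if r.category == cat]
        if not recs:
            logger.warning("category %s: no surviving transcripts", cat.value)
            rows[cat.value] = dict(n=0, mean_length_kb=0.0, mean_tpm=0.0,
                                   gc_percent=0.0, total_bp=0)
            continue
        lengths = np.array([r.length_bp for r in recs], dtype=float)
        gcs = np.array([r.gc_percent for r in recs if r.sequence is not None])
        mean_tpms = np.array([expr.mean_tpm(r.transcript_id) for r in recs])
        rows[cat.value] = dict(
            n=len(recs),
            mean_length_kb=float(lengths.mean()) / 1000.0,
            mean_tpm=float(mean_tpms.mean()),
            gc_percent=float(gcs.mean()) if len(gcs) else 0.0,
            total_bp=int(lengths.sum()),
        )
    return pd.DataFrame.from_dict(rows, orient="index")


def chromosome_distribution(final: Sequence[TranscriptRecord]) -> pd.DataFrame:
    """Counts per chromosome x category; unplaced scaffolds pooled as chrUn."""
    rows: dict[str, dict[str, int]] = {}
    for r in final:
        chrom = "chrUn" if r.chrom.startswith("chrUn") else r.chrom
        rows.setdefault(chrom, {})[r.category.value] = \
            rows.get(chrom, {}).get(r.category.value, 0) + 1
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    df = df.sort_index().sort_index(axis=1)
    df.index.name = "chrom"
    return df


def run_pipeline(
    records: Sequence[TranscriptRecord],
    expr: ExpressionMatrix,
    genes: Sequence[GeneSpan],
    protein_db: Path | str | Mapping[str, str] | None,
    motifs: Path | str | Sequence[tuple[str, str]] | None,
    lnc_db: Path | str | Mapping[str, str] | None,
    thresholds: PipelineThresholds = PipelineThresholds(),
) -> PipelineResult:
    """Run F1 -> F2 -> F3 -> rescue -> F4 and build the filter ledger.

    Each stage consumes exactly the previous stage's retained set (asserted).
    Deterministic for fixed inputs. Empty input yields an empty result with
    a warning.
    """
    records = list(records)
    if not records:
        logger.warning("pipeline called with no input transcripts")
    categories = sorted({r.category for r in records}, key=lambda c: c.value)

    stage_sets: dict[str, list[TranscriptRecord]] = {"initial": records}
    removed_by: dict[str, str] = {}
    tpm_removed: dict[str, pd.Series] = {}

    def record_stage(name: str, retained, removed, prev):
        assert len(retained) + len(removed) == len(prev), f"{name}: partition violated"
        for r in removed:
            removed_by[r.transcript_id] = name
        stage_sets[name] = retained
        tpm_removed[name] = _tpm_total(removed, expr)

    f1_ret, f1_rem = apply_filter1(records, expr, thresholds.f1)
    record_stage("F1", f1_ret, f1_rem, records)

    f2_ret, f2_rem = apply_filter2(f1_ret, thresholds.min_len,
                                   categories=thresholds.f2_categories)
    record_stage("F2", f2_ret, f2_rem, f1_ret)

    f3_ret, f3_rem = apply_filter3(f2_ret, protein_db, motifs,
                                   min_aa=thresholds.min_aa,
                                   evalue_max=thresholds.evalue_max,
                                   both_strands=thresholds.both_strands)
    record_stage("F3", f3_ret, f3_rem, f2_ret)

    rescued = rescue_op(f3_rem, lnc_db or {},
                        evalue_max=thresholds.rescue_evalue,
                        min_cov=thresholds.rescue_min_cov,
                        min_ident=thresholds.rescue_min_ident) if lnc_db else []
    rescued_ids = {r.transcript_id for r in rescued}
    assert rescued_ids <= {r.transcript_id for r in f3_rem}
    assert not rescued_ids & {r.transcript_id for r in f3_ret}
    if rescued:
        logger.info("rescue: %d transcript(s) reinstated before F4", len(rescued))
        for r in rescued:
            removed_by.pop(r.transcript_id, None)

    f4_input = f3_ret if thresholds.rescue_bypass_f4 else f3_ret + rescued
    f4_ret, f4_rem = apply_filter4(f4_input, genes, flank=thresholds.flank,
                                   same_strand_only=thresholds.same_strand_only)
    record_stage("F4", f4_ret, f4_rem, f4_input)
    # rescued transcripts that F4 removed again fall back to an F4 fate
    final = list(f4_ret) + (list(rescued) if thresholds.rescue_bypass_f4 else [])
    surviving_rescued = [r for r in final if r.transcript_id in rescued_ids]
    final_rescued_ids = {r.transcript_id for r in surviving_rescued}

    counts = pd.DataFrame(0, index=[c.value for c in categories], columns=list(STAGES),
                          dtype=int)
    tpm_df = pd.DataFrame(0.0, index=[c.value for c in categories],
                          columns=["F1", "F2", "F3", "F4"])
    counts["initial"] = _category_counts(records, categories)
    counts["F1"] = _category_counts(stage_sets["F1"], categories)
    counts["F2"] = _category_counts(stage_sets["F2"], categories)
    counts["F3"] = _category_counts(stage_sets["F3"], categories)
    counts["F4"] = _category_counts(
        [r for r in final if r.transcript_id not in final_rescued_ids], categories)
    counts["rescued"] = _category_counts(surviving_rescued, categories)
    counts["final"] = counts["F4"] + counts["rescued"]
    for stage in ("F1", "F2", "F3", "F4"):
        s = tpm_removed.get(stage, pd.Series(dtype=float))
        tpm_df[stage] = s.reindex(tpm_df.index).fillna(0.0)

    summary = summarize_categories(final, expr, categories)
    report = FilterReport(counts=counts, tpm_removed=tpm_df, summary=summary)
    report.validate()
    return PipelineResult(final=final, report=report, removed_by=removed_by,
                          rescued_ids=final_rescued_ids, thresholds=thresholds)
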