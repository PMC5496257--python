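"""TPM computation and Filter 1: removal of lowly expressed transcripts.

Filter 1 keeps a transcript when its arithmetic mean TPM across all tissues
(zeros included) reaches ``mean_tpm_min`` (default 0.1). Single-exon
transcripts face a stacked, more stringent requirement: in addition to the
mean rule, at least one tissue must reach ``single_exon_tpm_min`` TPM
(default 5). Both thresholds are inclusive (>=), so a transcript sitting
exactly at a threshold passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import ExpressionMatrix, TranscriptRecord

logger = logging.getLogger("equilnc")

__all__ = ["Filter1Params", "compute_tpm", "apply_filter1"]


@dataclass(frozen=True)
class Filter1Params:
    mean_tpm_min: float = 0.1
    single_exon_tpm_min: float = 5.0

    def __post_init__(self) -> None:
        if self.mean_tpm_min < 0 or self.single_exon_tpm_min < 0:
            raise ValueError("thresholds must be non-negative")


def compute_tpm(
    counts: pd.DataFrame,
    effective_lengths: pd.Series | Sequence[float],
    library_prep: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Transcripts-per-million from a count table and effective lengths.

    Per tissue column: ``TPM_i = (count_i / len_i) / sum_j(count_j / len_j) * 1e6``.
    Columns with no counts at all yield an all-zero TPM column (warning).

    Parameters
    ----------
    counts
        Transcript x tissue table of non-negative read counts.
    effective_lengths
        Effective transcript lengths (> 0), aligned with ``counts.index``.
    """
    lengths = pd.Series(np.asarray(effective_lengths, dtype=float), index=counts.index) \
        if not isinstance(effective_lengths, pd.Series) else effective_lengths.astype(float)
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("effective_lengths missing for some transcripts")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    vals = counts.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("counts must be non-negative")
    rate = vals / lengths.to_numpy()[:, None]
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        logger.warning("all-zero count column(s): %s",
                       list(counts.columns[np.flatnonzero(zero)]))
    colsum[zero] = 1.0  # avoid 0/0; those columns stay all-zero
    tpm = rate / colsum * 1e6
    df = pd.DataFrame(tpm, index=counts.index, columns=counts.columns)
    return ExpressionMatrix(df, dict(library_prep or {}))


def apply_filter1(
    records: Sequence[TranscriptRecord],
    expr: ExpressionMatrix,
    params: Filter1Params = Filter1Params(),
) -> tuple[list[TranscriptRecord], list[TranscriptRecord]]:
    """Split records into (retained, removed) by the expression rules.

    Transcripts absent from the matrix are treated as all-zero (removed
    unless thresholds are zero). Retained and removed partition the input
    and preserve input order.
    """
    retained: list[TranscriptRecord] = []
    removed: list[TranscriptRecord] = []
    for r in records:
        tpm = expr.tpm(r.transcript_id)
        mean_ok = (tpm.mean() if tpm.size else 0.0) >= params.mean_tpm_min
        keep = mean_ok
        if keep and r.n_exons == 1:
            keep = (tpm.max() if tpm.size else 0.0) >= params.single_exon_tpm_min
        (retained if keep else removed).append(r)
    return retained, removed
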