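"""Tissue-specific expression analyses for candidate lncRNA.

Definitions, applied literally (note the deliberate asymmetry of the
boundaries): a transcript is *expressed* in a tissue when its TPM is
strictly greater than 0.1; *uniquely present* in tissue k when TPM >= 0.1
there and < 0.1 in every other tissue; *uniquely absent* in tissue k when
TPM < 0.1 there and strictly above 0.1 in every other tissue. The variable
subset used for bi-clustering requires the TPM sum across tissues above
100 and the sample (n-1) standard deviation above 50.

Bi-clustering uses 1 - Pearson correlation across tissues as the
transcript distance and 1 - Spearman correlation across transcripts as the
tissue distance, with average linkage by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import spearmanr

from .io_model import ExpressionMatrix

__all__ = [
    "TissueReport",
    "expressed_set",
    "uniquely_present",
    "uniquely_absent",
    "select_variable",
    "bicluster",
    "tissue_report",
]


def expressed_set(expr: ExpressionMatrix, tissue: str, threshold: float = 0.1) -> set[str]:
    """Transcripts with TPM strictly greater than ``threshold`` in a tissue."""
    if tissue not in expr.values.columns:
        raise KeyError(f"unknown tissue {tissue!r}")
    col = expr.values[tissue]
    return set(col.index[col > threshold].astype(str))


def uniquely_present(expr: ExpressionMatrix, threshold: float = 0.1) -> dict[str, set[str]]:
    """Per tissue: transcripts >= threshold there and < threshold elsewhere."""
    if len(expr.tissues) < 2:
        raise ValueError("uniquely_present needs at least two tissues")
    vals = expr.values
    out: dict[str, set[str]] = {}
    ge = vals >= threshold
    for tissue in expr.tissues:
        others = [c for c in vals.columns if c != tissue]
        mask = ge[tissue] & ~ge[others].any(axis=1)
        out[tissue] = set(vals.index[mask].astype(str))
    return out


def uniquely_absent(expr: ExpressionMatrix, threshold: float = 0.1) -> dict[str, set[str]]:
    """Per tissue: transcripts < threshold there, strictly above elsewhere."""
    if len(expr.tissues) < 2:
        raise ValueError("uniquely_absent needs at least two tissues")
    vals = expr.values
    out: dict[str, set[str]] = {}
    gt = vals > threshold
    lt = vals < threshold
    for tissue in expr.tissues:
        others = [c for c in vals.columns if c != tissue]
        mask = lt[tissue] & gt[others].all(axis=1)
        out[tissue] = set(vals.index[mask].astype(str))
    return out


def select_variable(expr: ExpressionMatrix, sum_min: float = 100.0,
                    sd_min: float = 50.0) -> set[str]:
    """Transcripts with TPM sum > ``sum_min`` and sample sd > ``sd_min``."""
    if len(expr.tissues) < 2:
        raise ValueError("select_variable needs at least two tissues")
    vals = expr.values
    mask = (vals.sum(axis=1) > sum_min) & (vals.std(axis=1, ddof=1) > sd_min)
    return set(vals.index[mask].astype(str))


def _corr_distance(mat: np.ndarray, method: str) -> np.ndarray:
    """Condensed 1 - correlation distances between rows of ``mat``.

    Zero-variance rows (correlation undefined) are set to the maximum
    distance 2.0 against every other row, with a warning.
    """
    n = mat.shape[0]
    sd = mat.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance row(s); "
                      "distance set to 2.0", stacklevel=2)
    if method == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(mat)
    elif method == "spearman":
        if n == 2:
            corr = np.array([[1.0, spearmanr(mat[0], mat[1]).statistic],
                             [spearmanr(mat[0], mat[1]).statistic, 1.0]])
        else:
            corr = spearmanr(mat, axis=1).statistic
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    corr = np.atleast_2d(corr)
    dist = 1.0 - corr
    dist[degenerate, :] = 2.0
    dist[:, degenerate] = 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.nan_to_num(dist, nan=2.0)
    iu = np.triu_indices(n, k=1)
    return dist[iu]


def bicluster(
    expr_subset: ExpressionMatrix | pd.DataFrame,
    linkage_method: str = "average",
) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Hierarchically bi-cluster an expression submatrix.

    Transcripts (rows) are clustered on 1 - Pearson correlation of their
    expression across tissues; tissues (columns) on 1 - Spearman
    correlation of their expression profiles across transcripts; both with
    the given linkage. Returns (transcript_order, tissue_order,
    transcript_linkage, tissue_linkage); leaf orders are deterministic for
    fixed input (scipy tie-breaking by input order).
    """
    df = expr_subset.values if isinstance(expr_subset, ExpressionMatrix) else expr_subset
    if df.empty:
        raise ValueError("empty expression subset")
    if df.shape[1] < 2:
        raise ValueError("bicluster needs at least two tissues")
    mat = df.to_numpy(dtype=float)
    row_link = hierarchy.linkage(_corr_distance(mat, "pearson"), method=linkage_method)
    col_link = hierarchy.linkage(_corr_distance(mat.T, "spearman"), method=linkage_method)
    row_order = hierarchy.leaves_list(row_link)
    col_order = hierarchy.leaves_list(col_link)
    transcripts = [str(df.index[i]) for i in row_order]
    tissues = [str(df.columns[j]) for j in col_order]
    return transcripts, tissues, row_link, col_link


@dataclass
class TissueReport:
    """Per-tissue expression summary contrasting lncRNA with coding genes."""

    table: pd.DataFrame  # one row per tissue

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="tissue")


def tissue_report(
    expr: ExpressionMatrix,
    lnc_ids: set[str],
    coding_ids: set[str],
    threshold: float = 0.1,
) -> TissueReport:
    """Build the per-tissue report of expressed counts, ratios and unique sets.

    For each tissue: numbers of expressed lncRNA and coding transcripts
    (TPM > threshold), their lncRNA:coding ratio, cumulative TPM of the
    expressed sets, and counts / cumulative TPM of lncRNA uniquely present
    or uniquely absent in that tissue.
    """
    vals = expr.values
    lnc_idx = [i for i in vals.index if str(i) in lnc_ids]
    up = uniquely_present(expr.subset(lnc_idx), threshold) if len(expr.tissues) > 1 else {}
    ua = uniquely_absent(expr.subset(lnc_idx), threshold) if len(expr.tissues) > 1 else {}
    rows = []
    for tissue in expr.tissues:
        exp_set = expressed_set(expr, tissue, threshold)
        lnc_exp = exp_set & lnc_ids
        cod_exp = exp_set & coding_ids
        col = vals[tissue]
        up_t = up.get(tissue, set())
        rows.append({
            "library_prep": expr.library_prep.get(tissue, "unknown"),
            "n_expressed_lnc": len(lnc_exp),
            "n_expressed_coding": len(cod_exp),
            "ratio": len(lnc_exp) / len(cod_exp) if cod_exp else np.nan,
            "cumulative_tpm_lnc": float(col.loc[sorted(lnc_exp)].sum()),
            "cumulative_tpm_coding": float(col.loc[sorted(cod_exp)].sum()),
            "n_uniquely_present": len(up_t),
            "n_uniquely_absent": len(ua.get(tissue, set())),
            "cum_tpm_uniquely_present": float(col.loc[sorted(up_t)].sum()),
        })
    return TissueReport(pd.DataFrame(rows, index=pd.Index(expr.tissues, name="tissue")))
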