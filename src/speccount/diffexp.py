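"""Per-gene two-group differential expression on spectral counts.

Each gene is tested malignant vs non-malignant with the unpaired two-sided
Wilcoxon rank-sum test (exact null for small untied samples, otherwise the
normal approximation with tie and continuity corrections), p-values are
adjusted by the Benjamini-Hochberg step-up procedure, and the effect size is
the log2 ratio of group mean counts with a +1-to-both-means rule when either
mean is zero.  Genes significant at the FDR threshold are classified as
up/downregulated, or as detected-in-one-line-only when the other line shows
no spectra at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ingest import MALIGNANT, NON_MALIGNANT, SpectralCountMatrix

__all__ = [
    "DetectionPartition",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "log2_fold_change",
    "run_differential_expression",
    "STATUS_UP",
    "STATUS_DOWN",
    "STATUS_T_ONLY",
    "STATUS_N_ONLY",
    "STATUS_NS",
]

STATUS_UP = "upregulated"
STATUS_DOWN = "downregulated"
STATUS_T_ONLY = "malignant_only"
STATUS_N_ONLY = "non_malignant_only"
STATUS_NS = "not_significant"

#: exact Wilcoxon null is used only for untied samples this small; larger or
#: tied samples use the tie-corrected normal approximation with continuity
#: correction (the behaviour of the standard rank-sum implementations).
EXACT_MAX_N = 8


@dataclass(frozen=True)
class DetectionPartition:
    """Genes detected in both lines vs in exactly one of them."""

    shared: int
    t_only: int
    n_only: int

    @property
    def total(self) -> int:
        return self.shared + self.t_only + self.n_only


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided unpaired Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses the exact permutation null when both samples are untied and have at
    most ``EXACT_MAX_N`` observations; otherwise the normal approximation
    with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    untied = np.unique(pooled).size == pooled.size
    if untied and x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    if np.ptp(pooled) == 0:
        return 1.0  # no rank separation at all
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(min(res.pvalue, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(mean_t: float, mean_n: float) -> float:
    """log2(mean_t / mean_n) with +1 added to both means when either is zero.

    The zero rule keeps the ratio finite for genes detected in only one
    line while leaving genes quantified in both lines untouched.
    """
    if not (math.isfinite(mean_t) and math.isfinite(mean_n)):
        raise ValueError("means must be finite")
    if mean_t < 0 or mean_n < 0:
        raise ValueError("means must be non-negative")
    if mean_t == 0 or mean_n == 0:
        mean_t, mean_n = mean_t + 1.0, mean_n + 1.0
    return math.log2(mean_t / mean_n)


def _classify(q: float, alpha: float, log2_fc: float,
              detected_t: bool, detected_n: bool) -> str:
    if q >= alpha:
        return STATUS_NS
    if detected_t and not detected_n:
        return STATUS_T_ONLY
    if detected_n and not detected_t:
        return STATUS_N_ONLY
    return STATUS_UP if log2_fc > 0 else STATUS_DOWN


def run_differential_expression(
    matrix: SpectralCountMatrix,
    alpha: float = 0.1,
    collapse_technical: bool = False,
) -> tuple[pd.DataFrame, DetectionPartition]:
    """Test every gene malignant vs non-malignant and classify the outcome.

    Parameters
    ----------
    matrix
        Processed (consolidated, integerized) count matrix with both lines.
    alpha
        FDR threshold defining differential expression (default 0.1, i.e.
        at least 90% confidence after BH adjustment).
    collapse_technical
        Average technical replicates into their biological replicate before
        testing (conservative alternative to treating all runs as samples).

    Returns
    -------
    (table, partition)
        ``table`` has one row per gene — ``gene_symbol, p_value, q_value,
        log2_fc, mean_t, mean_n, mean_abundance, status`` — sorted by
        p-value; ``mean_abundance`` is the across-sample mean, the x-axis of
        an MA plot.  ``partition`` counts shared / malignant-only /
        non-malignant-only detection.
    """
    if collapse_technical:
        matrix = matrix.collapse_technical()
    t_cols = matrix.columns_for(MALIGNANT)
    n_cols = matrix.columns_for(NON_MALIGNANT)
    if not t_cols or not n_cols:
        raise ValueError("matrix must contain both cell lines")

    t_counts = matrix.counts[t_cols].to_numpy(dtype=float)
    n_counts = matrix.counts[n_cols].to_numpy(dtype=float)

    rows = []
    for i, key in enumerate(matrix.counts.index):
        x, y = t_counts[i], n_counts[i]
        mean_t, mean_n = float(x.mean()), float(y.mean())
        feat = matrix.features.iloc[i]
        symbol = feat["gene_symbol"] if pd.notna(feat["gene_symbol"]) else str(key)
        rows.append(
            {
                "gene_symbol": symbol,
                "p_value": wilcoxon_rank_sum(x, y),
                "log2_fc": log2_fold_change(mean_t, mean_n),
                "mean_t": mean_t,
                "mean_n": mean_n,
                "mean_abundance": float(np.concatenate([x, y]).mean()),
                "detected_t": bool(x.sum() > 0),
                "detected_n": bool(y.sum() > 0),
            }
        )
    table = pd.DataFrame(rows)
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["status"] = [
        _classify(r.q_value, alpha, r.log2_fc, r.detected_t, r.detected_n)
        for r in table.itertuples()
    ]

    partition = DetectionPartition(
        shared=int((table.detected_t & table.detected_n).sum()),
        t_only=int((table.detected_t & ~table.detected_n).sum()),
        n_only=int((~table.detected_t & table.detected_n).sum()),
    )
    table = table[
        ["gene_symbol", "p_value", "q_value", "log2_fc", "mean_t", "mean_n",
         "mean_abundance", "status", "detected_t", "detected_n"]
    ].sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return table, partition


def ma_table(table: pd.DataFrame) -> pd.DataFrame:
    """MA-plot data artifact: mean abundance (A) vs log2 fold change (M)."""
    return table[["gene_symbol", "mean_abundance", "log2_fc", "status"]].rename(
        columns={"mean_abundance": "A", "log2_fc": "M"}
    )


def fold_change_scatter(table: pd.DataFrame, alpha: float = 0.1) -> pd.DataFrame:
    """1-D fold-change scatter artifact: log2 fc with a DEP flag per gene."""
    out = table[["gene_symbol", "log2_fc"]].copy()
    out["is_dep"] = (table["q_value"] < alpha).to_numpy()
    return out
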