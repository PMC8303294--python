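"""Composite fibrotic score, cohort stratification and signature selection.

The fibrotic score (FS) of a sample aggregates the relative expression of
three fibrotic marker genes (COL1A1, FN1, ACTA2), each normalised to its
maximum over the cohort:

    FS(s) = 1/3 * [ Exp_s(COL1A1)/max(COL1A1)
                  + Exp_s(FN1)   /max(FN1)
                  + Exp_s(ACTA2) /max(ACTA2) ]

so 0 < FS <= 1 and the score is invariant to rescaling any single marker
across the cohort.  Samples are stratified Low/High against a score
threshold (default 0.25; the boundary itself is Low because High is defined
strictly as FS > threshold).  miRNAs are then ranked by the Pearson
correlation of their log2-normalised expression with FS, and the fibrosis
signature is the top-k of those exceeding a minimum correlation.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MARKER_GENES",
    "fibrotic_score",
    "stratify",
    "correlate_with_score",
    "select_signature",
]

MARKER_GENES = ("COL1A1", "FN1", "ACTA2")


def fibrotic_score(panel: pd.DataFrame, markers: Sequence[str] = MARKER_GENES) -> pd.Series:
    """Per-sample fibrotic score from a marker panel.

    Parameters
    ----------
    panel
        DataFrame indexed by sample with one column of strictly positive
        relative expression per marker gene.
    markers
        Marker column names; the max of each is taken over the whole input
        cohort (pass a pre-filtered panel to restrict the reference cohort).

    Returns
    -------
    pandas.Series of scores in (0, 1], named ``"FS"``.
    """
    if len(panel) < 2:
        raise ValueError("fibrotic score needs a cohort of >= 2 samples")
    missing = [m for m in markers if m not in panel.columns]
    if missing:
        raise ValueError(f"marker panel lacks columns: {missing}")
    expr = panel.loc[:, list(markers)].astype(float)
    if not np.all(np.isfinite(expr.to_numpy())) or (expr.to_numpy() <= 0).any():
        raise ValueError("marker expression must be finite and strictly positive")
    ratios = expr / expr.max(axis=0)
    return ratios.mean(axis=1).rename("FS")


def stratify(scores: pd.Series, threshold: float = 0.25) -> pd.Series:
    """Assign each sample to the High (FS > threshold) or Low stratum."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return pd.Series(
        np.where(scores.to_numpy(dtype=float) > threshold, "High", "Low"),
        index=scores.index,
        name="stratum",
    )


def correlate_with_score(log_expr: pd.DataFrame, scores: pd.Series) -> pd.DataFrame:
    """Pearson correlation of each miRNA's expression with the fibrotic score.

    Parameters
    ----------
    log_expr
        miRNA x sample matrix of log2-normalised expression (rows = miRNAs).
    scores
        Fibrotic score per sample; its index must equal the matrix columns
        as a set.

    Returns
    -------
    DataFrame indexed by miRNA with columns ``r`` (Pearson correlation with
    FS; NaN for zero-variance miRNAs), ``rank`` (dense rank by descending r,
    NaN rows unranked) and ``selected`` (False; set by
    :func:`select_signature`).
    """
    if set(log_expr.columns) != set(scores.index):
        raise ValueError("sample IDs of expression matrix and scores do not match")
    if log_expr.shape[1] < 3:
        raise ValueError("correlation needs >= 3 samples")
    fs = scores.reindex(log_expr.columns).to_numpy(dtype=float)
    x = log_expr.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    fc = fs - fs.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sf = np.sqrt((fc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(sx > 0, (xc @ fc) / (sx * sf), np.nan)
    table = pd.DataFrame({"r": r}, index=log_expr.index)
    order = table["r"].rank(ascending=False, method="first")
    table["rank"] = order
    table["selected"] = False
    return table


def select_signature(table: pd.DataFrame, r_min: float = 0.5, k: int = 25) -> pd.DataFrame:
    """Flag the fibrosis signature: the k best-correlated miRNAs with r > r_min.

    If fewer than ``k`` miRNAs exceed ``r_min`` all qualifying ones are
    selected.  Ties at the k-th rank are broken by miRNA identifier.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = table.copy()
    qualifying = out.index[out["r"] > r_min]
    ranked = sorted(qualifying, key=lambda m: (-out.at[m, "r"], str(m)))
    chosen = set(ranked[:k])
    out["selected"] = [m in chosen for m in out.index]
    return out


def significance_of_r(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation under the null (t-test)."""
    if n < 3:
        raise ValueError("need >= 3 samples")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), df=n - 2))
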