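"""Correlation-distance hierarchical clustering and miRNA profile archetypes.

Samples and miRNAs are clustered agglomeratively with Pearson correlation
distance (d = 1 - r) and complete linkage, the convention of heatmap
packages.  miRNA profiles from a 2x2 progenitor-by-treatment design
(FAP/MP x +/-TGFb1) are additionally classified into four archetypes by an
explicit rule table on cell-type enrichment and TGFb1 response:

    C1  MP-enriched,  down-regulated by TGFb1 (in MPs)
    C2  MP-enriched,  unresponsive to TGFb1
    C3  FAP-enriched, down-regulated by TGFb1 (in FAPs)
    C4  FAP-enriched, up-regulated by TGFb1 (in FAPs)

with everything else unclassified.  The response is always measured in the
enriched cell type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "zscore_rows",
    "pearson_distance",
    "hac_complete",
    "Dendrogram",
    "classify_archetype",
    "intersect_modulated",
    "CONDITIONS",
]

#: the four conditions of the progenitor x treatment design, fixed order
CONDITIONS = ("FAP-control", "FAP-TGFb", "MP-control", "MP-TGFb")


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Row-wise Z-scores (sample sd, n-1); constant rows are dropped.

    Returns the scaled matrix and the list of dropped (constant) row IDs.
    """
    if matrix.shape[1] < 2:
        raise ValueError("Z-scoring needs >= 2 columns")
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    dropped = list(matrix.index[~keep])
    z = (x[keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns), dropped


def pearson_distance(x, y) -> float:
    """Pearson correlation distance d = 1 - r(x, y), in [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("correlation distance undefined for constant vectors")
    r = float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))
    return 1.0 - r


def _pearson_distance_matrix(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    sd = np.sqrt((xc**2).sum(axis=1))
    if (sd == 0).any():
        raise ValueError("correlation distance undefined for constant rows")
    r = np.clip((xc @ xc.T) / np.outer(sd, sd), -1.0, 1.0)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over items clustered by Pearson distance."""

    #: scipy-format linkage matrix (merged pair, height, cluster size)
    linkage: np.ndarray
    items: list = field(default_factory=list)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list:
        return [self.items[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> pd.Series:
        """Cluster labels (1..k) from cutting the tree into k clusters."""
        if not 1 <= k <= len(self.items):
            raise ValueError("k must be between 1 and the number of items")
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.items, name="cluster")


def hac_complete(matrix: pd.DataFrame, axis: str = "rows") -> Dendrogram:
    """Complete-linkage agglomerative clustering with Pearson distance.

    Parameters
    ----------
    matrix
        Data frame; ``axis='rows'`` clusters the rows (e.g. miRNAs),
        ``axis='columns'`` the columns (samples).
    """
    if axis == "columns":
        matrix = matrix.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    if len(matrix) < 2:
        raise ValueError("clustering needs >= 2 items")
    d = _pearson_distance_matrix(matrix.to_numpy(dtype=float))
    z = hierarchy.linkage(squareform(d, checks=False), method="complete")
    return Dendrogram(linkage=z, items=list(matrix.index))


def classify_archetype(
    mean_expr: pd.DataFrame,
    e_min: float = 1.0,
    l_min: float = 1.0,
    expression_floor: float = 5.0,
    pseudo: float = 0.5,
) -> pd.DataFrame:
    """Classify miRNA profiles of the FAP/MP x +/-TGFb1 design into archetypes.

    Parameters
    ----------
    mean_expr
        miRNA x condition matrix of mean normalised expression with the four
        columns of :data:`CONDITIONS`.
    e_min
        Minimum |log2(FAP/MP)| to call a miRNA cell-type enriched.
    l_min
        Minimum |log2 TGFb1 response| (in the enriched cell type) to call a
        response.
    expression_floor
        miRNAs whose maximum condition mean is below this are unclassified.
    pseudo
        Pseudo-expression added before each log ratio.

    Returns
    -------
    DataFrame with ``cell_enrichment``, ``tgfb_response`` and ``class``
    (C1 | C2 | C3 | C4 | unclassified) per miRNA.
    """
    missing = [c for c in CONDITIONS if c not in mean_expr.columns]
    if missing:
        raise ValueError(f"missing design conditions: {missing}")
    fap_c = mean_expr["FAP-control"].to_numpy(dtype=float)
    fap_t = mean_expr["FAP-TGFb"].to_numpy(dtype=float)
    mp_c = mean_expr["MP-control"].to_numpy(dtype=float)
    mp_t = mean_expr["MP-TGFb"].to_numpy(dtype=float)

    fap_mean = (fap_c + fap_t) / 2
    mp_mean = (mp_c + mp_t) / 2
    enrichment = np.log2((fap_mean + pseudo) / (mp_mean + pseudo))
    resp_fap = np.log2((fap_t + pseudo) / (fap_c + pseudo))
    resp_mp = np.log2((mp_t + pseudo) / (mp_c + pseudo))
    # the response is read in whichever cell type the miRNA is enriched in
    response = np.where(enrichment >= 0, resp_fap, resp_mp)

    cls = np.full(len(mean_expr), "unclassified", dtype=object)
    expressed = mean_expr[list(CONDITIONS)].to_numpy(dtype=float).max(axis=1) >= expression_floor
    mp_enr = enrichment <= -e_min
    fap_enr = enrichment >= e_min
    cls[expressed & mp_enr & (response <= -l_min)] = "C1"
    cls[expressed & mp_enr & (np.abs(response) < l_min)] = "C2"
    cls[expressed & fap_enr & (response <= -l_min)] = "C3"
    cls[expressed & fap_enr & (response >= l_min)] = "C4"

    return pd.DataFrame(
        {"cell_enrichment": enrichment, "tgfb_response": response, "class": cls},
        index=mean_expr.index,
    )


def intersect_modulated(set_dmd, set_diff) -> tuple[int, int, int, pd.DataFrame]:
    """Venn-style intersection of two miRNA identifier sets.

    Returns (|A only|, |A and B|, |B only|) plus a sorted membership table
    with boolean columns ``in_dmd`` and ``in_diff``.
    """
    a, b = set(set_dmd), set(set_diff)
    members = sorted(a | b, key=str)
    table = pd.DataFrame(
        {"in_dmd": [m in a for m in members], "in_diff": [m in b for m in members]},
        index=pd.Index(members, name="mirna"),
    )
    return len(a - b), len(a & b), len(b - a), table
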