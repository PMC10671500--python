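"""FPKM transformation and hierarchical clustering of expression profiles.

Expression matrices are pandas DataFrames (genes x samples, non-negative
FPKM).  The heatmap-ready transform is log2(FPKM + 1); genes are grouped
by average-linkage agglomerative clustering under either correlation
(1 - Pearson) or Euclidean distance, with group labels ordered by
descending cluster mean expression.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["transform_fpkm", "cluster_genes"]


def transform_fpkm(m: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1); raises on negative values or missing cells."""
    values = m.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("expression matrix has missing cells")
    if (values < 0).any():
        raise ValueError("FPKM values must be non-negative")
    return pd.DataFrame(np.log2(values + 1.0), index=m.index, columns=m.columns)


def cluster_genes(
    m: pd.DataFrame,
    k: int,
    linkage: str = "average",
    distance: str = "correlation",
) -> Dict[str, int]:
    """Cut an agglomerative gene tree into k groups.

    distance 'correlation' is 1 - Pearson across samples; 'euclidean' is
    the usual L2.  Returns gene id -> group label in 1..k with group 1
    holding the highest mean expression.  Deterministic given inputs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = m.shape[0]
    if k > n:
        raise ValueError(f"k = {k} exceeds the {n} genes available")
    if distance not in {"correlation", "euclidean"}:
        raise ValueError(f"unknown distance {distance!r}")
    if linkage != "average":
        raise ValueError("only average linkage is supported")
    values = m.to_numpy(dtype=float)
    if k == 1:
        return {g: 1 for g in m.index}
    if distance == "correlation":
        sd = values.std(axis=1)
        if (sd == 0).any():
            flat = [g for g, s in zip(m.index, sd) if s == 0]
            raise ValueError(
                f"constant expression rows have no correlation distance: {flat}"
            )
    D = pdist(values, metric=distance)
    D = np.maximum(D, 0.0)  # clip fp noise on duplicate rows
    Z = hierarchy.linkage(D, method="average")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    means = {c: values[raw == c].mean() for c in np.unique(raw)}
    order = sorted(means, key=lambda c: -means[c])
    relabel = {c: i + 1 for i, c in enumerate(order)}
    return {g: relabel[c] for g, c in zip(m.index, raw)}
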