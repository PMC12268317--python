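"""Agreement of retention behaviour between systems.

Two complementary views: Pearson correlation of raw retention times
(sensitive to absolute spacing) and Spearman rank correlation of
retention order (invariant under any strictly increasing warp of one
system's time axis, hence robust to gradient-program differences).
Systems are then grouped by average-linkage hierarchical clustering on
the distance 1 - coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import InsufficientOverlapError
from .io import RetentionTable

logger = logging.getLogger(__name__)

MIN_OVERLAP = 3


def pairwise_correlation(rts_a, rts_b, method: str = "spearman") -> float:
    """Correlation of paired retention times from two systems.

    Pearson acts on raw RTs; Spearman is Pearson on average ranks
    (tie-aware).  Raises on n < 3 or zero variance.
    """
    a = np.asarray(rts_a, dtype=float)
    b = np.asarray(rts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < MIN_OVERLAP:
        raise InsufficientOverlapError(
            f"need >= {MIN_OVERLAP} shared compounds, got {a.size}"
        )
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise InsufficientOverlapError("zero variance: coefficient undefined")
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class SimilarityMatrix:
    """Square matrix of pairwise coefficients plus shared-compound counts."""

    cs_ids: list[str]
    method: str
    values: pd.DataFrame
    n_shared: pd.DataFrame


def similarity_matrix(table: RetentionTable, method: str = "spearman"
                      ) -> SimilarityMatrix:
    """All-pairs correlation on compounds (calibrants and suspects)
    detected by both systems; entries with insufficient overlap are NaN
    and logged."""
    ids = table.system_ids
    n = len(ids)
    vals = np.eye(n)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        counts[i, i] = len(table.detected(ids[i]))
        for j in range(i + 1, n):
            shared = table.shared_detected(ids[i], ids[j])
            counts[i, j] = counts[j, i] = len(shared)
            try:
                coef = pairwise_correlation(
                    table.rts(ids[i])[shared], table.rts(ids[j])[shared],
                    method,
                )
            except InsufficientOverlapError as exc:
                logger.warning("%s vs %s: %s", ids[i], ids[j], exc)
                coef = np.nan
            vals[i, j] = vals[j, i] = coef
    return SimilarityMatrix(
        cs_ids=list(ids),
        method=method,
        values=pd.DataFrame(vals, index=ids, columns=ids),
        n_shared=pd.DataFrame(counts, index=ids, columns=ids),
    )


def cluster_order(matrix: SimilarityMatrix):
    """Average-linkage agglomerative clustering on 1 - coefficient.

    Returns ``(ordered_cs_ids, linkage_matrix)``.  Systems enter in
    lexical cs_id order so ties resolve deterministically; missing
    entries are imputed to the column mean (logged).
    """
    ids = sorted(matrix.cs_ids)
    vals = matrix.values.loc[ids, ids].to_numpy(dtype=float).copy()
    if np.isnan(vals).any():
        logger.warning("similarity matrix has missing entries; imputing "
                       "column means before clustering")
        col_mean = np.nanmean(np.where(np.eye(len(ids), dtype=bool),
                                       np.nan, vals), axis=0)
        nan_r, nan_c = np.where(np.isnan(vals))
        vals[nan_r, nan_c] = col_mean[nan_c]
        vals = (vals + vals.T) / 2
    dist = 1.0 - vals
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    if np.ptp(condensed) < 1e-12:
        return ids, link  # single flat cluster: keep lexical order
    leaves = hierarchy.leaves_list(link)
    return [ids[i] for i in leaves], link
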