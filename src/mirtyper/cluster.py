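"""Consensus clustering and supervised clustering utilities.

Consensus clustering follows the Monti resampling scheme: the sample set
is repeatedly subsampled, each subsample is clustered hierarchically, and
the consensus matrix records how often each sample pair lands in the same
cluster among the subsamples containing both.  The area under the
consensus CDF across k, and its relative increments (delta area), guide
the choice of k — the selection is advisory and always reported next to
the full curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "ConsensusResult",
    "WardResult",
    "consensus_cluster",
    "select_k",
    "chi2_enrichment",
    "ward_cluster",
]

log = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    """Everything the resampling produced, per k = 2..max_k."""

    consensus: dict[int, pd.DataFrame]
    labels: dict[int, pd.Series]
    item_consensus: dict[int, pd.Series]
    areas: dict[int, float]
    deltas: dict[int, float]
    seed: int | None
    params: dict = field(default_factory=dict)


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between columns of X, as a square matrix."""
    r = np.corrcoef(X, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def _hclust_labels(dist: np.ndarray, ks: list[int], linkage: str) -> dict[int, np.ndarray]:
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    return {k: hierarchy.fcluster(Z, t=k, criterion="maxclust") for k in ks}


def consensus_cluster(
    expr: pd.DataFrame,
    max_k: int = 6,
    reps: int = 1000,
    p_item: float = 0.8,
    p_feature: float = 1.0,
    seed: int | None = None,
    linkage: str = "average",
    distance: str = "pearson",
) -> ConsensusResult:
    """Resampled hierarchical consensus clustering of the sample columns.

    ``expr`` is features x samples.  Each of ``reps`` draws keeps
    ceil(p_item * n) samples (and ceil(p_feature * m) features), clusters
    them by average linkage on 1 - Pearson distance, and cuts the tree at
    every k in 2..max_k.  consensus(i, j) = co-cluster count / co-sample
    count.  Final labels come from average linkage on 1 - consensus.
    """
    n = expr.shape[1]
    if n < max_k + 1:
        raise ValueError(f"need more than max_k={max_k} samples, got {n}")
    if distance != "pearson":
        raise ValueError("only the pearson distance is implemented")
    X = expr.to_numpy(dtype=float)
    const = X.std(axis=0) == 0
    if const.any():
        bad = list(expr.columns[const])
        raise ValueError(
            f"constant sample vector(s) — Pearson distance undefined: {bad}"
        )

    rng = np.random.default_rng(seed)
    ks = list(range(2, max_k + 1))
    n_item = math.ceil(p_item * n)
    m = expr.shape[0]
    n_feat = math.ceil(p_feature * m)

    co_sampled = np.zeros((n, n))
    co_clustered = {k: np.zeros((n, n)) for k in ks}
    for _ in range(reps):
        items = np.sort(rng.choice(n, size=n_item, replace=False))
        feats = (np.sort(rng.choice(m, size=n_feat, replace=False))
                 if n_feat < m else slice(None))
        sub = X[feats][:, items]
        sd = sub.std(axis=0)
        if (sd == 0).any():  # feature subsample left a sample constant
            keep = sd > 0
            items, sub = items[keep], sub[:, keep]
            if items.size < 3:
                continue
        dist = _pearson_distance(sub)
        lab_by_k = _hclust_labels(dist, ks, linkage)
        ii = np.ix_(items, items)
        co_sampled[ii] += 1
        for k, lab in lab_by_k.items():
            same = lab[:, None] == lab[None, :]
            co_clustered[k][ii] += same

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = {}
        for k in ks:
            M = co_clustered[k] / co_sampled
            np.fill_diagonal(M, 1.0)
            consensus[k] = pd.DataFrame(M, index=expr.columns, columns=expr.columns)
    never = (co_sampled == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        log.warning("consensus_cluster: %d sample pair(s) never co-sampled; "
                    "entries are NA and imputed for final clustering",
                    int(never.sum() // 2))

    labels: dict[int, pd.Series] = {}
    item_cons: dict[int, pd.Series] = {}
    areas: dict[int, float] = {}
    deltas: dict[int, float] = {}
    prev_area = None
    for k in ks:
        M = consensus[k].to_numpy().copy()
        if np.isnan(M).any():  # impute NA entries as column means
            col_means = np.nanmean(M, axis=0)
            nan_r, nan_c = np.where(np.isnan(M))
            M[nan_r, nan_c] = col_means[nan_c]
        D = 1.0 - M
        np.fill_diagonal(D, 0.0)
        D = (D + D.T) / 2
        lab = _hclust_labels(D, [k], linkage)[k]
        labels[k] = pd.Series(lab, index=expr.columns, name=f"k{k}")
        item_cons[k] = _item_consensus(pd.DataFrame(M, index=expr.columns,
                                                    columns=expr.columns), labels[k])
        areas[k] = _cdf_area(consensus[k])
        if prev_area is None:
            deltas[k] = areas[k]
        else:
            deltas[k] = (areas[k] - prev_area) / prev_area if prev_area > 0 else 0.0
        prev_area = areas[k]

    return ConsensusResult(
        consensus=consensus, labels=labels, item_consensus=item_cons,
        areas=areas, deltas=deltas, seed=seed,
        params=dict(max_k=max_k, reps=reps, p_item=p_item, p_feature=p_feature,
                    linkage=linkage, distance=distance),
    )


def _item_consensus(M: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Mean consensus of each item with the other members of its cluster."""
    out = {}
    arr = M.to_numpy()
    lab = labels.to_numpy()
    for i, sid in enumerate(M.index):
        members = np.where(lab == lab[i])[0]
        members = members[members != i]
        out[sid] = float(np.nanmean(arr[i, members])) if members.size else 1.0
    return pd.Series(out, name=labels.name)


def _cdf_area(M: pd.DataFrame) -> float:
    """Area under the empirical CDF of off-diagonal consensus entries.

    The CDF is integrated over the whole [0, 1] consensus range (it is 0
    below the smallest entry and 1 above the largest), so a perfectly
    binary consensus matrix scores 1 - (fraction of co-clustered pairs).
    """
    arr = M.to_numpy()
    iu = np.triu_indices_from(arr, k=1)
    vals = arr[iu]
    vals = np.sort(vals[~np.isnan(vals)])
    if vals.size == 0:
        return 0.0
    xs = np.unique(np.clip(vals, 0.0, 1.0))
    cdf = np.searchsorted(vals, xs, side="right") / vals.size
    area = 0.0
    prev_x, prev_cdf = 0.0, 0.0
    for x, c in zip(xs, cdf):
        area += (x - prev_x) * prev_cdf
        prev_x, prev_cdf = x, c
    area += (1.0 - prev_x) * prev_cdf
    return float(area)


def select_k(
    result: ConsensusResult | Mapping[int, float],
    threshold: float = 0.1,
    area_floor: float = 0.25,
) -> int:
    """Choose k from the delta-area curve.

    The selected k is the smallest one whose *next* increment falls below
    ``threshold`` — i.e. moving to k+1 buys less than a ``threshold``
    relative gain in consensus CDF area.  Two low-confidence situations
    are logged rather than hidden: all increments below threshold, and a
    2-cluster CDF area under ``area_floor`` (no stable split exists at
    all — relative gains against a near-zero baseline carry no evidence
    of real structure, so k=2 is returned flagged).
    """
    if isinstance(result, ConsensusResult) and result.areas:
        k0 = min(result.areas)
        if result.areas[k0] < area_floor:
            log.warning(
                "select_k: consensus CDF area %.3f at k=%d is below %.2f; "
                "no stable split — low-confidence selection of k=%d",
                result.areas[k0], k0, area_floor, k0,
            )
            return k0
    deltas = result.deltas if isinstance(result, ConsensusResult) else dict(result)
    ks = sorted(deltas)
    if len(ks) < 2:
        return ks[0] if ks else 2
    for k in ks[:-1]:
        if deltas[k + 1] < threshold:
            if deltas[k] < threshold:
                log.warning("select_k: all delta-areas below %.3g from k=%d; "
                            "low-confidence selection", threshold, k)
            return k
    return ks[-1]


def chi2_enrichment(
    cluster_labels: pd.Series, clinical_labels: pd.Series
) -> tuple[float, int, float, pd.DataFrame]:
    """Pearson chi-square association between cluster and clinical labels.

    Returns (statistic, dof, p, expected-count table); warns when any
    expected count is below 5.
    """
    a = pd.Series(cluster_labels).reset_index(drop=True)
    b = pd.Series(clinical_labels).reset_index(drop=True)
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    table = pd.crosstab(a, b)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("both label factors need >= 2 levels")
    res = stats.chi2_contingency(table.to_numpy(), correction=False)
    expected = pd.DataFrame(res.expected_freq, index=table.index,
                            columns=table.columns)
    if (expected.to_numpy() < 5).any():
        log.warning("chi2_enrichment: expected count(s) below 5; "
                    "chi-square approximation may be poor")
    return float(res.statistic), int(res.dof), float(res.pvalue), expected


@dataclass
class WardResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_labels: pd.Series
    col_labels: pd.Series


def ward_cluster(
    m: pd.DataFrame, cut_rows: int = 5, cut_cols: int = 4
) -> WardResult:
    """Euclidean/Ward (variance-minimizing, distance-squared update)
    agglomerative clustering of rows and columns of a (row-standardized)
    matrix, with k-cut labels for both axes."""
    if m.isna().any().any():
        raise ValueError("matrix contains NA entries")
    X = m.to_numpy(dtype=float)
    zr = hierarchy.linkage(X, method="ward")
    zc = hierarchy.linkage(X.T, method="ward")
    row_labels = pd.Series(
        hierarchy.fcluster(zr, t=cut_rows, criterion="maxclust"),
        index=m.index, name="row_cluster",
    )
    col_labels = pd.Series(
        hierarchy.fcluster(zc, t=cut_cols, criterion="maxclust"),
        index=m.columns, name="col_cluster",
    )
    return WardResult(zr, zc, row_labels, col_labels)
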