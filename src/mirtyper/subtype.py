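"""Reference-centered nearest-centroid intrinsic-subtype classification.

Each test sample is gene-centered against a fixed reference cohort (never
against the test cohort itself, so adding samples cannot shift existing
calls) and assigned the subtype whose centroid it correlates with best.
Samples whose best correlation stays below a threshold are left
unassigned rather than forced into a class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CentroidSet", "SubtypeCall", "center_to_reference",
           "nearest_centroid", "classify_cohort"]

log = logging.getLogger(__name__)


@dataclass
class CentroidSet:
    """Gene x subtype centroid matrix."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate genes in centroid matrix")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 subtype centroids")

    @property
    def subtypes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> pd.Index:
        return self.values.index


@dataclass
class SubtypeCall:
    sample_id: str
    correlations: pd.Series  # per subtype
    label: str | None        # None = unassigned
    margin: float            # best - second-best correlation
    reason: str | None = None


def center_to_reference(expr: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Subtract each gene's reference-cohort mean from every test sample.

    Only genes present in the reference are kept (dropped genes are
    logged); reference samples alone define the centering, so previously
    centered values are invariant to new test samples.
    """
    shared = expr.index.intersection(reference.index)
    missing = expr.index.difference(reference.index)
    if len(missing):
        log.warning("center_to_reference: %d gene(s) absent from reference, "
                    "excluded: %s", len(missing), list(missing[:5]))
    if not len(shared):
        raise ValueError("no genes shared between expression and reference")
    ref_means = reference.loc[shared].mean(axis=1)
    return expr.loc[shared].sub(ref_means, axis=0)


def _correlate(x: np.ndarray, y: np.ndarray, metric: str) -> float:
    if metric == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if metric == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown metric {metric!r}")


def nearest_centroid(
    sample: pd.Series,
    centroids: CentroidSet,
    metric: str = "spearman",
    threshold: float = 0.1,
) -> SubtypeCall:
    """Classify one (already centered) sample vector.

    Correlation is computed over the genes shared with the centroid set
    (>= 10 required).  Ties between top centroids are broken
    alphabetically and flagged in ``reason``.
    """
    shared = sample.index.intersection(centroids.genes)
    if len(shared) < 10:
        raise ValueError(
            f"only {len(shared)} genes shared with centroids; need >= 10"
        )
    x = sample.loc[shared].to_numpy(dtype=float)
    name = str(sample.name) if sample.name is not None else "sample"
    if np.all(x == x[0]):
        cors = pd.Series(np.nan, index=centroids.subtypes)
        return SubtypeCall(name, cors, None, 0.0, reason="constant sample vector")
    cors = pd.Series(
        {
            st: _correlate(x, centroids.values.loc[shared, st].to_numpy(float), metric)
            for st in centroids.subtypes
        }
    )
    ordered = cors.sort_values(ascending=False, kind="mergesort")
    # alphabetical tie-break among equal-best centroids
    best_val = ordered.iloc[0]
    tied = sorted(ordered[ordered == best_val].index)
    label = tied[0]
    margin = float(best_val - ordered.iloc[1]) if len(ordered) > 1 else 0.0
    reason = "tie between centroids: " + ",".join(tied) if len(tied) > 1 else None
    if best_val < threshold:
        return SubtypeCall(name, cors, None, margin,
                           reason="low correlation to all centroids")
    return SubtypeCall(name, cors, label, margin, reason=reason)


def classify_cohort(
    expr: pd.DataFrame,
    centroids: CentroidSet,
    reference: pd.DataFrame | None = None,
    metric: str = "spearman",
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Center (when a reference is given) and classify every sample.

    Returns a table with the assigned label (NaN when unassigned), the
    per-subtype correlations, and the call margin.
    """
    data = center_to_reference(expr, reference) if reference is not None else expr
    rows = []
    for sid in data.columns:
        call = nearest_centroid(data[sid], centroids, metric, threshold)
        row = {"sample_id": sid, "label": call.label, "margin": call.margin,
               "reason": call.reason}
        row.update({f"cor_{st}": call.correlations[st] for st in centroids.subtypes})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
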