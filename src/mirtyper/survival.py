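"""Median-split stratified survival analysis.

The workhorse is :func:`stratified_analysis`: within each stratum
(typically a molecular subtype), samples are split at the stratum median
of an expression score — the mean log2-CPM of a miRNA set such as the
miR-99a/let-7c/miR-125b cluster, or a single host-gene expression column —
and the high/low groups are compared by Kaplan-Meier curves and the
log-rank test.  An optional clinical filter restricts the stratum first
(e.g. ER+/HER2-, node-negative, endocrine-treated only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test

__all__ = [
    "cluster_score",
    "median_split",
    "km_estimate",
    "logrank",
    "stratified_analysis",
    "StratumResult",
]

log = logging.getLogger(__name__)


def cluster_score(expr: pd.DataFrame, members: list[str]) -> pd.Series:
    """Per-sample arithmetic mean of the member miRNAs' expression rows.

    ``members`` may name mature IDs directly or precursor stems; a stem
    matches every mature arm whose ID starts with it (so "mir-99a"
    averages both -5p and -3p when present).  Missing members are logged.
    """
    rows: list[str] = []
    missing: list[str] = []
    for m in members:
        if m in expr.index:
            rows.append(m)
            continue
        hits = [i for i in expr.index if str(i).startswith(m)]
        if hits:
            rows.extend(hits)
        else:
            missing.append(m)
    if missing:
        log.warning("cluster_score: member(s) not in matrix: %s", missing)
    if not rows:
        raise ValueError("no score members present in the expression matrix")
    return expr.loc[rows].mean(axis=0)


def median_split(scores: pd.Series) -> pd.Series:
    """Dichotomize at the median: score > median -> 'high', else 'low'."""
    scores = scores.dropna()
    if len(scores) < 2:
        raise ValueError("need at least 2 scores to split")
    med = scores.median()
    if scores.nunique() == 1:
        raise ValueError("all scores identical; no median split possible")
    groups = pd.Series(np.where(scores > med, "high", "low"),
                       index=scores.index, name="group")
    log.info("median_split: high=%d low=%d (median=%.4g)",
             (groups == "high").sum(), (groups == "low").sum(), med)
    return groups


def km_estimate(
    time: pd.Series | np.ndarray, event: pd.Series | np.ndarray
) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve.

    Returns a step table (time, survival, at_risk); survival starts at 1,
    is non-increasing, and drops only at event times.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index)
    out = pd.DataFrame({
        "time": sf.index.to_numpy(dtype=float),
        "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        "at_risk": at_risk.to_numpy(dtype=float),
    })
    return out.reset_index(drop=True)


def logrank(
    time: pd.Series | np.ndarray,
    event: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
) -> tuple[float, int, float]:
    """Log-rank test across 2+ groups: (chi-square, df, p)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("need >= 2 groups")
    if event.sum() == 0:
        raise ValueError("no events in any group")
    if levels.size == 2:
        a, b = (groups == levels[0]), (groups == levels[1])
        res = logrank_test(time[a], time[b], event_observed_A=event[a],
                           event_observed_B=event[b])
        return float(res.test_statistic), 1, float(res.p_value)
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), int(levels.size - 1), float(res.p_value)


@dataclass
class StratumResult:
    stratum: str
    n: int
    groups: pd.Series | None = None
    km: dict[str, pd.DataFrame] = field(default_factory=dict)
    chi2: float | None = None
    p: float | None = None
    note: str | None = None


def stratified_analysis(
    clinical: pd.DataFrame,
    scores: pd.Series,
    stratify_by: str = "subtype",
    subgroup_filter: dict[str, object] | None = None,
    time_col: str = "time",
    event_col: str = "event",
) -> dict[str, StratumResult]:
    """Median-split survival comparison within each stratum.

    ``clinical`` is indexed by sample with time/event/stratum (and any
    covariate) columns; ``scores`` is the expression score to split on.
    The optional ``subgroup_filter`` {column: required value} restricts
    samples *before* splitting.  Each stratum's median is computed from
    its own samples only.
    """
    df = clinical.copy()
    if subgroup_filter:
        for col, val in subgroup_filter.items():
            if col not in df.columns:
                raise KeyError(f"filter column {col!r} not in clinical table")
            df = df[df[col] == val]
    out: dict[str, StratumResult] = {}
    for stratum in sorted(clinical[stratify_by].dropna().unique()):
        sub = df[df[stratify_by] == stratum]
        res = StratumResult(stratum=str(stratum), n=len(sub))
        if len(sub) == 0:
            res.note = "no samples after filtering"
            out[str(stratum)] = res
            continue
        s = scores.reindex(sub.index).dropna()
        sub = sub.loc[s.index]
        res.n = len(sub)
        try:
            groups = median_split(s)
        except ValueError as e:
            res.note = str(e)
            out[str(stratum)] = res
            continue
        res.groups = groups
        for g in ("high", "low"):
            mask = groups == g
            if mask.any():
                res.km[g] = km_estimate(sub.loc[mask, time_col],
                                        sub.loc[mask, event_col])
        try:
            res.chi2, _, res.p = logrank(sub[time_col], sub[event_col], groups)
        except ValueError as e:
            res.note = str(e)
        out[str(stratum)] = res
    return out
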