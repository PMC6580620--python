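"""Differential-expression contrasts and the top-k union signature.

Contrasts come in two flavors: one subtype versus the rest, and all
pairwise subtype combinations.  The per-miRNA test is pluggable; the
default is the two-sided Wilcoxon rank-sum on log2-CPM values — a
distribution-free stand-in for a count-model test, adequate for the
cohort sizes this package targets.  Significance is controlled by
Benjamini-Hochberg FDR and the signature is the union of each contrast's
top-k members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContrastResult",
    "Signature",
    "ranksum_test",
    "de_contrast",
    "all_contrasts",
    "bh_adjust",
    "build_signature",
]

TestFunc = Callable[[np.ndarray, np.ndarray], float]
"""(values_group_a, values_group_b) -> two-sided p-value, per miRNA."""


def ranksum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value; 1.0 when all values tie."""
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


@dataclass
class ContrastResult:
    """Per-miRNA statistics for one contrast."""

    label: str
    table: pd.DataFrame  # index mature_id; columns log2_fc, p, q


@dataclass
class Signature:
    """Ordered union of top contrast hits with provenance."""

    members: list[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def de_contrast(
    expr: pd.DataFrame,
    labels: pd.Series,
    group_a: str | Sequence[str],
    group_b: str | Sequence[str] | None = None,
    label: str | None = None,
    test: TestFunc = ranksum_test,
) -> ContrastResult:
    """Test every miRNA between two sample groups.

    ``group_a`` (and ``group_b``) name subtype levels; ``group_b=None``
    means "the rest".  log2 fold-change is the difference of group means
    on the log2-CPM scale, positive when higher in ``group_a``.
    """
    labels = labels.reindex(expr.columns)
    a_levels = [group_a] if isinstance(group_a, str) else list(group_a)
    mask_a = labels.isin(a_levels).to_numpy()
    if group_b is None:
        mask_b = ~mask_a & labels.notna().to_numpy()
        b_name = "rest"
    else:
        b_levels = [group_b] if isinstance(group_b, str) else list(group_b)
        mask_b = labels.isin(b_levels).to_numpy()
        b_name = "+".join(b_levels)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(
            f"contrast needs >=2 samples per group "
            f"(got {int(mask_a.sum())} vs {int(mask_b.sum())})"
        )
    A = expr.values[:, mask_a]
    B = expr.values[:, mask_b]
    p = np.array([test(A[i], B[i]) for i in range(expr.shape[0])])
    fc = A.mean(axis=1) - B.mean(axis=1)
    table = pd.DataFrame(
        {"log2_fc": fc, "p": p, "q": bh_adjust(p)}, index=expr.index
    )
    a_name = "+".join(a_levels)
    return ContrastResult(label or f"{a_name}_vs_{b_name}", table)


def all_contrasts(
    expr: pd.DataFrame,
    labels: pd.Series,
    scheme: str = "both",
    test: TestFunc = ranksum_test,
) -> list[ContrastResult]:
    """One-vs-rest and/or all pairwise contrasts over the label levels."""
    levels = sorted(labels.dropna().unique())
    out: list[ContrastResult] = []
    if scheme in ("ovr", "both"):
        for lv in levels:
            out.append(de_contrast(expr, labels, lv, None, test=test))
    if scheme in ("pairwise", "both"):
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                out.append(de_contrast(expr, labels, a, b, test=test))
    if not out:
        raise ValueError(f"unknown contrast scheme {scheme!r}")
    return out


def build_signature(
    results: list[ContrastResult],
    k: int = 15,
    fdr: float = 0.01,
) -> Signature:
    """Union of each contrast's k most significant miRNAs at q <= fdr.

    Ties broken deterministically by (q, |log2_fc| descending, mature_id);
    provenance records which contrasts contributed each member.
    """
    if not results:
        raise ValueError("need at least one contrast result")
    provenance: dict[str, list[str]] = {}
    members: list[str] = []
    for res in results:
        t = res.table[res.table["q"] <= fdr].copy()
        t["absfc"] = t["log2_fc"].abs()
        t["_id"] = t.index.astype(str)
        t = t.sort_values(
            ["q", "absfc", "_id"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        top = t.head(k)
        for mid in top.index:
            if mid not in provenance:
                provenance[mid] = []
                members.append(mid)
            provenance[mid].append(res.label)
    members.sort()
    return Signature(members=members, provenance=provenance)
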