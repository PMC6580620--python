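"""log2-CPM normalization and expression-complexity summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "log2_cpm", "expressed_counts", "standardize_rows"]

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """log2-CPM values (mature_id x sample) with the parameters used."""

    values: pd.DataFrame
    prior: float
    lib_sizes: pd.Series


def log2_cpm(
    counts: pd.DataFrame,
    prior: float = 0.25,
    lib_sizes: pd.Series | None = None,
    library_scaled_prior: bool = True,
) -> ExpressionMatrix:
    """Counts-per-million on the log2 scale with a pseudo-count.

    For sample j with library size N_j the value for count c is

        log2( (c + p_j) / (N_j + 2 p_j) * 1e6 )

    with p_j = prior * N_j / mean(N) by default: the pseudo-count is
    scaled to each library so that zero counts land on a common floor
    regardless of sequencing depth (the behavior of the standard
    count-package implementation of this transform).  Set
    ``library_scaled_prior=False`` for a plain fixed pseudo-count.
    Normalization factors are fixed at 1: libraries are scaled by raw
    size only.
    """
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = lib_sizes.astype(float)
    zero = lib_sizes[lib_sizes <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    if library_scaled_prior:
        p = prior * lib_sizes / lib_sizes.mean()
    else:
        p = pd.Series(float(prior), index=lib_sizes.index)
    vals = np.log2(
        (counts.astype(float).add(p, axis=1))
        .div(lib_sizes + 2 * p, axis=1)
        * 1e6
    )
    return ExpressionMatrix(values=vals, prior=prior, lib_sizes=lib_sizes)


def expressed_counts(
    expr: ExpressionMatrix | pd.DataFrame,
    lo: float = -5.0,
    hi: float = 20.0,
    step: float = 0.5,
) -> pd.DataFrame:
    """Cumulative expressed-miRNA counts per sample over a threshold grid.

    For each threshold t in [lo, hi] (spacing ``step``), the number of
    miRNAs with log2-CPM >= t in each sample, plus a ``mean`` column over
    samples.  The curve is non-increasing in t by construction.
    """
    if not (lo < hi and step > 0):
        raise ValueError("need lo < hi and step > 0")
    vals = expr.values if isinstance(expr, ExpressionMatrix) else expr
    grid = np.arange(lo, hi + step / 2, step)
    rows = {t: (vals >= t).sum(axis=0) for t in grid}
    out = pd.DataFrame(rows).T
    out.index.name = "threshold"
    out["mean"] = out.mean(axis=1)
    return out


def standardize_rows(m: pd.DataFrame) -> pd.DataFrame:
    """Center each row to mean 0 and scale to sample SD (n-1 denominator) 1.

    Constant rows cannot be scaled; they are set to all-zeros with a
    warning rather than propagating NaN into downstream clustering.
    """
    mu = m.mean(axis=1)
    sd = m.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        log.warning("standardize_rows: %d constant row(s) set to zero",
                    int(const.sum()))
        sd = sd.mask(const, 1.0)
    out = m.sub(mu, axis=0).div(sd, axis=0)
    out.loc[const] = 0.0
    return out
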