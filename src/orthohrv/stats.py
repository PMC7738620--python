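"""Correlation surface between HRV indices and fatigue/workload indicators.

Pearson correlations with exact t-transform p-values are computed on
pooled athlete-day rows (pairwise-complete, QC-rejected sessions
excluded).  Because the orthostatic deltas share the supine phase, the
comparison of two dependent correlations r(x, y1) vs r(x, y2) uses
Williams' test in the Steiger (1980) t2 formulation:

    t = (r12 - r13) * sqrt( (n-1)(1+r23) /
          ( 2 |R| (n-1)/(n-3) + rbar^2 (1-r23)^3 ) ),   df = n - 3

with |R| = 1 - r12^2 - r13^2 - r23^2 + 2 r12 r13 r23 the determinant of
the 3x3 correlation matrix and rbar = (r12 + r13)/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class CorrelationCell:
    """One (indicator, index) correlation: coefficient, p-value, pairs used."""

    r: float
    p: float
    n: int


@dataclass(frozen=True)
class WilliamsResult:
    t_stat: float
    df: int
    p: float


def pearson_with_p(x, y) -> CorrelationCell:
    """Pearson r with a two-sided p-value from the exact t transform.

    Pairs with a missing value in either series are dropped.  Fewer than
    three complete pairs is an error; zero variance in either series
    leaves r (and p) undefined, returned as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationCell(float("nan"), float("nan"), n)
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationCell(r, p, n)


def correlation_table(
    records: pd.DataFrame,
    index_columns: Sequence[str],
    indicator_columns: Sequence[str],
    aggregate: str | None = None,
    bh_fdr: bool = False,
) -> pd.DataFrame:
    """Long-format correlation grid between indicators and HRV indices.

    Rows flagged ``rejected`` (column ``quality_flag``, when present) are
    excluded; missing data are handled pairwise.  ``aggregate="stage_mean"``
    first averages each column over athletes within a day, mimicking a
    stage-level analysis.  ``bh_fdr=True`` adds Benjamini-Hochberg
    adjusted p-values (off by default; the primary grid is unadjusted).
    """
    for col in list(index_columns) + list(indicator_columns):
        if col not in records.columns:
            raise KeyError(f"unknown column {col!r}")
    df = records
    if "quality_flag" in df.columns:
        df = df[df["quality_flag"] != "rejected"]
    if aggregate == "stage_mean":
        df = df.groupby("day_index", as_index=False)[
            list(dict.fromkeys(list(index_columns) + list(indicator_columns)))
        ].mean()
    elif aggregate is not None:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    rows = []
    for indicator in indicator_columns:
        for index in index_columns:
            cell = pearson_with_p(df[indicator], df[index])
            rows.append(
                {
                    "indicator": indicator,
                    "index": index,
                    "r": cell.r,
                    "p": cell.p,
                    "n": cell.n,
                }
            )
    out = pd.DataFrame(rows)
    if bh_fdr:
        out["p_bh"] = bh_adjust(out["p"].to_numpy())
    return out


def wide_correlation_table(long_table: pd.DataFrame, value: str = "r") -> pd.DataFrame:
    """Pivot the long grid into the indicator-by-index layout."""
    return long_table.pivot(index="indicator", columns="index", values=value)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (helper, off by default)."""
    from statsmodels.stats.multitest import multipletests

    mask = ~np.isnan(pvalues)
    out = np.full(len(pvalues), np.nan)
    if mask.any():
        out[mask] = multipletests(pvalues[mask], method="fdr_bh")[1]
    return out


def williams_test(r12: float, r13: float, r23: float, n: int) -> WilliamsResult:
    """Williams/Steiger t2 test for two dependent correlations sharing
    variable 1 (is r12 different from r13, given r23?).

    Two-sided p from a t distribution with n-3 degrees of freedom.  A
    correlation triple whose 3x3 matrix is not positive (determinant
    <= 0) is rejected as inconsistent.
    """
    for name, r in (("r12", r12), ("r13", r13), ("r23", r23)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly inside (-1, 1), got {r}")
    if n < 4:
        raise ValueError("Williams' test needs n >= 4")
    det = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    if det <= 0:
        raise ValueError(
            "inconsistent correlation triple: determinant of the correlation "
            f"matrix is {det:.4g} <= 0"
        )
    rbar = 0.5 * (r12 + r13)
    denom = 2.0 * det * (n - 1) / (n - 3) + rbar**2 * (1.0 - r23) ** 3
    t = (r12 - r13) * np.sqrt((n - 1) * (1.0 + r23) / denom)
    df = n - 3
    p = float(2.0 * sps.t.sf(abs(t), df))
    return WilliamsResult(float(t), df, p)
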