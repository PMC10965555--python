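"""Cohort-level statistics: rank correlations of mechanical metrics with
dilatation, and per-group summaries.

Spearman's rank-order correlation uses mid-ranks for ties; its p-value comes
from the t approximation ``t = rs sqrt((n-2)/(1-rs^2))`` on n-2 degrees of
freedom, or from exhaustive permutation enumeration for small samples
(n <= 8). Correlation strength follows the convention mild |rs| <= 0.5,
moderate 0.5 < |rs| <= 0.75, strong |rs| > 0.75 (boundaries inclusive as
written). No multiple-testing correction is applied; correlations are
reported per metric.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "spearman",
    "correlation_strength",
    "group_summary",
    "anova_tukey",
    "UndefinedCorrelationError",
]

_EXACT_N_MAX = 8


class UndefinedCorrelationError(ValueError):
    """Correlation undefined for a constant input vector."""


@dataclass(frozen=True)
class CorrelationResult:
    rs: float
    p_value: float
    n: int
    strength: str  # none | mild | moderate | strong
    direction: str  # positive | negative
    method: str  # "t" or "exact"


def correlation_strength(rs: float) -> str:
    """Strength label: mild |rs|<=0.5, moderate 0.5<|rs|<=0.75, strong |rs|>0.75."""
    a = abs(rs)
    if a > 1:
        raise ValueError(f"|rs| must be <= 1, got {rs}")
    if a == 0:
        return "none"
    if a <= 0.5:
        return "mild"
    if a <= 0.75:
        return "moderate"
    return "strong"


def _rank_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of mid-ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def _exact_p(x: np.ndarray, y: np.ndarray, rs_obs: float) -> float:
    """Two-sided p from full enumeration of rank permutations of y."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    denom_x = math.sqrt(rx_c @ rx_c)
    n = len(ry)
    count = 0
    total = 0
    tol = 1e-12
    for perm in itertools.permutations(range(n)):
        ryp = ry[list(perm)]
        ry_c = ryp - ryp.mean()
        rs = rx_c @ ry_c / (denom_x * math.sqrt(ry_c @ ry_c))
        total += 1
        if abs(rs) >= abs(rs_obs) - tol:
            count += 1
    return count / total


def spearman(x, y, method: str = "auto") -> CorrelationResult:
    """Spearman rank-order correlation with mid-rank tie handling.

    method: "t" (t approximation), "exact" (full permutation enumeration,
    n <= 8 only), or "auto" (exact when n <= 8).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation undefined for constant input")
    rs = _rank_corr(x, y)
    if method == "auto":
        method = "exact" if n <= _EXACT_N_MAX else "t"
    if method == "exact":
        if n > _EXACT_N_MAX:
            raise ValueError(f"exact enumeration limited to n <= {_EXACT_N_MAX}")
        p = _exact_p(x, y, rs)
    elif method == "t":
        if abs(rs) >= 1.0:
            p = 0.0
        else:
            t = rs * math.sqrt((n - 2) / (1.0 - rs * rs))
            p = 2.0 * stats.t.sf(abs(t), n - 2)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(
        rs=rs,
        p_value=float(p),
        n=n,
        strength=correlation_strength(rs),
        direction="positive" if rs >= 0 else "negative",
        method=method,
    )


def group_summary(
    df: pd.DataFrame, group: str = "genotype", metrics: list[str] | None = None
) -> pd.DataFrame:
    """Per-group mean +/- SEM table for each metric column.

    SEM = SD/sqrt(n) with ddof=1; reported as NaN (missing) for singleton
    groups rather than zero.
    """
    if metrics is None:
        metrics = [
            c for c in df.columns if c != group and pd.api.types.is_numeric_dtype(df[c])
        ]
    out = []
    for g, sub in df.groupby(group, sort=True):
        row: dict = {group: g, "n": len(sub)}
        for m in metrics:
            vals = sub[m].dropna().to_numpy()
            row[f"{m}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{m}_sem"] = (
                vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) >= 2 else np.nan
            )
        out.append(row)
    return pd.DataFrame(out)


def anova_tukey(df: pd.DataFrame, metric: str, group: str = "genotype"):
    """Convenience wrapper: one-way ANOVA plus Tukey HSD across groups.

    Delegates to scipy; returned as (anova_p, tukey_result). Not part of the
    correlation surface.
    """
    groups = [sub[metric].dropna().to_numpy() for _, sub in df.groupby(group)]
    f = stats.f_oneway(*groups)
    tukey = stats.tukey_hsd(*groups)
    return float(f.pvalue), tukey


def correlation_table(
    metrics_df: pd.DataFrame,
    against: str = "normalized_diameter",
    metrics: list[str] | None = None,
    method: str = "t",
) -> pd.DataFrame:
    """Spearman correlation of each metric against a reference column.

    Produces one row per metric: metric, rs, p_value, strength, direction, n.
    Metadata note: p-values are reported per metric with no multiple-testing
    correction.
    """
    if metrics is None:
        metrics = [
            c
            for c in metrics_df.columns
            if c != against and pd.api.types.is_numeric_dtype(metrics_df[c])
        ]
    rows = []
    for m in metrics:
        sub = metrics_df[[m, against]].dropna()
        try:
            r = spearman(sub[m], sub[against], method=method)
        except (ValueError, UndefinedCorrelationError):
            continue
        rows.append(
            dict(
                metric=m,
                rs=r.rs,
                p_value=r.p_value,
                strength=r.strength,
                direction=r.direction,
                n=r.n,
            )
        )
    return pd.DataFrame(rows)
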