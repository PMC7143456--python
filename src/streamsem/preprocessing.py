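"""Data conditioning: descriptive statistics, normality screening, log transform.

The Kolmogorov-Smirnov statistic is computed exactly at the order statistics
(both one-sided gaps of the empirical CDF against the normal CDF). P-values
come from the asymptotic Kolmogorov distribution when the normal parameters
are hypothesized ("known"), or from the Lilliefors approximation when they
are estimated from the sample (the default, since population moments are
unknown in practice).

The log transform uses the natural log; the base only rescales covariances
and leaves correlations and standardized path coefficients unchanged.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "DescriptiveRow",
    "NormalityResult",
    "describe",
    "ks_normality",
    "log_transform",
    "standardize",
]


@dataclasses.dataclass(frozen=True)
class DescriptiveRow:
    variable: str
    min: float
    max: float
    mean: float
    sd: float
    n: int


@dataclasses.dataclass(frozen=True)
class NormalityResult:
    variable: str
    D: float
    p: float
    variant: str  # "known" | "estimated"


def describe(table: pd.DataFrame) -> list[DescriptiveRow]:
    """Per-column min/max/mean/sample-SD (n-1 denominator)."""
    if table.empty:
        raise ValueError("cannot describe an empty table")
    rows: list[DescriptiveRow] = []
    for col in table.columns:
        series = table[col]
        values = pd.to_numeric(series, errors="coerce")
        bad = series.index[values.isna() & series.notna()]
        if len(bad) or values.isna().any():
            loc = bad[0] if len(bad) else values.index[values.isna()][0]
            raise ValueError(f"non-numeric value in column {col!r} at row {loc!r}")
        x = values.to_numpy(dtype=float)
        n = len(x)
        sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
        rows.append(
            DescriptiveRow(
                variable=str(col),
                min=float(x.min()),
                max=float(x.max()),
                mean=float(x.mean()),
                sd=sd,
                n=n,
            )
        )
    return rows


def _ks_statistic(x: np.ndarray, mu: float, sigma: float) -> float:
    # exact sup over both one-sided ECDF gaps at the order statistics
    x = np.sort(x)
    n = len(x)
    cdf = stats.norm.cdf((x - mu) / sigma)
    i = np.arange(1, n + 1)
    d_plus = float(np.max(i / n - cdf))
    d_minus = float(np.max(cdf - (i - 1) / n))
    return max(d_plus, d_minus)


def ks_normality(
    values,
    variant: str = "estimated",
    *,
    mean: float = 0.0,
    sd: float = 1.0,
    variable: str = "",
) -> NormalityResult:
    """Kolmogorov-Smirnov test of normality.

    ``variant="known"`` tests against N(``mean``, ``sd``^2) with the
    asymptotic Kolmogorov p-value; ``variant="estimated"`` (Lilliefors)
    estimates both parameters from the sample and uses the Lilliefors
    p-value approximation (requires n >= 4 and non-zero variance).
    """
    x = np.asarray(values, dtype=float).ravel()
    if variant == "known":
        if len(x) < 1:
            raise ValueError("need at least one observation")
        if sd <= 0:
            raise ValueError("sd must be positive")
        D = _ks_statistic(x, mean, sd)
        p = float(stats.kstwobign.sf(math.sqrt(len(x)) * D))
    elif variant == "estimated":
        if len(x) < 4:
            raise ValueError("parameters-estimated variant requires n >= 4")
        s_hat = float(np.std(x, ddof=1))
        if s_hat == 0.0:
            raise ValueError("zero variance: normality test is undefined")
        D = _ks_statistic(x, float(np.mean(x)), s_hat)
        _, p = lilliefors(x, dist="norm", pvalmethod="table")
        p = float(p)
    else:
        raise ValueError("variant must be 'known' or 'estimated'")
    return NormalityResult(variable=variable, D=D, p=min(max(p, 0.0), 1.0), variant=variant)


def log_transform(values, offset_policy: str | float = "auto") -> np.ndarray:
    """Natural log with a zero-handling offset.

    With ``offset_policy="auto"`` the offset is 0 when every value is
    positive, otherwise half the smallest positive value. A float fixes the
    offset explicitly. Strictly monotone; errors if any shifted value is
    non-positive.
    """
    x = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if offset_policy == "auto":
        if np.all(x > 0):
            eps = 0.0
        else:
            positive = x[x > 0]
            if len(positive) == 0:
                raise ValueError("no positive values: log transform impossible")
            eps = float(positive.min()) / 2.0
    else:
        eps = float(offset_policy)
    shifted = x + eps
    if np.any(shifted <= 0):
        raise ValueError(f"values remain non-positive after offset {eps}")
    return np.log(shifted)


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score every column (sample SD, n-1 denominator)."""
    out = table.copy()
    for col in out.columns:
        x = out[col].to_numpy(dtype=float)
        sd = np.std(x, ddof=1)
        if sd == 0:
            raise ValueError(f"column {col!r} has zero variance")
        out[col] = (x - x.mean()) / sd
    return out
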