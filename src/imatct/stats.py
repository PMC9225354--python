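"""Statistical layer: Pearson correlation, simple linear regression,
pooled-variance two-sample t-test, normal-approximation sample size, and
correlation tables in the two-group observational-study style.

No multiple-testing correction is applied by default (star flags at the
0.05 and 0.01 two-tailed levels); a Benjamini-Hochberg option exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "TTestResult",
    "PowerSpec",
    "pearson",
    "linear_regression",
    "two_sample_t",
    "sample_size_normal",
    "correlation_table",
]


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p_two_tailed: float
    n: int


@dataclass
class TTestResult:
    t: float
    df: int
    p_two_tailed: float
    group_means: tuple[float, float]
    pooled_sd: float


@dataclass
class PowerSpec:
    """Inputs of a two-group sample-size calculation.

    ``delta`` is the smallest group difference to detect and ``sd`` the
    common standard deviation, in the same units; ``power`` = 1 - beta.
    """

    delta: float
    sd: float
    power: float = 0.80
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError("delta must be > 0")
        if not self.sd > 0:
            raise ValueError("sd must be > 0")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate input: zero variance")
    return x, y


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-tailed t-distribution p-value
    (t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom)."""
    x, y = _check_pair(x, y)
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r, r * r, float(res.pvalue), x.size)


def linear_regression(x, y) -> tuple[float, float, float]:
    """Ordinary least squares y = slope*x + intercept; returns
    (slope, intercept, R^2).  For simple regression R^2 equals the squared
    Pearson correlation."""
    x, y = _check_pair(x, y)
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue) ** 2


def two_sample_t(a, b) -> TTestResult:
    """Independent two-sample Student's t-test with pooled variance
    (not Welch), two-tailed."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / df
    return TTestResult(
        t=float(res.statistic),
        df=df,
        p_two_tailed=float(res.pvalue),
        group_means=(float(a.mean()), float(b.mean())),
        pooled_sd=math.sqrt(pooled_var),
    )


def sample_size_normal(spec: PowerSpec, exact: bool = False) -> int:
    """Per-group sample size for a two-sided two-sample comparison.

    Normal approximation (default):
        n = ceil( 2 * (z_{1-alpha/2} + z_{power})^2 * (sd/delta)^2 )

    With ``exact=True`` the noncentral-t power function is solved instead,
    which yields a (never smaller) sample size that accounts for the
    estimated variance.
    """
    z_a = sps.norm.ppf(1 - spec.alpha / 2)
    z_b = sps.norm.ppf(spec.power)
    n_norm = math.ceil(2 * (z_a + z_b) ** 2 * (spec.sd / spec.delta) ** 2)
    if not exact:
        return n_norm

    def power_at(n: int) -> float:
        df = 2 * n - 2
        nc = spec.delta / (spec.sd * math.sqrt(2.0 / n))
        tcrit = sps.t.ppf(1 - spec.alpha / 2, df)
        return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))

    n = max(n_norm, 2)
    while power_at(n) < spec.power:
        n += 1
    return n


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_table(metrics: pd.DataFrame, outcomes: pd.DataFrame,
                      pairs: list[tuple[str, str]],
                      key: str = "subject_id",
                      bh_correct: bool = False) -> pd.DataFrame:
    """One Pearson correlation per requested (metric, outcome) pair.

    The two tables are joined on ``key``; each row of the result carries the
    pair, r, the two-tailed p and a star flag (* p<0.05, ** p<0.01).  With
    ``bh_correct`` the p-values are Benjamini-Hochberg adjusted before
    flagging (off by default).
    """
    merged = metrics.merge(outcomes, on=key, how="inner", suffixes=("", "_out"))
    if merged.empty:
        raise ValueError("no shared subject keys between tables")
    rows = []
    for x_col, y_col in pairs:
        res = pearson(merged[x_col].to_numpy(), merged[y_col].to_numpy())
        rows.append({
            "x": x_col, "y": y_col, "n": res.n,
            "r": res.r, "r_squared": res.r_squared, "p": res.p_two_tailed,
        })
    table = pd.DataFrame(rows)
    p_for_flags = table["p"].to_numpy()
    if bh_correct:
        p_for_flags = sps.false_discovery_control(p_for_flags)
        table["p_adjusted"] = p_for_flags
    table["flag"] = [_stars(p) for p in p_for_flags]
    return table
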