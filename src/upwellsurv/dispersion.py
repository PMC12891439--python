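"""Variance-heterogeneity tests and low-pH seasonal summaries.

The contrast between a semi-permanent and a seasonal upwelling site is
primarily one of environmental *variability*, so homogeneity-of-variance
tests (Brown-Forsythe/Levene and Fligner-Killeen) are the relevant
inferential tools for the temperature and pH series, and the seasonal
distribution of corrosive low-pH days summarizes upwelling phenology.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceTestResult",
    "brown_forsythe",
    "fligner_killeen",
    "low_ph_season_summary",
    "AUSTRAL_SEASONS",
]


class VarianceTestResult(NamedTuple):
    statistic: float
    df: tuple
    pvalue: float


def _check_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for g in gs:
        if g.size < 2:
            raise ValueError("every group needs at least two values")
    return gs


def brown_forsythe(groups, center: str = "median") -> VarianceTestResult:
    """Levene-type test of variance homogeneity.

    The default is the Brown-Forsythe variant (one-way ANOVA on absolute
    deviations from group medians), the robust choice in modern software;
    ``center="mean"`` gives Levene's original mean-centered statistic.
    Returns (F, (k-1, N-k), p).
    """
    gs = _check_groups(groups)
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    stat, p = stats.levene(*gs, center=center)
    k = len(gs)
    N = sum(g.size for g in gs)
    return VarianceTestResult(float(stat), (k - 1, N - k), float(p))


def fligner_killeen(groups) -> VarianceTestResult:
    """Fligner-Killeen rank-based test of variance homogeneity.

    Pooled ranks of |x - group median| are mapped through the standard
    normal quantile function; the statistic is chi-squared with k-1 df.
    """
    gs = _check_groups(groups)
    stat, p = stats.fligner(*gs, center="median")
    return VarianceTestResult(float(stat), (len(gs) - 1,), float(p))


AUSTRAL_SEASONS = ("spring", "summer", "autumn", "winter")

_MONTH_SEASON = {
    9: "spring", 10: "spring", 11: "spring",
    12: "summer", 1: "summer", 2: "summer",
    3: "autumn", 4: "autumn", 5: "autumn",
    6: "winter", 7: "winter", 8: "winter",
}


def low_ph_season_summary(
    series: pd.DataFrame | pd.Series, threshold: float = 7.3
) -> pd.DataFrame:
    """Count days below a pH threshold by austral season.

    ``series`` is a DataFrame with columns ``date`` and ``ph`` (or a Series
    indexed by date).  Southern-hemisphere convention: spring Sep-Nov,
    summer Dec-Feb, autumn Mar-May, winter Jun-Aug.  Percentages are
    reported to one decimal.
    """
    if isinstance(series, pd.Series):
        dates = pd.DatetimeIndex(series.index)
        ph = series.to_numpy(dtype=float)
    else:
        if "date" not in series or "ph" not in series:
            raise ValueError("need 'date' and 'ph' columns")
        dates = pd.DatetimeIndex(pd.to_datetime(series["date"]))
        ph = series["ph"].to_numpy(dtype=float)
    if dates.isna().any():
        raise ValueError("undated values in series")
    low = ph < threshold
    months = dates.month.to_numpy()
    counts = {s: 0 for s in AUSTRAL_SEASONS}
    for m in months[low]:
        counts[_MONTH_SEASON[int(m)]] += 1
    total = int(low.sum())
    rows = [
        {
            "season": s,
            "n_days": counts[s],
            "percent": round(100.0 * counts[s] / total, 1) if total else 0.0,
        }
        for s in AUSTRAL_SEASONS
    ]
    out = pd.DataFrame(rows)
    out.attrs["total_low_ph_days"] = total
    out.attrs["threshold"] = threshold
    return out
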