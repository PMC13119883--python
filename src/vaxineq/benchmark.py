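"""Cross-country benchmarking: medians with confidence intervals.

Setting-level measure values are summarized as the sample median with a 95%
confidence interval, globally and by World Bank income group. The CI is the
distribution-free order-statistic interval: the tightest pair of order
statistics whose exact Binomial(n, 1/2) coverage reaches the nominal level.
This makes no distributional assumption and is conservative by construction.
A seeded bootstrap percentile interval is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BenchmarkSummary",
    "median_with_ci",
    "median_with_bootstrap_ci",
    "benchmark",
    "subgroup_range",
    "national_percentile_table",
]

#: when several dimensions yield a recomputed national average for the same
#: survey, take the first available in this order (quintile shares are exact
#: by construction, so the wealth breakdown is the most reliable)
_NATIONAL_DIMENSION_PRIORITY = ("wealth", "residence", "sex", "education", "age")


@dataclass(frozen=True)
class BenchmarkSummary:
    grouping: str  # "global" or "income_group"
    group_value: str
    indicator_id: str
    dimension_id: str
    measure_or_subgroup: str
    n_settings: int
    median: float
    ci_low: float
    ci_high: float
    min: float
    max: float
    note: str = ""


def median_with_ci(
    values: Sequence[float], level: float = 0.95
) -> tuple[float, float, float, str]:
    """Sample median with a distribution-free order-statistic CI.

    Among all pairs of order statistics x_(l) <= x_(u), the interval
    [x_(l), x_(u)] covers the population median with probability
    P(l <= B <= u - 1) for B ~ Binomial(n, 1/2); the tightest pair (smallest
    u - l, most symmetric on ties) whose coverage reaches ``level`` is
    returned. For n < 6 no pair reaches 95%, so the full range is returned
    with a low-coverage note. Returns (median, ci_low, ci_high, note).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("median_with_ci: empty input")
    if not np.all(np.isfinite(x)):
        raise ValueError("median_with_ci: non-finite values")
    med = float(np.median(x))
    if n < 6:
        return med, float(x[0]), float(x[-1]), "low coverage: n < 6, CI is (min, max)"
    ranks = _ci_ranks(n, level)
    if ranks is None:
        return med, float(x[0]), float(x[-1]), "low coverage: CI is (min, max)"
    lo, hi = ranks
    return med, float(x[lo - 1]), float(x[hi - 1]), ""


@lru_cache(maxsize=None)
def _ci_ranks(n: int, level: float) -> Optional[tuple[int, int]]:
    """Tightest 1-based order-statistic rank pair covering the median."""
    cdf = stats.binom.cdf(np.arange(-1, n + 1), n, 0.5)  # cdf[k+1] = P(B <= k)
    best: Optional[tuple[int, int, int, int]] = None
    for lo in range(1, n + 1):
        for hi in range(lo + 1, n + 1):
            cover = cdf[hi] - cdf[lo]  # P(lo <= B <= hi-1), B = #obs below median
            if cover >= level:
                width = hi - lo
                asym = abs((lo - 1) - (n - hi))
                key = (width, asym, lo, hi)
                if best is None or key < best:
                    best = key
                break  # wider hi only less tight for this lo
    if best is None:
        return None
    return best[2], best[3]


def median_with_bootstrap_ci(
    values: Sequence[float],
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float, str]:
    """Percentile bootstrap CI for the median (comparison alternative)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("median_with_bootstrap_ci: empty input")
    rng = np.random.default_rng(seed)
    meds = np.median(rng.choice(x, size=(n_boot, x.size), replace=True), axis=1)
    alpha = 1.0 - level
    lo, hi = np.quantile(meds, [alpha / 2, 1 - alpha / 2])
    return float(np.median(x)), float(lo), float(hi), f"bootstrap ({n_boot} resamples)"


def benchmark(
    results: pd.DataFrame,
    value_col: str = "value",
    level: float = 0.95,
) -> pd.DataFrame:
    """Summarize setting-level values globally and by income group.

    ``results`` needs columns setting_id, income_group, indicator_id,
    dimension_id, measure and ``value_col``; one row per setting per
    (indicator, dimension, measure). Settings without an income group are
    skipped from the income-group rows (counted in ``n_skipped`` of the
    global row) but enter the global summary.
    """
    df = results.dropna(subset=[value_col])
    rows = []
    group_cols = ["indicator_id", "dimension_id", "measure"]

    def summarize(sub: pd.DataFrame, grouping: str, group_value: str, n_skipped: int):
        vals = sub[value_col].to_numpy()
        med, lo, hi, note = median_with_ci(vals, level)
        key = sub.iloc[0]
        rows.append(
            {
                "grouping": grouping,
                "group_value": group_value,
                "indicator_id": key["indicator_id"],
                "dimension_id": key["dimension_id"],
                "measure": key["measure"],
                "n_settings": sub["setting_id"].nunique(),
                "n_skipped": n_skipped,
                "median": med,
                "ci_low": lo,
                "ci_high": hi,
                "min": float(vals.min()),
                "max": float(vals.max()),
                "note": note,
            }
        )

    for _, sub in df.groupby(group_cols, sort=True):
        no_group = sub["income_group"].isin(["", None]) | sub["income_group"].isna()
        summarize(sub, "global", "all", int(sub[no_group]["setting_id"].nunique()))
        for group_value, gsub in sub[~no_group].groupby("income_group", sort=True):
            summarize(gsub, "income_group", str(group_value), 0)
    return pd.DataFrame(
        rows,
        columns=[
            "grouping", "group_value", "indicator_id", "dimension_id", "measure",
            "n_settings", "n_skipped", "median", "ci_low", "ci_high", "min", "max",
            "note",
        ],
    )


def national_percentile_table(
    cells: Sequence, era: tuple[int, int] = (2014, 2023)
) -> pd.DataFrame:
    """Cross-country percentiles of national averages, one row per indicator.

    Takes each setting's latest survey in ``era``, its national average from
    the highest-priority available dimension breakdown, and reports n, min,
    25th percentile, median, 75th percentile and max across settings.
    """
    rows = []
    per_setting: dict[tuple[str, str], tuple] = {}
    prio = {d: i for i, d in enumerate(_NATIONAL_DIMENSION_PRIORITY)}
    for cell in cells:
        if not era[0] <= cell.year <= era[1]:
            continue
        key = (cell.setting_id, cell.indicator_id)
        rank = (-cell.year, prio.get(cell.dimension_id, len(prio)))
        if key not in per_setting or rank < per_setting[key][0]:
            per_setting[key] = (rank, cell.with_national_average().national_average)
    values: dict[str, list[float]] = {}
    for (_, indicator), (_, natavg) in per_setting.items():
        values.setdefault(indicator, []).append(natavg)
    for indicator in sorted(values):
        v = np.asarray(values[indicator])
        q25, q75 = np.quantile(v, [0.25, 0.75])
        rows.append(
            {
                "indicator_id": indicator,
                "n_settings": v.size,
                "min": float(v.min()),
                "p25": float(q25),
                "median": float(np.median(v)),
                "p75": float(q75),
                "max": float(v.max()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["indicator_id", "n_settings", "min", "p25", "median", "p75", "max"],
    )


def subgroup_range(cells: Sequence, level: float = 0.95) -> pd.DataFrame:
    """Per-subgroup distribution of estimates across settings.

    For one indicator-dimension's complete cells, returns per subgroup the
    median, min, max and interquartile range across settings (the quantities
    shown in dot-and-range panels). Quartiles use linear interpolation of
    order statistics.
    """
    rows = []
    by_subgroup: dict[str, list[float]] = {}
    order: list[str] = []
    for cell in cells:
        for rec in cell.records:
            if rec.subgroup_id not in by_subgroup:
                by_subgroup[rec.subgroup_id] = []
                order.append(rec.subgroup_id)
            by_subgroup[rec.subgroup_id].append(rec.estimate)
    for subgroup in order:
        vals = np.asarray(by_subgroup[subgroup], dtype=float)
        q1, q3 = np.quantile(vals, [0.25, 0.75])  # linear interpolation
        rows.append(
            {
                "subgroup_id": subgroup,
                "n_settings": vals.size,
                "median": float(np.median(vals)),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "q1": float(q1),
                "q3": float(q3),
                "iqr": float(q3 - q1),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["subgroup_id", "n_settings", "median", "min", "max", "q1", "q3", "iqr"],
    )
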