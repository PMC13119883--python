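"""Change in inequality over a decade from paired surveys.

The latest survey in the recent era (2014-2023 by default) anchors each
setting; among older-era surveys (2004-2013) the one closest to 10 years
before the anchor is paired with it, subject to a 5-15 year window. Because
indicator availability differs between surveys, pairing is done per
(setting, indicator), so two different older surveys may serve different
indicators of one setting.

Changes are normalized to a per-decade scale:
``(value_t1 - value_t0) / intervening_years * 10``, applied identically to
difference, ratio, SII and RII (ratio-scale measures are differenced on
their own scale, not log-transformed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "DEFAULT_ERA_0",
    "DEFAULT_ERA_1",
    "SurveyPair",
    "TrendResult",
    "pair_surveys",
    "change_per_decade",
    "trend_frame",
    "trend_cell_gate",
]

DEFAULT_ERA_0 = (2004, 2013)
DEFAULT_ERA_1 = (2014, 2023)
MIN_GAP = 5
MAX_GAP = 15


@dataclass(frozen=True)
class SurveyPair:
    setting_id: str
    indicator_id: str
    year_t0: int
    year_t1: int

    @property
    def intervening_years(self) -> int:
        return self.year_t1 - self.year_t0


@dataclass(frozen=True)
class TrendResult:
    measure: str
    value_t0: float
    value_t1: float
    intervening_years: int

    @property
    def change_per_decade(self) -> float:
        return (self.value_t1 - self.value_t0) / self.intervening_years * 10.0


def pair_surveys(
    available: Mapping[tuple[str, str], Sequence[int]],
    era_0: tuple[int, int] = DEFAULT_ERA_0,
    era_1: tuple[int, int] = DEFAULT_ERA_1,
    min_gap: int = MIN_GAP,
    max_gap: int = MAX_GAP,
) -> tuple[list[SurveyPair], list[tuple[str, str, str]]]:
    """Pair each (setting, indicator)'s anchor survey with an older one.

    ``available`` maps (setting_id, indicator_id) to the survey years with
    data for that indicator. The anchor is the latest year in the recent era;
    the chosen partner minimizes |anchor - 10 - year| among older-era years
    within the [min_gap, max_gap] window. Equidistant candidates resolve to
    the earlier year (the longer window gives a more stable annualized
    change). Unpairable combinations are returned in a log with a reason.
    """
    pairs: list[SurveyPair] = []
    unpaired: list[tuple[str, str, str]] = []
    for (setting, indicator), years in sorted(available.items()):
        t1_candidates = [y for y in years if era_1[0] <= y <= era_1[1]]
        if not t1_candidates:
            unpaired.append((setting, indicator, "no recent-era survey"))
            continue
        t1 = max(t1_candidates)
        t0_candidates = [
            y
            for y in years
            if era_0[0] <= y <= era_0[1] and min_gap <= t1 - y <= max_gap
        ]
        if not t0_candidates:
            unpaired.append((setting, indicator, "no eligible older-era survey"))
            continue
        target = t1 - 10
        t0 = min(t0_candidates, key=lambda y: (abs(y - target), y))
        pairs.append(SurveyPair(setting, indicator, t0, t1))
    return pairs, unpaired


def change_per_decade(
    value_t0: float, value_t1: float, intervening_years: int, measure: str = ""
) -> TrendResult:
    """Per-decade change: (t1 - t0) / intervening years x 10.

    ``intervening_years`` must lie in the pairing window [5, 15].
    """
    if not MIN_GAP <= intervening_years <= MAX_GAP:
        raise ValueError(
            f"intervening_years {intervening_years} outside [{MIN_GAP}, {MAX_GAP}]"
        )
    return TrendResult(measure, value_t0, value_t1, intervening_years)


def trend_frame(
    measures: pd.DataFrame,
    pairs: Iterable[SurveyPair],
) -> pd.DataFrame:
    """Per-decade change for every paired measure value.

    ``measures`` is a :func:`vaxineq.measures.measures_frame` table holding
    both survey years. Rows where either endpoint is inapplicable are
    dropped. Columns: setting_id, indicator_id, dimension_id, income_group,
    measure, year_t0, year_t1, value_t0, value_t1, change_per_decade.
    """
    applicable = measures[measures["applicable"]]
    indexed = applicable.set_index(
        ["setting_id", "indicator_id", "year", "dimension_id", "measure"]
    )["value"].sort_index()
    income = (
        measures.drop_duplicates("setting_id")
        .set_index("setting_id")["income_group"]
        .to_dict()
    )
    rows = []
    for pair in pairs:
        try:
            t0_block = indexed.loc[pair.setting_id, pair.indicator_id, pair.year_t0]
            t1_block = indexed.loc[pair.setting_id, pair.indicator_id, pair.year_t1]
        except KeyError:
            continue
        joined = pd.concat(
            [t0_block.rename("value_t0"), t1_block.rename("value_t1")],
            axis=1,
            join="inner",
        ).dropna()
        for (dimension, measure), row in joined.iterrows():
            res = change_per_decade(
                row["value_t0"], row["value_t1"], pair.intervening_years, measure
            )
            rows.append(
                {
                    "setting_id": pair.setting_id,
                    "indicator_id": pair.indicator_id,
                    "dimension_id": dimension,
                    "income_group": income.get(pair.setting_id, ""),
                    "measure": measure,
                    "year_t0": pair.year_t0,
                    "year_t1": pair.year_t1,
                    "value_t0": res.value_t0,
                    "value_t1": res.value_t1,
                    "change_per_decade": res.change_per_decade,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "setting_id", "indicator_id", "dimension_id", "income_group", "measure",
            "year_t0", "year_t1", "value_t0", "value_t1", "change_per_decade",
        ],
    )


def trend_cell_gate(
    trends: pd.DataFrame, min_settings: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop indicator-dimension trend cells observed in too few settings.

    Reproduces the exclusion of sparsely observed indicators (fewer than 5
    settings with an earlier time point, as happens for rotavirus) from the
    change-over-time analysis. Returns (retained, exclusion log); the log has
    one row per dropped (indicator, dimension) with its setting count.
    """
    if min_settings < 1:
        raise ValueError("min_settings must be >= 1")
    counts = (
        trends.groupby(["indicator_id", "dimension_id"])["setting_id"]
        .nunique()
        .rename("n_settings")
        .reset_index()
    )
    bad = counts[counts["n_settings"] < min_settings]
    bad_keys = set(zip(bad["indicator_id"], bad["dimension_id"]))
    mask = [
        (i, d) not in bad_keys
        for i, d in zip(trends["indicator_id"], trends["dimension_id"])
    ]
    return trends[mask].reset_index(drop=True), bad.reset_index(drop=True)
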