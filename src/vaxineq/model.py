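"""Data model for disaggregated inequality data.

The unit of input is a *disaggregated record*: one subgroup estimate of one
immunization indicator, in one setting (country, area or territory) and survey
year, along one dimension of inequality (e.g. wealth quintile 3 of household
economic status). Estimates are percentages of children aged ~12-23 months;
population shares are the subgroup's share of that reference population.

Indicators carry a *polarity*: coverage indicators are favourable (higher is
better), non-receipt indicators are adverse (lower is better). Polarity flips
the direction of the pairwise measures (difference, ratio) and the
interpretation of PAR.

Dimensions carry an ordering from most-disadvantaged to most-advantaged, the
pair of subgroups used for pairwise comparisons, and a flag for the child-sex
convention (male minus female by convention, without an advantage claim).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

__all__ = [
    "IncomeGroup",
    "SurveySource",
    "Polarity",
    "DisaggregatedRecord",
    "IndicatorMeta",
    "DimensionMeta",
    "AnalysisCell",
    "INDICATORS",
    "DIMENSIONS",
    "COVERAGE_INDICATORS",
    "NONRECEIPT_INDICATORS",
]


class IncomeGroup(str, enum.Enum):
    """World Bank income groups in study scope (high income is out of scope)."""

    LOW = "low"
    LOWER_MIDDLE = "lower_middle"
    UPPER_MIDDLE = "upper_middle"


class SurveySource(str, enum.Enum):
    DHS = "DHS"
    MICS = "MICS"
    RHS = "RHS"
    NSS = "NSS"


class Polarity(str, enum.Enum):
    FAVOURABLE = "favourable"  # coverage: higher is better
    ADVERSE = "adverse"  # non-receipt: lower is better


@dataclass(frozen=True)
class DisaggregatedRecord:
    """One subgroup estimate.

    ``estimate`` is a percentage in [0, 100]; ``population_share`` the
    subgroup's share of the reference population in [0, 1].
    """

    setting_id: str
    setting_name: str
    income_group: Optional[IncomeGroup]
    survey_source: SurveySource
    year: int
    indicator_id: str
    dimension_id: str
    subgroup_id: str
    estimate: float
    population_share: float
    standard_error: Optional[float] = None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if not 0.0 <= self.estimate <= 100.0:
            problems.append(f"estimate {self.estimate!r} outside [0, 100]")
        if not 0.0 <= self.population_share <= 1.0:
            problems.append(
                f"population_share {self.population_share!r} outside [0, 1]"
            )
        if self.standard_error is not None and self.standard_error < 0:
            problems.append(f"standard_error {self.standard_error!r} negative")
        return problems


@dataclass(frozen=True)
class IndicatorMeta:
    indicator_id: str
    label: str
    polarity: Polarity
    age_window: str = "12-23 months"

    @property
    def favourable(self) -> bool:
        return self.polarity is Polarity.FAVOURABLE


@dataclass(frozen=True)
class DimensionMeta:
    """A dimension of inequality.

    ``subgroups`` are ordered most-disadvantaged first, most-advantaged last.
    For child sex no advantage is asserted; ``sex_convention`` marks that the
    pairwise comparison is male minus female by convention.
    """

    dimension_id: str
    label: str
    ordered: bool
    subgroups: tuple[str, ...]
    sex_convention: bool = False

    def __post_init__(self) -> None:
        if len(self.subgroups) < 2:
            raise ValueError(f"dimension {self.dimension_id}: needs >=2 subgroups")

    @property
    def disadvantaged_subgroup(self) -> str:
        return self.subgroups[0]

    @property
    def advantaged_subgroup(self) -> str:
        return self.subgroups[-1]


@dataclass(frozen=True)
class AnalysisCell:
    """All subgroup records for one (setting, year, indicator, dimension).

    A cell is only constructed when every subgroup of the dimension is present
    exactly once (the completeness rule). ``national_average`` is the supplied
    setting average when available, else the population-share-weighted mean of
    the subgroup estimates.
    """

    setting_id: str
    year: int
    indicator_id: str
    dimension_id: str
    records: tuple[DisaggregatedRecord, ...]
    national_average: Optional[float] = None
    income_group: Optional[IncomeGroup] = None

    def estimate_of(self, subgroup_id: str) -> float:
        for r in self.records:
            if r.subgroup_id == subgroup_id:
                return r.estimate
        raise KeyError(subgroup_id)

    def share_of(self, subgroup_id: str) -> float:
        for r in self.records:
            if r.subgroup_id == subgroup_id:
                return r.population_share
        raise KeyError(subgroup_id)

    def weighted_average(self) -> float:
        """Population-share-weighted mean of the subgroup estimates."""
        total = sum(r.population_share for r in self.records)
        return sum(r.estimate * r.population_share for r in self.records) / total

    def with_national_average(self) -> "AnalysisCell":
        if self.national_average is not None:
            return self
        return replace(self, national_average=self.weighted_average())


def _ind(indicator_id: str, label: str, polarity: Polarity) -> IndicatorMeta:
    return IndicatorMeta(indicator_id=indicator_id, label=label, polarity=polarity)


#: The nine built-in indicators. Seven coverage indicators (favourable) and two
#: non-receipt indicators (adverse).
INDICATORS: dict[str, IndicatorMeta] = {
    m.indicator_id: m
    for m in [
        _ind("bcg", "BCG (1 dose)", Polarity.FAVOURABLE),
        _ind("dtp3", "DTP3 (3 doses)", Polarity.FAVOURABLE),
        _ind("measles", "Measles (1 dose)", Polarity.FAVOURABLE),
        _ind("polio3", "Polio (3 doses)", Polarity.FAVOURABLE),
        _ind("full", "Full immunization (BCG, DTP3, measles, polio)", Polarity.FAVOURABLE),
        _ind("hib3", "Hib3 (3 doses)", Polarity.FAVOURABLE),
        _ind("rotavirus", "Rotavirus (last dose)", Polarity.FAVOURABLE),
        _ind("zero_dose_dtp", "Zero-dose (no DTP)", Polarity.ADVERSE),
        _ind("no_bcg_dtp_measles_polio", "Non-receipt of BCG, DTP, measles and polio", Polarity.ADVERSE),
    ]
}

COVERAGE_INDICATORS = tuple(
    k for k, m in INDICATORS.items() if m.polarity is Polarity.FAVOURABLE
)
NONRECEIPT_INDICATORS = tuple(
    k for k, m in INDICATORS.items() if m.polarity is Polarity.ADVERSE
)

#: The five built-in dimensions of inequality, subgroups ordered
#: most-disadvantaged -> most-advantaged.
DIMENSIONS: dict[str, DimensionMeta] = {
    d.dimension_id: d
    for d in [
        DimensionMeta(
            "sex", "Child sex", ordered=False,
            subgroups=("female", "male"), sex_convention=True,
        ),
        DimensionMeta(
            "age", "Mother's age", ordered=True,
            subgroups=("15-19", "20-49"),
        ),
        DimensionMeta(
            "education", "Mother's education", ordered=True,
            subgroups=("none", "primary", "secondary+"),
        ),
        DimensionMeta(
            "wealth", "Household economic status", ordered=True,
            subgroups=("q1", "q2", "q3", "q4", "q5"),
        ),
        DimensionMeta(
            "residence", "Place of residence", ordered=True,
            subgroups=("rural", "urban"),
        ),
    ]
}
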