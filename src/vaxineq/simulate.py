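"""Synthetic multi-country disaggregated immunization panels.

The generator emulates the structure of survey-based disaggregated coverage
data: up to ~92 low- and middle-income settings, nine indicators (seven
coverage, two non-receipt), five dimensions of inequality, and two survey
eras roughly a decade apart. Every setting receives

* a national true value per indicator: the indicator baseline, shifted by
  income group and a setting-level random effect;
* linear subgroup gradients along each ordered dimension (the configured
  most-vs-least-advantaged gap), with low-income settings receiving a larger
  multiplier so economic-related inequality is largest there;
* non-receipt indicators coupled to their coverage counterpart (zero-dose to
  DTP3; non-receipt of the four basic vaccines to full immunization), so
  settings with lower coverage have more unvaccinated children by
  construction, with reversed and rescaled gradients;
* an era-0 survey 5-15 years before the era-1 survey, with configured
  per-decade trends in the national value and in the gradients.

Estimates are sampled as binomial proportions with a configurable denominator
(``sample_size=None`` gives the noise-free limit); true subgroup
probabilities are clamped to [0.5, 99.5] percent before sampling. The same
seed always yields bit-identical output. :func:`truth_table` returns the
noise-free summary-measure values implied by the constructed probabilities —
the oracle for parameter-recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import measures
from .model import (
    DIMENSIONS,
    INDICATORS,
    AnalysisCell,
    DisaggregatedRecord,
    IncomeGroup,
    SurveySource,
)

__all__ = ["ScenarioConfig", "generate", "truth_table"]

#: true subgroup probabilities are clamped here (percent) before sampling
TRUTH_CLAMP = (0.5, 99.5)

#: adverse indicator -> the coverage indicator it is coupled to
ADVERSE_COUNTERPART = {"zero_dose_dtp": "dtp3", "no_bcg_dtp_measles_polio": "full"}

_DEFAULT_BASELINE = {
    # cross-country median levels typical of recent household surveys
    "bcg": 94.7,
    "dtp3": 81.9,
    "measles": 78.9,
    "polio3": 76.0,
    "full": 63.2,
    "hib3": 81.3,
    "rotavirus": 80.5,
    "zero_dose_dtp": 7.0,
    "no_bcg_dtp_measles_polio": 3.7,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic panel.

    Gradients are most-advantaged minus most-disadvantaged gaps in percentage
    points on coverage indicators, as of the recent era; non-receipt
    indicators get the same gradients reversed and scaled by
    ``adverse_gradient_scale``. Trends are per-decade changes from the older
    to the recent era.
    """

    n_settings: Mapping[str, int] = field(
        default_factory=lambda: {"low": 20, "lower_middle": 40, "upper_middle": 32}
    )
    indicators: tuple[str, ...] = tuple(INDICATORS)
    baseline: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_BASELINE))
    education_gradient: float = 12.0  # pp, most vs least educated
    wealth_gradient: float = 12.0  # pp, richest vs poorest quintile
    residence_gap: float = 2.0  # pp, urban vs rural
    sex_gap: float = 0.0  # pp, male vs female
    age_gap: float = 4.4  # pp, mothers 20-49 vs 15-19
    adverse_gradient_scale: float = 0.6  # non-receipt gaps are smaller in pp terms
    low_income_gradient_multiplier: float = 1.5
    income_shift: Mapping[str, float] = field(
        default_factory=lambda: {"low": -12.0, "lower_middle": 0.0, "upper_middle": 6.0}
    )
    setting_sd: float = 10.0  # sd of the setting-level random effect, pp
    adverse_coupling: float = 0.5  # pp of non-receipt per pp of counterpart coverage
    era_trend: float = 5.0  # pp change per decade in national coverage
    inequality_trend: float = -2.0  # pp change per decade in gradients
    sample_size: Optional[int] = 500  # binomial denominator; None = noise-free
    overdispersion: float = 1.0  # variance inflation (effective n divisor)
    missingness: float = 0.05  # P(a subgroup estimate is absent)
    rotavirus_era0_inclusion: float = 0.04  # P(era-0 survey covers rotavirus)
    era_0: tuple[int, int] = (2004, 2013)
    era_1: tuple[int, int] = (2014, 2023)
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.n_settings.values()):
            raise ValueError("n_settings must be non-negative")
        unknown = [i for i in self.indicators if i not in INDICATORS]
        if unknown:
            raise ValueError(f"unknown indicator(s) {unknown}")
        for name in ("missingness", "rotavirus_era0_inclusion"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sample_size is not None and self.sample_size < 1:
            raise ValueError("sample_size must be >= 1 or None")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1")
        if self.setting_sd < 0:
            raise ValueError("setting_sd must be >= 0")
        missing_base = [i for i in self.indicators if i not in self.baseline]
        if missing_base:
            raise ValueError(f"baseline missing for {missing_base}")


_DIM_GRADIENT_FIELD = {
    "education": "education_gradient",
    "wealth": "wealth_gradient",
    "residence": "residence_gap",
    "age": "age_gap",
    "sex": "sex_gap",
}


def _setting_frame(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-setting structural draws: income group, years, shares, effects."""
    rows = []
    idx = 0
    for group, n in config.n_settings.items():
        for _ in range(n):
            idx += 1
            y1 = int(rng.integers(config.era_1[0], config.era_1[1] + 1))
            lo_gap = max(5, y1 - config.era_0[1])
            hi_gap = min(15, y1 - config.era_0[0])
            gap = int(rng.integers(lo_gap, hi_gap + 1))
            rural = rng.uniform(0.4, 0.8)
            young = rng.uniform(0.05, 0.2)
            female = rng.uniform(0.47, 0.51)
            edu = rng.dirichlet(np.array([0.25, 0.35, 0.40]) * 30.0)
            rows.append(
                {
                    "setting_id": f"S{idx:03d}",
                    "setting_name": f"Setting {idx:03d}",
                    "income_group": group,
                    "year_t1": y1,
                    "year_t0": y1 - gap,
                    "gap": gap,
                    "source_t0": rng.choice(["DHS", "MICS"]),
                    "source_t1": rng.choice(["DHS", "MICS"]),
                    # one draw per setting: the older survey either covered
                    # the late-schedule vaccine or it did not
                    "rotavirus_era0": bool(
                        rng.uniform() < config.rotavirus_era0_inclusion
                    ),
                    "shares_wealth": tuple([0.2] * 5),
                    "shares_education": tuple(edu),
                    "shares_residence": (rural, 1.0 - rural),
                    "shares_age": (young, 1.0 - young),
                    "shares_sex": (female, 1.0 - female),
                }
            )
    df = pd.DataFrame(rows)
    coverage = [i for i in config.indicators if i not in ADVERSE_COUNTERPART]
    for ind in coverage:
        df[f"effect_{ind}"] = rng.normal(0.0, config.setting_sd, size=len(df))
    return df


def _national_truth(
    config: ScenarioConfig, setting: pd.Series, indicator: str, era: int
) -> float:
    """True national level (percent) for one setting, indicator and era."""
    decades = 0.0 if era == 1 else -setting["gap"] / 10.0
    if indicator in ADVERSE_COUNTERPART:
        counterpart = ADVERSE_COUNTERPART[indicator]
        cov = _national_truth(config, setting, counterpart, era)
        value = config.baseline[indicator] + config.adverse_coupling * (
            config.baseline[counterpart] - cov
        )
    else:
        value = (
            config.baseline[indicator]
            + config.income_shift[setting["income_group"]]
            + setting[f"effect_{indicator}"]
            + config.era_trend * decades
        )
    return float(np.clip(value, *TRUTH_CLAMP))


def _gradient(
    config: ScenarioConfig, setting: pd.Series, indicator: str, dimension: str, era: int
) -> float:
    """Signed true advantaged-minus-disadvantaged gap in percentage points."""
    g = getattr(config, _DIM_GRADIENT_FIELD[dimension])
    if setting["income_group"] == "low":
        g *= config.low_income_gradient_multiplier
    if era == 0:
        g -= config.inequality_trend * setting["gap"] / 10.0
    if indicator in ADVERSE_COUNTERPART:
        g *= -config.adverse_gradient_scale
    return g


def _subgroup_truth(
    national: float, gradient: float, n_subgroups: int
) -> np.ndarray:
    """Linear-in-order true subgroup percentages, clamped to the truth range."""
    if n_subgroups == 1:
        offsets = np.array([0.0])
    else:
        offsets = np.linspace(-0.5, 0.5, n_subgroups)
    return np.clip(national + gradient * offsets, *TRUTH_CLAMP)


def _iter_true_cells(config: ScenarioConfig, settings: pd.DataFrame):
    """Yield (setting row, era, year, source, indicator, dimension, shares, probs)."""
    for _, s in settings.iterrows():
        for era, year, source in (
            (0, s["year_t0"], s["source_t0"]),
            (1, s["year_t1"], s["source_t1"]),
        ):
            for indicator in config.indicators:
                for dim_id, dim in DIMENSIONS.items():
                    shares = np.asarray(s[f"shares_{dim_id}"], dtype=float)
                    national = _national_truth(config, s, indicator, era)
                    grad = _gradient(config, s, indicator, dim_id, era)
                    probs = _subgroup_truth(national, grad, len(dim.subgroups))
                    yield s, era, int(year), source, indicator, dim, shares, probs


def generate(config: ScenarioConfig) -> list[DisaggregatedRecord]:
    """Generate a two-era disaggregated panel under ``config``.

    Identical configs (including seed) yield bit-identical record lists.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    child_struct, child_noise = ss.spawn(2)
    rng_struct = np.random.default_rng(child_struct)
    rng_noise = np.random.default_rng(child_noise)
    settings = _setting_frame(config, rng_struct)

    records: list[DisaggregatedRecord] = []
    for s, era, year, source, indicator, dim, shares, probs in _iter_true_cells(
        config, settings
    ):
        if indicator == "rotavirus" and era == 0 and not s["rotavirus_era0"]:
            continue
        for j, subgroup in enumerate(dim.subgroups):
            missing = rng_noise.uniform() < config.missingness
            p = probs[j] / 100.0
            if config.sample_size is None:
                estimate = float(probs[j])
                se = None
            else:
                n_eff = max(1, int(round(config.sample_size / config.overdispersion)))
                k = rng_noise.binomial(n_eff, p)
                estimate = 100.0 * k / n_eff
                phat = k / n_eff
                se = 100.0 * float(np.sqrt(max(phat * (1 - phat), 1e-8) / n_eff))
            if missing:
                continue  # drawn before the skip so the rng stream is stable
            records.append(
                DisaggregatedRecord(
                    setting_id=s["setting_id"],
                    setting_name=s["setting_name"],
                    income_group=IncomeGroup(s["income_group"]),
                    survey_source=SurveySource(source),
                    year=year,
                    indicator_id=indicator,
                    dimension_id=dim.dimension_id,
                    subgroup_id=subgroup,
                    estimate=estimate,
                    population_share=float(shares[j]),
                    standard_error=se,
                )
            )
    return records


def truth_table(
    config: ScenarioConfig, links: Sequence[str] = ("linear", "logit")
) -> pd.DataFrame:
    """Noise-free summary-measure values implied by the construction.

    One row per (setting, era, indicator, dimension) with the true national
    average, difference, ratio, SII and RII under the requested links, and
    (for the education dimension) PAR. Shares and setting effects come from
    the same seeded draws as :func:`generate`, so the table is the exact
    sampling-free oracle for the corresponding panel.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    child_struct, _ = ss.spawn(2)
    rng_struct = np.random.default_rng(child_struct)
    settings = _setting_frame(config, rng_struct)

    rows = []
    for s, era, year, source, indicator, dim, shares, probs in _iter_true_cells(
        config, settings
    ):
        recs = tuple(
            DisaggregatedRecord(
                setting_id=s["setting_id"],
                setting_name=s["setting_name"],
                income_group=IncomeGroup(s["income_group"]),
                survey_source=SurveySource(source),
                year=year,
                indicator_id=indicator,
                dimension_id=dim.dimension_id,
                subgroup_id=subgroup,
                estimate=float(probs[j]),
                population_share=float(shares[j]),
            )
            for j, subgroup in enumerate(dim.subgroups)
        )
        cell = AnalysisCell(
            setting_id=s["setting_id"],
            year=year,
            indicator_id=indicator,
            dimension_id=dim.dimension_id,
            records=recs,
            income_group=IncomeGroup(s["income_group"]),
        ).with_national_average()
        meta = INDICATORS[indicator]
        row = {
            "setting_id": s["setting_id"],
            "income_group": s["income_group"],
            "era": era,
            "year": year,
            "indicator_id": indicator,
            "dimension_id": dim.dimension_id,
            "national_average": cell.national_average,
            "difference": measures.difference(cell, meta, dim).value,
            "ratio": measures.ratio(cell, meta, dim).value,
        }
        if dim.ordered:
            spec = measures.compute_ranks(cell, dim)
            for link_name in links:
                link = measures.Link(link_name)
                row[f"sii_{link_name}"] = measures.sii(cell, dim, link, spec).value
                row[f"rii_{link_name}"] = measures.rii(cell, dim, link, spec).value
        if dim.dimension_id == "education":
            row["par"] = measures.par(cell, dim).value
        rows.append(row)
    return pd.DataFrame(rows)
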