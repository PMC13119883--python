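"""Summary measures of within-country inequality for one analysis cell.

Five measures are computed per (setting, year, indicator, dimension):

* **difference** (percentage points) and **ratio** (unitless): pairwise
  comparisons of the most-advantaged and most-disadvantaged subgroups. For
  favourable (coverage) indicators, difference = advantaged - disadvantaged
  and ratio = advantaged / disadvantaged; for adverse (non-receipt)
  indicators both are reversed, so that positive difference / ratio > 1
  always means inequality to the detriment of the disadvantaged subgroup.
  Child sex uses the male-minus-female convention without an advantage claim.

* **SII** (slope index of inequality, percentage points) and **RII**
  (relative index of inequality, unitless): regression-based measures for
  ordered dimensions. Subgroups are placed on a 0-1 axis at the midpoint of
  their cumulative population share (most-disadvantaged first); the estimate
  is regressed on this rank, weighted by population share. SII is the
  difference, RII the ratio, of the predicted values at rank 1 (most
  advantaged extreme) and rank 0 (most disadvantaged extreme). The default
  link is logistic on the proportion scale, which keeps predictions inside
  [0, 100]; a linear link is available, and every result records the link
  that produced it. By default SII/RII are reported only for economic status
  and education.

* **PAR** (population attributable risk, percentage points): reference
  subgroup estimate minus national average — the change in the national
  average attainable if every subgroup matched the reference (most-educated)
  subgroup. ``potential_average`` is the national average plus PAR, clamped
  to [0, 100].

Missing prerequisites never raise: the result comes back with
``applicable=False`` and an explanatory note.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .model import (
    DIMENSIONS,
    INDICATORS,
    AnalysisCell,
    DimensionMeta,
    IndicatorMeta,
    Polarity,
)

__all__ = [
    "Measure",
    "Link",
    "SummaryMeasureResult",
    "RegressionSpec",
    "difference",
    "ratio",
    "compute_ranks",
    "sii",
    "rii",
    "par",
    "potential_average",
    "compute_all",
    "measures_frame",
]

#: estimates of exactly 0 or 100 are clipped here before the logit transform
LOGIT_CLIP = (0.01, 99.99)

#: dimensions for which SII/RII are reported by default
DEFAULT_SII_DIMENSIONS = ("wealth", "education")


class Measure(str, enum.Enum):
    DIFFERENCE = "difference"
    RATIO = "ratio"
    SII = "sii"
    RII = "rii"
    PAR = "par"
    POTENTIAL_AVERAGE = "potential_average"


class Link(str, enum.Enum):
    LOGIT = "logit"
    LINEAR = "linear"


@dataclass(frozen=True)
class SummaryMeasureResult:
    measure: Measure
    value: Optional[float]
    applicable: bool = True
    note: str = ""

    @staticmethod
    def not_applicable(measure: Measure, note: str) -> "SummaryMeasureResult":
        return SummaryMeasureResult(measure, None, applicable=False, note=note)


@dataclass(frozen=True)
class RegressionSpec:
    """Design of the weighted rank regression behind SII/RII.

    ``ranks`` are midpoint cumulative population shares in [0, 1], ordered
    most-disadvantaged to most-advantaged; ``weights`` are the population
    shares; ``estimates`` the subgroup percentages in the same order.
    """

    ranks: tuple[float, ...]
    weights: tuple[float, ...]
    estimates: tuple[float, ...]


def _comparison_pair(
    cell: AnalysisCell, dim: DimensionMeta
) -> Optional[tuple[float, float]]:
    """(advantaged, disadvantaged) estimates, or None when either is missing."""
    try:
        adv = cell.estimate_of(dim.advantaged_subgroup)
        dis = cell.estimate_of(dim.disadvantaged_subgroup)
    except KeyError:
        return None
    return adv, dis


def difference(
    cell: AnalysisCell,
    indicator: Optional[IndicatorMeta] = None,
    dim: Optional[DimensionMeta] = None,
) -> SummaryMeasureResult:
    """Pairwise absolute inequality in percentage points.

    Favourable: advantaged - disadvantaged. Adverse: disadvantaged -
    advantaged. Child sex: male - female (reversed for adverse indicators).
    """
    indicator = indicator or INDICATORS[cell.indicator_id]
    dim = dim or DIMENSIONS[cell.dimension_id]
    pair = _comparison_pair(cell, dim)
    if pair is None:
        return SummaryMeasureResult.not_applicable(
            Measure.DIFFERENCE, "comparison subgroup missing"
        )
    adv, dis = pair
    value = adv - dis if indicator.favourable else dis - adv
    return SummaryMeasureResult(Measure.DIFFERENCE, value)


def ratio(
    cell: AnalysisCell,
    indicator: Optional[IndicatorMeta] = None,
    dim: Optional[DimensionMeta] = None,
) -> SummaryMeasureResult:
    """Pairwise relative inequality (unitless); direction rules as difference."""
    indicator = indicator or INDICATORS[cell.indicator_id]
    dim = dim or DIMENSIONS[cell.dimension_id]
    pair = _comparison_pair(cell, dim)
    if pair is None:
        return SummaryMeasureResult.not_applicable(
            Measure.RATIO, "comparison subgroup missing"
        )
    adv, dis = pair
    num, den = (adv, dis) if indicator.favourable else (dis, adv)
    if den == 0:
        return SummaryMeasureResult.not_applicable(Measure.RATIO, "undefined ratio")
    return SummaryMeasureResult(Measure.RATIO, num / den)


def compute_ranks(
    cell: AnalysisCell, dim: Optional[DimensionMeta] = None
) -> Optional[RegressionSpec]:
    """Midpoint cumulative-population ranks for an ordered dimension.

    Each subgroup's rank is the cumulative share of all more-disadvantaged
    subgroups plus half its own share; equal quintile shares give
    (0.1, 0.3, 0.5, 0.7, 0.9). Returns None for non-ordered dimensions.
    """
    dim = dim or DIMENSIONS[cell.dimension_id]
    if not dim.ordered:
        return None
    shares = np.array([cell.share_of(sg) for sg in dim.subgroups], dtype=float)
    shares = shares / shares.sum()
    cum = np.concatenate([[0.0], np.cumsum(shares)])
    ranks = cum[:-1] + shares / 2.0
    estimates = tuple(cell.estimate_of(sg) for sg in dim.subgroups)
    return RegressionSpec(tuple(ranks), tuple(shares), estimates)


def _fit_predict_extremes(spec: RegressionSpec, link: Link) -> tuple[float, float]:
    """Predicted estimates (percent) at rank 0 and rank 1 from the weighted fit."""
    x = np.asarray(spec.ranks)
    w = np.asarray(spec.weights)
    y = np.asarray(spec.estimates, dtype=float)
    X = sm.add_constant(x)
    X_extreme = np.array([[1.0, 0.0], [1.0, 1.0]])
    with warnings.catch_warnings():
        # two-subgroup cells are saturated fits: zero residual df and
        # "perfect prediction" are expected there, not a problem
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        if link is Link.LINEAR:
            fit = sm.WLS(y, X, weights=w).fit()
            p0, p1 = X_extreme @ fit.params
            return float(p0), float(p1)
        p = np.clip(y, *LOGIT_CLIP) / 100.0
        model = sm.GLM(p, X, family=sm.families.Binomial(), var_weights=w)
        fit = model.fit(tol=1e-12, maxiter=200)
    eta0, eta1 = X_extreme @ fit.params
    mu = 100.0 / (1.0 + np.exp(-np.array([eta0, eta1])))
    return float(mu[0]), float(mu[1])


def _regression_result(
    measure: Measure,
    cell: AnalysisCell,
    dim: Optional[DimensionMeta],
    link: Link,
    spec: Optional[RegressionSpec],
) -> tuple[Optional[SummaryMeasureResult], Optional[tuple[float, float]]]:
    dim = dim or DIMENSIONS[cell.dimension_id]
    if not dim.ordered:
        return (
            SummaryMeasureResult.not_applicable(measure, "non-ordered dimension"),
            None,
        )
    spec = spec or compute_ranks(cell, dim)
    assert spec is not None
    if len(spec.ranks) < 2:
        return SummaryMeasureResult.not_applicable(measure, "fewer than 2 subgroups"), None
    try:
        p0, p1 = _fit_predict_extremes(spec, link)
    except (np.linalg.LinAlgError, ValueError):
        return SummaryMeasureResult.not_applicable(measure, "singular fit"), None
    return None, (p0, p1)


def sii(
    cell: AnalysisCell,
    dim: Optional[DimensionMeta] = None,
    link: Link = Link.LOGIT,
    spec: Optional[RegressionSpec] = None,
) -> SummaryMeasureResult:
    """Slope index of inequality: predicted(rank 1) - predicted(rank 0), in pp."""
    failure, preds = _regression_result(Measure.SII, cell, dim, link, spec)
    if failure is not None:
        return failure
    p0, p1 = preds
    return SummaryMeasureResult(Measure.SII, p1 - p0, note=f"link={link.value}")


def rii(
    cell: AnalysisCell,
    dim: Optional[DimensionMeta] = None,
    link: Link = Link.LOGIT,
    spec: Optional[RegressionSpec] = None,
) -> SummaryMeasureResult:
    """Relative index of inequality: predicted(rank 1) / predicted(rank 0)."""
    failure, preds = _regression_result(Measure.RII, cell, dim, link, spec)
    if failure is not None:
        return failure
    p0, p1 = preds
    if p0 <= 0:
        return SummaryMeasureResult.not_applicable(
            Measure.RII, f"predicted value at rank 0 is {p0:.4g} <= 0 (link={link.value})"
        )
    return SummaryMeasureResult(Measure.RII, p1 / p0, note=f"link={link.value}")


def par(
    cell: AnalysisCell,
    dim: Optional[DimensionMeta] = None,
    reference_subgroup: Optional[str] = None,
    truncate: bool = False,
) -> SummaryMeasureResult:
    """Population attributable risk: reference estimate minus national average.

    The reference defaults to the most-advantaged subgroup (most educated, for
    the education dimension the measure is reported for). Positive PAR on a
    coverage indicator means the national average would rise by that much if
    inequality were eliminated; negative PAR on a non-receipt indicator means
    it would fall. ``truncate`` maps values with the "wrong" sign to 0.
    """
    dim = dim or DIMENSIONS[cell.dimension_id]
    reference_subgroup = reference_subgroup or dim.advantaged_subgroup
    cell = cell.with_national_average()
    try:
        ref = cell.estimate_of(reference_subgroup)
    except KeyError:
        return SummaryMeasureResult.not_applicable(
            Measure.PAR, f"reference subgroup {reference_subgroup!r} missing"
        )
    value = ref - cell.national_average
    if truncate:
        favourable = INDICATORS[cell.indicator_id].favourable
        wrong_sign = value < 0 if favourable else value > 0
        if wrong_sign:
            return SummaryMeasureResult(Measure.PAR, 0.0, note="truncated to 0")
    return SummaryMeasureResult(Measure.PAR, value)


def potential_average(
    cell: AnalysisCell,
    dim: Optional[DimensionMeta] = None,
    reference_subgroup: Optional[str] = None,
) -> SummaryMeasureResult:
    """National average attainable by eliminating inequality: national + PAR."""
    cell = cell.with_national_average()
    p = par(cell, dim, reference_subgroup)
    if not p.applicable:
        return SummaryMeasureResult.not_applicable(Measure.POTENTIAL_AVERAGE, p.note)
    value = cell.national_average + p.value
    note = ""
    if value < 0 or value > 100:
        value = float(np.clip(value, 0.0, 100.0))
        note = "clamped to [0, 100]"
    return SummaryMeasureResult(Measure.POTENTIAL_AVERAGE, value, note=note)


def compute_all(
    cell: AnalysisCell,
    link: Link = Link.LOGIT,
    sii_dimensions: Sequence[str] = DEFAULT_SII_DIMENSIONS,
    par_dimensions: Sequence[str] = ("education",),
) -> list[SummaryMeasureResult]:
    """All applicable summary measures for one cell.

    Pairwise measures are computed for every dimension; SII/RII only for the
    dimensions in ``sii_dimensions`` (economic status and education by
    default); PAR and the potential average only for ``par_dimensions``
    (education by default). Pass ``sii_dimensions=None`` to lift the
    restriction to any ordered dimension.
    """
    dim = DIMENSIONS[cell.dimension_id]
    indicator = INDICATORS[cell.indicator_id]
    out = [difference(cell, indicator, dim), ratio(cell, indicator, dim)]
    if sii_dimensions is None or cell.dimension_id in sii_dimensions:
        out.append(sii(cell, dim, link))
        out.append(rii(cell, dim, link))
    if cell.dimension_id in par_dimensions:
        out.append(par(cell, dim))
        out.append(potential_average(cell, dim))
    return out


def measures_frame(
    cells: Iterable[AnalysisCell],
    link: Link = Link.LOGIT,
    sii_dimensions: Optional[Sequence[str]] = DEFAULT_SII_DIMENSIONS,
    par_dimensions: Sequence[str] = ("education",),
) -> pd.DataFrame:
    """Long-format table of measures for many cells.

    Columns: setting_id, year, indicator_id, dimension_id, income_group,
    measure, value, applicable, note.
    """
    rows = []
    for cell in cells:
        for res in compute_all(cell, link, sii_dimensions, par_dimensions):
            rows.append(
                {
                    "setting_id": cell.setting_id,
                    "year": cell.year,
                    "indicator_id": cell.indicator_id,
                    "dimension_id": cell.dimension_id,
                    "income_group": (
                        "" if cell.income_group is None else cell.income_group.value
                    ),
                    "measure": res.measure.value,
                    "value": np.nan if res.value is None else res.value,
                    "applicable": res.applicable,
                    "note": res.note,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "setting_id", "year", "indicator_id", "dimension_id", "income_group",
            "measure", "value", "applicable", "note",
        ],
    )
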