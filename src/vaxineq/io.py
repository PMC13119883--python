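"""Long-format CSV input/output and cell construction.

The on-disk layout is one row per (setting, survey year, indicator, dimension,
subgroup). Fixed UTF-8 header::

    setting_id,setting_name,income_group,survey_source,year,indicator_id,
    dimension_id,subgroup_id,estimate,population_share,standard_error

Optional fields (``income_group``, ``standard_error``) are blank when absent.
``build_cells`` enforces the completeness rule: a (setting, year, indicator,
dimension) cell enters the analysis only when every subgroup of the dimension
is present; incomplete cells are excluded and logged. ``eligibility_filter``
enforces the study-scope rule: only settings classified as low, lower-middle
or upper-middle income are retained.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .model import (
    DIMENSIONS,
    AnalysisCell,
    DimensionMeta,
    DisaggregatedRecord,
    IncomeGroup,
    SurveySource,
)

__all__ = [
    "COLUMNS",
    "FormatError",
    "ValidationError",
    "Exclusion",
    "read_disaggregated",
    "write_disaggregated",
    "records_to_frame",
    "frame_to_records",
    "build_cells",
    "eligibility_filter",
    "write_exclusions",
]

log = logging.getLogger(__name__)

COLUMNS = (
    "setting_id",
    "setting_name",
    "income_group",
    "survey_source",
    "year",
    "indicator_id",
    "dimension_id",
    "subgroup_id",
    "estimate",
    "population_share",
    "standard_error",
)

#: population shares within a cell must sum to 1 within this before rescaling
SHARE_SUM_TOL = 1e-3


class FormatError(ValueError):
    """The file does not have the documented header/layout."""


class ValidationError(ValueError):
    """A row violates a range or uniqueness invariant (strict mode)."""


@dataclass(frozen=True)
class Exclusion:
    """One excluded (setting, year, indicator, dimension) with a reason."""

    setting_id: str
    year: Optional[int]
    indicator_id: str
    dimension_id: str
    reason: str


def _parse_row(row: pd.Series) -> DisaggregatedRecord:
    income = row["income_group"]
    se = row["standard_error"]
    return DisaggregatedRecord(
        setting_id=str(row["setting_id"]),
        setting_name=str(row["setting_name"]),
        income_group=None if pd.isna(income) or income == "" else IncomeGroup(income),
        survey_source=SurveySource(str(row["survey_source"])),
        year=int(row["year"]),
        indicator_id=str(row["indicator_id"]),
        dimension_id=str(row["dimension_id"]),
        subgroup_id=str(row["subgroup_id"]),
        estimate=float(row["estimate"]),
        population_share=float(row["population_share"]),
        standard_error=None if pd.isna(se) else float(se),
    )


def read_disaggregated(
    path: Union[str, Path], strict: bool = True
) -> list[DisaggregatedRecord]:
    """Read a long-format CSV of disaggregated estimates.

    In strict mode any row violating a range invariant raises
    :class:`ValidationError` naming the row; in lenient mode offending rows
    are dropped and the count is logged.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"setting_id": str, "subgroup_id": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    records: list[DisaggregatedRecord] = []
    dropped = 0
    for idx, row in df.iterrows():
        try:
            rec = _parse_row(row)
        except (ValueError, KeyError) as exc:
            if strict:
                raise ValidationError(f"{path} row {idx}: {exc}") from exc
            dropped += 1
            continue
        problems = rec.validate()
        if problems:
            if strict:
                raise ValidationError(f"{path} row {idx}: {'; '.join(problems)}")
            dropped += 1
            continue
        records.append(rec)

    seen: set[tuple] = set()
    for rec in records:
        key = (rec.setting_id, rec.year, rec.indicator_id, rec.dimension_id,
               rec.subgroup_id)
        if key in seen:
            raise ValidationError(f"{path}: duplicate record for {key}")
        seen.add(key)

    if dropped:
        log.warning("%s: dropped %d invalid row(s) in lenient mode", path, dropped)
        read_disaggregated.last_dropped = dropped  # type: ignore[attr-defined]
    else:
        read_disaggregated.last_dropped = 0  # type: ignore[attr-defined]
    return records


def records_to_frame(records: Iterable[DisaggregatedRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "setting_id": r.setting_id,
                "setting_name": r.setting_name,
                "income_group": "" if r.income_group is None else r.income_group.value,
                "survey_source": r.survey_source.value,
                "year": r.year,
                "indicator_id": r.indicator_id,
                "dimension_id": r.dimension_id,
                "subgroup_id": r.subgroup_id,
                "estimate": r.estimate,
                "population_share": r.population_share,
                "standard_error": "" if r.standard_error is None else r.standard_error,
            }
        )
    return pd.DataFrame(rows, columns=list(COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[DisaggregatedRecord]:
    return [_parse_row(row) for _, row in df.iterrows()]


def write_disaggregated(
    records: Iterable[DisaggregatedRecord], path: Union[str, Path]
) -> None:
    """Write records as the documented long-format CSV (UTF-8, one dialect)."""
    records_to_frame(records).to_csv(path, index=False, encoding="utf-8")


def build_cells(
    records: Sequence[DisaggregatedRecord],
    dims: Mapping[str, DimensionMeta] = DIMENSIONS,
    national_averages: Optional[Mapping[tuple, float]] = None,
) -> tuple[list[AnalysisCell], list[Exclusion]]:
    """Group records into complete analysis cells.

    A cell is emitted only when every subgroup of its dimension is present
    exactly once; anything else is excluded with a reason. Population shares
    are rescaled to sum to 1 when within ``SHARE_SUM_TOL`` of 1 (repository
    extracts carry rounding); larger deviations are validation errors.

    ``national_averages`` optionally maps (setting_id, year, indicator_id) to
    a survey-reported national average; otherwise the population-weighted mean
    of the subgroup estimates is used.
    """
    by_cell: dict[tuple, list[DisaggregatedRecord]] = {}
    for rec in records:
        if rec.dimension_id not in dims:
            raise KeyError(f"unknown dimension_id {rec.dimension_id!r}")
        key = (rec.setting_id, rec.year, rec.indicator_id, rec.dimension_id)
        by_cell.setdefault(key, []).append(rec)

    cells: list[AnalysisCell] = []
    exclusions: list[Exclusion] = []
    for (setting, year, indicator, dimension), recs in sorted(by_cell.items()):
        dim = dims[dimension]
        present = {r.subgroup_id for r in recs}
        expected = set(dim.subgroups)
        if present != expected:
            missing = sorted(expected - present)
            extra = sorted(present - expected)
            reason = []
            if missing:
                reason.append(f"missing subgroup(s) {missing}")
            if extra:
                reason.append(f"unexpected subgroup(s) {extra}")
            exclusions.append(
                Exclusion(setting, year, indicator, dimension, "; ".join(reason))
            )
            continue

        share_sum = sum(r.population_share for r in recs)
        if abs(share_sum - 1.0) > SHARE_SUM_TOL:
            raise ValidationError(
                f"cell {(setting, year, indicator, dimension)}: population "
                f"shares sum to {share_sum:.6f}, outside 1 +/- {SHARE_SUM_TOL}"
            )
        by_id = {r.subgroup_id: r for r in recs}
        ordered = tuple(
            dataclasses.replace(
                by_id[sg], population_share=by_id[sg].population_share / share_sum
            )
            for sg in dim.subgroups
        )
        natavg = None
        if national_averages is not None:
            natavg = national_averages.get((setting, year, indicator))
        income = next((r.income_group for r in recs if r.income_group), None)
        cell = AnalysisCell(
            setting_id=setting,
            year=year,
            indicator_id=indicator,
            dimension_id=dimension,
            records=ordered,
            national_average=natavg,
            income_group=income,
        ).with_national_average()
        cells.append(cell)
    return cells, exclusions


def eligibility_filter(
    records: Sequence[DisaggregatedRecord],
    income_catalogue: Mapping[str, str],
) -> tuple[list[DisaggregatedRecord], list[Exclusion]]:
    """Keep only settings classified low / lower-middle / upper-middle income.

    ``income_catalogue`` maps setting_id to one of the in-scope income groups,
    ``"high"`` or ``"unclassified"``. Settings absent from the catalogue pass
    through with a warning (their income group stays as-is).
    """
    in_scope = {g.value for g in IncomeGroup}
    kept: list[DisaggregatedRecord] = []
    excluded: dict[str, str] = {}
    warned: set[str] = set()
    for rec in records:
        cls = income_catalogue.get(rec.setting_id)
        if cls is None:
            if rec.setting_id not in warned:
                log.warning("setting %s absent from income catalogue", rec.setting_id)
                warned.add(rec.setting_id)
            kept.append(rec)
        elif cls in in_scope:
            kept.append(rec)
        else:
            reason = "high-income" if cls == "high" else "unclassified"
            excluded[rec.setting_id] = reason
    exclusions = [
        Exclusion(setting, None, "*", "*", reason)
        for setting, reason in sorted(excluded.items())
    ]
    return kept, exclusions


def write_exclusions(exclusions: Sequence[Exclusion], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "setting_id": e.setting_id,
                "year": "" if e.year is None else e.year,
                "indicator_id": e.indicator_id,
                "dimension_id": e.dimension_id,
                "reason": e.reason,
            }
            for e in exclusions
        ],
        columns=["setting_id", "year", "indicator_id", "dimension_id", "reason"],
    ).to_csv(path, index=False, encoding="utf-8")
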