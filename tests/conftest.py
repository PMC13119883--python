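from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vaxineq.model import (
    DIMENSIONS,
    INDICATORS,
    AnalysisCell,
    DisaggregatedRecord,
    IncomeGroup,
    SurveySource,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_cell(
    dimension_id: str,
    estimates,
    shares=None,
    indicator_id: str = "dtp3",
    setting_id: str = "S001",
    year: int = 2019,
    income_group=IncomeGroup.LOW,
    national_average=None,
) -> AnalysisCell:
    """Build a complete analysis cell from raw numbers (test helper)."""
    dim = DIMENSIONS[dimension_id]
    assert len(estimates) == len(dim.subgroups)
    if shares is None:
        shares = [1.0 / len(dim.subgroups)] * len(dim.subgroups)
    records = tuple(
        DisaggregatedRecord(
            setting_id=setting_id,
            setting_name=setting_id,
            income_group=income_group,
            survey_source=SurveySource.DHS,
            year=year,
            indicator_id=indicator_id,
            dimension_id=dimension_id,
            subgroup_id=sg,
            estimate=float(e),
            population_share=float(s),
        )
        for sg, e, s in zip(dim.subgroups, estimates, shares)
    )
    return AnalysisCell(
        setting_id=setting_id,
        year=year,
        indicator_id=indicator_id,
        dimension_id=dimension_id,
        records=records,
        national_average=national_average,
        income_group=income_group,
    ).with_national_average()


@pytest.fixture
def cell_factory():
    return make_cell


def random_cell(rng: np.random.Generator, n_subgroups: int | None = None):
    """A random ordered cell: ranks from Dirichlet shares, estimates in (5, 95)."""
    k = n_subgroups or int(rng.integers(2, 6))
    shares = rng.dirichlet(np.ones(k) * 2.0)
    estimates = rng.uniform(5.0, 95.0, size=k)
    return shares, estimates


@pytest.fixture
def rng():
    return np.random.default_rng(20260)
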