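"""Unit and property tests for the five summary measures."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import oracles
from vaxineq.measures import (
    Link,
    Measure,
    RegressionSpec,
    compute_ranks,
    difference,
    par,
    potential_average,
    ratio,
    rii,
    sii,
)
from vaxineq.model import DIMENSIONS, INDICATORS, DimensionMeta

from conftest import make_cell, random_cell


def spec_from(shares, estimates) -> RegressionSpec:
    shares = np.asarray(shares, float)
    shares = shares / shares.sum()
    ranks = np.cumsum(shares) - shares / 2.0
    return RegressionSpec(tuple(ranks), tuple(shares), tuple(estimates))


ADHOC_DIMS = {
    k: DimensionMeta(f"adhoc{k}", f"ad-hoc {k}", True, tuple(f"g{i}" for i in range(k)))
    for k in range(2, 6)
}


class TestPairwiseMeasures:
    @pytest.mark.parametrize(
        "dimension, indicator, estimates, expected_d, expected_r",
        [
            # favourable: advantaged minus / over disadvantaged
            ("residence", "dtp3", (75.0, 85.0), 10.0, 85.0 / 75.0),
            ("wealth", "dtp3", (45.0, 50.0, 60.0, 70.0, 90.0), 45.0, 2.0),
            # adverse: reversed, so detriment of the disadvantaged stays positive
            ("residence", "zero_dose_dtp", (12.0, 4.0), 8.0, 3.0),
            ("wealth", "zero_dose_dtp", (10.0, 8.0, 6.0, 4.0, 2.5), 7.5, 4.0),
            # child sex: male minus female by convention
            ("sex", "dtp3", (82.0, 80.0), -2.0, 80.0 / 82.0),
            # equal subgroups: no inequality
            ("residence", "dtp3", (70.0, 70.0), 0.0, 1.0),
        ],
    )
    def test_direction_rules(self, dimension, indicator, estimates, expected_d, expected_r):
        cell = make_cell(dimension, estimates, indicator_id=indicator)
        assert difference(cell).value == pytest.approx(expected_d, abs=1e-12)
        assert ratio(cell).value == pytest.approx(expected_r, rel=1e-12)

    def test_zero_denominator_ratio_is_not_applicable(self):
        cell = make_cell("residence", (0.0, 50.0), indicator_id="dtp3")
        res = ratio(cell)
        assert not res.applicable and "undefined" in res.note

    @given(
        adv=st.floats(0.0, 100.0),
        dis=st.floats(0.0, 100.0),
    )
    def test_difference_zero_iff_equal_and_sign_tracks_gap(self, adv, dis):
        cell = make_cell("residence", (dis, adv), indicator_id="dtp3")
        d = difference(cell).value
        assert d == pytest.approx(adv - dis)
        assert (d == 0) == (adv == dis)
        # adverse polarity flips the sign
        cell_a = make_cell("residence", (dis, adv), indicator_id="zero_dose_dtp")
        assert difference(cell_a).value == pytest.approx(dis - adv)


class TestRanks:
    @pytest.mark.parametrize(
        "shares, expected",
        [
            ([0.2] * 5, (0.1, 0.3, 0.5, 0.7, 0.9)),
            ([0.5, 0.5], (0.25, 0.75)),
            ([0.2, 0.8], (0.1, 0.6)),
        ],
    )
    def test_midpoint_ranks(self, shares, expected):
        dim_id = {5: "wealth", 2: "residence"}[len(shares)]
        cell = make_cell(dim_id, [50.0] * len(shares), shares=shares)
        spec = compute_ranks(cell)
        assert spec.ranks == pytest.approx(expected)
        assert all(b > a for a, b in zip(spec.ranks, spec.ranks[1:]))

    def test_non_ordered_dimension_has_no_ranks(self):
        cell = make_cell("sex", (50.0, 50.0))
        assert compute_ranks(cell) is None


class TestRegressionMeasures:
    def test_two_point_linear_closed_form(self):
        # ranks 0.25/0.75; the line through (0.25, 40), (0.75, 60) predicts
        # 30 at rank 0 and 70 at rank 1
        spec = spec_from([0.5, 0.5], [40.0, 60.0])
        cell = make_cell("residence", (40.0, 60.0))
        assert sii(cell, link=Link.LINEAR).value == pytest.approx(40.0, abs=1e-9)
        assert rii(cell, link=Link.LINEAR).value == pytest.approx(7.0 / 3.0, rel=1e-9)

    @pytest.mark.parametrize("link", [Link.LINEAR, Link.LOGIT])
    @pytest.mark.parametrize("dim_id", ["wealth", "education", "residence", "age"])
    def test_flat_gradient_gives_no_inequality(self, link, dim_id):
        k = len(DIMENSIONS[dim_id].subgroups)
        cell = make_cell(dim_id, [70.0] * k)
        assert sii(cell, link=link).value == pytest.approx(0.0, abs=1e-8)
        assert rii(cell, link=link).value == pytest.approx(1.0, abs=1e-8)

    def test_five_quintile_linear_matches_normal_equation_oracle(self):
        estimates = [50.0, 60.0, 70.0, 80.0, 90.0]
        cell = make_cell("wealth", estimates)
        spec = compute_ranks(cell)
        sii_exp, rii_exp = oracles.sii_rii_linear(spec.ranks, estimates, spec.weights)
        assert sii(cell, link=Link.LINEAR).value == pytest.approx(sii_exp, rel=1e-10)
        assert rii(cell, link=Link.LINEAR).value == pytest.approx(rii_exp, rel=1e-10)

    def test_five_quintile_logit_matches_irls_oracle(self):
        estimates = [50.0, 60.0, 70.0, 80.0, 90.0]
        cell = make_cell("wealth", estimates)
        spec = compute_ranks(cell)
        sii_exp, rii_exp = oracles.sii_rii_logit(spec.ranks, estimates, spec.weights)
        assert sii(cell, link=Link.LOGIT).value == pytest.approx(sii_exp, rel=1e-8)
        assert rii(cell, link=Link.LOGIT).value == pytest.approx(rii_exp, rel=1e-8)

    @pytest.mark.parametrize("link", [Link.LINEAR, Link.LOGIT])
    def test_strictly_increasing_estimates_give_positive_inequality(self, link, rng):
        for _ in range(20):
            k = int(rng.integers(2, 6))
            estimates = np.sort(rng.uniform(10.0, 90.0, size=k))
            estimates += np.arange(k) * 0.5  # enforce strict increase
            shares = rng.dirichlet(np.ones(k) * 2.0)
            spec = spec_from(shares, estimates)
            dim = ADHOC_DIMS[k]
            assert sii(None, dim=dim, link=link, spec=spec).value > 0
            r = rii(None, dim=dim, link=link, spec=spec)
            if r.applicable:
                assert r.value > 1
            else:
                # only the documented linear-link degeneracy may occur:
                # extrapolation to rank 0 at or below zero
                assert link is Link.LINEAR and "<= 0" in r.note

    def test_boundary_estimates_are_clipped_not_fatal(self):
        cell = make_cell("residence", (0.0, 100.0))
        res = sii(cell, link=Link.LOGIT)
        assert res.applicable and 0 < res.value <= 100

    def test_non_ordered_dimension_not_applicable(self):
        cell = make_cell("sex", (50.0, 60.0))
        assert not sii(cell).applicable
        assert not rii(cell).applicable

    def test_permuting_record_order_changes_nothing(self):
        estimates = [35.0, 55.0, 75.0]
        cell = make_cell("education", estimates, shares=[0.3, 0.3, 0.4])
        shuffled = cell.__class__(
            setting_id=cell.setting_id,
            year=cell.year,
            indicator_id=cell.indicator_id,
            dimension_id=cell.dimension_id,
            records=cell.records[::-1],
            national_average=cell.national_average,
            income_group=cell.income_group,
        )
        for fn in (difference, ratio, sii, rii, par):
            assert fn(cell).value == pytest.approx(fn(shuffled).value, rel=1e-12)


class TestOracleEquivalence:
    """The fitting routine agrees with brute-force solvers on random cells."""

    def test_random_cells_match_both_oracles(self, rng):
        for _ in range(100):
            shares, estimates = random_cell(rng)
            k = len(shares)
            spec = spec_from(shares, estimates)
            dim = ADHOC_DIMS[k]
            s_lin = sii(None, dim=dim, link=Link.LINEAR, spec=spec).value
            r_lin = rii(None, dim=dim, link=Link.LINEAR, spec=spec)
            s_log = sii(None, dim=dim, link=Link.LOGIT, spec=spec).value
            r_log = rii(None, dim=dim, link=Link.LOGIT, spec=spec).value
            es_lin, er_lin = oracles.sii_rii_linear(spec.ranks, estimates, spec.weights)
            es_log, er_log = oracles.sii_rii_logit(spec.ranks, estimates, spec.weights)
            assert s_lin == pytest.approx(es_lin, rel=1e-8, abs=1e-10)
            if r_lin.applicable:
                assert r_lin.value == pytest.approx(er_lin, rel=1e-8)
            else:
                # oracle confirms the linear extrapolation at rank 0 is <= 0
                a, _ = oracles.weighted_linear_fit(
                    spec.ranks, estimates, spec.weights
                )
                assert a <= 0
            assert s_log == pytest.approx(es_log, rel=1e-8, abs=1e-10)
            assert r_log == pytest.approx(er_log, rel=1e-8)


class TestParAndPotential:
    @pytest.mark.parametrize(
        "indicator, estimates, national, expected_par",
        [
            ("dtp3", (60.0, 80.0, 95.0), 80.0, 15.0),
            ("zero_dose_dtp", (12.0, 7.0, 2.0), 7.0, -5.0),
        ],
    )
    def test_par_is_reference_minus_national(
        self, indicator, estimates, national, expected_par
    ):
        cell = make_cell(
            "education", estimates, indicator_id=indicator, national_average=national
        )
        assert par(cell).value == pytest.approx(expected_par)
        pot = potential_average(cell)
        assert pot.value == pytest.approx(national + expected_par)

    def test_par_zero_when_reference_equals_national(self):
        cell = make_cell("education", (80.0, 80.0, 80.0))
        assert par(cell).value == pytest.approx(0.0)
        assert potential_average(cell).value == pytest.approx(cell.national_average)

    def test_truncation_mode_zeroes_wrong_sign(self):
        # most educated *below* the national average on a coverage indicator
        cell = make_cell("education", (90.0, 85.0, 70.0), national_average=82.0)
        assert par(cell).value == pytest.approx(-12.0)
        assert par(cell, truncate=True).value == 0.0

    @given(
        e0=st.floats(1.0, 99.0),
        e1=st.floats(1.0, 99.0),
        e2=st.floats(1.0, 99.0),
    )
    def test_potential_minus_national_equals_par(self, e0, e1, e2):
        cell = make_cell("education", (e0, e1, e2))
        p = par(cell).value
        pot = potential_average(cell).value
        if 0.0 <= cell.national_average + p <= 100.0:
            assert pot - cell.national_average == pytest.approx(p, abs=1e-9)
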