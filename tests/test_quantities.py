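"""GUM combination primitives: certificate conversion, RSS, dof pooling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assayunc import (
    BudgetComponent,
    InvalidInputError,
    UncertainQuantity,
    build_budget,
    combine_rss,
    contribution_shares,
    coverage_factor,
    expand,
    relative_uncertainty,
    standard_from_expanded,
    welch_satterthwaite,
)
from assayunc.quantities import round_dof

INF = math.inf

# the four-source budgets of the urine assay study (relative u, dof)
AP_BUDGET = [
    BudgetComponent("urine_dilution", 0.000866, INF),
    BudgetComponent("calibrator_preparation", 0.018953, INF),
    BudgetComponent("calibration_curve", 0.025458, 5),
    BudgetComponent("repeatability", 0.019355, 55),
]
HA_BUDGET = [
    BudgetComponent("urine_dilution", 0.000866, INF),
    BudgetComponent("calibrator_preparation", 0.019036, INF),
    BudgetComponent("calibration_curve", 0.032891, 5),
    BudgetComponent("repeatability", 0.028505, 51),
]

finite_u = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


@pytest.mark.parametrize(
    "expanded, k, expected",
    [(0.1, 2, 0.05), (0.006, 2, 0.003), (0.0, 3.7, 0.0), (1.5, 2, 0.75)],
)
def test_standard_from_expanded(expanded, k, expected):
    assert standard_from_expanded(expanded, k) == pytest.approx(expected)


def test_standard_from_expanded_rejects_bad_coverage():
    with pytest.raises(InvalidInputError):
        standard_from_expanded(0.1, 0.0)
    with pytest.raises(InvalidInputError):
        standard_from_expanded(-0.1, 2.0)


@pytest.mark.parametrize(
    "u, value, expected",
    [(0.003, 1.0, 0.003), (0.75, 1000, 0.00075), (0.0, 5.0, 0.0)],
)
def test_relative_uncertainty(u, value, expected):
    assert relative_uncertainty(u, value) == pytest.approx(expected)


def test_relative_uncertainty_names_quantity_on_zero():
    with pytest.raises(InvalidInputError, match="stock"):
        relative_uncertainty(0.1, 0.0, name="stock")


@pytest.mark.parametrize(
    "values, expected, tol",
    [
        ([0.000866, 0.018953, 0.025458, 0.019355], 0.037184, 1e-5),
        ([0.000866, 0.019036, 0.032891, 0.028505], 0.047512, 2e-6),
        ([0.042], 0.042, 1e-15),
    ],
)
def test_combine_rss_reproduces_study_budgets(values, expected, tol):
    assert combine_rss(values) == pytest.approx(expected, abs=tol)


def test_combine_rss_rejects_empty_and_negative():
    with pytest.raises(InvalidInputError):
        combine_rss([])
    with pytest.raises(InvalidInputError):
        combine_rss([0.1, -0.2])


@settings(deadline=None)
@given(st.lists(finite_u, min_size=1, max_size=8))
def test_combine_rss_matches_brute_force_and_order(values):
    brute = math.sqrt(sum(v * v for v in values))
    assert combine_rss(values) == pytest.approx(brute, rel=1e-12, abs=1e-300)
    assert combine_rss(list(reversed(values))) == pytest.approx(
        combine_rss(values), rel=1e-12, abs=1e-300
    )


@pytest.mark.parametrize(
    "budget, expected_round",
    [(AP_BUDGET, 22), (HA_BUDGET, 21)],
)
def test_welch_satterthwaite_study_dofs(budget, expected_round):
    veff = welch_satterthwaite(budget)
    assert round_dof(veff) == expected_round


def test_welch_satterthwaite_floor_mode_is_conservative():
    veff = welch_satterthwaite(HA_BUDGET)  # 20.63 raw
    assert round_dof(veff, "floor") == 20
    assert round_dof(veff, "nearest") == 21


def test_welch_satterthwaite_single_component_identity():
    comp = BudgetComponent("only", 0.0123, 7)
    assert welch_satterthwaite([comp]) == pytest.approx(7.0, rel=1e-12)


def test_welch_satterthwaite_all_infinite_dof():
    comps = [BudgetComponent("a", 0.01), BudgetComponent("b", 0.02)]
    assert math.isinf(welch_satterthwaite(comps))


@settings(deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(min_value=1e-4, max_value=0.5),
            st.floats(min_value=1.0, max_value=200.0),
        ),
        min_size=1,
        max_size=6,
    )
)
def test_welch_satterthwaite_matches_direct_formula(pairs):
    comps = [BudgetComponent(f"c{i}", u, v) for i, (u, v) in enumerate(pairs)]
    uc = combine_rss(comps)
    direct = uc**4 / sum(u**4 / v for u, v in pairs)
    assert welch_satterthwaite(comps, uc) == pytest.approx(direct, rel=1e-12)


@pytest.mark.parametrize(
    "dof, expected", [(22, 2.07), (21, 2.08), (INF, 1.959964)]
)
def test_coverage_factor_values(dof, expected):
    assert coverage_factor(dof, 0.95) == pytest.approx(expected, abs=0.01)


def test_coverage_factor_monotone_and_normal_limit():
    ks = [coverage_factor(v, 0.95) for v in (2, 5, 10, 50, 200, 5000)]
    assert all(a > b for a, b in zip(ks, ks[1:]))
    assert ks[-1] == pytest.approx(coverage_factor(INF, 0.95), abs=5e-4)


def test_expand_study_examples():
    ur, u, interval = expand(0.037184, 2.07, 99.74)
    assert ur == pytest.approx(0.076971, abs=1e-6)
    assert u == pytest.approx(7.68, abs=0.01)
    assert interval[0] == pytest.approx(92.06, abs=0.01)
    assert interval[1] == pytest.approx(107.42, abs=0.01)
    _, u4, _ = expand(0.047512, 2.08, 11.33)
    assert u4 == pytest.approx(1.12, abs=0.005)


@given(
    st.floats(min_value=1e-4, max_value=0.2),
    st.floats(min_value=1.0, max_value=3.0),
    st.floats(min_value=0.1, max_value=1e3),
    st.floats(min_value=0.1, max_value=10.0),
)
def test_expand_is_homogeneous_in_measured_value(urc, k, value, scale):
    ur1, u1, _ = expand(urc, k, value)
    ur2, u2, _ = expand(urc, k, value * scale)
    assert ur1 == ur2
    assert u2 == pytest.approx(u1 * scale, rel=1e-12)
    assert ur1 == pytest.approx(k * urc, rel=1e-12)


@pytest.mark.parametrize(
    "budget, expected",
    [
        (AP_BUDGET, [0.05, 25.98, 46.87, 27.09]),
        (HA_BUDGET, [0.03, 16.05, 47.92, 35.99]),
    ],
)
def test_contribution_shares_study_budgets(budget, expected):
    shares = contribution_shares(budget)
    assert shares == pytest.approx(expected, abs=0.05)
    assert sum(shares) == pytest.approx(100.0, abs=0.05)


def test_contribution_shares_degenerate_cases():
    assert contribution_shares([0.3]) == [100.0]
    with pytest.raises(InvalidInputError):
        contribution_shares([0.0, 0.0])


@settings(deadline=None)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=10))
def test_contribution_shares_conservation(values):
    assert sum(contribution_shares(values)) == pytest.approx(100.0, abs=1e-9)


def test_uniform_quantity_moments():
    q = UncertainQuantity.from_uniform_bounds("VTf", -0.0745, 0.0745, unit="mL")
    assert q.value == pytest.approx(0.0)
    assert q.std_uncertainty == pytest.approx(0.0745 / math.sqrt(3), rel=1e-12)
    assert (q.lower, q.upper) == (pytest.approx(-0.0745), pytest.approx(0.0745))


def test_uncertain_quantity_validation():
    with pytest.raises(InvalidInputError):
        UncertainQuantity("bad", 1.0, -0.1)
    with pytest.raises(InvalidInputError):
        UncertainQuantity("bad", 1.0, 0.1, distribution="triangular")


def test_budget_serialization_round_trip(tmp_path):
    budget = build_budget(AP_BUDGET, measured_value=99.74)
    d = budget.to_dict()
    assert [c["name"] for c in d["components"]] == [c.name for c in AP_BUDGET]
    assert d["components"][0]["dof"] is None  # infinite dof -> null, not a sentinel
    assert d["expanded"]["absolute"] == pytest.approx(7.68, abs=0.01)
    budget.to_json(tmp_path / "budget.json")
    budget.to_csv(tmp_path / "budget.csv")
    frame = budget.to_frame()
    assert list(frame["source"])[:4] == [c.name for c in AP_BUDGET]
    assert (tmp_path / "budget.json").exists()
    assert (tmp_path / "budget.csv").exists()
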