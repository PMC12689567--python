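"""Sensitive-indicator selection and scenario recomputation."""

from fractions import Fraction

import numpy as np
import pytest

from pmckit.coding import CoverageProfile
from pmckit.engine import evaluate_from_first_level
from pmckit.sensitivity import (
    ScenarioSpec,
    apply_scenario,
    average_pmc_from_counts,
    run_sensitivity_table,
    select_sensitive_indicators,
)
from pmckit.synthetic import SyntheticCodingConfig, generate_coding_matrix


@pytest.fixture(scope="module")
def result(study, scale):
    return evaluate_from_first_level(study.scores_thirds, scale)


@pytest.fixture(scope="module")
def profile(study):
    return CoverageProfile(counts=study.counts, n_policies=study.n_policies)


def test_selection_matches_study(result, profile, schema):
    sel = select_sensitive_indicators(result, profile, k_dimensions=3, schema=schema)
    assert sel.dimensions == ("X4", "X6", "X8")
    # per selected dimension, all secondaries tied at the minimum coverage
    assert sel.secondaries == ("X4-2", "X6-1", "X6-2", "X8-3")
    # X8-3 has the lowest coverage of all 27 indicators
    assert min(profile.counts, key=profile.counts.get) == "X8-3"


def test_selection_tie_break_schema_order(schema, scale, study):
    uniform = study.scores_thirds.copy()
    uniform[:] = 2
    res = evaluate_from_first_level(uniform, scale)
    prof = CoverageProfile(counts={c: 10 for c in schema.secondary_codes}, n_policies=22)
    sel = select_sensitive_indicators(res, prof, k_dimensions=2, schema=schema)
    assert sel.dimensions == ("X1", "X2")


def test_selection_caps_k_with_warning(result, profile, schema):
    with pytest.warns(UserWarning):
        sel = select_sensitive_indicators(result, profile, k_dimensions=99, schema=schema)
    assert len(sel.dimensions) == 9


@pytest.mark.parametrize(
    "kind, mode, expected",
    [
        ("full", None, Fraction(22)),
        ("partial", "expected_value", Fraction(52, 5)),  # 8 x 1.3 = 10.4
        ("partial", "round_down", Fraction(10)),
        ("partial", "round_up", Fraction(11)),
        ("baseline", None, Fraction(8)),
    ],
)
def test_apply_scenario_counts(study, kind, mode, expected):
    spec = ScenarioSpec("X6-1", kind, mode=mode or "expected_value")
    out = apply_scenario(study.counts, spec, n_policies=22)
    assert out["X6-1"] == expected
    # untouched indicators keep their counts
    assert out["X1-1"] == study.counts["X1-1"]


def test_saturated_partial_is_noop_with_warning(study):
    spec = ScenarioSpec("X9-2", "partial")
    with pytest.warns(UserWarning):
        out = apply_scenario(study.counts, spec, n_policies=22)
    assert out["X9-2"] == 22


def test_unknown_code_rejected(study):
    with pytest.raises(KeyError):
        apply_scenario(study.counts, ScenarioSpec("X0-0", "full"), n_policies=22)


def test_stochastic_mode_requires_seed():
    with pytest.raises(ValueError):
        ScenarioSpec("X6-1", "partial", mode="stochastic")


def test_scenario_table_matches_study(study, scale):
    """Full-optimisation column 6.50/6.50/6.50/6.61 and partial X6-1 6.32."""
    table = run_sensitivity_table(
        study.counts, study.n_policies, ["X4-2", "X6-1", "X6-2", "X8-3"], scale
    )
    assert table["baseline"].tolist() == [6.29] * 4
    assert table["full"].tolist() == [6.50, 6.50, 6.50, 6.61]
    assert table.set_index("target").loc["X6-1", "partial"] == 6.32
    assert not table["grade_changed"].any()
    assert (table["baseline_grade"] == "Excellent").all()


def test_full_optimisation_closed_form(study):
    """Δ(average) = (n - count)/(3n), exactly."""
    base = average_pmc_from_counts(study.counts, 22)
    for code, count in study.counts.items():
        out = apply_scenario(study.counts, ScenarioSpec(code, "full"), n_policies=22)
        delta = average_pmc_from_counts(out, 22) - base
        assert delta == Fraction(22 - count, 66)


def test_scenarios_never_decrease_average(study):
    base = average_pmc_from_counts(study.counts, 22)
    for code in study.counts:
        for kind in ("partial", "full"):
            out = apply_scenario(study.counts, ScenarioSpec(code, kind), n_policies=22)
            avg = average_pmc_from_counts(out, 22)
            assert avg >= base
            if study.counts[code] == 22:
                assert avg == base  # saturation: equality


def test_matrix_scenarios_deterministic_and_seeded(study, schema):
    config = SyntheticCodingConfig(
        n_policies=22, coverage={c: k / 22 for c, k in study.counts.items()},
        seed=3, mode="quota",
    )
    matrix = generate_coding_matrix(config, schema)
    full = apply_scenario(matrix, ScenarioSpec("X6-1", "full"))
    j = matrix.indicator_codes.index("X6-1")
    assert full.values[:, j].sum() == 22
    spec = ScenarioSpec("X6-1", "partial", mode="stochastic", seed=42)
    a = apply_scenario(matrix, spec)
    b = apply_scenario(matrix, spec)
    assert np.array_equal(a.values, b.values)  # bit-identical rerun
    assert a.values[:, j].sum() >= matrix.values[:, j].sum()


def test_stochastic_counts_mean_matches_expectation(study):
    """Across seeds the realised count averages to the expected-value rule."""
    realised = [
        float(apply_scenario(study.counts,
                             ScenarioSpec("X6-1", "partial", mode="stochastic", seed=s),
                             n_policies=22)["X6-1"])
        for s in range(200)
    ]
    assert set(realised) <= {10.0, 11.0}
    assert abs(np.mean(realised) - 10.4) < 0.15  # binomial CI at p=0.4, n=200
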