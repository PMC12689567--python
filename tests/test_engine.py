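"""Exact PMC scoring, grading, ranking and corpus summaries."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmckit.coding import CodingMatrix, reconstruct_matrix
from pmckit.engine import (
    DimensionScore,
    dimension_score,
    evaluate_corpus,
    evaluate_from_first_level,
    pmc_index,
)
from pmckit.rounding import round_half_up


@pytest.mark.parametrize(
    "bits, num", [((1, 1, 0), 2), ((0, 0, 0), 0), ((1, 1, 1), 3)]
)
def test_dimension_score(bits, num, schema):
    s = dimension_score(bits, schema.dimensions[0])
    assert (s.numerator, s.denominator) == (num, 3)
    assert s.display == round_half_up(Fraction(num, 3))


def test_dimension_score_rejects_bad_rows(schema):
    with pytest.raises(ValueError):
        dimension_score((1, 1), schema.dimensions[0])
    with pytest.raises(ValueError):
        dimension_score({"X1-1": 1}, schema.dimensions[0])


def test_pmc_index_exactness(schema):
    # 22/3 displays as 7.33; summing pre-rounded cells would give 7.34
    nums = [3, 3, 3, 1, 3, 3, 2, 2, 2]
    scores = [
        DimensionScore(d, n, 3) for d, n in zip(schema.dimension_codes, nums)
    ]
    pmc = pmc_index(scores, schema)
    assert pmc == Fraction(22, 3)
    assert round_half_up(pmc) == 7.33
    assert sum(round_half_up(Fraction(n, 3)) for n in nums) == pytest.approx(7.34)


def test_pmc_index_validates_dimensions(schema):
    scores = [DimensionScore(d, 3, 3) for d in schema.dimension_codes[:-1]]
    with pytest.raises(ValueError):
        pmc_index(scores, schema)
    assert pmc_index([DimensionScore(d, 3, 3) for d in schema.dimension_codes]) == 9


def test_corpus_summary_matches_published_table(study, scale):
    """The packaged 22-policy corpus reproduces the published scorecard."""
    res = evaluate_from_first_level(study.scores_thirds, scale)
    assert res.average_pmc_display == 6.29
    assert res.average_grade == "Excellent"
    assert res.grade_histogram == {
        "Poor": 0, "Acceptable": 4, "Good": 2, "Excellent": 8, "Superb": 6, "Perfect": 2,
    }
    by_id = {c.policy_id: c for c in res.scorecards}
    assert by_id["P11"].pmc_display == 8.00 and by_id["P11"].grade == "Perfect"
    assert by_id["P11"].rank == 1  # 8.00 tie with P6 broken by input order
    assert by_id["P6"].rank == 2
    assert by_id["P2"].pmc_display == 7.33 and by_id["P2"].grade == "Superb"
    assert by_id["P12"].pmc_display == 7.00 and by_id["P12"].grade == "Superb"
    avgs = {d: round_half_up(v) for d, v in res.dimension_averages.items()}
    assert avgs == {
        "X1": 0.76, "X2": 0.76, "X3": 0.80, "X4": 0.53, "X5": 0.65,
        "X6": 0.45, "X7": 0.85, "X8": 0.59, "X9": 0.89,
    }


def test_rank_consistency(study, scale):
    res = evaluate_from_first_level(study.scores_thirds, scale)
    ranks = [c.rank for c in res.scorecards]
    assert ranks == list(range(1, 23))
    pmcs = [c.pmc for c in res.scorecards]
    assert all(a >= b for a, b in zip(pmcs, pmcs[1:]))


def test_single_all_zero_policy(schema, scale):
    matrix = CodingMatrix(("p1",), tuple(schema.secondary_codes),
                          np.zeros((1, 27), dtype=int))
    res = evaluate_corpus(matrix, schema, scale)
    card = res.scorecards[0]
    assert card.pmc == 0 and card.grade == "Poor" and card.rank == 1


def test_path_equivalence(study, schema, scale):
    """Matrix-level and first-level evaluation agree exactly on any feasible witness."""
    matrix = reconstruct_matrix(study.scores_thirds, study.counts, schema)
    res_m = evaluate_corpus(matrix, schema, scale)
    res_s = evaluate_from_first_level(study.scores_thirds, scale, schema)
    assert res_m.average_pmc == res_s.average_pmc
    for a, b in zip(res_m.scorecards, res_s.scorecards):
        assert (a.policy_id, a.pmc, a.grade, a.rank) == (b.policy_id, b.pmc, b.grade, b.rank)


def test_conservation(study, scale):
    """Per policy pmc x 3 = its ones; corpus average = total ones / (3 n)."""
    res = evaluate_from_first_level(study.scores_thirds, scale)
    for card in res.scorecards:
        assert card.pmc * 3 == sum(s.numerator for s in card.scores)
    assert res.average_pmc == Fraction(study.total_ones, 3 * study.n_policies)
    assert study.total_ones == 415


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    data=st.data(),
    row=st.lists(st.integers(0, 1), min_size=27, max_size=27),
)
def test_single_bit_flip_raises_pmc_by_a_third(data, row, schema, scale):
    """Flipping any single 0 to 1 increases that policy's PMC by exactly 1/3."""
    values = np.array([row])
    zeros = [j for j, v in enumerate(row) if v == 0]
    if not zeros:
        return
    j = data.draw(st.sampled_from(zeros))
    matrix = CodingMatrix(("p1",), tuple(schema.secondary_codes), values)
    flipped_values = values.copy()
    flipped_values[0, j] = 1
    flipped = CodingMatrix(("p1",), tuple(schema.secondary_codes), flipped_values)
    before = evaluate_corpus(matrix, schema, scale).scorecards[0].pmc
    after = evaluate_corpus(flipped, schema, scale).scorecards[0].pmc
    assert after - before == Fraction(1, 3)


def test_first_level_rejects_non_third_displays(scale, schema):
    table = pd.DataFrame({d: [0.5] for d in schema.dimension_codes}, index=["p1"])
    with pytest.raises(ValueError):
        evaluate_from_first_level(table, scale, schema, thirds=False)
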