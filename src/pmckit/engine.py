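"""PMC scoring engine: dimension means, index, grades, ranks, corpus summaries.

The PMC (Policy Modeling Consistency) index of a policy is

    PMC = sum_i ( sum_j X_ij / T_i )

where ``X_ij`` in {0, 1} codes whether the policy addresses criterion j of
dimension i and ``T_i`` is the number of criteria in dimension i.  With the
default 9x3 system the index ranges over [0, 9] in steps of 1/3.

All arithmetic is exact: dimension scores are integer numerators over small
denominators and the index is a :class:`fractions.Fraction`.  Two-decimal
half-up rounding is applied only for display, which is what makes sums of
scores printed as 0.33/0.67 come out right (e.g. a policy with 22/3 prints
7.33, not the 7.34 that summing rounded cells would give).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coding import CodingMatrix
from .rounding import round_half_up, third_from_display
from .schema import Dimension, GradeScale, IndicatorSchema, default_grade_scale, default_schema

__all__ = [
    "DimensionScore",
    "PolicyScoreCard",
    "EvaluationResult",
    "dimension_score",
    "pmc_index",
    "evaluate_corpus",
    "evaluate_from_first_level",
    "parse_first_level_scores",
]


@dataclass(frozen=True)
class DimensionScore:
    """Exact score of one dimension: satisfied criteria over criterion count."""

    code: str
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError(
                f"{self.code}: numerator {self.numerator} outside 0..{self.denominator}"
            )

    @property
    def value(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    @property
    def display(self) -> float:
        return round_half_up(self.value)


@dataclass
class PolicyScoreCard:
    """Per-policy dimension scores, exact PMC index, grade and rank."""

    policy_id: str
    scores: tuple[DimensionScore, ...]
    grade: str = ""
    rank: int = 0

    @property
    def pmc(self) -> Fraction:
        return sum((s.value for s in self.scores), Fraction(0))

    @property
    def pmc_display(self) -> float:
        return round_half_up(self.pmc)

    def score(self, code: str) -> DimensionScore:
        for s in self.scores:
            if s.code == code:
                return s
        raise KeyError(code)


@dataclass
class EvaluationResult:
    """Ranked scorecards plus corpus-level summaries."""

    scorecards: list[PolicyScoreCard]
    dimension_averages: dict[str, Fraction]
    average_pmc: Fraction
    grade_histogram: dict[str, int]
    scale: GradeScale = field(default_factory=default_grade_scale)

    @property
    def n_policies(self) -> int:
        return len(self.scorecards)

    @property
    def average_pmc_display(self) -> float:
        return round_half_up(self.average_pmc)

    @property
    def average_grade(self) -> str:
        return self.scale.classify(self.average_pmc)

    def to_frame(self) -> pd.DataFrame:
        """Scorecard table: policy, per-dimension 2-dp scores, Sum, Rank, Performance."""
        dims = [s.code for s in self.scorecards[0].scores]
        rows = [
            {
                "policy_id": c.policy_id,
                **{s.code: s.display for s in c.scores},
                "Sum": c.pmc_display,
                "Rank": c.rank,
                "Performance": c.grade,
            }
            for c in self.scorecards
        ]
        avg = {
            "policy_id": "Average",
            **{d: round_half_up(self.dimension_averages[d]) for d in dims},
            "Sum": self.average_pmc_display,
            "Rank": pd.NA,
            "Performance": self.average_grade,
        }
        return pd.DataFrame(rows + [avg])

    def summary(self) -> dict:
        return {
            "n_policies": self.n_policies,
            "average_pmc": self.average_pmc_display,
            "average_grade": self.average_grade,
            "dimension_averages": {
                d: round_half_up(v) for d, v in self.dimension_averages.items()
            },
            "grade_histogram": dict(self.grade_histogram),
        }


def dimension_score(row: Mapping[str, int] | Sequence[int], dimension: Dimension) -> DimensionScore:
    """Mean of a dimension's binary criteria, held exactly.

    ``row`` is either a mapping from secondary code to 0/1 or a sequence in
    the dimension's criterion order.
    """
    if isinstance(row, Mapping):
        try:
            values = [int(row[s.code]) for s in dimension.secondaries]
        except KeyError as exc:
            raise ValueError(f"missing value for secondary {exc.args[0]}") from exc
    else:
        values = [int(v) for v in row]
        if len(values) != dimension.size:
            raise ValueError(
                f"{dimension.code}: expected {dimension.size} values, got {len(values)}"
            )
    if any(v not in (0, 1) for v in values):
        raise ValueError(f"{dimension.code}: non-binary criterion value")
    return DimensionScore(dimension.code, numerator=sum(values), denominator=dimension.size)


def pmc_index(scores: Sequence[DimensionScore], schema: IndicatorSchema | None = None) -> Fraction:
    """Exact PMC index: the sum of the dimension scores.

    If ``schema`` is given, requires exactly one score per schema dimension.
    """
    if schema is not None:
        got = [s.code for s in scores]
        if sorted(got) != sorted(schema.dimension_codes) or len(set(got)) != len(got):
            raise ValueError(
                f"need exactly one score per dimension {schema.dimension_codes}, got {got}"
            )
    return sum((s.value for s in scores), Fraction(0))


def _finalize(cards: list[PolicyScoreCard], scale: GradeScale) -> EvaluationResult:
    # rank by exact pmc descending; ties keep input order (stable sort)
    cards = sorted(cards, key=lambda c: -c.pmc)
    for rank, card in enumerate(cards, start=1):
        card.rank = rank
        card.grade = scale.classify(card.pmc)
    n = len(cards)
    dims = [s.code for s in cards[0].scores]
    dim_avgs = {
        d: sum((c.score(d).value for c in cards), Fraction(0)) / n for d in dims
    }
    avg = sum((c.pmc for c in cards), Fraction(0)) / n
    hist = Counter(c.grade for c in cards)
    histogram = {label: hist.get(label, 0) for label in scale.labels}
    return EvaluationResult(
        scorecards=cards,
        dimension_averages=dim_avgs,
        average_pmc=avg,
        grade_histogram=histogram,
        scale=scale,
    )


def evaluate_corpus(
    matrix: CodingMatrix,
    schema: IndicatorSchema | None = None,
    scale: GradeScale | None = None,
) -> EvaluationResult:
    """Score every policy in a coding matrix and summarise the corpus."""
    schema = schema or default_schema()
    scale = scale or default_grade_scale()
    if not matrix.conforms_to(schema):
        raise ValueError("coding matrix columns do not match the schema")
    frame = matrix.to_frame()
    cards = []
    for pid, row in frame.iterrows():
        scores = tuple(dimension_score(row.to_dict(), dim) for dim in schema.dimensions)
        cards.append(PolicyScoreCard(policy_id=str(pid), scores=scores))
    return _finalize(cards, scale)


def parse_first_level_scores(
    table: pd.DataFrame, schema: IndicatorSchema | None = None
) -> pd.DataFrame:
    """Convert a displayed first-level score table to exact integer numerators.

    Input cells are two-decimal displays of k/T (with the default system,
    multiples of 1/3 shown as 0.00/0.33/0.67/1.00); output cells are the
    integers k.  Raises ``ValueError`` on any cell that is not a display of
    an admissible score.
    """
    schema = schema or default_schema()
    out = {}
    for dim in schema.dimensions:
        if dim.code not in table.columns:
            raise ValueError(f"score table missing dimension {dim.code}")
        if dim.size != 3:
            raise ValueError(
                "display parsing assumes 3 criteria per dimension; "
                f"{dim.code} has {dim.size}"
            )
        out[dim.code] = [third_from_display(v) for v in table[dim.code]]
    return pd.DataFrame(out, index=table.index)


def evaluate_from_first_level(
    scores_table: pd.DataFrame,
    scale: GradeScale | None = None,
    schema: IndicatorSchema | None = None,
    *,
    thirds: bool | None = None,
) -> EvaluationResult:
    """Evaluate directly from per-policy dimension scores.

    ``scores_table`` is policies x dimensions, holding either integer
    numerators 0..T (``thirds=True``) or two-decimal displays such as 0.67
    (``thirds=False``); by default integer dtypes are treated as numerators.
    Contract identical to :func:`evaluate_corpus` on any coding matrix with
    matching dimension sums.
    """
    schema = schema or default_schema()
    scale = scale or default_grade_scale()
    if thirds is None:
        thirds = all(
            pd.api.types.is_integer_dtype(scores_table[d.code])
            for d in schema.dimensions
            if d.code in scores_table.columns
        )
    numerators = (
        scores_table if thirds else parse_first_level_scores(scores_table, schema)
    )
    cards = []
    for pid, row in numerators.iterrows():
        scores = tuple(
            DimensionScore(dim.code, numerator=int(row[dim.code]), denominator=dim.size)
            for dim in schema.dimensions
        )
        cards.append(PolicyScoreCard(policy_id=str(pid), scores=scores))
    return _finalize(cards, scale)
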