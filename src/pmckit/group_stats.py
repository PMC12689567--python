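"""Within-dimension consistency statistics.

For each first-level dimension the three binary criterion columns form a
3x2 contingency table (rows = criteria, columns = ones/zeros counts over
the n policies).  A Pearson chi-square homogeneity test on this table asks
whether the criteria are covered at significantly different rates: a small
p-value marks a dimension with one dominant criterion, a large one marks a
dimension whose criteria are uniformly high or uniformly low.  No
continuity correction is applied.  Per-criterion summaries report the mean
(coverage rate) and the n-1 sample standard deviation of the binary
column, sqrt(n p (1-p) / (n-1)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .coding import CodingMatrix
from .schema import IndicatorSchema, default_schema

__all__ = [
    "ContingencyTable",
    "ChiSqResult",
    "within_dimension_table",
    "pearson_chisq",
    "indicator_summary",
    "dimension_chisq_frame",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Criteria x {ones, zeros} counts for one dimension."""

    dimension: str
    codes: tuple[str, ...]
    ones: tuple[int, ...]
    n_policies: int

    def __post_init__(self) -> None:
        for code, k in zip(self.codes, self.ones):
            if not 0 <= k <= self.n_policies:
                raise ValueError(f"{code}: count {k} outside 0..{self.n_policies}")

    @property
    def zeros(self) -> tuple[int, ...]:
        return tuple(self.n_policies - k for k in self.ones)

    def as_array(self) -> np.ndarray:
        return np.array([[k, self.n_policies - k] for k in self.ones], dtype=int)


@dataclass(frozen=True)
class ChiSqResult:
    dimension: str
    statistic: float
    df: int
    p_value: float
    degenerate: bool = False


def within_dimension_table(
    source: CodingMatrix | Mapping[str, int],
    dimension_code: str,
    n_policies: int | None = None,
    schema: IndicatorSchema | None = None,
) -> ContingencyTable:
    """Contingency table for one dimension from a matrix or a counts mapping."""
    schema = schema or default_schema()
    dim = schema.dimension(dimension_code)
    if isinstance(source, CodingMatrix):
        counts = source.column_counts()
        n_policies = source.n_policies
    else:
        counts = dict(source)
        if n_policies is None:
            raise ValueError("n_policies is required for counts input")
    try:
        ones = tuple(int(counts[s.code]) for s in dim.secondaries)
    except KeyError as exc:
        raise ValueError(f"missing count for secondary {exc.args[0]}") from exc
    return ContingencyTable(
        dimension=dim.code,
        codes=tuple(s.code for s in dim.secondaries),
        ones=ones,
        n_policies=n_policies,
    )


def pearson_chisq(table: ContingencyTable) -> ChiSqResult:
    """Pearson chi-square homogeneity test, no continuity correction.

    A table with an all-zero column (every criterion saturated, or none
    covered) has no variation to test; the statistic is defined as 0 with
    p = 1 and a warning.  Expected counts below 5 warn but do not block —
    small evaluation corpora routinely violate the rule of thumb.
    """
    arr = table.as_array()
    df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    col_totals = arr.sum(axis=0)
    if (col_totals == 0).any():
        warnings.warn(
            f"{table.dimension}: a column total is zero; statistic defined as 0"
        )
        return ChiSqResult(table.dimension, 0.0, df, 1.0, degenerate=True)
    expected = np.outer(arr.sum(axis=1), col_totals) / arr.sum()
    if (expected < 5).any():
        warnings.warn(
            f"{table.dimension}: expected count below 5; chi-square approximation is rough"
        )
    stat, p, df, _ = chi2_contingency(arr, correction=False)
    return ChiSqResult(table.dimension, float(stat), int(df), float(p))


def indicator_summary(counts: Mapping[str, int], n_policies: int) -> pd.DataFrame:
    """Per-indicator mean and n-1 sample SD of the binary column."""
    if n_policies < 2:
        raise ValueError("sample SD requires n >= 2")
    rows = []
    for code, k in counts.items():
        p = k / n_policies
        sd = math.sqrt(n_policies * p * (1 - p) / (n_policies - 1))
        rows.append({"code": code, "mean": p, "within_sd": sd})
    return pd.DataFrame(rows)


def dimension_chisq_frame(
    counts: Mapping[str, int],
    n_policies: int,
    schema: IndicatorSchema | None = None,
    exclude: tuple[str, ...] = (),
) -> pd.DataFrame:
    """One chi-square row per dimension; ``exclude`` skips dimensions whose
    counts are not attested (e.g. imputed splits)."""
    schema = schema or default_schema()
    rows = []
    for dim in schema.dimensions:
        if dim.code in exclude:
            continue
        table = within_dimension_table(counts, dim.code, n_policies, schema)
        res = pearson_chisq(table)
        rows.append(
            {
                "dimension": res.dimension,
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)
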