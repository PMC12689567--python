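"""Binary coding matrices: data model, CSV I/O, coverage accounting, and
feasible-matrix reconstruction from marginals.

A coding matrix records, for each policy document and each second-level
criterion, whether the policy text explicitly addresses the criterion
(1) or not (0).  Coverage of a criterion is the fraction of policies coded
1 on it.

Full policy-by-criterion matrices are rarely published; evaluations usually
print only the per-policy dimension scores and the per-criterion means.
``counts_from_means`` and ``reconstruct_matrix`` recover a feasible binary
matrix from exactly those marginals, which suffices for every PMC-level
quantity (all of which depend on the marginals only).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import IndicatorSchema

__all__ = [
    "CodingError",
    "CodingMatrix",
    "CoverageProfile",
    "read_coding_matrix",
    "write_coding_matrix",
    "coverage_rates",
    "counts_from_means",
    "reconstruct_matrix",
]


class CodingError(ValueError):
    """Invalid coding data: non-binary cells, schema mismatch, infeasible marginals."""


@dataclass(frozen=True)
class CodingMatrix:
    """Policies x second-level indicators, every cell 0 or 1."""

    policy_ids: tuple[str, ...]
    indicator_codes: tuple[str, ...]
    values: np.ndarray  # shape (n_policies, n_indicators), dtype int8

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != (len(self.policy_ids), len(self.indicator_codes)):
            raise CodingError(
                f"value grid shape {vals.shape} does not match "
                f"{len(self.policy_ids)} policies x {len(self.indicator_codes)} indicators"
            )
        if len(set(self.policy_ids)) != len(self.policy_ids):
            raise CodingError("policy ids are not unique")
        if len(set(self.indicator_codes)) != len(self.indicator_codes):
            raise CodingError("indicator codes are not unique")
        bad = np.argwhere(~np.isin(vals, (0, 1)))
        if bad.size:
            r, c = bad[0]
            raise CodingError(
                f"non-binary cell at policy {self.policy_ids[r]!r}, "
                f"indicator {self.indicator_codes[c]!r}: {vals[r, c]!r}"
            )
        object.__setattr__(self, "values", vals.astype(np.int8))

    @property
    def n_policies(self) -> int:
        return len(self.policy_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.policy_ids, name="policy_id"),
            columns=list(self.indicator_codes),
        )

    def column_counts(self) -> dict[str, int]:
        return dict(zip(self.indicator_codes, self.values.sum(axis=0).tolist()))

    def conforms_to(self, schema: IndicatorSchema) -> bool:
        return list(self.indicator_codes) == schema.secondary_codes

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CodingMatrix":
        return cls(
            policy_ids=tuple(str(i) for i in frame.index),
            indicator_codes=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(),
        )


@dataclass(frozen=True)
class CoverageProfile:
    """Per-indicator ones-counts and coverage rates over a corpus of n policies."""

    counts: Mapping[str, int]
    n_policies: int

    def rate(self, code: str) -> Fraction:
        return Fraction(self.counts[code], self.n_policies)

    def rates(self) -> dict[str, Fraction]:
        return {c: self.rate(c) for c in self.counts}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "code": list(self.counts),
                "count": list(self.counts.values()),
                "n": self.n_policies,
                "coverage": [float(self.rate(c)) for c in self.counts],
            }
        )


def read_coding_matrix(source: str | Path | io.TextIOBase, schema: IndicatorSchema | None = None) -> CodingMatrix:
    """Read a CSV coding matrix (header = indicator codes, first column = policy_id).

    Cells must be exactly 0 or 1; a non-binary or missing cell raises
    :class:`CodingError` naming the offending row and column.  If ``schema``
    is given the columns must match its secondary codes in schema order.
    """
    frame = pd.read_csv(source, dtype=str, comment="#")
    if frame.columns[0] != "policy_id":
        raise CodingError(f"first column must be 'policy_id', got {frame.columns[0]!r}")
    frame = frame.set_index("policy_id")
    values = np.empty(frame.shape, dtype=np.int8)
    for i, pid in enumerate(frame.index):
        for j, code in enumerate(frame.columns):
            cell = frame.iat[i, j]
            if cell not in ("0", "1"):
                raise CodingError(
                    f"non-binary cell at policy {pid!r}, indicator {code!r}: {cell!r}"
                )
            values[i, j] = int(cell)
    matrix = CodingMatrix(
        policy_ids=tuple(str(i) for i in frame.index),
        indicator_codes=tuple(str(c) for c in frame.columns),
        values=values,
    )
    if schema is not None and not matrix.conforms_to(schema):
        raise CodingError(
            "indicator columns do not match the schema's secondary codes in order"
        )
    return matrix


def write_coding_matrix(matrix: CodingMatrix, path: str | Path, header: str | None = None) -> None:
    """Write a coding matrix as CSV, optionally with a leading '#' metadata line."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        if header:
            fh.write(f"# {header}\n")
        matrix.to_frame().to_csv(fh)


def coverage_rates(matrix: CodingMatrix) -> CoverageProfile:
    """Exact per-indicator ones-counts and coverage rates."""
    return CoverageProfile(counts=matrix.column_counts(), n_policies=matrix.n_policies)


def counts_from_means(
    means: Sequence[float],
    n: int,
    codes: Sequence[str] | None = None,
    atol: float = 0.005,
) -> list[int]:
    """Recover integer ones-counts from printed per-indicator means.

    Each count is the nearest integer to ``mean * n``; the recovery is
    rejected if the implied rate differs from the printed mean by more than
    ``atol`` (i.e. the mean cannot be a rounding of any count/n).
    """
    if n < 1:
        raise CodingError("n must be >= 1")
    counts = []
    for k, mean in enumerate(means):
        if not 0.0 <= float(mean) <= 1.0:
            label = codes[k] if codes else f"index {k}"
            raise CodingError(f"mean out of [0, 1] for {label}: {mean}")
        count = int(round(float(mean) * n))
        if abs(count / n - float(mean)) > atol:
            label = codes[k] if codes else f"index {k}"
            raise CodingError(
                f"mean {mean} for {label} is inconsistent with any count/{n} "
                f"(nearest count {count} gives {count / n:.4f})"
            )
        counts.append(count)
    return counts


def reconstruct_matrix(
    first_level_thirds: pd.DataFrame,
    counts: Mapping[str, int],
    schema: IndicatorSchema,
) -> CodingMatrix:
    """Build a feasible binary matrix from dimension scores and column counts.

    ``first_level_thirds`` holds, per policy and dimension, the integer
    numerator of the dimension score over its criterion count (0..T); the
    row sum of a policy within a dimension is therefore fixed.  ``counts``
    gives the required column sum for every secondary code.  The problem
    decomposes per dimension into a 0/1 matrix-with-given-marginals fill,
    solved by the classic greedy: process policies in input order and assign
    each policy's ones to the secondaries with the largest remaining column
    demand (ties broken by schema order).  The greedy succeeds whenever the
    marginals are feasible; any feasible witness is acceptable since all
    PMC-level quantities depend on the marginals only.

    Raises :class:`CodingError` naming the dimension if the marginals are
    infeasible (including total mismatch).
    """
    policy_ids = [str(i) for i in first_level_thirds.index]
    columns: dict[str, np.ndarray] = {}
    for dim in schema.dimensions:
        if dim.code not in first_level_thirds.columns:
            raise CodingError(f"score table missing dimension {dim.code}")
        row_sums = first_level_thirds[dim.code].astype(int).to_numpy()
        if ((row_sums < 0) | (row_sums > dim.size)).any():
            raise CodingError(f"dimension {dim.code}: row sums outside 0..{dim.size}")
        try:
            demand = {s.code: int(counts[s.code]) for s in dim.secondaries}
        except KeyError as exc:
            raise CodingError(f"missing count for secondary {exc.args[0]}") from exc
        if sum(demand.values()) != int(row_sums.sum()):
            raise CodingError(
                f"dimension {dim.code}: column counts sum to {sum(demand.values())} "
                f"but scores require {int(row_sums.sum())}"
            )
        block = {code: np.zeros(len(policy_ids), dtype=np.int8) for code in demand}
        order = [s.code for s in dim.secondaries]
        for i, r in enumerate(row_sums):
            # ones go to the r columns with largest remaining demand
            ranked = sorted(order, key=lambda c: (-demand[c], order.index(c)))
            for code in ranked[: int(r)]:
                if demand[code] <= 0:
                    raise CodingError(
                        f"dimension {dim.code}: infeasible marginals "
                        f"(column {code} exhausted at policy {policy_ids[i]})"
                    )
                block[code][i] = 1
                demand[code] -= 1
        if any(v != 0 for v in demand.values()):
            raise CodingError(f"dimension {dim.code}: infeasible marginals (unmet demand)")
        columns.update(block)

    values = np.column_stack([columns[c] for c in schema.secondary_codes])
    matrix = CodingMatrix(
        policy_ids=tuple(policy_ids),
        indicator_codes=tuple(schema.secondary_codes),
        values=values,
    )
    # marginal exactness is asserted on every call
    got = matrix.column_counts()
    assert all(got[c] == int(counts[c]) for c in schema.secondary_codes)
    return matrix
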