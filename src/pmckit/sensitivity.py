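"""Scenario-based sensitivity analysis of the corpus-average PMC.

Stability of an evaluation is probed one indicator at a time: pick the
weakest second-level indicators (lowest coverage within the lowest-scoring
dimensions), then recompute the corpus-average PMC under three
counterfactual coverage scenarios

* baseline — coverage unchanged;
* partial  — coverage raised by a relative fraction (default +30%);
* full     — coverage raised to 100% (every policy codes 1).

Because the average PMC equals (total ones)/(T x n), each scenario has the
closed form  Δ(average PMC) = Δ(ones)/(T x n); full optimisation adds
exactly (n - count) ones.  The verdict is whether the consistency grade
band of the displayed average changes.

The partial scenario's "+30% coverage" is a relative increase of the
ones-count (count x 1.3), which is generally fractional.  The default
``expected_value`` mode keeps the fractional count for analytic averaging;
``round_down``/``round_up`` flip whole policies chosen deterministically in
policy order; ``stochastic`` flips a seeded random subset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coding import CodingMatrix, CoverageProfile
from .engine import EvaluationResult
from .rounding import round_half_up
from .schema import GradeScale, IndicatorSchema, default_grade_scale, default_schema

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "SensitivitySelection",
    "select_sensitive_indicators",
    "apply_scenario",
    "run_sensitivity_table",
    "average_pmc_from_counts",
]

PARTIAL_MODES = ("expected_value", "round_down", "round_up", "stochastic")


@dataclass(frozen=True)
class ScenarioSpec:
    """One counterfactual recoding of a single target indicator."""

    target: str
    kind: str  # baseline | partial | full
    increase: float = 0.30
    mode: str = "expected_value"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("baseline", "partial", "full"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "partial":
            if self.increase <= 0:
                raise ValueError("partial increase fraction must be > 0")
            if self.mode not in PARTIAL_MODES:
                raise ValueError(f"unknown partial mode {self.mode!r}")
            if self.mode == "stochastic" and self.seed is None:
                raise ValueError("stochastic partial mode requires a seed")


@dataclass(frozen=True)
class ScenarioResult:
    target: str
    kind: str
    baseline_pmc: float
    scenario_pmc: float
    baseline_grade: str
    scenario_grade: str
    grade_changed: bool


@dataclass(frozen=True)
class SensitivitySelection:
    """Lowest-scoring dimensions and their lowest-coverage secondaries."""

    dimensions: tuple[str, ...]
    secondaries: tuple[str, ...]


def select_sensitive_indicators(
    result: EvaluationResult,
    profile: CoverageProfile,
    k_dimensions: int = 3,
    k_secondaries: int | None = None,
    schema: IndicatorSchema | None = None,
) -> SensitivitySelection:
    """Pick the k lowest-average dimensions and their minimum-coverage secondaries.

    Within each selected dimension every secondary tied at the dimension's
    minimum coverage is selected; ``k_secondaries`` optionally caps the
    overall list (kept in ascending coverage, ties by schema order).  All
    tie-breaks are deterministic by schema order.
    """
    schema = schema or default_schema()
    if not result.scorecards or not profile.counts:
        raise ValueError("empty evaluation result or coverage profile")
    order = {c: i for i, c in enumerate(schema.dimension_codes)}
    dims_sorted = sorted(
        result.dimension_averages, key=lambda d: (result.dimension_averages[d], order[d])
    )
    if k_dimensions > len(dims_sorted):
        warnings.warn(
            f"k_dimensions={k_dimensions} exceeds {len(dims_sorted)} dimensions; capped"
        )
        k_dimensions = len(dims_sorted)
    chosen_dims = tuple(sorted(dims_sorted[:k_dimensions], key=order.__getitem__))

    sec_order = {c: i for i, c in enumerate(schema.secondary_codes)}
    secondaries: list[str] = []
    for dcode in chosen_dims:
        dim = schema.dimension(dcode)
        cov = {s.code: profile.counts[s.code] for s in dim.secondaries}
        low = min(cov.values())
        secondaries.extend(c for c in cov if cov[c] == low)
    secondaries.sort(key=lambda c: (profile.counts[c], sec_order[c]))
    if k_secondaries is not None:
        if k_secondaries > len(secondaries):
            warnings.warn(
                f"k_secondaries={k_secondaries} exceeds {len(secondaries)} candidates; capped"
            )
        secondaries = secondaries[:k_secondaries]
    secondaries.sort(key=sec_order.__getitem__)
    return SensitivitySelection(dimensions=chosen_dims, secondaries=tuple(secondaries))


def apply_scenario(
    state: Mapping[str, int] | CodingMatrix,
    spec: ScenarioSpec,
    n_policies: int | None = None,
) -> dict[str, Fraction] | CodingMatrix:
    """Apply one scenario to per-indicator counts or to a concrete matrix.

    Counts input returns a new ``{code: Fraction}`` mapping (fractional for
    the expected-value partial mode); matrix input returns a new matrix with
    whole policies flipped.  Raising coverage on a saturated indicator is a
    warning no-op.
    """
    if isinstance(state, CodingMatrix):
        return _apply_to_matrix(state, spec)
    if n_policies is None:
        raise ValueError("n_policies is required for counts input")
    counts = {c: Fraction(v) for c, v in state.items()}
    if spec.target not in counts:
        raise KeyError(f"unknown indicator code {spec.target!r}")
    current = counts[spec.target]
    if spec.kind == "baseline":
        return counts
    if current >= n_policies and spec.kind in ("partial", "full"):
        if spec.kind == "partial":
            warnings.warn(f"{spec.target} is saturated; partial increase is a no-op")
        counts[spec.target] = Fraction(n_policies)
        return counts
    if spec.kind == "full":
        counts[spec.target] = Fraction(n_policies)
        return counts
    raised = current * (1 + Fraction(spec.increase).limit_denominator(10**6))
    raised = min(raised, Fraction(n_policies))
    if spec.mode == "expected_value":
        counts[spec.target] = raised
    elif spec.mode == "round_down":
        counts[spec.target] = Fraction(math.floor(raised))
    elif spec.mode == "round_up":
        counts[spec.target] = Fraction(math.ceil(raised))
    else:  # stochastic: realised count is a rounding of the expectation
        rng = np.random.default_rng(spec.seed)
        frac = raised - math.floor(raised)
        counts[spec.target] = Fraction(math.floor(raised) + int(rng.random() < frac))
    return counts


def _apply_to_matrix(matrix: CodingMatrix, spec: ScenarioSpec) -> CodingMatrix:
    if spec.target not in matrix.indicator_codes:
        raise KeyError(f"unknown indicator code {spec.target!r}")
    j = matrix.indicator_codes.index(spec.target)
    values = matrix.values.copy()
    zeros = np.flatnonzero(values[:, j] == 0)
    if spec.kind == "baseline":
        return matrix
    if zeros.size == 0:
        if spec.kind == "partial":
            warnings.warn(f"{spec.target} is saturated; partial increase is a no-op")
        return matrix
    if spec.kind == "full":
        values[:, j] = 1
    else:
        current = int(values[:, j].sum())
        raised = min(current * (1 + spec.increase), matrix.n_policies)
        if spec.mode in ("expected_value", "round_down"):
            # a concrete matrix cannot hold fractional ones; fall back to floor
            extra = math.floor(raised) - current
        elif spec.mode == "round_up":
            extra = math.ceil(raised) - current
        else:
            rng = np.random.default_rng(spec.seed)
            frac = raised - math.floor(raised)
            extra = math.floor(raised) - current + int(rng.random() < frac)
        extra = max(0, min(extra, zeros.size))
        if spec.mode == "stochastic":
            rng = np.random.default_rng(spec.seed)
            flip = rng.choice(zeros, size=extra, replace=False)
        else:
            flip = zeros[:extra]  # deterministic: earliest policies first
        values[flip, j] = 1
    return CodingMatrix(matrix.policy_ids, matrix.indicator_codes, values)


def average_pmc_from_counts(
    counts: Mapping[str, Fraction | int], n_policies: int, criteria_per_dimension: int = 3
) -> Fraction:
    """Corpus-average PMC from per-indicator ones-counts: total/(T x n)."""
    total = sum((Fraction(v) for v in counts.values()), Fraction(0))
    return total / (criteria_per_dimension * n_policies)


def run_sensitivity_table(
    counts: Mapping[str, int],
    n_policies: int,
    targets: Sequence[str],
    scale: GradeScale | None = None,
    increase: float = 0.30,
    mode: str = "expected_value",
    seed: int | None = None,
) -> pd.DataFrame:
    """Baseline / partial / full scenario averages for each target indicator.

    Returns one row per target with the three displayed averages and a flag
    for whether the partial or full grade band differs from baseline (bands
    compared on the displayed two-decimal values).
    """
    scale = scale or default_grade_scale()
    base_avg = average_pmc_from_counts(counts, n_policies)
    base_disp = round_half_up(base_avg)
    base_grade = scale.classify(base_disp)
    rows = []
    for target in targets:
        row = {"target": target, "baseline": base_disp}
        changed = False
        for kind in ("partial", "full"):
            spec = ScenarioSpec(
                target=target, kind=kind, increase=increase, mode=mode, seed=seed
            )
            new_counts = apply_scenario(counts, spec, n_policies=n_policies)
            avg = average_pmc_from_counts(new_counts, n_policies)
            disp = round_half_up(avg)
            row[kind] = disp
            changed = changed or scale.classify(disp) != base_grade
        row["grade_changed"] = changed
        row["baseline_grade"] = base_grade
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["target", "baseline", "partial", "full", "grade_changed", "baseline_grade"]
    )
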