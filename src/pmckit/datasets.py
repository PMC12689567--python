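"""Packaged study dataset: the MQIMP evaluation marginals.

The bundled fixture transcribes the published evaluation of 22 Chinese
medical-quality intelligent-management policies (MQIMPs) against the default
9x3 indicator system.  The full 22x27 binary coding matrix was never
published; what is packaged are the two marginals every PMC-level quantity
depends on:

* ``first_level_scores.csv`` — per-policy dimension scores, printed at two
  decimals and parsed back to exact thirds;
* ``secondary_counts.csv`` — per-criterion ones-counts at n = 22, recovered
  from printed per-criterion means.

The X8 criterion means as printed are internally inconsistent (values
impossible for binary data); the fixture stores the externally attested
X8-3 count of 1 and an imputed X8-1/X8-2 split of (20, 18) — the pair is
constrained to sum to 38 by the X8 dimension column but its split is not
recoverable, so those two rows carry ``imputed = 1`` and are excluded from
chi-square reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path

import pandas as pd

from .engine import parse_first_level_scores
from .rounding import round_half_up
from .schema import IndicatorSchema, default_schema

__all__ = ["StudyFixture", "load_mqimp_fixture"]


class FixtureError(RuntimeError):
    """Packaged fixture failed its load-time self-checks."""


@dataclass(frozen=True)
class StudyFixture:
    """The packaged MQIMP evaluation marginals."""

    #: policies x dimensions, integer numerators of thirds (0..3)
    scores_thirds: pd.DataFrame
    #: secondary code -> ones-count at n policies
    counts: dict[str, int]
    n_policies: int
    #: secondary codes whose counts are imputed, not attested
    imputed: frozenset[str]
    schema: IndicatorSchema

    @property
    def total_ones(self) -> int:
        return sum(self.counts.values())

    @property
    def average_pmc(self) -> Fraction:
        """Corpus-average PMC, exact: total ones / (3 x n policies)."""
        return Fraction(self.total_ones, 3 * self.n_policies)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pmckit").joinpath("data", name)))


def load_mqimp_fixture() -> StudyFixture:
    """Load and self-check the packaged MQIMP marginals.

    Self-checks on every load: per-dimension count totals equal the
    dimension column sums of the score table (in thirds); the grand total
    of ones is 415; and the implied corpus average displays as 6.29.
    """
    schema = default_schema()
    scores = pd.read_csv(_data_path("first_level_scores.csv"), index_col="policy_id")
    thirds = parse_first_level_scores(scores, schema)
    counts_tbl = pd.read_csv(_data_path("secondary_counts.csv"))
    n = int(counts_tbl["n"].iloc[0])
    if (counts_tbl["n"] != n).any():
        raise FixtureError("inconsistent n across count rows")
    counts = dict(zip(counts_tbl["code"], counts_tbl["count"].astype(int)))
    imputed = frozenset(counts_tbl.loc[counts_tbl["imputed"] == 1, "code"])

    if list(counts) != schema.secondary_codes:
        raise FixtureError("count rows do not match the schema's secondary codes")
    if len(thirds) != n:
        raise FixtureError(f"score table has {len(thirds)} policies, counts say n={n}")
    for dim in schema.dimensions:
        col_total = int(thirds[dim.code].sum())
        cnt_total = sum(counts[s.code] for s in dim.secondaries)
        if col_total != cnt_total:
            raise FixtureError(
                f"dimension {dim.code}: score column sums to {col_total} thirds "
                f"but secondary counts sum to {cnt_total}"
            )
    total = sum(counts.values())
    if total != 415:
        raise FixtureError(f"fixture total ones {total} != 415")
    if round_half_up(Fraction(total, 3 * n)) != 6.29:
        raise FixtureError("fixture corpus average does not display as 6.29")
    return StudyFixture(
        scores_thirds=thirds,
        counts=counts,
        n_policies=n,
        imputed=imputed,
        schema=schema,
    )
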