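"""Indicator system and grade scale: declarative definition, validation, loading.

A PMC evaluation runs over a two-level indicator system: first-level
*dimensions* (X1..X9 in the default system) each owning a small ordered set
of binary second-level *criteria* (X1-1, X1-2, ...).  A policy's dimension
score is the mean of its binary criteria; the PMC index is the sum of the
dimension scores, so its range is [0, number of dimensions].

The default packaged system has 9 dimensions x 3 criteria = 27 binary
indicators, with uniform weights, and a six-band consistency grade scale
over [0, 9]: Poor, Acceptable, Good, Excellent, Superb, Perfect.

Both the indicator system and the grade scale are data, not code: they load
from YAML/JSON mappings so the toolkit generalises beyond the default 9x3
system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from numbers import Real
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import yaml

__all__ = [
    "SchemaError",
    "Secondary",
    "Dimension",
    "IndicatorSchema",
    "GradeBand",
    "GradeScale",
    "load_schema",
    "load_grade_scale",
    "default_schema",
    "default_grade_scale",
    "classify_grade",
]


class SchemaError(ValueError):
    """Raised when an indicator system or grade scale fails validation."""


@dataclass(frozen=True)
class Secondary:
    """One binary second-level criterion."""

    code: str
    name: str = ""
    criterion: str = ""
    #: Reserved for future weighted aggregation; the default pipeline assumes
    #: uniform weights and ignores this field.
    weight: float = 1.0


@dataclass(frozen=True)
class Dimension:
    """A first-level dimension owning >= 1 second-level criteria."""

    code: str
    name: str = ""
    secondaries: tuple[Secondary, ...] = ()

    @property
    def size(self) -> int:
        """Number of second-level criteria (the T in the per-dimension mean)."""
        return len(self.secondaries)


@dataclass(frozen=True)
class IndicatorSchema:
    """Validated two-level indicator system."""

    dimensions: tuple[Dimension, ...]

    def __post_init__(self) -> None:
        if not self.dimensions:
            raise SchemaError("schema has no dimensions")
        dim_codes = [d.code for d in self.dimensions]
        dupes = _duplicates(dim_codes)
        if dupes:
            raise SchemaError(f"duplicate dimension code(s): {sorted(dupes)}")
        sec_codes: list[str] = []
        for dim in self.dimensions:
            if not dim.secondaries:
                raise SchemaError(f"dimension {dim.code!r} has no secondaries")
            for sec in dim.secondaries:
                if not sec.code.startswith(dim.code):
                    raise SchemaError(
                        f"secondary code {sec.code!r} is not prefixed by its "
                        f"dimension code {dim.code!r}"
                    )
                sec_codes.append(sec.code)
        dupes = _duplicates(sec_codes)
        if dupes:
            raise SchemaError(f"duplicate secondary code(s): {sorted(dupes)}")

    @property
    def dimension_codes(self) -> list[str]:
        return [d.code for d in self.dimensions]

    @property
    def secondary_codes(self) -> list[str]:
        return [s.code for d in self.dimensions for s in d.secondaries]

    @property
    def n_dimensions(self) -> int:
        return len(self.dimensions)

    @property
    def n_secondaries(self) -> int:
        return sum(d.size for d in self.dimensions)

    @property
    def max_pmc(self) -> int:
        """Upper end of the PMC range (one point per dimension)."""
        return len(self.dimensions)

    def dimension(self, code: str) -> Dimension:
        for d in self.dimensions:
            if d.code == code:
                return d
        raise KeyError(code)

    def dimension_of(self, secondary_code: str) -> Dimension:
        """The dimension owning a given secondary code."""
        for d in self.dimensions:
            if any(s.code == secondary_code for s in d.secondaries):
                return d
        raise KeyError(secondary_code)


@dataclass(frozen=True)
class GradeBand:
    label: str
    lower: Fraction
    upper: Fraction


@dataclass(frozen=True)
class GradeScale:
    """Contiguous grade bands covering [0, max].

    Bands are lower-inclusive / upper-exclusive; the top band also includes
    its upper endpoint so the maximum score is classifiable.  This is the
    only convention under which a score sitting exactly on an interior
    boundary (e.g. 8.00 with bands ...[7,8),[8,9]) lands in the higher band.
    """

    bands: tuple[GradeBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise SchemaError("grade scale has no bands")
        prev_upper = self.bands[0].lower
        for band in self.bands:
            if band.upper <= band.lower:
                raise SchemaError(f"band {band.label!r} is empty or inverted")
            if band.lower != prev_upper:
                raise SchemaError(
                    f"bands are not contiguous at {band.label!r} "
                    f"(expected lower {prev_upper}, got {band.lower})"
                )
            prev_upper = band.upper

    @property
    def minimum(self) -> Fraction:
        return self.bands[0].lower

    @property
    def maximum(self) -> Fraction:
        return self.bands[-1].upper

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.bands]

    def classify(self, value: Real | Fraction) -> str:
        return classify_grade(value, self)

    def band_index(self, value: Real | Fraction) -> int:
        v = _as_fraction(value)
        if v < self.minimum or v > self.maximum:
            raise ValueError(
                f"value {float(v):g} outside grade range "
                f"[{float(self.minimum):g}, {float(self.maximum):g}]"
            )
        for i, band in enumerate(self.bands):
            if band.lower <= v < band.upper:
                return i
        return len(self.bands) - 1  # == maximum: closed top band


def classify_grade(value: Real | Fraction, scale: GradeScale | None = None) -> str:
    """Grade label for a PMC value under the band convention above.

    Raises ``ValueError`` if the value falls outside the scale's range.
    """
    scale = scale or default_grade_scale()
    return scale.bands[scale.band_index(value)].label


def _as_fraction(value: Real | Fraction) -> Fraction:
    if isinstance(value, Fraction):
        return value
    return Fraction(value).limit_denominator(10**9)


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _load_mapping(source: str | Path | Mapping[str, Any]) -> Mapping[str, Any]:
    if isinstance(source, Mapping):
        return source
    text = Path(source).read_text(encoding="utf-8")
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, Mapping):
        raise SchemaError(f"config {source!s} does not parse to a mapping")
    return data


def load_schema(source: str | Path | Mapping[str, Any]) -> IndicatorSchema:
    """Load and validate an indicator system from YAML/JSON or a mapping.

    Expected shape::

        dimensions:
          - code: X1
            name: ...
            secondaries:
              - {code: X1-1, name: ..., criterion: ...}
    """
    data = _load_mapping(source)
    try:
        raw_dims: Sequence[Mapping[str, Any]] = data["dimensions"]
    except KeyError as exc:
        raise SchemaError("missing required key 'dimensions'") from exc
    dims = []
    for rd in raw_dims:
        if "code" not in rd:
            raise SchemaError("dimension entry missing 'code'")
        secs = tuple(
            Secondary(
                code=rs["code"],
                name=rs.get("name", ""),
                criterion=rs.get("criterion", ""),
                weight=float(rs.get("weight", 1.0)),
            )
            for rs in rd.get("secondaries", ())
        )
        dims.append(Dimension(code=rd["code"], name=rd.get("name", ""), secondaries=secs))
    return IndicatorSchema(dimensions=tuple(dims))


def load_grade_scale(source: str | Path | Mapping[str, Any]) -> GradeScale:
    """Load a grade scale: ``bands: [{label, lower, upper}, ...]``."""
    data = _load_mapping(source)
    try:
        raw = data["bands"]
    except KeyError as exc:
        raise SchemaError("missing required key 'bands'") from exc
    bands = tuple(
        GradeBand(
            label=rb["label"],
            lower=_as_fraction(rb["lower"]),
            upper=_as_fraction(rb["upper"]),
        )
        for rb in raw
    )
    return GradeScale(bands=bands)


def _packaged(name: str) -> Path:
    return Path(str(resources.files("pmckit").joinpath("data", name)))


def default_schema() -> IndicatorSchema:
    """The packaged 9x3 MQIMP indicator system."""
    return load_schema(_packaged("indicator_schema.yaml"))


def default_grade_scale() -> GradeScale:
    """The packaged six-band scale over [0, 9]."""
    return load_grade_scale(_packaged("grade_scale.yaml"))
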