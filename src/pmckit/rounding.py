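"""Exact-rational display helpers.

PMC arithmetic is carried exactly (integer counts of satisfied criteria over
small denominators); rounding happens only at presentation.  Two-decimal
display uses half-up rounding, the convention under which 22/3 prints as
7.33 and thirds print as 0.33 / 0.67.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from numbers import Real

__all__ = ["round_half_up", "fmt2", "third_from_display", "THIRD_DISPLAYS"]

#: Two-decimal renderings of the admissible per-dimension scores k/3, k=0..3.
THIRD_DISPLAYS = {"0.00": 0, "0.33": 1, "0.67": 2, "1.00": 3}


def _to_decimal(x: Real | Fraction) -> Decimal:
    if isinstance(x, Fraction):
        return Decimal(x.numerator) / Decimal(x.denominator)
    if isinstance(x, int):
        return Decimal(x)
    return Decimal(repr(float(x)))


def round_half_up(x: Real | Fraction, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals, exactly for rationals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(_to_decimal(x).quantize(q, rounding=ROUND_HALF_UP))


def fmt2(x: Real | Fraction) -> str:
    """Two-decimal string under half-up rounding (e.g. Fraction(2,3) -> '0.67')."""
    q = Decimal("0.01")
    return str(_to_decimal(x).quantize(q, rounding=ROUND_HALF_UP))


def third_from_display(value: Real | str, atol: float = 0.005) -> int:
    """Map a two-decimal display of k/3 back to the exact numerator k.

    Accepts the canonical strings '0.00'/'0.33'/'0.67'/'1.00' or numbers
    within ``atol`` of a third; raises ``ValueError`` otherwise.  This undoes
    the display rounding of score tables so downstream sums stay exact.
    """
    if isinstance(value, str):
        value = float(value)
    for k in range(4):
        if abs(float(value) - round_half_up(Fraction(k, 3))) <= atol:
            return k
    raise ValueError(f"{value!r} is not a two-decimal display of a third")
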