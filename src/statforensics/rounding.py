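"""Exact arithmetic for printed decimal values.

A statistic printed as ``4.27`` at precision 0.01 does not denote a single real
number: it stands for every true value in the half-interval ``[4.265, 4.275]``.
Both endpoints are treated as *inclusive*, because a value landing exactly on a
rounding boundary (e.g. 0.125 printed to two decimals) may legitimately have
been rounded either up or down.  This convention is deliberately conservative:
it can only make a reported value easier, never harder, to explain.

All interval endpoints and granularity computations are carried out in exact
base-10 arithmetic (`decimal.Decimal` for printed values, `fractions.Fraction`
for derived quantities).  Binary floating point is never used for interval
membership, so values sitting exactly on representational boundaries cannot be
flagged spuriously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, InvalidOperation
from fractions import Fraction

from .errors import InvalidInputError

__all__ = [
    "RoundedValue",
    "as_decimal",
    "infer_precision",
    "achievable_roundings",
    "round_to_precision",
]


def as_decimal(x) -> Decimal:
    """Convert to Decimal exactly; floats go through their shortest repr."""
    if isinstance(x, Decimal):
        return x
    if isinstance(x, float):
        return Decimal(repr(x))
    try:
        return Decimal(x)
    except (InvalidOperation, TypeError) as exc:
        raise InvalidInputError(f"not a decimal value: {x!r}") from exc


def infer_precision(text: str) -> Decimal:
    """Precision implied by a printed decimal: ``"2.30"`` -> 0.01, ``"2.3"`` -> 0.1.

    Trailing zeros are significant, which is why printed statistics must be
    kept as text until this point.
    """
    d = Decimal(str(text).strip())
    exponent = d.as_tuple().exponent
    if not isinstance(exponent, int) or exponent > 0:
        exponent = 0
    return Decimal(1).scaleb(exponent)


@dataclass(frozen=True)
class RoundedValue:
    """A printed decimal together with its reporting precision.

    Attributes
    ----------
    value:
        The number exactly as printed.
    precision:
        The decimal step of the report, e.g. 0.01 for two decimal places or
        0.1 for percentages printed with one decimal.
    """

    value: Decimal
    precision: Decimal = Decimal("0.01")

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", as_decimal(self.value))
        object.__setattr__(self, "precision", as_decimal(self.precision))
        if self.precision <= 0:
            raise InvalidInputError(f"precision must be > 0, got {self.precision}")
        ratio = Fraction(self.value) / Fraction(self.precision)
        if ratio.denominator != 1:
            raise InvalidInputError(
                f"{self.value} is not an integer multiple of precision {self.precision}"
            )

    @classmethod
    def from_text(cls, text: str, precision: Decimal | str | None = None) -> "RoundedValue":
        """Parse a printed decimal, inferring precision from its trailing zeros."""
        value = Decimal(str(text).strip())
        prec = as_decimal(precision) if precision is not None else infer_precision(text)
        return cls(value, prec)

    def interval(self) -> tuple[Fraction, Fraction]:
        """Inclusive interval of true values that print as this value."""
        v = Fraction(self.value)
        half = Fraction(self.precision) / 2
        return (v - half, v + half)

    def contains(self, x: Fraction | int) -> bool:
        lo, hi = self.interval()
        return lo <= x <= hi

    def __str__(self) -> str:  # keep printed form
        return str(self.value)


def achievable_roundings(x: Fraction | int, precision: Decimal | str) -> list[Decimal]:
    """All printed values that the exact quantity ``x`` can round to.

    Usually a single grid point; an exact midpoint yields both neighbours
    (the same both-ways convention as :meth:`RoundedValue.interval`).
    """
    x = Fraction(x)
    precision = as_decimal(precision)
    p = Fraction(precision)
    k0 = math.floor(x / p)
    out: list[Decimal] = []
    for k in (k0 - 1, k0, k0 + 1):
        if abs(x - k * p) * 2 <= p:
            g = Decimal(k) * precision
            if g not in out:
                out.append(g)
    return out


def round_to_precision(x: Fraction | int, precision: Decimal | str) -> Decimal:
    """Round an exact rational half-away-from-zero to a decimal grid."""
    x = Fraction(x)
    precision = as_decimal(precision)
    p = Fraction(precision)
    q = x / p
    fl = math.floor(q)
    rem = q - fl
    if rem > Fraction(1, 2):
        fl += 1
    elif rem == Fraction(1, 2) and x >= 0:
        fl += 1
    # rem == 1/2 with x < 0 keeps fl (i.e. rounds away from zero)
    return Decimal(fl) * precision
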