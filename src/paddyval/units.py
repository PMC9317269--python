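"""Monetary scale handling and price-index adjustment.

Every valuation in the engine is carried internally as plain CNY at full
floating precision.  The Chinese reporting unit 万 (wàn, 10,000 CNY) and the
English "million"/"billion" scales exist only at the reporting boundary:
source material on agro-ecosystem valuation routinely mixes all four scales,
so the engine makes the scale explicit and impossible to mix silently.

Rounding happens only when a report is rendered; all intermediate arithmetic
is unrounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class YearMismatchError(ValueError):
    """Two monetary quantities with different reference years were combined."""


#: CNY per unit of each reporting scale.
SCALE_FACTORS: dict[str, float] = {
    "CNY": 1.0,
    "wan": 1e4,       # 万 = 10,000 CNY
    "million": 1e6,
    "billion": 1e9,
}


@dataclass(frozen=True, slots=True)
class Money:
    """An amount of money in CNY tied to a price reference year.

    ``amount`` may be negative (a net debit, e.g. greenhouse-gas emissions
    exceeding fixation).  Arithmetic between two ``Money`` values requires
    matching reference years.
    """

    amount: float
    reference_year: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.amount):
            raise ValueError(f"Money amount must be finite, got {self.amount}")

    def _check_year(self, other: "Money") -> None:
        if self.reference_year != other.reference_year:
            raise YearMismatchError(
                f"cannot combine CNY amounts referenced to {self.reference_year} "
                f"and {other.reference_year}; adjust by a price index first"
            )

    def __add__(self, other: "Money") -> "Money":
        self._check_year(other)
        return Money(self.amount + other.amount, self.reference_year)

    def __sub__(self, other: "Money") -> "Money":
        self._check_year(other)
        return Money(self.amount - other.amount, self.reference_year)

    def __neg__(self) -> "Money":
        return Money(-self.amount, self.reference_year)

    def __mul__(self, factor: float) -> "Money":
        return Money(self.amount * factor, self.reference_year)

    __rmul__ = __mul__


@dataclass(frozen=True, slots=True)
class PriceIndexRatio:
    """Multiplicative price-index ratio carrying a value from one year to another.

    Published price indices are usually available only as before/after value
    pairs, so the ratio itself is a configuration input, not something the
    engine computes.
    """

    source_year: int
    target_year: int
    ratio: float

    def __post_init__(self) -> None:
        if not (self.ratio > 0 and math.isfinite(self.ratio)):
            raise ValueError(f"price-index ratio must be a positive finite number, got {self.ratio}")
        if self.source_year == self.target_year and self.ratio != 1.0:
            raise ValueError(
                f"identity year pair {self.source_year}->{self.target_year} requires ratio 1, "
                f"got {self.ratio}"
            )


def adjust_by_price_index(value: Money, r: PriceIndexRatio) -> Money:
    """Carry ``value`` from ``r.source_year`` prices to ``r.target_year`` prices."""
    if value.reference_year != r.source_year:
        raise YearMismatchError(
            f"value is referenced to {value.reference_year} but the index ratio "
            f"starts at {r.source_year}"
        )
    return Money(value.amount * r.ratio, r.target_year)


def rescale_money(value: Money, scale: str) -> float:
    """Express ``value`` as a scalar in the given reporting scale.

    ``scale`` is one of ``CNY``, ``wan`` (万 = 10⁴ CNY), ``million``, ``billion``.
    The divide/multiply round trip with :func:`money_from_scale` is exact to
    engine precision (one ulp).
    """
    try:
        factor = SCALE_FACTORS[scale]
    except KeyError:
        raise ValueError(
            f"unknown money scale {scale!r}; expected one of {sorted(SCALE_FACTORS)}"
        ) from None
    return value.amount / factor


def money_from_scale(scalar: float, scale: str, reference_year: int) -> Money:
    """Inverse of :func:`rescale_money`: build a ``Money`` from a scaled scalar."""
    try:
        factor = SCALE_FACTORS[scale]
    except KeyError:
        raise ValueError(
            f"unknown money scale {scale!r}; expected one of {sorted(SCALE_FACTORS)}"
        ) from None
    return Money(scalar * factor, reference_year)
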