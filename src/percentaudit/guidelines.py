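"""Ideal decimal places for a percent, classification, and formatting.

Cole's presentation guidelines for percents are operationalized as a band
rule for the ideal number of decimal places d*:

=====================  ====
value v (percent)       d*
=====================  ====
v = 0                    1
0 < v < 0.001            4
0.001 <= v < 0.01        3
0.01 <= v < 0.1          2
0.1 <= v < 10            1
10 <= v <= 90            0
90 < v < 100             1
v >= 100                 0
=====================  ====

The extra decimal in (90, 100) accommodates a natural upper bound at 100%
(e.g. sensitivity: 99.9%, not 100%).  Bands are half-open; exactly 10 and 90
take the integer rule and exactly 100 takes 0 decimals.  A mention printed
with d decimals is "too few" when d < d*, "just right" when d = d* and "too
many" when d > d*.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

from .extraction import PercentMention

__all__ = ["Category", "ClassifiedPercent", "ideal_decimal_places", "classify", "format_percent"]


class Category(str, Enum):
    """Sign of observed-minus-ideal decimal places."""

    TOO_FEW = "too_few"
    JUST_RIGHT = "just_right"
    TOO_MANY = "too_many"


@dataclass(frozen=True)
class ClassifiedPercent:
    """A mention with its ideal decimal places and guideline category."""

    mention: PercentMention
    ideal_decimals: int
    difference: int  # observed minus ideal
    category: Category


def ideal_decimal_places(value: float) -> int:
    """Ideal number of decimal places d* for a percent value.

    Total on [0, inf); raises ValueError for negative input (signs are
    stripped during extraction, so a negative here is a caller bug).
    """
    if value < 0:
        raise ValueError(f"percent value must be non-negative, got {value}")
    if value == 0:
        return 1
    if value >= 100:
        return 0
    if value > 90:
        return 1
    if value >= 10:
        return 0
    if value >= 0.1:
        return 1
    if value >= 0.01:
        return 2
    if value >= 0.001:
        return 3
    return 4


def classify(mention: PercentMention) -> ClassifiedPercent:
    """Compare printed decimals with the ideal and categorise the mention."""
    ideal = ideal_decimal_places(mention.value)
    difference = mention.decimals - ideal
    if difference < 0:
        category = Category.TOO_FEW
    elif difference == 0:
        category = Category.JUST_RIGHT
    else:
        category = Category.TOO_MANY
    return ClassifiedPercent(mention=mention, ideal_decimals=ideal, difference=difference, category=category)


def format_percent(value: float) -> str:
    """Render a percent with its ideal decimal places.

    Rounds half away from zero and keeps trailing zeros, so 100*263/8313
    renders as "3.2" and 100*1947/9482 as "21".  When rounding carries the
    value across a band boundary (9.96 rounds to 10 at one decimal), the
    ideal is re-evaluated on the rounded value until stable, so the printed
    token always carries the ideal decimals of the number it shows.
    """
    exact = Decimal(repr(float(value)))
    digits = ideal_decimal_places(value)
    for _ in range(4):
        rounded = exact.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_UP)
        digits_of_rounded = ideal_decimal_places(float(rounded))
        if digits_of_rounded == digits:
            return str(rounded)
        digits = digits_of_rounded
    return str(rounded)  # pragma: no cover
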