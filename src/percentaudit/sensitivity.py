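"""Sensitivity-analysis exclusions: digit preference and the 90–100 band.

Spikes at round values (multiples of 10, and 75) printed without decimals
suggest pre-rounded thresholds rather than computed results; values between
90% and 100% may or may not sit under a natural upper bound at 100, which
makes their ideal precision ambiguous.  The sensitivity analysis drops both
groups and re-tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .extraction import PercentMention
from .guidelines import ClassifiedPercent

__all__ = ["SensitivityFlags", "is_digit_preference", "in_upper_bound_band", "apply_sensitivity"]


@dataclass(frozen=True)
class SensitivityFlags:
    """Which exclusions are active; both off reproduces the main analysis."""

    exclude_digit_preference: bool = False
    exclude_90_100: bool = False


def is_digit_preference(mention: PercentMention) -> bool:
    """True iff printed with no decimals and a multiple of 10, or exactly 75.

    The multiple-of-10 test is exact on the printed integer (a "50.0" with
    one printed decimal is not digit preference).
    """
    if mention.decimals != 0 or not float(mention.value).is_integer():
        return False
    value = int(mention.value)
    return value % 10 == 0 or value == 75


def in_upper_bound_band(mention: PercentMention) -> bool:
    """True iff 90 <= value <= 100 (both endpoints included)."""
    return 90 <= mention.value <= 100


def apply_sensitivity(
    classified: Iterable[ClassifiedPercent], flags: SensitivityFlags
) -> list[ClassifiedPercent]:
    """Drop classified mentions matching the active exclusions, order kept."""
    kept = []
    for item in classified:
        if flags.exclude_digit_preference and is_digit_preference(item.mention):
            continue
        if flags.exclude_90_100 and in_upper_bound_band(item.mention):
            continue
        kept.append(item)
    return kept
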