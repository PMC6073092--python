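"""Normalize abstract text and extract percent mentions.

A percent mention is a number immediately suffixed by "%" (at most one space
in between).  For each mention we record the printed token, its numeric
value, the number of decimal places as printed (trailing zeros count) and
the significant figures, together with the character span in the normalized
text.  Ranges contribute only the number adjacent to the "%" ("5 to 10%"
yields 10), and leading signs or comparison symbols are dropped so "–10%"
and "<10%" both yield 10.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

__all__ = [
    "PercentMention",
    "normalize_text",
    "find_percents",
    "count_decimals",
    "count_sig_figs",
]

logger = logging.getLogger(__name__)

# Character-level cleanup applied before extraction: strip the plus-minus
# symbol, map exotic spaces to ASCII space, unicode minus and dashes to "-",
# the full-width percent to "%", and the mid-dot decimal marker (Lancet
# house style, "12·3") to ".".
_NORMALIZE_TABLE = str.maketrans(
    {
        "±": None,  # ±
        " ": " ",  # no-break space
        " ": " ",  # figure space
        " ": " ",  # thin space
        " ": " ",  # narrow no-break space
        "​": None,  # zero-width space
        "⁠": None,  # word joiner
        "−": "-",  # unicode minus
        "–": "-",  # en dash
        "—": "-",  # em dash
        "％": "%",  # full-width percent
        "·": ".",  # middle dot decimal marker
        "⋅": ".",  # dot operator
    }
)

# Numeric part: digits with optional comma thousands separators and at most
# one decimal point; a bare ".5" (no leading zero) is accepted.  The
# lookbehind stops matches starting mid-number ("31.69%" never yields ".69%",
# "4,214.53%" never yields "214.53%").
_NUMBER = r"(?:\d{1,3}(?:,\d{3})+|\d+)(?:\.\d+)?|\.\d+"
_PERCENT_RE = re.compile(rf"(?<![\d.,])({_NUMBER}) ?%")

# A number preceded by a mantissa-exponent prefix ("1e-4%") is scientific
# notation, which the token grammar cannot represent; skip it with a warning
# rather than record the exponent as a percent.
_SCI_PREFIX_RE = re.compile(r"\d\s?[eE]\s?[-+]?$")


@dataclass(frozen=True)
class PercentMention:
    """One extracted percent.

    Attributes
    ----------
    raw_token:
        The exact matched substring including "%" (leading sign/comparison
        characters are never part of the token).
    value:
        Numeric value in percent points; always ≥ 0.
    decimals:
        Digits printed after the decimal point (0 when none; trailing zeros
        count).
    sig_figs:
        Significant figures of the printed digits (≥ 1).
    span:
        0-based half-open character offsets into the normalized text.
    record_id:
        Identifier of the owning abstract, when known.
    """

    raw_token: str
    value: float
    decimals: int
    sig_figs: int
    span: tuple[int, int]
    record_id: str | None = None


def normalize_text(text: str) -> str:
    """Apply the character-level cleanup; idempotent, order-preserving."""
    return text.translate(_NORMALIZE_TABLE)


def count_decimals(numeric_token: str) -> int:
    """Decimal places of a printed numeric token ("50.0" → 1, "64" → 0)."""
    if "." not in numeric_token:
        return 0
    return len(numeric_token.rsplit(".", 1)[1])


def count_sig_figs(numeric_token: str) -> int:
    """Significant figures of the printed digits.

    Leading zeros are not significant; trailing zeros after a decimal point
    are; trailing zeros of a bare integer are counted as printed ("50" → 2).
    An all-zero token ("0", "0.0") counts its post-point zeros, minimum 1.
    """
    digits = numeric_token.replace(",", "").replace(".", "")
    stripped = digits.lstrip("0")
    if stripped:
        return len(stripped)
    return max(1, count_decimals(numeric_token))


def find_percents(text: str, record_id: str | None = None) -> list[PercentMention]:
    """Extract every percent mention from normalized text, left to right.

    ``text`` is assumed already normalized (see :func:`normalize_text`);
    extraction is stable under re-normalization.  Returns an empty list when
    there are no matches.
    """
    mentions: list[PercentMention] = []
    for match in _PERCENT_RE.finditer(text):
        if _SCI_PREFIX_RE.search(text, 0, match.start()):
            logger.warning(
                "skipping scientific-notation percent near %r", text[max(0, match.start() - 8) : match.end()]
            )
            continue
        token = match.group(1)
        mentions.append(
            PercentMention(
                raw_token=match.group(0),
                value=abs(float(token.replace(",", ""))),
                decimals=count_decimals(token),
                sig_figs=count_sig_figs(token),
                span=(match.start(), match.end()),
                record_id=record_id,
            )
        )
    return mentions
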