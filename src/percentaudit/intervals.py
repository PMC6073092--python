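"""Exclude percents that label statistical intervals or significance levels.

"95%" in "95% CI 6-21%" names the level of a confidence interval, not a
result, and must not be audited.  A mention is excluded when (a) its printed
value is one of a rule's trigger values with zero decimal places, and (b) an
interval/significance keyword occurs within the rule's character window on
an admissible side.  The keyword vocabulary covers the standard phrases
("confidence interval", "credible interval", ...), the acronyms CI, PI and
the transposed IC, and known in-the-wild variants such as the typo
"uncertainly interval".  Rules are plain data and can be serialized to JSON
so new dialects can be added without code changes.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .extraction import PercentMention

__all__ = [
    "ExclusionRule",
    "DEFAULT_INTERVAL_RULES",
    "DEFAULT_SIGNIFICANCE_RULES",
    "DEFAULT_RULES",
    "is_interval_label",
    "is_significance_label",
    "filter_labels",
    "load_rules",
    "dump_rules",
]

_INTERVAL_PHRASES = (
    "Bayesian credible interval",
    "confidence interval",
    "credible interval",
    "uncertainty interval",
    "uncertainly interval",  # observed typo
    "prediction interval",
    "posterior interval",
    "CI",
    "PI",
    "IC",
)

_SIGNIFICANCE_PHRASES = (
    "statistical significance",
    "significance",
    "alpha level",
)


@dataclass(frozen=True)
class ExclusionRule:
    """One trigger-value/keyword pairing.

    ``side`` restricts where the keyword may sit relative to the percent
    token ("before", "after" or "either"); ``window`` is the maximum number
    of characters between token and keyword.
    """

    trigger_values: frozenset
    keywords: tuple[str, ...]
    side: str = "either"
    window: int = 30
    name: str = ""

    def __post_init__(self) -> None:
        if not self.trigger_values:
            raise ValueError("trigger_values must be non-empty")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.side not in ("before", "after", "either"):
            raise ValueError(f"invalid side: {self.side!r}")

    def _patterns(self) -> list[re.Pattern]:
        patterns = []
        for keyword in self.keywords:
            escaped = r"\s+".join(re.escape(part) for part in keyword.split())
            # Short acronyms need word boundaries so "CI" cannot fire inside
            # e.g. "precision"; phrases are safe as substrings.
            if len(keyword) <= 3:
                escaped = rf"\b{escaped}\b"
            patterns.append(re.compile(escaped, re.IGNORECASE))
        return patterns

    def matches(self, mention: PercentMention, text: str) -> bool:
        """True iff the mention triggers this rule in its textual context."""
        if mention.decimals != 0 or mention.value not in self.trigger_values:
            return False
        start, end = mention.span
        for pattern in self._patterns():
            for hit in pattern.finditer(text):
                if hit.end() <= start:
                    gap, side = start - hit.end(), "before"
                elif hit.start() >= end:
                    gap, side = hit.start() - end, "after"
                else:
                    continue
                if gap <= self.window and self.side in ("either", side):
                    return True
        return False


#: Interval-level labels: 80/90/95/99% next to an interval phrase or acronym.
#: "range" gets its own tight window because it is common English.
DEFAULT_INTERVAL_RULES: tuple[ExclusionRule, ...] = (
    ExclusionRule(
        trigger_values=frozenset({80.0, 90.0, 95.0, 99.0}),
        keywords=_INTERVAL_PHRASES,
        side="either",
        window=30,
        name="interval",
    ),
    ExclusionRule(
        trigger_values=frozenset({80.0, 90.0, 95.0, 99.0}),
        keywords=("range",),
        side="either",
        window=5,
        name="range",
    ),
)

#: Significance levels: 1/5/10% next to a significance phrase.
DEFAULT_SIGNIFICANCE_RULES: tuple[ExclusionRule, ...] = (
    ExclusionRule(
        trigger_values=frozenset({1.0, 5.0, 10.0}),
        keywords=_SIGNIFICANCE_PHRASES,
        side="either",
        window=30,
        name="significance",
    ),
)

DEFAULT_RULES: tuple[ExclusionRule, ...] = DEFAULT_INTERVAL_RULES + DEFAULT_SIGNIFICANCE_RULES


def is_interval_label(
    mention: PercentMention,
    text: str,
    rules: Sequence[ExclusionRule] = DEFAULT_INTERVAL_RULES,
) -> bool:
    """True iff the mention labels a statistical interval in ``text``."""
    return any(rule.matches(mention, text) for rule in rules)


def is_significance_label(
    mention: PercentMention,
    text: str,
    rules: Sequence[ExclusionRule] = DEFAULT_SIGNIFICANCE_RULES,
) -> bool:
    """True iff the mention labels a statistical-significance level."""
    return any(rule.matches(mention, text) for rule in rules)


def filter_labels(
    mentions: Iterable[PercentMention],
    text: str,
    rules: Sequence[ExclusionRule] = DEFAULT_RULES,
) -> tuple[list[PercentMention], list[PercentMention]]:
    """Partition mentions into (kept, removed) label mentions, order kept.

    Exclusion is per-mention: a sentence may contain both an excluded label
    and retained results ("from 12% [95% CI 6-21%]" keeps 12 and 21).
    """
    kept: list[PercentMention] = []
    removed: list[PercentMention] = []
    for mention in mentions:
        if any(rule.matches(mention, text) for rule in rules):
            removed.append(mention)
        else:
            kept.append(mention)
    return kept, removed


def dump_rules(rules: Sequence[ExclusionRule], path: str | Path) -> None:
    """Serialize rules to a JSON config file."""
    payload = [
        {
            "trigger_values": sorted(rule.trigger_values),
            "keywords": list(rule.keywords),
            "side": rule.side,
            "window": rule.window,
            "name": rule.name,
        }
        for rule in rules
    ]
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def load_rules(path: str | Path) -> list[ExclusionRule]:
    """Load rules from a JSON config file written by :func:`dump_rules`."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        ExclusionRule(
            trigger_values=frozenset(float(v) for v in entry["trigger_values"]),
            keywords=tuple(entry["keywords"]),
            side=entry.get("side", "either"),
            window=int(entry.get("window", 30)),
            name=entry.get("name", ""),
        )
        for entry in payload
    ]
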