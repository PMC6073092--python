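"""End-to-end audit: extract, exclude labels, classify, tabulate."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .corpus_io import AbstractRecord
from .extraction import PercentMention, find_percents, normalize_text
from .guidelines import ClassifiedPercent, classify
from .intervals import DEFAULT_RULES, ExclusionRule, filter_labels

__all__ = ["AuditResult", "audit_corpus"]


@dataclass
class AuditResult:
    """Outcome of auditing a corpus.

    ``classified`` holds the retained (non-label) mentions with their
    guideline categories — the main-analysis sample; sensitivity exclusions
    are applied downstream with :func:`percentaudit.sensitivity.apply_sensitivity`.
    ``mentions`` is the flat per-mention table including excluded labels.
    """

    classified: list[ClassifiedPercent]
    removed_labels: list[PercentMention]
    journals: dict[str, str]
    mentions: pd.DataFrame


def audit_corpus(
    records: Iterable[AbstractRecord],
    rules: Sequence[ExclusionRule] = DEFAULT_RULES,
) -> AuditResult:
    """Run the full audit over abstract records.

    Each abstract's text is normalized, its percent mentions extracted,
    statistical-interval and significance labels removed, and the remaining
    mentions classified against the ideal-decimal-places rule.
    """
    classified: list[ClassifiedPercent] = []
    removed_all: list[PercentMention] = []
    journals: dict[str, str] = {}
    rows: list[dict] = []

    for record in records:
        journals[record.record_id] = record.journal
        text = normalize_text(record.abstract_text)
        mentions = find_percents(text, record_id=record.record_id)
        kept, removed = filter_labels(mentions, text, rules)
        removed_set = {m.span for m in removed}
        removed_all.extend(removed)
        items = {m.span: classify(m) for m in kept}
        classified.extend(items.values())
        for mention in mentions:
            item = items.get(mention.span)
            rows.append(
                {
                    "record_id": record.record_id,
                    "journal": record.journal,
                    "raw_token": mention.raw_token,
                    "value": mention.value,
                    "decimals": mention.decimals,
                    "sig_figs": mention.sig_figs,
                    "span_start": mention.span[0],
                    "span_end": mention.span[1],
                    "excluded_label": mention.span in removed_set,
                    "ideal_decimals": item.ideal_decimals if item else pd.NA,
                    "difference": item.difference if item else pd.NA,
                    "category": item.category.value if item else pd.NA,
                }
            )

    columns = [
        "record_id", "journal", "raw_token", "value", "decimals", "sig_figs",
        "span_start", "span_end", "excluded_label", "ideal_decimals",
        "difference", "category",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return AuditResult(
        classified=classified, removed_labels=removed_all, journals=journals, mentions=table
    )
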