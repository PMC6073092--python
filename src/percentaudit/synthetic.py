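"""Synthetic abstracts with planted ground truth.

Each generated abstract embeds percent tokens at recorded character spans
inside digit-free filler sentences, so the planted mentions are the only
extractable tokens.  The generator emulates the statistical structure of
percents in real biomedical abstracts:

* percents per abstract follow a shifted negative binomial calibrated to
  median 3 with inter-quartile range 2-6 (see
  ``scripts/calibrate_count_distribution.py``);
* values heap at round numbers: multiples of 10 and 75 for ideally-printed
  integers, and 1, 5 and 95 for under-rounded ones (digit preference);
* each mention is planted as too few / just right / too many decimal places
  with configurable probabilities, and a small fraction of values exceed
  100;
* a configurable fraction of abstracts carry a statistical-interval or
  significance label ("(95% CI 1.8-5.1%)", "alpha level of 5%") that the
  exclusion stage must remove.

Every planted token carries a :class:`SyntheticGroundTruth` row, enabling
exact end-to-end checks: extraction must find precisely the planted spans,
exclusion must remove precisely the flagged labels, and classification must
reproduce the planted categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus_io import AbstractRecord
from .guidelines import Category, ideal_decimal_places

__all__ = [
    "GeneratorConfig",
    "SyntheticGroundTruth",
    "generate_corpus",
    "render_percent",
    "truth_to_frame",
    "write_truth_csv",
]

# Calibrated offline by grid search over scipy.stats.nbinom quantiles:
# 1 + NB(size=1.03, prob=0.23) has quartiles (2, 3, 6), with the CDF at
# each quartile boundary at least 0.03 away from the target probability so
# sampled quartiles are stable.
_NB_SIZE = 1.03
_NB_PROB = 0.23

_ROUND_SPIKES = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 75.0)
_UNDER_ROUNDED_SPIKES = (1.0, 5.0, 95.0)

# Filler sentences: one "{p}" slot each, free of digits, "%" and every
# exclusion keyword, so planted tokens are the only extractable percents and
# none is excluded spuriously.
_TEMPLATES = (
    "The primary outcome occurred in {p} of participants.",
    "Adherence to the allocated therapy reached {p} across sites.",
    "We observed a relative reduction of {p} in the intervention arm.",
    "Overall prevalence in the cohort was {p}.",
    "Sensitivity of the screening assay was {p}.",
    "Response rates improved by {p} after covariate adjustment.",
    "The programme covered {p} of the eligible population.",
    "All-cause mortality at final follow-up was {p}.",
    "Vaccine uptake among eligible adults reached {p}.",
    "The readmission rate within thirty days was {p}.",
)

_OPENERS = (
    "We conducted a multicentre observational study of adults admitted with acute illness.",
    "This randomised trial compared standard care with an enhanced follow-up protocol.",
    "We analysed routinely collected surveillance data from participating hospitals.",
    "A population-based cohort was assembled from linked registry data.",
)

# Decoy fragments for adversarial mode: numbers that must NOT be extracted
# because they lack the "%" suffix.
_DECOYS = (
    "Statistical analyses used a two-sided P = 0.05 threshold.",
    "This was a Phase 3 trial of a fixed 5 mg dose.",
    "Median follow-up was 4.2 years (IQR 2.1 to 6.8).",
)

_DEFAULT_JOURNALS = (
    ("J Clin Stud", 0.35),
    ("Ann Med Res", 0.25),
    ("Open Health Rep", 0.2),
    ("Glob Epidemiol", 0.15),
    ("Clin Trials Q", 0.05),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus; the seed fully determines the output."""

    n_abstracts: int = 1000
    journals: tuple[tuple[str, float], ...] = _DEFAULT_JOURNALS
    category_probs: tuple[float, float, float] = (0.12, 0.55, 0.33)
    interval_label_rate: float = 0.2
    digit_preference_rate: float = 0.25
    over_100_rate: float = 0.005
    adversarial: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_abstracts < 0:
            raise ValueError("n_abstracts must be >= 0")
        if not self.journals or any(w <= 0 for _, w in self.journals):
            raise ValueError("journals must be non-empty with positive weights")
        if len(self.category_probs) != 3 or any(p < 0 for p in self.category_probs):
            raise ValueError("category_probs must be three non-negative numbers")
        if abs(sum(self.category_probs) - 1.0) > 1e-9:
            raise ValueError("category_probs must sum to 1")
        for name in ("interval_label_rate", "digit_preference_rate", "over_100_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Planted truth for one percent token."""

    record_id: str
    span: tuple[int, int]
    true_value: float
    planted_decimals: int
    planted_category: Category
    is_interval_label: bool
    is_digit_preference: bool


def render_percent(true_value: float, planted_decimals: int) -> str:
    """Render a value with exactly the planted decimals, half away from zero."""
    if not 0 <= planted_decimals <= 6:
        raise ValueError("planted_decimals must be in 0..6")
    quantum = Decimal(1).scaleb(-planted_decimals)
    return str(Decimal(repr(float(true_value))).quantize(quantum, rounding=ROUND_HALF_UP))


def _digit_preference(value: float, decimals: int) -> bool:
    return decimals == 0 and float(value).is_integer() and (int(value) % 10 == 0 or int(value) == 75)


def _category_of(decimals: int, parsed_value: float) -> Category:
    diff = decimals - ideal_decimal_places(parsed_value)
    if diff < 0:
        return Category.TOO_FEW
    if diff == 0:
        return Category.JUST_RIGHT
    return Category.TOO_MANY


def _loguniform(rng: np.random.Generator, low: float, high: float) -> float:
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))


def _sample_regular(
    rng: np.random.Generator, category: Category, cfg: GeneratorConfig, avoid_triggers: bool = False
) -> tuple[float, int, str]:
    """Draw (true_value, decimals, token) for a planted non-label mention.

    Rejection sampling guarantees the rendered token classifies exactly as
    the planted category and that rounding does not shift the value across a
    guideline band.  With ``avoid_triggers`` the token also avoids integer
    80/90/95/99 and 1/5/10, so it can sit safely next to interval keywords.
    """
    for _ in range(500):
        if category is Category.JUST_RIGHT:
            draw = rng.random()
            if draw < cfg.digit_preference_rate:
                value = float(rng.choice(_ROUND_SPIKES))
                decimals = 0
            elif draw < cfg.digit_preference_rate + cfg.over_100_rate:
                value = float(np.round(rng.uniform(101.0, 1000.0)))
                decimals = 0
            else:
                value = _loguniform(rng, 0.002, 99.0)
                decimals = ideal_decimal_places(value)
        elif category is Category.TOO_FEW:
            if rng.random() < cfg.digit_preference_rate:
                value = float(rng.choice(_UNDER_ROUNDED_SPIKES))
            elif rng.random() < 0.12:
                value = float(rng.uniform(90.6, 99.4))
            else:
                value = _loguniform(rng, 0.11, 9.4)
            decimals = max(0, ideal_decimal_places(value) - 1)
        else:
            value = _loguniform(rng, 0.002, 99.0)
            decimals = ideal_decimal_places(value) + (1 if rng.random() < 0.8 else 2)
        decimals = min(decimals, 6)
        token = render_percent(value, decimals)
        parsed = float(token)
        if ideal_decimal_places(parsed) != ideal_decimal_places(value):
            continue
        if _category_of(decimals, parsed) is not category:
            continue
        if avoid_triggers and decimals == 0 and parsed in (80.0, 90.0, 95.0, 99.0, 1.0, 5.0, 10.0):
            continue
        return value, decimals, token
    raise RuntimeError("could not sample a consistent mention")  # pragma: no cover


class _AbstractBuilder:
    """Accumulates sentences while tracking mention spans."""

    def __init__(self, record_id: str) -> None:
        self.record_id = record_id
        self.parts: list[str] = []
        self.length = 0
        self.truths: list[SyntheticGroundTruth] = []

    def add_text(self, text: str) -> None:
        self.parts.append(text)
        self.length += len(text)

    def add_mention(
        self,
        value: float,
        decimals: int,
        token: str,
        *,
        spaced: bool = False,
        is_label: bool = False,
    ) -> None:
        mention_text = token + (" %" if spaced else "%")
        start = self.length
        self.add_text(mention_text)
        self.truths.append(
            SyntheticGroundTruth(
                record_id=self.record_id,
                span=(start, self.length),
                true_value=value,
                planted_decimals=decimals,
                planted_category=_category_of(decimals, float(token)),
                is_interval_label=is_label,
                is_digit_preference=_digit_preference(float(token), decimals),
            )
        )

    def text(self) -> str:
        return "".join(self.parts)


def _add_label_sentence(
    builder: _AbstractBuilder,
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    kind: str,
) -> None:
    """Append one interval- or significance-label construction.

    ``kind`` is "interval_bound" (the CI's upper bound is itself a planted
    result, "(95% CI 1.8-5.1%)"), "interval_plain" (plain un-suffixed
    bounds) or "significance".  Sentence prefixes keep every keyword more
    than 30 characters away from the previous sentence's final token, so
    labels never bleed into neighbouring mentions.
    """
    if kind in ("interval_bound", "interval_plain"):
        level = int(rng.choice([80, 90, 95, 99], p=[0.05, 0.1, 0.75, 0.1]))
        keyword = str(rng.choice(["CI", "confidence interval", "credible interval",
                                  "uncertainty interval", "prediction interval",
                                  "uncertainly interval"],
                                 p=[0.5, 0.3, 0.08, 0.05, 0.05, 0.02]))
        est_v, est_d, est_t = _sample_regular(rng, _draw_category(rng, cfg), cfg, avoid_triggers=True)
        builder.add_text("In the adjusted analysis, the effect estimate was ")
        builder.add_mention(est_v, est_d, est_t)
        if kind == "interval_bound":
            hi_v, hi_d, hi_t = _sample_regular(rng, _draw_category(rng, cfg), cfg, avoid_triggers=True)
            lo_t = render_percent(float(hi_t) * 0.6, hi_d)
            builder.add_text(" (")
            builder.add_mention(float(level), 0, str(level), is_label=True)
            builder.add_text(f" {keyword} {lo_t}-")
            builder.add_mention(hi_v, hi_d, hi_t)
            builder.add_text(").")
        else:
            # Reversed dialect "CI 95%" with plain (un-suffixed) bounds.
            lo_t = render_percent(float(est_t) * 0.6, est_d)
            hi_t = render_percent(float(est_t) * 1.4, est_d)
            builder.add_text(f" ({keyword} ")
            builder.add_mention(float(level), 0, str(level), is_label=True)
            builder.add_text(f": {lo_t} to {hi_t}).")
    else:
        level = int(rng.choice([1, 5, 10], p=[0.15, 0.7, 0.15]))
        phrase = str(rng.choice(["significance level", "alpha level"]))
        builder.add_text("In the prespecified statistical plan, all tests used an " + phrase + " of ")
        builder.add_mention(float(level), 0, str(level), is_label=True)
        builder.add_text(".")


def _draw_category(rng: np.random.Generator, cfg: GeneratorConfig) -> Category:
    index = int(rng.choice(3, p=np.asarray(cfg.category_probs, dtype=float)))
    return (Category.TOO_FEW, Category.JUST_RIGHT, Category.TOO_MANY)[index]


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[AbstractRecord], list[SyntheticGroundTruth]]:
    """Generate abstracts and their planted ground truth, deterministically."""
    rng = np.random.default_rng(config.seed)
    journal_names = [name for name, _ in config.journals]
    weights = np.array([w for _, w in config.journals], dtype=float)
    weights /= weights.sum()

    records: list[AbstractRecord] = []
    truths: list[SyntheticGroundTruth] = []
    for index in range(config.n_abstracts):
        record_id = f"synth-{index:06d}"
        builder = _AbstractBuilder(record_id)
        builder.add_text(str(rng.choice(_OPENERS)) + " ")
        if config.adversarial:
            builder.add_text(str(rng.choice(_DECOYS)) + " ")

        n_mentions = 1 + int(rng.negative_binomial(_NB_SIZE, _NB_PROB))
        # The label construction's estimate (and optional bound) are drawn
        # from the abstract's own mention budget, so labels do not change
        # the per-abstract count of result percents.
        label_kind: str | None = None
        if rng.random() < config.interval_label_rate:
            if rng.random() < 0.75:
                label_kind = "interval_bound" if n_mentions >= 2 and rng.random() < 0.7 else "interval_plain"
            else:
                label_kind = "significance"
        consumed = {"interval_bound": 2, "interval_plain": 1, "significance": 0, None: 0}[label_kind]
        for position in range(n_mentions - consumed):
            category = _draw_category(rng, config)
            value, decimals, token = _sample_regular(rng, category, config)
            template = str(rng.choice(_TEMPLATES))
            before, after = template.split("{p}")
            builder.add_text(before)
            builder.add_mention(value, decimals, token, spaced=rng.random() < 0.08)
            builder.add_text(after)
            builder.add_text(" ")
        if label_kind is not None:
            _add_label_sentence(builder, rng, config, label_kind)

        journal = journal_names[int(rng.choice(len(journal_names), p=weights))]
        types = ["Journal Article"]
        if rng.random() < 0.2:
            types.append("Randomized Controlled Trial")
        records.append(
            AbstractRecord(
                record_id=record_id,
                journal=journal,
                year=2017,
                publication_types=types,
                abstract_text=builder.text(),
            )
        )
        truths.extend(builder.truths)
    return records, truths


def truth_to_frame(truths: list[SyntheticGroundTruth]) -> pd.DataFrame:
    """Tabulate ground-truth rows (one per planted token)."""
    return pd.DataFrame(
        {
            "record_id": [t.record_id for t in truths],
            "span_start": [t.span[0] for t in truths],
            "span_end": [t.span[1] for t in truths],
            "true_value": [t.true_value for t in truths],
            "planted_decimals": [t.planted_decimals for t in truths],
            "planted_category": [t.planted_category.value for t in truths],
            "is_interval_label": [t.is_interval_label for t in truths],
            "is_digit_preference": [t.is_digit_preference for t in truths],
        }
    )


def write_truth_csv(truths: list[SyntheticGroundTruth], path: str | Path) -> None:
    truth_to_frame(truths).to_csv(path, index=False)
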