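"""Aggregate classifications: counts, proportions, and credible intervals.

Category counts (too few / just right / too many) are summarised with a
Dirichlet-multinomial model: with prior Dirichlet(a1, a2, a3) and counts
(n1, n2, n3) the posterior is Dirichlet(a + n), and each category's marginal
is Beta(a_i + n_i, sum_{j != i}(a_j + n_j)), from which equal-tailed
credible intervals come directly as Beta quantiles.  A Monte-Carlo mode
draws from the posterior Dirichlet instead, for cross-validation of the
quantile route.  No adjustment is made for clustering of multiple percents
within one abstract.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .guidelines import Category, ClassifiedPercent, format_percent

__all__ = [
    "CategoryCounts",
    "CategorySummary",
    "tally",
    "all_ideal_share",
    "dirichlet_intervals",
    "render_summary_table",
    "histogram_bins",
    "write_summary_overall",
    "write_summary_by_journal",
]

_CATEGORIES = (Category.TOO_FEW, Category.JUST_RIGHT, Category.TOO_MANY)


@dataclass(frozen=True)
class CategoryCounts:
    """Per-group counts of the three guideline categories."""

    group: str
    n_too_few: int
    n_just_right: int
    n_too_many: int

    @property
    def total(self) -> int:
        return self.n_too_few + self.n_just_right + self.n_too_many

    def as_array(self) -> np.ndarray:
        return np.array([self.n_too_few, self.n_just_right, self.n_too_many], dtype=float)


@dataclass(frozen=True)
class CategorySummary:
    """Counts plus proportions and equal-tailed credible intervals.

    ``proportions`` are the observed shares n_i / total (posterior means
    when total is zero); ``intervals`` are (low, high) pairs on [0, 1] for
    too few, just right, too many in that order.
    """

    counts: CategoryCounts
    proportions: tuple[float, float, float]
    ci_level: float
    intervals: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]


def tally(
    classified: Iterable[ClassifiedPercent],
    group_by: str = "all",
    journals: Mapping[str, str] | None = None,
) -> list[CategoryCounts]:
    """Count categories, overall or per journal.

    With ``group_by="journal"``, ``journals`` maps record_id to journal name.
    The overall mode always returns one group ("ALL"), zeros included.
    """
    if group_by not in ("all", "journal"):
        raise ValueError(f"unknown group_by: {group_by!r}")
    if group_by == "journal" and journals is None:
        raise ValueError("group_by='journal' requires a record_id -> journal mapping")

    buckets: dict[str, dict[Category, int]] = defaultdict(lambda: {c: 0 for c in _CATEGORIES})
    if group_by == "all":
        buckets["ALL"]  # materialise even when input is empty
    for item in classified:
        if group_by == "all":
            key = "ALL"
        else:
            record_id = item.mention.record_id
            key = journals[record_id]  # type: ignore[index]
        buckets[key][item.category] += 1
    return [
        CategoryCounts(
            group=group,
            n_too_few=counts[Category.TOO_FEW],
            n_just_right=counts[Category.JUST_RIGHT],
            n_too_many=counts[Category.TOO_MANY],
        )
        for group, counts in sorted(buckets.items())
    ]


def all_ideal_share(classified: Iterable[ClassifiedPercent]) -> tuple[int, int]:
    """(abstracts whose every retained percent is just right, abstracts with >= 1 percent)."""
    per_abstract: dict[str, bool] = {}
    for item in classified:
        record_id = item.mention.record_id
        if record_id is None:
            raise ValueError("all_ideal_share requires mentions with record_id")
        ideal = item.category is Category.JUST_RIGHT
        per_abstract[record_id] = per_abstract.get(record_id, True) and ideal
    n_all_ideal = sum(per_abstract.values())
    return n_all_ideal, len(per_abstract)


def dirichlet_intervals(
    counts: CategoryCounts,
    prior: Sequence[float] = (1.0, 1.0, 1.0),
    level: float = 0.95,
    method: str = "quantile",
    n_draws: int = 100_000,
    rng: np.random.Generator | None = None,
) -> CategorySummary:
    """Posterior summary of category proportions under a Dirichlet prior.

    Parameters
    ----------
    counts:
        Observed category counts.
    prior:
        Dirichlet concentration parameters, all > 0 (flat (1,1,1) default).
    level:
        Credible level in (0, 1).
    method:
        "quantile" evaluates each marginal Beta's quantiles (deterministic);
        "mc" draws ``n_draws`` samples from the posterior Dirichlet and takes
        empirical quantiles (for validation).
    """
    prior_arr = np.asarray(prior, dtype=float)
    if prior_arr.shape != (3,):
        raise ValueError("prior must have three components")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if counts.total == 0 and np.any(prior_arr <= 0):
        raise ValueError("zero counts with a degenerate prior: posterior undefined")
    if np.any(prior_arr <= 0):
        raise ValueError("prior components must be positive")

    posterior = prior_arr + counts.as_array()
    alpha_total = posterior.sum()
    tail = (1.0 - level) / 2.0

    if method == "quantile":
        lows = stats.beta.ppf(tail, posterior, alpha_total - posterior)
        highs = stats.beta.ppf(1.0 - tail, posterior, alpha_total - posterior)
    elif method == "mc":
        if rng is None:
            rng = np.random.default_rng()
        draws = rng.dirichlet(posterior, size=n_draws)
        lows = np.quantile(draws, tail, axis=0)
        highs = np.quantile(draws, 1.0 - tail, axis=0)
    else:
        raise ValueError(f"unknown method: {method!r}")

    if counts.total > 0:
        proportions = counts.as_array() / counts.total
    else:
        proportions = posterior / alpha_total
    return CategorySummary(
        counts=counts,
        proportions=tuple(proportions),
        ci_level=level,
        intervals=tuple((float(lo), float(hi)) for lo, hi in zip(lows, highs)),
    )


def render_summary_table(summaries: Sequence[CategorySummary]) -> pd.DataFrame:
    """Table-ready rows: one per (group, category).

    Proportions are printed with their guideline-ideal decimal places
    (55.36...% of 43,119 renders as "55"); counts get thousands separators.
    """
    rows = []
    labels = ("Too few", "Just right", "Too many")
    for summary in summaries:
        values = summary.counts.as_array().astype(int)
        for label, count, proportion, (low, high) in zip(
            labels, values, summary.proportions, summary.intervals
        ):
            rows.append(
                {
                    "group": summary.counts.group,
                    "category": label,
                    "percent": format_percent(100.0 * proportion),
                    "count": f"{int(count):,}",
                    "ci_low": round(100.0 * low, 1),
                    "ci_high": round(100.0 * high, 1),
                }
            )
    return pd.DataFrame(rows, columns=["group", "category", "percent", "count", "ci_low", "ci_high"])


def histogram_bins(values: Iterable[float]) -> pd.DataFrame:
    """1-percent-bin histogram over [0, 100]; values above 100 are dropped."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[arr <= 100.0]
    counts, edges = np.histogram(arr, bins=np.arange(0, 101, 1))
    return pd.DataFrame(
        {"bin_start": edges[:-1].astype(int), "bin_end": edges[1:].astype(int), "count": counts}
    )


def write_summary_overall(
    path: str | Path,
    main: CategorySummary,
    sensitivity: CategorySummary | None = None,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Write the overall category table, optionally with a sensitivity column.

    ``provenance`` entries (e.g. active sensitivity flags) are recorded as
    "# key=value" comment lines above the header.
    """
    main_rows = render_summary_table([main]).drop(columns=["group"])
    if sensitivity is not None:
        sens_rows = render_summary_table([sensitivity]).drop(columns=["group"])
        main_rows = main_rows.merge(
            sens_rows, on="category", suffixes=("", "_sensitivity")
        )
    with Path(path).open("w", encoding="utf-8") as handle:
        for key, value in (provenance or {}).items():
            handle.write(f"# {key}={value}\n")
        main_rows.to_csv(handle, index=False)


def write_summary_by_journal(path: str | Path, summaries: Sequence[CategorySummary]) -> None:
    """Write the per-journal table (percents with credible-interval bounds)."""
    render_summary_table(summaries).to_csv(path, index=False)
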