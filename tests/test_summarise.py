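import numpy as np
import pytest

from percentaudit.extraction import PercentMention
from percentaudit.guidelines import classify
from percentaudit.summarise import (
    CategoryCounts,
    all_ideal_share,
    dirichlet_intervals,
    histogram_bins,
    render_summary_table,
    tally,
)


def _classified(value, decimals, record_id="r1"):
    token = str(int(value)) if decimals == 0 else f"{value:.{decimals}f}"
    return classify(PercentMention(token + "%", value, decimals, 1, (0, 1), record_id))


class TestTally:
    def test_one_mention_per_category(self):
        items = [_classified(3.0, 0), _classified(64.0, 0), _classified(31.69, 2)]
        (counts,) = tally(items)
        assert (counts.n_too_few, counts.n_just_right, counts.n_too_many) == (1, 1, 1)
        assert counts.total == 3

    def test_empty_input_yields_zero_group(self):
        (counts,) = tally([])
        assert counts.group == "ALL" and counts.total == 0

    def test_journal_grouping_partitions_the_input(self):
        items = [_classified(3.0, 0, "a"), _classified(64.0, 0, "b"), _classified(5.5, 1, "a")]
        groups = tally(items, group_by="journal", journals={"a": "J1", "b": "J2"})
        assert {g.group: g.total for g in groups} == {"J1": 2, "J2": 1}
        assert sum(g.total for g in groups) == len(items)

    def test_journal_grouping_requires_mapping(self):
        with pytest.raises(ValueError):
            tally([], group_by="journal")


class TestAllIdealShare:
    def test_mixed_and_fully_ideal_abstracts(self):
        items = [
            _classified(64.0, 0, "a"), _classified(5.5, 1, "a"),  # all ideal
            _classified(64.0, 0, "b"), _classified(3.0, 0, "b"),  # mixed
        ]
        assert all_ideal_share(items) == (1, 2)

    def test_all_abstracts_ideal(self):
        items = [_classified(64.0, 0, "a"), _classified(5.5, 1, "b")]
        assert all_ideal_share(items) == (2, 2)


class TestDirichletIntervals:
    def test_symmetric_counts_give_identical_widths(self):
        summary = dirichlet_intervals(CategoryCounts("ALL", 40, 40, 40))
        widths = [hi - lo for lo, hi in summary.intervals]
        assert np.allclose(widths, widths[0])
        assert np.allclose(sum(summary.proportions), 1.0)

    def test_quantile_matches_monte_carlo_oracle(self):
        counts = CategoryCounts("ALL", 2, 3, 5)
        quantile = dirichlet_intervals(counts)
        mc = dirichlet_intervals(
            counts, method="mc", n_draws=10**6, rng=np.random.default_rng(20170)
        )
        for (ql, qh), (ml, mh) in zip(quantile.intervals, mc.intervals):
            assert ql == pytest.approx(ml, abs=2e-3)
            assert qh == pytest.approx(mh, abs=2e-3)

    def test_width_shrinks_with_total_count(self):
        widths = []
        for scale in (10, 100, 1000, 10000):
            counts = CategoryCounts("ALL", 2 * scale, 5 * scale, 3 * scale)
            summary = dirichlet_intervals(counts)
            widths.append(max(hi - lo for lo, hi in summary.intervals))
        assert widths == sorted(widths, reverse=True)

    def test_interval_bounds_ordered_and_in_unit_range(self):
        summary = dirichlet_intervals(CategoryCounts("ALL", 0, 7, 2))
        for low, high in summary.intervals:
            assert 0.0 <= low <= high <= 1.0

    def test_zero_counts_with_degenerate_prior_rejected(self):
        with pytest.raises(ValueError):
            dirichlet_intervals(CategoryCounts("ALL", 0, 0, 0), prior=(0.0, 1.0, 1.0))

    def test_coverage_of_95_percent_intervals(self):
        """Equal-tailed 95% intervals cover fixed true proportions 92-98% of the time."""
        rng = np.random.default_rng(99)
        truth = np.array([0.12, 0.55, 0.33])
        n, replicates = 2000, 500
        draws = rng.multinomial(n, truth, size=replicates)
        covered = np.zeros(3)
        for counts in draws:
            summary = dirichlet_intervals(CategoryCounts("ALL", *counts.tolist()))
            for i, (low, high) in enumerate(summary.intervals):
                covered[i] += low <= truth[i] <= high
        coverage = covered / replicates
        assert np.all(coverage >= 0.92) and np.all(coverage <= 0.98)


class TestRendering:
    def test_table_percent_uses_guideline_formatting(self):
        summary = dirichlet_intervals(CategoryCounts("ALL", 4981, 23872, 14266))
        table = render_summary_table([summary])
        assert list(table["percent"]) == ["12", "55", "33"]
        assert list(table["count"]) == ["4,981", "23,872", "14,266"]

    def test_exact_half_renders_as_integer(self):
        summary = dirichlet_intervals(CategoryCounts("ALL", 25, 50, 25))
        table = render_summary_table([summary])
        assert table.loc[table["category"] == "Just right", "percent"].item() == "50"

    def test_histogram_bins_drop_values_over_100(self):
        table = histogram_bins([0.5, 1.2, 99.9, 100.0, 150.0])
        assert table["count"].sum() == 4
        assert table.shape[0] == 100
        assert table.loc[table["bin_start"] == 99, "count"].item() == 2
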