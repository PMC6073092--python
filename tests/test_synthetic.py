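import numpy as np
import pytest

from percentaudit.extraction import find_percents, normalize_text
from percentaudit.guidelines import Category, ideal_decimal_places
from percentaudit.pipeline import audit_corpus
from percentaudit.sensitivity import SensitivityFlags, apply_sensitivity
from percentaudit.synthetic import (
    GeneratorConfig,
    generate_corpus,
    render_percent,
    truth_to_frame,
)


class TestRenderPercent:
    @pytest.mark.parametrize(
        "value, decimals, token",
        [(3.1637, 1, "3.2"), (64, 0, "64"), (0.0004, 4, "0.0004"), (10.5, 0, "11"), (50, 1, "50.0")],
    )
    def test_exact_decimals_half_away_from_zero(self, value, decimals, token):
        assert render_percent(value, decimals) == token

    def test_decimals_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            render_percent(1.0, 7)


class TestGeneratorConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_abstracts": -1},
            {"category_probs": (0.5, 0.5, 0.5)},
            {"interval_label_rate": 1.5},
            {"journals": ()},
        ],
    )
    def test_invalid_config_rejected_before_output(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorConfig(**kwargs)


class TestGenerateCorpus:
    def test_seed_determinism(self):
        a = generate_corpus(GeneratorConfig(n_abstracts=40, seed=5))
        b = generate_corpus(GeneratorConfig(n_abstracts=40, seed=5))
        assert a == b

    def test_truth_invariants(self, small_corpus):
        _, records, truths = small_corpus
        texts = {r.record_id: r.abstract_text for r in records}
        for truth in truths:
            start, end = truth.span
            token_text = texts[truth.record_id][start:end]
            assert token_text.endswith("%")
            # planted category consistent with the decimals-minus-ideal sign
            diff = truth.planted_decimals - ideal_decimal_places(truth.true_value)
            expected = (
                Category.TOO_FEW if diff < 0 else Category.JUST_RIGHT if diff == 0 else Category.TOO_MANY
            )
            assert truth.planted_category is expected

    def test_forced_just_right_classifies_perfectly(self):
        config = GeneratorConfig(
            n_abstracts=30, seed=9, category_probs=(0.0, 1.0, 0.0), interval_label_rate=0.0
        )
        records, _ = generate_corpus(config)
        result = audit_corpus(records)
        assert result.removed_labels == []
        assert all(c.category is Category.JUST_RIGHT for c in result.classified)

    def test_percents_per_abstract_median_and_iqr(self):
        records, truths = generate_corpus(GeneratorConfig(n_abstracts=1500, seed=13))
        frame = truth_to_frame(truths)
        counts = frame[~frame.is_interval_label].groupby("record_id").size()
        q1, median, q3 = np.percentile(counts, [25, 50, 75])
        assert median == 3
        assert (q1, q3) == (2, 6)

    def test_normalization_is_noop_on_generated_text(self, small_corpus):
        _, records, _ = small_corpus
        for record in records[:50]:
            assert normalize_text(record.abstract_text) == record.abstract_text


class TestEndToEndOracle:
    def test_extraction_exclusion_and_classification_match_truth(self, small_corpus):
        _, records, truths = small_corpus
        result = audit_corpus(records)
        truth_map = {(t.record_id, *t.span): t for t in truths}

        found = {(r.record_id, r.span_start, r.span_end) for r in result.mentions.itertuples()}
        assert found == set(truth_map)  # precision = recall = 1

        removed = {(m.record_id, *m.span) for m in result.removed_labels}
        flagged = {k for k, t in truth_map.items() if t.is_interval_label}
        assert removed == flagged

        for item in result.classified:
            truth = truth_map[(item.mention.record_id, *item.mention.span)]
            assert item.category is truth.planted_category

    def test_sensitivity_filters_remove_exactly_flagged_mentions(self, small_corpus):
        _, records, truths = small_corpus
        result = audit_corpus(records)
        truth_map = {(t.record_id, *t.span): t for t in truths}
        kept = apply_sensitivity(result.classified, SensitivityFlags(True, True))
        expected = [
            c
            for c in result.classified
            if not truth_map[(c.mention.record_id, *c.mention.span)].is_digit_preference
            and not 90 <= c.mention.value <= 100
        ]
        assert kept == expected

    def test_adversarial_decoys_not_extracted(self):
        config = GeneratorConfig(n_abstracts=100, seed=17, adversarial=True)
        records, truths = generate_corpus(config)
        planted = {(t.record_id, *t.span) for t in truths}
        found = set()
        for record in records:
            for mention in find_percents(record.abstract_text, record.record_id):
                found.add((record.record_id, *mention.span))
        assert found == planted
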