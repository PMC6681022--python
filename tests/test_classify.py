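import math

import numpy as np
import pytest

from chipseek.classify import (
    ConcurrentEvent,
    HitCategory,
    classify_hit,
    default_ruleset,
    detect_litter,
    extract_concurrent,
    sample_hits,
    tabulate_classifications,
)
from chipseek.search import HitSet, find_hits
from chipseek.synth import GeneratorConfig, generate

from conftest import make_record


class TestClassifyHit:
    @pytest.mark.parametrize(
        "text, category",
        [
            (
                "microchip implanted 956000012345678, batch sticker attached",
                HitCategory.IMPLANTATION_EVENT,
            ),
            ("Weight: __ Microchip: __ Vacc: __", HitCategory.BLANK_PREPOPULATED_FORM),
            ("owner declined microchipping at this time", HitCategory.OWNER_REFUSAL),
            ("microcytic hypochromic anaemia", HitCategory.OTHER_WORD_OR_TYPO),
            ("scanned, existing microchip confirmed", HitCategory.PREEXISTING_CHIP_CONFIRMATION),
            ("plan: microchip at next visit", HitCategory.FUTURE_PLAN),
            ("scanned, no microchip found", HitCategory.ABSENCE_NOTED),
            ("microchip brochure in puppy pack", HitCategory.NONE_OF_THE_ABOVE),
            (
                "swelling at microchip implantation site",
                HitCategory.IMPLANTATION_COMPLICATION,
            ),
        ],
    )
    def test_default_rule_table(self, rules, text, category):
        assert classify_hit(make_record(text), rules) is category

    def test_deterministic_first_match_wins(self, rules):
        # Contains both a complication phrase and an implantation phrase;
        # the complication rule is ordered first.
        rec = make_record("microchip implanted; swelling at microchip implantation site")
        assert classify_hit(rec, rules) is HitCategory.IMPLANTATION_COMPLICATION

    def test_zero_noise_corpus_recovered_exactly(self, rules):
        cfg = GeneratorConfig(
            n_patients=3000, hit_fraction=0.3, typo_rate=0.0, confounder_rate=0.0, seed=21
        )
        corpus, truth = generate(cfg)
        hits = truth.hit_refs()
        assert hits, "expected hit records"
        assert all(classify_hit(corpus[i], rules) is truth.category[i] for i in hits)


class TestSampleHits:
    def _hitset(self, n):
        return HitSet(term="t", record_refs=frozenset(range(n)), patient_ids=frozenset())

    def test_full_sample_is_permutation(self):
        hits = self._hitset(8)
        sample = sample_hits(hits, 8, seed=1)
        assert sorted(sample) == list(range(8))

    def test_same_seed_same_sample(self):
        hits = self._hitset(100)
        assert sample_hits(hits, 10, seed=3) == sample_hits(hits, 10, seed=3)
        assert sample_hits(hits, 10, seed=3) != sample_hits(hits, 10, seed=4)

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            sample_hits(self._hitset(3), 4, seed=0)

    def test_uniformity_of_single_draws(self):
        hits = self._hitset(10)
        n_reps = 10_000
        freq = (
            sum(sample_hits(hits, 1, seed=s)[0] == 7 for s in range(n_reps)) / n_reps
        )
        se = math.sqrt(0.1 * 0.9 / n_reps)
        assert abs(freq - 0.1) < 3 * se


class TestLitterAndConcurrent:
    def test_litter_flag_wins(self, rules):
        rec = make_record("microchip implanted", litter=True)
        assert detect_litter(rec, rules)

    def test_litter_text_pattern(self, rules):
        assert detect_litter(make_record("litter of 6 pups all microchipped"), rules)

    def test_individual_record_not_litter(self, rules):
        assert not detect_litter(make_record("microchip implanted at vacc"), rules)

    @pytest.mark.parametrize(
        "text, events",
        [
            ("C5 vaccination given, microchip implanted", {ConcurrentEvent.VACCINATION}),
            ("spay + microchip under same GA", {ConcurrentEvent.SPAY}),
            ("microchip implanted, no other procedures", {ConcurrentEvent.NONE}),
            (
                "castration and C5 vaccination, microchip implanted",
                {ConcurrentEvent.CASTRATION, ConcurrentEvent.VACCINATION},
            ),
        ],
    )
    def test_extract_concurrent(self, rules, text, events):
        assert extract_concurrent(make_record(text), rules) == events


class TestTabulate:
    def test_counts_conserve_n(self):
        labels = [HitCategory.IMPLANTATION_EVENT] * 3
        table = tabulate_classifications(labels)
        assert table[HitCategory.IMPLANTATION_EVENT] == 3
        assert table.total == 3
        assert sum(table.counts.values()) == 3

    def test_empty_labels(self):
        table = tabulate_classifications([])
        assert table.total == 0
        assert all(table[c] == 0 for c in HitCategory)

    def test_generator_labels_pass_through(self):
        cfg = GeneratorConfig(n_patients=1000, hit_fraction=1.0, seed=7)
        _, truth = generate(cfg)
        table = tabulate_classifications(truth.category)
        assert table.total == 1000
        # exact pass-through of the mixture draw
        for cat in HitCategory:
            assert table[cat] == sum(1 for c in truth.category if c is cat)


class TestRuleSetSerialization:
    def test_yaml_round_trip(self, tmp_path, rules):
        path = tmp_path / "rules.yaml"
        rules.to_yaml(path)
        from chipseek.classify import RuleSet

        loaded = RuleSet.from_yaml(path)
        assert [(r.pattern, r.category) for r in loaded.rules] == [
            (r.pattern, r.category) for r in rules.rules
        ]
        assert loaded.default is rules.default
        assert loaded.litter_patterns == rules.litter_patterns
        assert loaded.concurrent_patterns == rules.concurrent_patterns
        rec = make_record("scanned, no microchip found")
        assert classify_hit(rec, loaded) is classify_hit(rec, rules)
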