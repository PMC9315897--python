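import math

import numpy as np
import pytest

from depehr import SimConfig, generate_cohort, inject_misspelling, render_note
from depehr.cohort import write_cohort
from depehr.negation import validate_bio
from depehr.synth import (
    FILLERS,
    SentencePlan,
    SynthError,
    emit_negation_corpus,
    perturb_surface,
)
from depehr.textmine import TermMatcher, tokenize

from oracles import ref_osa_distance


class TestSimConfig:
    def test_invalid_probability_rejected(self):
        with pytest.raises(SynthError):
            SimConfig(p_depression_after=1.2).validate()

    def test_stage_probs_must_sum_to_one(self):
        with pytest.raises(SynthError):
            SimConfig(stage_probs=(0.5, 0.5, 0.5, 0.0, 0.0)).validate()


class TestDeterminismAndConservation:
    def test_same_seed_gives_byte_identical_cohorts(self, tmp_path):
        cfg = SimConfig(n_patients=30, seed=9)
        for sub in ("a", "b"):
            patients, truth = generate_cohort(cfg)
            write_cohort(patients, tmp_path / sub)
            truth.to_json(tmp_path / sub / "truth.json")
        for name in ("patients.csv", "visits.csv", "notes.jsonl", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_zero_prevalence_means_zero_planted_evidence(self):
        cfg = SimConfig(
            n_patients=40,
            seed=1,
            p_depression_before=0.0,
            p_depression_after=0.0,
            negation_rate=0.0,
        )
        patients, truth = generate_cohort(cfg)
        assert truth.mentions == []
        for classes in truth.channel_classes.values():
            assert set(classes.values()) == {"none"}

    def test_temporal_classes_partition_cohort(self, small_cohort):
        cfg, _, truth = small_cohort
        for channel in ("icd", "drug", "disorder"):
            counts = truth.class_counts(channel)
            assert sum(counts.values()) == cfg.n_patients

    def test_noise_free_config_plants_exact_unnegated_surfaces(self, lexicon):
        cfg = SimConfig(n_patients=60, seed=4, misspelling_rate=0.0, negation_rate=0.0)
        _, truth = generate_cohort(cfg)
        surfaces = {e.surface for e in lexicon}
        assert truth.mentions, "expected planted evidence"
        for m in truth.mentions:
            assert not m.negated and not m.misspelled
            assert m.surface in surfaces


class TestPlantedFrequencies:
    def test_after_only_frequency_matches_binomial_expectation(self):
        """The generator samples before/after depression independently, so
        P(after_only planted on >=1 channel) = p_after*(1-p_before)*q where
        q = P(any channel emits) — compare the observed rate against its
        exact binomial three-sigma band."""
        p_after, p_before = 0.15, 0.02
        cfg = SimConfig(
            n_patients=4000,
            seed=77,
            p_depression_before=p_before,
            p_depression_after=p_after,
            misspelling_rate=0.0,
        )
        _, truth = generate_cohort(cfg)
        q_any = 1.0 - math.prod(
            1 - p for p in cfg.channel_probs.values()
        )  # >=1 channel emits given a depressed period
        # after-only on the combined-evidence level
        p_expected = p_after * q_any * (1 - p_before * q_any)
        observed = 0
        for classes in truth.channel_classes.values():
            after = any(c in ("after_only", "both") for c in classes.values())
            before = any(c in ("before_only", "both") for c in classes.values())
            if after and not before:
                observed += 1
        n = cfg.n_patients
        sd = math.sqrt(n * p_expected * (1 - p_expected))
        assert abs(observed - n * p_expected) < 3 * sd


class TestMisspelling:
    def test_injected_misspellings_are_distance_one(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            word = "citalopram"
            out = inject_misspelling(word, rng)
            assert out != word
            assert ref_osa_distance(word, out) == 1

    def test_short_words_returned_unchanged(self):
        rng = np.random.default_rng(0)
        assert inject_misspelling("no", rng) == "no"

    def test_property_over_random_words(self):
        rng = np.random.default_rng(123)
        letters = np.array(list("abcdefghijklmnopqrstuvwxyz"))
        for _ in range(2000):
            word = "".join(rng.choice(letters, size=int(rng.integers(4, 12))))
            out = inject_misspelling(word, rng)
            assert ref_osa_distance(word, out) == 1

    def test_perturbed_surface_unambiguous(self, lexicon):
        rng = np.random.default_rng(5)
        surfaces = {e.normalized for e in lexicon}
        for surf in ["citalopram", "trastorno depresivo", "sertralina"]:
            out = perturb_surface(surf, rng, surfaces)
            assert ref_osa_distance(surf, out) == 1
            for other in surfaces - {surf}:
                assert ref_osa_distance(out, other) > 1


class TestRenderNote:
    def test_positive_plan_span_indexes_surface(self, lexicon):
        rng = np.random.default_rng(0)
        entry = next(e for e in lexicon if e.surface == "citalopram")
        text, mentions, _ = render_note(
            [SentencePlan("positive", entry)], "es", rng, lexicon=lexicon
        )
        (m,) = mentions
        assert text[m.start : m.end] == "citalopram"
        assert not m.negated

    def test_negated_plan_places_term_inside_scope(self, lexicon):
        rng = np.random.default_rng(1)
        entry = next(e for e in lexicon if e.surface == "trastorno depresivo")
        text, mentions, sentences = render_note(
            [SentencePlan("negated", entry)], "es", rng, lexicon=lexicon
        )
        (m,) = mentions
        assert m.negated
        (s,) = sentences
        assert s.scope is not None and s.marker is not None
        assert s.scope[0] <= m.start and m.end <= s.scope[1]
        assert s.marker[1] <= s.scope[0]

    def test_wrong_language_entry_rejected(self, lexicon):
        rng = np.random.default_rng(2)
        entry = next(e for e in lexicon if e.language == "ca")
        with pytest.raises(SynthError):
            render_note([SentencePlan("positive", entry)], "es", rng, lexicon=lexicon)

    def test_fillers_contain_no_lexicon_surface(self, lexicon):
        matcher = TermMatcher(lexicon, max_edits=1)
        for lang in ("es", "ca"):
            for sent in FILLERS[lang]:
                assert matcher.match(sent) == []


class TestNegationCorpus:
    def test_default_corpus_language_split(self, negation_corpus):
        train, heldout = negation_corpus
        sentences = train + heldout
        langs = [s.language for s in sentences]
        assert langs.count("es") == 572
        assert langs.count("ca") == 277

    def test_labels_are_valid_bio(self, negation_corpus):
        train, heldout = negation_corpus
        validate_bio(train + heldout)

    def test_o_tokens_lie_outside_planted_scopes(self, small_cohort):
        _, _, truth = small_cohort
        for sent in truth.sentences[:500]:
            if sent.scope is None:
                continue
            toks = tokenize(sent.text)
            scope = (sent.scope[0] - sent.start, sent.scope[1] - sent.start)
            marker = (sent.marker[0] - sent.start, sent.marker[1] - sent.start)
            for t in toks:
                inside = scope[0] <= t.start and t.end <= scope[1]
                in_marker = marker[0] <= t.start and t.end <= marker[1]
                if not inside and not in_marker:
                    # an O token must not overlap the scope at all
                    assert t.end <= scope[0] or t.start >= scope[1]

    def test_oversized_request_raises(self, small_cohort):
        _, _, truth = small_cohort
        with pytest.raises(SynthError):
            emit_negation_corpus(truth, n_es=10**6, n_ca=10)
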