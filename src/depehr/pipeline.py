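"""End-to-end orchestration: notes -> mentions -> classifications -> report.

Ties the stages together the way the study applies them: language
identification per note, language-specific term matching, negation
filtering, per-channel temporal classification against the index date,
and the paired-table statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cohort import PatientRecord
from .lexicons import CodeSet, Lexicon, default_lexicon
from .negation import TaggerModel, find_negation_spans, is_negated
from .phenotyping import apply_selection_criteria, classify_cohort
from .report import StudyReport, build_report
from .textmine import Mention, TermMatcher, detect_language, mark_negated, tokenize


@dataclass
class MiningConfig:
    max_edits: int = 1
    negation_mode: str = "rule"  # "rule" | "crf"
    negation_window: int = 5
    diagnosis_day_is_after: bool = True


def mine_notes(
    patients: list[PatientRecord],
    lexicon: Lexicon | None = None,
    config: MiningConfig | None = None,
    tagger: TaggerModel | None = None,
) -> list[Mention]:
    """Detect negation-flagged term mentions in every note of a cohort."""
    config = config or MiningConfig()
    lexicon = lexicon or default_lexicon()
    matchers = {
        "es": TermMatcher(lexicon.for_language("es"), config.max_edits),
        "ca": TermMatcher(lexicon.for_language("ca"), config.max_edits),
        "unknown": TermMatcher(lexicon, config.max_edits),
    }
    mentions: list[Mention] = []
    for p in patients:
        for v in p.visits:
            for idx, note in enumerate(v.notes):
                lang = detect_language(note.text)
                tokens = tokenize(note.text)
                found = matchers[lang].match(
                    note.text,
                    tokens,
                    patient_id=p.patient_id,
                    visit_id=v.visit_id,
                    note_index=idx,
                )
                if not found:
                    continue
                note_key = f"{p.patient_id}/{v.visit_id}/{idx}"
                spans = find_negation_spans(
                    note.text,
                    mode=config.negation_mode,
                    model=tagger,
                    language=lang,
                    window=config.negation_window,
                    note_key=note_key,
                )
                for m in found:
                    mentions.append(mark_negated(m, is_negated(m, spans)))
    return mentions


def run_study(
    patients: list[PatientRecord],
    lexicon: Lexicon | None = None,
    config: MiningConfig | None = None,
    tagger: TaggerModel | None = None,
    depression_codes: CodeSet | None = None,
) -> tuple[StudyReport, list[Mention]]:
    """Selection, mining, classification, and reporting in one call."""
    config = config or MiningConfig()
    included, exclusions = apply_selection_criteria(patients)
    mentions = mine_notes(included, lexicon, config, tagger)
    classifications = classify_cohort(
        included,
        mentions,
        depression_codes=depression_codes,
        diagnosis_day_is_after=config.diagnosis_day_is_after,
    )
    report = build_report(included, classifications, exclusions)
    return report, mentions
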