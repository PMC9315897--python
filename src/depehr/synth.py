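"""Synthetic cancer-cohort generator with full ground truth.

Emulates the statistical structure of a two-cancer (breast/colorectal)
hospital cohort: registry attributes, per-patient visit timelines
straddling the cancer-diagnosis index date, ICD-coded depression
diagnoses, and bilingual (Spanish/Catalan) template-based clinical notes
containing positive, negated, and misspelled mentions of disorder terms
and antidepressant names. Every planted fact is recorded — character
spans, negation scopes, per-channel temporal classes — so the whole
downstream pipeline can be validated offline against known truth.

Note text is template-based rather than freely generated: that is what
makes exact span/scope ground truth possible. See docs/methods.md for
what this does and does not emulate.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cohort import Note, PatientRecord, Visit
from .editdist import osa_distance
from .lexicons import Lexicon, LexiconEntry, default_lexicon
from .textmine import tokenize

logger = logging.getLogger(__name__)

CHANNELS = ("icd", "drug", "disorder")
TEMPORAL_CLASSES = ("none", "before_only", "after_only", "both")

DEPRESSION_CODES = ["311", "296.20", "296.30", "300.4", "309.0", "309.1", "298.0"]
BREAST_CODES = ["174.9", "174.4", "174.8"]
COLORECTAL_CODES = ["153.4", "153.9", "154.0", "154.1"]
BENIGN_CODES = ["401.9", "250.00", "530.81", "466.0", "715.90", "272.4"]

# --- note templates --------------------------------------------------------
# ⟦...⟧ marks the negation marker, ⟨...⟩ its scope; {term} is the planted
# lexicon surface. Fillers contain no lexicon surface and no trigger word.

FILLERS = {
    "es": [
        "Paciente acude a consulta de seguimiento programada.",
        "Se revisan las pruebas complementarias y la analitica.",
        "Exploracion fisica dentro de la normalidad.",
        "Se ajusta la pauta y se cita para control.",
        "Evolucion favorable desde la ultima visita.",
        "Tolera bien la medicacion pautada.",
        "Constantes estables durante la exploracion de hoy.",
    ],
    "ca": [
        "Pacient acudeix a consulta de seguiment programada.",
        "Es revisen les proves complementaries i la analitica.",
        "Exploracio fisica dins de la normalitat.",
        "S'ajusta la pauta i es cita per a control.",
        "Evolucio favorable des de la darrera visita.",
        "Tolera be la medicacio pautada.",
        "Constants estables durant la exploracio de avui.",
    ],
}

POSITIVE_TEMPLATES = {
    ("es", "drug"): [
        "En tratamiento con {term}.",
        "Se inicia tratamiento con {term}.",
        "Se pauta {term} por indicacion de psiquiatria.",
        "Continua con {term} a dosis habituales.",
    ],
    ("es", "disorder"): [
        "Presenta {term} en seguimiento por psiquiatria.",
        "Diagnostico de {term} en tratamiento actual.",
        "Cuadro compatible con {term} desde hace meses.",
    ],
    ("ca", "drug"): [
        "En tractament amb {term}.",
        "S'inicia tractament amb {term}.",
        "Es pauta {term} per indicacio de psiquiatria.",
        "Continua amb {term} a dosis habituals.",
    ],
    ("ca", "disorder"): [
        "Presenta {term} en seguiment per psiquiatria.",
        "Diagnostic de {term} en tractament actual.",
        "Quadre compatible amb {term} des de fa mesos.",
    ],
}

NEGATED_TEMPLATES = {
    "es": [
        "⟦No⟧ ⟨refiere {term}⟩.",
        "⟦Niega⟧ ⟨{term} en la actualidad⟩.",
        "⟦Sin⟧ ⟨signos de {term}⟩.",
        "⟦No⟧ ⟨se observa {term}⟩.",
        "⟦No⟧ ⟨refiere {term}⟩ pero persiste insomnio.",
        "⟦No⟧ ⟨refiere sintomatologia compatible con {term} en la actualidad⟩.",
    ],
    "ca": [
        "⟦No⟧ ⟨refereix {term}⟩.",
        "⟦Nega⟧ ⟨{term} en aquest moment⟩.",
        "⟦Sense⟧ ⟨signes de {term}⟩.",
        "⟦No⟧ ⟨hi ha evidencia de {term}⟩.",
        "⟦No⟧ ⟨refereix {term}⟩ pero persisteix insomni.",
        "⟦No⟧ ⟨refereix simptomatologia compatible amb {term} en aquest moment⟩.",
    ],
}


class SynthError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator settings; defaults follow the study cohort's structure.

    Probabilities: ``p_depression_before``/``after`` give the chance a
    patient has depression evidence in each period (sampled
    independently); ``channel_probs`` gives, per evidence channel, the
    chance that a depressed period actually emits that kind of evidence.
    """

    n_patients: int = 1000
    cancer_mix: float = 0.48  # fraction breast
    stage_probs: tuple[float, ...] = (0.17, 0.26, 0.31, 0.18, 0.08)
    p_depression_before: float = 0.08
    p_depression_after: float = 0.27
    channel_probs: dict = field(
        default_factory=lambda: {"icd": 0.65, "drug": 0.55, "disorder": 0.35}
    )
    negation_rate: float = 0.15  # per-visit chance of a negated decoy mention
    misspelling_rate: float = 0.1
    visits_per_patient: tuple[int, int] = (4, 12)
    language_mix: float = 0.6  # fraction of notes in Spanish
    p_chemo: dict = field(
        default_factory=lambda: {"breast": 0.446, "colorectal": 0.256}
    )
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.cancer_mix,
            self.p_depression_before,
            self.p_depression_after,
            self.negation_rate,
            self.misspelling_rate,
            self.language_mix,
            *self.channel_probs.values(),
            *self.p_chemo.values(),
            *self.stage_probs,
        ]
        if any(p < 0 or p > 1 for p in probs):
            raise SynthError("all probabilities must lie in [0, 1]")
        if abs(sum(self.stage_probs) - 1.0) > 1e-9:
            raise SynthError("stage_probs must sum to 1")
        if len(self.stage_probs) != 5:
            raise SynthError("stage_probs needs 5 entries (in_situ..IV)")
        if set(self.channel_probs) != set(CHANNELS):
            raise SynthError(f"channel_probs must cover {CHANNELS}")
        lo, hi = self.visits_per_patient
        if lo < 4 or hi < lo:
            raise SynthError("visits_per_patient range must be >= 4")
        if self.n_patients < 1:
            raise SynthError("n_patients must be positive")


@dataclass
class PlantedMention:
    note_key: str  # patient_id/visit_id/note_index
    start: int
    end: int
    surface: str
    category: str
    concept_id: str
    negated: bool
    misspelled: bool


@dataclass
class PlantedSentence:
    note_key: str
    language: str
    text: str
    start: int  # offsets within the note
    end: int
    marker: tuple[int, int] | None  # note coordinates
    scope: tuple[int, int] | None


@dataclass
class CohortTruth:
    channel_classes: dict[str, dict[str, str]]  # patient -> channel -> class
    mentions: list[PlantedMention]
    sentences: list[PlantedSentence]

    def class_counts(self, channel: str) -> dict[str, int]:
        counts = {c: 0 for c in TEMPORAL_CLASSES}
        for classes in self.channel_classes.values():
            counts[classes[channel]] += 1
        return counts

    def to_json(self, path: str | Path) -> None:
        payload = {
            "channel_classes": self.channel_classes,
            "mentions": [asdict(m) for m in self.mentions],
            "sentences": [asdict(s) for s in self.sentences],
        }
        Path(path).write_text(json.dumps(payload, ensure_ascii=False))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            channel_classes=payload["channel_classes"],
            mentions=[PlantedMention(**m) for m in payload["mentions"]],
            sentences=[
                PlantedSentence(
                    **{
                        **s,
                        "marker": tuple(s["marker"]) if s["marker"] else None,
                        "scope": tuple(s["scope"]) if s["scope"] else None,
                    }
                )
                for s in payload["sentences"]
            ],
        )


# ---------------------------------------------------------------------------
# Misspelling injection

_LETTERS = string.ascii_lowercase


def inject_misspelling(word: str, rng: np.random.Generator) -> str:
    """One random OSA edit (substitution, deletion, insertion, adjacent
    transposition) on a letter position; words shorter than 4 characters
    are returned unchanged with a warning."""
    if len(word) < 4:
        logger.warning("word %r too short to misspell; returned unchanged", word)
        return word
    letter_pos = [i for i, ch in enumerate(word) if ch.isalpha()]
    for _ in range(100):
        op = rng.integers(0, 4)
        i = int(rng.choice(letter_pos))
        if op == 0:  # substitution
            ch = _LETTERS[rng.integers(0, 26)]
            cand = word[:i] + ch + word[i + 1 :]
        elif op == 1:  # deletion (avoid emptying a 1-letter token)
            left = i > 0 and word[i - 1].isalpha()
            right = i + 1 < len(word) and word[i + 1].isalpha()
            if not (left or right):
                continue
            cand = word[:i] + word[i + 1 :]
        elif op == 2:  # insertion
            ch = _LETTERS[rng.integers(0, 26)]
            cand = word[:i] + ch + word[i:]
        else:  # adjacent transposition
            if i + 1 >= len(word) or not word[i + 1].isalpha():
                continue
            cand = word[:i] + word[i + 1] + word[i] + word[i + 2 :]
        if cand != word and "  " not in cand and cand.strip() == cand:
            return cand
    raise SynthError(f"could not misspell {word!r}")


def perturb_surface(
    normalized: str,
    rng: np.random.Generator,
    all_surfaces: set[str],
) -> str:
    """Misspell a normalized lexicon surface such that it stays at OSA
    distance exactly 1 from its origin and >= 2 from every other surface
    (so recovery is unambiguous)."""
    others = [s for s in all_surfaces if s != normalized]
    for _ in range(100):
        cand = inject_misspelling(normalized, rng)
        if cand in all_surfaces:
            continue
        if any(osa_distance(cand, s, max_dist=1) <= 1 for s in others):
            continue
        return cand
    raise SynthError(f"could not unambiguously misspell {normalized!r}")


# ---------------------------------------------------------------------------
# Note rendering


@dataclass
class SentencePlan:
    kind: str  # filler | positive | negated
    entry: LexiconEntry | None = None
    misspelled: bool = False
    template_idx: int | None = None


def _parse_marked_template(rendered: str) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Strip ⟦marker⟧/⟨scope⟩ delimiters, returning plain text and spans."""
    text = []
    pos = 0
    marker = scope = None
    opens: dict[str, int] = {}
    for ch in rendered:
        if ch == "⟦":
            opens["m"] = pos
        elif ch == "⟧":
            marker = (opens["m"], pos)
        elif ch == "⟨":
            opens["s"] = pos
        elif ch == "⟩":
            scope = (opens["s"], pos)
        else:
            text.append(ch)
            pos += 1
    assert marker is not None and scope is not None
    return "".join(text), marker, scope


def render_note(
    plan: list[SentencePlan],
    language: str,
    rng: np.random.Generator,
    lexicon: Lexicon | None = None,
    note_key: str = "",
) -> tuple[str, list[PlantedMention], list[PlantedSentence]]:
    """Render a clinical note from sentence plans, returning the text and
    exact annotations for every planted mention and negation scope."""
    if language not in ("es", "ca"):
        raise SynthError(f"unsupported language {language!r}")
    parts: list[str] = []
    mentions: list[PlantedMention] = []
    sentences: list[PlantedSentence] = []
    offset = 0
    all_surfaces = (
        {e.normalized for e in lexicon} if lexicon is not None else set()
    )
    for sp in plan:
        if sp.kind == "filler":
            pool = FILLERS[language]
            idx = sp.template_idx
            sent = pool[idx if idx is not None else int(rng.integers(0, len(pool)))]
            marker = scope = None
            term_span = None
            surface = None
        else:
            entry = sp.entry
            if entry is None:
                raise SynthError("mention plan requires a lexicon entry")
            if entry.language not in (language, "both"):
                raise SynthError(
                    f"term {entry.surface!r} ({entry.language}) not usable "
                    f"in a {language} note"
                )
            surface = entry.surface
            if sp.misspelled:
                surface = perturb_surface(entry.normalized, rng, all_surfaces)
            cat = "drug" if entry.category.startswith("drug") else "disorder"
            if sp.kind == "positive":
                pool = POSITIVE_TEMPLATES[(language, cat)]
                idx = sp.template_idx
                tpl = pool[idx if idx is not None else int(rng.integers(0, len(pool)))]
                pre = tpl.index("{term}")
                sent = tpl.format(term=surface)
                term_span = (pre, pre + len(surface))
                marker = scope = None
            elif sp.kind == "negated":
                pool = NEGATED_TEMPLATES[language]
                idx = sp.template_idx
                tpl = pool[idx if idx is not None else int(rng.integers(0, len(pool)))]
                rendered = tpl.format(term=surface)
                sent, marker, scope = _parse_marked_template(rendered)
                pre = sent.index(surface)
                term_span = (pre, pre + len(surface))
            else:
                raise SynthError(f"unknown sentence kind {sp.kind!r}")
        start = offset
        parts.append(sent)
        offset += len(sent) + 1  # single-space join
        end = start + len(sent)
        sentences.append(
            PlantedSentence(
                note_key=note_key,
                language=language,
                text=sent,
                start=start,
                end=end,
                marker=(marker[0] + start, marker[1] + start) if marker else None,
                scope=(scope[0] + start, scope[1] + start) if scope else None,
            )
        )
        if sp.kind != "filler":
            assert term_span is not None and surface is not None and sp.entry
            mentions.append(
                PlantedMention(
                    note_key=note_key,
                    start=term_span[0] + start,
                    end=term_span[1] + start,
                    surface=surface,
                    category=sp.entry.category,
                    concept_id=sp.entry.concept_id,
                    negated=sp.kind == "negated",
                    misspelled=sp.misspelled,
                )
            )
    return " ".join(parts), mentions, sentences


# ---------------------------------------------------------------------------
# Cohort generation


def _temporal_class(before: bool, after: bool) -> str:
    if before and after:
        return "both"
    if before:
        return "before_only"
    if after:
        return "after_only"
    return "none"


def generate_cohort(
    config: SimConfig, lexicon: Lexicon | None = None
) -> tuple[list[PatientRecord], CohortTruth]:
    """Generate ``config.n_patients`` synthetic patients with ground truth.

    Pure function of the config (seed included): identical configs give
    identical cohorts.
    """
    config.validate()
    if lexicon is None:
        lexicon = default_lexicon()
    rng = np.random.default_rng(config.seed)
    by_lang_cat: dict[tuple[str, str], list[LexiconEntry]] = {}
    for e in lexicon:
        langs = ("es", "ca") if e.language == "both" else (e.language,)
        cat = "drug" if e.category.startswith("drug") else "disorder"
        for lang in langs:
            by_lang_cat.setdefault((lang, cat), []).append(e)
    for lang in ("es", "ca"):
        for cat in ("drug", "disorder"):
            if not by_lang_cat.get((lang, cat)):
                raise SynthError(f"lexicon has no {cat} terms usable in {lang}")

    patients: list[PatientRecord] = []
    channel_classes: dict[str, dict[str, str]] = {}
    all_mentions: list[PlantedMention] = []
    all_sentences: list[PlantedSentence] = []
    base_date = dt.date(2010, 1, 1)

    for pi in range(config.n_patients):
        pid = f"P{pi:06d}"
        breast = rng.random() < config.cancer_mix
        cancer_type = "breast" if breast else "colorectal"
        sex = "F" if breast else ("M" if rng.random() < 0.579 else "F")
        age_mu, age_sd = (62.3, 13.2) if breast else (70.5, 11.4)
        age = float(np.clip(rng.normal(age_mu, age_sd), 25, 95).round(1))
        stage = ["in_situ", "I", "II", "III", "IV"][
            int(rng.choice(5, p=config.stage_probs))
        ]
        chemo = bool(rng.random() < config.p_chemo[cancer_type])
        diagnosis_date = base_date + dt.timedelta(days=int(rng.integers(0, 2000)))

        n_visits = int(rng.integers(*config.visits_per_patient, endpoint=True))
        n_before = int(rng.integers(2, n_visits - 2, endpoint=True))
        before_offsets = sorted(
            -int(d) for d in rng.integers(30, 1095, size=n_before)
        )
        after_offsets = sorted(
            int(d) for d in rng.integers(0, 1095, size=n_visits - n_before)
        )
        visit_dates = [
            diagnosis_date + dt.timedelta(days=d)
            for d in before_offsets + after_offsets
        ]

        # which periods carry depression evidence, and on which channels
        dep = {
            "before": rng.random() < config.p_depression_before,
            "after": rng.random() < config.p_depression_after,
        }
        emits: dict[str, dict[str, bool]] = {
            ch: {
                period: bool(dep[period] and rng.random() < config.channel_probs[ch])
                for period in ("before", "after")
            }
            for ch in CHANNELS
        }

        visits: list[Visit] = []
        visit_period = ["before"] * n_before + ["after"] * (n_visits - n_before)
        # per-visit plans
        icd_plan: dict[int, list[str]] = {i: [] for i in range(n_visits)}
        mention_plan: dict[int, list[SentencePlan]] = {
            i: [] for i in range(n_visits)
        }
        lang_for_visit = [
            "es" if rng.random() < config.language_mix else "ca"
            for _ in range(n_visits)
        ]

        for period in ("before", "after"):
            idxs = [i for i, p in enumerate(visit_period) if p == period]
            if emits["icd"][period]:
                i = int(rng.choice(idxs))
                icd_plan[i].append(
                    DEPRESSION_CODES[int(rng.integers(0, len(DEPRESSION_CODES)))]
                )
            for ch, cat in (("drug", "drug"), ("disorder", "disorder")):
                if emits[ch][period]:
                    i = int(rng.choice(idxs))
                    pool = by_lang_cat[(lang_for_visit[i], cat)]
                    entry = pool[int(rng.integers(0, len(pool)))]
                    missp = (
                        rng.random() < config.misspelling_rate
                        and len(entry.normalized) >= 5
                    )
                    mention_plan[i].append(
                        SentencePlan("positive", entry, misspelled=missp)
                    )

        # decoy negated mentions
        for i in range(n_visits):
            if rng.random() < config.negation_rate:
                cat = "drug" if rng.random() < 0.5 else "disorder"
                pool = by_lang_cat[(lang_for_visit[i], cat)]
                entry = pool[int(rng.integers(0, len(pool)))]
                missp = (
                    rng.random() < config.misspelling_rate
                    and len(entry.normalized) >= 5
                )
                mention_plan[i].append(
                    SentencePlan("negated", entry, misspelled=missp)
                )

        cancer_codes = BREAST_CODES if breast else COLORECTAL_CODES
        for i in range(n_visits):
            vid = f"{pid}V{i:03d}"
            codes = list(icd_plan[i])
            if visit_period[i] == "after" and i == n_before:
                codes.append(cancer_codes[int(rng.integers(0, len(cancer_codes)))])
            if rng.random() < 0.3:
                codes.append(BENIGN_CODES[int(rng.integers(0, len(BENIGN_CODES)))])
            lang = lang_for_visit[i]
            plan = [SentencePlan("filler")]
            plan.extend(mention_plan[i])
            if rng.random() < 0.4:
                plan.append(SentencePlan("filler"))
            note_key = f"{pid}/{vid}/0"
            text, mentions, sentences = render_note(
                plan, lang, rng, lexicon=lexicon, note_key=note_key
            )
            all_mentions.extend(mentions)
            all_sentences.extend(sentences)
            visits.append(
                Visit(
                    visit_id=vid,
                    date=visit_dates[i],
                    icd_codes=codes,
                    notes=[Note(language=lang, text=text)],
                )
            )

        patients.append(
            PatientRecord(
                patient_id=pid,
                sex=sex,
                age_at_diagnosis=age,
                cancer_type=cancer_type,
                stage=stage,
                chemotherapy=chemo,
                diagnosis_date=diagnosis_date,
                visits=visits,
            )
        )
        channel_classes[pid] = {
            ch: _temporal_class(emits[ch]["before"], emits[ch]["after"])
            for ch in CHANNELS
        }

    truth = CohortTruth(
        channel_classes=channel_classes,
        mentions=all_mentions,
        sentences=all_sentences,
    )
    return patients, truth


# ---------------------------------------------------------------------------
# Negation corpus


def emit_negation_corpus(
    truth: CohortTruth,
    n_es: int = 572,
    n_ca: int = 277,
    negated_fraction: float = 0.7,
    split: tuple[float, float] = (0.7, 0.3),
    seed: int = 0,
):
    """Sample an annotated BIO sentence corpus from a cohort's planted
    sentences; defaults mirror the study corpus size (572 es + 277 ca).

    Returns ``(train, heldout)`` lists of
    :class:`~depehr.negation.LabeledSentence`.
    """
    from .negation import LabeledSentence  # avoid import cycle

    if abs(sum(split) - 1.0) > 1e-9 or any(f <= 0 for f in split):
        raise SynthError("split fractions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    selected: list[LabeledSentence] = []
    for lang, n_total in (("es", n_es), ("ca", n_ca)):
        neg = [
            s for s in truth.sentences if s.language == lang and s.scope is not None
        ]
        plain = [
            s for s in truth.sentences if s.language == lang and s.scope is None
        ]
        n_neg = min(int(round(n_total * negated_fraction)), n_total)
        n_plain = n_total - n_neg
        if len(neg) < n_neg or len(plain) < n_plain:
            raise SynthError(
                f"cohort has too few {lang} sentences for the requested "
                f"corpus ({len(neg)} negated / {len(plain)} plain available, "
                f"{n_neg} / {n_plain} requested)"
            )
        for pool, n in ((neg, n_neg), (plain, n_plain)):
            idxs = rng.choice(len(pool), size=n, replace=False)
            for i in sorted(int(j) for j in idxs):
                selected.append(_to_labeled(pool[i], LabeledSentence))
    order = rng.permutation(len(selected))
    shuffled = [selected[int(i)] for i in order]
    n_train = int(round(split[0] * len(shuffled)))
    return shuffled[:n_train], shuffled[n_train:]


def _to_labeled(sent: PlantedSentence, cls):
    tokens = tokenize(sent.text)
    labels = []
    # spans in sentence-local coordinates
    marker = (
        (sent.marker[0] - sent.start, sent.marker[1] - sent.start)
        if sent.marker
        else None
    )
    scope = (
        (sent.scope[0] - sent.start, sent.scope[1] - sent.start)
        if sent.scope
        else None
    )
    prev_kind = "O"
    for t in tokens:
        kind = "O"
        if marker and t.start >= marker[0] and t.end <= marker[1]:
            kind = "MARK"
        elif scope and t.start >= scope[0] and t.end <= scope[1]:
            kind = "SCOPE"
        if kind == "O":
            labels.append("O")
        elif prev_kind == kind:
            labels.append(f"I-{kind}")
        else:
            labels.append(f"B-{kind}")
        prev_kind = kind
    return cls(tokens=[t.surface for t in tokens], labels=labels, language=sent.language)
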