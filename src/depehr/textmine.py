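"""Note-level NLP: language identification, tokenization, term matching.

Matching is dictionary-driven and misspelling-tolerant: every k-token
window of a note is compared to the k-token lexicon surfaces in a
normalized (casefolded, diacritic-free) space, accepting hits up to
Damerau-Levenshtein distance 1 for surfaces of >= 5 characters and exact
hits otherwise. Overlapping candidates resolve to the longest span, then
the smallest edit distance, then the leftmost start.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable

from .editdist import osa_distance, within_one_edit
from .lexicons import Lexicon, LexiconEntry, normalize_surface

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)
_SENT_SPLIT_RE = re.compile(r"[.;\n]")

FUZZY_MIN_SURFACE_LEN = 5  # shorter surfaces must match exactly


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int
    normalized: str


@dataclass(frozen=True)
class Mention:
    patient_id: str
    visit_id: str
    note_index: int
    surface: str
    start: int
    end: int
    category: str
    concept_id: str
    canonical: str
    edit_distance: int
    negated: bool = False


def tokenize(text: str, language: str = "es") -> list[Token]:
    """Split on whitespace and punctuation, keeping punctuation as tokens.

    Offsets are 0-based half-open into ``text``; surfaces plus the
    inter-token gaps reassemble the input exactly.
    """
    from .lexicons import LexiconError

    tokens = []
    for m in _TOKEN_RE.finditer(text):
        surf = m.group(0)
        try:
            norm = normalize_surface(surf)
        except LexiconError:
            norm = surf.casefold()  # e.g. a bare diacritic mark
        tokens.append(
            Token(surface=surf, start=m.start(), end=m.end(), normalized=norm)
        )
    return tokens


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Sentence spans, splitting at '.', ';' and newline (kept with the
    preceding sentence)."""
    spans = []
    start = 0
    for m in _SENT_SPLIT_RE.finditer(text):
        end = m.end()
        if text[start:end].strip():
            spans.append((start, end))
        start = end
    if text[start:].strip():
        spans.append((start, len(text)))
    return spans


# ---------------------------------------------------------------------------
# Language identification


def _load_profiles() -> dict:
    path = resources.files("depehr").joinpath("data", "lang_profiles.json")
    with path.open(encoding="utf-8") as fh:
        return json.load(fh)


_PROFILES: dict | None = None


def detect_language(text: str, margin: int = 1) -> str:
    """Classify a note as Spanish ('es'), Catalan ('ca'), or 'unknown'.

    Counts hits against two fixed profiles of discriminative function
    words and word-final character n-grams; 'unknown' when the winning
    margin is below ``margin`` or no evidence is found.
    """
    global _PROFILES
    if _PROFILES is None:
        _PROFILES = _load_profiles()
    words = [m.group(0).lower() for m in re.finditer(r"\w+", text)]
    scores = {}
    for lang in ("es", "ca"):
        prof = _PROFILES[lang]
        wordset = set(prof["words"])
        score = sum(1 for w in words if w in wordset)
        score += sum(
            1
            for w in words
            for suf in prof["suffixes"]
            if len(w) > len(suf) and w.endswith(suf)
        )
        scores[lang] = score
    es, ca = scores["es"], scores["ca"]
    if es == ca == 0 or abs(es - ca) < margin:
        return "unknown"
    return "es" if es > ca else "ca"


# ---------------------------------------------------------------------------
# Term matching


class MatcherError(ValueError):
    pass


@dataclass
class _Candidate:
    start: int
    end: int
    entry: LexiconEntry
    distance: int
    surface: str  # raw text at the span


class TermMatcher:
    """Indexed fuzzy matcher over a (language-filtered) lexicon.

    For each surface token count k, k-token windows are probed against an
    exact hash, and — for fuzzy-eligible surfaces — against first-character
    buckets plus suffix maps that together cover every string within one
    OSA edit.
    """

    def __init__(self, lexicon: Lexicon, max_edits: int = 1):
        if max_edits not in (0, 1):
            raise MatcherError("max_edits must be 0 or 1")
        self.max_edits = max_edits
        self._by_k: dict[int, dict] = {}
        for e in lexicon:
            if e.normalized != normalize_surface(e.surface):
                raise MatcherError(f"lexicon entry {e.surface!r} not normalized")
            k = len(e.normalized.split(" "))
            idx = self._by_k.setdefault(
                k,
                {"exact": {}, "by_first": {}, "by_suffix": {}, "fuzzy": []},
            )
            idx["exact"].setdefault(e.normalized, []).append(e)
            if max_edits >= 1 and len(e.normalized) >= FUZZY_MIN_SURFACE_LEN:
                idx["fuzzy"].append(e)
                idx["by_first"].setdefault(e.normalized[0], []).append(e)
                idx["by_suffix"].setdefault(e.normalized[1:], []).append(e)

    def _fuzzy_candidates(self, idx: dict, w: str) -> list[LexiconEntry]:
        cands: dict[int, LexiconEntry] = {}
        buckets: list[list[LexiconEntry]] = []
        if w:
            buckets.append(idx["by_first"].get(w[0], []))
        if len(w) > 1:
            # transposition or deletion at position 0 makes the window start
            # with the surface's second character
            buckets.append(idx["by_first"].get(w[1], []))
            # substitution at position 0 (equal length) or an extra leading
            # character on the surface side
            buckets.append(idx["by_suffix"].get(w[1:], []))
            buckets.append(idx["by_suffix"].get(w, []))
            # extra leading character on the window side
            buckets.append(idx["exact"].get(w[1:], []))
        for bucket in buckets:
            for e in bucket:
                if id(e) in cands or e.normalized == w:
                    continue
                if len(e.normalized) < FUZZY_MIN_SURFACE_LEN:
                    continue  # short surfaces require exact matches
                if abs(len(e.normalized) - len(w)) <= 1 and within_one_edit(
                    e.normalized, w
                ):
                    cands[id(e)] = e
        return list(cands.values())

    def match(
        self,
        text: str,
        tokens: list[Token] | None = None,
        patient_id: str = "",
        visit_id: str = "",
        note_index: int = 0,
    ) -> list[Mention]:
        if tokens is None:
            tokens = tokenize(text)
        candidates: list[_Candidate] = []
        for k, idx in self._by_k.items():
            for i in range(len(tokens) - k + 1):
                window = tokens[i : i + k]
                if any(not t.normalized.isalnum() for t in window):
                    continue  # punctuation never participates in a term
                w = " ".join(t.normalized for t in window)
                span = (window[0].start, window[-1].end)
                for e in idx["exact"].get(w, []):
                    candidates.append(_Candidate(*span, e, 0, text[span[0] : span[1]]))
                if self.max_edits >= 1:
                    for e in self._fuzzy_candidates(idx, w):
                        candidates.append(
                            _Candidate(*span, e, 1, text[span[0] : span[1]])
                        )
        resolved = resolve_overlaps(candidates)
        return [
            Mention(
                patient_id=patient_id,
                visit_id=visit_id,
                note_index=note_index,
                surface=c.surface,
                start=c.start,
                end=c.end,
                category=c.entry.category,
                concept_id=c.entry.concept_id,
                canonical=c.entry.canonical,
                edit_distance=c.distance,
            )
            for c in resolved
        ]


def resolve_overlaps(candidates: Iterable[_Candidate]) -> list[_Candidate]:
    """Longest span, then smallest edit distance, then leftmost; ties broken
    by category and concept id for determinism. Returned in span order."""
    ordered = sorted(
        candidates,
        key=lambda c: (
            -(c.end - c.start),
            c.distance,
            c.start,
            c.entry.category,
            c.entry.concept_id,
            c.entry.normalized,
        ),
    )
    accepted: list[_Candidate] = []
    for c in ordered:
        if all(c.end <= a.start or c.start >= a.end for a in accepted):
            accepted.append(c)
    accepted.sort(key=lambda c: (c.start, c.end))
    return accepted


def match_terms(
    text: str,
    tokens: list[Token] | None,
    lexicon: Lexicon,
    max_edits: int = 1,
    **note_ref,
) -> list[Mention]:
    """Convenience wrapper: build a :class:`TermMatcher` and match one note."""
    return TermMatcher(lexicon, max_edits=max_edits).match(
        text, tokens, **note_ref
    )


# ---------------------------------------------------------------------------
# Mention IO (mentions.jsonl)


def write_mentions(mentions: Iterable[Mention], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(json.dumps(m.__dict__, ensure_ascii=False) + "\n")


def read_mentions(path) -> list[Mention]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            out.append(Mention(**json.loads(line)))
    return out


def mark_negated(mention: Mention, negated: bool = True) -> Mention:
    return replace(mention, negated=negated)
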