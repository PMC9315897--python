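"""Detection vocabularies: term lexicons and ICD-9-CM code sets.

Three lexicon categories drive mention detection in clinical notes:
antidepressant active substances, their brand names, and depressive-disorder
terms (SNOMED CT-style concepts). A separate ICD-9-CM code set defines the
coded-diagnosis evidence channel. Defaults ship as package data and are
user-overridable; the pipeline itself is lexicon-agnostic.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

CATEGORIES = ("drug_substance", "drug_brand", "disorder_term")
LANGUAGES = ("es", "ca", "both")

_ICD_RE = re.compile(r"^\d{3}(\.\d{1,2})?$")
_WS_RE = re.compile(r"\s+")


class LexiconError(ValueError):
    """Malformed lexicon content or invalid lexicon input."""


def normalize_surface(text: str, language: str = "both") -> str:
    """Casefold, strip diacritics, and collapse whitespace.

    Clinical notes use accents inconsistently ("depresión" vs "depresion"),
    so matching happens in a folded space; raw surfaces are kept for
    reporting. Idempotent. The ``language`` tag is accepted for interface
    symmetry; folding is language-independent.
    """
    if not text or not text.strip():
        raise LexiconError("cannot normalize empty or whitespace-only text")
    folded = unicodedata.normalize("NFKD", text)
    folded = unicodedata.normalize("NFKD", folded.casefold())
    folded = "".join(ch for ch in folded if not unicodedata.combining(ch))
    folded = _WS_RE.sub(" ", folded).strip()
    if not folded:
        # inputs made solely of combining marks fold to nothing
        raise LexiconError(f"no textual content after folding: {text!r}")
    return folded


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    language: str  # es | ca | both
    category: str  # drug_substance | drug_brand | disorder_term
    concept_id: str
    canonical: str
    normalized: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.language not in LANGUAGES:
            raise LexiconError(f"bad language tag {self.language!r}")
        if self.category not in CATEGORIES:
            raise LexiconError(f"bad category {self.category!r}")
        if not self.surface.strip():
            raise LexiconError("empty surface")
        if not self.normalized:
            object.__setattr__(
                self, "normalized", normalize_surface(self.surface)
            )


class Lexicon:
    """A validated set of term entries with normalized surfaces.

    Invariants: (normalized surface, category) is unique; every drug_brand
    concept_id resolves to exactly one drug_substance concept.
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        self.entries: list[LexiconEntry] = []
        seen: dict[tuple[str, str], LexiconEntry] = {}
        for e in entries:
            key = (e.normalized, e.category)
            if key in seen:
                logger.warning(
                    "duplicate lexicon entry %r (%s) collapsed", e.surface, e.category
                )
                continue
            seen[key] = e
            self.entries.append(e)
        self._validate_brands()

    def _validate_brands(self) -> None:
        substance_ids = {
            e.concept_id for e in self.entries if e.category == "drug_substance"
        }
        for e in self.entries:
            if e.category == "drug_brand" and e.concept_id not in substance_ids:
                raise LexiconError(
                    f"brand {e.surface!r} maps to unknown substance "
                    f"concept {e.concept_id!r}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries)

    def by_category(self, category: str) -> list[LexiconEntry]:
        return [e for e in self.entries if e.category == category]

    def concepts(self, category: str | None = None) -> set[str]:
        return {
            e.concept_id
            for e in self.entries
            if category is None or e.category == category
        }

    def for_language(self, language: str) -> "Lexicon":
        """Entries usable in ``language`` (tag matches or is 'both')."""
        return Lexicon(
            e for e in self.entries if e.language in (language, "both")
        )

    def merged_with(self, other: "Lexicon") -> "Lexicon":
        return Lexicon(list(self.entries) + list(other.entries))

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("surface\tlanguage\tcategory\tconcept_id\tcanonical\n")
            for e in self.entries:
                fh.write(
                    f"{e.surface}\t{e.language}\t{e.category}\t"
                    f"{e.concept_id}\t{e.canonical}\n"
                )


def load_lexicon(
    path: str | Path, category_filter: str | None = None
) -> Lexicon:
    """Read a TSV lexicon (surface, language, category, concept_id, canonical).

    UTF-8, header row, ``#`` comment lines. Malformed rows raise with their
    line number; duplicate (normalized, category) pairs collapse with a
    logged warning.
    """
    entries: list[LexiconEntry] = []
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # header row
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise LexiconError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                entry = LexiconEntry(*[p.strip() for p in parts])
            except LexiconError as exc:
                raise LexiconError(f"{path}:{lineno}: {exc}") from exc
            if category_filter is None or entry.category == category_filter:
                entries.append(entry)
    if not entries:
        logger.warning("lexicon %s is empty", path)
    return Lexicon(entries)


@dataclass(frozen=True)
class CodeSet:
    """ICD-9-CM codes, closed under hierarchical prefix extension.

    A 3-digit member such as "174" matches every subcode ("174.9"); prefix
    membership is how the study states its cancer code criteria.
    """

    codes: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        for c in self.codes:
            if not _ICD_RE.match(c):
                raise LexiconError(f"invalid ICD-9-CM code {c!r}")


def code_matches(code: str, code_set: CodeSet) -> bool:
    """True iff ``code`` equals a member or extends a member prefix."""
    if not _ICD_RE.match(code):
        raise LexiconError(f"invalid ICD-9-CM code {code!r}")
    if code in code_set.codes:
        return True
    for member in code_set.codes:
        if "." not in member and code.startswith(member + "."):
            return True
        if "." in member and code.startswith(member):
            # "296.2" matches "296.2" and "296.20"-style extensions
            if code != member and code.startswith(member):
                return True
    return False


def load_code_set(path: str | Path, label: str = "") -> CodeSet:
    """One code per line, plain text, ``#`` comments."""
    codes = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                codes.append(line)
    return CodeSet(frozenset(codes), label=label)


# ---------------------------------------------------------------------------
# Bundled defaults

def _data_path(name: str) -> Path:
    return Path(str(resources.files("depehr").joinpath("data", name)))


def default_drug_lexicon() -> Lexicon:
    """Antidepressant substances and Spanish-market brand names."""
    return load_lexicon(_data_path("drug_lexicon.tsv"))


def default_disorder_lexicon() -> Lexicon:
    """Bilingual depressive-disorder terms (SNOMED CT-style concepts)."""
    return load_lexicon(_data_path("disorder_lexicon.tsv"))


def default_lexicon() -> Lexicon:
    return default_drug_lexicon().merged_with(default_disorder_lexicon())


def default_depression_codes() -> CodeSet:
    return load_code_set(_data_path("depression_codes.txt"), label="depression")


def breast_cancer_codes() -> CodeSet:
    return CodeSet(frozenset({"174"}), label="breast")


def colorectal_cancer_codes() -> CodeSet:
    return CodeSet(frozenset({"153", "154"}), label="colorectal")
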