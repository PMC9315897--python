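"""Negation detection for Spanish/Catalan clinical text.

Two detectors share one output type: a CRF token-sequence tagger (BIO
labels over negation markers and their scopes, trained on an annotated
sentence corpus) and a NegEx-style rule baseline (a trigger word opens a
fixed-width scope truncated at conjunctions/punctuation). Mentions whose
character span overlaps a detected scope are excluded from phenotype
evidence.
"""

from __future__ import annotations

import hashlib
import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

from .crf import LinearChainCRF, bio_repair
from .textmine import Mention, Token, split_sentences, tokenize

LABELS = ["O", "B-MARK", "I-MARK", "B-SCOPE", "I-SCOPE"]
FEATURE_VERSION = "orthographic-trigger-v1"

# Negation trigger words (single tokens, diacritics-folded for lookup)
TRIGGERS = {
    "es": frozenset({"no", "sin", "niega", "descarta", "tampoco", "nunca", "ausencia"}),
    "ca": frozenset({"no", "sense", "nega", "descarta", "tampoc", "mai", "absencia"}),
}
# Scope terminators for the rule-based detector (plus any punctuation)
TERMINATORS = frozenset({"pero", "aunque", "sino", "sinó", "encara"})


class NegationError(ValueError):
    pass


def _fold(s: str) -> str:
    folded = unicodedata.normalize("NFKD", s.casefold())
    return "".join(ch for ch in folded if not unicodedata.combining(ch))


@dataclass(frozen=True)
class NegationSpan:
    marker: tuple[int, int]
    scope: tuple[int, int]
    language: str = "unknown"
    note_key: str = ""


@dataclass
class LabeledSentence:
    tokens: list[str]
    labels: list[str]
    language: str = "unknown"


# ---------------------------------------------------------------------------
# Features

_SHAPE_MAP = {}


def _word_shape(w: str) -> str:
    out = []
    last = None
    for ch in w:
        if ch.isdigit():
            c = "d"
        elif ch.isalpha():
            c = "X" if ch.isupper() else "x"
        else:
            c = ch
        if c != last:
            out.append(c)
        last = c
    return "".join(out)


def featurize(tokens: list[str], index: int) -> list[str]:
    """Orthographic + trigger-lexicon features for one token position.

    Deterministic; includes the same descriptors for window offsets
    -2..+2 plus begin/end-of-sentence flags. No part-of-speech input.
    """
    feats: list[str] = []

    def token_feats(j: int, prefix: str, full: bool) -> None:
        w = tokens[j]
        lw = _fold(w)
        feats.append(f"{prefix}w={lw}")
        if lw in TRIGGERS["es"]:
            feats.append(f"{prefix}trig_es")
        if lw in TRIGGERS["ca"]:
            feats.append(f"{prefix}trig_ca")
        if full:
            feats.append(f"{prefix}shape={_word_shape(w)}")
            feats.append(f"{prefix}pre3={lw[:3]}")
            feats.append(f"{prefix}suf3={lw[-3:]}")
            if not any(ch.isalnum() for ch in w):
                feats.append(f"{prefix}punct")
            if w.isdigit():
                feats.append(f"{prefix}digit")

    token_feats(index, "", full=True)
    for off in (-2, -1, 1, 2):
        j = index + off
        if 0 <= j < len(tokens):
            token_feats(j, f"{off:+d}:", full=False)
    if index == 0:
        feats.append("BOS")
    if index == len(tokens) - 1:
        feats.append("EOS")
    return feats


def featurize_sentence(tokens: list[str]) -> list[list[str]]:
    return [featurize(tokens, i) for i in range(len(tokens))]


# ---------------------------------------------------------------------------
# Corpus IO (CoNLL-style TSV)


def validate_bio(sentences: list[LabeledSentence]) -> None:
    bad = []
    for i, s in enumerate(sentences):
        prev = "O"
        for lab in s.labels:
            if lab not in LABELS:
                bad.append(i)
                break
            if lab.startswith("I-") and prev not in (
                "B-" + lab[2:],
                "I-" + lab[2:],
            ):
                bad.append(i)
                break
            prev = lab
    if bad:
        raise NegationError(f"invalid BIO label sequences in sentences {bad}")


def write_conll(sentences: list[LabeledSentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(f"# language={s.language}\n")
            for tok, lab in zip(s.tokens, s.labels):
                fh.write(f"{tok}\t{lab}\n")
            fh.write("\n")


def read_conll(path: str | Path) -> list[LabeledSentence]:
    sentences: list[LabeledSentence] = []
    tokens: list[str] = []
    labels: list[str] = []
    language = "unknown"
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#"):
                if "language=" in line:
                    language = line.split("language=", 1)[1].strip()
                continue
            if not line.strip():
                if tokens:
                    sentences.append(LabeledSentence(tokens, labels, language))
                    tokens, labels, language = [], [], "unknown"
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise NegationError(f"bad CoNLL line: {line!r}")
            tokens.append(parts[0])
            labels.append(parts[1])
    if tokens:
        sentences.append(LabeledSentence(tokens, labels, language))
    return sentences


def corpus_hash(sentences: list[LabeledSentence]) -> str:
    h = hashlib.sha256()
    for s in sentences:
        h.update("\x1f".join(s.tokens).encode())
        h.update("\x1e".encode())
        h.update("\x1f".join(s.labels).encode())
        h.update("\x1d".encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Tagger


@dataclass
class TaggerModel:
    crf: LinearChainCRF
    feature_version: str = FEATURE_VERSION
    labels: tuple[str, ...] = tuple(LABELS)
    metadata: dict = field(default_factory=dict)

    def predict_labels(self, tokens: list[str]) -> list[str]:
        if not tokens:
            return []
        raw = self.crf.predict(featurize_sentence(tokens))
        return bio_repair(raw)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.crf.save(str(path))
        real = path if path.suffix == ".npz" else path.with_suffix(
            path.suffix + ".npz"
        )
        sidecar = Path(str(real) + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "feature_version": self.feature_version,
                    "labels": list(self.labels),
                    "metadata": self.metadata,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "TaggerModel":
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        sidecar = json.loads(Path(str(path) + ".json").read_text())
        model = cls(
            crf=LinearChainCRF.load(str(path)),
            feature_version=sidecar["feature_version"],
            labels=tuple(sidecar["labels"]),
            metadata=sidecar["metadata"],
        )
        if model.feature_version != FEATURE_VERSION:
            raise NegationError(
                f"model feature version {model.feature_version!r} does not "
                f"match featurizer {FEATURE_VERSION!r}"
            )
        return model


def train_tagger(
    corpus: list[LabeledSentence],
    l2: float = 0.5,
    max_iter: int = 120,
    seed: int = 0,
) -> TaggerModel:
    """Fit the CRF on an annotated corpus (reproducible: the objective is
    deterministic and convex, so the seed is recorded but does not alter
    the fit)."""
    if not corpus:
        raise NegationError("empty training corpus")
    validate_bio(corpus)
    X = [featurize_sentence(s.tokens) for s in corpus]
    y = [s.labels for s in corpus]
    crf = LinearChainCRF(labels=LABELS, l2=l2, max_iter=max_iter).fit(X, y)
    n_tokens = sum(len(s.tokens) for s in corpus)
    correct = sum(
        sum(p == g for p, g in zip(bio_repair(crf.predict(xi)), yi))
        for xi, yi in zip(X, y)
    )
    model = TaggerModel(
        crf=crf,
        metadata={
            "seed": seed,
            "corpus_hash": corpus_hash(corpus),
            "n_sentences": len(corpus),
            "n_tokens": n_tokens,
            "train_token_accuracy": correct / max(n_tokens, 1),
            "l2": l2,
            "max_iter": max_iter,
        },
    )
    return model


def _spans_from_labels(
    tokens: list[Token], labels: list[str], language: str, note_key: str = ""
) -> list[NegationSpan]:
    runs: list[tuple[str, int, int]] = []  # (kind, first_tok, last_tok)
    for i, lab in enumerate(labels):
        if lab.startswith("B-"):
            runs.append((lab[2:], i, i))
        elif lab.startswith("I-") and runs and runs[-1][0] == lab[2:] and runs[-1][2] == i - 1:
            kind, a, _ = runs[-1]
            runs[-1] = (kind, a, i)
    markers = [
        (tokens[a].start, tokens[b].end) for kind, a, b in runs if kind == "MARK"
    ]
    spans = []
    for kind, a, b in runs:
        if kind != "SCOPE":
            continue
        scope = (tokens[a].start, tokens[b].end)
        preceding = [m for m in markers if m[0] <= scope[0]]
        marker = preceding[-1] if preceding else (scope[0], scope[0])
        spans.append(
            NegationSpan(
                marker=marker, scope=scope, language=language, note_key=note_key
            )
        )
    return spans


def tag_negation(
    tokens: list[Token],
    model: TaggerModel,
    language: str = "unknown",
    note_key: str = "",
) -> list[NegationSpan]:
    """CRF-decode marker/scope spans for one sentence's tokens."""
    if not tokens:
        return []
    labels = model.predict_labels([t.surface for t in tokens])
    return _spans_from_labels(tokens, labels, language, note_key)


def rule_based_negation(
    tokens: list[Token],
    language: str = "unknown",
    window: int = 5,
    note_key: str = "",
) -> list[NegationSpan]:
    """NegEx-style baseline: each trigger opens a scope over the next
    ``window`` tokens, truncated at punctuation or a conjunction
    terminator."""
    if window < 1:
        raise NegationError("window must be >= 1")
    if language in TRIGGERS:
        triggers = TRIGGERS[language]
    else:
        triggers = TRIGGERS["es"] | TRIGGERS["ca"]
    spans = []
    for i, tok in enumerate(tokens):
        if _fold(tok.surface) not in triggers:
            continue
        scope_toks: list[Token] = []
        for j in range(i + 1, min(i + 1 + window, len(tokens))):
            w = _fold(tokens[j].surface)
            if w in TERMINATORS or not any(c.isalnum() for c in w):
                break
            scope_toks.append(tokens[j])
        if not scope_toks:
            continue
        spans.append(
            NegationSpan(
                marker=(tok.start, tok.end),
                scope=(scope_toks[0].start, scope_toks[-1].end),
                language=language,
                note_key=note_key,
            )
        )
    return spans


def find_negation_spans(
    text: str,
    mode: str = "rule",
    model: TaggerModel | None = None,
    language: str = "unknown",
    window: int = 5,
    note_key: str = "",
) -> list[NegationSpan]:
    """Detect negation spans for a whole note, sentence by sentence."""
    spans: list[NegationSpan] = []
    for s_start, s_end in split_sentences(text):
        sent_tokens = [
            t for t in tokenize(text[s_start:s_end])
        ]
        shifted = [
            Token(t.surface, t.start + s_start, t.end + s_start, t.normalized)
            for t in sent_tokens
        ]
        if mode == "crf":
            if model is None:
                raise NegationError("crf mode requires a trained model")
            spans.extend(tag_negation(shifted, model, language, note_key))
        elif mode == "rule":
            spans.extend(
                rule_based_negation(shifted, language, window, note_key)
            )
        else:
            raise NegationError(f"unknown negation mode {mode!r}")
    return spans


def is_negated(mention: Mention, spans: list[NegationSpan]) -> bool:
    """True iff the mention overlaps any scope span by >= 1 character."""
    mkey = f"{mention.patient_id}/{mention.visit_id}/{mention.note_index}"
    for sp in spans:
        if sp.note_key and mkey.strip("/") and sp.note_key != mkey:
            raise NegationError(
                f"cross-note negation check: mention {mkey} vs span "
                f"{sp.note_key}"
            )
        if mention.start < sp.scope[1] and sp.scope[0] < mention.end:
            return True
    return False


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class TaggerEvaluation:
    per_class: dict[str, tuple[float, float, float]]  # class -> (P, R, F1)
    token_accuracy: float
    confusion: dict[tuple[str, str], int]

    def f1(self, cls: str) -> float:
        return self.per_class[cls][2]


def _token_class(label: str) -> str:
    return "O" if label == "O" else label[2:]


def evaluate_tagger(
    model: TaggerModel, heldout: list[LabeledSentence]
) -> TaggerEvaluation:
    """Token-level precision/recall/F1 for the MARK and SCOPE classes."""
    return evaluate_predictions(
        [model.predict_labels(s.tokens) for s in heldout], heldout
    )


def evaluate_predictions(
    predicted: list[list[str]], heldout: list[LabeledSentence]
) -> TaggerEvaluation:
    if not heldout:
        raise NegationError("empty held-out corpus")
    confusion: dict[tuple[str, str], int] = {}
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    correct = total = 0
    for pred, sent in zip(predicted, heldout):
        for p, g in zip(pred, sent.labels):
            confusion[(g, p)] = confusion.get((g, p), 0) + 1
            total += 1
            if p == g:
                correct += 1
            pc, gc = _token_class(p), _token_class(g)
            if pc == gc and pc != "O":
                tp[pc] = tp.get(pc, 0) + 1
            else:
                if pc != "O":
                    fp[pc] = fp.get(pc, 0) + 1
                if gc != "O":
                    fn[gc] = fn.get(gc, 0) + 1
    per_class = {}
    for cls in ("MARK", "SCOPE"):
        p_den = tp.get(cls, 0) + fp.get(cls, 0)
        r_den = tp.get(cls, 0) + fn.get(cls, 0)
        prec = tp.get(cls, 0) / p_den if p_den else 0.0
        rec = tp.get(cls, 0) / r_den if r_den else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[cls] = (prec, rec, f1)
    return TaggerEvaluation(
        per_class=per_class,
        token_accuracy=correct / max(total, 1),
        confusion=confusion,
    )
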