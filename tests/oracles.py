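"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own algorithms: edit distance via
memoized recursion over the explicit operation set, matching via
exhaustive window x surface scans, metrics via hand-style counting.
"""

from __future__ import annotations

import functools
import string


def ref_osa_distance(a: str, b: str) -> int:
    """Memoized recursive optimal-string-alignment distance."""

    @functools.lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        best = d(i - 1, j) + 1  # delete from a
        best = min(best, d(i, j - 1) + 1)  # insert into a
        best = min(best, d(i - 1, j - 1) + (a[i - 1] != b[j - 1]))
        if (
            i > 1
            and j > 1
            and a[i - 1] == b[j - 2]
            and a[i - 2] == b[j - 1]
        ):
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    return d(len(a), len(b))


def one_edit_neighbourhood(word: str, alphabet: str = string.ascii_lowercase) -> set[str]:
    """All strings at OSA distance exactly <= 1 (including the word)."""
    out = {word}
    for i in range(len(word)):
        out.add(word[:i] + word[i + 1 :])  # deletion
        for ch in alphabet:
            out.add(word[:i] + ch + word[i + 1 :])  # substitution
            out.add(word[:i] + ch + word[i:])  # insertion
        if i + 1 < len(word):
            out.add(word[:i] + word[i + 1] + word[i] + word[i + 2 :])
    for ch in alphabet:
        out.add(word + ch)
    return out


def brute_force_match(text, tokens, lexicon, max_edits=1):
    """Exhaustive matcher: every k-token window against every k-token
    surface, with the same tie-breaking contract as the package matcher
    (longest span, smallest distance, leftmost, then category/concept)."""
    by_k = {}
    for e in lexicon:
        by_k.setdefault(len(e.normalized.split(" ")), []).append(e)
    candidates = []
    for k, entries in by_k.items():
        for i in range(len(tokens) - k + 1):
            window = tokens[i : i + k]
            if any(not t.normalized.isalnum() for t in window):
                continue
            w = " ".join(t.normalized for t in window)
            for e in entries:
                if abs(len(e.normalized) - len(w)) > max_edits:
                    continue
                dist = ref_osa_distance(w, e.normalized)
                limit = max_edits if len(e.normalized) >= 5 else 0
                if dist <= limit:
                    candidates.append(
                        (window[0].start, window[-1].end, dist, e)
                    )
    ordered = sorted(
        candidates,
        key=lambda c: (
            -(c[1] - c[0]),
            c[2],
            c[0],
            c[3].category,
            c[3].concept_id,
            c[3].normalized,
        ),
    )
    accepted = []
    for c in ordered:
        if all(c[1] <= a[0] or c[0] >= a[1] for a in accepted):
            accepted.append(c)
    accepted.sort(key=lambda c: (c[0], c[1]))
    return [
        (start, end, dist, e.category, e.concept_id, e.canonical)
        for start, end, dist, e in accepted
    ]
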