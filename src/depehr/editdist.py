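"""Damerau-Levenshtein (optimal string alignment) edit distance.

The matcher tolerates the single-keystroke errors that dominate clinical-note
misspellings: substitution, deletion, insertion, and adjacent transposition.
Distances here are OSA ("restricted" Damerau-Levenshtein): a transposed pair
cannot be edited again, which is the right model for one-off typos.
"""

from __future__ import annotations


def osa_distance(a: str, b: str, max_dist: int | None = None) -> int:
    """Optimal-string-alignment distance between ``a`` and ``b``.

    With ``max_dist`` set, returns ``max_dist + 1`` as soon as the distance
    provably exceeds it (banded early exit).
    """
    la, lb = len(a), len(b)
    if max_dist is not None and abs(la - lb) > max_dist:
        return max_dist + 1
    if la == 0:
        return lb
    if lb == 0:
        return la

    prev2: list[int] | None = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        row_min = i
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                assert prev2 is not None
                d = min(d, prev2[j - 2] + 1)
            cur[j] = d
            if d < row_min:
                row_min = d
        if max_dist is not None and row_min > max_dist:
            return max_dist + 1
        prev2, prev = prev, cur
    return prev[lb]


def within_one_edit(a: str, b: str) -> bool:
    """True iff OSA distance(a, b) <= 1, in a single linear scan."""
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if a == b:
        return True
    if la == lb:
        # one substitution, or one adjacent transposition
        i = 0
        while i < la and a[i] == b[i]:
            i += 1
        # i is the first mismatch (exists because a != b)
        if a[i + 1 :] == b[i + 1 :]:
            return True  # substitution at i
        return (
            i + 1 < la
            and a[i] == b[i + 1]
            and a[i + 1] == b[i]
            and a[i + 2 :] == b[i + 2 :]
        )
    # lengths differ by one: single insertion/deletion
    if la > lb:
        a, b = b, a
        la, lb = lb, la
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1 :]
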