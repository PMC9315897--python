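"""Paired and association statistics for the before/after analysis.

The headline test is McNemar's chi-square on the discordant pair counts
(b = evidence only before, c = only after the index date) with the
Edwards continuity correction,

    chi2 = (|b - c| - 1)^2 / (b + c),   df = 1,

which is the variant that reproduces the published statistics of this
analysis from the published discordant counts. Associations between categorical patient
attributes (e.g. chemotherapy x depression) use Pearson's chi-square
without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class McNemarResult:
    b: int
    c: int
    chi2: float
    df: int
    p: float


def mcnemar_cc(b: int, c: int, correction: bool = True) -> McNemarResult:
    """Continuity-corrected McNemar test on discordant counts.

    With ``correction=False`` the uncorrected (b-c)^2/(b+c) statistic is
    used instead. Symmetric in (b, c).
    """
    if b < 0 or c < 0:
        raise StatsError("discordant counts must be non-negative")
    if b + c == 0:
        raise StatsError("McNemar test undefined for b = c = 0")
    if correction:
        chi2 = (abs(b - c) - 1) ** 2 / (b + c)
    else:
        chi2 = (b - c) ** 2 / (b + c)
    p = float(sps.chi2.sf(chi2, df=1))
    return McNemarResult(b=b, c=c, chi2=float(chi2), df=1, p=p)


def mcnemar_exact_p(b: int, c: int) -> float:
    """Exact two-sided binomial sign-test p-value (cross-check for the
    chi-square approximation)."""
    if b + c == 0:
        raise StatsError("undefined for b = c = 0")
    n = b + c
    k = min(b, c)
    p = 2.0 * float(sps.binom.cdf(k, n, 0.5))
    if b == c:
        p -= float(sps.binom.pmf(k, n, 0.5))
    return min(p, 1.0)


def chisq_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence on an r x k contingency table
    (no continuity correction)."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise StatsError("need an r x k table with r, k >= 2")
    if (arr < 0).any():
        raise StatsError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise StatsError("degenerate margins (zero row or column total)")
    chi2, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    return float(chi2), int(dof), float(p)


def round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(n: int, d: int, ndigits: int = 1) -> float:
    if d <= 0:
        raise StatsError("denominator must be positive")
    if not 0 <= n <= d:
        raise StatsError("numerator must lie in [0, denominator]")
    return round_half_up(100.0 * n / d, ndigits)


def proportion_cell(n: int, d: int) -> str:
    """Format a count as ``"n/N (%)"`` with a one-decimal half-up percent;
    integer-valued percents print bare (``"(91)"`` rather than
    ``"(91.0)"``), matching the report style."""
    pct = percent(n, d)
    pct_str = str(int(pct)) if pct == int(pct) else f"{pct:.1f}"
    return f"{n}/{d} ({pct_str})"
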