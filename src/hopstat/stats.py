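"""Exact 2x2 contingency testing and printed-percent count recovery.

The Fisher exact test is computed by direct hypergeometric enumeration: with
both margins fixed, every admissible table's point probability is evaluated
via log-factorials, and the two-tailed p-value is the sum over tables no
more probable than the observed one (the minimum-likelihood convention used
by mainstream statistical software). A relative tolerance of 1e-7 treats
tables within floating error of the observed probability as ties.

``recover_count_from_percent`` inverts manuscript rounding: given a percent
printed to one decimal and a group size, it brute-forces the unique integer
count that rounds (half away from zero) to that percent — the bridge that
turns printed percentages back into integer contingency cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.special import gammaln

from .chromatin import ContingencyTable

__all__ = [
    "EnrichmentResult",
    "fisher_exact_two_tailed",
    "odds_ratio",
    "recover_count_from_percent",
    "enrichment_result",
]

TIE_RELTOL = 1e-7


def _as_cells(table: ContingencyTable | list | tuple | np.ndarray) -> tuple[int, int, int, int]:
    if isinstance(table, ContingencyTable):
        return (
            table.canonical_assoc,
            table.canonical_not,
            table.non_canonical_assoc,
            table.non_canonical_not,
        )
    (a, b), (c, d) = table
    cells = (int(a), int(b), int(c), int(d))
    if any(x != y for x, y in zip(cells, (a, b, c, d))):
        raise ValueError("contingency cells must be integers")
    return cells


def _log_pmf(support: np.ndarray, r1: int, r2: int, c1: int, n: int) -> np.ndarray:
    """log hypergeometric point probability for each table in the support,
    parameterized by the top-left cell value."""
    k = support
    return (
        gammaln(r1 + 1)
        + gammaln(r2 + 1)
        + gammaln(c1 + 1)
        + gammaln(n - c1 + 1)
        - gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(r1 - k + 1)
        - gammaln(c1 - k + 1)
        - gammaln(r2 - c1 + k + 1)
    )


def fisher_exact_two_tailed(table: ContingencyTable | list | tuple) -> float:
    """Two-tailed Fisher exact p-value for a 2x2 table of counts.

    Enumerates all tables with the observed margins under the hypergeometric
    null; p sums the point probabilities of tables whose probability is at
    most the observed one (within 1e-7 relative tolerance for ties).
    """
    a, b, c, d = _as_cells(table)
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be nonnegative")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        raise ValueError("both margins must be positive for the exact test")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = _log_pmf(support, r1, r2, c1, n)
    logp_obs = logp[a - lo]
    # sum in the log domain for numerical headroom on large tables
    keep = logp <= logp_obs + math.log1p(TIE_RELTOL)
    m = logp[keep].max()
    p = math.exp(m) * float(np.exp(logp[keep] - m).sum())
    return min(p, 1.0)


def odds_ratio(table: ContingencyTable | list | tuple) -> float:
    """Sample odds ratio (a*d)/(b*c) with the zero-cell conventions:
    +inf when only b*c vanishes, 0 when only a*d vanishes, error when both."""
    a, b, c, d = _as_cells(table)
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be nonnegative")
    ad, bc = a * d, b * c
    if ad == 0 and bc == 0:
        raise ValueError("odds ratio undefined: both diagonal products are zero")
    if bc == 0:
        return math.inf
    return ad / bc


def _round_half_away_tenths(value: Fraction) -> int:
    """round(100 * value, 1 dp) expressed in integer tenths-of-a-percent,
    half away from zero (manuscript rounding)."""
    x = value * 1000  # tenths of a percent, exact rational
    sign = 1 if x >= 0 else -1
    return sign * int(abs(x) + Fraction(1, 2))


def recover_count_from_percent(percent: float, total: int) -> int:
    """The unique count k in [0, total] whose percentage of ``total`` rounds
    to ``percent`` at one decimal (half away from zero).

    Raises if no such count exists (the printed percent is inconsistent with
    the total) or if several do (the total is too large for one-decimal
    precision to pin the count down; the error lists the candidates).
    """
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    if not 0 <= percent <= 100:
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    target_tenths = round(percent * 10)
    if abs(percent * 10 - target_tenths) > 1e-6:
        raise ValueError(f"percent {percent} is not given to one decimal place")
    candidates = [
        k
        for k in range(total + 1)
        if _round_half_away_tenths(Fraction(k, total)) == target_tenths
    ]
    if not candidates:
        raise ValueError(
            f"no count out of {total} rounds to {percent}% at one decimal"
        )
    if len(candidates) > 1:
        raise ValueError(
            f"{percent}% of {total} is ambiguous at one-decimal precision: "
            f"candidates {candidates}"
        )
    return candidates[0]


@dataclass
class EnrichmentResult:
    """Exact-test output bundled with the table and group fractions."""

    table: ContingencyTable
    odds_ratio: float
    p_two_tailed: float
    fraction_canonical: Fraction
    fraction_non_canonical: Fraction


def enrichment_result(table: ContingencyTable) -> EnrichmentResult:
    a, b, c, d = _as_cells(table)
    return EnrichmentResult(
        table=table if isinstance(table, ContingencyTable) else ContingencyTable(a, b, c, d),
        odds_ratio=odds_ratio(table),
        p_two_tailed=fisher_exact_two_tailed(table),
        fraction_canonical=Fraction(a, a + b),
        fraction_non_canonical=Fraction(c, c + d),
    )
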