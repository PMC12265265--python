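"""Independent brute-force oracles for the statistical test battery.

These implementations deliberately avoid scipy/statsmodels and work from
first principles (exhaustive enumeration, exact rational arithmetic) so
they can validate the production implementations without sharing code
paths with them.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from typing import Sequence


def mann_whitney_exact_two_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments.

    Requires tie-free pooled data. Counts assignments whose U is at least
    as far from the null mean n*m/2 as the observed U.
    """
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n, m = len(x), len(y)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    r_obs = sum(rank[v] for v in x)
    u_obs = r_obs - n * (n + 1) / 2
    center = n * m / 2
    total = 0
    extreme = 0
    for combo in itertools.combinations(range(1, n + m + 1), n):
        u = sum(combo) - n * (n + 1) / 2
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            extreme += 1
    return extreme / total


def fisher_exact_two_sided(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration.

    Point-probability method: sums the probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's. Exact rational arithmetic throughout.
    """
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, c1)

    def prob(k: int) -> Fraction:
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > n - r1:
            return Fraction(0)
        return Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)

    p_obs = prob(a)
    # tiny relative guard mirroring floating-point comparison conventions
    cutoff = p_obs * Fraction(10_000_001, 10_000_000)
    total = Fraction(0)
    for k in range(0, min(r1, c1) + 1):
        pk = prob(k)
        if pk > 0 and pk <= cutoff:
            total += pk
    return float(min(total, Fraction(1)))


def bh_step_up(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the step-up definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, p_values[i] * m / (pos + 1))
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def chisq_gof_statistic(observed: Sequence[float], proportions: Sequence[float]) -> float:
    total = sum(observed)
    return sum(
        (o - total * p) ** 2 / (total * p) for o, p in zip(observed, proportions)
    )
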