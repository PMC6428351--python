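"""Independent brute-force oracles used to freeze expected test values.

Everything here is deliberately naive — exhaustive enumeration and
direct formula transcription — and shares no code with the package.
"""

from __future__ import annotations

import math
from itertools import combinations


def hypergeom_tail_enumeration(
    population: int, successes: int, draws: int, observed: int
) -> float:
    """P(X >= observed) by enumerating every possible draw set."""
    success_items = set(range(successes))
    hits = 0
    total = 0
    for draw in combinations(range(population), draws):
        total += 1
        if len(success_items.intersection(draw)) >= observed:
            hits += 1
    return hits / total


def binomial_tail_enumeration(k: int, n: int, p: float) -> float:
    """P(X >= k) by enumerating all 2^n success/failure outcomes."""
    total = 0.0
    for outcome in range(2**n):
        successes = bin(outcome).count("1")
        if successes >= k:
            total += p**successes * (1 - p) ** (n - successes)
    return total


def bh_step_up(p_values):
    """Benjamini-Hochberg step-up q-values by direct rule application."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running_min = min(running_min, p_values[i] * m / rank)
        q[i] = min(running_min, 1.0)
    return q


def kld_direct(p_columns, q_columns) -> float:
    """Sum of p * log2(p/q) over aligned columns, 0*log(0/q) = 0."""
    total = 0.0
    for pc, qc in zip(p_columns, q_columns):
        for pv, qv in zip(pc, qc):
            if pv > 0:
                total += pv * math.log2(pv / qv)
    return total
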