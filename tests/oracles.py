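"""Independent brute-force oracles used only by the test suite.

Each function re-derives a statistic from first principles (closed formula
or exhaustive enumeration) without touching the library code paths it
checks.
"""

from __future__ import annotations

import math

from scipy.stats import t as t_dist


def welch_ttest(case, control) -> tuple[float, float]:
    """Welch t and two-sided p from the textbook formula with
    Satterthwaite degrees of freedom."""
    n1, n2 = len(case), len(control)
    m1 = sum(case) / n1
    m2 = sum(control) / n2
    v1 = sum((x - m1) ** 2 for x in case) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in control) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return t, p


def bh_stepup(p_values) -> list[float]:
    """Benjamini-Hochberg by direct step-up enumeration:
    adj_(i) = min over j >= i of m * p_(j) / j, capped at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        adjusted[i] = min(running, 1.0)
    return adjusted


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by exhaustive summation
    of binomial-coefficient terms."""
    denom = math.comb(N, n)
    upper = min(K, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x) for x in range(k, upper + 1)
    ) / denom


def degree_counts(edges) -> dict[str, int]:
    """Node degrees by direct counting over a de-duplicated undirected
    edge list."""
    seen = set()
    degrees: dict[str, int] = {}
    for a, b in edges:
        key = (min(a, b), max(a, b))
        if a == b or key in seen:
            continue
        seen.add(key)
        degrees[a] = degrees.get(a, 0) + 1
        degrees[b] = degrees.get(b, 0) + 1
    return degrees
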