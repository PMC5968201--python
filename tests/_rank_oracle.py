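"""Independent brute-force Mann-Whitney oracle for the test suite.

Deliberately naive and structurally different from the library's
implementation: it enumerates every binary label assignment (2^(n+m)
masks filtered to group size n) and computes mid-ranks by scanning the
sorted pool, without numpy or scipy.
"""

from __future__ import annotations


def midranks(values: list[float]) -> list[float]:
    """Mid-ranks (1-based) of values, averaging over ties."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_force_p(x: list[float], y: list[float], alternative: str) -> float:
    """Exact rank-sum p-value by enumerating all 2^(n+m) label masks."""
    n, m = len(x), len(y)
    pooled = list(x) + list(y)
    ranks = midranks(pooled)
    observed = sum(ranks[:n])
    total = 0
    le = 0
    ge = 0
    eps = 1e-9
    for mask in range(1 << (n + m)):
        if bin(mask).count("1") != n:
            continue
        total += 1
        s = sum(ranks[i] for i in range(n + m) if mask >> i & 1)
        if s <= observed + eps:
            le += 1
        if s >= observed - eps:
            ge += 1
    p_less = le / total
    p_greater = ge / total
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2.0 * min(p_less, p_greater))
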