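"""Independent brute-force oracles used to check the production code.

These deliberately use the most literal possible formulations (exhaustive
recursion, direct summation, all-pairs loops) and share no code with the
package.
"""

from __future__ import annotations

import math
from functools import lru_cache


def levenshtein_recursive(a: str, b: str) -> int:
    """Exhaustive recursive Levenshtein distance (memoized)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        return min(
            rec(i - 1, j) + 1,      # delete
            rec(i, j - 1) + 1,      # insert
            rec(i - 1, j - 1) + cost,  # substitute / match
        )

    return rec(len(a), len(b))


def entropy_literal(sizes) -> float:
    """Shannon entropy by literal summation over clone probabilities."""
    total = sum(sizes)
    h = 0.0
    for s in sizes:
        p = s / total
        h -= p * math.log(p)
    return h


def evenness_literal(sizes) -> float:
    if len(sizes) == 1:
        return 0.0
    return entropy_literal(sizes) / math.log(len(sizes))


def brute_force_edges(nodes, threshold: int, mode: str):
    """All-pairs edge enumeration for the similarity network.

    nodes: list of (node_key, cdr3b_aa, cdr3a_aa).  Returns the set of
    frozensets of endpoint keys.
    """
    edges = set()
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            ki, bi, ai = nodes[i]
            kj, bj, aj = nodes[j]
            db = levenshtein_recursive(bi, bj)
            da = levenshtein_recursive(ai, aj)
            if mode == "sum":
                hit = db + da <= threshold
            else:
                hit = db <= threshold and da <= threshold
            if hit:
                edges.add(frozenset((ki, kj)))
    return edges


def pearson_literal(x, y) -> float:
    """Closed-form Pearson correlation on two equal-length vectors."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)
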