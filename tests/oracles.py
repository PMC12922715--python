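"""Independent brute-force oracles used to validate the closed forms.

These deliberately avoid the package's formulas: kappa is recomputed from
first principles on explicit tables, and the flip machinery is explored by
breadth-first search over all states reachable by accuracy-preserving
pair-flips.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def kappa_direct(n11: int, n10: int, n01: int, n00: int) -> float:
    """Kappa from first principles on one table (None where undefined)."""
    n = n11 + n10 + n01 + n00
    p1 = (n11 + n10) / n
    p2 = (n11 + n01) / n
    p_o = (n11 + n00) / n
    p_e = p1 * p2 + (1 - p1) * (1 - p2)
    if p_e >= 1.0:
        return None
    return (p_o - p_e) / (1 - p_e)


def pair_flip_moves(state: tuple[int, int, int, int]):
    """All states reachable by ONE accuracy-preserving pair-flip.

    A pair-flip picks, in a single observer, one currently-correct and one
    currently-incorrect trial and flips both, so that observer's accuracy
    is unchanged.  For observer A the (correct, incorrect) trial may come
    from cells (11 or 10, 01 or 00); symmetrically for B.  Each move flips
    exactly 2 trials.
    """
    n11, n10, n01, n00 = state
    moves = set()
    # observer A: correct cell x in {11, 10} -> flipped; incorrect y in {01, 00}
    for x, y in itertools.product(("11", "10"), ("01", "00")):
        s = [n11, n10, n01, n00]
        idx = {"11": 0, "10": 1, "01": 2, "00": 3}
        if s[idx[x]] < 1 or s[idx[y]] < 1:
            continue
        # flipping A in cell 11 -> 01; 10 -> 00; 01 -> 11; 00 -> 10
        dest = {"11": "01", "10": "00", "01": "11", "00": "10"}
        s[idx[x]] -= 1
        s[idx[dest[x]]] += 1
        s[idx[y]] -= 1
        s[idx[dest[y]]] += 1
        moves.add(tuple(s))
    # observer B: correct cell in {11, 01}; incorrect in {10, 00}
    for x, y in itertools.product(("11", "01"), ("10", "00")):
        s = [n11, n10, n01, n00]
        idx = {"11": 0, "10": 1, "01": 2, "00": 3}
        if s[idx[x]] < 1 or s[idx[y]] < 1:
            continue
        dest = {"11": "10", "01": "00", "10": "11", "00": "01"}
        s[idx[x]] -= 1
        s[idx[dest[x]]] += 1
        s[idx[y]] -= 1
        s[idx[dest[y]]] += 1
        moves.add(tuple(s))
    return moves


def flip_search(state: tuple[int, int, int, int]):
    """BFS over all pair-flip-reachable tables.

    Returns (kappa_max, min_flipped_trials_to_reach_it) by exhaustive
    exploration; every move costs 2 flipped trials.
    """
    start = tuple(state)
    dist = {start: 0}
    queue = deque([start])
    while queue:
        s = queue.popleft()
        for nxt in pair_flip_moves(s):
            if nxt not in dist:
                dist[nxt] = dist[s] + 2
                queue.append(nxt)
    best_kappa = -np.inf
    best_cost = None
    for s, cost in dist.items():
        k = kappa_direct(*s)
        if k is None:
            continue
        if k > best_kappa + 1e-12:
            best_kappa, best_cost = k, cost
        elif abs(k - best_kappa) <= 1e-12 and cost < best_cost:
            best_cost = cost
    return best_kappa, best_cost


def all_tables(n_max: int):
    """Every 2x2 contingency table with 1 <= n <= n_max."""
    for n in range(1, n_max + 1):
        for n11 in range(n + 1):
            for n10 in range(n - n11 + 1):
                for n01 in range(n - n11 - n10 + 1):
                    yield (n11, n10, n01, n - n11 - n10 - n01)


def kappa_max_by_table_enumeration(n11: int, n10: int, n01: int, n00: int):
    """Max kappa over ALL tables with the same n and both marginals."""
    n = n11 + n10 + n01 + n00
    a = n11 + n10
    b = n11 + n01
    best = -np.inf
    for m11 in range(max(0, a + b - n), min(a, b) + 1):
        k = kappa_direct(m11, a - m11, b - m11, n - a - b + m11)
        if k is not None:
            best = max(best, k)
    return best
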