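"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — exhaustive enumeration or direct
definition-chasing — and shares no code with the package internals it
checks.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations


# --- hypergeometric tail by exhaustive carrier placement -------------------

def hypergeom_tail_enum(c_obs: int, m1: int, m2: int, N: int) -> float:
    """P(|A n B| >= c_obs) for a fixed A = {0..m1-1} and all C(N, m2)
    placements of B, each equally likely."""
    hits = 0
    total = 0
    for B in combinations(range(N), m2):
        total += 1
        overlap = sum(1 for b in B if b < m1)
        if overlap >= c_obs:
            hits += 1
    return hits / total


def overlap_tail_table(m1: int, m2: int, N: int) -> list[float]:
    """Tail probabilities for every c_obs in 0..min(m1, m2)."""
    counts = [0] * (min(m1, m2) + 1)
    total = 0
    for B in combinations(range(N), m2):
        total += 1
        counts[sum(1 for b in B if b < m1)] += 1
    tails = []
    for c in range(min(m1, m2) + 1):
        tails.append(sum(counts[c:]) / total)
    return tails


# --- core numbers by subset search ----------------------------------------

def core_numbers_brute(edges: list[tuple], nodes: list) -> dict:
    """core(v) = max over vertex subsets S containing v of the minimum
    induced degree of S.  Exponential; fine for n <= 8."""
    nodes = list(nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [set() for _ in range(n)]
    for u, v in edges:
        adj[idx[u]].add(idx[v])
        adj[idx[v]].add(idx[u])
    best = [0] * n
    for mask in range(1, 1 << n):
        members = [i for i in range(n) if mask >> i & 1]
        mdeg = min(len(adj[i] & set(members)) for i in members)
        for i in members:
            if mdeg > best[i]:
                best[i] = mdeg
    return {nodes[i]: best[i] for i in range(n)}


# --- naive ordered-forest edit distance -----------------------------------

def tree_to_tuple(node) -> tuple:
    return (node.label, tuple(tree_to_tuple(c) for c in node.children))


def _forest_size(forest: tuple) -> int:
    return sum(1 + _forest_size(children) for _, children in forest)


@lru_cache(maxsize=None)
def _forest_dist(f: tuple, g: tuple) -> int:
    if not f and not g:
        return 0
    if not f:
        return _forest_size(g)
    if not g:
        return _forest_size(f)
    (vl, vc), frest = f[-1], f[:-1]
    (wl, wc), grest = g[-1], g[:-1]
    delete_v = _forest_dist(frest + vc, g) + 1
    insert_w = _forest_dist(f, grest + wc) + 1
    match = (_forest_dist(frest, grest) + _forest_dist(vc, wc)
             + (0 if vl == wl else 1))
    return min(delete_v, insert_w, match)


def ted_naive(t1, t2) -> int:
    """Edit distance between two rooted ordered trees via the classic
    (unmemoized-recurrence) forest recursion."""
    return _forest_dist((tree_to_tuple(t1),), (tree_to_tuple(t2),))


# --- exhaustive secondary-structure enumeration ---------------------------

_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}


def all_structures(seq: str, min_loop: int = 3) -> list[frozenset]:
    """Every valid (nested, loop-constrained, canonical-pair) structure
    of a sequence, as frozensets of 0-based (i, j) pairs."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple:
        if i > j:
            return (frozenset(),)
        out = set(rec(i, j - 1))
        for k in range(i, j - min_loop):
            if seq[k] + seq[j] in _PAIRS:
                for left in rec(i, k - 1):
                    for right in rec(k + 1, j - 1):
                        out.add(left | right | {(k, j)})
        return tuple(out)

    return list(rec(0, len(seq) - 1)) if seq else [frozenset()]


def max_pairs_enum(seq: str, min_loop: int = 3) -> int:
    return max(len(s) for s in all_structures(seq, min_loop))


# --- exhaustive global alignment ------------------------------------------

def nw_best_score(a: str, b: str, match: float = 1.0, mismatch: float = 0.0,
                  gap: float = -1.0) -> float:
    """Best global-alignment score over all alignments (memoized
    recursion independent of the DP-table implementation)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


# --- exact rank-sum enumeration -------------------------------------------

def ranksum_enum(x, y, alternative: str = "two_sided") -> float:
    """Exact Mann-Whitney p by enumerating all C(n+m, n) assignments of
    the pooled observations to the first sample (no ties assumed)."""
    pooled = sorted(list(x) + list(y))
    n = len(x)

    def u_stat(sample):
        rest = list(pooled)
        for v in sample:
            rest.remove(v)
        return sum(1 for xv in sample for yv in rest if xv > yv)

    u_obs = u_stat(list(x))
    us = [u_stat(list(c)) for c in combinations(pooled, n)]
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2.0 * min(p_le, p_ge))
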