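"""Sequence and secondary-structure similarity of cooperative miRNAs.

Mature/seed/precursor sequences are compared by global-alignment identity;
precursor hairpin structures are compared by an ordered tree edit distance
on the standard pair/unpaired tree encoding of dot-bracket strings.  A
base-pair-maximization folder is included so synthetic precursors can be
folded without any external RNA package.  The module ends with the
within-module / between-module / random distribution comparison that asks
whether co-operating miRNAs look alike at each layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

__all__ = [
    "StructureTree",
    "SimilarityReport",
    "extract_seed",
    "pairwise_identity",
    "parse_dotbracket",
    "base_pair_distance",
    "tree_edit_distance",
    "nussinov_fold",
    "ranksum_test",
    "compare_similarity_distributions",
    "similarity_table",
    "LAYERS",
]

RNA_ALPHABET = frozenset("ACGU")

#: canonical base pairs used by the folder: Watson-Crick plus GU wobble
CANONICAL_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})

LAYERS = ("seed", "mature", "precursor_seq", "precursor_struct")


# ---------------------------------------------------------------------------
# seeds and sequence identity
# ---------------------------------------------------------------------------

def extract_seed(mature_seq: str, start: int = 2, end: int = 8) -> str:
    """Return the seed window of a mature miRNA (1-based, inclusive).

    The default window is residues 2-8; shifted windows such as 1-7 or
    4-10 are obtained by passing other coordinates.
    """
    if not (1 <= start <= end):
        raise ValueError(f"invalid seed window ({start}, {end})")
    if end > len(mature_seq):
        raise ValueError(
            f"seed window ({start}, {end}) exceeds mature sequence of "
            f"length {len(mature_seq)}"
        )
    return mature_seq[start - 1 : end]


def _needleman_wunsch(a: str, b: str, match: float, mismatch: float,
                      gap: float) -> tuple[float, int, int]:
    """Global alignment of a vs b; returns (score, n_matches, aln_length).

    Traceback is deterministic: diagonal preferred over an up step
    (gap in b) over a left step (gap in a).
    """
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1), dtype=float)
    score[0, :] = np.arange(m + 1) * gap
    score[:, 0] = np.arange(n + 1) * gap
    sub = np.empty((n, m), dtype=float)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    for i in range(n):
        sub[i] = np.where(bb == ord(a[i]), match, mismatch)
    for i in range(1, n + 1):
        prev = score[i - 1]
        cur = score[i]
        row_sub = sub[i - 1]
        for j in range(1, m + 1):
            cur[j] = max(prev[j - 1] + row_sub[j - 1],
                         prev[j] + gap,
                         cur[j - 1] + gap)
    i, j = n, m
    matches = 0
    length = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(
                score[i, j], score[i - 1, j - 1] + sub[i - 1, j - 1]):
            if a[i - 1] == b[j - 1]:
                matches += 1
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(score[i, j], score[i - 1, j] + gap):
            i -= 1
        else:
            j -= 1
        length += 1
    return float(score[n, m]), matches, length


def pairwise_identity(a: str, b: str, match: float = 1.0,
                      mismatch: float = 0.0, gap: float = -1.0) -> float:
    """Global-alignment identity between two RNA strings, in [0, 1].

    Identity is matches / alignment length along an optimal global
    alignment (match +1, mismatch 0, linear gap -1 by default).  The
    arguments are canonically ordered before alignment, so the score is
    symmetric by construction.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if b < a:
        a, b = b, a
    _, matches, length = _needleman_wunsch(a, b, match, mismatch, gap)
    return matches / length


# ---------------------------------------------------------------------------
# dot-bracket parsing and tree encoding
# ---------------------------------------------------------------------------

class DotBracketError(ValueError):
    """Raised for unbalanced or malformed dot-bracket strings."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at position {position}")
        self.position = position


@dataclass
class StructureTree:
    """Ordered rooted tree encoding of a secondary structure.

    Internal ``P`` nodes are base pairs, ``U`` leaves are unpaired
    positions and the root is a virtual ``R`` node, so the in-order
    traversal of the tree recovers the dot-bracket string.
    """

    label: str
    children: list["StructureTree"] = field(default_factory=list)

    @property
    def size(self) -> int:
        """Total node count including this node."""
        return 1 + sum(c.size for c in self.children)

    def to_dotbracket(self) -> str:
        parts = []
        for child in self.children:
            if child.label == "U":
                parts.append(".")
            else:
                parts.append("(" + child.to_dotbracket() + ")")
        return "".join(parts)


def parse_dotbracket(struct: str) -> tuple[StructureTree, set[tuple[int, int]]]:
    """Parse a dot-bracket string into its structure tree and pair set.

    Pairs are 1-based (i, j) with i < j.  Unbalanced strings raise
    :class:`DotBracketError` carrying the offending position.
    """
    root = StructureTree("R")
    stack: list[tuple[StructureTree, int]] = [(root, 0)]
    pairs: set[tuple[int, int]] = set()
    for pos, ch in enumerate(struct, start=1):
        if ch == "(":
            node = StructureTree("P")
            stack[-1][0].children.append(node)
            stack.append((node, pos))
        elif ch == ")":
            if len(stack) == 1:
                raise DotBracketError("unbalanced ')'", pos)
            _, open_pos = stack.pop()
            pairs.add((open_pos, pos))
        elif ch == ".":
            stack[-1][0].children.append(StructureTree("U"))
        else:
            raise DotBracketError(f"invalid character {ch!r}", pos)
    if len(stack) > 1:
        raise DotBracketError("unbalanced '('", len(struct))
    return root, pairs


def base_pair_distance(s1: str, s2: str) -> int:
    """Symmetric-difference size of the base-pair sets of two equal-length
    structures (a fast alternative to the tree edit distance)."""
    if len(s1) != len(s2):
        raise ValueError(
            "base_pair_distance requires equal-length structures "
            f"({len(s1)} vs {len(s2)}); use tree_edit_distance instead"
        )
    _, p1 = parse_dotbracket(s1)
    _, p2 = parse_dotbracket(s2)
    return len(p1 ^ p2)


# ---------------------------------------------------------------------------
# ordered tree edit distance (Zhang-Shasha)
# ---------------------------------------------------------------------------

def _postorder(tree: StructureTree) -> tuple[list[str], list[int]]:
    """Postorder labels and leftmost-leaf indices (0-based postorder)."""
    labels: list[str] = []
    lml: list[int] = []

    def visit(node: StructureTree) -> int:
        first = None
        for child in node.children:
            idx = visit(child)
            if first is None:
                first = lml[idx]
        labels.append(node.label)
        my_index = len(labels) - 1
        lml.append(first if first is not None else my_index)
        return my_index

    visit(tree)
    return labels, lml


def _keyroots(lml: Sequence[int]) -> list[int]:
    seen: dict[int, int] = {}
    for i, l in enumerate(lml):
        seen[l] = i  # keep the highest postorder index per leftmost leaf
    return sorted(seen.values())


def tree_edit_distance(t1: StructureTree, t2: StructureTree) -> int:
    """Ordered tree edit distance with unit insert/delete/relabel costs.

    Relabeling between a pair node and an unpaired leaf costs 1; matching
    identical labels costs 0.  Computed with the Zhang-Shasha dynamic
    program over LR-keyroots, so it is exact for ordered trees.
    """
    lab1, lml1 = _postorder(t1)
    lab2, lml2 = _postorder(t2)
    n1, n2 = len(lab1), len(lab2)
    kr1, kr2 = _keyroots(lml1), _keyroots(lml2)
    td = np.zeros((n1, n2), dtype=np.int64)

    for i in kr1:
        li = lml1[i]
        for j in kr2:
            lj = lml2[j]
            rows = i - li + 2
            cols = j - lj + 2
            fd = np.zeros((rows, cols), dtype=np.int64)
            fd[:, 0] = np.arange(rows)
            fd[0, :] = np.arange(cols)
            for di in range(1, rows):
                i1 = li + di - 1  # postorder index in t1
                for dj in range(1, cols):
                    j1 = lj + dj - 1
                    if lml1[i1] == li and lml2[j1] == lj:
                        relabel = 0 if lab1[i1] == lab2[j1] else 1
                        fd[di, dj] = min(
                            fd[di - 1, dj] + 1,
                            fd[di, dj - 1] + 1,
                            fd[di - 1, dj - 1] + relabel,
                        )
                        td[i1, j1] = fd[di, dj]
                    else:
                        fd[di, dj] = min(
                            fd[di - 1, dj] + 1,
                            fd[di, dj - 1] + 1,
                            fd[lml1[i1] - li, lml2[j1] - lj]
                            + td[i1, j1],
                        )
    return int(td[n1 - 1, n2 - 1])


def structure_distance(s1: str, s2: str) -> int:
    """Tree edit distance between two dot-bracket strings."""
    t1, _ = parse_dotbracket(s1)
    t2, _ = parse_dotbracket(s2)
    return tree_edit_distance(t1, t2)


# ---------------------------------------------------------------------------
# base-pair-maximization folding
# ---------------------------------------------------------------------------

def _can_pair(x: str, y: str) -> bool:
    return x + y in CANONICAL_PAIRS


def nussinov_fold(seq: str, min_loop: int = 3) -> str:
    """Fold an RNA string by base-pair maximization.

    Watson-Crick and GU wobble pairs are allowed; hairpin loops must span
    at least ``min_loop`` unpaired bases.  The traceback is deterministic:
    pairing the right end is preferred over leaving it unpaired, and the
    leftmost pairing partner is chosen, so identical inputs always yield
    identical structures.
    """
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    n = len(seq)
    if n == 0:
        return ""
    M = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            row_i = M[i]
            best = row_i[j - 1]
            sj = seq[j]
            for k in range(i, j - min_loop):
                if _can_pair(seq[k], sj):
                    cand = 1 + M[k + 1][j - 1]
                    if k > i:
                        cand += row_i[k - 1]
                    if cand > best:
                        best = cand
            row_i[j] = best
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or M[i][j] == 0:
            continue
        paired = False
        sj = seq[j]
        for k in range(i, j - min_loop):
            if _can_pair(seq[k], sj):
                cand = 1 + M[k + 1][j - 1]
                if k > i:
                    cand += M[i][k - 1]
                if cand == M[i][j]:
                    struct[k], struct[j] = "(", ")"
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    paired = True
                    break
        if not paired:
            stack.append((i, j - 1))
    return "".join(struct)


# ---------------------------------------------------------------------------
# rank-sum test
# ---------------------------------------------------------------------------

_ALTERNATIVES = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


def ranksum_test(x: Sequence[float], y: Sequence[float],
                 alternative: str = "two_sided") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses exact enumeration of the rank distribution when n + m <= 12 and
    there are no ties, otherwise the normal approximation with tie
    correction (no continuity correction, so a fully tied comparison
    reports p = 1).
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("ranksum_test requires non-empty samples")
    combined = np.concatenate([x, y])
    n_distinct = np.unique(combined).size
    if n_distinct == 1:
        return 1.0  # degenerate: every observation tied, no evidence
    has_ties = n_distinct < combined.size
    method = "exact" if (combined.size <= 12 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative=_ALTERNATIVES[alternative],
                       method=method, use_continuity=False)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# within / between / random comparison
# ---------------------------------------------------------------------------

@dataclass
class SimilarityReport:
    """Distributional comparison of pairwise similarities for one layer.

    ``within`` pools all member pairs inside each module, ``between`` all
    pairs spanning two modules, ``random`` pairs drawn uniformly from the
    full record set.  p-values are one-sided (within more similar);
    ``p_within_vs_between`` is None when only one module is available.
    """

    layer: str
    within: list[float]
    between: list[float]
    random: list[float]
    p_within_vs_between: float | None
    p_within_vs_random: float | None


def _layer_scorer(layer: str, records_by_id: dict, seed_window: tuple[int, int]):
    cache: dict = {}

    def seq_of(mid: str) -> str:
        rec = records_by_id[mid]
        if layer == "seed":
            return extract_seed(rec.mature_seq, *seed_window)
        if layer == "mature":
            return rec.mature_seq
        return rec.precursor_seq

    if layer == "precursor_struct":
        trees = {
            mid: parse_dotbracket(rec.precursor_struct)[0]
            for mid, rec in records_by_id.items()
        }

        def score(a: str, b: str) -> float:
            # negated distance: larger = more similar, matching the
            # one-sided direction used for the sequence layers
            return -float(tree_edit_distance(trees[a], trees[b]))

        return score

    def score(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = pairwise_identity(seq_of(key[0]), seq_of(key[1]))
        return cache[key]

    return score


def compare_similarity_distributions(
    cmms: Iterable,
    records: Sequence,
    layer: str,
    n_random_pairs: int = 1000,
    rng_seed: int = 0,
    seed_window: tuple[int, int] = (2, 8),
) -> SimilarityReport:
    """Compare within-module, between-module and random pairwise
    similarities at one layer and test whether module members are more
    similar (one-sided rank-sum).

    ``layer`` is one of seed / mature / precursor_seq / precursor_struct;
    the structure layer scores by negated tree edit distance so "greater"
    means "more similar" for every layer.
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    records_by_id = {rec.mirna_id: rec for rec in records}
    modules = [sorted(getattr(c, "mirnas", c)) for c in cmms]
    for members in modules:
        for m in members:
            if m not in records_by_id:
                raise KeyError(f"no hairpin record for module member {m!r}")
    rng = np.random.default_rng(rng_seed)
    score = _layer_scorer(layer, records_by_id, seed_window)

    within_pairs = [p for members in modules for p in combinations(members, 2)]
    between_pairs = sorted(
        {
            tuple(sorted((a, b)))
            for i, j in combinations(range(len(modules)), 2)
            for a in modules[i]
            for b in modules[j]
            if a != b
        }
    )
    if len(between_pairs) > n_random_pairs:
        idx = rng.choice(len(between_pairs), size=n_random_pairs, replace=False)
        between_pairs = [between_pairs[i] for i in sorted(idx)]

    all_ids = sorted(records_by_id)
    random_pairs = []
    for _ in range(len(within_pairs)):
        a, b = rng.choice(len(all_ids), size=2, replace=False)
        random_pairs.append((all_ids[a], all_ids[b]))

    within = [score(a, b) for a, b in within_pairs]
    between = [score(a, b) for a, b in between_pairs]
    random_scores = [score(a, b) for a, b in random_pairs]

    p_wb = ranksum_test(within, between, "greater") if between else None
    p_wr = ranksum_test(within, random_scores, "greater") if random_scores else None
    return SimilarityReport(layer, within, between, random_scores, p_wb, p_wr)


def split_by_species(records: Sequence) -> dict[str, list]:
    """Group hairpin records by species prefix (hsa-, mmu-, ...).

    Records without a recognizable prefix are pooled under ``"all"``.
    """
    groups: dict[str, list] = {}
    for rec in records:
        head = rec.mirna_id.split("-", 1)[0].lower()
        key = head if head in {"hsa", "mmu", "rno", "dme", "cel"} else "all"
        groups.setdefault(key, []).append(rec)
    return groups


def similarity_table(cmms, records, n_random_pairs: int = 1000,
                     rng_seed: int = 0, seed_window: tuple[int, int] = (2, 8)):
    """Table of one-sided p-values (rows = layers, columns = comparisons),
    analogous to the within/between/random similarity summary."""
    import pandas as pd

    rows = []
    for layer in LAYERS:
        rep = compare_similarity_distributions(
            cmms, records, layer, n_random_pairs=n_random_pairs,
            rng_seed=rng_seed, seed_window=seed_window)
        rows.append({
            "layer": layer,
            "p_within_vs_between": rep.p_within_vs_between,
            "p_within_vs_random": rep.p_within_vs_random,
            "n_within": len(rep.within),
            "n_between": len(rep.between),
        })
    return pd.DataFrame(rows).set_index("layer")
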