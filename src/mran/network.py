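"""Condition-specific miRNA association network (MRAN) construction.

A static miRNA->target map is intersected with one condition's paired
expression profiles: a predicted pair is kept only when miRNA and target
are inversely co-expressed (Pearson r < r_max, default r < 0).  MiRNAs
are then linked by the Jaccard overlap of their condition-specific target
sets, edges are kept when the overlap is significant under the exact
(hypergeometric) randomization null, and edge weights encode 1 - p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy import stats

from .io import ExpressionMatrix, TargetMap, normalize_id

log = logging.getLogger(__name__)

__all__ = [
    "CoexpressionPair",
    "InversePairResult",
    "ConditionMRAN",
    "pearson_correlation",
    "inverse_pair_filter",
    "jaccard_overlap",
    "overlap_pvalue",
    "build_condition_mran",
]


@dataclass(frozen=True)
class CoexpressionPair:
    """A retained miRNA-target pair with its Pearson correlation."""

    mirna_id: str
    gene_id: str
    r: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")
        if self.n < 3:
            raise ValueError("correlation needs n >= 3 samples")


@dataclass
class InversePairResult:
    """Output of inverse_pair_filter: retained pairs plus a skip summary."""

    pairs: list[CoexpressionPair]
    cond_targets: dict[str, frozenset[str]]
    n_samples: int
    n_skipped_unmeasured: int = 0
    n_skipped_zero_variance: int = 0


@dataclass
class ConditionMRAN:
    """One condition's weighted undirected miRNA association network.

    Edges carry t (Jaccard target overlap), p (randomization
    significance) and weight = 1 - p; cond_targets holds each node's
    condition-specific target set.
    """

    condition: str
    graph: nx.Graph
    cond_targets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-edge on {u!r}")
            if not d.get("t", 0) > 0:
                raise ValueError(f"edge ({u}, {v}) with t <= 0")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation of two equal-length vectors (n >= 3).

    Zero variance in either vector makes the coefficient undefined and
    raises ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson_correlation requires equal-length vectors")
    if x.size < 3:
        raise ValueError("pearson_correlation requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def _corr_pvalue_less(r: float, n: int) -> float:
    """One-sided P(R < r) under the null of no correlation (t-test)."""
    t = r * np.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
    return float(stats.t.cdf(t, df=n - 2))


def inverse_pair_filter(
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    targets: TargetMap,
    r_max: float = 0.0,
    alpha_corr: float | None = None,
) -> InversePairResult:
    """Keep static miRNA-target pairs that are inversely co-expressed.

    A pair survives when both members are measured and PCC < r_max
    (strictly; the default r_max = 0 is the plain r < 0 rule).  When
    alpha_corr is given, the one-sided correlation t-test must also reach
    p < alpha_corr.  Pairs whose miRNA or gene is unmeasured are skipped
    and counted; miRNAs retaining no pair are dropped from the node set.
    """
    if r_max > 0:
        raise ValueError("r_max must be <= 0 for an inverse-expression filter")
    shared = [s for s in mirna_expr.sample_ids
              if s in set(mrna_expr.sample_ids)]
    if not shared:
        raise ValueError("no overlapping samples between miRNA and mRNA "
                         "matrices")
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} overlapping samples; "
                         "correlation needs >= 3")
    mi = mirna_expr.data[shared]
    mr = mrna_expr.data[shared]
    mirna_lookup = {normalize_id(f): f for f in mi.index}
    gene_lookup = {normalize_id(f): f for f in mr.index}

    n = len(shared)
    mi_z, mi_ok = _standardize(mi.to_numpy(dtype=float))
    mr_z, mr_ok = _standardize(mr.to_numpy(dtype=float))
    mi_row = {f: i for i, f in enumerate(mi.index)}
    mr_row = {f: i for i, f in enumerate(mr.index)}

    pairs: list[CoexpressionPair] = []
    cond_targets: dict[str, set[str]] = {}
    skipped_unmeasured = 0
    skipped_zero_var = 0
    for mirna in sorted(targets.targets_of):
        mfeat = mirna_lookup.get(normalize_id(mirna))
        if mfeat is None:
            skipped_unmeasured += len(targets.targets_of[mirna])
            continue
        i = mi_row[mfeat]
        if not mi_ok[i]:
            skipped_zero_var += len(targets.targets_of[mirna])
            continue
        for gene in sorted(targets.targets_of[mirna]):
            gfeat = gene_lookup.get(normalize_id(gene))
            if gfeat is None:
                skipped_unmeasured += 1
                continue
            j = mr_row[gfeat]
            if not mr_ok[j]:
                skipped_zero_var += 1
                continue
            r = float(mi_z[i] @ mr_z[j])
            r = max(-1.0, min(1.0, r))
            if r < r_max and (alpha_corr is None
                              or _corr_pvalue_less(r, n) < alpha_corr):
                pairs.append(CoexpressionPair(mirna, gene, r, n))
                cond_targets.setdefault(mirna, set()).add(gene)
    if skipped_unmeasured or skipped_zero_var:
        log.info("inverse_pair_filter: skipped %d unmeasured and %d "
                 "zero-variance pairs", skipped_unmeasured, skipped_zero_var)
    return InversePairResult(
        pairs=pairs,
        cond_targets={m: frozenset(g) for m, g in cond_targets.items()},
        n_samples=n,
        n_skipped_unmeasured=skipped_unmeasured,
        n_skipped_zero_variance=skipped_zero_var,
    )


def _standardize(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardize so that z_i @ z_j is the Pearson correlation."""
    mean = arr.mean(axis=1, keepdims=True)
    centered = arr - mean
    ss = np.sqrt((centered ** 2).sum(axis=1, keepdims=True))
    ok = ss[:, 0] > 0
    ss[~ok, 0] = 1.0
    return centered / ss, ok


# ---------------------------------------------------------------------------
# target overlap scoring
# ---------------------------------------------------------------------------

def jaccard_overlap(targets_i: frozenset | set, targets_j: frozenset | set) -> float:
    """Jaccard target overlap t = |i n j| / |i u j| between two miRNAs'
    condition-specific target sets (1 when the sets are identical, which
    covers the i = j diagonal)."""
    if not targets_i or not targets_j:
        raise ValueError("jaccard_overlap requires non-empty target sets; "
                         "miRNAs without condition targets should have been "
                         "dropped upstream")
    inter = len(targets_i & targets_j)
    union = len(targets_i | targets_j)
    return inter / union


def overlap_pvalue(
    size_i: int,
    size_j: int,
    overlap: int,
    universe: int,
    method: str = "exact",
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> float:
    """Significance of an observed target-set overlap.

    Under the null, two sets of the given sizes are drawn uniformly
    without replacement from the condition's target universe.  ``exact``
    gives the closed-form hypergeometric upper tail P(K >= overlap) --
    equivalent to exhaustive randomization at fixed sizes; ``permutation``
    draws n_perm random set pairs and reports the add-one Monte-Carlo
    estimate (#{overlap* >= overlap} + 1) / (n_perm + 1).
    """
    if overlap > min(size_i, size_j):
        raise ValueError(f"overlap {overlap} exceeds min set size "
                         f"{min(size_i, size_j)}")
    if overlap < 0 or size_i <= 0 or size_j <= 0:
        raise ValueError("sizes must be positive and overlap non-negative")
    if size_i > universe or size_j > universe:
        raise ValueError("set size exceeds universe")
    if universe < size_i + size_j - overlap:
        raise ValueError(f"universe {universe} too small for sets of "
                         f"{size_i} and {size_j} sharing {overlap}")
    if method == "exact":
        return float(stats.hypergeom.sf(overlap - 1, universe, size_i, size_j))
    if method == "permutation":
        rng = np.random.default_rng(rng_seed)
        hits = 0
        for _ in range(n_perm):
            a = rng.choice(universe, size=size_i, replace=False)
            b = rng.choice(universe, size=size_j, replace=False)
            if np.intersect1d(a, b, assume_unique=True).size >= overlap:
                hits += 1
        return (hits + 1) / (n_perm + 1)
    raise ValueError(f"unknown method {method!r}; expected exact or "
                     "permutation")


def build_condition_mran(
    result: InversePairResult | dict[str, frozenset[str]],
    condition: str,
    alpha_edge: float = 0.05,
    sig_method: str = "exact",
    n_perm: int = 1000,
    rng_seed: int = 0,
    universe: int | None = None,
) -> ConditionMRAN:
    """Assemble one condition's MRAN from condition-specific target sets.

    Every miRNA with a non-empty condition target set becomes a node;
    an edge joins (i, j) when t_ij > 0 and p_ij < alpha_edge (strict, as
    in "p value < 0.05").  The randomization universe defaults to the
    union of all condition target sets; pass ``universe`` to score
    against a larger gene background.  Edge weight is 1 - p.
    """
    if not 0 < alpha_edge <= 1:
        raise ValueError(f"alpha_edge must be in (0, 1], got {alpha_edge}")
    cond_targets = (result.cond_targets
                    if isinstance(result, InversePairResult) else result)
    cond_targets = {m: frozenset(g) for m, g in cond_targets.items() if g}
    g = nx.Graph()
    g.add_nodes_from(sorted(cond_targets))
    universe_genes = frozenset().union(*cond_targets.values()) \
        if cond_targets else frozenset()
    if universe is None:
        universe = len(universe_genes)
    elif universe < len(universe_genes):
        raise ValueError("universe smaller than the union of condition "
                         "target sets")
    if g.number_of_nodes() < 2:
        log.warning("condition %r: fewer than 2 miRNAs with condition "
                    "targets; returning an edgeless network", condition)
        return ConditionMRAN(condition, g, cond_targets)

    # only pairs sharing at least one gene can have t > 0
    by_gene: dict[str, list[str]] = {}
    for m in sorted(cond_targets):
        for gene in cond_targets[m]:
            by_gene.setdefault(gene, []).append(m)
    candidates = sorted({
        pair for members in by_gene.values()
        for pair in combinations(members, 2)
    })
    for k, (i, j) in enumerate(candidates):
        ti, tj = cond_targets[i], cond_targets[j]
        t = jaccard_overlap(ti, tj)
        p = overlap_pvalue(len(ti), len(tj), len(ti & tj), universe,
                           method=sig_method, n_perm=n_perm,
                           rng_seed=rng_seed + k)
        if t > 0 and p < alpha_edge:
            g.add_edge(i, j, t=t, p=p, weight=1.0 - p)
    return ConditionMRAN(condition, g, cond_targets)
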