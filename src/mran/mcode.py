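"""Global MRAN assembly and cooperative-module extraction (MCODE).

Condition-specific networks are merged into one simple graph whose edges
remember every contributing condition.  Cooperative miRNA modules (CMMs)
are then extracted with a molecular-complex-detection procedure: vertices
are weighted by the core clustering coefficient (k_max times the density
of the highest k-core of the closed neighborhood), complexes grow
greedily from high-weight seeds admitting neighbors above a weight
fraction of the seed, and post-processing keeps only complexes containing
at least a 2-core (haircut removes stray degree-1 members).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .network import ConditionMRAN

__all__ = [
    "GlobalMRAN",
    "CMM",
    "merge_condition_mrans",
    "core_decomposition",
    "vertex_weight",
    "vertex_weights",
    "mcode_complexes",
    "annotate_modules",
]


@dataclass
class GlobalMRAN:
    """Merged multi-condition association network.

    Stored as a simple graph whose edges carry ``records``: the list of
    (condition, t, p) triples contributed by the per-condition networks,
    so the underlying multigraph is recoverable while clustering runs on
    the collapsed simple view.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if not d.get("records"):
                raise ValueError(f"edge ({u}, {v}) without condition records")

    @property
    def simple_view(self) -> nx.Graph:
        """The collapsed simple graph (one edge per miRNA pair)."""
        return self.graph

    @property
    def conditions(self) -> list[str]:
        return sorted({c for _, _, d in self.graph.edges(data=True)
                       for c, _, _ in d["records"]})


@dataclass
class CMM:
    """A cooperative miRNA module extracted from the global MRAN."""

    module_id: int
    mirnas: frozenset[str]
    seed_vertex: str
    score: float
    density: float
    links: int = 0
    target_union: frozenset[str] = field(default_factory=frozenset)
    conditions: frozenset[str] = field(default_factory=frozenset)

    @property
    def size(self) -> int:
        return len(self.mirnas)


def merge_condition_mrans(nets: list[ConditionMRAN]) -> GlobalMRAN:
    """Union the per-condition networks into the global MRAN.

    Node sets are unioned; per-pair condition records are concatenated.
    """
    if not nets:
        raise ValueError("merge_condition_mrans requires at least one network")
    g = nx.Graph()
    for net in nets:
        g.add_nodes_from(net.graph.nodes)
        for u, v, d in net.graph.edges(data=True):
            rec = (net.condition, float(d["t"]), float(d["p"]))
            if g.has_edge(u, v):
                g.edges[u, v]["records"].append(rec)
            else:
                g.add_edge(u, v, records=[rec])
    return GlobalMRAN(g)


# ---------------------------------------------------------------------------
# vertex weighting
# ---------------------------------------------------------------------------

def core_decomposition(graph: nx.Graph) -> dict[str, int]:
    """k-core numbers by iterative minimum-degree pruning."""
    if graph.number_of_nodes() == 0:
        return {}
    return dict(nx.core_number(graph))


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def vertex_weight(graph: nx.Graph, v) -> float:
    """Core clustering coefficient weight of a vertex.

    weight(v) = k_max * density of the highest k-core of the closed
    neighborhood N[v]; isolated vertices weigh 0.
    """
    if v not in graph:
        raise KeyError(f"vertex {v!r} not in graph")
    nbhd = graph.subgraph([v, *graph.neighbors(v)])
    cores = core_decomposition(nbhd)
    k_max = max(cores.values(), default=0)
    if k_max == 0:
        return 0.0
    top = nbhd.subgraph([u for u, k in cores.items() if k >= k_max])
    return k_max * _density(top)


def vertex_weights(graph: nx.Graph) -> dict:
    return {v: vertex_weight(graph, v) for v in graph.nodes}


# ---------------------------------------------------------------------------
# complex prediction and post-processing
# ---------------------------------------------------------------------------

def _haircut(sub: nx.Graph) -> nx.Graph:
    """Iteratively strip vertices of degree < 2."""
    sub = sub.copy()
    while True:
        stray = [v for v, d in sub.degree() if d < 2]
        if not stray:
            return sub
        sub.remove_nodes_from(stray)


def mcode_complexes(
    graph: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.2,
    min_core: int = 2,
) -> list[CMM]:
    """Extract dense complexes from a simple undirected graph.

    Seeds are processed in descending vertex weight (ties broken by id);
    a breadth-first expansion admits unvisited neighbors whose weight
    exceeds seed_weight * (1 - vwp), and each vertex joins at most one
    complex during prediction.  Complexes lacking a ``min_core``-core are
    dropped; haircut removes degree-1 members iteratively; fluff (off by
    default) adds boundary neighbors whose closed-neighborhood density
    exceeds ``fluff_density``.  Results are ranked by score =
    density * size, descending, with a deterministic id tie-break.
    """
    if not 0 <= vwp < 1:
        raise ValueError(f"vwp must be in [0, 1), got {vwp}")
    weights = vertex_weights(graph)
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    raw: list[tuple[set, object]] = []
    for seed in order:
        if seed in visited:
            continue
        threshold = weights[seed] * (1.0 - vwp)
        members = {seed}
        queue = [seed]
        while queue:
            u = queue.pop(0)
            for nb in sorted(graph.neighbors(u), key=str):
                if nb in visited or nb in members:
                    continue
                if weights[nb] > threshold:
                    members.add(nb)
                    queue.append(nb)
        visited |= members
        if len(members) >= 2:
            raw.append((members, seed))

    finished: list[tuple[frozenset, str, float]] = []
    for members, seed in raw:
        sub = graph.subgraph(members).copy()
        if haircut:
            sub = _haircut(sub)
        cores = core_decomposition(sub)
        if not cores or max(cores.values()) < min_core:
            continue
        if fluff:
            boundary = {
                nb for v in sub.nodes for nb in graph.neighbors(v)
                if nb not in sub
            }
            for nb in sorted(boundary, key=str):
                nbhd = graph.subgraph([nb, *graph.neighbors(nb)])
                if _density(nbhd) > fluff_density:
                    sub.add_node(nb)
                    for v in graph.neighbors(nb):
                        if v in sub:
                            sub.add_edge(nb, v)
        density = _density(sub)
        finished.append((frozenset(sub.nodes), str(seed), density))

    ranked = sorted(
        finished,
        key=lambda rec: (-rec[2] * len(rec[0]), tuple(sorted(rec[0]))),
    )
    modules = []
    for rank, (members, _, density) in enumerate(ranked, start=1):
        seed_vertex = max(members, key=lambda v: (weights[v], str(v)))
        sub = graph.subgraph(members)
        modules.append(CMM(
            module_id=rank,
            mirnas=members,
            seed_vertex=seed_vertex,
            score=density * len(members),
            density=density,
            links=sub.number_of_edges(),
        ))
    return modules


def annotate_modules(cmms: list[CMM], nets: list[ConditionMRAN]) -> list[CMM]:
    """Fill link counts and target unions of extracted modules.

    The target union pools each member's condition-specific targets over
    every condition that contributes at least one intra-module edge.
    """
    known = set()
    for net in nets:
        known |= set(net.graph.nodes)
    annotated = []
    for cmm in cmms:
        missing = sorted(cmm.mirnas - known)
        if missing:
            raise KeyError(f"module {cmm.module_id} member(s) absent from "
                           f"all condition networks: {missing}")
        conditions = set()
        links = set()
        for net in nets:
            sub = net.graph.subgraph(cmm.mirnas)
            if sub.number_of_edges():
                conditions.add(net.condition)
                links.update(tuple(sorted(e)) for e in sub.edges)
        union: set[str] = set()
        for net in nets:
            if net.condition not in conditions:
                continue
            for m in cmm.mirnas:
                union |= net.cond_targets.get(m, frozenset())
        annotated.append(CMM(
            module_id=cmm.module_id,
            mirnas=cmm.mirnas,
            seed_vertex=cmm.seed_vertex,
            score=cmm.score,
            density=cmm.density,
            links=len(links),
            target_union=frozenset(union),
            conditions=frozenset(conditions),
        ))
    return annotated
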