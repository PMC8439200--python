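"""Molecular Complex Detection (MCODE) for synchronous networks.

MCODE finds densely connected node groups in three stages:

1. *Vertex weighting.*  Each node is scored by the density of the highest
   k-core of its closed neighborhood times that core's k ("core-clustering
   coefficient" x core number).  This rewards membership in dense local
   cliques while damping the effect of loosely attached neighbors.
2. *Complex prediction.*  Starting from the highest-weighted unvisited
   node, the complex grows outward, admitting neighbors whose weight is
   within ``node_score_cutoff`` of the seed weight (weight >= seed x
   (1 - cutoff)).  Visited nodes are never reused, so complexes are
   disjoint.
3. *Post-processing.*  Complexes that do not contain a ``k_core`` are
   discarded; the *haircut* option strips singly-connected nodes; the
   *fluff* option (off by default) adds back dense neighborhoods.

Module detection runs on the strongly synchronized graph (edges with
|tau| past the synchronous cut); the tau sign travels along as an edge
attribute, so anti-synchronous edges take part in modules rather than
splitting them.  All ties break lexicographically by node id, making the
result independent of input edge order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .syncnet import SyncNetwork

__all__ = ["ModuleParams", "Module", "ModuleSet",
           "sync_graph", "vertex_weights", "find_modules"]


@dataclass(frozen=True)
class ModuleParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.2
    min_size: int = 3


@dataclass
class Module:
    nodes: frozenset[str]
    score: float
    seed: str

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class ModuleSet:
    modules: list[Module]
    parameters: ModuleParams
    source_condition: str

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def node_union(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.modules:
            out |= m.nodes
        return frozenset(out)


def sync_graph(net: SyncNetwork, strong_only: bool = True) -> nx.Graph:
    """Simple undirected graph from a synchronous network.

    By default only strongly synchronized edges (|tau| past the sync cut,
    either sign) are kept; the tau value rides along as the ``tau`` edge
    attribute and its sign as ``relation``.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(net.nodes))
    edges = net.strong_edges() if strong_only else net.edges
    for u, v, t, cls in edges:
        g.add_edge(u, v, tau=t, relation=cls)
    return g


def _highest_kcore(g: nx.Graph) -> tuple[nx.Graph, int]:
    core_num = nx.core_number(g) if g.number_of_edges() else {n: 0 for n in g}
    k_max = max(core_num.values(), default=0)
    sub = g.subgraph([n for n, c in core_num.items() if c >= k_max])
    return sub, k_max


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def vertex_weights(graph: SyncNetwork | nx.Graph,
                   degree_cutoff: int = 2) -> dict[str, float]:
    """MCODE vertex weight for every node.

    weight(v) = density(highest k-core of v's closed neighborhood) x k.
    Isolated nodes and nodes with degree below ``degree_cutoff`` score 0.
    """
    g = graph if isinstance(graph, nx.Graph) else sync_graph(graph)
    weights: dict[str, float] = {}
    for v in g.nodes:
        if g.degree(v) < degree_cutoff or g.degree(v) == 0:
            weights[v] = 0.0
            continue
        nbhd = g.subgraph(list(g.neighbors(v)) + [v])
        core, k = _highest_kcore(nbhd)
        weights[v] = _density(core) * k
    return weights


def _expand(g: nx.Graph, seed: str, weights: dict[str, float],
            cutoff: float, visited: set[str]) -> set[str]:
    threshold = weights[seed] * (1.0 - cutoff)
    members = {seed}
    frontier = [seed]
    while frontier:
        node = frontier.pop()
        for nb in sorted(g.neighbors(node)):
            if nb in visited or nb in members:
                continue
            if weights[nb] >= threshold:
                members.add(nb)
                frontier.append(nb)
    return members


def find_modules(net: SyncNetwork | nx.Graph,
                 params: ModuleParams | None = None) -> ModuleSet:
    """Greedy seed-and-expand MCODE complexes, highest score first.

    Module score is density x size of the module subgraph.  Deterministic
    for a given graph: seeds are taken in descending weight order with
    lexicographic node-id tie-break, and expansion visits neighbors in
    sorted order.
    """
    params = params or ModuleParams()
    if isinstance(net, nx.Graph):
        g, condition = net, "graph"
    else:
        g, condition = sync_graph(net), net.condition
    if g.number_of_nodes() == 0:
        return ModuleSet(modules=[], parameters=params,
                         source_condition=condition)
    weights = vertex_weights(g, degree_cutoff=params.degree_cutoff)
    order = sorted(g.nodes, key=lambda v: (-weights[v], str(v)))
    visited: set[str] = set()
    modules: list[Module] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        members = _expand(g, seed, weights, params.node_score_cutoff, visited)
        visited |= members
        sub = g.subgraph(members)
        # must contain a k_core
        core = nx.k_core(sub, k=params.k_core)
        if core.number_of_nodes() == 0:
            continue
        if params.haircut:
            keep = {v for v in members if sub.degree(v) >= 2}
            sub = g.subgraph(keep)
            members = keep
        if params.fluff:
            extra: set[str] = set()
            for v in sorted(members):
                for nb in g.neighbors(v):
                    if nb in members or nb in extra:
                        continue
                    nbhd = g.subgraph(list(g.neighbors(nb)) + [nb])
                    if _density(nbhd) > params.fluff_density:
                        extra.add(nb)
            members = members | extra
            sub = g.subgraph(members)
        if len(members) < params.min_size:
            continue
        modules.append(Module(nodes=frozenset(members),
                              score=_density(sub) * len(members),
                              seed=seed))
    modules.sort(key=lambda m: (-m.score, sorted(m.nodes)))
    return ModuleSet(modules=modules, parameters=params,
                     source_condition=condition)
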