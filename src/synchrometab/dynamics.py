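"""Cross-dose comparison of synchronous modules.

A module detected in the pooled DH1-DH4 network is a *full-course*
module; modules of the adjacent-dose pair networks (DH1/DH2, DH2/DH3,
DH3/DH4) that have no full-course counterpart are *partial*.  Matching a
low-dose pair's modules against the high-dose pair's modules yields the
*conservative allosteric* node set (nodes shared by matched modules);
pair modules with no counterpart in the preceding pair are *emerging*.
Module correspondence across networks is decided by Jaccard overlap of
node sets, greedy best match first.

Separately, *persistent pairs* are metabolite pairs whose tau passes the
synchronous cut (either sign) in every single-dose network — pairs that
travel together across the whole dose range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .mcode import Module, ModuleSet
from .syncnet import SyncNetwork

__all__ = ["MatchedPair", "ModuleDynamics", "jaccard", "match_modules",
           "classify_dynamics", "persistent_pairs"]


def jaccard(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


@dataclass(frozen=True)
class MatchedPair:
    index_a: int
    index_b: int
    jaccard: float
    shared: frozenset[str]


def match_modules(a: ModuleSet, b: ModuleSet,
                  jaccard_min: float = 0.5) -> list[MatchedPair]:
    """Greedy best-Jaccard one-to-one matching between two module sets.

    Candidate pairs are ranked by Jaccard (ties broken by module index),
    picked greedily without reuse, and kept when Jaccard >= jaccard_min.
    """
    if not (0 < jaccard_min <= 1):
        raise ValueError("jaccard_min must be in (0, 1]")
    candidates = sorted(
        (
            (-jaccard(ma.nodes, mb.nodes), i, j)
            for i, ma in enumerate(a.modules)
            for j, mb in enumerate(b.modules)
        ),
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    out: list[MatchedPair] = []
    for neg_j, i, j in candidates:
        jac = -neg_j
        if jac < jaccard_min:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append(MatchedPair(index_a=i, index_b=j, jaccard=jac,
                               shared=frozenset(a.modules[i].nodes
                                                & b.modules[j].nodes)))
    return out


def persistent_pairs(networks: Mapping[str, SyncNetwork]) -> list[tuple[str, str]]:
    """Node pairs strongly synchronized (|tau| past sync cut) in every network."""
    common: set[tuple[str, str]] | None = None
    for net in networks.values():
        pairs = {tuple(sorted((u, v))) for u, v, _t, _c in net.strong_edges()}
        common = pairs if common is None else common & pairs
    return sorted(common or set())


@dataclass
class ModuleDynamics:
    """Classified module behavior across the dose course."""

    full_course: list[Module]
    partial: dict[str, list[Module]]
    conservative_allosteric: frozenset[str]
    emerging: dict[str, list[frozenset[str]]]
    persistent_pairs: list[tuple[str, str]]
    match_threshold: float

    def to_dict(self) -> dict:
        return {
            "full_course": [sorted(m.nodes) for m in self.full_course],
            "partial": {c: [sorted(m.nodes) for m in ms]
                        for c, ms in self.partial.items()},
            "conservative_allosteric": sorted(self.conservative_allosteric),
            "emerging": {c: [sorted(s) for s in sets]
                         for c, sets in self.emerging.items()},
            "persistent_pairs": [list(p) for p in self.persistent_pairs],
            "match_threshold": self.match_threshold,
        }


def classify_dynamics(modulesets: Mapping[str, ModuleSet],
                      networks: Mapping[str, SyncNetwork] | None = None,
                      jaccard_min: float = 0.5,
                      pair_conditions: Sequence[str] = ("DH1/DH2", "DH2/DH3",
                                                        "DH3/DH4"),
                      full_condition: str = "DH1-DH4") -> ModuleDynamics:
    """Label modules as full-course, partial, conservative or emerging.

    ``modulesets`` must contain the full-course condition and every pair
    condition; ``networks`` (per single-dose group) feeds persistent-pair
    detection and may be omitted.  The conservative allosteric set is the
    union of shared nodes over matched low-dose-pair vs high-dose-pair
    modules; an emerging set is a pair module's nodes minus the preceding
    pair's module-node union, reported when the module has no match in
    the preceding pair.
    """
    missing = [c for c in (*pair_conditions, full_condition)
               if c not in modulesets]
    if missing:
        raise KeyError(f"missing module set(s) for condition(s): {missing}")

    full = modulesets[full_condition]
    partial: dict[str, list[Module]] = {}
    for cond in pair_conditions:
        matched = {m.index_a for m in
                   match_modules(modulesets[cond], full, jaccard_min)}
        partial[cond] = [m for i, m in enumerate(modulesets[cond].modules)
                         if i not in matched]

    low, high = pair_conditions[0], pair_conditions[-1]
    conserved: set[str] = set()
    for pair in match_modules(modulesets[low], modulesets[high], jaccard_min):
        conserved |= pair.shared

    emerging: dict[str, list[frozenset[str]]] = {}
    for prev, cond in zip(pair_conditions[:-1], pair_conditions[1:]):
        prev_union = modulesets[prev].node_union()
        matched_here = {m.index_a for m in
                        match_modules(modulesets[cond], modulesets[prev],
                                      jaccard_min)}
        sets = []
        for i, mod in enumerate(modulesets[cond].modules):
            if i in matched_here:
                continue
            novel = frozenset(mod.nodes - prev_union)
            if novel:
                sets.append(novel)
        emerging[cond] = sets

    pairs = persistent_pairs(networks) if networks else []
    return ModuleDynamics(full_course=list(full.modules), partial=partial,
                          conservative_allosteric=frozenset(conserved),
                          emerging=emerging, persistent_pairs=pairs,
                          match_threshold=jaccard_min)
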