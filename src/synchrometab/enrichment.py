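"""Over-representation analysis of module node sets against pathway sets.

For a module of n metabolites drawn from a universe of M, of which K
belong to a pathway, the chance of seeing k or more pathway members in
the module under random draws is the upper hypergeometric tail

    p = sum_{i>=k} C(K, i) C(M-K, n-i) / C(M, n),

computed one-sided per pathway and corrected across pathways with the
Benjamini-Hochberg FDR.  The EASE variant (one success discounted before
taking the tail) is available behind a flag.  Pathway sets are read and
written in the plain-text GMT format (name, description, members).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["PathwayLibrary", "read_gmt", "write_gmt", "enrich"]


@dataclass
class PathwayLibrary:
    """Named metabolite sets plus the universe they are drawn from."""

    pathways: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {name!r} is empty")
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"pathway {name!r} has members outside the universe: "
                    f"{sorted(stray)}"
                )


def read_gmt(path: str | Path,
             universe: Iterable[str] | None = None) -> PathwayLibrary:
    """Read a GMT file: one pathway per tab-separated line
    (name, description, member...).  If no universe is given, the union
    of all pathway members is used."""
    pathways: dict[str, frozenset[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        pathways[fields[0]] = frozenset(fields[2:])
    if universe is None:
        uni: set[str] = set()
        for members in pathways.values():
            uni |= members
        universe = uni
    return PathwayLibrary(pathways=pathways, universe=frozenset(universe))


def write_gmt(lib: PathwayLibrary, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for name in sorted(lib.pathways):
            members = "\t".join(sorted(lib.pathways[name]))
            fh.write(f"{name}\tna\t{members}\n")


def enrich(module_nodes: Iterable[str], lib: PathwayLibrary,
           alpha: float = 0.05, ease: bool = False) -> pd.DataFrame:
    """Hypergeometric over-representation of a node set in each pathway.

    Returns a DataFrame sorted by raw p with columns pathway,
    pathway_size, overlap, p, p_adj (BH) and significant (p_adj < alpha).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    module = frozenset(module_nodes)
    stray = module - lib.universe
    if stray:
        raise ValueError(
            f"module nodes outside the pathway universe: {sorted(stray)}"
        )
    M = len(lib.universe)
    n = len(module)
    rows = []
    for name in sorted(lib.pathways):
        members = lib.pathways[name]
        K = len(members)
        k = len(module & members)
        k_eff = max(k - 1, 0) if ease else k
        # P(X >= k_eff) for X ~ Hypergeom(M, K, n); sf(k-1) is the >= k tail
        p = float(stats.hypergeom.sf(k_eff - 1, M, K, n)) if k_eff > 0 else 1.0
        rows.append({"pathway": name, "pathway_size": K, "overlap": k, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        _rej, p_adj, _a, _b = multipletests(table["p"], method="fdr_bh")
        table["p_adj"] = p_adj
        table["significant"] = table["p_adj"] < alpha
        table = table.sort_values(["p", "pathway"], kind="stable",
                                  ignore_index=True)
    return table
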