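"""Reading and writing expression studies, designs and networks.

The on-disk conventions are deliberately plain: expression matrices and
sample designs are CSV/TSV, networks go out as Cytoscape-readable SIF or
GraphML (or a flat edge-list CSV), and structured results are JSON.  All
writers emit rows in sorted order so that a fixed input produces
byte-identical output.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionStudy",
    "read_study",
    "write_study",
    "write_network",
    "read_network_graphml",
]


@dataclass
class ExpressionStudy:
    """A metabolite x sample abundance matrix plus its sample design.

    Parameters
    ----------
    values
        DataFrame with metabolite ids as the index and sample ids as
        columns.  Abundances are on whatever (positive) scale the analyst
        chose; log-ratios are taken downstream.
    design
        DataFrame indexed by sample id with columns ``group`` (label) and
        ``dose`` (ml/kg, 0 for untreated groups).
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        vals = self.values
        if vals.index.duplicated().any():
            dups = sorted(vals.index[vals.index.duplicated()].unique())
            raise ValueError(f"duplicate metabolite ids: {dups}")
        if vals.columns.duplicated().any():
            dups = sorted(vals.columns[vals.columns.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dups}")
        if not np.issubdtype(vals.to_numpy().dtype, np.number):
            raise ValueError("expression matrix contains non-numeric cells")
        if vals.isna().any().any():
            bad = [
                (str(m), str(s))
                for m, s in zip(*np.nonzero(vals.isna().to_numpy()))
            ]
            raise ValueError(
                "expression matrix contains missing values at (row, col) "
                f"positions {bad[:5]}; imputation is not performed"
            )
        if "group" not in self.design.columns:
            raise ValueError("design table must have a 'group' column")
        missing = [s for s in vals.columns if s not in self.design.index]
        if missing:
            raise ValueError(
                f"samples present in matrix but absent from design: {missing}"
            )
        if self.design.index.duplicated().any():
            dups = sorted(self.design.index[self.design.index.duplicated()])
            raise ValueError(f"duplicate sample ids in design: {dups}")

    # -- convenience accessors --------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [str(m) for m in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.columns]

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance in the design."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(str(self.design.loc[s, "group"]), None)
        return list(seen)

    def samples_of(self, groups: str | Iterable[str]) -> list[str]:
        if isinstance(groups, str):
            groups = [groups]
        wanted = set(groups)
        return [
            s for s in self.sample_ids
            if str(self.design.loc[s, "group"]) in wanted
        ]

    def group_values(self, groups: str | Iterable[str]) -> pd.DataFrame:
        """Sub-matrix restricted to the samples of one or more groups."""
        samples = self.samples_of(groups)
        if not samples:
            raise ValueError(f"no samples found for group(s) {groups!r}")
        return self.values[samples]

    def dose_of(self, group: str) -> float:
        samples = self.samples_of(group)
        if not samples:
            raise KeyError(group)
        return float(self.design.loc[samples[0], "dose"])


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_study(matrix_path: str | Path, design_path: str | Path) -> ExpressionStudy:
    """Read an expression matrix and its sample design into a study.

    The matrix has metabolites in rows (first column = metabolite id,
    header row = sample ids); the design has columns sample, group and
    optionally dose.  Delimiters are inferred from the file extension
    (``.tsv``/``.tab``/``.txt`` means tab, anything else comma).
    """
    matrix_path, design_path = Path(matrix_path), Path(design_path)
    vals = pd.read_csv(matrix_path, sep=_delimiter(matrix_path), index_col=0)
    non_numeric = vals.columns[
        [not np.issubdtype(dt, np.number) for dt in vals.dtypes]
    ]
    if len(non_numeric):
        raise ValueError(
            f"non-numeric cells in matrix column(s): {list(non_numeric)}"
        )
    design = pd.read_csv(design_path, sep=_delimiter(design_path), index_col=0)
    if "dose" not in design.columns:
        design["dose"] = 0.0
    return ExpressionStudy(values=vals, design=design)


def write_study(study: ExpressionStudy, matrix_path: str | Path,
                design_path: str | Path) -> None:
    matrix_path, design_path = Path(matrix_path), Path(design_path)
    study.values.to_csv(matrix_path, sep=_delimiter(matrix_path),
                        index_label="metabolite")
    study.design.to_csv(design_path, sep=_delimiter(design_path),
                        index_label="sample")


# -- network export ---------------------------------------------------------

def _edge_records(net) -> list[tuple[str, str, float, str]]:
    """Normalize a WeightedNetwork or SyncNetwork to (u, v, weight, relation)."""
    if hasattr(net, "edges"):  # SyncNetwork
        rel = {"synchronous": "sync", "anti-synchronous": "antisync",
               "weak": "weak"}
        return sorted(
            (min(u, v), max(u, v), float(t), rel[c])
            for u, v, t, c in net.edges
        )
    # WeightedNetwork: dense adjacency, emit all nonzero entries
    recs = []
    nodes = list(net.nodes)
    adj = np.asarray(net.adjacency)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if adj[i, j] != 0:
                u, v = sorted((nodes[i], nodes[j]))
                recs.append((u, v, float(adj[i, j]), "cor"))
    return sorted(recs)


def write_network(net, path: str | Path, format: str = "sif") -> None:
    """Write a network as SIF, GraphML or an edge-list CSV.

    SIF lines are ``source <tab> relation <tab> target``; isolated nodes
    are written as bare single-column lines per the SIF convention.
    GraphML carries the edge weight (tau or soft-powered correlation) as
    an edge attribute.  Output ordering is sorted, hence deterministic.
    """
    path = Path(path)
    fmt = format.lower()
    nodes = sorted(str(n) for n in net.nodes)
    records = _edge_records(net)
    if fmt == "sif":
        linked = {u for u, _, _, _ in records} | {v for _, v, _, _ in records}
        with open(path, "w", newline="") as fh:
            for u, v, _w, rel in records:
                fh.write(f"{u}\t{rel}\t{v}\n")
            for n in nodes:
                if n not in linked:
                    fh.write(f"{n}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for u, v, w, rel in records:
            g.add_edge(u, v, weight=w, relation=rel)
        nx.write_graphml(g, path, named_key_ids=True, edge_id_from_attribute=None)
    elif fmt in {"csv", "edgelist"}:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight", "relation"])
            for u, v, w, rel in records:
                writer.writerow([u, v, repr(w), rel])
    else:
        raise ValueError(f"unknown network format {format!r}; "
                         "expected sif, graphml or csv")


def read_network_graphml(path: str | Path) -> nx.Graph:
    """Read a GraphML network back as a networkx graph (weights as floats)."""
    g = nx.read_graphml(Path(path))
    for _u, _v, d in g.edges(data=True):
        if "weight" in d:
            d["weight"] = float(d["weight"])
    return g
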