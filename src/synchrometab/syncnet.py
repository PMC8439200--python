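"""Kendall tau-a rank correlation and synchronous network construction.

For two metabolite profiles sampled on the same animals, a pair of samples
is *concordant* if both metabolites move in the same direction between the
two samples and *discordant* if they move in opposite directions.  The
tau-a statistic is

    t_n = (C - D) / C(n, 2),

the proportion of concordant minus discordant sample pairs; tied pairs
contribute zero and no tie correction is applied, so the value is always a
rational number with denominator C(n, 2).

A pair of metabolites is *synchronous* when tau exceeds ``sync_cut``
(default 0.7), *anti-synchronous* when tau is below ``-sync_cut``, and a
weaker association with ``|tau| > edge_cut`` (default 0.5) still enters
the network as a "weak" edge.  All threshold comparisons are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import ExpressionStudy

__all__ = [
    "kendall_tau",
    "TauMatrix",
    "tau_matrix",
    "SyncNetwork",
    "build_sync_network",
    "condition_label",
]


def kendall_tau(x: Sequence[float], y: Sequence[float],
                variant: str = "a") -> float:
    """Kendall rank correlation between two equal-length sequences.

    ``variant="a"`` (default) divides the concordant-minus-discordant count
    by all C(n, 2) pairs, counting ties as zero.  ``variant="b"`` applies
    the usual tie correction in the denominator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"inputs must be equal-length 1-D sequences, got {x.shape} and {y.shape}"
        )
    n = x.size
    if n < 2:
        raise ValueError("kendall tau needs at least 2 observations")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    prod = (sx * sy)[iu]
    num = int(prod.sum())
    n_pairs = n * (n - 1) // 2
    if variant == "a":
        return num / n_pairs
    if variant == "b":
        tx = n_pairs - int(np.count_nonzero(sx[iu]))
        ty = n_pairs - int(np.count_nonzero(sy[iu]))
        denom = np.sqrt((n_pairs - tx) * (n_pairs - ty))
        return float(num / denom) if denom > 0 else 0.0
    raise ValueError(f"unknown tau variant {variant!r}")


@dataclass
class TauMatrix:
    """All-pairs Kendall tau over the pooled samples of a condition."""

    nodes: list[str]
    tau: np.ndarray
    n_samples: int
    condition: str
    constant_nodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = np.asarray(self.tau, dtype=float)
        if t.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("tau matrix shape does not match node list")
        if not np.allclose(t, t.T, atol=1e-12):
            raise ValueError("tau matrix must be symmetric")
        self.tau = t


def condition_label(groups: str | Iterable[str]) -> str:
    if isinstance(groups, str):
        return groups
    return "/".join(groups)


def tau_matrix(study: ExpressionStudy, condition: str | Iterable[str],
               variant: str = "a") -> TauMatrix:
    """Pairwise Kendall tau between all metabolites on pooled samples.

    ``condition`` is one group label or an iterable of labels whose
    samples are pooled (e.g. the DH2/DH3 network uses the 20 samples of
    both groups).  A metabolite that is constant across the pooled
    samples ties with everything; its tau against every other node is
    defined as 0 and it is flagged in ``constant_nodes``.
    """
    groups = [condition] if isinstance(condition, str) else list(condition)
    sub = study.group_values(groups)
    n = sub.shape[1]
    if n < 3:
        raise ValueError(
            f"condition {condition_label(groups)!r} has {n} pooled samples; "
            "at least 3 are required"
        )
    vals = sub.to_numpy(dtype=float)
    m = vals.shape[0]
    # sign of within-metabolite sample differences, shape (m, n, n)
    signs = np.sign(vals[:, :, None] - vals[:, None, :])
    iu = np.triu_indices(n, k=1)
    flat = signs[:, iu[0], iu[1]]                       # (m, n_pairs)
    n_pairs = n * (n - 1) // 2
    tau = (flat @ flat.T) / n_pairs
    constant = [str(sub.index[i]) for i in range(m)
                if not np.any(flat[i])]
    if variant == "b":
        nz = np.count_nonzero(flat, axis=1).astype(float)
        denom = np.sqrt(np.outer(nz, nz))
        with np.errstate(invalid="ignore", divide="ignore"):
            tau = np.where(denom > 0, (flat @ flat.T) / denom, 0.0)
    const_idx = [i for i in range(m) if not np.any(flat[i])]
    for i in const_idx:
        tau[i, :] = 0.0
        tau[:, i] = 0.0
    np.fill_diagonal(tau, 1.0)
    return TauMatrix(nodes=[str(i) for i in sub.index], tau=tau,
                     n_samples=n, condition=condition_label(groups),
                     constant_nodes=constant)


@dataclass
class SyncNetwork:
    """Thresholded tau network: nodes, classed edges and the cuts used.

    Edges are ``(u, v, tau, edge_class)`` with class synchronous,
    anti-synchronous or weak; isolated nodes stay in ``nodes``.
    """

    nodes: list[str]
    edges: list[tuple[str, str, float, str]]
    thresholds: tuple[float, float]
    condition: str

    def edge_counts(self) -> dict[str, int]:
        counts = {"synchronous": 0, "anti-synchronous": 0, "weak": 0}
        for _u, _v, _t, c in self.edges:
            counts[c] += 1
        return counts

    def strong_edges(self) -> list[tuple[str, str, float, str]]:
        """Edges past the synchronous cut (both signs), for module detection."""
        return [e for e in self.edges if e[3] != "weak"]


def build_sync_network(tm: TauMatrix, edge_cut: float = 0.5,
                       sync_cut: float = 0.7) -> SyncNetwork:
    """Filter a tau matrix into a classed synchronous network.

    An edge exists iff ``|tau| > edge_cut`` (strict); it is synchronous iff
    ``tau > sync_cut``, anti-synchronous iff ``tau < -sync_cut``, weak
    otherwise.  Values exactly at a cut are excluded / stay weak.
    """
    if not (0 <= edge_cut <= sync_cut <= 1):
        raise ValueError("need 0 <= edge_cut <= sync_cut <= 1")
    edges: list[tuple[str, str, float, str]] = []
    m = len(tm.nodes)
    for i in range(m):
        for j in range(i + 1, m):
            t = float(tm.tau[i, j])
            if abs(t) <= edge_cut:
                continue
            if t > sync_cut:
                cls = "synchronous"
            elif t < -sync_cut:
                cls = "anti-synchronous"
            else:
                cls = "weak"
            edges.append((tm.nodes[i], tm.nodes[j], t, cls))
    return SyncNetwork(nodes=list(tm.nodes), edges=edges,
                       thresholds=(edge_cut, sync_cut),
                       condition=tm.condition)
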