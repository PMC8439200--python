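"""Weighted correlation networks, scale-free soft thresholding and entropy.

Per-group networks follow the weighted co-expression convention: the
adjacency between metabolites i and j is ``|cor(i, j)|**beta`` with the
soft power beta picked by the scale-free topology criterion — the smallest
candidate power whose connectivity distribution fits a power law with
R^2 at least ``r2_cut`` (falling back to the best-fitting power).

The network structure entropy summarizes how evenly connectivity is
spread over the nodes.  With k_i the (weighted) connectivity of node i,
node importance is I_i = k_i / sum_j k_j and

    E = -sum_i I_i ln I_i,

which is maximal (ln N) when all nodes are equally connected and drops as
connectivity concentrates on hubs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import ExpressionStudy

__all__ = [
    "WeightedNetwork",
    "EntropyResult",
    "scale_free_fit",
    "build_correlation_network",
    "network_entropy",
    "entropy_recovery",
]


@dataclass
class WeightedNetwork:
    """Soft-powered correlation adjacency for one group of samples."""

    nodes: list[str]
    adjacency: np.ndarray          # symmetric, zero diagonal, in [0, 1]
    soft_power: int
    scalefree_r2: float
    group: str
    signed: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape does not match node list")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.abs(np.diag(a)) > 0):
            raise ValueError("adjacency diagonal must be zero")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")
        self.adjacency = a

    def connectivity(self) -> np.ndarray:
        """Weighted connectivity k_i = row sums of the adjacency."""
        return self.adjacency.sum(axis=1)


@dataclass
class EntropyResult:
    """Node importances and the degree-based structure entropy."""

    importance: dict[str, float]
    entropy: float
    n_nodes: int
    degrees: dict[str, float]


def scale_free_fit(degrees: Mapping[str, float] | Sequence[float],
                   n_bins: int = 10) -> float:
    """R^2 of the log-log power-law fit to a connectivity distribution.

    Connectivities are split into ``n_bins`` equal-width bins; empty bins
    are dropped, then log10 of the bin frequency is regressed on log10 of
    the mean connectivity per bin.  Degenerate inputs (all connectivities
    equal, or fewer than two occupied bins) return 0.0 with a warning; a
    two-bin fit is trivially perfect and is flagged as low-confidence.
    """
    if isinstance(degrees, Mapping):
        k = np.asarray(list(degrees.values()), dtype=float)
    else:
        k = np.asarray(list(degrees), dtype=float)
    k = k[k > 0]
    if k.size < 5:
        raise ValueError("scale-free fit needs >= 5 nodes with positive connectivity")
    if np.ptp(k) == 0:
        warnings.warn("all connectivities equal; scale-free R^2 undefined, "
                      "returning 0", stacklevel=2)
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    k_mean, freq = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            k_mean.append(k[mask].mean())
            freq.append(mask.sum() / k.size)
    if len(k_mean) < 2:
        warnings.warn("fewer than two occupied connectivity bins; returning 0",
                      stacklevel=2)
        return 0.0
    if len(k_mean) == 2:
        warnings.warn("only two occupied bins: two-point fit is trivially "
                      "perfect (low confidence)", stacklevel=2)
    res = stats.linregress(np.log10(k_mean), np.log10(freq))
    return float(res.rvalue ** 2)


def build_correlation_network(study: ExpressionStudy, group: str,
                              powers: Sequence[int] = tuple(range(1, 21)),
                              r2_cut: float = 0.8,
                              signed: bool = False,
                              n_bins: int = 10) -> WeightedNetwork:
    """Soft-thresholded correlation network for one group's samples.

    adjacency = |pearson r|^beta (unsigned, the default) or
    ((1 + r)/2)^beta (signed).  beta is the smallest candidate power
    whose scale-free fit reaches ``r2_cut``; if none does, the power with
    the best fit is used.
    """
    sub = study.group_values(group)
    if sub.shape[1] < 3:
        raise ValueError(f"group {group!r} has fewer than 3 samples")
    if sub.shape[0] < 3:
        raise ValueError("need at least 3 metabolites")
    vals = sub.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if np.any(sd == 0):
        bad = [str(sub.index[i]) for i in np.nonzero(sd == 0)[0]]
        raise ValueError(
            f"zero-variance metabolite(s) in group {group!r}: {bad}; "
            "correlation undefined"
        )
    r = np.corrcoef(vals)
    base = (1 + r) / 2 if signed else np.abs(r)
    np.fill_diagonal(base, 0.0)
    base = np.clip(base, 0.0, 1.0)

    if base.shape[0] < 5:
        # too few nodes for a meaningful connectivity distribution:
        # keep the gentlest candidate power and flag the fit as absent
        beta = min(powers)
        adj = base ** beta
        np.fill_diagonal(adj, 0.0)
        warnings.warn("fewer than 5 metabolites; scale-free criterion "
                      "skipped, using the smallest candidate power",
                      stacklevel=2)
        return WeightedNetwork(nodes=[str(i) for i in sub.index],
                               adjacency=adj, soft_power=int(beta),
                               scalefree_r2=0.0, group=group, signed=signed)

    chosen_beta, chosen_r2, best_beta, best_r2 = None, None, None, -np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for beta in powers:
            adj = base ** beta
            r2 = scale_free_fit(adj.sum(axis=1), n_bins=n_bins)
            if r2 > best_r2:
                best_beta, best_r2 = beta, r2
            if chosen_beta is None and r2 >= r2_cut:
                chosen_beta, chosen_r2 = beta, r2
                break
    if chosen_beta is None:
        chosen_beta, chosen_r2 = best_beta, best_r2
    adj = base ** chosen_beta
    np.fill_diagonal(adj, 0.0)
    return WeightedNetwork(nodes=[str(i) for i in sub.index], adjacency=adj,
                           soft_power=int(chosen_beta),
                           scalefree_r2=float(chosen_r2), group=group,
                           signed=signed)


def network_entropy(net: WeightedNetwork | None = None,
                    degrees: Mapping[str, float] | None = None,
                    binary: bool = False,
                    hard_threshold: float = 0.5) -> EntropyResult:
    """Degree-based network structure entropy E = -sum I_i ln I_i.

    Connectivity k_i defaults to the weighted row sum of the adjacency;
    ``binary=True`` instead counts edges with weight above
    ``hard_threshold``.  Alternatively pass a precomputed ``degrees``
    mapping.  0 * ln 0 is taken as 0, so zero-connectivity nodes simply
    contribute nothing.
    """
    if degrees is not None:
        names = [str(n) for n in degrees]
        k = np.asarray([degrees[n] for n in degrees], dtype=float)
    elif net is not None:
        names = list(net.nodes)
        if binary:
            k = (net.adjacency > hard_threshold).sum(axis=1).astype(float)
        else:
            k = net.connectivity()
    else:
        raise ValueError("pass a network or a degrees mapping")
    if np.any(k < 0):
        raise ValueError("connectivities must be nonnegative")
    total = k.sum()
    if total <= 0:
        raise ValueError("all connectivities are zero; importance undefined")
    imp = k / total
    nz = imp[imp > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return EntropyResult(
        importance={n: float(v) for n, v in zip(names, imp)},
        entropy=entropy,
        n_nodes=len(names),
        degrees={n: float(v) for n, v in zip(names, k)},
    )


def entropy_recovery(e_sham: float, e_vehicle: float, e_dose: float) -> float:
    """Percent recovery of a dose group's entropy toward the healthy level.

    Returns 100 * (e_dose - e_vehicle) / (e_sham - e_vehicle): 0% means
    the treated network is still at the diseased (vehicle) entropy, 100%
    means full return to the sham level.
    """
    denom = e_sham - e_vehicle
    if denom == 0:
        raise ZeroDivisionError(
            "sham and vehicle entropies are equal; recovery undefined"
        )
    return 100.0 * (e_dose - e_vehicle) / denom
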