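"""Six-pattern Yin/Yang classification of two-stage expression changes.

Each metabolite gets two signed log2 fold changes: v1 compares the
diseased (vehicle) group against sham, v2 compares a treated dose group
against vehicle.  The (v1, v2) plane is partitioned into six named
regions plus a no-change label:

===========  ==================================  =========
pattern      region                              direction
===========  ==================================  =========
PT           v1 < 0 < v2 (reversal upward)       Yang
NT           v2 < 0 < v1 (reversal downward)     Yin
PA           0 < v1 < v2 (positive, growing)     Yang
PR           0 < v2 < v1 (positive, shrinking)   Yin
NA           v1 < v2 < 0 (negative, recovering)  Yang
NR           v2 < v1 < 0 (negative, sinking)     Yin
NC           any zero or v1 == v2 after snapping neutral
===========  ==================================  =========

Yang patterns carry an upregulation character, Yin patterns a
downregulation character; counting them per dose group gives the
separate (PT vs NT) and overall Yin/Yang ratio and difference
statistics, whose trends against dose quantify the dose-response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import ExpressionStudy

__all__ = [
    "PATTERNS", "YANG", "YIN",
    "ChangePair", "PatternAssignment", "YinYangSummary", "DoseTrend",
    "classify", "classify_pattern", "compute_changes",
    "summarize", "vehicle_yinyang", "dose_trend", "yinyang_of",
]

PATTERNS = ("PT", "NT", "PA", "PR", "NA", "NR", "NC")
YANG = frozenset({"PT", "PA", "NA"})
YIN = frozenset({"NT", "PR", "NR"})


def yinyang_of(pattern: str) -> str:
    if pattern in YANG:
        return "Yang"
    if pattern in YIN:
        return "Yin"
    return "neutral"


@dataclass(frozen=True)
class ChangePair:
    """The two signed stage changes for one metabolite in one dose group."""

    metabolite: str
    v1: float       # log2 FC, vehicle vs sham
    v2: float       # log2 FC, dose group vs vehicle
    group: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.v1) and math.isfinite(self.v2)):
            raise ValueError(f"non-finite change for {self.metabolite}")


@dataclass(frozen=True)
class PatternAssignment:
    metabolite: str
    group: str
    pattern: str
    yinyang: str
    v1: float = 0.0
    v2: float = 0.0


def classify(v1: float, v2: float) -> str:
    """Map one epsilon-snapped (v1, v2) point to its pattern label.

    Total on the plane: every point falls in exactly one of the six
    regions or in NC (any zero coordinate, or v1 == v2).
    """
    if v1 == 0 or v2 == 0 or v1 == v2:
        return "NC"
    if v1 < 0 < v2:
        return "PT"
    if v2 < 0 < v1:
        return "NT"
    if 0 < v1 < v2:
        return "PA"
    if 0 < v2 < v1:
        return "PR"
    if v1 < v2 < 0:
        return "NA"
    return "NR"           # v2 < v1 < 0


def classify_pattern(pair: ChangePair) -> PatternAssignment:
    p = classify(pair.v1, pair.v2)
    return PatternAssignment(metabolite=pair.metabolite, group=pair.group,
                             pattern=p, yinyang=yinyang_of(p),
                             v1=pair.v1, v2=pair.v2)


def _snap(v: float, eps: float) -> float:
    return 0.0 if abs(v) < eps else v


def _group_means(study: ExpressionStudy, group: str) -> np.ndarray:
    means = study.group_values(group).to_numpy(dtype=float).mean(axis=1)
    if np.any(means <= 0):
        bad = [m for m, v in zip(study.metabolite_ids, means) if v <= 0]
        raise ValueError(
            f"nonpositive group mean in {group!r} for {bad}; "
            "log fold change undefined"
        )
    return means


def compute_changes(study: ExpressionStudy, eps: float = 0.05,
                    sham: str = "sham", vehicle: str = "vehicle",
                    dose_groups: Sequence[str] | None = None
                    ) -> list[ChangePair]:
    """Two-stage log2 fold changes for every metabolite and dose group.

    v1 = log2(mean_vehicle / mean_sham), v2 = log2(mean_group /
    mean_vehicle), per metabolite.  Changes smaller than ``eps`` (in log2
    units) are snapped to exactly 0 so the classifier can treat them as
    no change.
    """
    if dose_groups is None:
        dose_groups = [g for g in study.groups if g not in {sham, vehicle}]
    m_sham = _group_means(study, sham)
    m_veh = _group_means(study, vehicle)
    v1 = np.log2(m_veh / m_sham)
    out: list[ChangePair] = []
    for g in dose_groups:
        m_g = _group_means(study, g)
        v2 = np.log2(m_g / m_veh)
        for met, a, b in zip(study.metabolite_ids, v1, v2):
            out.append(ChangePair(metabolite=met, v1=_snap(float(a), eps),
                                  v2=_snap(float(b), eps), group=g))
    return out


@dataclass
class YinYangSummary:
    """Per-group pattern counts and the four Yin/Yang statistics.

    Ratios with a zero denominator are reported as ``inf`` (undefined).
    """

    group: str
    counts: dict[str, int]
    separate_ratio: float = field(init=False)
    separate_difference: int = field(init=False)
    overall_ratio: float = field(init=False)
    overall_difference: int = field(init=False)

    def __post_init__(self) -> None:
        c = self.counts
        yang = c["PT"] + c["PA"] + c["NA"]
        yin = c["NT"] + c["PR"] + c["NR"]
        self.separate_ratio = c["PT"] / c["NT"] if c["NT"] else math.inf
        self.separate_difference = c["PT"] - c["NT"]
        self.overall_ratio = yang / yin if yin else math.inf
        self.overall_difference = yang - yin

    @property
    def yang_total(self) -> int:
        return self.counts["PT"] + self.counts["PA"] + self.counts["NA"]

    @property
    def yin_total(self) -> int:
        return self.counts["NT"] + self.counts["PR"] + self.counts["NR"]


def summarize(assignments: Iterable[PatternAssignment],
              group: str) -> YinYangSummary:
    """Cumulative pattern counts and ratio/difference statistics for a group."""
    counts = {p: 0 for p in PATTERNS}
    for a in assignments:
        if a.group != group:
            raise ValueError(
                f"assignment for {a.metabolite!r} belongs to group "
                f"{a.group!r}, not {group!r}"
            )
        counts[a.pattern] += 1
    return YinYangSummary(group=group, counts=counts)


def vehicle_yinyang(study: ExpressionStudy, eps: float = 0.05,
                    sham: str = "sham",
                    vehicle: str = "vehicle") -> dict[str, str]:
    """Yin/Yang state of the diseased (vehicle) condition by v1 sign alone."""
    m_sham = _group_means(study, sham)
    m_veh = _group_means(study, vehicle)
    v1 = np.log2(m_veh / m_sham)
    out = {}
    for met, v in zip(study.metabolite_ids, v1):
        v = _snap(float(v), eps)
        out[met] = "Yang" if v > 0 else ("Yin" if v < 0 else "neutral")
    return out


@dataclass
class DoseTrend:
    r: float
    slope: float
    intercept: float
    axis: str
    defined: bool = True


def dose_trend(counts_by_group: Mapping[str, float],
               axis: str = "rank",
               dose_levels: Mapping[str, float] | None = None) -> DoseTrend:
    """Pearson correlation and least-squares line of counts against dose.

    ``axis`` picks the x coordinate: "rank" (1..G in the mapping's
    order), "dose" (requires ``dose_levels``) or "log2dose".  Constant
    counts leave r undefined (flagged, slope 0).
    """
    groups = list(counts_by_group)
    if len(groups) < 3:
        raise ValueError("dose trend needs at least 3 groups")
    y = np.asarray([counts_by_group[g] for g in groups], dtype=float)
    if axis == "rank":
        x = np.arange(1, len(groups) + 1, dtype=float)
    elif axis in {"dose", "log2dose"}:
        if dose_levels is None:
            raise ValueError("dose_levels required for dose-based axes")
        x = np.asarray([dose_levels[g] for g in groups], dtype=float)
        if axis == "log2dose":
            if np.any(x <= 0):
                raise ValueError("log2 dose axis needs positive doses")
            x = np.log2(x)
    else:
        raise ValueError(f"unknown dose axis {axis!r}")
    if np.ptp(y) == 0:
        return DoseTrend(r=math.nan, slope=0.0, intercept=float(y[0]),
                         axis=axis, defined=False)
    res = stats.linregress(x, y)
    return DoseTrend(r=float(res.rvalue), slope=float(res.slope),
                     intercept=float(res.intercept), axis=axis)
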