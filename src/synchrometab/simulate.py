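"""Synthetic dose-response metabolomics studies with planted ground truth.

The generator emulates a six-group rodent study design — sham, vehicle
(diseased) and four treatment dose groups — with a fixed number of
animals per group.  Three kinds of structure are planted on a
log2-abundance scale:

* **Pattern labels.**  Group means are constructed so that the two-stage
  signed changes (vehicle vs sham, dose group vs vehicle) land each
  planned metabolite in its target transformation-pattern region.  The
  vehicle-vs-sham shift is one ``effect_size`` unit; dose-group shifts
  scale monotonically with dose rank, giving the planned pattern counts a
  built-in dose trend.
* **Synchronous modules.**  Metabolites of a planted module load on a
  shared latent factor within the module's active groups.  The loading is
  set through the Gaussian sine relation tau = (2/pi) * arcsin(rho), so a
  target Kendall tau translates into the Pearson correlation
  rho = sin(pi * tau / 2) of the latent mixture.  A negative module sign
  alternates loading signs, producing anti-synchronous edges.
* **Noise.**  I.i.d. Gaussian noise on the log2 scale everywhere else.

Samples are exported as positive abundances (2 ** log2-value), so
downstream log-ratio statistics see exactly the planted shifts in
expectation.  The same seed and config always produce a bit-identical
matrix.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import ExpressionStudy, write_study
from .syncnet import condition_label

__all__ = [
    "PlantedModule", "SimulationConfig", "GroundTruth",
    "simulate_study", "default_config", "config_from_yaml",
    "write_simulation", "DEFAULT_METABOLITES",
]

_PATTERN_V1_SIGN = {"PT": -1, "NA": -1, "NR": -1,
                    "NT": +1, "PA": +1, "PR": +1, "NC": 0}

# 41 serum metabolites typical of an amino-acid / fatty-acid panel.
DEFAULT_METABOLITES: tuple[str, ...] = (
    "taurine", "L-tyrosine", "L-leucine", "L-isoleucine",
    "hexadecanoic acid", "oleic acid", "linoleate", "myristic acid",
    "glyoxylate", "L-glutamate", "L-valine", "glycine",
    "hydroxypyruvate", "stearic acid", "tetrahydrofolate", "arachidonate",
    "Cys-Gly", "cystathionine", "anandamide", "octadecatrienoic acid",
    "phytosphingosine", "L-alanine", "L-proline", "L-phenylalanine",
    "L-tryptophan", "L-methionine", "L-glutamine", "L-lysine",
    "L-histidine", "palmitoleic acid", "docosahexaenoic acid",
    "L-carnitine", "L-arginine", "xanthine", "N-acetyl-L-glutamate",
    "L-threonine", "L-serine", "creatinine", "hypoxanthine", "uric acid",
    "citric acid",
)

DEFAULT_GROUPS = ("sham", "vehicle", "DH1", "DH2", "DH3", "DH4")
DEFAULT_DOSES = {"sham": 0.0, "vehicle": 0.0,
                 "DH1": 1.0, "DH2": 2.5, "DH3": 5.0, "DH4": 10.0}


@dataclass(frozen=True)
class PlantedModule:
    """A latent-factor-correlated node set active in a set of groups."""

    nodes: tuple[str, ...]
    tau: float
    sign: int = +1                 # -1 alternates loading signs
    groups: tuple[str, ...] = ("DH1", "DH2", "DH3", "DH4")

    def loadings(self) -> dict[str, int]:
        if self.sign >= 0:
            return {n: +1 for n in self.nodes}
        return {n: (+1 if i % 2 == 0 else -1)
                for i, n in enumerate(self.nodes)}

    @property
    def condition(self) -> str:
        return condition_label(self.groups)


@dataclass
class SimulationConfig:
    metabolites: Sequence[str] = DEFAULT_METABOLITES
    n_per_group: int = 10
    group_names: Sequence[str] = DEFAULT_GROUPS
    dose_levels: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DOSES))
    pattern_plan: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    module_plan: Sequence[PlantedModule] = ()
    vehicle_sign: Mapping[str, int] = field(default_factory=dict)
    noise_sd: float = 0.1
    baseline_mean: float = 10.0
    effect_size: float = 1.0
    seed: int = 0
    sham: str = "sham"
    vehicle: str = "vehicle"

    @property
    def dose_groups(self) -> list[str]:
        return [g for g in self.group_names
                if g not in {self.sham, self.vehicle}]

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        mets = list(self.metabolites)
        if len(set(mets)) != len(mets):
            raise ValueError("duplicate metabolite names")
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3 (rank correlation on "
                             "fewer samples is degenerate)")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("noise_sd and effect_size must be nonnegative")
        known = set(mets)
        dhi = set(self.dose_groups)
        for met, per_group in self.pattern_plan.items():
            if met not in known:
                raise ValueError(f"pattern_plan names unknown metabolite {met!r}")
            for g, p in per_group.items():
                if g not in dhi:
                    raise ValueError(
                        f"pattern for {met!r} targets non-dose group {g!r}")
                if p not in _PATTERN_V1_SIGN:
                    raise ValueError(f"unknown pattern label {p!r} for {met!r}")
        for mod in self.module_plan:
            for n in mod.nodes:
                if n not in known:
                    raise ValueError(f"module_plan names unknown metabolite {n!r}")
            if not (0 < mod.tau <= 1):
                raise ValueError(f"module target tau must be in (0, 1], got {mod.tau}")
            for g in mod.groups:
                if g not in set(self.group_names):
                    raise ValueError(f"module targets unknown group {g!r}")
        # one active module per metabolite per group
        claims: dict[tuple[str, str], str] = {}
        for mod in self.module_plan:
            for g in mod.groups:
                for n in mod.nodes:
                    if (n, g) in claims:
                        raise ValueError(
                            f"metabolite {n!r} belongs to two modules active "
                            f"in group {g!r}")
                    claims[(n, g)] = mod.condition
        self._v1_signs()
        self._check_module_trend_conflicts()

    def _v1_signs(self) -> dict[str, int]:
        """Required vehicle-vs-sham sign per metabolite; conflicts are errors."""
        signs: dict[str, int] = {}
        for met, per_group in self.pattern_plan.items():
            req = {_PATTERN_V1_SIGN[p] for p in per_group.values()} - {0}
            if len(req) > 1:
                raise ValueError(
                    f"contradictory plan for metabolite {met!r}: patterns "
                    f"{sorted(set(per_group.values()))} require opposite "
                    "vehicle-vs-sham directions")
            signs[met] = req.pop() if req else 0
        for met, s in self.vehicle_sign.items():
            if met in signs and signs[met] != 0 and s != signs[met]:
                raise ValueError(
                    f"contradictory plan for metabolite {met!r}: "
                    f"vehicle_sign {s} conflicts with its patterns")
            signs[met] = s if signs.get(met, 0) == 0 else signs[met]
        return signs

    def _mean_matrix(self) -> pd.DataFrame:
        """Planted log2 group means, metabolites x groups."""
        mets = list(self.metabolites)
        mu = pd.DataFrame(self.baseline_mean, index=mets,
                          columns=list(self.group_names), dtype=float)
        signs = self._v1_signs()
        E = self.effect_size
        dhi = self.dose_groups
        n_dhi = max(len(dhi), 1)
        for met in mets:
            s = signs.get(met, 0)
            v1 = s * E
            mu.loc[met, self.vehicle] = self.baseline_mean + v1
            per_group = self.pattern_plan.get(met, {})
            for g in dhi:
                rank = dhi.index(g) + 1
                c = rank / n_dhi
                delta = E * c
                p = per_group.get(g, "NC")
                if p == "NC":
                    v2 = 0.0
                elif p == "PT":
                    v2 = delta
                elif p == "NT":
                    v2 = -delta
                elif p == "PA":
                    v2 = E + delta
                elif p == "PR":
                    v2 = E * (1 - c / 2)
                elif p == "NA":
                    v2 = -E * (1 - c / 2)
                else:                      # NR
                    v2 = -E - delta
                mu.loc[met, g] = mu.loc[met, self.vehicle] + v2
        return mu

    def _check_module_trend_conflicts(self) -> None:
        """Reject members whose planted mean trends oppose their loadings.

        Within a multi-group module, two members with same-sign loadings
        must not have strictly opposite mean trends across the module's
        groups (and vice versa for opposite loadings): the latent factor
        and the mean structure would then fight over the pooled tau.
        """
        mu = self._mean_matrix()
        for mod in self.module_plan:
            if len(mod.groups) < 2:
                continue
            load = mod.loadings()
            trend = {}
            for n in mod.nodes:
                prof = mu.loc[n, list(mod.groups)].to_numpy()
                trend[n] = int(np.sign(prof[-1] - prof[0]))
            for i, a in enumerate(mod.nodes):
                for b in mod.nodes[i + 1:]:
                    t = trend[a] * trend[b]
                    if t != 0 and t != load[a] * load[b]:
                        raise ValueError(
                            f"contradictory plan: metabolites {a!r} and {b!r} "
                            f"have mean trends opposing their module loadings "
                            f"in module {mod.condition}")


@dataclass
class GroundTruth:
    """What was planted: labels, modules and the generating parameters."""

    true_patterns: dict[tuple[str, str], str]
    true_modules: dict[str, list[frozenset[str]]]
    generating_parameters: SimulationConfig

    def patterns_for_group(self, group: str) -> dict[str, str]:
        return {m: p for (m, g), p in self.true_patterns.items() if g == group}

    def to_json_dict(self) -> dict:
        cfg = self.generating_parameters
        return {
            "true_patterns": [
                {"metabolite": m, "group": g, "pattern": p}
                for (m, g), p in sorted(self.true_patterns.items())
            ],
            "true_modules": {c: [sorted(s) for s in sets]
                             for c, sets in self.true_modules.items()},
            "generating_parameters": {
                "metabolites": list(cfg.metabolites),
                "n_per_group": cfg.n_per_group,
                "group_names": list(cfg.group_names),
                "dose_levels": dict(cfg.dose_levels),
                "noise_sd": cfg.noise_sd,
                "baseline_mean": cfg.baseline_mean,
                "effect_size": cfg.effect_size,
                "seed": cfg.seed,
                "module_plan": [
                    {"nodes": list(m.nodes), "tau": m.tau, "sign": m.sign,
                     "groups": list(m.groups)} for m in cfg.module_plan
                ],
            },
        }


def simulate_study(config: SimulationConfig,
                   seed: int | None = None) -> tuple[ExpressionStudy, GroundTruth]:
    """Draw one study from the configured design.

    Returns the abundance matrix (metabolites x samples, positive scale)
    with its design, and the ground truth behind it.  ``seed`` overrides
    ``config.seed`` when given.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mets = list(config.metabolites)
    groups = list(config.group_names)
    n = config.n_per_group
    mu = config._mean_matrix()

    sample_ids = [f"{g}_{i + 1:02d}" for g in groups for i in range(n)]
    col_of_group = {g: slice(gi * n, (gi + 1) * n)
                    for gi, g in enumerate(groups)}
    log2x = np.repeat(mu.to_numpy(), n, axis=1).astype(float)
    noise = rng.standard_normal(log2x.shape)

    met_idx = {m: i for i, m in enumerate(mets)}
    for mod in config.module_plan:
        rho = math.sin(math.pi * min(mod.tau, 1.0) / 2)
        load = mod.loadings()
        a, b = math.sqrt(rho), math.sqrt(1 - rho)
        for g in mod.groups:
            factor = rng.standard_normal(n)
            resid = rng.standard_normal((len(mod.nodes), n))
            for r, node in enumerate(mod.nodes):
                noise[met_idx[node], col_of_group[g]] = (
                    a * load[node] * factor + b * resid[r]
                )
    log2x += config.noise_sd * noise

    values = pd.DataFrame(np.exp2(log2x), index=mets, columns=sample_ids)
    design = pd.DataFrame(
        {
            "group": [g for g in groups for _ in range(n)],
            "dose": [float(config.dose_levels.get(g, 0.0))
                     for g in groups for _ in range(n)],
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    study = ExpressionStudy(values=values, design=design)

    truth = GroundTruth(
        true_patterns={(m, g): p
                       for m, per in config.pattern_plan.items()
                       for g, p in per.items()},
        true_modules={},
        generating_parameters=config,
    )
    for mod in config.module_plan:
        truth.true_modules.setdefault(mod.condition, []).append(
            frozenset(mod.nodes))
    return study, truth


# -- the default study conditions -------------------------------------------

def default_config(seed: int = 0) -> SimulationConfig:
    """Study conditions mirroring a six-group, 10-animal dose-response design.

    About two thirds of the 41 metabolites start downregulated (Yin) in
    the diseased state.  Planted pattern counts move monotonically with
    dose — upward reversals (PT) grow, downward reversals (NT) shrink —
    and three four-node synchronous modules are planted at tau 0.9: one
    active across all four dose groups, one only at the low-dose pair and
    one only at the high-dose pair.
    """
    mets = DEFAULT_METABOLITES
    conservative = mets[0:4]       # taurine .. L-isoleucine
    low_pair = mets[4:8]           # hexadecanoic acid .. myristic acid
    high_pair = mets[8:12]         # glyoxylate .. glycine
    yin_pool = list(mets[12:31])   # 19 metabolites, diseased-downregulated
    yang_pool = list(mets[31:40])  # 9 metabolites, diseased-upregulated

    pt = {"DH1": 6, "DH2": 7, "DH3": 8, "DH4": 9}
    na = {"DH1": 3, "DH2": 4, "DH3": 5, "DH4": 6}
    nr = {"DH1": 2, "DH2": 2, "DH3": 2, "DH4": 4}
    nt = {"DH1": 6, "DH2": 5, "DH3": 3, "DH4": 2}
    pr = {"DH1": 1, "DH2": 2, "DH3": 3, "DH4": 4}
    pa = {"DH1": 1, "DH2": 1, "DH3": 2, "DH4": 2}

    plan: dict[str, dict[str, str]] = {}

    def assign(pool: list[str], counts: Mapping[str, int], label: str,
               offset: Mapping[str, int]) -> None:
        for g, c in counts.items():
            start = offset[g]
            for met in pool[start:start + c]:
                plan.setdefault(met, {})[g] = label
            offset[g] += c

    off_yin = {g: 0 for g in pt}
    assign(yin_pool, pt, "PT", off_yin)
    assign(yin_pool, na, "NA", off_yin)
    assign(yin_pool, nr, "NR", off_yin)
    off_yang = {g: 0 for g in nt}
    assign(yang_pool, nt, "NT", off_yang)
    assign(yang_pool, pr, "PR", off_yang)
    assign(yang_pool, pa, "PA", off_yang)

    vehicle_sign = {m: -1 for m in
                    ("taurine", "L-leucine", "hexadecanoic acid", "oleic acid",
                     "linoleate", "glyoxylate", "L-glutamate", "glycine")}
    vehicle_sign.update({m: +1 for m in
                         ("L-tyrosine", "L-isoleucine", "myristic acid",
                          "L-valine")})
    vehicle_sign["citric acid"] = 0

    modules = (
        PlantedModule(nodes=tuple(conservative), tau=0.9, sign=+1,
                      groups=("DH1", "DH2", "DH3", "DH4")),
        PlantedModule(nodes=tuple(low_pair), tau=0.9, sign=+1,
                      groups=("DH1", "DH2")),
        PlantedModule(nodes=tuple(high_pair), tau=0.9, sign=+1,
                      groups=("DH3", "DH4")),
    )
    return SimulationConfig(pattern_plan=plan, module_plan=modules,
                            vehicle_sign=vehicle_sign, seed=seed)


def config_from_yaml(path: str | Path) -> SimulationConfig:
    """Build a config from a YAML file; omitted keys fall back to the
    default study conditions (an empty file gives ``default_config()``)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    base = default_config(seed=int(raw.get("seed", 0)))
    kwargs: dict = {}
    if "metabolites" in raw:
        kwargs["metabolites"] = list(raw["metabolites"])
    elif "n_metabolites" in raw:
        kwargs["metabolites"] = [f"M{i + 1:02d}"
                                 for i in range(int(raw["n_metabolites"]))]
    for key in ("n_per_group", "noise_sd", "baseline_mean", "effect_size",
                "seed", "sham", "vehicle"):
        if key in raw:
            kwargs[key] = raw[key]
    if "group_names" in raw:
        kwargs["group_names"] = list(raw["group_names"])
    if "dose_levels" in raw:
        kwargs["dose_levels"] = dict(raw["dose_levels"])
    if "pattern_plan" in raw:
        kwargs["pattern_plan"] = {m: dict(v)
                                  for m, v in raw["pattern_plan"].items()}
    if "vehicle_sign" in raw:
        kwargs["vehicle_sign"] = dict(raw["vehicle_sign"])
    if "module_plan" in raw:
        kwargs["module_plan"] = tuple(
            PlantedModule(nodes=tuple(m["nodes"]), tau=float(m["tau"]),
                          sign=int(m.get("sign", 1)),
                          groups=tuple(m.get("groups",
                                             ("DH1", "DH2", "DH3", "DH4"))))
            for m in raw["module_plan"]
        )
    custom_structure = any(k in raw for k in
                           ("metabolites", "n_metabolites", "pattern_plan",
                            "module_plan", "group_names"))
    if custom_structure:
        defaults = SimulationConfig()
        for key in ("pattern_plan", "module_plan", "vehicle_sign"):
            kwargs.setdefault(key, getattr(defaults, key))
        return SimulationConfig(**kwargs)
    return SimulationConfig(**{**_as_kwargs(base), **kwargs})


def _as_kwargs(cfg: SimulationConfig) -> dict:
    return {
        "metabolites": cfg.metabolites, "n_per_group": cfg.n_per_group,
        "group_names": cfg.group_names, "dose_levels": cfg.dose_levels,
        "pattern_plan": cfg.pattern_plan, "module_plan": cfg.module_plan,
        "vehicle_sign": cfg.vehicle_sign, "noise_sd": cfg.noise_sd,
        "baseline_mean": cfg.baseline_mean, "effect_size": cfg.effect_size,
        "seed": cfg.seed, "sham": cfg.sham, "vehicle": cfg.vehicle,
    }


def write_simulation(study: ExpressionStudy, truth: GroundTruth,
                     outdir: str | Path) -> dict[str, Path]:
    """Write expression.csv, design.csv and ground_truth.json to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.csv",
        "design": outdir / "design.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_study(study, paths["expression"], paths["design"])
    paths["ground_truth"].write_text(
        json.dumps(truth.to_json_dict(), indent=2, sort_keys=True) + "\n")
    return paths
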