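"""Synthetic study generator: planted patterns, modules and determinism."""

import numpy as np
import pytest

from synchrometab.simulate import (DEFAULT_METABOLITES, PlantedModule,
                                   SimulationConfig, config_from_yaml,
                                   default_config, simulate_study,
                                   write_simulation)
from synchrometab.yinyang import classify_pattern, compute_changes
from test_syncnet import brute_force_tau


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = default_config()
        s1, _ = simulate_study(cfg, seed=7)
        s2, _ = simulate_study(cfg, seed=7)
        assert np.array_equal(s1.values.to_numpy(), s2.values.to_numpy())

    def test_different_seed_differs(self):
        cfg = default_config()
        s1, _ = simulate_study(cfg, seed=7)
        s2, _ = simulate_study(cfg, seed=8)
        assert not np.array_equal(s1.values.to_numpy(), s2.values.to_numpy())


class TestPlantedPatterns:
    def test_noiseless_labels_exact(self):
        cfg = default_config()
        cfg.noise_sd = 0.0
        study, truth = simulate_study(cfg, seed=0)
        assignments = {(a.metabolite, a.group): a.pattern
                       for a in map(classify_pattern, compute_changes(study))}
        for key, pattern in truth.true_patterns.items():
            assert assignments[key] == pattern

    def test_zero_effect_zero_noise_all_no_change(self):
        cfg = SimulationConfig(metabolites=["a", "b", "c"], noise_sd=0.0,
                               effect_size=0.0)
        study, _ = simulate_study(cfg, seed=0)
        for p in compute_changes(study):
            assert classify_pattern(p).pattern == "NC"

    def test_single_pattern_forced(self):
        cfg = SimulationConfig(metabolites=["m1", "m2", "m3"], noise_sd=0.0,
                               pattern_plan={"m1": {"DH1": "PT"}})
        study, _ = simulate_study(cfg, seed=0)
        got = {(p.metabolite, p.group): classify_pattern(p).pattern
               for p in compute_changes(study)}
        assert got[("m1", "DH1")] == "PT"

    def test_truth_covers_exactly_the_plan(self, default_truth):
        cfg = default_truth.generating_parameters
        planned = {(m, g) for m, per in cfg.pattern_plan.items() for g in per}
        assert set(default_truth.true_patterns) == planned


class TestPlantedModules:
    def test_module_pair_tau_above_cut_in_most_seeds(self):
        # Monte-Carlo: target tau 0.9 in one group should put the sample
        # tau of a member pair past the 0.7 synchronous cut almost always
        cfg = SimulationConfig(
            metabolites=["m1", "m2", "m3", "m4", "m5"],
            module_plan=(PlantedModule(nodes=("m1", "m2", "m3"), tau=0.9,
                                       groups=("DH3",)),),
            noise_sd=0.05)
        hits = 0
        for seed in range(200):
            study, _ = simulate_study(cfg, seed=seed)
            sub = study.group_values("DH3")
            t = brute_force_tau(list(sub.loc["m1"]), list(sub.loc["m2"]))
            hits += t > 0.7
        assert hits >= 190    # >= 95% of 200 seeds

    def test_negative_sign_module_gives_anti_synchronous_tau(self):
        cfg = SimulationConfig(
            metabolites=["m1", "m2", "m3"],
            module_plan=(PlantedModule(nodes=("m1", "m2"), tau=0.9, sign=-1,
                                       groups=("DH1",)),),
            noise_sd=0.05)
        taus = []
        for seed in range(30):
            study, _ = simulate_study(cfg, seed=seed)
            sub = study.group_values("DH1")
            taus.append(brute_force_tau(list(sub.loc["m1"]),
                                        list(sub.loc["m2"])))
        assert np.mean(taus) < -0.7

    def test_module_inactive_outside_its_groups(self):
        cfg = SimulationConfig(
            metabolites=["m1", "m2", "m3"],
            module_plan=(PlantedModule(nodes=("m1", "m2"), tau=0.9,
                                       groups=("DH3",)),),
            noise_sd=0.05)
        taus = []
        for seed in range(50):
            study, _ = simulate_study(cfg, seed=seed)
            sub = study.group_values("DH1")
            taus.append(brute_force_tau(list(sub.loc["m1"]),
                                        list(sub.loc["m2"])))
        assert abs(np.mean(taus)) < 0.25

    def test_truth_records_module_condition(self, default_truth):
        assert frozenset(DEFAULT_METABOLITES[0:4]) in \
            default_truth.true_modules["DH1/DH2/DH3/DH4"]
        assert frozenset(DEFAULT_METABOLITES[8:12]) in \
            default_truth.true_modules["DH3/DH4"]


class TestPlanValidation:
    def test_conflicting_pattern_directions_named(self):
        cfg = SimulationConfig(
            metabolites=["m1", "m2", "m3"],
            pattern_plan={"m1": {"DH1": "PT", "DH2": "NT"}})
        with pytest.raises(ValueError, match="m1"):
            simulate_study(cfg, seed=0)

    def test_unknown_metabolite_rejected(self):
        cfg = SimulationConfig(metabolites=["m1", "m2", "m3"],
                               pattern_plan={"zz": {"DH1": "PT"}})
        with pytest.raises(ValueError, match="zz"):
            simulate_study(cfg)

    def test_module_tau_out_of_range(self):
        cfg = SimulationConfig(
            metabolites=["m1", "m2", "m3"],
            module_plan=(PlantedModule(nodes=("m1", "m2"), tau=1.5),))
        with pytest.raises(ValueError, match="tau"):
            simulate_study(cfg)

    def test_overlapping_modules_in_same_group_rejected(self):
        cfg = SimulationConfig(
            metabolites=["m1", "m2", "m3", "m4"],
            module_plan=(PlantedModule(nodes=("m1", "m2"), tau=0.9,
                                       groups=("DH1",)),
                         PlantedModule(nodes=("m2", "m3"), tau=0.9,
                                       groups=("DH1",))))
        with pytest.raises(ValueError, match="m2"):
            simulate_study(cfg)

    def test_module_loading_vs_trend_conflict_rejected(self):
        # two members with opposite planted mean trends but same-sign
        # loadings cannot both hit the target tau in the pooled condition
        cfg = SimulationConfig(
            metabolites=["m1", "m2", "m3"],
            pattern_plan={"m1": {"DH1": "PT", "DH2": "PT"},
                          "m2": {"DH1": "NA", "DH2": "NR"}},
            module_plan=(PlantedModule(nodes=("m1", "m2"), tau=0.9,
                                       groups=("DH1", "DH2")),))
        with pytest.raises(ValueError, match="contradictory"):
            simulate_study(cfg)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n_per_group"):
            simulate_study(SimulationConfig(metabolites=["a", "b"],
                                            n_per_group=2))


class TestOutputs:
    def test_round_trip_through_files(self, tmp_path, default_sim):
        from synchrometab.io import read_study
        study, truth = default_sim
        paths = write_simulation(study, truth, tmp_path)
        back = read_study(paths["expression"], paths["design"])
        assert back.values.shape == study.values.shape
        assert paths["ground_truth"].exists()

    def test_yaml_config_round_trip(self, tmp_path):
        cfg_file = tmp_path / "cfg.yaml"
        cfg_file.write_text(
            "n_metabolites: 6\n"
            "n_per_group: 5\n"
            "noise_sd: 0.2\n"
            "pattern_plan:\n  M01:\n    DH1: PT\n"
            "module_plan:\n"
            "  - nodes: [M02, M03, M04]\n    tau: 0.8\n    groups: [DH2]\n")
        cfg = config_from_yaml(cfg_file)
        assert len(list(cfg.metabolites)) == 6
        assert cfg.n_per_group == 5
        assert cfg.pattern_plan["M01"]["DH1"] == "PT"
        study, truth = simulate_study(cfg, seed=2)
        assert study.values.shape == (6, 30)
        assert truth.true_modules == {"DH2": [frozenset({"M02", "M03", "M04"})]}
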