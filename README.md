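# synchrometab

Dose–response analysis of metabolic networks for targeted metabolomics
studies with a sham / vehicle / multi-dose treatment design (for example a
rodent cerebral-ischemia model treated at four doses of an injection).
The package answers three questions a pharmacologist asks of such data:

1. **How disordered is the metabolic network in each condition?**
   Per-group weighted correlation networks are built with scale-free soft
   thresholding (adjacency `|r_ij|^β`), and summarized by the degree-based
   network structure entropy

   ```
   I_i = k_i / Σ_j k_j          E = −Σ_i I_i ln I_i
   ```

   with `k_i` the weighted connectivity of metabolite *i*. `E` is maximal
   (`ln N`) when connectivity is spread evenly and drops as it concentrates
   on hubs; the percent recovery of a dose group's entropy from the
   diseased (vehicle) level toward the healthy (sham) level,
   `100·(E_dose − E_vehicle)/(E_sham − E_vehicle)`, quantifies restoration.

2. **Which direction does each metabolite move, and how does the balance
   shift with dose?**  Each metabolite gets two signed log2 fold changes —
   `v1` (vehicle vs sham) and `v2` (dose group vs vehicle) — and is
   classified into six transformation patterns: PT (`v1<0<v2`),
   NT (`v2<0<v1`), PA (`0<v1<v2`), PR (`0<v2<v1`), NA (`v1<v2<0`),
   NR (`v2<v1<0`), plus a no-change label for snapped zeros and ties.
   PT/PA/NA are upregulation-direction (Yang), NT/PR/NR downregulation
   (Yin).  Per-group cumulative counts feed ratio and difference
   statistics (`PTᵃ/NTᵃ`, `PTᵃ−NTᵃ`, and their overall Yang/Yin
   analogues) and linear dose trends.

3. **Which metabolites move together, and is that coupling conserved
   across doses?**  All-pairs Kendall tau-a
   (`t_n = (C−D)/C(n,2)`, ties counted as zero) over the pooled samples
   of a condition defines a network whose edges with `|τ| > 0.5` are kept
   and classed synchronous (`τ > 0.7`) or anti-synchronous (`τ < −0.7`).
   A from-scratch MCODE implementation (core-clustering-coefficient
   vertex weights, greedy seed-and-expand, haircut post-processing)
   extracts modules; Jaccard matching across dose conditions labels them
   full-course, partial, conservative-allosteric or emerging, and
   persistent synchronous pairs are tracked across every single dose.

A synthetic-study generator plants pattern labels, latent-factor
synchronous modules at a target tau (via `τ = (2/π)·arcsin ρ`), and dose
trends, so every stage can be validated against known ground truth.
Hypergeometric over-representation analysis against GMT pathway sets
covers the enrichment step.

## Worked example

```python
from synchrometab import (default_config, simulate_study, tau_matrix,
                          build_sync_network, find_modules,
                          build_correlation_network, network_entropy)

config = default_config()                 # 41 metabolites, 6 groups of 10
study, truth = simulate_study(config, seed=1)

net = build_correlation_network(study, "vehicle")
ent = network_entropy(net)
print(f"vehicle: beta={net.soft_power}  scale-free R2={net.scalefree_r2:.2f}  "
      f"entropy={ent.entropy:.3f}")

sync = build_sync_network(tau_matrix(study, ["DH1", "DH2"]))
print("DH1/DH2 edges:", sync.edge_counts())
for module in find_modules(sync):
    print(f"module (score {module.score:.2f}):", ", ".join(sorted(module.nodes)))
```

prints

```
vehicle: beta=7  scale-free R2=0.92  entropy=3.518
DH1/DH2 edges: {'synchronous': 13, 'anti-synchronous': 0, 'weak': 72}
module (score 4.00): L-isoleucine, L-leucine, L-tyrosine, taurine
module (score 4.00): hexadecanoic acid, linoleate, myristic acid, oleic acid
```

The vehicle network selects soft power β = 7 at scale-free fit R² = 0.92
and has entropy 3.518 (upper bound ln 41 ≈ 3.714).  The pooled low-dose
(DH1/DH2) tau network contains 13 synchronous edges, and MCODE returns
exactly the two modules planted in that condition: the always-active
module (taurine, L-tyrosine, L-leucine, L-isoleucine) and the
low-dose-only fatty-acid module — both perfect 4-cliques, score
density × size = 4.

The same pipeline is available from the shell:

```sh
synchrometab simulate --seed 1 --out sim/
synchrometab build-network --matrix sim/expression.csv --design sim/design.csv \
    --group vehicle --out nets/
synchrometab sync --matrix sim/expression.csv --design sim/design.csv \
    --groups DH1,DH2 --out nets/
synchrometab modules --matrix sim/expression.csv --design sim/design.csv \
    --groups DH1,DH2 --out nets/
synchrometab compare --matrix sim/expression.csv --design sim/design.csv --out dyn/
```

## Documentation

See `docs/methods.md` for the statistical model, the synthetic-data
generator's assumptions, parameter defaults and known limitations.
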