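# Methods

## Study design and data model

The pipeline operates on an `ExpressionStudy`: a metabolite × sample
matrix of positive abundances plus a design mapping each sample to a
group (sham, vehicle, and an ordered series of treatment dose groups,
DH1–DH4 by default, at doses 1, 2.5, 5 and 10 ml/kg) and requiring at
least three samples per group for any correlation stage.  Missing values
are a hard error: the downstream statistics (log fold changes, ranks,
correlations) would all silently change under imputation, so imputation
is left to the analyst.

## Weighted correlation networks and entropy

Per group, the adjacency between metabolites i and j is
`a_ij = |r_ij|^β` with `r` the Pearson correlation over that group's
samples (an unsigned network; a signed variant `((1+r)/2)^β` is
available).  β is selected by the scale-free topology criterion: the
weighted connectivities `k_i = Σ_j a_ij` are split into `n_bins = 10`
equal-width bins, log10 bin frequency is regressed on log10 mean bin
connectivity, and the smallest candidate power (1–20) whose fit reaches
`R² ≥ 0.8` is chosen, falling back to the best-fitting power.  Each
group selects its own β, since network construction is per condition.
Degenerate inputs are flagged rather than hidden: all-equal
connectivities return R² = 0 with a warning, a two-bin fit is warned as
trivially perfect, and fewer than five metabolites skip the criterion
entirely (smallest power, R² recorded as 0).

Network structure entropy uses the weighted connectivity as the node
degree (the co-expression convention; a hard-thresholded binary degree is
available behind a flag): importance `I_i = k_i / Σ k`, entropy
`E = −Σ I_i ln I_i` with `0·ln 0 = 0`, natural log throughout.  `E` lies
in `[0, ln N]`, is permutation invariant, and never decreases when
connectivity is transferred from a better- to a worse-connected node —
all three properties are asserted in the test suite.  Dose-group
restoration is summarized as
`100·(E_dose − E_vehicle)/(E_sham − E_vehicle)`; this linear
interpolation between the diseased and healthy entropy levels is the
package's chosen definition of "percent recovery" and is recorded as
such in its output.

## Six-pattern Yin/Yang classification

Stage changes are mean-based log2 fold changes: `v1 =
log2(mean_vehicle/mean_sham)` and, per dose group,
`v2 = log2(mean_group/mean_vehicle)` — the second comparison is always
against vehicle, not against the previous dose.  Values with
`|v| < eps` (default 0.05 log2 units, about a 3.5% abundance change) are
snapped to exactly zero.  The classifier is a total partition of the
(v1, v2) plane: PT `v1<0<v2`, NT `v2<0<v1`, PA `0<v1<v2`, PR `0<v2<v1`,
NA `v1<v2<0`, NR `v2<v1<0`, with strict inequalities; any zero
coordinate or exact tie is labelled NC (no change).  NC is this
package's addition — the six named regions do not cover the axes or the
diagonal.  PT/PA/NA are Yang (upward character), NT/PR/NR Yin.

Group summaries count each pattern and form `PTᵃ/NTᵃ`, `PTᵃ−NTᵃ`, and
the overall Yang/Yin ratio and difference; a zero denominator reports
the ratio as undefined.  Dose trends are Pearson correlations of counts
against a configurable dose axis — group rank 1–4 by default, since
counts in this design are roughly linear in rank rather than in the
2–10× spaced doses; actual dose and log2 dose are available and the axis
used is recorded in the output.

## Kendall tau-a synchronous networks

Pairwise association under a condition uses Kendall tau-a:
`t_n = (C − D)/C(n,2)` over all sample pairs, tied pairs contributing
zero and no tie correction (HPLC-scale abundances essentially never
tie; tau-b is available behind a flag).  The estimator is exact integer
arithmetic divided by the pair count and is tested for exact equality
against a brute-force double loop up to n = 50.  A condition is a single
group or a pooled set of groups (the DH2/DH3 network uses all 20 pooled
samples); a consensus mode requiring each edge to pass in every group
separately is available, pooled being the default.  A metabolite
constant across the pooled samples has tau defined as 0 against
everything and is flagged.

Edges require `|τ| > 0.5` (strict) and are classed synchronous
(`τ > 0.7`), anti-synchronous (`τ < −0.7`) or weak.  Module detection
runs on the strong (±0.7) graph only, with the tau sign carried as an
edge attribute rather than a barrier, so anti-synchronous couplings can
sit inside a module.

## MCODE

Vertex weight = density of the highest k-core of the node's closed
neighborhood × that core's k; nodes below the degree cutoff (2) weigh 0.
Complexes grow greedily from the highest-weight unvisited node, admitting
neighbors with weight ≥ seed weight × (1 − node_score_cutoff), default
cutoff 0.2; visited nodes are never reused, so complexes are disjoint.
Post-processing discards complexes without a 2-core, the haircut (on by
default) strips singly-connected members in one pass, and fluff (off by
default) optionally adds dense neighborhoods back.  Module score is
subgraph density × size; all ties break lexicographically by node id,
making results independent of input edge order.  Parameter defaults are
the algorithm's published defaults; the analysis they serve prints none.

## Module dynamics across doses

Modules are compared across the pooled full-course network (DH1–DH4) and
the adjacent-dose pair networks (DH1/DH2, DH2/DH3, DH3/DH4).  Module
identity across two networks is greedy best-first Jaccard matching with
a floor of 0.5 — the identity rule is this package's formalization, as
visual correspondence does not compose into a pipeline.  Full-course
modules are those of the DH1–DH4 network; pair modules with no
full-course match are partial; the conservative-allosteric node set is
the union of shared nodes over matched low-pair vs high-pair modules;
a pair module with no match in the preceding pair contributes its novel
nodes (those absent from the preceding pair's module union) as an
emerging set.  Persistent pairs are edges past the synchronous cut in
every single-dose network, regardless of the pooling mode used for
modules.

## Enrichment

Over-representation of a module in a pathway is the one-sided
hypergeometric upper tail, Benjamini–Hochberg corrected across pathways,
significant at adjusted p < 0.05.  The EASE modification (discount one
overlapping member before taking the tail) is available behind a flag but
off by default, there being no canonical definition of a "modified"
exact test.  The default universe is the study's own metabolite list;
pathway sets are user-supplied GMT.

## The synthetic-data generator

Defaults emulate the six-group design: 41 named serum metabolites
(amino acids, fatty acids and related small molecules), 10 samples per
group, baseline log2 abundance 10, i.i.d. Gaussian noise with
`noise_sd = 0.1` on the log2 scale, and `effect_size = 1.0` log2 units
(a two-fold change) for the vehicle-vs-sham shift.  Abundances are
exported as `2^x`, so mean-ratio log fold changes recover the planted
shifts in expectation.

*Patterns.*  A plan maps metabolites to target patterns per dose group.
The vehicle shift is `±effect_size` as the patterns require (a plan
demanding both directions for one metabolite is rejected, naming it);
dose-group shifts scale with dose rank r as `δ_r = effect_size·r/4`, so
planned counts trend monotonically with dose.  The default plan makes
about two-thirds of metabolites Yin in the vehicle state, with upward
reversals (PT) growing 6→9 and downward reversals (NT) shrinking 6→2
across the four doses.  Metabolites whose diseased-state direction
matters but which should stay flat across doses (module members, the
one neutral metabolite) carry a `vehicle_sign` instead of pattern
entries.

*Modules.*  Module members mix a shared per-group latent factor into
their noise: `ε = σ·(√ρ·ℓ·f + √(1−ρ)·e)` with loading sign ℓ and
`ρ = sin(π·τ_target/2)`, the Gaussian relation between Pearson and
Kendall correlation, giving analytic control of the target tau; a
negative module sign alternates loadings.  The default plan plants three
4-node modules at tau 0.9: one active at every dose (hence conservative
across the low and high pairs), one only at DH1/DH2, one only at DH3/DH4
(hence emerging).  Validation rejects members of a multi-group module
whose planted mean trends strictly oppose their loading signs, since
pooled-condition tau would then be indeterminate between the two forces.

*What the generator does not emulate:* LC–MS acquisition artifacts,
missing values, heavy-tailed or heteroscedastic abundance noise,
metabolite-specific variances, and correlations other than the planted
latent factors.  Dose-responsive mean shifts do induce mild rank
concordance between unrelated metabolites in pooled networks — visible
as occasional extra modules in the full-course network — which is a real
property of pooled dose-course correlation, not a bug; planted-module
recovery is therefore assessed in the conditions where the modules are
planted.  Passing tests demonstrate correctness of the estimators and
recoverability of planted structure under these idealized conditions,
not performance on real serum metabolomics.

## Problem sizes and numerical choices

Recovery rates are estimated over 100 replicate studies (about 3 s of
compute); the Monte-Carlo check of the generator's tau calibration uses
200 replicates of a 5-metabolite study.  Tolerances: exact equality for
tau-a against enumeration; 1e-12 for entropy against direct evaluation;
threshold comparisons are strict everywhere, so a tau of exactly 0.7
is weak and a change of exactly eps is not snapped.  Ratios with zero
denominators are reported as undefined rather than clipped; zero-variance
metabolites abort correlation-network construction with the offending
name rather than propagating NaN.

## Known limitations

- The pooled-vs-consensus ambiguity for multi-group networks is real;
  both are implemented and results can differ materially on weakly
  coupled pairs.
- Greedy Jaccard matching is order-stable but not globally optimal; with
  many near-equal overlaps an assignment-problem matcher would differ.
- The scale-free R² on 41-node networks rests on ~10 occupied bins and
  is a coarse criterion; β selection can jump between adjacent powers
  under resampling.
- Entropy on weighted connectivities depends on the chosen β through the
  adjacency scale; comparisons across groups are meaningful because each
  group's network is built by the same rule, not because E is
  β-invariant.
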