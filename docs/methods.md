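# Methods

`faconn` implements an analysis chain relating white-matter structural
connectivity to motor outcome in a two-group (case/control) design:
probability-weighted tract FA, FA-weighted graph metrics,
covariate-adjusted correlations with FDR control, and a network-based
statistic (NBS) for group differences in the edge-weight–score slope.
This note records the models, the defaults and why they are set where
they are, the synthetic-data assumptions, and the numerical choices.

## Data model

A subject's connectome is an undirected 84-node network on the
Desikan–Killiany cortical + subcortical parcellation (34 cortical, 7
subcortical and 1 cerebellar node per hemisphere). Edge weight
`w_ij ∈ [0, 1]` is the mean fractional anisotropy over the streamlines
joining regions *i* and *j*; `w_ij = 0` means no streamline. Matrices
must be symmetric with zero diagonal; on load, halves are averaged only
when the maximum asymmetry is below 1e-8, otherwise the file is
rejected (larger asymmetries indicate a malformed input, not round-off).

Tractography, parcellation and registration are out of scope: inputs
are the already-assembled matrices (TSV with label row/column) or
streamline summaries `(node_i, node_j, mean_fa)`, and for the tract
stage FA volumes already resampled to atlas space.

## Tract FA

For tract *t* with probabilistic mask `p_t`,
`FA_t = Σ_v p_t(v)·FA(v) / Σ_v p_t(v)`, continuous weighting by default
(a probability threshold is exposed but off, since the atlas
probabilities carry information the threshold would discard). NaN
voxels are excluded from numerator and denominator with a log entry;
FA values outside [0, 1] are *included* but warned about — they usually
flag tensor-fit artefacts and silently clipping them would hide data
problems. An all-zero mask is an error. The canonical 18-tract set is
8 bilateral pairs (ATR, CG, CH, CST, IFOF, ILF, SLF, UF) plus the
forceps minor and major.

## Graph metrics

All seven metrics operate on the weighted, undirected matrix:

- **Average strength** — mean over nodes of the row sums.
- **Characteristic path length / global efficiency** — Dijkstra
  shortest paths on edge lengths `1/w` (absent edges are +∞, never a
  large finite number). `L` averages distances over *connected* ordered
  pairs, warning when pairs are excluded; `E_glob` averages `1/d` over
  all ordered pairs with `1/∞ = 0`. These are the standard conventions
  that keep disconnected graphs finite.
- **Clustering coefficient** — Onnela weighted clustering with weights
  normalised by the network maximum,
  `C_i = Σ_{j,h}(ŵ_ij ŵ_ih ŵ_jh)^{1/3} / [k_i(k_i−1)]`; nodes with
  degree < 2 contribute 0.
- **Local efficiency** — the weighted variant that measures paths
  between neighbours of *i* inside the neighbourhood subgraph on
  cube-rooted lengths, combining them with the connection weights as
  `(w_ij w_ih)^{1/3}`; this is the Brain Connectivity Toolbox
  formulation, matched deliberately so values are comparable with the
  bulk of the connectomics literature.
- **Modularity** — weighted Newman Q at resolution γ = 1, optimised by
  seeded Louvain with 100 restarts (the optimiser is stochastic and
  restarts are cheap at n = 84); the returned Q is always re-evaluated
  directly from the partition, so Q and partition cannot drift apart.
- **Small-world propensity** —
  `φ = 1 − √((ΔC² + ΔL²)/2)`,
  `ΔC = (C_latt − C_obs)/(C_latt − C_rand)`,
  `ΔL = (L_obs − L_rand)/(L_latt − L_rand)`, each clipped to [0, 1].
  Surrogates are matched in node count, edge count and weight
  distribution: the lattice places the sorted weights on a ring with
  the strongest weights at the shortest ring distances (ties shuffled),
  the random surrogate places the shuffled weights on uniformly chosen
  pairs. Ten surrogate pairs per graph by default — enough to hold the
  Monte-Carlo SD of φ well below the between-subject spread at n = 84 —
  averaged before the deltas are formed. If a delta's denominator is
  degenerate (|den| < 1e-12) the delta is set to 0 when the observed
  value already beats the favourable null and 1 otherwise, with a
  warning.

Per-subject RNG substreams for the stochastic metrics are keyed on the
master seed *and* a hash of the weight matrix, so a fixed seed is fully
reproducible and identical connectomes always produce identical rows.

## Associations

For each feature (tract FA or network metric), each group separately:
both the feature and the score are residualized by OLS on
[1, age, sex], and r is the Pearson correlation of the residuals with
`t = r√(df/(1−r²))`, `df = n − 2 − n_covariates`, two-tailed p.
Benjamini–Hochberg step-up adjustment is applied within each
(group × feature-family): the 18 tract measures form one family, the 7
network metrics another, mirroring how the analyses are reported.
Significance is adjusted p < 0.05. Sex is coded 0/1; age in years.
Subjects missing the score are dropped from that analysis with a log
entry, never silently.

Demographic comparisons use Fisher's exact test (two-sided, ties in the
table probability resolved with the conventional 1e-7 relative slack)
and the Wilcoxon rank-sum test, exact when the pooled sample is ≤ 20
without ties, otherwise the tie-corrected normal approximation.

## NBS for the group × score interaction

Per testable edge, the full GLM
`w ~ 1 + group + score + group·score + age + sex` is compared with the
reduced model lacking the interaction:
`F = (RSS_red − RSS_full) / (RSS_full/(n − p_full))`, df = (1, n − 6).
Testable edges are those present (`w > 0`) in strictly more than 50% of
subjects in each group — exactly 50% is excluded. Edges with
`F ≥ F_crit` are kept; connected components of the surviving edges are
the candidate subnetworks (singleton edges count, size = edge count).
The component p-value is the fraction of K permutations whose largest
component is at least as large (`p = b/K`; the add-one variant
`(b+1)/(K+1)` is available by flag, and with the plain estimator p = 0
is possible at finite K).

`F_crit` can be given explicitly — e.g. the conventional printed value
7.1488 for df (1, 52) — or as a tail probability α_edge (default 0.01)
converted at the design's *actual* residual df. With two groups of
22/32 and age + sex covariates the interaction model has 6 parameters,
so the residual df is 48, not 52; a published df of 52 implies a design
with two fewer fitted columns. The package always computes and reports
the df of the design it actually fits, and accepts an explicit F when a
specific printed threshold must be reproduced.

**Permutation scheme.** The default permutes the *group assignment* as
a whole row: the group main-effect and interaction columns are rebuilt
from the permuted labels while score, age and sex stay attached to
their subjects. When the two groups are exchangeable under the null,
this scheme is exact — not only per edge but, critically, for the
max-component-size statistic. The Freedman–Lane scheme (permuting
reduced-model residuals with the nuisance fit held to the subjects) is
also provided. It is the usual recommendation for single GLM contrasts
with nuisance covariates, but for the *component-level* statistic it
has a measurable small-sample defect: the same permutation is applied
to every edge, so the permuted residual covariance `P R_Z Pᵀ ≠ R_Z`
couples edges. At n = 54 this inflates the variance of the
per-permutation supra-threshold edge count (measured ≈19 vs the
binomial ≈12 at ~1220 edges, α_edge = 0.01), fattening the null
max-component tail and pushing component p-values toward conservatism
(empirical FWER ≈ 0.01 at nominal 0.05). Both schemes control FWER; the
group-label scheme is the default because it is calibrated.

Even with the exact scheme the test remains somewhat conservative: the
max-component size is a small integer (null maxima concentrate on 1–4
edges at these settings), so the attainable rejection rate sits below
the nominal level — measured at 0.032 over 1000 replicate null cohorts
against nominal 0.05. This is a property of NBS itself, not of the
implementation.

When the analysis is repeated across the total score and the three
subscales, no correction across scores is applied; each score's
subnetworks carry their own FWER-corrected p.

One master seed spawns a substream per permutation, so results do not
depend on execution order.

## Synthetic cohorts

The generator reproduces the statistical skeleton of the study the
analysis is designed for: 22 cases / 32 controls by default; ages
uniform on 6–8 years; sex Bernoulli(0.5); MABC-2-style scores with
population mean 10, SD 3, truncated to the standardized range [1, 19]
(subscales share a latent correlation of 0.5 with the total — a
plausible convention, as no empirical value is available). Connectomes
share one edge skeleton drawn at density 0.35 — typical of
streamline-filtered FA-weighted 84-node networks — with per-edge base
weights Normal(0.40, 0.05) (FA units; a convention, since empirical
edge-weight distributions are not published for this cohort) and
per-subject noise SD 0.02. An optional per-subject edge dropout
exercises the prevalence filter. A planted subnetwork (default: 24
nodes, 34 edges, connected by construction) adds
`slope_g · (score − 10)` to its edge weights, with separate slopes per
group; all other edges are independent of the score. Weights are
clipped to [0, 1] with a tiny positive floor so "present" (w > 0)
remains distinguishable from dropout zeros. The RNG is numpy PCG64;
one global seed expands into named substreams (skeleton, edge base,
demographics, scores, noise, dropout) so enabling a later stage never
perturbs earlier draws, and the algorithm/version are recorded in the
ground-truth metadata.

The tract fixture places disjoint cuboid probability masks on a voxel
grid and shifts each subject's in-mask FA by a mixture of the
standardized score and noise, targeting a chosen FA–score correlation;
ground truth stores mask-weighted means accumulated voxel-by-voxel, an
arithmetic route independent of the vectorised extractor.

What the generator does *not* emulate: spatially correlated noise,
distance- or module-structured connectivity, group differences in mean
edge weight or covariate distributions, integer-valued scores, missing
data patterns, or any tractography geometry. Passing recovery and
calibration tests therefore shows the estimators and the inference
machinery are correct under the stated model — not that real cohorts
satisfy that model.

## Validation protocols and problem sizes

`faconn.validation` holds the two simulation protocols used by both the
test suite and `scripts/acceptance.py`: FWER calibration (200 null
cohorts, K = 500 permutations; the fraction with any component at
p < 0.05 is compared with the exact binomial 95% band around 0.05,
[0.023, 0.089]) and planted-subnetwork recovery (20 replicate cohorts,
slope difference 0.010 FA per score point, noise SD 0.02, K = 1000;
median Jaccard overlap between significant components and the planted
edges, typically ≈0.8). Numerical primitives are validated against
independent oracles: Floyd–Warshall path enumeration on all random
graphs with ≤ 6 nodes, brute-force neighbourhood subgraph enumeration
for local efficiency, the textbook step-up definition for BH,
exhaustive same-margin table enumeration for Fisher's test (all tables
with N ≤ 30 plus a seeded sample up to N = 60), and the
precision-matrix closed form for partial correlation.

## Limitations

- The NBS component p-values inherit the discreteness conservatism
  described above; reported FWER is controlled but below nominal.
- Louvain is a heuristic; Q is a lower bound on the optimum even with
  restarts (the partition is returned so Q can always be re-checked).
- The small-world surrogate construction is one of several in use;
  φ values are comparable within this package, and across packages only
  when the surrogate construction matches.
- Group-label permutation assumes the groups are exchangeable under the
  null given the modelled covariates; strong unmodelled group-covariate
  dependence would favour the Freedman–Lane flag despite its
  conservatism.
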