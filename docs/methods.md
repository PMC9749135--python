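# Methods

## The F:T statistic

`ftstab` quantifies *ecological functional stability* (EFS) of a planktonic
microbial community as the ratio of functional to taxonomic between-sample
variation. Given a set of n samples with per-sample relative-abundance
vectors for functional pathways and for taxonomic groups, the package
computes the Euclidean distance matrix in each space,

    D[i, j] = sqrt( sum_k (x_ik − x_jk)^2 ),

then summarizes each sample by its mean off-diagonal distance,

    m_i = (1 / (n − 1)) * sum_{j != i} D[i, j],

yielding F (functional space), T_bac, T_arc (single-domain taxonomic
spaces) and T_mic (bacteria and archaea concatenated). Per-sample ratios
F:T_mic, F:T_bac, F:T_arc and T_bac:T_arc follow. The order of operations
is mean-distance first, ratio second — the ratio of summaries, not the
summary of pairwise ratios.

Interpretation: F:T < 1 means taxa turn over more than function, i.e.
multiple taxa carry the same functions (functional redundancy) and the
function is buffered against species turnover; F:T = 1 means synchronous
variation; F:T > 1 means function is more volatile than structure.
Stability classes use a tolerance band of ±0.05 around 1 (`stable`,
`synchronous`, `unstable`); the band is a presentation device, not part of
the statistic, since 1 is a conceptual boundary with no natural width.

### Normalization and scale coupling

The ratio is only meaningful when both spaces live on comparable scales,
so all distance inputs are per-sample relative tables. For T_mic two
conventions are supported:

* `block` (default): each domain block is row-normalized to 1 separately,
  so the concatenated row sums to 2 and both domains contribute equally
  regardless of their feature counts;
* `joint`: the concatenated row is renormalized to sum to 1.

The two differ by a constant factor sqrt(2)-ish in T_mic and therefore by
a constant factor in F:T_mic; comparisons *within* one convention are
unaffected. Note one exact identity only holds under `joint`: if the gene
table literally equals the concatenated taxa table (the synthetic
redundancy-1, zero-noise construction), F:T_mic = 1 exactly under `joint`,
while `block` yields a constant 0.5 because the functional table is
normalized to row sum 1 but the block-normalized microbial table to row
sum 2. This scale asymmetry is intrinsic to block normalization and is
why F:T is documented as invariant to *common* rescaling of all tables but
not to rescaling F alone.

F is computed on pathway-level vectors by default (six groups: C-fixation,
C-degradation, CH4 metabolism, N-, P-, S-cycling), with gene-level vectors
available behind a flag; diversity, by contrast, defaults to the
finest-grained table supplied.

## Supporting statistics

* **Diversity** — Shannon–Wiener H′ = −Σ p ln p in nats; 0 ≤ H′ ≤ ln(richness).
* **Group contrasts** — two-sided t-tests, Welch by default (group sizes
  and variances are unequal throughout a reservoir/river design); Student
  optional. Degenerate zero-variance cases are guarded: identical constant
  groups report t = 0, p = 1; separated constant groups an epsilon-scaled
  statistic.
* **Inflow:reservoir ratios** — per reservoir, mean(inflow metric) /
  mean(reservoir metric) for F, T_mic and F:T_mic, then a two-sided
  one-sample t-test against 1 across reservoirs; when the ratios are
  numerically constant the t-test degenerates and a sign test on
  (ratio − 1) is reported instead.
* **Mantel test** — Pearson (default) or Spearman correlation of the
  strictly-lower distance triangles, with p = (1 + #{r_perm ≥ r_obs}) /
  (n_perm + 1) under simultaneous row/column permutation of the second
  matrix; 999 permutations and the one-tailed "greater" convention by
  default, seeded. Spearman ranks the triangle once up front — ranking
  commutes with simultaneous row/column permutation. Environmental
  variables are z-standardized before their Euclidean distances are taken
  (mixed units), with sample dropping on missing values (distance matrices
  must be complete; plain correlations use pairwise-complete data).
* **Multiple testing** — Benjamini–Hochberg step-up adjustment over the
  full family of tested pairs.
* **Co-occurrence networks** — an edge between two variables requires
  |r| > 0.6 and BH-adjusted p < 0.05 over all tested pairs. |r| rather
  than r is thresholded so negative associations are retained with their
  sign (`positive_only` restores the literal positive-only reading).
  Topology: density 2E/(N(N−1)), mean degree, mean clustering
  coefficient, greedy-modularity communities with node-id-sorted
  insertion order for determinism, hubs by degree.
* **OLS** — closed-form simple regression; p from t = slope/se on n − 2
  df; adjusted r² via 1 − (1 − r²)(n − 1)/(n − 2). The seasonal-EFS
  regression uses per-reservoir Δ = mean(F:T_mic | August) −
  mean(F:T_mic | December) — a two-stage mean, so each reservoir is one
  point — against log10 hydraulic load. The sign convention
  (August − December) is a choice; reversing it flips the slope sign only.
  Hydraulic load is consumed as metadata and never computed; its units
  are the caller's responsibility.

## Carbonate speciation

Dissolved CO2, HCO3⁻, CO3²⁻ and DIC are derived from titration alkalinity,
pH (activity scale) and water temperature. Constants: Plummer & Busenberg
(1982) temperature fits for K1 and K2 of carbonic acid, a Harned–Owen-form
fit for Kw, and Davies-equation activity coefficients from the ionic
strength I = ½ Σ c z² of the supplied major ions (valid to I ≈ 0.5 M,
orders of magnitude above river water). The alkalinity model is carbonate
plus water alkalinity only — appropriate for HCl-titrated freshwater where
borate, phosphate and silicate contributions are negligible. Carbonate
alkalinity = ALK − [OH⁻] + [H⁺]; HCO3 and CO3 follow from the K2′/a_H
ratio, CO2 from a_H·[HCO3]/K1′, and DIC is their sum (an exact invariant
of every call). A negative carbonate alkalinity (high pH with tiny ALK)
is reported as an inconsistency error. Computed species are labelled
`*_computed` in output to distinguish them from titrated or measured DIC
columns. DIN is the plain sum of NO3-N, NO2-N and NH4-N; the Ca/Sr molar
ratio converts mg/L inputs through atomic masses (Ca 40.078, Sr 87.62).

## The synthetic-data generator

The generator emulates a cascade-reservoir survey: four reservoirs (CST,
LT, YT, DH) sampled in August and December at one inflow station, a depth
profile (CST 0–55 m over 6 depths, LT 0–140 m over 8, YT 0–50 m over 6,
DH 0–25 m over 5), and one released-water station — 58 samples per run.
Defaults: 57 bacterial phyla, 9 archaeal phyla, 71 functional genes
(12/12/12 across the three C pathways, 22 N, 8 P, 5 S), library sizes
drawn uniformly within ±15% of 20,000 reads.

**Taxa.** Each domain has one base composition drawn from a symmetric
Dirichlet whose concentration sets evenness (bacteria 0.8; archaea 0.25,
reflecting much less even archaeal communities), producing a few dominant
phyla and a sub-1% tail. Reservoir/season groups perturb the base
(Dirichlet with concentration 80·base), and each sample perturbs its group
composition with a Dirichlet whose concentration scales as 15/turnover
(turnover 0.3 by default; turnover → 0 collapses to the group
composition). Inflow samples multiply turnover by 2.5, making riverine
water compositionally more volatile than the impounded water body. Counts
are multinomial draws.

**Function.** A gene-content incidence matrix couples genes to taxa: each
gene column has exactly `redundancy` nonzero entries with equal weights
1/redundancy (redundancy 5 by default). Gene abundance per sample is the
block-relative taxa vector times the incidence matrix, times multiplicative
lognormal(0, σ) noise (σ = 0.2; lognormal because qPCR copy numbers are
positive and right-skewed), times a 3×10⁵ copies/L scale. A tiny detection
floor keeps noisy tables strictly positive. The incidence-matrix coupling
is a deliberately simple stand-in — no quantitative taxa→gene coupling is
observable at phylum level — but it realizes the defining mechanism of
functional redundancy and yields two analytic limits: redundancy 1 with an
identity-like matrix reproduces the taxa table (F:T_mic = 1 under joint
normalization), and full redundancy makes every gene constant across
samples (F → 0).

**Environment.** August profiles of the yearly regulated reservoirs (CST,
LT — long retention times of ~380/310 d, hydraulic loads 4.2/7.5) are
thermally and chemically stratified: logistic WT, DO and pH profiles with
a thermocline near 12 m; the daily regulated YT and DH (HRT 18/8 d, loads
110/180) are unstratified; December is depth-homogeneous everywhere. WT is
clipped to 13.3–29.5 °C and other variables to plausible reservoir ranges;
CST gets elevated Ca/Sr, DIN and Chl a. Inflows get +2 mg/L DO.

All randomness flows from one seed through numpy's PCG64; per-stage
streams are `default_rng([seed, stage])`, and the pipeline derives stage
seeds as SHA-256(root_seed:stage_name) mod 2³¹, so any stage can be
reproduced in isolation.

**What passing tests do and do not show.** The generator has no
phylogenetic structure, no OTU-level richness (tables are phylum-level, so
absolute H′ values are far below OTU-level field values), no sequencing
error model, and no mechanistic environment→community coupling. Tests on
it demonstrate that the statistics recover planted structure (redundancy,
inflow turnover, stratification), not that field data would show the same
effect sizes.

## Problem sizes and numerical choices

Tests and the acceptance script run reduced designs where full size adds
nothing: a 2-reservoir × 3-depth preset (20 samples, 38 taxa, 24 genes)
for replicated simulation studies, 199 permutations for Mantel calibration
loops, 5 seeds per redundancy level for monotonicity checks. Tolerances:
distance and BH oracles at 1e-12, OLS oracle at 1e-10, speciation vs the
independent root-finding oracle at 2%. Ties in greedy modularity are fixed
by sorted node insertion. Degenerate inputs (zero-sum rows, zero
denominators, constant distance triangles, zero-variance variables) are
either flagged per sample/variable or raised as contract errors, as
documented per function.

## Known limitations

* Euclidean distance on relative abundances ignores compositional
  constraints; Aitchison-type alternatives are out of scope.
* The F:T level depends on the chosen feature resolution (pathway vs gene,
  dominant-phyla threshold); only comparisons at matched settings are
  meaningful.
* The network module does not correct for compositionality (SparCC-type
  approaches are documented alternatives, not implemented).
* Structural equation modeling is not implemented.
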