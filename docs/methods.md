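# Methods

## The generative model

Each simulated gene g carries a baseline log₂ level (N(8, 1.5²) across
genes), a wild-minus-domesticated offset *effect* (log₂ units) and an
inheritance mode. True group means per stage are

* wild W = baseline + effect/2, domesticated D = baseline − effect/2,
* hybrid H by mode: additive H = (W+D)/2; maternal dominant H = D (the
  hybrid's dam is domesticated); paternal dominant H = W; overdominant
  H pushed `overdominance_shift` log₂ units beyond one parent (default
  shift = effect, giving δ/α = ±3; any shift > |effect|/4 keeps
  |δ/α| > 1.5, smaller shifts are rejected as inconsistent).

A gene with effect 0 is a planted null. `stage_specific` confines the
effect to the feeding stage. Observed intensities per probe and array:

    sample    = 2^(μ_group + b_g,array + t_s + dye(A))
    reference = 2^(μ_pool  + t_r)

with b ~ N(0, biological_sd²) drawn per gene × array and shared by all
probes of the gene (a biological replicate deviate), t_s, t_r ~
N(0, technical_sd²) per probe × array × channel, and μ_pool the
equal-weight mean of the six group means — an equimolar reference pool.
The per-replicate SD of M = log₂(sample/reference) is therefore
√(biological_sd² + 2·technical_sd²); a test checks this identity
empirically. `dye(A)` is an optional smooth function of the noiseless mean
log-intensity, the target of the lowess stage. Detection-flag failures are
i.i.d. Bernoulli per probe × array (no structure is assumed).

Defaults: biological_sd 0.25, technical_sd 0.05, flag_failure_rate 0.05.
The magnitudes of biological vs technical variance are this package's own
choices (typical of replicate pooled-sample two-colour data, where pooling
suppresses individual variation); they are configuration values, not
measured quantities. The default planted mode mix (45 / 42.2 / 6.1 / 6.7%
additive / maternal / paternal / overdominant) mirrors the observed
feeding-fry mix; maternal-side overdominance probability is configurable
(a 3:1 maternal skew is available; the default is symmetric).

What the generator does **not** emulate: dye-swap designs, spatial array
artefacts, probe-sequence affinity effects, correlated flag failures, and
pooling of individuals within a replicate (arrays are the replicate unit).
Passing tests therefore demonstrate correctness of the statistics under an
idealised noise model, not performance on real arrays.

## QC and normalisation

Intensities ≤ 1 are floored to 1 before taking logs. Lowess normalisation
is per array: M is regressed on A (span 0.2, 3 robustness iterations) and
the fitted trend subtracted. The span default was set by requiring that a
refit of the lowess curve on normalised data with an injected smooth bias
0.5·sin(A/4) stays below 0.01 log₂ units: a 30% span leaves ≈ 0.016 of
boundary bias at the extreme-A edge even without noise, while 0.2 leaves
≈ 0.001. The flatness check itself runs on the bias-only configuration
(noise SDs 0): with replicate noise present, the refit's own sampling error
at the sparse edges of the A distribution exceeds 0.01 regardless of the
normaliser, so a noisy refit measures the check, not the method.

Probe retention: flagged on ≥ ceil(0.75·n_g) arrays in ≥ 2 groups, with
n_g the group's array count after exclusions (ceiling because "at least
75%" reads as ≥). The outlier screen projects arrays onto the first two
principal components and flags arrays farther from the coordinate-wise
median than `threshold_sd` robust SDs (1.4826·MAD of the distances). It
only flags — exclusion is an analyst decision — and it is sensitive when
arrays form one cloud (realistic, since differential structure is a small
fraction of total probe variance); strong planted group structure can mask
a corrupted array, which is why the screen is evaluated on mostly-null
panels.

## Differential expression

Welch (unequal-variance) statistics throughout: two-sample t for the three
pairwise cross comparisons within a stage, and the Welch one-way ANOVA F*
approximation across the three crosses, vectorised over probes. Degenerate
rows (all groups constant) get p = 1 when means agree and p = 0 otherwise.
Fold changes derive from log₂ group means and are reported with the signed
convention (r if r ≥ 1 else −1/r); a linear-scale switch exists because
the choice of averaging scale is a genuine open point. Strict lists
(p ≤ 0.01, |FC| ≥ 1.3) are deliberately uncorrected — they feed Venn
comparisons, not inference — while the ANOVA feeding the inheritance
analysis is BH-corrected at q ≤ 0.10 across all retained probes *before*
collapsing to unique annotated genes (most significant probe per gene,
ties by probe id). BH q-values come from the standard step-up
(statsmodels `fdr_bh`).

## Gene-set perturbation test

A GAGE-style re-implementation, not a clone. Choices fixed here:

* unpaired one-on-one contrasts — one column per treat/control array pair
  (36 for 6 vs 6), per-gene log₂ differences;
* per column, a two-sample Welch t of set genes vs all other measured
  genes; one-tailed for up/down, on |contrast| for two-way perturbation;
* per-column p-values converted to z and summed; the sum is scaled by
  √(K·(1 + ((n_t−1)+(n_c−1))/2)) rather than √K, because pair columns
  sharing an array have correlation ½ under array-level noise — the
  independence Stouffer denominator would be anticonservative by a factor
  ≈ 2.4 at 6 × 6 and null set p-values would be far from uniform (with the
  correction they pass a KS uniformity test);
* BH across sets within each direction, significant at q ≤ 0.1; sets with
  fewer than 10 measured genes are skipped (the smallest reported set size
  in this kind of table is 10); a functional-group exclusion (default
  "Human Diseases") removes hard-to-interpret pathways before testing.

Redundancy grouping merges significant sets when the smaller shares ≥ 50%
of its measured genes with the other, transitively; the representative is
the smallest-p member. Essential genes are members of ≥ 1 significant set
whose mean contrast lies > 1 SD from the grand mean of all genes' mean
contrasts. Clustering uses 1 − Pearson r and average linkage; zero-variance
rows are reported and excluded; scipy's deterministic tie-breaking (lower
original index first) fixes the leaf order.

## Inheritance classification

α = (W − D)/2 and δ = (W + D)/2 − H are computed from mean normalised log₂
values (a linear-scale switch exists; log₂ keeps consistency with the
normalised matrix). Intervals are closed below and open above
([−0.5, 0.5) additive, [0.5, 1.5) maternal, [−1.5, −0.5) paternal,
otherwise overdominant); the published strict inequalities leave the
boundaries undefined, and they occur with probability zero on continuous
data. α = 0 is classified additive when δ = 0 and overdominant otherwise.
Overdominant genes are additionally split by the overshot parent
(δ/α ≥ 1.5 maternal side, ≤ −1.5 paternal side). With only one hybrid
cross direction (domesticated dam), maternal effects and genetic dominance
toward the dam are confounded by construction; the simulator's "maternal
dominant" mode deliberately models the mixture, and a reciprocal-cross
simulation is out of scope. Scatter-table error bars are the SDs of α and
δ/α recomputed per replicate index (r-th array of each group, groups
truncated to the smallest size); how such bars should be propagated to a
ratio is genuinely underdetermined, and per-axis replicate SD is the
convention adopted. Rows with |δ/α| above a plot limit (default 5) are
flagged for exclusion from plots but kept in tables.

## Evaluation scenarios and problem sizes

`salmoarray.benchmarks` (driven by `scripts/acceptance.py` and the
acceptance tests) measures, at sizes chosen to keep each scenario within
about a minute on one CPU:

* mode recovery: 2,000 DE genes, effect 1.0 log₂, biological SD 0.25,
  n = 6, through flooring → lowess → probe filter → classification. Under
  these conditions the group-mean SE is ≈ 0.10 log₂, the delta-method SD
  of the estimated δ/α is ≈ 0.25–0.33, and the expected misclassification
  of complete-dominance genes (true δ/α = ±1, 0.5 from both boundaries)
  is ≈ 8–13%; measured recovery is ≈ 90%, with the leakage visibly
  inflating the overdominant fraction. This is a property of the
  statistic's noise geometry at this effect size, not of the
  implementation; recovery rises above 99% once the ratio-noise SD falls
  below ≈ 0.25 (e.g. biological SD 0.1 at the same effect).
* type-I error: 10,000 planted-null probes, Welch-t fraction at p ≤ 0.01
  compared against 3 binomial SDs; BH-ANOVA mean false-discovery
  proportion over 20 independent null replicates (on full-null data the
  per-replicate FDP is 1 whenever anything is called, so the mean over
  replicates is the estimate of E[FDP] ≤ 0.10).
* lowess flatness (bias-only, 3,000 probes) and exact brute-force oracles
  for the probe filter (1,000 probes) and Venn partition.
* pathway detection: 20 replicates of one coordinated set among 199 null
  sets (2,000 genes, set size 25, effect 1.0, biological SD 0.1 — the
  low-noise coordinated-perturbation regime); success = the planted set is
  the unique up-direction call at q ≤ 0.1.

## Known limitations

* The reference-channel pool is exact in expectation; real pools drift.
* The GAGE-style correlation correction assumes homoscedastic array-level
  noise; heavy-tailed or array-specific variance would need a robust
  variant.
* The outlier screen uses two principal components only.
* No empirical-Bayes variance moderation: at n = 6 the Welch tests are
  noticeably noisier than limma-style statistics would be; this mirrors
  the analysis being reproduced rather than best current practice.
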