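# Methods

## Pipeline overview

The pipeline maps each subject's region × time signal matrix to 21 dynamic
connectivity features and then runs three inference stages over the cohort.
All stages are deterministic given the master seed; per-subject and
per-repetition seeds are spawned with `numpy.random.SeedSequence`.

1. **Windowing.** The first `drop_initial` volumes (default 2, steady-state
   magnetization) are discarded; the rest is cut into consecutive,
   non-overlapping windows of `round(window_len_s / tr_s)` timepoints,
   dropping any trailing remainder. Defaults (30 s at TR = 3 s on a
   200-volume scan) give 19 windows over 190 volumes; 60 s gives 9 windows
   over 180. A `window_timepoints` override exists because some window
   lengths (e.g. 39 timepoints ≈ 117 s) are not expressible in whole
   seconds at a given TR.
2. **Layers.** Window connectivity is the Pearson correlation matrix with
   negative values and the diagonal set to zero. A region with zero
   variance inside a window gets a zeroed row/column and a warning rather
   than an error, so scrubbing-like artifacts degrade gracefully. No
   Fisher transform is applied.
3. **Multilayer coupling.** Layers are ordered in time and coupled
   node-to-self between adjacent layers only (ordinal coupling) with
   weight ω ≥ 0 (default 0.5).

## Multilayer modularity and its optimization

Quality function: Q = (1/2μ) Σ[(A_ijs − γP_ijs)δ_sr + δ_ij ω_jsr] δ(g_is, g_jr),
with P the per-layer Newman–Girvan expectation k_i k_j / 2m_s (zero for an
empty layer) and 2μ the total intralayer strength plus every interlayer
coupling counted in both directions. The intralayer sum runs over ordered
node pairs including i = j (A_ii = 0 but P_ii ≠ 0), which is what makes the
all-in-one partition of a single layer score exactly 0. Hand-checkable
fixtures: two disconnected unit 3-cliques give Q = 0.5 in a single layer
and Q = 0.6 when duplicated into two layers at ω = 0.5 (2μ = 24 + 6).

Optimization is a stochastic Louvain scheme on the sparse supra-modularity
matrix (slot = node × layer): randomized single-slot moves to local
optimality (ties and sub-tolerance gains keep the current community; gain
tolerance 1e−12), aggregation of communities, recursion on the aggregated
matrix, and outer iteration until neither slot-level moves nor aggregated
merges improve Q. The returned assignment is therefore locally optimal at
the level of single node-layer moves; its `q_value` is re-evaluated with
the quality function and a monotone `q_trace` records the outer passes.
Because the landscape is rugged, the pipeline runs `n_repetitions`
independent optimizations (default 100) from spawned seeds and all
downstream measures are ensemble statistics. Labels are positive integers,
comparable across layers within one optimization; empty communities are
compacted away.

## Dynamic measures

- Node flexibility: adjacent-layer label changes / (L − 1), averaged over
  repetitions, then over each system's nodes.
- Module allegiance P_ij: fraction of (layer, repetition) samples with i
  and j co-assigned; P_ii = 1. Computed via one-hot Gram matrices;
  an explicit quadruple-loop implementation backs it in the tests.
- Recruitment of system k: mean of P over ordered within-system pairs
  *including the diagonal*, so a perfectly stable system scores exactly 1.
  The exclusive-diagonal variant is available via `include_diagonal=False`.
- Integration of system k: mean of P over pairs with exactly one end in k.
- Feature vector: measure-major concatenation (flexibility, recruitment,
  integration) × systems in canonical order (VIS, SM, DAN, SVAN, LIMB,
  CON, DMN); 7 systems ⇒ 21 features.

## Synthetic cohort generator

The generator emulates a four-group amyloid-stratified aging cohort
(CN Aβ−, CN Aβ+, MCI Aβ+, AD Aβ+; default sizes 86/37/34/22) of 200-region,
200-volume, TR = 3 s scans. Within an epoch, node i in block b follows
x_i = a·g + c·f_b + e_i with iid N(0,1) factors and noise, and loadings
a² = r_b/(1 − r_w), c² = (r_w − r_b)/(1 − r_w), so same-block pairs have
population correlation r_w (default 0.6) and cross-block pairs r_b
(default 0.1). The seven block sizes (30, 32, 26, 24, 12, 30, 46) mirror a
200-parcel seven-system functional atlas, including its small limbic
system.

Two structural choices matter:

- **Window-exact factor realizations.** The global and block factor time
  courses are made exactly orthogonal, centered, and equal-norm within each
  analysis-window segment (QR on the centered factor block). Raw iid factor
  draws carry sample correlations of order 1/√(window length) that are
  shared by *every* node pair across a block pair; at 10 samples per window
  these swamp the planted structure and make block pairs merge spuriously.
  Orthogonalization pins the realized factor correlations at their
  population value, while node-level noise — whose pair-level fluctuations
  average out across a block — is left untouched. Margins that enter no
  window keep raw draws; `factor_alignment=False` disables the scheme.
- **Excursion switching.** Epochs (default 60 s, aligned to window
  boundaries) re-draw block memberships: each epoch, a fraction
  `switch_fraction` (default 0.2) of nodes is displaced from its *base*
  RSN block to a random other block, reverting afterwards unless
  re-selected. This keeps the RSN template as the stable backbone, the
  pattern real allegiance matrices show; cumulative relabeling would
  randomize the template over the scan.

Group effects are additive shifts on (r_w, r_b, switch_fraction), default
graded along the continuum (more between-system coupling, less switching).
Demographics: age ~ normal with group-specific means (75–82 y), sex a fair
coin, APOE ε4 group-specific Bernoulli (rates 0.23/0.46/0.56/0.55),
education ~ normal. Outcomes (MMSE, ADAS Q4, tau and amyloid SUVR) are
linear in the planted per-subject levels (realized switch rate, effective
between/within correlation) plus Gaussian noise, with slopes chosen so the
four groups' expected outcomes span the qualitative ranges of such a
cohort.

What the generator does **not** model: haemodynamics, scanner noise,
temporal autocorrelation, spatial geometry, or head motion. Passing tests
therefore demonstrate the pipeline's correctness and sensitivity under a
clean block-switching model, not performance on real fMRI.

## Statistics

- MAD screening: |v − median| / (1.4826·MAD) > 3, applied to each subject's
  three system-averaged measures, pooled over the sample; a subject flagged
  on any measure is removed. When MAD = 0, any deviation from the median is
  infinitely many MADs away and is flagged (all-equal samples flag
  nothing).
- Group tests: features residualized on intercept + age + sex across the
  retained sample, then two-sided permutation tests (statistic: mean
  difference; add-one p-value; 10,000 permutations) for each Aβ+ group vs
  CN Aβ−, BH-FDR at q = 0.05 across the full 63-test family. The default
  scheme is residualize-then-permute; `scheme="freedman_lane"` keeps the
  covariate adjustment inside the permutation distribution (permuted
  reduced-model residuals re-projected onto the covariates' residual
  space). Both are calibrated in the null simulations and agree closely at
  this covariate set.
- Classification: bidirectional stepwise search from the intercept-only
  model minimizing AIC (ties toward the smaller model, then lexicographic;
  candidate fits that fail or yield non-finite AIC are skipped; possible
  separation triggers a warning with the iteration-capped fit kept).
  Selected columns are sorted into a canonical order shared by fitting and
  prediction. ROC/AUC uses the tie-corrected Mann–Whitney rank formula;
  the bootstrap (default 1000 replicates) is stratified by class so every
  replicate contains both classes; the cutpoint maximizes
  sensitivity + specificity (Youden's J). AUCs are in-sample, matching the
  procedure the pipeline mirrors; they are optimistic and the desk-scale
  example shows saturated values for strongly separated groups.
- PLS: one PLS1 model per response (NIPALS backend), predictors
  log(x + ε)-transformed (ε = half the column's smallest positive value;
  binary columns z-only) then z-scored. Latent-variable count minimizes
  K-fold (default 10) cross-validated MSE, capped at 10, ties toward fewer.
  VIP_j = sqrt(p Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a) with
  SS_a = q_a²‖t_a‖²; Σ VIP² = p by construction and VIP > 1 flags
  significance. Cognitive status enters as a binary covariate (0 for the
  cognitively normal Aβ+ group, 1 for MCI/AD).

## Problem sizes of the shipped experiments

The validation benchmarks and the acceptance script choose sizes the
package treats as its standard desk-scale conditions: planted-recovery NMI
runs one full default subject (200 regions, 19 or 9 layers) with a
10-repetition ensemble; the planted-effect power experiment runs 100
simulations of 8 + 8 subjects on a 40-region, 4-block, 12-window design
with 5-repetition ensembles; the analysis drivers default to a 58-subject
cohort with 10 repetitions (flags expose the full 179/100 configuration).

## Known limitations

- At the default 30-s windows each correlation rests on 10 samples. Under
  the default planted design, partitions that deviate from the planted
  blocks by ~5–10% of nodes per layer achieve *higher* multilayer Q than
  the planted partition (measured: planted Q ≈ 0.249 vs best detected
  ≈ 0.255), so per-layer recovery saturates around NMI 0.75–0.9 regardless
  of optimizer quality; the 60-s configuration recovers at NMI ≥ 0.92. The
  planted-recovery benchmark reports both.
- Stepwise AIC admits ~16% of pure-noise candidates per variable and
  in-sample ROC (the default, matching the mirrored procedure) is
  optimistic; `cross_validate=True` scores the *selected* model out of
  fold, which removes refit optimism but not selection optimism.
- Group contrasts in the *detected* measures combine both planted shifts:
  at the default noise level, the patient groups' increased between-system
  coupling weakens the modular signal inside each 10-sample window and
  thereby raises detected flexibility through noise-induced label
  switching, overriding the planted switching decrease in most systems
  (the DMN group means still trend downward). The pure-switching power
  benchmark manipulates only the switch fraction and is free of this
  confound.
- The generator's epochs are aligned to window boundaries by default;
  `epoch_jitter_s` adds a per-subject random shift of the epoch grid, but
  misaligned dynamics (window-straddling transitions) are not part of the
  validated regime.
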