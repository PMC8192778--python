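# Methods

This note documents the models, estimators, parameter choices and known
limitations of `rrbdyn`.  It is the package's own account of its science;
every number quoted here is computed by the test suite or
`scripts/acceptance.py`.

## Windowed connectivity

Dynamic functional connectivity is estimated as a sequence of weighted
Pearson correlation matrices.  The taper of length `W` samples assigns the
raw weight `exp(-lambda * (W-1-j))` to offset `j` (`j = 0` oldest), then
normalizes to sum one, so the newest sample inside the window dominates —
an exponentially weighted moving estimator.  `lambda` defaults to `3/W`,
which places about 95% of the weight inside the window while keeping an
effective sample size of roughly `0.6 W`.  A rectangular taper (uniform
`1/W`) reduces the estimator to the ordinary sample correlation and is the
standard robustness alternative, as is a longer window (the config
expresses window length in seconds; it is converted per subject by
rounding `window_seconds / TR` to the nearest integer, floored at 2).

The weighted covariance uses population normalization (weights sum to 1,
no small-sample correction): correlations are scale-free, so the
normalization constant cancels.  Windows advance by `step` samples
(default 1, maximally overlapping).  A window in which some channel has
zero weighted variance raises an error naming the channel rather than
imputing — constant channels indicate invalid input.  The batched
implementation is algebraically identical to the per-window formula and is
tested against a brute-force direct-summation oracle at 1e-10.

## Brain states

Windowed matrices from all subjects of one group are vectorized (strict
lower triangle in row-major i>j order) and optionally Fisher
z-transformed (`atanh`, |r| clipped at 1-1e-7; on by default since z
approximately stabilizes the variance of correlations).  k-means
(Euclidean, `n_restarts` seeded restarts, best within-cluster sum of
squares kept) is fitted for each candidate k; the chosen k maximizes the
mean silhouette coefficient, ties broken toward smaller k.  Groups are
fitted separately, so both the repertoires and k may differ between
groups.  Silhouette is undefined at k=1, so the candidate range starts at
2; a best silhouette below 0.25 sets a one-state flag in the report rather
than forcing a k.  Candidate k is capped at one less than the number of
distinct rows.  Empty clusters are repaired by the k-means
implementation's internal relocation of the emptied centroid.

Defaults: `k_range = (2, 8)`, `n_restarts = 50`, full-sample silhouette
(a seeded subsample option exists for large runs and is used by the
acceptance script with 4000 windows).

## Network interaction indices

Per window, `CNII = r(SN, CEN) - r(SN, DMN)` with the two-node CEN
resolved by averaging `r(SN, lCEN)` and `r(SN, rCEN)` (a single-node CEN
override is available through `CircuitSpec`), and `MNII = r(cMN, sMN)`.
CNII lies in [-2, 2], MNII in [-1, 1].

Subject-level summaries support two aggregations.  `by_state` (CNII
default) first averages the subject's windows within each brain state and
then takes the unweighted mean and sample SD across the states the subject
visits — state-level averaging, not occupancy-weighted; an
occupancy-weighted variant is the `by_window` mode (MNII default), which
summarizes across all windows directly.  The asymmetric defaults mirror
the two circuits' standard treatments; both modes are available for either
circuit so sensitivity to the choice can be tested.  A subject who visits
a single state has no state-level SD; the value is reported missing and
such subjects are dropped (with a logged count) from variability
comparisons rather than imputed as zero.

## Group inference

The primary test is the two-sided pooled-variance (Student) t-test with
`df = n1 + n2 - 2`, reported with signed Cohen's d (pooled-SD units,
group order ASD, TD) and its magnitude; Welch's form is a config option.
Confound adjustment fits one linear model `feature ~ group + age + sex +
motion + iq` (group ASD=1/TD=0, sex F=1, continuous covariates
mean-centered) and reports the group coefficient's t and p — equivalent to
residualize-then-test under this coding, but in a single model.
Rank-deficient designs and zero-variance covariates are errors that name
the offending columns.

## Brain–behavior analysis

"Non-parametric linear regression" is implemented as OLS with
permutation-based inference: the overall F of the predictor block is
recomputed under `n_permutations` (default 5000) seeded permutations of
the outcome, `p = (1 + #{F_perm >= F_obs}) / (1 + B)`.  Since F is a
monotone function of R^2 at fixed dimensions, permuted statistics are
evaluated by projecting each permuted outcome onto an orthonormal basis of
the centered predictors — identical to refitting, verified against an
explicit-refit oracle in the tests.

Cross-validation assigns folds by a seeded random permutation (sizes
differ by at most one), fits OLS per training fold and reports the Pearson
correlation between concatenated out-of-fold predictions and the actual
outcome.  Its permutation p permutes the outcome *before* the (fixed,
seeded) fold assignment and reruns the entire cross-validation, preserving
the null dependence structure of out-of-fold r (which is slightly
negatively biased under the null — the permutation reference accounts for
this).  Out-of-fold OLS predictions are linear in the outcome, so the
permutation loop evaluates a precomputed n-by-n prediction operator; the
tests verify it equals explicit per-fold refits to 1e-10.

Predictor blocks follow the circuit structure: cognitive = {mean CNII, SD
CNII} (numerator df 2), motor = {mean MNII} (df 1).  The specificity
report evaluates all six circuit-by-outcome cells and flags the
dissociation pattern (cognitive -> CI/IS, motor -> RM).

## RRB factor scores

Raw ADI-R item scores take values {0,1,2,3,6,7,8}; the special codes
6/7/8 are recoded to 0.  PCA is computed on the item *correlation* matrix
(items share a scale, but correlation-matrix PCA is the convention for
varimax'd item analysis).  The number of components is the count of
eigenvalues above 1 — the automated arm of the usual selection rule; the
full eigenvalue profile is written out as scree data for human judgment,
never decided algorithmically.  Retained loadings (eigenvectors scaled by
sqrt(eigenvalue)) are varimax-rotated with Kaiser row normalization
(tolerance 1e-8, at most 1000 iterations); component signs are fixed so
each component's largest-magnitude loading is positive.  Subject scores
use the regression method, `Z L (L'L)^{-1}` on standardized items.
Components are labeled CI/IS/RM when their squared-loading mass and
top-loading item match the canonical grouping CI={68,76}, IS={67,70},
RM={69,77,78}; otherwise they keep numeric labels.  External
(previously published) factor weights are user-supplied input and applied
as weighted sums of standardized items.

The 9-item set includes two items beyond the seven canonical ones; their
identity is configurable, with items 71 and 75 as the defaults (loading on
CI and IS respectively in the generator).

## Synthetic cohort generator

Each subject is a zero-mean Gaussian time series whose correlation matrix
switches among latent states following a Markov chain with uniform
off-diagonal transitions and `p_stay = 1 - 1/mean_dwell`; white
measurement noise of SD `noise_sd` is added (attenuating all correlations
by `1/(1+noise_sd^2)`), an optional AR(1) coefficient colors the
innovations (default 0 — the pipeline operates on correlations only), and
channels are standardized.  Default conditions emulate the study design:
48 subjects per group, 180 samples at TR = 2 s (6-minute scans), four
ASD-like vs two TD-like states, mean dwell 40 samples, and demographics
drawn from simple distributions matching the cohort description (age
~N(10.9, 1.8) years, ~15% female, IQ ~N(115, 16)/N(118, 11), mean
framewise displacement log-normal around 0.08 mm).

State repertoires are random two-factor correlation matrices,
rejection-sampled so that pairwise Frobenius distances are at least
`state_separation` (default 0.6) and — by default — no larger than 1.35x
the smallest (`state_balance_ratio`).  The balance constraint exists
because silhouette-based selection of k is ill-posed on repertoires with
hierarchical super-pair structure: merging close states is then genuinely
the better-scoring partition, and no estimator should be expected to
recover the planted k.

Planted effects are placed in exactly the statistics the pipeline
measures.  The extra ASD-like states have their four circuit-pair entries
(SN-lCEN, SN-rCEN, SN-DMN, cMN-sMN) pinned to the TD-repertoire average by
alternating projections with the nearest-PSD repair, so they add no
spurious group offset; mean effects are planted by shifting every
ASD-like state's CNII by `-delta_c` (split symmetrically over the CEN and
DMN entries) and MNII by `+delta_m`.  Converting a requested Cohen's d
into `delta` requires the between-subject SD of the measured windowed mean
NII, which depends on scan length and windowing; the generator estimates
it with an internal pilot simulation (128 subjects per group, unshifted
states, seeded from the cohort seed) and multiplies by the noise
attenuation factor.  State-level CNII variability is widened in the
ASD-like group by mean-preserving +/- offsets on the extra states whose
size adapts to the TD repertoire's own state-level spread, so the
variability ordering holds for every master seed.  For replicate-cohort
simulations, `resolve_cohort_spec` freezes one state repertoire (one
generative truth) and replicates redraw subjects only.

Behavioral scores: latent CI and IS each correlate `planted_behavior_r`
(default 0.4) with *both* the mean and the SD of the subject's realized
CNII (shared standardized-sum signal), RM with mean MNII; nine items are
generated from a fixed 3-factor loading pattern (loading 0.8, uniqueness
noise SD 0.4), discretized by fixed quantile cuts of the latent value onto
0–3 (mass roughly 35/30/23/12%), with a 3% rate of special codes 6/7/8.
A stand-alone item generator (`simulate_item_table`, n=126 by default,
iid standard-normal factors) emulates the larger clinical-only cohort used
for the factor analysis.

What the generator does *not* emulate: hemodynamic smoothing, scanner
drift and physiological noise, site effects, non-Gaussian tails, real
ADI-R response styles, or any true coupling between demographics and
connectivity.  Passing tests therefore demonstrate that the estimators
recover what this generative model plants at realistic sizes and noise
levels — not that the scientific findings themselves are reproduced.

## Problem sizes and numerical choices

Simulation-based tests run at deliberately chosen desk scales: state
recovery uses 6 subjects of 1920 samples with dwell 240 and a 60-sample
window stepped by 5 (dwell >= window, window noise small against the
state separation — the regime in which recovery is well-posed);
group-difference calibration uses 50 planted and 400 null cohorts at the
full 48/48 size with windowed (`by_window`) aggregation, since clustering
450 cohorts would dominate runtime without changing the measured contrast
(the planted shift moves every ASD state equally); brain-behavior power
uses 100 replicates of the 48-subject ASD-like arm with 1000 permutations.
Ground-truth window labels in recovery tests are the taper-weighted
majority of the latent state path within the window.

One calibration fact worth stating plainly: with 48 subjects per group the
sampling SD of estimated Cohen's d is about 0.21, so roughly 84% of
perfectly calibrated replicates fall within +/-0.3 of the planted d = 0.8
— an intrinsic property of the design size, observed exactly in the test
suite (42/50 cohorts).

Numerical details: correlations are clipped to [-1, 1] and symmetrized
with an exact unit diagonal; Fisher z clips |r| at 1-1e-7; k-means seeds
derive deterministically from the config seed per (group, circuit, k);
PSD repair clips eigenvalues at 1e-8 and renormalizes the diagonal;
assignment ties go to the lower state id; permutation p-values use the
add-one convention and are exact at achievable levels.

## Limitations

- Silhouette cannot select k=1; genuinely stationary groups are only
  flagged, not modeled.
- At 6-minute scan length with the default 30-s window, window noise is
  large enough that silhouette typically resolves fewer states than the
  planted four in the ASD-like group; the acceptance script reports the
  selected k honestly rather than forcing the planted value.
- The exact taper constant, window overlap, clustering metric and
  permutation scheme of the original analysis are not fully specified
  anywhere we could consult; the choices above are documented defaults,
  all exposed in `PipelineConfig`.
- The confound model is linear and complete-case; no multiple-comparison
  correction is applied across the four feature-by-circuit group tests
  (raw p-values are reported).
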