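# Methods

This note documents the models implemented in `wmnet`, the defaults and
why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that matter for
reproducibility.

## Task model and synthetic designs

A WM trial unfolds as cue → encode → maintain → probe, followed by a
rest interval (ITI) that serves as the implicit GLM baseline. Defaults:
10 s for encode/maintain/probe, 10 s ITI, TR = 2 s. The cue duration is
not fixed by the task description; we default to 2 s and expose it
(`cue_duration_s`). Two factorial designs are built in:

- **Study-1-shaped**: 3 domains × 3 loads, 2 repeats per cell per run →
  18 trials/run; 19 subjects × 3 runs × 18 trials × 4 stages = 4104
  stage events.
- **Study-2-shaped**: 2 manipulation × 2 domains × 2 loads, 2 repeats →
  16 trials/run; 16 subjects × 3 runs × 16 trials × 4 stages = 3072
  stage events.

Trial order is a uniform shuffle of the within-run cell list under the
config seed ("pseudo-random" with exact cell balance, no adjacency
constraint). All outputs are fully determined by the seed.

## Generative BOLD model

ROI series are generated in the same regression form the connectivity
estimator fits. Each ROI's *base* series is HRF-convolved
condition activation plus a slow cosine drift and white Gaussian noise;
a target ROI t additionally receives, per condition c and source s, the
term `coupling[c][s, t] · (base_s ⊙ H(X_c))`. The interaction is formed
in BOLD space (observed series × convolved psychological regressor),
not at a deconvolved neural level — matching the estimator exactly so
that recovery is a property of the estimator, not of a model mismatch.
The HRF is the canonical double-gamma (peak ≈ 5 s, undershoot ≈ 15 s),
unit-peak normalized, built on a 16× oversampled grid and decimated to
scan times; generator and estimator share this code path.

Nuisance is simulated as six standardized random-walk "motion" traces.
Not emulated: physiological/vascular noise structure, spatial
autocorrelation between voxels, response-time jitter of the probe
(fixed at stage duration by default), scanner drift nonstationarity.
Consequently, passing recovery tests demonstrates estimator
correctness and calibration under the assumed noise model — not
robustness to the full noise structure of real fMRI.

### Feature-stack generator

Class-conditional Gaussian stacks place class means on orthogonal
directions with centroid separation `effect_size` (unit noise sd) at
the lowest load, scaled geometrically up to `effect_size × load_gain`
at the highest load. With `stage_specific=True`, half of the squared
class-pattern norm is shared across stages and half is stage-unique, so
stage-trained decoders transfer imperfectly. Subject identity adds a
shared offset (`subject_sd`, default 0.25) to every event of a subject,
giving the subject-level split something real to guard against.
Subject, load and stage are assigned by mixed-radix decomposition of
the event index so the three factors are crossed, not confounded.

## Mini-block GLM

One HRF-convolved boxcar per (trial, stage); nuisance columns are the
24-parameter Volterra motion expansion `[m, m₋₁, m², m₋₁²]` plus one
indicator per spike-flagged scan; drift is a discrete cosine basis with
cutoff period equal to half the run length (equivalent to high-pass
filtering inside the design, keeping estimation a single OLS). The ITI
is left unmodeled as baseline. Rank deficiency is an error naming the
collinear columns — never silently regularized. No autocorrelation
prewhitening is applied (OLS point estimates are unbiased under AR
noise; only the optional T statistics assume white residuals).

## Conjunction and cluster correction

Contrast maps are thresholded at a relaxed voxel p (default 0.01,
one-sided normal). Cluster extent p-values are add-one tail
proportions against a pooled Monte-Carlo null: Gaussian volumes
smoothed to the map's estimated FWHM (lag-1 autocorrelation estimator,
Gaussian-ACF assumption), re-standardized, thresholded identically.
Benjamini–Hochberg across the observed clusters at q (default 0.05)
selects survivors; conjunctions are the voxelwise AND of individually
corrected maps. Cluster connectivity is 26-neighbour throughout. Dice
of two empty masks is defined as 0 (with a warning) to avoid 0/0.
The minimum-T variant of conjunction inference is not implemented; the
AND-of-corrected-maps reading is the operational one.

## Watershed parcellation

Basins are flooded from the local minima of the inverted statistic
*within the mask* (outside voxels act as +inf). Flooding is
deterministic with ties broken by voxel scan order. The size filter is
strict: an ROI must exceed `min_size` voxels (default 50, i.e. a
50-voxel basin is excluded). Surviving ROIs are renumbered 1..k by
descending size for stable, human-readable ids. No pre-smoothing is
applied — input maps are assumed already smooth.

## gPPI estimation

For each ordered pair (source, target): OLS on
`[1, Y_S, H(X), E, Y_S × H(X)]`. The source is mean-centered before
forming the interaction, decorrelating it from the H(X) main effect;
this is a package choice, exposed but on by default. No deconvolution.
Directed coefficients are triangle-averaged,
`M[i,j] = (β_j(i→j) + β_j(j→i))/2`; the diagonal is undefined (NaN). A
failed fit (e.g. a constant source, whose interaction is collinear with
H(X)) voids the affected edges as missing — never zero — and is
recorded. Single-trial stacks use one psychological column per
trial-stage event with the same estimator. Note an identifiability
limit: with exactly noise-free sources the source series lies in
span(H(X)) and the design is rank-deficient by construction; recovery
is therefore stated as a noise → 0 limit.

## Clustering and purity

Two-way structure discovery is two independent one-axis agglomerative
clusterings (Ward linkage, Euclidean distance) of the
condition-averaged events × ROIs matrix. Flat clusters cut links whose
inconsistency — (link height − mean subtree height) / subtree height
sd, over subtree depth 5 — exceeds a threshold. The threshold value is
not fixed by the method description; the default is 1.15 and it is
surfaced in config and reports. Zero-variance subtrees define
inconsistency as 0. Purity matches each cluster to its most frequent
class: `(1/N) Σᵢ maxⱼ |ωᵢ ∩ cⱼ|`; it is bounded below by the largest
class share, so it is only informative relative to that baseline.

## Decoding and inference

Dense models: per-class linear SVMs in a one-vs-all error-correcting
output code; prediction minimizes the hinge loss between the decision
vector and class codewords. Features are z-scored with training-set
statistics only (leakage guard). Sparse models: L1-penalized
multinomial logistic regression along a decreasing lambda path
(default: data-driven glmnet-style path from the smallest
all-zeroing lambda down three decades); the operating lambda is the
knee — maximal absolute second difference — of the summed validation
cross-entropy curve, ties broken toward the sparser model.

Inference: events are split 75/25 at the subject level
(round-to-nearest, at least one subject per side; train/holdout subject
disjointness is asserted on every run). Training events are
bootstrapped (stratified by class by default) and every true-label
model is paired with a model trained on shuffled labels. Over
m = n_partitions × n_bootstraps paired resamples,
`p = (b + 1)/(m + 1)` with b the number of resamples where the null
model outperformed the true one; the effect size is the rank-biserial
transform of the Mann–Whitney U statistic. Default desk-scale settings
are 5 partitions × 20 bootstraps (m = 100, minimum p ≈ 0.0099); the
full-scale 10 × 100 setting is a parameter away. Resamples within a
run share partitions and are therefore correlated: calibration checks
should aggregate across independent datasets rather than rank-sum raw
resample values.

Stage transfer trains one domain decoder per stage plus a global model
and evaluates every model on every holdout stage; match is the mean
diagonal, mismatch the mean off-diagonal. Load-stratified evaluation
reports per-load accuracy and a rank-sum contrast of per-subject
accuracies at the highest vs lowest load.

## Edge-wise mixed models

Per edge: `Y = 1 + study + domain × load + (1|subject)` fitted by REML
(statsmodels MixedLM), with per-term Wald chi-square tests for study,
domain, load and domain × load. Wald tests are used because MixedLM
exposes no denominator-df ANOVA; with the balanced designs used here
they agree closely with F-based decompositions. Domain and load are
categorical by default (numeric load is an option). BH FDR runs across
edges separately per effect (the family definition is a package
choice), default q = 0.01. Non-convergence is flagged per edge, never
silently dropped.

## Problem sizes and numerical conventions

Tests and the acceptance script run at desk scale: 3–6 ROIs and single
runs for recovery tests, 32³ volumes for watershed, 8–20 subjects for
decoding, 24 edges × 14 subjects for edge models, m = 100 permutation
resamples. These sizes were chosen so each property is measurable with
comfortable Monte-Carlo margins. Seeds determine all randomness;
`numpy.random.default_rng` child seeds are drawn below 2³¹. Tolerances:
OLS estimators match normal-equation oracles at 1e-8; noise → 0 gPPI
recovery at 1e-6; stochastic pattern checks use explicit Monte-Carlo
slack stated in each test.

## Known limitations

- Voxel-mode (NIfTI) inputs are supported through `roi_reduce` and the
  conjunction/parcellation stages, but the end-to-end synthetic
  pipeline operates at ROI level.
- The cluster-extent null assumes stationary Gaussian smoothness;
  random-field and TFCE corrections are out of scope.
- Directed/effective connectivity is out of scope; gPPI edges are
  undirected averages.
- Purity and decoding results on synthetic stacks bound what the code
  does, not what real fMRI data would yield.
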