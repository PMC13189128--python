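# Methods

This note documents the models and procedures implemented in `popdyn`, the
parameter choices that matter, the numerical conventions, and what the
synthetic sessions do and do not emulate.

## Data model and conventions

All times are milliseconds, trial-relative, with fixation-spot onset at 0;
coordinates are degrees of visual angle with the fixation point at the
origin, x rightward, y upward. A `Session` holds units (per-trial spike
times), trials (event timeline, 11-item array composition with 2
same-category targets on 20 locations, the fixation sequence with item
labels and history flags), optional 1-kHz LFP traces, the array geometry,
and — for synthetic sessions — the planted `GroundTruth`. Sessions
round-trip through a versioned HDF5 container (ragged per-trial arrays
stored as concatenated data + offsets); unset labels are explicit strings,
never magic numbers, and every structural invariant is validated on write
and read.

The canonical array layout places three concentric arcs at 5.5°, 8° and
10.5° eccentricity (three locations per arc per hemifield, mirror
symmetric) plus midline points at (0, ±6°) — any layout satisfying the
5–11° range and the 9+9+2 symmetry would do; the realised one is recorded
in the session.

## Synthetic sessions

The generator reproduces the statistical structure the analyses assume.

**Behaviour.** Fixation-spot 400 ms; cue duration uniform 500–1300 ms;
delay 500 ms; search up to 4000 ms; a correct trial ends with an 800-ms
hold on one of the two targets. Fixation durations are log-normal with
mean 208 ms (SD 100 ms, floor 80 ms); saccade gaps ~40 ms; the first
saccade lands ~220 ms after array onset. Item selection mixes uniform
sampling of uninspected items, target guidance (probability 0.30, toward
unvisited targets), and an explicit return-fixation branch (probability
0.10, calibrated once so that ~12–13% of correct trials contain a
refixation); a target fixation converts to the terminal hold with
probability 0.75, and 10% of trials are fated to fail. These settings give
a mean of ~3 fixations per correct trial and ~88% accuracy, wide enough a
fixation-count distribution for the efficiency analyses.

**Spiking.** Rates are piecewise constant per trial and spikes are drawn
exactly (Poisson counts per segment, uniform times within segments); no
refractoriness, since every analysis consumes rates, not ISI structure.
Per unit: baseline *b* ~ clipped normal (10 ± 4 Hz, floor 2 Hz); a
visually evoked rate *e* = *b*·U(0.6, 1.4); response latency 50 ms
(matching the 50-ms-post-onset analysis windows). Foveal units respond to
the fixated stimulus: cue rate (*b* + *e*)·catfac, search-fixation rate
(*b* + *e*)·catfac·attfac·historyfac·posfac, where catfac is g_cat for the
preferred category (default 2 for tuned units), 1/g_cat for the opposite,
1 for flower/hand; attfac = g_att (default 2) on target fixations;
historyfac applies a 0.8 refixation gain and 0.85 post-target-found gain
on V4/IT foveal units; posfac = 1 + A·exp(−d²/2σ²) is an eye-position gain
field (A ~ 1.0–1.5, σ = 3°) that makes fixation responses depend smoothly
on the fixated location — the substrate of the spatial-layout code.
Delay-epoch rates carry a maintenance gain (g_cat^0.5 for category-tuned
units) and cue/delay rates carry exp(slope·(n_fix − 3)), the planted
search-efficiency relation (slope ±0.06 for 25% / 11% of responsive
units). Peripheral-localized units are driven additively by array items
within 1σ of a Gaussian RF (σ = 2.5°) with the same category/attention
factors plus an on-target-fixation state gain (1.5); because the drive is
a linear function of the 12-dimensional one-hot fixation design, the
planted `encoding_coefficients` are exactly the generative betas the lasso
model estimates. Peripheral-unlocalized units respond to array onset
uniformly; nonresponsive units stay at baseline (and carry no efficiency
slope — a silent epoch cannot express one).

**LFP.** Per area, 1/f-amplitude background noise plus a theta sinusoid
(8 Hz) whose amplitude in the cue and delay epochs follows
base·(1 + slope·(n_fix − 3)) with opposite default slopes (+0.15 cue,
−0.15 delay), planting the epoch-dissociated power–efficiency relation.

**Randomness.** Every draw comes from a `numpy` generator seeded with
`(seed, stream, unit index, trial index)`, so output is bit-reproducible
and adding units or channels never perturbs existing trials.

**What is not emulated.** Saccade kinematics and eye-position noise;
retinotopic remapping of peripheral RFs during gaze shifts (peripheral
RFs are screen-fixed, which is exact for the central-fixation epochs and
an approximation during search); spike waveforms; cross-area synchrony;
inter-unit correlated variability (units are conditionally independent
given the task events). Passing tests therefore certify the estimators
against the assumed generative structure, not against biological
confounds absent from it.

## Spike density and normalization

Spikes are convolved with K(t) = (1 − e^(−t/1 ms))·e^(−t/20 ms) for
t ≥ 0, zero otherwise, sampled on a 1-ms grid and normalised to unit area
so convolution conserves spike count (the kernel tail is truncated at 30
decay constants, relative weight < 1e−13). Spikes are floored (not
rounded) onto the grid so no spike influences earlier grid points; the FFT
path equals direct per-spike summation to < 1e−9 spikes/s. Rates are
divided by the unit's mean pre-cue baseline (−150–0 ms before cue onset
across trials); units with zero baseline are excluded from normalized
analyses rather than divided.

## Unit selection

RF classes come from two rank-sum tests (response 50–200 ms post onset vs
baseline −150–0 ms, for cue and for array): cue-only → focal foveal, both
→ broad foveal, array-only → peripheral, neither → nonresponsive.
Peripheral units are localized if their array response depends on which
locations are occupied (per-location occupied-vs-empty rank-sum tests,
Bonferroni ×20) — a spatial-tuning test playing the role of a separate
RF-mapping task.

Category selectivity combines a face-vs-house rank-sum test (α = 0.05)
with SI = (R_face − R_house)/(R_face + R_house) on baseline-subtracted
responses, clamped to ±1 when the responses have opposite signs;
|SI| > 0.13 (the "130%" criterion) fixes the sign, a significant test with
|SI| ≤ 0.13 is `undefined`. Foveal units are scored on cue responses,
peripheral units on trials with exactly one face/house item inside the RF;
search-epoch activity is never used, to avoid contamination by attention.

Attention selectivity compares fixation responses (150–225 ms after
fixation onset) on targets versus distractors with a two-tailed Wilcoxon
signed-rank test over per-exemplar paired means — the same stimuli when
they served as targets versus as distractors — falling back to an
unpaired rank-sum when fewer than six exemplars appear in both roles. The
attentional effect is the mean paired rate difference. Minimum counts
default to 10 trials/fixations per condition.

Overlap between unit classes uses a 2×2 chi-squared test (proportion of
B within A against the base rate of B), with an optional Bonferroni factor
across areas.

## dPCA and trajectory statistics

The condition-averaged matrix (rows condition-major: T time bins per
condition; columns units; normalized rates) is centered and split into
condition, time, and condition×time marginalization averages. For each
marginalization the decoder/encoder pair minimises
‖X_φ − X D Fᵀ‖² + λ‖D Fᵀ‖² at rank q (default 3), solved by ridge
regression followed by SVD truncation. Numerical conventions that matter:

* λ defaults to 5% of the mean per-unit variance. A vanishing ridge lets
  the decoder whiten onto low-variance noise directions and destroys axis
  recovery; cross-validating λ inside permutation refits would multiply
  cost a thousandfold for no measurable change in the recovered axes at
  these problem sizes, so a fixed data-scaled default is used (λ is a
  keyword everywhere).
* Decoder axes are normalized to unit norm (encoders rescaled so the
  reconstruction D Fᵀ is unchanged) — projections are then
  scale-comparable across refits, which the shuffle null requires.
* Axis signs are fixed so the first canonical condition (face / target)
  projects positively on its leading axis.
* Explained-variance fractions use ‖X d‖²·‖f‖²/‖X‖²; within a
  marginalization the component contributions are orthogonal, and the
  total across marginalizations is bounded by 1.

Trajectories are projections onto the top three axes across
marginalizations by explained variance. Condition separation per bin (mean
pairwise Euclidean distance between condition points) is compared with a
null that permutes condition labels across trials/fixations — never across
bins, preserving within-trial autocorrelation — refitting the
decomposition per permutation (the conservative choice); p-values use the
add-one rule and Benjamini–Hochberg correction across bins at 0.05. Axes
can be fit on one epoch (e.g. target responses, or averaged face/house
responses) and applied unchanged to another via
`demixing_from_reference`, which requires identical unit sets and order.

## Parallel axis and orthogonal plane

From the (N×3) component coefficients, the population-average-rate axis is
τ_i = Σ_n w_{i,n}; a uniform rate change moves the state along τ. Points
decompose into the signed parallel coordinate (sign of P·τ) and signed 2-D
coordinates in the plane through the origin orthogonal to τ, whose x axis
seeds from projecting [10, 0, 0] into the plane (fallback [0, 10, 0] when
collinear) and y = τ×x̂/‖τ×x̂‖. The decomposition is exact: Pythagoras and
reconstruction hold to 1e−9 on random points. The 32-condition analysis
(8 face + 8 house exemplars × target/distractor, chosen greedily by the
rarer of the two role counts so every condition is populated) uses nine
30-ms bins centered at −45…195 ms around fixation onset. Classification
from a single component uses LDA with stratified 5-fold cross-validation;
sample-wise leave-one-out is avoided because at zero signal it
anti-learns (the held-out point always sits on the wrong side of the
training mean, accuracy → 0 rather than 0.5); in-sample accuracy is
reported alongside.

## Representational geometry

Neuronal vectors are per-condition population patterns (time-averaged
normalized rates, or regression coefficients for the encoding model);
geometry is Euclidean distance and arccos cosine similarity (degrees),
with mean-pairwise summaries over condition sets. Hyperplanes come from
linear SVMs (a maximum-margin linear separator, matching the
weight-averaging recipe): 100 balanced subsamples (min-class count drawn
without replacement) per label scheme, weights and intercepts averaged;
the angle null retrains both classifiers on shuffled labels 1000 times
using one subsample per shuffle — averaging 100 subsamples inside every
shuffle would dominate runtime while the null's location (≈90°) is set by
label exchangeability, not subsample averaging. Category classifiers train
on distractor fixations, attention classifiers on face/house fixations,
both on rates averaged 0–255 ms post fixation onset, normalized (the
package-wide convention; raw rates only rescale the margin, and the angle
is scale-invariant).

Subspace layouts are compared by centered orthogonal Procrustes with
isotropic scaling; reflections are disabled by default (flagged when they
would help) and enabled where the reference is physical space, where a
recording has no preferred handedness.

Task-context comparisons (first fixation vs refixation; distractor
fixations before vs after the first target fixation) use per-unit mean
normalized rates 150–250 ms post fixation onset per fixated category, a
two-tailed paired t-test across units on the category-averaged means, and
the 4-condition geometry per context.

## Peripheral encoding model

Each fixation's 12-long indicator vector marks every RF-resident item's
stimulus type (face/house target, face/house/flower/hand distractor —
target categories defined by the trial's cue) inside the block matching
the fixation type (on-target vs on-distractor); an empty RF yields an
all-zero, intercept-only row. RF membership for synthetic units is
"within 1σ of the planted center"; for other data a location mask is
supplied. The response is the mean rate 0–250 ms post fixation onset. The
lasso strength is chosen once per unit by 10-fold cross-validated mean
squared error (the held-out Gaussian likelihood criterion), then held
fixed across 100 random half-splits → 200 coefficient vectors, averaged;
the intercept is unpenalised and fits are bit-reproducible given a seed.
Population geometry per foveal attentional state treats the per-state
6-coefficient blocks across units as neuronal vectors; pattern separation
and angles are compared by a paired t-test across 15 random ~80% unit
subsets (the subset count is configurable; 15 mirrors the
degrees-of-freedom convention of the source analyses and is reported with
the result).

## Spatial RSA

Per 50-ms window (0–50 … 150–200 ms post fixation onset), fixations are
grouped by fixated location (pooling across item categories — location is
the condition); locations with fewer than 5 fixations are dropped from
both matrices. Neural dissimilarity is 1 − Pearson r between per-location
mean population vectors; physical dissimilarity is Euclidean distance in
degrees. Spearman's ρ over the lower triangles measures correspondence;
significance requires the observed ρ to exceed the location-shuffle null's
95th percentile (1000 runs), Bonferroni-corrected across the four windows.
Per-window 2-D PCA layouts of the location vectors are Procrustes-aligned
to the physical coordinates; the normalized residual quantifies layout
preservation.

## Search efficiency and theta power

Per unit, Pearson correlations of windowed mean rates (cue 0–500 ms post
cue onset; delay 0–200 ms post delay onset) with the trial's fixation
count; the class label (positive/negative/none) follows the delay-window
test at α = 0.05, and correlations over fixation-count group means
(the 7 lowest counts) and per cue category are reported alongside the
trial-level ones, since both conventions are defensible. Population
divergence between search onset and completion compares face- vs
house-cue population vectors (normalized rates 0–225 ms after the
first/final fixation onset) by distance and angle, with a paired t-test
across 15 random unit subsets and a cue-label shuffle null at both time
points. Theta power is the 4–12-Hz band integral of a Welch PSD (200-ms
Hann segments, 50% overlap, rectangle-rule band integration — appropriate
at the 5-Hz resolution these segments give), per trial per epoch, averaged
within fixation-count groups and correlated with the count.

## Pipeline and problem sizes

`run_pipeline` executes eight stages (selection, state space, efficiency,
orthogonal subspace, peripheral encoding, context, spatial RSA,
hyperplanes) in a fixed dependency-checked order, on a loaded container or
a freshly simulated session, and writes a JSON bundle containing every
stage report plus the fully serialized configuration and package version;
reruns with the same seed are byte-identical. The default configuration —
96 units across four areas, 300 trials, 200 trajectory permutations, 500
RSA permutations, 100 hyperplane shuffles — completes in about a minute on
one CPU; the test suite and the acceptance script use comparable or
smaller sizes so the full check runs in a few minutes. Permutation counts,
unit counts and trial counts are all configuration fields for
larger-scale runs.

## Known limitations

* dPCA regularization is a fixed data-scaled default, not cross-validated
  per dataset; for very low trial counts per condition the condition axes
  can absorb noise.
* The signed-rank pairing for attention selectivity assumes exemplars
  recur in both roles; sessions with very few trials fall back to the
  unpaired test, which is slightly anticonservative under strong category
  tuning.
* Peripheral RFs are screen-fixed during search, so the encoding model's
  design matrix is exact for the simulated data but approximate for real
  free-gaze recordings, where retinal RF content shifts with every
  saccade.
* The permutation and FDR machinery controls error rates per analysis
  call; no correction is applied across the pipeline's stages.
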