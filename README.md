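# popdyn

Population-dynamics analyses of goal-directed visual search in multi-area
extracellular recordings, with a synthetic-session generator that plants
recoverable ground truth.

## The problem

During free-gaze visual search a primate holds a category cue in mind
(e.g. *find a face*), maintains it over a delay, then saccades through an
array of items until it fixates a target. Large-scale recordings from V4,
IT, OFC and LPFC during such a task pose a chain of population-level
questions that this package answers end to end:

* which units respond to the fovea versus the periphery, and which are
  **category-selective** (faces vs houses) or **attention-selective**
  (targets vs distractors);
* whether population **trajectories in state space** encode the cue during
  presentation, the delay, and search, even when mean rates barely differ;
* whether task information lives on the **population-average firing-rate
  axis** or in the **orthogonal subspace** — patterns that change with no
  net rate change;
* how foveal attentional state reshapes **peripheral representational
  geometry** (pattern separation, angles between neuronal vectors);
* whether presearch activity and **theta-band (4–12 Hz) LFP power**
  predict how many fixations the search will need;
* whether the population preserves the **spatial layout** of the search
  array (representational similarity analysis against physical geometry).

Real recordings of this kind are not redistributable at desk scale, so the
package ships a first-class generator of synthetic sessions — task
timeline (400-ms fixation, 500–1300-ms cue, 500-ms delay, ≤4-s search,
800-ms target hold), 20 array locations at 5–11° eccentricity, log-normal
fixation durations (≈208 ms mean), return fixations, inhomogeneous-Poisson
spiking with per-unit tuning, and LFP with an epoch-dependent theta
component — every planted parameter recorded as ground truth so each
analysis has a recoverable target.

## The core quantities

* **Spike density**: spikes convolved with the causal EPSP-like kernel
  K(t) = (1 − e^(−t/τ_g)) e^(−t/τ_d), τ_g = 1 ms, τ_d = 20 ms, unit area;
  rates divided by each unit's pre-cue baseline.
* **Selectivity index**: SI = (R_face − R_house)/(R_face + R_house) on
  baseline-subtracted responses, clamped to ±1 when the two responses have
  opposite signs; face-selective needs rank-sum p < 0.05 *and* SI > 0.13.
* **dPCA**: the condition-averaged (T·C) × N matrix is split into
  condition, time and condition×time marginalizations; each gets
  encoder/decoder axes from reduced-rank ridge regression, so the leading
  condition axes carry condition information unmixed from shared dynamics.
  Per-bin condition separation is tested against trial-level label
  shuffles with Benjamini–Hochberg correction across bins.
* **Parallel axis / orthogonal plane**: in the 3-D component space the
  population-average-rate axis is τ_i = Σ_n w_{i,n}; every point splits
  into a signed coordinate along τ and 2-D coordinates in the orthogonal
  plane through the origin, each fed to a linear discriminant separately.
* **Representational geometry**: Euclidean distance and cosine angle
  between neuronal vectors; classifier hyperplane angles
  arccos(w₁·w₂/‖w₁‖‖w₂‖) with balanced-subsample averaging and label
  shuffle nulls; rotation + isotropic-scaling (Procrustes) alignment of
  condition layouts across subspaces.
* **Peripheral encoding**: per fixation a 12-long one-hot design (6
  stimulus types × on-target/on-distractor fixation), lasso-regressed onto
  the 0–250-ms response, 100 random half-splits → 200 coefficient
  estimates averaged.
* **Spatial RSA**: per-location population vectors in four 50-ms windows;
  neural dissimilarity 1 − Pearson r versus physical Euclidean distances,
  Spearman correspondence with a 1000-run location-shuffle null,
  Bonferroni-corrected across windows.

## Worked example

`examples/` holds one short script per capability. For instance:

```bash
$ python examples/spatial_geometry_rsa.py
window (ms)   Spearman rho   perm p    significant (Bonferroni x4)
  0-50              0.080     0.1449          no
 50-100             0.569     0.0010         yes
100-150             0.581     0.0010         yes
150-200             0.578     0.0010         yes
```

The neural dissimilarity structure across the 20 array locations starts
matching the physical layout ~50 ms after fixation onset (the planted
response latency) and stays correlated through 200 ms: the population
carries a map of the array. And:

```bash
$ python examples/orthogonal_subspace_decoding.py
gain code: parallel accuracy = 1.00, orthogonal accuracy = 0.50 (stratified 5-fold)
pattern code: parallel accuracy = 0.48, orthogonal accuracy = 1.00 (stratified 5-fold)
```

A class signal planted as a pure rate gain is decodable only from the
parallel (population-rate) coordinate, a pattern signal only from the
orthogonal plane — information can be invisible to mean firing rates yet
fully linearly decodable.

The full chain — simulate → classify → all seven figure-level analyses —
runs as one deterministic pipeline:

```bash
popdyn run --seed 1 --out results/        # or: popdyn.pipeline.run_pipeline
popdyn simulate --seed 1 --out session.h5 # write a session container
popdyn classify --session session.h5      # one stage on an existing file
```

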