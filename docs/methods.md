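# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `dtuemp`, and what the synthetic experiments do and do not
show about real recordings.

## Trial model and synthetic generator

The study protocol is a 20-second bout of maximal-speed elbow
flexion-extension filmed at 30 FPS. The generator idealises it as a
triangular wave in the wrist-elbow angle: each cycle is a linear flexion
ramp (angle_min → angle_max) followed by a linear extension ramp back, with
per-cycle periods drawn from Normal(μ, σ) truncated at 0.2 s and each
half-cycle quantised to a whole number of frames. A triangular wave was
chosen over a sinusoid because its vertices are exact phase boundaries, so
segmentation and metric code can be tested against a frame-exact oracle.
Phase records use an exclusive end boundary (the frame where the next phase
starts), making durations exact frame counts.

Defaults: duration 20 s, 30 FPS, cycle period 2.0 ± 0.2 s, angular range
0-120°, forearm 100 px with the elbow anchored at (120, 120), keypoint
jitter SD 1 px. These are plausible values for older adults performing the
task "as quickly as possible"; the true distribution of cycle-time
variability in any clinical population is not modelled, so generator
defaults characterise the pipeline, not a patient group.

Detector errors are modelled as isolated single-frame displacements of the
wrist (the fast-moving, blur-prone joint) by a fixed magnitude (default
80 px) in a uniformly random direction. A Binomial(n, rate) count of frames
is placed under a no-two-adjacent constraint, matching the correction
algorithm's stated assumption; the renderer flags injected frames so tests
can audit them. Image y points down, so the wrist offset uses −sin θ and
increasing angle moves the wrist up on screen.

`render_frames` produces small grayscale frames — a fixed smoothed random
background (amplitude 0.5) plus unit Gaussian blobs at the joints — purely
as optical-flow fixtures. Nothing about them is photorealistic: no limb
occlusion, lighting change, motion blur, or camera shake. Tests passing on
these frames show the flow and correction machinery is numerically sound,
not that it survives real video degradation.

## Pose backend

Any estimator that writes the keypoint CSV (`frame,joint,x,y,confidence,flag`)
is an acceptable backend; the deep network that produced the original
heatmaps is deliberately out of scope. Heatmap decoding is the plain local
maximum: global argmax with row-major tie-breaking and no sub-pixel
refinement, so the backend contract is bit-exact. Confidence is the max
score after min-max normalisation; a constant heatmap returns the origin
with confidence 0 and a warning.

## Lucas-Kanade flow

Sparse, single-level LK over a 15 px window: central-difference spatial
gradients of the first frame form the structure tensor G; the temporal
difference against the second frame (warped by the current estimate with
bicubic interpolation) forms the right-hand side; the 2×2 system is
re-solved until the update falls below 1e-3 px (max 10 iterations). The
iterative warp keeps the linearisation valid for the ≤ 2 px inter-frame
motions the protocol produces — a single linearised solve is accurate to
roughly half a pixel on smooth textures, which is not enough to gate
substitutions reliably. Degeneracy is reported, never guessed: least
eigenvalue of G below 1e-6 or condition number above 1e6 → `aperture_failure`;
window (plus its 1 px gradient margin) outside the image → `out_of_bounds`.
No pyramid is built; motions beyond a few pixels per frame would need one.

## Coordinate correction

Per joint independently, frame t ≥ 1:

1. predict p̂ = accepted(t−1) + flow(t−1);
2. if ‖network(t) − p̂‖ > threshold and frame t−1 was not itself a
   substitution, accept p̂; otherwise accept network(t).

Frame 0 and frames with failed flow always take the network. The prediction
chains from the last *accepted* coordinate rather than the raw network
coordinate, so a detected error does not poison the next prediction. The
default threshold is 0.25 × median per-frame forearm length, which is
scale-invariant across camera distances; an absolute-pixel mode exists.

The one-consecutive-substitution cap is the algorithm's only flow-distrust
mechanism. When the assumption is violated (two consecutive network errors),
the trace is: first error substituted, second error accepted from the
network, and the *following* good frame substituted once from a prediction
chained through the accepted error — a bounded, isolated artifact rather
than a runaway. The correction report records every substitution,
disagreement magnitude, and flow failure.

On the standard synthetic fixture (5% isolated 80 px wrist outliers, exact
flow, 1 px jitter) the corrected angle sequence removes ≥ 80% of the RMSE
of the uncorrected one on average; raising the threshold never increases
the substitution count on these fixtures.

## Segmentation and metrics

Extrema are located by `scipy.signal.find_peaks` with prominence 10° and
minimum separation 5 frames (~0.17 s) — both guard against jitter peaks and
are exposed in the config. Strict alternation is enforced by keeping the
lowest minimum between consecutive maxima (and symmetrically); spans before
the first and after the last retained extremum are discarded. No
pre-smoothing is applied by default so results are bit-reproducible from
the correction stage; an optional 5-frame moving average exists behind a
flag. SDs use the sample (n−1) denominator. Cycles pair each flexion phase
with the immediately following extension phase; with fewer than two phases
of a kind the mean is reported from available data and the SD is NaN.
Because all six metrics are durations, they are invariant to the angle
reference convention.

## Agreement statistics

* Spearman: mid-rank Pearson with the t approximation (scipy), labelled
  weak/moderate/strong at 0.35/0.67.
* ICC(2,1): two-way random effects, absolute agreement, single measures,
  computed from the two-way ANOVA mean squares with k = 2 raters; p from
  the F test of MSR/MSE. This form was chosen because the comparison is
  between two measurement *systems*, where a constant offset must count
  against agreement. Labels at 0.50/0.75/0.90.
* Normality: adjusted Fisher-Pearson skewness, excess kurtosis, and a
  Shapiro-Wilk gate at α = 0.05.
* Inverse-normal transform: Blom fractional ranks (r − 3/8)/(n + 1/4) with
  mid-ranks for ties, through the standard normal quantile.
* Partial correlation: residual method — both variables regressed on
  [1, age, sex, BMI], Pearson on the residuals, two-sided p at n − 2 − k
  df. A non-normal outcome is first rank-inverse-normal transformed (the
  covariate-side variable is not transformed). Sex is coded 0/1.

No multiple-testing correction is applied; each statistic is reported with
its own p-value.

## Multi-task regression

The objective is Σ_i ‖X_i w_i − y_i‖² + ρ₁‖W‖₁ + ρ_L2‖W‖_F² with outcomes
centred per task (intercepts are task means). The solver is monotone FISTA:
proximal soft-thresholding steps with the ridge term in the smooth part,
step 1/L from the exact largest task Gram eigenvalue, momentum restarts on
non-descent, termination when the relative objective change drops below
1e-8 *and* the subgradient optimality residual is below 1e-6 (the objective
can plateau before the iterate settles, so the change criterion alone is
unreliable). The trace is non-increasing by construction.

Evaluation follows a nested design: outer 5-fold CV (shuffled, seeded);
within each training fold, features are z-scored and ρ₁ is chosen by
3-fold CV over a 7-point logarithmic grid {10⁻³…10¹}·ρ_max, where
ρ_max = max 2|Xᵀy_c| is the smallest penalty that zeroes W. The multi-task
model picks one ρ₁ minimising the mean inner MAPE across tasks; the
single-task benchmark picks ρ₁ per task. Standardisation and selection
never see held-out data (z-scoring is re-fit per fold — a deliberate
leakage-avoiding refinement over fitting one global scale). MAPE is pooled
over all out-of-fold predictions (primary) and also reported as the mean of
per-fold MAPEs.

A structural note: because ‖W‖₁ is elementwise, the multi-task objective
decouples across tasks at fixed penalties, so with a regularised
single-task benchmark the entire multi-task effect lives in the shared
hyperparameter selection (one ρ₁ estimated from twice the data). On
synthetic cohorts with a shared sparse support this yields a small,
consistent edge in mean out-of-fold MAPE for both outcomes, but per-cohort
win rates hover near 55-60% — joint selection stabilises, it does not
transform. A larger margin would require either task-coupling penalties
(group sparsity) or an unregularised single-task benchmark, both outside
this package's scope.

## Synthetic cohorts

Cohorts emulate the regime the multi-task model targets: six
standard-normal features (stand-ins for the z-scored movement metrics), a
single random support of 3 features shared by both outcomes with
task-specific positive magnitudes (scale 1.5), MMSE = 24 − Xw + ε
(ε SD 2 points, clipped to [0, 30]) and TUG = 12 + Xw′ + ε′ (ε′ SD 1.5 s,
floored at 3 s), so active features depress cognition and slow mobility
together. Offsets and noise SDs are plausible for a mildly impaired
older-adult cohort (MMSE test-retest error ≈ 2 points; TUG ≈ 1-2 s).
Covariates (age 75 ± 6, sex Bernoulli 0.5, BMI 25 ± 4) are drawn
independently of the features, so they exercise the partial-correlation
machinery without confounding.

## Determinism and problem sizes

Every generator is a pure function of its spec (seed included), with
independent deterministic streams per stage; pipeline outputs are
byte-reproducible from (inputs, config, seed), and every run's report
carries a provenance block (version, config hash, seed). The default
experiment sizes — 100 trials for correction efficacy, 100 textures for
flow accuracy, 20 random problems for solver optimality, 60 cohorts in the
acceptance script (200 in the test suite) for the MTL/STL comparison — are
large enough that the reported means are stable to well under their
decision margins while keeping a full run in the low minutes on one CPU.

## Known limitations

* The generator's kinematics are piecewise-linear; real angle traces have
  rounded reversals, tremor, and amplitude drift. Duration metrics are
  robust to these, but the segmentation defaults (10° prominence) have only
  been validated on synthetic shapes.
* The flow stage assumes locally rigid, small motion; real motion blur at
  the wrist violates the brightness-constancy assumption in exactly the
  frames where the detector fails, so real-world substitution accuracy will
  be worse than the synthetic figures.
* Correction handles isolated errors by design; bursts of consecutive
  detector failures are accepted (capped substitution runs) and will leak
  into the angle sequence.
* The clinical association and regression stages are validated against
  formula oracles and synthetic cohorts only; no claim is made about
  predictive performance on real patients.
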