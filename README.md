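# dtuemp

Video-derived **dual-task upper-extremity motor performance** (DTUEMP):
tools to turn per-frame elbow/wrist keypoints from a short repetitive elbow
flexion-extension test into duration metrics, validate them against a
reference measurement system, and jointly predict cognitive (MMSE) and motor
(TUG) scores with an ℓ1-regularised multi-task linear model.

The intended users are movement-analysis and digital-biomarker researchers
who already have a pose estimator (any network that emits per-frame elbow and
wrist coordinates) and want the downstream pipeline: robust angle sequences,
phase segmentation, agreement statistics, and outcome regression — plus a
synthetic-trial generator so every stage is testable without recordings.

## The method

A subject flexes and extends the elbow as fast as possible for 20 s at
30 FPS while counting backwards. Per frame, the forearm orientation is the
rotation angle of the wrist-elbow line,
θ<sub>t</sub> = atan2(−(y<sub>w</sub>−y<sub>e</sub>), x<sub>w</sub>−x<sub>e</sub>).

**Coordinate correction.** Pose networks occasionally misplace the
fast-moving wrist in isolated frames. Lucas-Kanade optical flow predicts
each joint one frame ahead from the last *accepted* coordinate; when the
network observation disagrees with that prediction by more than a threshold
(default 0.25 × median forearm length) and the previous frame was not itself
a substitution, the flow prediction is accepted instead. The cap of one
consecutive substitution per joint encodes the working assumption that the
network and the flow do not both fail in two consecutive frames.

**Metrics.** Local maxima/minima of the corrected angle sequence split it
into alternating phases — maximum→minimum is extension, minimum→maximum is
flexion — and the six DTUEMP metrics are the mean and sample SD of flexion,
extension, and full-cycle durations.

**Agreement and clinical association.** Spearman ρ<sub>s</sub> (cut-offs
0.35 / 0.67), ICC(2,1) (two-way random effects, absolute agreement; cut-offs
0.50 / 0.75 / 0.90), and partial correlation controlling age, sex, and BMI,
with a fractional-rank inverse-normal (Blom) transform for non-normal
outcomes.

**Outcome regression.** With task designs X<sub>i</sub> and outcomes
y<sub>i</sub>, the weight matrix W minimises

    Σ_i ‖X_i w_i − y_i‖² + ρ₁‖W‖₁ + ρ_L2‖W‖_F²

solved by monotone FISTA; z-scored metrics are the predictors. Five-fold
cross-validation with an inner 3-fold grid search over ρ₁ scores the
multi-task model against a single-task Lasso benchmark by MAPE
(cut-offs 5% / 25%).

## Worked example

Simulate a 20-second trial whose detector misplaces the wrist by 80 px in
5% of isolated frames, then run the full pipeline:

```sh
printf 'outlier_rate: 0.05\njitter_sd_px: 1.0\n' > trial.yaml
dtuemp simulate trial --out sim --config trial.yaml --seed 11
dtuemp run --keypoints sim/keypoints.csv --flow sim/exact_flow_wrist.npy --out out
```

which prints

```
flex_mean_s=0.9889 flex_sd_s=0.0957 ext_mean_s=0.9900 ext_sd_s=0.0903 cycle_mean_s=1.9778 cycle_sd_s=0.1915
```

The trial was generated with 2.0 ± 0.2 s cycles, so flexion and extension
each average ≈ 0.99 s and a full cycle ≈ 1.98 s, with the cycle-to-cycle SD
near 0.19 s. `out/report.json` records that 32 wrist frames were substituted
from the flow prediction (disagreement gate 25.0 px): the duration metrics
are identical to what the same trial yields with no injected outliers — the
correction stage fully absorbs isolated detector errors.

The same library surface is available in Python:

```python
from dtuemp import TrialSpec, generate_trial, render_keypoints, run_pipeline
trial = generate_trial(TrialSpec(outlier_rate=0.05, seed=11))
```

For the regression stage:

```sh
dtuemp simulate cohort --out coh --seed 11
dtuemp mtl --cohort coh/cohort.csv --model mtl --seed 1
```

```
MTL mmse: MAPE=11.24% (moderate)
MTL tug: MAPE=14.74% (moderate)
```

MAPE here is the pooled out-of-fold error of the jointly fitted model on a
20-subject synthetic cohort; "moderate" is the 5-25% accuracy band.

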