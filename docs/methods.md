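# Methods

This note documents the models, parameter choices and numerical decisions in
`pupiladapt`, and what the synthetic-data tests do and do not establish about
real data.

## Task and plant model

Reaches are forward center-out movements of amplitude 12 cm (abrupt
configuration) or 10 cm (switching/gradual configurations), with a prescribed
minimal-jerk forward profile of default duration 600 ms.  Coordinates: x
rightward-positive, y toward the target; a clockwise (CW) field has `B > 0`
and pushes rightward during forward motion (`f_x = B·v_y`, `f_y = −B·v_x`).

The lateral dynamics are a 1 kg point mass driven by the curl-field force,
the learner's feedforward compensation (`−B̂·v_y`, opposing the anticipated
field), optional PD feedback toward the straight path (defaults 100 N/m,
10 N·s/m) and Gaussian motor-force noise (default SD 0.01 N), integrated with
RK4 at 5 substeps per 200 Hz sample.  No plant is prescribed by the task
definition itself; these values produce millimetre-scale perturbed errors
with a clean signal-to-noise structure, which is what the downstream
statistics consume (all error-driven quantities in the model are ratios, so
the absolute error scale is immaterial).

Channel trials replace the field with a spring–damper (7 000 N/m and
30 N/(m·s⁻¹), or 2 500 and 25).  The recorded channel force is the
feedforward compensation plus the PD feedback force on the wall, signed so
that compensating the CW field is positive.  With feedback on, the feedback
term responds to the µm-scale static deflection and attenuates the readout by
`kp/(kc+kp)` (≈1.4 % at the 7 000 N/m stiffness); the analytic
learning-index identity (learning index = B under full compensation) is
therefore exact only with feedback gains zero, which is how the identity
tests and the acceptance script run.  Cohort simulations keep feedback on;
the attenuation is irrelevant to every statistic computed on cohorts.

Event markers use the online 3.5 cm/s velocity trigger; analysis-grade reach
segmentation uses the 10 %-of-peak threshold on the smoothed tangential
speed.  RT and MT come from the online markers.

## Perturbation schedules

Printed trial numbers index *reaching* trials cumulatively across blocks;
light-reflex calibration trials carry a separate index.  The abrupt design
has five blocks of 59/59/59/44/59 session trials, the first and last two of
each being light-reflex trials (55/55/55/40/55 reaching trials); the field
(B = 0.15) spans reaching trials 66–175.  The switching designs are five
blocks of 50 reaching trials with the CW/CCW sets fixed per subgroup
(B = ±0.12); the gradual designs ramp B by 5 % of 0.12 every 11 trials from
the 16th trial of block 2, with removal at the 11th trial of block 7 (or a
constant-channel final block in the no-removal variant).

Channel trials occupy 20 % of reaching trials, one per 5-trial cycle at a
seeded random position, with a minimum gap of one trial and never on a
field-transition trial (so transitions remain kinematically observable).
Change points are trials where the field's sign category flips, strictly
inside a block and not clamped by a channel; gradual 5 % increments do not
flip the sign category and are not change points.

## Generative pupil model

Latent state per participant: a tonic level (percent of the light-reflex
range) and a running error expectation.  Per reaching trial, with observed
absolute lateral error `o`:

```
s       = min(o / max(expected, floor), cap)
tonic'  = floor_t + decay·(tonic − floor_t) + gain_t·max(s − 1, 0) + bump·[block start]
expected' = expected + habituation·(o − expected)
```

Defaults: tonic floor 30 %, decay 0.85 per trial, tonic surprise gain 2 % per
unit excess surprise, novelty bump 8 % at block starts, habituation rate 0.3,
error floor 10 µm, surprise cap 6.  The cap is a deliberate saturation: the
baseline error under motor noise alone is µm-scale, so the first perturbation
would otherwise yield a surprise ratio of ~30 and push the tonic latent past
100 % of the light-reflex range; bounded arousal responses are the realistic
regime.  Channel trials update the latents neutrally (observed error set to
the current expectation) because the channel clamps the kinematic error.

The trace for a trial maps `tonic + gain_phasic·s·h(t − onset)` onto mm via
the participant's light-reflex range (defaults 2–6 mm), where `h` is a
gamma-family impulse response with shape 10.1 and peak 930 ms after movement
onset, normalized to unit peak; the peak time places the 300–700 ms
dilation-velocity window on the rising phase.  AR(1) noise (coefficient 0.95,
stationary SD 0.5 %) and a trial-level tonic jitter (SD 1.5 %) are added;
blink intervals are drawn at 0.2 events/trial and overwritten with a
tracker-loss artifact value.  RT and MT increase with the tonic latent
(5 ms/% and 2 ms/%), which yields the early-block slowing that the set-break
analysis measures.  The recorded trace spans 2 s of the pre-go hold (the only
part any analysis consumes is the final 1 s baseline window; the tonic latent
is per-trial, so recording the full variable wait would add data without
information), the reaction and movement, and 1.8 s after movement offset.

Light-reflex trials follow first-order dynamics (τ = 250 ms) from the
resting diameter toward the dilation peak (dark, 1.5 s stimulus) or the
constriction trough (bright), then recover; measurement noise defaults to
0.01 mm so raw-trace extrema are essentially unbiased estimators of the
limits.

Recall-report vectors (for the median-split analysis) are generated with a
per-block presence probability that is logistic in the participant's mean
tonic latent for that block, so the split has a recoverable ground truth.

## Preprocessing

All conditioning follows one chain per trial, never across trials: blink
margins of 100 ms before and 150 ms after each blink are discarded and filled
with monotone piecewise-cubic (pchip) interpolation through surviving
samples (nearest-value extension, flagged, when a blink touches a trace
edge); kinematics, forces and gaze are smoothed with a 35 ms-FWHM Gaussian
and pupil with 235 ms, using reflection padding (edge policy chosen to avoid
attenuating baseline estimates; the Gaussian is truncated at 8σ so impulse
responses match the closed form to 1e−9); gaze is converted to visual angle
(atan of display offset over eye distance: 160/350/440 mm per configuration)
before saccade detection; angular velocity comes from a second-order
Savitzky–Golay filter with a 55 ms frame followed by a first difference
(velocity sample i is the derivative at the midpoint of samples i, i+1);
saccades are maximal runs of angular speed (Euclidean norm of the two axes)
at or above 30 deg/s, with runs closer than 10 ms merged.  Pupil is
normalized to percent of the light-reflex range (trough→0, peak→100; the
trough anchors 0 %), with per-block extrema averaged over blocks.

Trial features: baseline pupil is the mean normalized diameter over the final
1.0 s before the go cue (the averaging span within the variable wait is not
dictated by the task; it is a config knob).  Dilation velocity is the mean of
the pupil-velocity trace over 300–700 ms after movement onset, and is missing
whenever any detected saccade overlaps the movement period
[onset, offset].  PVE is the signed lateral deviation at peak tangential
speed; EPE the hand-target distance at offset; PVE and learning index are
sign-flipped for counter-clockwise-field participants.

## Statistics

*Running tests.*  Per-frame two-sided paired t on subject-level mean traces,
with pairwise deletion of subjects missing a frame; zero-variance nonzero
differences report the distribution-limit p of 0 and are flagged; identical
conditions give t = 0, p = 1.  Holm–Bonferroni and Benjamini–Hochberg
rejection masks use the standard inclusive inequalities, implemented
directly (vectorized) and cross-checked against statsmodels in the tests.

*Cluster test.*  Clusters are maximal runs of frames with |t| above the
two-sided p = 0.01 t quantile; the statistic is the signed sum of t in the
run, positive and negative clusters separate, compared against the max-|mass|
sign-flip null.  For n ≤ 12 subjects all 2ⁿ sign patterns are enumerated
(removes Monte-Carlo error where cheap); otherwise 10 000 sampled flips by
default (the permutation count is recorded in the output).  The add-one
estimator (1 + #{null ≥ obs})/(n + 1) keeps p values valid and nonzero.
Frames missing any subject are dropped from cluster formation, not imputed.

*Two-state fitting.*  The parameter vector is optimized in a transformed box
(`A_s = A_f + (1−A_f)·u`, `B_f = B_s + (1−B_s)·w`) so the retention/learning
order constraints hold by construction; 20 seeded multi-starts by default,
tolerances 1e−14.  Flat series pin the learning rates at the lower bound and
are flagged unidentifiable.  The washout band is the 2.5/97.5 percentile of
participant-resampled refits simulated forward; resamples with fewer than two
unique participants are redrawn.  The %-change transform maps each phase to
0 at its own start level (mean of the first 2 samples) and 100 at its plateau
(mean of the last 5 cycle entries or 25 trials), which flips a decaying
washout series into a rising index; latency at threshold x is the index of
the n-th exceedance (n = 10 for trial-wise kinematic error, 3 for cycle-wise
learning index).

*Mixed models.*  The error→pupil prediction test, the change-point trend
model and the subgroup×block model delegate to statsmodels MixedLM (REML).
Group (3 levels) and per-block cycle slopes are treated as fixed effects:
crossed random effects with so few levels are weakly identified and MixedLM
cannot express them under participant grouping.  The change-point model has
random intercept and change-point-number slope per participant, with the
slope's contribution assessed by a REML likelihood-ratio test against the
intercept-only structure (χ², 2 df, conservative).  Singular fits fall back
to simpler structures and are flagged.  The subgroup model is
interaction-only (per-block subgroup contrasts, no subgroup main effect),
with per-block Wald p values corrected by both Holm–Bonferroni and
Benjamini–Hochberg; median-split ties go to the high group, and the per-block
2×2 χ² uses no continuity correction (both choices exposed as options).

## What the synthetic tests show — and don't

The generator produces the qualitative phenomena by construction: a
perturbation-evoked dilation-velocity cluster, a tonic baseline increase on
the trial after the first perturbation, declining change-point response
amplitudes under habituation, block-start baseline/RT/MT elevation, and
recall reports coupled to tonic uncertainty.  Passing tests therefore
establish that the pipeline *recovers known structure at realistic noise
levels and sample sizes* (e.g. n = 28 for the end-to-end checks) and that its
inferential procedures are calibrated (cluster-test type-I error at the
nominal 0.05 over 500 null datasets; bootstrap washout bands covering
truth-generated group-mean trajectories in cohorts with heterogeneous
learner parameters — with homogeneous participants the participant-resampling
band is tight by construction and nominal coverage of a noisy realized mean
is not expected).  They do not establish anything about effect sizes in real
pupillometry, about pupil foreshortening or other optical artifacts the
generator omits, or about violations of the two-state form in real learners.

Problem sizes in the default test run are the package's own choices: the
end-to-end cohort uses the full 28 participants on the complete abrupt
schedule, the zero-gain controls use three 28-participant cohorts of the
design's first two blocks (the contrast consumes only those trials), recovery
suites use 100 replicates, and permutation/bootstrap counts in tests are
500–2 000/150–200 (the pipeline defaults remain 10 000 and 1 000).
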