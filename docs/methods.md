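# Methods

This note documents the models, estimators, numerical choices and
simulation conditions implemented in `avdecode`, and what the test suite
does and does not establish about real data.

## Forward model and decoder

The observed sensor data at one timepoint are modelled as
`B = WC + E`, with `B` (m sensors × n presentations), `C` (5 channels ×
n) the hypothesised channel activities, and `W` (m × 5) the
sensor-loading weights. Channel k's tuning curve is
`max(0, cos(2π(θ − c_k)/λ))^p` with centres `c_k` evenly spaced over
[−15°, +15°], exponent `p = 5`, and spatial period `λ = 60°` by default.
The period is a genuine free parameter: 60° gives each half-wave a 30°
support spanning the stimulus range, and the 5×5 matrix of channel
responses at the five stimulus azimuths is then well conditioned
(condition number ≪ 10⁶), which an invariant test guards for any
configured period. Location space is treated as linear (azimuth is not
circular).

Weights are estimated by ordinary least squares, `W = BCᵀ(CCᵀ)⁻¹`.
The decoder is the noise-covariance-weighted inverse
`D = (WᵀΣ⁻¹W)⁻¹WᵀΣ⁻¹`, which reduces to the Moore–Penrose pseudoinverse
when Σ ∝ I; both estimators are verified against brute-force numerical
optimisers in the tests. Σ is the sample covariance of the residuals
`E = B − WC` shrunk toward its diagonal with the analytic
(Schäfer–Strimmer) intensity `λ* = Σ Var(s_ij) / Σ s_ij²` over
off-diagonal entries, clipped to [0, 1]; shrinkage keeps Σ positive
definite even when trials per fold are scarce, and a tiny ridge
(10⁻¹⁰ of the largest variance) guards exactly-zero-variance sensors.
The shrinkage intensity is computed from sufficient statistics rather
than the (sensors × sensors × trials) tensor of outer products, so
batched per-timepoint estimation stays within memory at full scale.

Cross-validation is 10-fold (configurable), stratified by stimulus
location and seeded; models are fit per timepoint and applied to the same
timepoint of held-out trials, so every trial is decoded exactly once by a
model that never saw it. In the noiseless limit the reconstructions equal
the design-matrix columns to 10⁻⁶, which the acceptance suite asserts.

Per-sensor information maps treat time samples inside a window (default
150–250 ms) as features of a single-sensor model. A single sensor's
expected weight matrix is rank one in channel space (one tuning profile
times one temporal kernel), so the plain GLS inversion only amplifies
noise; the per-sensor decoder therefore uses a heavy relative Tikhonov
term (`ridge = 10`, i.e. effectively a trace-normalised matched filter),
whose expected score is the bounded quadratic form
`mᵀ[Σ_θ c(θ)(v̂(θ) − v̄)ᵀ]m / ‖m‖²` in the sensor's tuning weights `m` —
a closed form the tests verify at rank correlation > 0.9.

## Decoding metrics

*Accuracy* (arbitrary units): each ideal channel vector (the basis
response at one stimulus location) is mean-centred across channels and
unit-normalised; a trial's score is the projection of its reconstruction
onto the true location's ideal vector minus the mean projection onto all
locations' ideal vectors. Centring makes the score invariant to constant
offsets across channels and places chance exactly at 0, matching
against-zero group tests. Cosine similarity is a configurable
alternative reading of "similarity"; the centred projection is the
default because its chance level is exact.

*Sensitivity* (d′): the reconstruction is reduced to a location estimate
by the rectified centroid `Σ_k c_k max(0, z_k) / Σ_k max(0, z_k)` (0,
flagged, if all activities are non-positive); centre-location trials are
omitted; with "right" as signal, `H = P(est > 0 | θ > 0)`,
`F = P(est > 0 | θ < 0)`, proportions clipped to [1/(2N), 1 − 1/(2N)],
and `d′ = Φ⁻¹(H) − Φ⁻¹(F)`, computed per participant per timepoint.

## Super-additivity baselines

The MLE prediction `d′_AV = √(d′_A² + d′_V²)` is computed per participant
and timepoint from that participant's unisensory timecourses. The
aggregate baseline pairs auditory and visual trials randomly (seeded)
within each stimulus location — subsampling to the smaller count — and
concatenates each pair across sensors; the resulting 2m-sensor condition
contains both unisensory patterns with independent noise but no
interaction. The contrast `d′_AV − baseline` is tested one-sided
(AV > baseline), since the super-additivity hypothesis is directional.

Two properties make these baselines meaningful, and both shaped the
synthetic generator (below): the aggregate and MLE baselines must agree
with each other under an exactly additive signal, and the contrast's
false-positive rate must be controlled. Note that the MLE prediction
computed from noisy d′ estimates is biased upward by estimation noise
(E√(x²+y²) > √(Ex² + Ey²) − var terms); at the simulation scales used
here the residual disagreement between the two baselines is under 10%,
which is the consistency bound the acceptance suite asserts.

## Cluster statistics

Pointwise paired or one-sample t statistics are thresholded at the
two-sided 5% critical value (the cluster-forming alpha is not a
corrected quantity; 0.05 is the conventional default); maximal contiguous
runs of same-sign supra-threshold samples form clusters whose mass is the
summed t. Family-wise control compares each observed cluster's mass with
the 95th percentile of the maximum-mass null of the matching sign.

Two nulls are implemented, and the distinction matters:

* **Sign-flipping** (participant-level) for paired contrasts — ERP
  additive contrast, AV vs MLE, AV vs aggregate. Difference timecourses
  between identically-distributed estimates are symmetric about zero
  under the null, which is exactly the condition sign-flip tests require.
  Calibration is verified by simulation (false-positive rate ≤ 0.075 at
  nominal 0.05 over 200 experiments). When 2^n ≤ the requested
  permutation count the exact enumeration over all sign patterns is used.
* **Label permutation** for decoding-vs-chance. Cross-validated decoding
  accuracy at chance is *not* symmetric: the inversion of noise-fitted
  weight matrices produces a left-skewed per-participant distribution
  (measured skew ≈ −1 at 8 sensors / 200 trials), and a sign-flip
  surrogate then inflates the positive false-positive rate several-fold.
  The implemented null re-decodes each participant's data under shuffled
  location labels (a bank of permuted timecourses per participant) and
  assembles group-level null samples by drawing one bank entry per
  participant — exact at the participant level by construction, and
  measured at a 2% family-wise rate at nominal 5% in calibration runs.
  The test is one-sided (above-chance decoding is directional).

The permutation t statistics are computed from sufficient statistics
(per-timepoint sums of squares are sign-invariant), and per-permutation
maximum cluster masses are extracted with a vectorised run-length scan,
so 5000 permutations over a few hundred timepoints take well under a
second.

## Behavioural analyses

Psychometric functions are maximum-likelihood cumulative Gaussians
`p(rightward | x) = lapse/2 + (1 − lapse)Φ((x − PSE)/σ)` with the lapse
fixed (default 0); sensitivity is the slope at the PSE,
`(1 − lapse)/(σ√(2π))`. The fit is a direct Nelder–Mead likelihood
optimisation in (PSE, log σ) and is cross-checked against probit GLM
regression. The MLE-predicted audiovisual slope is
`√(slope_A² + slope_V²)`, which follows from slope ∝ 1/σ and
`1/σ²_AV = 1/σ²_A + 1/σ²_V`.

The EEG-session task (which side received more of the 20 stimuli) is
scored by d′ with tie sequences excluded. The Wilcoxon signed-rank test
drops zero differences, mid-ranks ties, and uses the continuity-corrected
normal approximation (the convention under which a Z value is defined);
it is cross-checked against an exact small-n enumeration and scipy.
Neurobehavioural correlations are Spearman's rho between behavioural d′
and mean decoding d′ over 150–250 ms, with no outlier rejection.

## Synthetic data generator

The generator's defaults mirror the study conditions: 3 conditions
(A, V, AV); EEG session 12 blocks × 10 trials × 20 presentations = 2400
presentations per condition over azimuths {−15, −7.5, 0, 7.5, 15}°;
behavioural session 384 two-interval forced-choice targets per condition,
48 at each of 8 evenly spaced azimuths in [−15°, 15°]; 64 sensors; 512 Hz
epochs from −100 to 500 ms (the half-open window yields 307 samples).

Each presentation evokes:

* a **tuned component** `M_cond c(θ) a(t)` — channel activities from the
  same basis the analysis assumes, projected through smooth random
  sensor loadings and modulated by a Gaussian temporal kernel peaking at
  180 ms (σ 30 ms), matching where location information peaks in scalp
  recordings. The auditory and visual modalities project through
  *distinct* loading matrices `M_A`, `M_V` (as on a real scalp, where
  auditory location information sits over temporal and visual over
  occipital sensors). The audiovisual tuned signal is
  `g_A M_A + g_V M_V + γ(M_A + M_V)/2` applied to `c(θ)`: with γ = 0 it
  is exactly the sum of the unisensory tuned signals, which makes the
  additive regime both ERP-additive and MLE-consistent for decoding —
  distinct topographies are what make `√(d′_A² + d′_V²)` (rather than
  `d′_A + d′_V`) the correct additive bound;
* an **untuned evoked component** identical across locations, peaking at
  100 ms (σ 20 ms) — the ERP. Its topography is shared across the cohort
  (a common cortical generator), so group-level ERP statistics behave
  like grand averages; its audiovisual amplitude defaults to the sum of
  the unisensory amplitudes (additive ERP regime, independently
  configurable to inject ERP-level super-additivity);
* **sensor noise** drawn per sample from N(0, Σ) with a smooth spatial
  correlation kernel (length 0.2 in normalised sensor distance),
  optionally AR(1) in time.

The MLE observer estimates each stimulus location as `θ + N(0, σ²_m)`
with `σ²_AV = σ²_A σ²_V/(σ²_A + σ²_V)`; 2IFC responses compare the
target and reference estimates, and the EEG-session response is the
majority of per-stimulus sign judgements (ties guessed) — how human
observers integrate 20 sequential stimuli into one judgement is unknown,
so the majority rule is a configurable policy, not a claim. Default observer noise
(σ_A = 13°, σ_V = 20°) produces behavioural slopes in the 0.02–0.04
per-degree range typical for this task. Gaze traces are fixation jitter
(SD 0.1°) plus optional step saccades, for exercising the 3.75°
exclusion rule.

All randomness flows from one seed through `numpy` seed sequences; equal
seeds give bit-identical output end to end, including the file-based
pipeline.

What the generator does *not* emulate: biophysical head volume
conduction, blinks/line noise/muscle artifacts, trial-to-trial latency
jitter, or learning effects. Passing tests therefore establish that the
estimators and statistics behave correctly under the assumed linear
model with known ground truth — not that real recordings satisfy those
assumptions.

## Simulation scales used by the test and acceptance suites

Full-scale cohorts (41 participants × 2400 presentations × 64 sensors ×
307 samples) are the generator's defaults but are far larger than needed
to exercise the estimators, so the quantitative suites run a reduced
study whose conditions were fixed once, before the calibration outcomes
were read off at final scale:

* **Calibration experiments** (baseline consistency, false-positive
  rate, super-additivity recovery): 24 synthetic participants, 8
  sensors, 128 Hz epochs over [−0.05, 0.35] s, 200 presentations per
  condition, 5-fold CV, noise σ = 3 (unisensory decoder d′ ≈ 1, safely
  inside the unclipped range), 1000 permutations, 200 null / 50 power
  experiments.
* **Chance calibration**: 12 participants, signal-free epochs (tuned and
  evoked gains 0, noise σ = 1), 100 presentations per condition, banks
  of 12 label permutations per participant, 200 null runs.
* **Preprocessing / unit tests** run on toys of a few trials and sensors.

At these scales the whole suite completes in roughly ten minutes on one
CPU core.

## Known limitations

* The decoding-vs-chance label-permutation null costs one full re-decode
  per bank entry; the pipeline default (20 per participant) is a
  granularity/cost compromise.
* The MLE-prediction upward bias from noisy d′ estimates is inherent to
  the method (it affects real-data analyses equally); at low SNR it makes
  the AV-vs-MLE contrast conservative.
* Psychometric lapse is fixed, not estimated; strongly lapsing observers
  bias σ upward.
* The aggregate baseline doubles the sensor count, so its covariance
  estimate needs roughly twice the training trials for comparable
  conditioning; with very few trials per location its d′ is biased low.
* The stereo renderer applies only the relative interaural delay and
  inverse-distance gains; it is a cue model, not an HRTF simulation.
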