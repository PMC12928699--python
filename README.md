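# avdecode

Inverted encoding of multichannel EEG responses to audiovisual stimuli,
with super-additivity testing against maximum-likelihood and aggregate
additive baselines.

## The scientific problem

When a sound and a flash occur together at the same place and time, single
multisensory neurons often respond *super-additively* — more than the sum
of their auditory and visual responses. In human EEG, however, the evoked
potential to an audiovisual stimulus usually looks merely additive. One
explanation is that the interaction lives in the *pattern* of activity
across the scalp rather than in net amplitude, so univariate ERP analyses
cannot see it.

`avdecode` implements the multivariate analysis that tests this idea, for
researchers working on multisensory integration or EEG decoding:

1. **Inverted encoding model (IEM).** The sensor pattern evoked by a
   stimulus at azimuth θ is modelled as a weighted sum of five idealised
   location channels, `B = WC + E`, where each channel's tuning curve is a
   half-wave rectified sinusoid raised to the fifth power with centres
   evenly spaced over ±15°. Weights `W` (sensors × 5) are estimated per
   timepoint by least squares; the decoder inverts the model taking the
   residual noise covariance Σ into account,
   `D = (WᵀΣ⁻¹W)⁻¹WᵀΣ⁻¹`, with Σ estimated by analytic shrinkage toward
   its diagonal. Reconstruction is 10-fold cross-validated, stratified by
   location, so every trial is decoded by a model that never saw it.
2. **Decoding metrics.** Reconstructions are scored as *decoding accuracy*
   (projection onto the centred, unit-normalised ideal channel vector of
   the true location minus the mean projection over all locations; chance
   is exactly 0) and *decoder sensitivity* d′ = Φ⁻¹(H) − Φ⁻¹(F) from
   left/right classification of the rectified-centroid location estimate,
   with centre-location trials omitted and proportions clipped to
   [1/(2N), 1 − 1/(2N)].
3. **Super-additivity test.** Audiovisual sensitivity is compared against
   two linear baselines: the MLE prediction
   `d′_AV = √(d′_A² + d′_V²)` and an *aggregate* condition built by
   matching auditory and visual trials within location and concatenating
   them across sensors. AV exceeding both indicates a non-linear
   multisensory interaction.
4. **Statistics.** Timecourse comparisons use mass-based cluster
   permutation correction (pointwise t, summed-t cluster mass, max-mass
   null at the 95th percentile). Paired contrasts use participant-level
   sign flipping; decoding-vs-chance uses a label-permutation null built
   from re-decoded shuffled labels. Behavioural sessions are summarised by
   maximum-likelihood cumulative-Gaussian psychometric fits (sensitivity =
   slope at the PSE), Wilcoxon signed-rank tests, and Spearman rank
   correlations between decoding and behaviour.
5. **Synthetic data.** A generator reproduces both session designs
   (two-interval forced choice with 384 targets over 8 azimuths;
   EEG sequences of 20 stimuli over 5 azimuths, 2400 presentations per
   condition), an MLE observer (σ²_AV = σ²_A σ²_V / (σ²_A + σ²_V)), gaze
   traces for the 3.75° eye-movement exclusion rule, and multichannel
   epochs with known tuned gains and a controllable non-linear audiovisual
   interaction γ — so every stage has a parameter-recovery test surface.
   Spatially localised stereo tones (ITD/ILD from ear-to-source path
   lengths) can be rendered and written to WAV.

## Worked example

Simulate a 24-participant cohort whose audiovisual tuned gain is twice the
sum of the unisensory gains (a strong super-additive interaction), decode
all conditions, and test AV sensitivity against the MLE prediction:

```python
import numpy as np
from avdecode import simulate_cohort_dprimes, mle_dprime, superadditivity_contrast

sim = dict(n_sensors=8, sample_rate_hz=128.0, epoch_window_s=(-0.05, 0.35),
           noise_sigma=3.0, gamma=2.0)  # AV tuned gain = 2 x (gA + gV)
d, times = simulate_cohort_dprimes(n_participants=24, sim_kwargs=sim,
                                   n_blocks=2, k=5, seed=7)
pred = mle_dprime(d["A"], d["V"])
print("peak group-mean d': A=%.2f  V=%.2f  AV=%.2f  MLE pred=%.2f  aggregate=%.2f"
      % tuple(x.mean(axis=0).max() for x in (d["A"], d["V"], d["AV"], pred, d["AGG"])))
diffs, res = superadditivity_contrast(d["AV"], pred, n_perm=1000, seed=7, times=times)
for c in res.significant_clusters:
    print("super-additive cluster: %.0f-%.0f ms, mass %.1f, p=%.3f"
          % (1000 * c.start_time, 1000 * c.end_time, c.mass, c.p))
```

Output:

```
peak group-mean d': A=0.87  V=1.05  AV=2.54  MLE pred=1.38  aggregate=1.44
super-additive cluster: 130-231 ms, mass 77.7, p=0.000
```

Unisensory decoding peaks near d′ ≈ 1; the MLE prediction and the
aggregate baseline agree with each other (≈1.4), as they must when the
baselines are consistent; the audiovisual condition far exceeds both, and
the one-sided cluster test localises the super-additive interval around
the 180 ms information peak. With `gamma=0.0` the AV curve instead falls
on the baselines and no cluster survives.

The full file-based pipeline (simulation → preprocessing → ERP → decoding
→ fusion → behaviour → statistics → report) is driven by a JSON config:

```bash
avdecode all --config config.json --out results/
```

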