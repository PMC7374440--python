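# Methods

## Scope

`myocoh` implements the computational core of an EMG-driven neurofeedback
protocol for severe chronic stroke, exercised end-to-end on synthetic
EMG/EEG whose ground truth is known analytically. Three method families
are covered:

1. an **extensor-ratio biofeedback engine** with an adaptive difficulty
   staircase (the training task);
2. a **static-hold tracking assessment** scored by the median absolute
   deviation (MAD) of a feedback cursor from a trapezoid target;
3. **corticomuscular coherence statistics**: pooled magnitude-squared
   coherence with an analytic confidence limit, Fisher-Z pre/post
   difference spectra, and Stouffer composite Z per frequency band.

Hardware acquisition, VR rendering and clinical instruments are out of
scope; bad-channel handling is explicit exclusion lists rather than
automated artifact reconstruction.

## Signal conditioning

EMG is band-passed 15–450 Hz (Butterworth, zero-phase by default). Two
envelopes are used, matching their distinct purposes:

* **rectified moving average** (`emg.moving_envelope`) — the real-time
  feedback quantity. The window is *causal* (trailing), because the
  original feedback loop ran in real time and could not see the future;
  samples earlier than one full window average over what is available
  rather than padding with fabricated data. The training task uses a
  480 ms window emitted at 250 Hz; the static-hold cursor uses a 1 s
  window. Whether the original 480 ms window was causal or centered is
  not documented; causal is assumed for both, for consistency.
* **Hilbert analytic magnitude** (`emg.hilbert_envelope`) — the offline
  envelope used for coherence, computed after the 15–450 Hz band-pass and
  then standardized to zero mean and unit variance.

Normalization is either division by the amplitude recorded during a
maximal power grip (units: fraction-of-maximum) or a Z-score against a
reference session's mean and SD. EEG preprocessing is a 6th-order
zero-phase Butterworth band-pass 5–100 Hz followed by common-average
re-referencing over the retained channels. "6th-order zero-phase" is read
as a 6th-order design applied forward-backward (effective 12th-order
magnitude), the common convention in offline EEG work.

## Training task and staircase

The extensor ratio is `ER = E / (E + F)`, where `E` and `F` are the
summed grip-normalized envelope amplitudes of the extensor (ECR, ECU) and
flexor (FCR, FCU) groups. Group sums are expressed as fractions of the
group's own maximum (sum of normalized channels / channel count), which
makes "30% of the maximal summed activity" read directly as 0.30. ER is
undefined (NaN) when total activity is below a floor of 1% of maximum —
this avoids 0/0 at rest; the floor is configurable.

A 5 s movement-attempt trial succeeds when, for 2 s *contiguously*, the
extensor sum exceeds 0.30 and ER exceeds the adaptive threshold
("maintain for 2 s" is read as continuity; a cumulative variant is
available via `FeedbackParams(contiguous=False)` but off by default).
The ER threshold starts each session at 0.5 and moves ±0.3 within
[0.3, 0.97] after three consecutive successes/failures. The three-trial
counter accumulates outcomes since the last adjustment and the
*most recent three* must be homogeneous; the counter clears after every
adjustment, so a fourth consecutive success cannot trigger two
adjustments one trial apart.

## Static-hold assessment

The target is the 4 s plateau of a 6 s trapezoid at 15% of maximum; ramp
durations are not documented and default to a symmetric 1 s + 1 s. Error
per hold is the median of `|cursor − plateau_level|` over the last 3 s of
the plateau — deviation about the *target*, not about the sample median,
since the target is the stated reference. Pre/post comparison is a paired
t-test over hold pairs (hold k before vs hold k after — the only pairing
available) per participant, and over participant means at the group
level. Zero-variance difference vectors are flagged degenerate rather
than reported as infinite t.

## Coherence statistics

Coherence is estimated by Welch-averaged periodograms on 512 ms Hann
segments with 75% overlap, tiled **within** epochs so no segment
straddles a concatenation boundary (concatenating unrelated epochs would
otherwise create spurious spectra). Pooling over channel pairs or
participants extends the epoch lists, so individual- and group-level
analyses share one code path.

The 95% confidence limit for a null coherence profile is
`CL = 1 − 0.05^(1/(L−1))`. `L` is the *variance-equivalent* number of
independent segments: the raw count divided by `1 + 2·Σ_m ρ_m`, where
`ρ_m` is the squared normalized overlap correlation of the taper at lag
`m` hops (Hann at 75% overlap: factor ≈ 1.92). The literature offers
several overlap corrections; the variance-equivalent one is used because
it is exact for the estimator's variance and is reported (`L`,
`n_segments`) in every spectrum so alternates can be swapped in. Its
known small bias: the null *tail* behaves like slightly more degrees of
freedom than the variance-equivalent count, so empirical coverage of the
CL runs ≈ 95.5–96.5% rather than exactly 95%.

Pre/post change per frequency uses the Fisher transform
`FZ = atanh(√Coh)`, whose asymptotic variance is `1/(2L)` for true
coherence away from 0. The default Z statistic is

```
z = (FZ_post − FZ_pre) / sqrt(1/(2·L_pre) + 1/(2·L_post))
```

which reduces to `diff / sqrt(1/L)` when the segment counts match. A
conservative single-L mode (`min(L_pre, L_post)`) is selectable. Two
calibration caveats, verified by simulation and reflected in the tests:

* at exactly zero true coherence the `1/(2L)` asymptotic fails (the
  estimate is folded near the boundary; per-bin null SD ≈ 0.66), so null
  calibration is assessed at a nonzero common coherence (no *change*
  between sessions), where the per-bin z is standard normal;
* the Hann taper correlates neighboring frequency bins (adjacent-bin
  cross-spectral correlation ≈ 0.44) even without overlap, which inflates
  the Stouffer composite's null exceedance to ~14% at nominal 5%.
  Composite null-rate checks therefore use boxcar, non-overlapping
  segmentation, under which white-noise DFT bins are independent and the
  rate sits at ~4–5%. With the default Hann/75% settings the composite Z
  should be read as anticonservative near the threshold.

Band composites are `Σz/√n` over the bins in alpha (8–12), beta (12–30)
and gamma (30–50 Hz), significant at |Z| > 1.96.

## Synthetic data generator

The generator's job is exactness of ground truth, not physiological
realism.

* **EMG model**: `x(t) = A(t)·c(t)` with `A ≥ 0` the activation envelope
  (fraction of a fixed per-channel simulated power-grip maximum) and `c`
  a **constant-modulus FM carrier** — `cos` of a 150 Hz phase modulated
  by two slow tones with random phases. Because `|c| = 1` and its Carson
  band (~110–190 Hz) is clear of the envelope band, the Hilbert magnitude
  of `x` recovers `A` essentially exactly (relative error ≈ 5%), and the
  rectified moving average converges to `A·2/π`; the stored grip
  reference uses the same `2/π` convention, so normalized envelopes are
  exact fractions of maximum. A Gaussian-noise carrier was rejected: its
  Rayleigh envelope fluctuations inject multiplicative in-band noise that
  overwhelms the configured envelope noise and breaks the closed-form
  coherence below (realized ≈ 0.13 where 0.64 is configured).
* **Coherent pair**: a shared drive `s` (white noise band-passed to
  12–30 Hz) enters the EEG channel (`√r₁·s` + white noise) and the EMG
  envelope (`√r₂·s` + 45 Hz low-passed noise), giving in-band coherence
  `r₁r₂/((1+r₁)(1+r₂))` — e.g. 0.25 at r=1, 0.64 at r=4 — and zero out of
  band. The exact theoretical spectrum follows the realized filter
  responses and is returned with the record.
* **Training sessions** follow the 7 s rest / 5 s attempt schedule
  (default 6 blocks × 20 trials = 120 trials). Per-trial extensor
  amplitude is log-normal around `activation_level` with SD
  `0.4·(1 − agent_skill)`; flexor amplitude is `coactivation_ratio` times
  the extensor draw. Log-amplitude noise keeps amplitudes positive.
* **Static holds**: rest 4 s, then a 1–4–1 s trapezoid, 16 holds by
  default. `tracking_noise` is defined as the SD of the *post-smoothing*
  cursor deviation: the injected 2 Hz low-passed noise is pre-scaled by
  the analytic attenuation of the downstream 1 s moving average, so the
  realized cursor error has the requested SD and the mean per-hold MAD
  approaches `σ·Φ⁻¹(0.75)`.

What the generator does *not* emulate: motor-unit dynamics, line noise,
motion artifacts, electrode lift, nonstationary baselines, volume
conduction across EEG channels, or realistic patient signal-to-noise
(which the source protocol does not quantify). Passing tests demonstrate
correctness of the estimators and statistics under the stated model, not
robustness to real-recording pathologies.

## Demo pipeline and problem sizes

`run_demo` simulates the full program: pre/post static holds (MAD), pre/
post coherence records, and seven training sessions with a linear ramp of
agent skill and (downward) co-activation. Coherence during holds in the
source protocol is, in the demo, carried by dedicated coherent-pair
records per condition, since the two generators have independent
ground-truth contracts. All randomness derives from one master seed;
reports are bit-reproducible.

Default sizes (chosen as desk-scale analogues): 120 s coherence records,
16 holds, 6×20 trials × 7 sessions. The test suite uses smaller records
(31–60 s coherence, 1–2 blocks) and Monte-Carlo repetition counts
(200 replicates for null calibration, 10–20 for confidence-limit
coverage, 5 seeds for the scenario contrast) selected to keep sampling
error well inside the asserted tolerances.

## Numerical conventions

* Envelope ticks are causal: output sample k is the window ending at
  `(k+1)/rate` seconds; annotation slicing uses `(start, end]`.
* Coherence is clipped to [0, 1−10⁻¹²] before `atanh(√·)`.
* A run of m feedback samples counts as `m/rate` seconds sustained.
* Paired-t degeneracy triggers when the SD of differences is below
  10⁻¹² of the dominant scale (float rounding of identical vectors).
* Exact Spearman p-values (n ≤ 9, tie-free) enumerate all rank
  permutations, cached per n; ties or larger n fall back to the
  t-approximation with midranks.

## Known limitations

* The overlap correction for `L` is one defensible choice among several;
  CL coverage is ≈ 1 pp conservative-side high (see above).
* Stouffer composites over Hann-tapered bins are anticonservative; use
  boxcar non-overlap segmentation when calibrated null rates matter.
* The individual-level hold pairing (hold k vs hold k) is arbitrary but
  harmless under exchangeability of holds within a session.
* The drive band-pass skirt leaks a little shared power into the 8–12 Hz
  alpha edge, so strong simulated beta-band changes can also register a
  (smaller) alpha composite.
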