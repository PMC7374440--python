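# myocoh

EMG biofeedback simulation and corticomuscular coherence statistics.

After severe stroke, residual muscle activity often survives even when
overt movement does not. EMG-driven neurofeedback exploits this: surface
EMG from the forearm extensors and flexors drives a game that rewards
wrist-extensor activation *without* antagonist co-contraction, while
static-hold tracking tasks and EEG–EMG (corticomuscular) coherence
quantify, before and after training, whether muscle control and
corticospinal communication changed. `myocoh` is a tested, reusable
implementation of that computational core — the feedback engine, the
assessments and the statistics — exercised end-to-end on synthetic EMG/EEG
whose ground truth (activation profiles, co-activation ratios, EEG–EMG
coherence) is known analytically. It is aimed at researchers prototyping
or auditing EMG-biofeedback analysis pipelines.

## The quantities it computes

**Extensor ratio (the trained signal).** With `E` and `F` the summed,
grip-normalized envelope amplitudes of the extensor and flexor groups
(480 ms rectified moving window at 250 Hz):

    ER = E / (E + F)

A trial succeeds when, for a contiguous 2 s of the 5 s attempt, `E`
exceeds 30% of its power-grip maximum and `ER` exceeds an adaptive
threshold (start 0.5, steps of 0.3 within [0.3, 0.97], moving after three
consecutive successes or failures).

**Tracking error.** Per static hold, the median absolute deviation of
the 1 s-smoothed feedback cursor from the 15%-of-maximum target over the
last 3 s of each 4 s plateau; paired t-tests compare sessions.

**Corticomuscular coherence.** Magnitude-squared coherence between EEG
and the standardized Hilbert envelope of band-passed EMG, Welch-estimated
on 512 ms Hann segments with 75% overlap, pooled over epochs without
segments straddling epoch boundaries. With `L` the effective
(variance-equivalent) segment count:

    CL     = 1 − 0.05^(1/(L−1))                      (95% confidence limit)
    FZ     = atanh(√Coh)                             (Fisher transform)
    z(f)   = (FZ_post − FZ_pre) / √(1/(2L_pre) + 1/(2L_post))
    Z_band = Σ_f z(f) / √n_f                         (Stouffer composite)

Band composites over alpha (8–12), beta (12–30) and gamma (30–50 Hz) are
significant at |Z| > 1.96.

## Worked example

Run the bundled synthetic study (a "recovery" scenario: stronger shared
cortical drive and lower tracking noise after training):

```
$ myocoh demo --seed 1 --out-dir demo_out
{
 "alpha": { "z": 3.765369867095131, "n_bins": 2, "significant": true },
 "beta":  { "z": 28.377354726351953, "n_bins": 9, "significant": true },
 "gamma": { "z": 1.9136528551289307, "n_bins": 10, "significant": false }
}
static hold mean error pre/post: 0.0270 / 0.0137
```

Reading the output: the beta-band composite Z of 28.4 far exceeds the
1.96 significance threshold — the simulated post-training records carry
much stronger 12–30 Hz EEG–EMG coupling, exactly as configured. The mean
static-hold tracking error halves from 2.7% to 1.4% of the power-grip
maximum (16 holds each; the written report includes the per-participant
paired t-test, here t = −4.65, p = 0.0003). The small alpha composite is
edge leakage of the simulated beta-band drive. Re-running with
`--scenario no-change` leaves all composites inside ±1.96 and the
tracking error statistically unchanged. `demo_out/` contains the
spectra, per-trial results, session trend table and a JSON manifest
recording every seed and parameter.

The same stages are available as library calls (`myocoh.synth`,
`myocoh.feedback.run_session`, `myocoh.statichold`, `myocoh.coherence`,
`myocoh.stats`) and as CLI subcommands (`simulate`, `train-sim`,
`static-hold`, `coherence`, `stats`).

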