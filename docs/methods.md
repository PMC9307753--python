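# Methods

This note documents the models, conventions and design choices behind
`neurovoc`, in the order the pipeline runs. It states no empirical claim
that the test suite or `scripts/acceptance.py` does not itself compute.

## The synthetic world

Every analysis stage is exercised on generated sessions whose structure
matches the assumptions of the decoding model, so that recovery can be
judged against a known answer.

**Task timing.** `make_schedule` produces `n_words` trials of a
`word_duration` (default 2 s) prompt followed by a
`fixation_duration` (default 1 s) gap; trial k starts at exactly
3k seconds. The default 100-word session lasts 300 s. Labels are drawn
with replacement from a placeholder vocabulary and carried through the
event files but never used numerically.

**Audio.** During each word window a voiced burst is synthesized: a
randomized fundamental f0 ~ U(100, 250) Hz with its full harmonic stack
up to min(8 kHz, 0.45 × rate) under a 1/h amplitude tilt, plus a weak
broadband aspiration-noise component roughly 26 dB below the harmonic
stack, a raised-cosine utterance envelope covering ~70 % of the window
(with a randomized onset delay, so the voice does not fill the
presentation window — as in the real task), and a 3–7 Hz syllabic
amplitude modulation. The harmonic stack must span the whole 0–8 kHz
analysis range: with only a handful of harmonics the upper mel bands
would contain nothing but the noise floor and would be undecodable in
principle, which is a property of a badly posed generator, not of the
decoder. Between words only a noise floor 80 dB below the voiced peak
remains (contract: ≥ 60 dB). Peak amplitude is 0.95.

**Neural traces.** Channel c at 1024 Hz is

```
x_c(t) = pink(t) + Σ_f a·sin(2πft + φ)        f ∈ {50, 100, 150} Hz
       + carrier_c(t) · (1 + d · m_c(t))
       + σ · white(t)
```

with `pink` 1/f-power background (unit RMS), line amplitude `a`
(default 1), `carrier_c` independent Gaussian noise band-passed to
70–170 Hz with the *same* filter the analysis uses (unit RMS; the
planted signal therefore lives exactly in the analysis band),
modulation depth `d` (default 1) and white-noise scale `σ` (default
0.1 — the "low noise" condition). The modulation `m_c(t)` is the
channel's planted weight row applied to the mean-centered log-mel
trajectory of the session audio (computed with the package's own audio
feature chain — dogfooding), interpolated to 1024 Hz, smoothed with a
100 ms moving average, and scaled per channel to max |m| = 1 so the
envelope gain `1 + d·m` stays non-negative at d ≤ 1. The weight matrix
(channels × 23, standard normal) is returned with the session as ground
truth. The mapping is a test harness, not a claim about speech
physiology.

**Contamination positive controls.** `inject_contamination` adds the
anti-alias-resampled audio to every neural channel with a gain, *after*
all other components, so a clean/contaminated pair differs only by the
leak term. Gain 0 returns a bitwise-identical copy.

What the generator does **not** emulate: sEEG morphology (spikes,
artifacts, sleep structure), epileptiform activity, channel-specific
noise spectra, electrode geometry, or any anatomical information. A
green end-to-end test therefore establishes that the pipeline recovers
a linear high-gamma-to-mel coupling embedded in realistic nuisance at
realistic scale — not that it would decode any particular real brain.

## Feature extraction

* Band-pass 70–170 Hz and band-stops 98–102 / 148–152 Hz: Butterworth
  order 4, applied forward–backward (`sosfiltfilt`), i.e. zero phase and
  effective order 8. Band-stop widths of ±2 Hz suppress the line
  harmonics by well over 20 dB while costing < 3 dB at 120 Hz.
* Envelope: magnitude of the FFT-based analytic signal, computed on the
  full continuous recording (not per trial), then averaged in
  50 ms / 10 ms frames. Frame k covers [k·10 ms, k·10 ms + 50 ms); with
  a non-integer samples-per-window count (51.2 at 1024 Hz) the window
  boundaries are mapped to sample indices by ceiling, and frame counts
  follow `floor((T − 0.05)/0.01) + 1` — 29,996 frames for 300 s at any
  rate, so neural and audio grids always align.
* Context: 9 windows at ±{0, 50, 100, 150, 200} ms (5-hop strides on
  the 10 ms grid — non-overlapping 50 ms windows). Frames lacking full
  context are dropped, not padded; the 20 first and last mel target
  rows are dropped identically.
* Normalization: per-feature z-scoring with training-fold statistics
  only; standard deviations are floored at 1e-8 and flat features are
  logged and warned about.

Audio: polyphase resampling to 16 kHz behind a long kaiser-window FIR
(the `resample_poly` default filter leaves aliases only ~26 dB down;
ours reaches > 70 dB), STFT with periodic Hann 800/160 and a 1024-point
FFT, 23 triangular filters on the HTK mel scale (2595·log10(1 + f/700))
between 0 and 8 kHz, *power* (squared-magnitude) pooling, natural log,
floor 1e-10. The power-log convention is shared with the synthesis
inverse and must not drift.

## Decoding and evaluation

Folds are contiguous temporal blocks (`[floor(b·n/k), floor((b+1)·n/k))`,
no shuffling) so temporal autocorrelation cannot leak across the
train/test boundary. Per fold: normalizer → PCA (full SVD, deterministic,
capped at min(50, n_features, n_rows − 1) with a logged warning) → OLS
with intercept (minimum-norm solution under rank deficiency, logged).
The intercept costs nothing after PCA centering and makes the
train-mean-prediction property exact. The decode path contains no
randomness.

The chance baseline rotates the target spectrogram at 1000 split points
drawn uniformly from [⌈0.1 N⌉, ⌊0.9 N⌋] and correlates the rotated copy
with the original, per bin. Because mean and variance are rotation
invariant, the Pearson correlation at every lag is the circular
autocorrelation, which is computed exactly for all lags at once via the
FFT and then indexed at the drawn splits (a naive rotate-and-correlate
oracle checks this in the tests). The achieved mean correlation is
compared against the draws' mean-over-bins; per-bin comparisons are
also available (`draws_per_bin`). Aggregation is whole-session, not
per fold. Note that with a strictly periodic 3 s trial design, rotations
near multiples of 3 s partially realign the spectrogram, so this null
has a heavy right tail and is conservative.

## Waveform reconstruction

Mel inversion exponentiates to mel power, applies the Moore–Penrose
pseudo-inverse of the filterbank, clamps negatives to zero, and takes
the square root back to magnitude; energies at the log floor are mapped
to exactly zero so silence stays silent. Griffin–Lim runs 32 iterations
(default) with phase initialized uniformly in (−π, π] from a seeded
generator. The inverse STFT is the least-squares overlap-add inverse
(window-weighted OLA over summed squared window), which makes each
iteration an alternating projection and the spectral-convergence error
non-increasing — asserted in the tests. Output is peak-normalized to
≤ 1; an all-zero magnitude returns an all-zero waveform.

## Contamination audit

The audio is resampled to the neural rate (1024 Hz), both streams are
decomposed into 50 ms / 10 ms energy spectrograms on the resulting
shared frequency axis (26 bins up to the 512 Hz neural Nyquist — the
range in which speech energy could leak), and the contamination matrix
correlates every neural bin (per-frame **maximum across channels**, so a
leak into one channel is not diluted; per-channel matrices can be
emitted for inspection) with every audio bin across frames.

Each diagonal bin is tested one-sided against 1000 circular rotations of
its audio energy series (10 % margin). Raw per-bin p-values
`(1 + #{r_surr ≥ r_obs})/(1 + 1000)` are reported, but the verdict uses
**Westfall–Young single-step maxT adjusted p-values**: observed and
surrogate correlations are standardized per bin by the surrogate mean
and sd, and each bin is referred to the surrogate distribution of the
maximum across bins. Rationale: at a raw per-bin α = 0.01 over 26 bins
a genuinely clean session is flagged with probability ≈ 1 − 0.99²⁶ ≈
23 % (measured: 28 % over clean synthetic seeds), which makes the raw
rule useless as a session-level verdict; Bonferroni is unavailable
because 0.01/26 is below the smallest attainable permutation p
(1/1001). The maxT verdict keeps the session-level false-alarm rate at
≈ α (measured ≤ 4 % over 50 clean seeds) while an injected leak at
neural-RMS amplitude is still detected at the minimum attainable p.

**Known limitation.** A diagonal-only statistic cannot distinguish
genuine zero-lag neural tracking of speech energy at frequencies inside
the audio band from acoustic leakage — and the generator's planted
coupling creates exactly such tracking in the 70–170 Hz bins. The
periodic trial design makes the rotation null conservative enough that
planted-coupling sessions usually still read clean, but not reliably so.
Negative controls and false-positive calibration therefore use sessions
with modulation depth 0, which isolates the leak pathway; a
contaminated/clean pair differs only by the leak term either way.

## Defaults that matter

| parameter | default | why |
|---|---|---|
| word / fixation duration | 2 s / 1 s | standard task timing |
| n_words | 100 | standard session (300 s) |
| neural / audio rate | 1024 Hz / 48 kHz | acquisition rates being emulated |
| high-gamma band | 70–170 Hz | broadband high-frequency activity |
| frame window / hop | 50 ms / 10 ms | shared neural–audio grid |
| context | ±200 ms, 9 windows | temporal information for decoding |
| mel bands | 23, 0–8 kHz, HTK | audio target representation |
| PCA components | 50 | dimensionality of the decoding problem |
| CV folds | 10, contiguous | non-shuffled protocol |
| baseline draws / margin | 1000 / 10 % | chance distribution resolution |
| Griffin–Lim iterations | 32 | error plateau well before this |
| modulation depth / noise σ | 1.0 / 0.1 | planted-recovery ("low noise") condition |
| contamination α | 0.01 | familywise, maxT-adjusted |

Test-suite economies: most unit and property tests run 30–60 s sessions
with 3–6 channels and 16 kHz audio; only the end-to-end acceptance test
and the acceptance script run the full 300 s / 20-channel / 48 kHz
world. All randomness is seeded; the decode path is deterministic.
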