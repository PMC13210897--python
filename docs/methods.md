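# Methods

This note records the models, parameter choices and numerical decisions
behind `scgbeat`, and what the synthetic studies do and do not show.

## Signal model of the synthetic generator

The generator (`scgbeat.sim`) emulates a resting chest-strap SCG
measurement. Per axis *a*:

```
s_a(t) = Σ_k A_a · m(t_k) · w_a(t − t_k) + r_a(t) + n_a(t)
```

- **Beat wavelet** `w_a`: a causal exponentially decaying sinusoid
  (Gabor-like atom), `exp(−t/τ)·sin(2π f_a t)`, with axis carriers
  (18, 12, 22) Hz and decay τ = 40 ms. Carriers sit in the 10–25 Hz band
  that the SCG literature attributes to cardiomechanical chest vibrations;
  the dorso-ventral (z) axis is given the largest amplitude
  (A = (0.6, 0.4, 1.0)). With probability 0.05 a beat receives a second,
  half-amplitude wavelet 0.12 s later — the "dual acceleration pattern"
  morphology that makes detectors pick either peak.
- **Respiration** `r_a`: a 0.25 Hz baseline (amplitude 0.3 per axis, fixed
  per-axis phases, plus a 0.3-weighted second harmonic — all below 2 Hz so
  the high-pass removes it) and a multiplicative ±20% amplitude modulation
  of the beat wavelets at the same frequency.
- **Noise** `n_a`: white Gaussian, with per-channel variance set so total
  beat-wavelet power over total noise power equals `noise_snr_db`
  (default 15 dB; empirically within 1 dB for records ≥ 60 s). 15 dB is a
  deliberately favourable, "quiet supine measurement" figure; no public
  calibration of chest-strap SCG SNR exists, so this default is a stated
  assumption rather than a fit to any database.
- **RR process**: RR(k) = 60/HR(k) + RSA + jitter, where HR follows a
  Gaussian random walk (per-beat step SD = `hr_sd_bpm`/√(beats per min),
  so `hr_sd_bpm` ≈ the drift over a minute; reflected into [30, 180] bpm),
  RSA is a 40 ms sinusoid at the breathing rate, jitter is 5 ms white
  noise, and RR is clipped to [60/180, 60/30] s. The first beat is placed
  half an interval after t = 0.
- **Motion bursts** (`inject_motion`): band-limited (2–25 Hz) Gaussian
  noise added over Poisson-like burst intervals, scaled against the clean
  recording's own segment energies so that any 10 s analysis segment
  overlapping a burst by ≥ 1 s exceeds `energy_multiplier` × the largest
  clean-segment energy (with a 10% margin for the strict ">" rule).

All randomness derives from `numpy.random.default_rng([seed, stream])`
with a fixed stream id per operation — identical configs reproduce
bit-identical outputs, and beat times can be regenerated independently of
waveform noise.

What the generator does **not** model: hemodynamic waveform detail (AO/AC
fiducials), posture- or subject-dependent morphology families, arrhythmia
beyond RR jitter, sensor nonlinearity, or wrist-worn BCG morphology.
Passing the synthetic studies therefore demonstrates that the pipeline's
machinery is correct and self-consistent under realistic band structure,
drift and noise — not that any particular accuracy will transfer to real
chest-strap or smartwatch data.

## Preprocessing

- High-pass: Butterworth of order 4 designed at 2 Hz and applied
  forward–backward (`sosfiltfilt`), i.e. zero phase. The family is our
  choice (maximally flat passband); the doubled effective attenuation of
  the two passes is accepted and covered by the filter-contract test
  (0.3 Hz ≥ 40 dB down, 15 Hz ≤ 1 dB). Edge handling is `sosfiltfilt`'s
  default odd-reflection padding; recordings must exceed 3× the filter
  order in samples.
- Resampling: linear interpolation onto the uniform target grid. A
  4th-order low-pass at 0.45× the target rate precedes any downsampling;
  upsampling interpolates directly (no anti-alias filter needed).
  `np.interp` clamps beyond the final input sample, so the last
  sub-sample-period of an upsampled record holds the edge value.
- Median scaling: per channel, the recording is cut into 4096-sample
  windows (final partial window kept if ≥ half length); the medians of
  window-wise minima and maxima give robust bounds [m, M] mapped affinely
  to [−1, 1] and clipped at ±1.5. The clip range preserves mild overshoot
  while capping spikes; scaling is per-channel (axes differ in gain), and
  a flat channel maps to zero with a logged warning instead of an error so
  batch jobs never abort.

## Segmentation network

A 1D encoder–decoder with symmetric skip connections. Encoder stage *s*
(s = 0…depth−1) holds `init_filters·2^s` filters as two
(conv → batch-norm → ReLU) blocks followed by stride-2 max pooling; the
bridge is two blocks at `init_filters·2^depth`; the decoder mirrors the
encoder with kernel-2 stride-2 transposed convolutions and channel
concatenation of the matching skip; the head is a kernel-1 convolution to
2 classes with softmax per sample. The per-sample linear head keeps the
network shape-agnostic: any input length divisible by `2^depth` works at
inference. Convolutions use "same" zero padding so encoder/decoder
lengths match.

The implementation is plain NumPy: im2col + BLAS matmul convolutions with
exact backward passes (verified against central finite differences to
≤ 1e-4 relative error), standard batch-norm statistics with momentum 0.1,
and Adam (β = 0.9/0.999). float32 is the working precision; float64 is
available for gradient checks. Training on one CPU is deterministic for a
fixed seed.

Training follows class-weighted cross entropy (weights = inverse class
frequency of the training masks, normalised to mean 1 — with 0.2 s masks
at resting rates roughly one quarter of samples are heartbeat class),
batch 128, Adam from 1e-3, rate ÷10 after 2 epochs without validation
improvement (strict, no tolerance), stop when the rate would fall below
1e-6 or at `max_epochs`; the best-validation weights are restored.

Whole-recording inference tiles the signal into `input_len` windows at
50% overlap (tail window right-aligned; shorter recordings are
reflect-padded and cropped) and averages overlapping probabilities.

**Default vs study configuration.** The package default (`UNetConfig()`)
is depth 5, 16 initial filters, kernel 30, 4096-sample windows. The
synthetic studies in `scgbeat.experiments` train a reduced instance of
the same family — depth 3, 8 initial filters, kernel 9, 1024-sample
windows at 200 Hz (~116k parameters), batch 32 — which converges in about
a dozen epochs on a few hundred segments within a couple of minutes on a
single CPU. This is a problem-size choice for the bundled studies, not a
change to the architecture's defaults.

## Beat localisation

Probabilities are linearly interpolated to 1000 Hz and binarised at a
strictly-greater 0.8 threshold (a plateau at exactly 0.8 is excluded;
the boundary convention is documented rather than significant). Maximal
supra-threshold runs narrower than 160 samples (80% of the 200-sample
reference mask width) are discarded. A 0.55 s minimum separation between
run centres is then enforced left to right: of two conflicting runs the
one with the higher mean probability survives (ties keep the earlier),
and the scan continues against the survivor — since centres increase
monotonically, no earlier pair can be re-violated. The beat time is the
unweighted mean index of the surviving run.

Note on timing resolution: a mask built at 200 Hz quantises window edges
to 5 ms, so beats at arbitrary (off-grid) times round-trip with up to
~2.5 ms error; masks built at the 1000 Hz detection rate round-trip
within 0.5 ms. The sub-millisecond round-trip guarantee therefore applies
at the detection rate.

## Heart rate

`beats_to_ibi` differences the beat times. The corrector is a
running-median scheme standing in for commercial beat-correction
software (the cited algorithms are proprietary or not reproduced here;
no claim of equivalence is made):

- Reference: an 11-point running median, replaced by a global
  contamination-robust reference (the median of the series augmented with
  sums of adjacent short pairs — an extra beat splits one interval into
  two short ones whose sum restores it) wherever the local median strays
  more than 20% from it.
- Outlier gate: deviation from the reference beyond 3.5× the quartile
  deviation of all deviations plus a 30 ms floor, capped at 35% of the
  reference (resting RR does not legitimately jump by a third).
- Rules, left to right, all sum-preserving: ~2× reference → missed beat,
  split in halves; two consecutive shorts summing to ~1 reference →
  extra beat, merged; opposite-sign pair summing to ~2 references →
  misaligned beat, redistributed equally; other interior outliers →
  redistributed over the outlier and both neighbours preserving their
  total; anything else (series edges, long anomalous runs) → excluded.
  Because every rule preserves the spanned time exactly, downstream onsets
  never shift.

HR = 60 / mean(IBI) over sliding windows (default 20 s, step = window,
i.e. non-overlapping; a step parameter exposes true sliding). The
effective length is the summed duration of *good* intervals — neither
corrected nor excluded — lying fully inside the window, divided by the
window length; HR is reported only where this fraction strictly exceeds
0.5. Intervals overlapping flagged artifact segments can additionally be
excluded via `exclude_artifact_overlap`.

## Artifact detection

Per 10 s segment, energy = Σ over the three axes of squared STFT
magnitudes in 2–25 Hz (1 s Hann window, 50% overlap; the final partial
segment is dropped). A segment is flagged when its energy strictly
exceeds 5× the recording's minimum segment energy. The STFT window and
band are our choices: the band starts at the high-pass cutoff and ends
above the beat carriers, and the 1 s Hann window trades frequency
resolution for within-segment time resolution — its soft band edge lets a
1 Hz tone leak ~17% of its power past 2 Hz, while the 0.25 Hz respiration
default leaks < 1%. Recordings with fewer than two segments cannot
self-normalise and are left unflagged with a warning.

## Evaluation

Greedy chronological one-to-one matching: each prediction takes the
nearest unmatched reference within the (inclusive) 0.1 s tolerance, ties
to the earlier reference. When references are separated by more than
twice the tolerance — guaranteed after the 0.55 s separation rule — each
prediction has at most one feasible reference, so the greedy pairing is
provably maximum-cardinality (and is tested against exhaustive bipartite
matching). PPV, sensitivity and F1 report `None` on undefined
denominators rather than 0. HR agreement aligns two windowed series on
their centre times (rounded to 1 ms) and computes MAE, RMSE, Pearson r
(None under zero variance), Bland–Altman bias, 1.96·SD limits of
agreement and the SD of differences; fewer than two common defined
windows yields `None`.

## Study conditions and problem sizes

`run_end_to_end` trains on 300 independent clean segments (per-segment
mean HR uniform in 50–100 bpm), validates on 48, and tests on 50 unseen
30 s recordings; beats within 0.25 s of a recording edge are not scored
(their masks and probability runs are truncated by construction).
Windowed HR (20 s windows, 5 s step) from corrected detected beats is
compared with the same windows computed from the true beats.
`run_artifact_study` uses 50 seeded 300 s recordings with ~1 burst/min at
20× energy; ground truth counts segments overlapping a burst by ≥ 1 s.
Typical results at these sizes: F1 ≈ 0.97 with PPV ≈ 1.0 (the width rule
drops weak-beat runs, trading sensitivity for precision — the same
behaviour the rules are designed to prefer), HR MAE ≈ 0.2 bpm, artifact
sensitivity 1.0 with false-flag rate ≈ 0.02 (the "false" flags sit in
segments that genuinely contain < 1 s of injected burst).

## Known limitations

- The NumPy network is CPU-bound; the full-size default configuration is
  practical for inference but slow to train at scale.
- The IBI corrector is a documented simplification; heavily contaminated
  series (> ~40% anomalous intervals) can defeat its reference estimate.
- The temporal anchor between an external RR stream and the SCG clock
  must be supplied (`RrSeries.anchor_s`); no automatic alignment is
  performed.
- Band-edge leakage makes the artifact detector partially sensitive to
  strong 1–2 Hz content despite the 2 Hz band start.
- Evaluation assumes reference beats respect physiological spacing; the
  greedy-matcher optimality argument does not cover references closer
  than twice the tolerance.
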