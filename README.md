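# scgbeat

Heartbeat detection and heart-rate estimation from tri-axial
seismocardiography (SCG).

SCG measures the micro-vibrations of the chest wall produced by the
beating heart, using an ordinary accelerometer in a chest strap, phone or
watch. `scgbeat` implements a complete pipeline that turns raw tri-axial
acceleration into beat times and windowed heart rate:

1. **Preprocessing** — linear-interpolation resampling to 200 Hz, a
   fourth-order zero-phase Butterworth high-pass at 2 Hz (removes
   respiration and posture drift without shifting beat timing), and
   median-of-segment-extrema amplitude scaling onto [-1, 1]; a sample-gap
   validator (max 0.05 s) screens wrist-worn data.
2. **Ground truth** — reference RR intervals (ms) are cumulated into beat
   times and painted into binary per-sample masks, one symmetric 0.1 s
   half-width window per beat.
3. **Segmentation network** — a 1D U-Net style encoder–decoder (default:
   depth 5, 16 initial filters doubling per stage, kernel 30, 4096-sample
   3-channel inputs) maps each sample to P(heartbeat). Implemented in
   NumPy (im2col convolutions, batch norm, max pooling, transposed-conv
   upsampling, Adam) and trained with class-weighted cross entropy under a
   reduce-on-plateau schedule (1e-3 → 1e-6, factor 10, patience 2 epochs).
4. **Beat localisation** — probabilities are interpolated to 1000 Hz,
   thresholded at 0.8, runs narrower than 160 samples are discarded, a
   0.55 s minimum separation is enforced, and each surviving run's mean
   index is the beat time.
5. **Heart rate** — inter-beat intervals are repaired (missed-beat splits,
   extra-beat merges, misaligned-pair redistribution; all span-preserving)
   and HR = 60 / mean(IBI) is computed in 20 s windows, reported only when
   good-quality intervals cover more than 50% of the window.
6. **Artifact rejection** — 10 s segments whose 2–25 Hz STFT energy
   exceeds 5x the recording's minimum segment energy are flagged as
   motion-corrupted.
7. **Evaluation** — one-to-one beat matching at 0.1 s tolerance
   (PPV / sensitivity / F1) and Bland–Altman HR agreement
   (MAE, RMSE, Pearson r, bias, 1.96-SD limits of agreement).

A seeded synthetic SCG generator (decaying-sinusoid beat wavelets in the
10–25 Hz band, respiration baseline and amplitude modulation, RR process
with slow drift + respiratory sinus arrhythmia + jitter, optional
dual-peak morphology and calibrated motion bursts) provides ground truth
for every stage, so the whole pipeline is testable without any data
downloads.

## Worked example

`examples/train_and_detect.py` trains a CPU-sized instance of the
segmentation network (depth 3, 8 filters, kernel 9, 1024-sample windows)
on 120 clean synthetic segments and detects beats on an unseen 30 s
recording:

```
network: depth 3, filters [8, 16, 32], 116162 parameters
trained 10 epochs: val loss 0.629 -> 0.222
unseen recording: 31 true beats, 29 detected; TP=29 FP=0 FN=2
PPV=1.000 sensitivity=0.935 F1=0.967
timing error of matched beats: median 0.9 ms
```

Every detected beat is a true beat (PPV 1.0); two weak beats produced
probability runs narrower than the 160-sample width rule and were dropped
(the rules prefer precision over recall). Matched beats are localised to
about a millisecond.

The other examples cover one capability each:

- `examples/simulate_and_roundtrip.py` — ground-truth masks localise every
  beat with < 0.5 ms error (validates the mask/localiser plumbing);
- `examples/heart_rate_estimation.py` — after deleting 10% of beats, the
  IBI corrector restores windowed HR to within ~0.2 bpm of truth;
- `examples/artifact_flagging.py` — injected 20x-energy motion bursts are
  flagged exactly, clean segments are not.

There is also a thin CLI over the same library (`scgbeat simulate`,
`preprocess`, `train`, `detect`, `hr`, `artifacts`, `evaluate`,
`run-all`), configured by YAML; every run writes a manifest with the
config hash and seed.

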