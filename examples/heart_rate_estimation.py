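"""Beat correction and quality-gated heart-rate estimation.

Simulates 5 minutes of beats at a known heart rate, deletes 10% of them
(emulating missed detections), repairs the inter-beat-interval series with
the running-median corrector, and estimates HR in 20 s windows gated on
>50% effective length of good-quality intervals.
"""
import numpy as np

from scgbeat import BeatAnnotation, SimConfig, beats_to_ibi, correct_ibi, estimate_hr
from scgbeat.datatypes import CORRECTED, EXCLUDED, GOOD
from scgbeat.sim import simulate_beat_times

cfg = SimConfig(duration_s=300.0, mean_hr_bpm=72.0, hr_sd_bpm=1.0, seed=8)
beats = simulate_beat_times(cfg).times_s
rng = np.random.default_rng(8)
keep = rng.random(beats.size) > 0.1
keep[[0, -1]] = True
print(f"{beats.size} true beats; {np.sum(~keep)} deleted (missed detections)")

ibi = beats_to_ibi(BeatAnnotation(beats[keep]))
corrected = correct_ibi(ibi)
counts = {name: int(np.sum(corrected.flags == code))
          for name, code in (("good", GOOD), ("corrected", CORRECTED),
                             ("excluded", EXCLUDED))}
print(f"corrector flags: {counts} "
      f"(span drift {1000 * abs(corrected.span_s - ibi.span_s):.3f} ms)")

hr = estimate_hr(corrected, window_s=20.0)
ref = estimate_hr(beats_to_ibi(BeatAnnotation(beats)), window_s=20.0)
ok = hr.defined() & ref.defined()
mae = np.mean(np.abs(hr.hr_bpm[ok] - ref.hr_bpm[ok]))
print(f"{int(ok.sum())}/{hr.hr_bpm.size} windows pass the 50% quality gate")
print(f"windowed HR MAE vs truth: {mae:.3f} bpm "
      f"(mean effective fraction {hr.effective_fraction[ok].mean():.2f})")
print("-> missed-beat splits conserve the series span, so windowed HR "
      "stays within a fraction of a bpm of the true rate.")
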