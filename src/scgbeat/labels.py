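"""Ground-truth construction: RR intervals -> beat times -> sample masks.

Reference heartbeat positions come as beat-to-beat RR intervals in
milliseconds (chest-strap export style).  Beats are the cumulative sums of
the intervals from an explicit anchor time; each beat is then painted into
a binary per-sample mask as a symmetric window of half-width 0.1 s (total
width 0.2 s), which is the segmentation target for the network.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import BeatAnnotation, SampleMask

__all__ = ["RrSeries", "rr_to_beat_times", "beats_to_mask"]

RR_VALID_MS = (200.0, 3000.0)


@dataclass
class RrSeries:
    """Ordered RR intervals (ms) anchored on the recording timeline.

    ``anchor_s`` is the time of the beat preceding the first interval.
    """

    intervals_ms: np.ndarray
    anchor_s: float = 0.0

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=np.float64).ravel()
        if self.intervals_ms.size and np.any(self.intervals_ms <= 0):
            raise ValueError("RR intervals must be positive")
        if self.anchor_s < 0:
            raise ValueError(f"anchor_s must be >= 0; got {self.anchor_s}")

    def validate_range(self) -> "RrSeries":
        """Check all intervals lie in the physiological 200–3000 ms band."""
        lo, hi = RR_VALID_MS
        bad = (self.intervals_ms < lo) | (self.intervals_ms > hi)
        if np.any(bad):
            raise ValueError(
                f"{int(bad.sum())} RR interval(s) outside [{lo}, {hi}] ms"
            )
        return self


def rr_to_beat_times(rr: RrSeries) -> BeatAnnotation:
    """Beat k sits at anchor_s plus the cumulative RR sum up to k."""
    if rr.intervals_ms.size == 0:
        return BeatAnnotation(np.empty(0))
    times = rr.anchor_s + np.cumsum(rr.intervals_ms) / 1000.0
    return BeatAnnotation(times)


def beats_to_mask(
    beats: BeatAnnotation,
    fs: float,
    length: int,
    half_width_s: float = 0.1,
    t0: float = 0.0,
) -> SampleMask:
    """Paint each beat as a symmetric window of ones, OR-merged on overlap.

    A sample at time ``t`` is 1 iff ``|t - t_beat| <= half_width_s`` for
    some beat; windows are truncated at the mask edges.  At 1000 Hz an
    interior beat covers 201 samples (±100 around the centre sample).
    """
    if fs <= 0:
        raise ValueError(f"fs must be positive; got {fs}")
    if length < 1:
        raise ValueError(f"length must be >= 1; got {length}")
    duration = length / fs
    values = np.zeros(length)
    for tb in beats.times_s:
        if tb >= t0 + duration or tb < t0:
            raise ValueError(
                f"beat at {tb:.3f} s lies outside the mask span "
                f"[{t0:.3f}, {t0 + duration:.3f}) s"
            )
        lo = int(np.ceil((tb - half_width_s - t0) * fs - 1e-9))
        hi = int(np.floor((tb + half_width_s - t0) * fs + 1e-9))
        values[max(lo, 0) : min(hi, length - 1) + 1] = 1.0
    return SampleMask(values, fs=fs, t0=t0)
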