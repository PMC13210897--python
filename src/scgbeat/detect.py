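"""Rule-based beat localisation from per-sample probability masks.

Pipeline: interpolate the probability sequence to 1000 Hz, binarise at a
confidence threshold (strictly greater than 0.8 by default), keep maximal
supra-threshold runs at least 160 samples wide (80% of the 200-sample
reference mask width), enforce a 0.55 s minimum separation between run
centres, and report each surviving run's mean sample index as the beat
time.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import BeatAnnotation, SampleMask

__all__ = ["DetectionParams", "localize_beats"]


@dataclass
class DetectionParams:
    interp_fs: float = 1000.0
    prob_threshold: float = 0.8
    min_width_samples: int = 160
    min_separation_s: float = 0.55

    def __post_init__(self) -> None:
        if not 0 < self.prob_threshold < 1:
            raise ValueError(
                f"prob_threshold must lie in (0, 1); got {self.prob_threshold}"
            )
        if self.min_width_samples < 1:
            raise ValueError(
                f"min_width_samples must be >= 1; got {self.min_width_samples}"
            )
        if self.min_separation_s <= 0:
            raise ValueError(
                f"min_separation_s must be > 0; got {self.min_separation_s}"
            )


def _runs(binary: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) index pairs."""
    padded = np.concatenate([[False], binary, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def localize_beats(
    prob: SampleMask, params: DetectionParams | None = None
) -> BeatAnnotation:
    """Convert a probability mask into discrete beat times.

    When two surviving runs sit closer than ``min_separation_s``, the run
    with the higher mean probability wins (ties keep the earlier run); the
    scan then continues left to right against the kept run.
    """
    params = params or DetectionParams()

    # 1. interpolate the probability sequence to the detection rate
    duration = prob.duration_s
    n_out = int(round(duration * params.interp_fs))
    if n_out < 1:
        return BeatAnnotation(np.empty(0))
    t_old = np.arange(prob.n_samples) / prob.fs
    t_new = np.arange(n_out) / params.interp_fs
    p = np.interp(t_new, t_old, prob.values)

    # 2–4. binarise (strict >), extract runs, apply the width rule
    binary = p > params.prob_threshold
    runs = [
        (s, e) for s, e in _runs(binary) if e - s >= params.min_width_samples
    ]
    if not runs:
        return BeatAnnotation(np.empty(0))

    centers = np.array([(s + e - 1) / 2.0 for s, e in runs])
    mean_p = np.array([p[s:e].mean() for s, e in runs])

    # 5. minimum-separation rule, resolved by mean probability
    min_sep = params.min_separation_s * params.interp_fs
    kept: list[int] = []
    for i in range(len(runs)):
        if not kept:
            kept.append(i)
            continue
        if centers[i] - centers[kept[-1]] < min_sep:
            if mean_p[i] > mean_p[kept[-1]]:
                kept[-1] = i
            # tie or lower: earlier run stays
        else:
            kept.append(i)

    # 6. beat time = mean index of each surviving run
    times = prob.t0 + centers[kept] / params.interp_fs
    return BeatAnnotation(times)
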