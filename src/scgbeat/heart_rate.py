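"""Inter-beat intervals, beat correction, and quality-gated HR estimation.

``beats_to_ibi`` differences detected beats; ``correct_ibi`` repairs
missed, extra and misaligned beats with sum-preserving interpolation-based
adjustments (a documented stand-in for commercial beat-correction
software); ``estimate_hr`` computes HR = 60 / mean(IBI) over sliding
windows, reporting a window only when the effective length of good-quality
intervals exceeds half the window.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import CORRECTED, EXCLUDED, GOOD, BeatAnnotation, IbiSeries

__all__ = [
    "CorrectionConfig",
    "HrSeries",
    "beats_to_ibi",
    "correct_ibi",
    "estimate_hr",
    "exclude_artifact_overlap",
]


@dataclass
class CorrectionConfig:
    """Thresholds for the running-median outlier rules.

    An interval is an outlier when it deviates from the local reference by
    more than ``qd_scale`` times the quartile deviation of all such
    deviations (plus a small absolute floor guarding near-constant
    series), capped at ``rel_cap`` times the reference — deviations beyond
    ~a third of the local RR are implausible at rest regardless of the
    series' spread.
    """

    median_window: int = 11
    qd_scale: float = 3.5
    abs_floor_s: float = 0.03
    rel_cap: float = 0.35
    ratio_tol: float = 0.3  # acceptance band around 2x / 0.5x the reference

    def __post_init__(self) -> None:
        if self.median_window < 3 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 3")


@dataclass
class HrSeries:
    """Windowed HR estimates; hr_bpm is NaN where the quality gate fails."""

    window_centers_s: np.ndarray
    hr_bpm: np.ndarray
    effective_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.window_centers_s = np.asarray(self.window_centers_s, dtype=np.float64)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=np.float64)
        self.effective_fraction = np.asarray(
            self.effective_fraction, dtype=np.float64
        )

    def defined(self) -> np.ndarray:
        return np.isfinite(self.hr_bpm)


def beats_to_ibi(beats: BeatAnnotation) -> IbiSeries:
    """Successive differences of beat times; all flags start good."""
    if len(beats) < 2:
        return IbiSeries(np.empty(0), np.empty(0))
    return IbiSeries(beats.times_s[:-1].copy(), np.diff(beats.times_s))


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def correct_ibi(
    ibi: IbiSeries, cfg: CorrectionConfig | None = None
) -> IbiSeries:
    """Detect and repair missed, extra and misaligned beats.

    Rules, applied left to right against a running median m:

    * interval ~ 2m (missed beat): split into two halves, both corrected;
    * two consecutive intervals each ~ m/2 summing to ~ m (extra beat):
      merged into one corrected interval;
    * adjacent long/short pair summing to ~ 2m (misaligned beat): the pair
      is redistributed equally, both corrected;
    * any other isolated outlier: the outlier and its two neighbours are
      re-interpolated preserving their total, all three corrected;
    * outliers that match no rule (e.g. at the series edge): excluded.

    Every rule preserves the total spanned time exactly, so onsets of
    untouched intervals never move.
    """
    cfg = cfg or CorrectionConfig()
    x = ibi.intervals_s
    if x.size == 0:
        return IbiSeries(np.empty(0), np.empty(0))

    # Global reference robust to extra-beat contamination: augment the
    # series with sums of adjacent short pairs (an extra beat splits one
    # normal interval into two short ones; their sum restores it) before
    # taking the median.
    gmed = float(np.median(x))
    pair_sums = [
        x[i] + x[i + 1]
        for i in range(x.size - 1)
        if x[i] < gmed and x[i + 1] < gmed
    ]
    ref_global = float(np.median(np.concatenate([x, np.asarray(pair_sums)]))) \
        if pair_sums else gmed

    # Local reference: running median where trustworthy, else the global.
    med = _running_median(x, cfg.median_window)
    ref = np.where(np.abs(med - ref_global) <= 0.2 * ref_global, med, ref_global)

    dev = np.abs(x - ref)
    q1, q3 = np.percentile(dev, [25, 75])
    thr = np.minimum(
        cfg.qd_scale * (q3 - q1) / 2.0 + cfg.abs_floor_s, cfg.rel_cap * ref
    )
    outlier = dev > thr

    new_int: list[float] = []
    new_flag: list[int] = []
    i = 0
    n = x.size
    while i < n:
        xi, ri = x[i], ref[i]
        if not outlier[i]:
            new_int.append(xi)
            new_flag.append(GOOD)
            i += 1
            continue
        # missed beat: one long interval ~ twice the local reference
        if xi > 1.5 * ri and abs(xi / (2 * ri) - 1) < cfg.ratio_tol:
            new_int += [xi / 2, xi / 2]
            new_flag += [CORRECTED, CORRECTED]
            i += 1
            continue
        # extra beat: consecutive short pair summing to ~ one reference
        if (
            i + 1 < n
            and xi < 0.75 * ri
            and x[i + 1] < 0.75 * ref[i + 1]
            and abs((xi + x[i + 1]) / ri - 1) < cfg.ratio_tol
        ):
            new_int.append(xi + x[i + 1])
            new_flag.append(CORRECTED)
            i += 2
            continue
        # misaligned beat: long/short pair with opposite deviations whose
        # sum matches two references
        if (
            i + 1 < n
            and outlier[i + 1]
            and (xi - ri) * (x[i + 1] - ref[i + 1]) < 0
            and abs((xi + x[i + 1]) / (ri + ref[i + 1]) - 1) < cfg.ratio_tol
        ):
            s = xi + x[i + 1]
            new_int += [s / 2, s / 2]
            new_flag += [CORRECTED, CORRECTED]
            i += 2
            continue
        # isolated outlier with two neighbours: sum-preserving smoothing
        if 0 < i < n - 1 and not outlier[i + 1] and new_int:
            prev = new_int.pop()
            new_flag.pop()
            s = prev + xi + x[i + 1]
            target = (prev + x[i + 1]) / 2.0
            scale = s / (prev + target + x[i + 1])
            new_int += [prev * scale, target * scale, x[i + 1] * scale]
            new_flag += [CORRECTED, CORRECTED, CORRECTED]
            i += 2
            continue
        # unreconcilable (edges, long anomalous runs)
        new_int.append(xi)
        new_flag.append(EXCLUDED)
        i += 1

    intervals = np.asarray(new_int)
    onsets = ibi.onsets_s[0] + np.concatenate([[0.0], np.cumsum(intervals[:-1])])
    return IbiSeries(onsets, intervals, np.asarray(new_flag, dtype=np.int8))


def estimate_hr(
    ibi: IbiSeries,
    window_s: float = 20.0,
    step_s: float | None = None,
    min_effective: float = 0.5,
) -> HrSeries:
    """Sliding-window HR with the effective-length quality gate.

    Per window, effective length is the summed duration of good intervals
    lying fully inside the window, divided by ``window_s``.  HR is defined
    only where that fraction strictly exceeds ``min_effective`` and equals
    60 / mean(good IBI in window) bpm.
    """
    if window_s <= 0:
        raise ValueError(f"window_s must be > 0; got {window_s}")
    step_s = step_s if step_s is not None else window_s
    if step_s <= 0:
        raise ValueError(f"step_s must be > 0; got {step_s}")

    if len(ibi) == 0:
        return HrSeries(np.empty(0), np.empty(0), np.empty(0))

    t_start = ibi.onsets_s[0]
    t_end = ibi.onsets_s[-1] + ibi.intervals_s[-1]
    starts = np.arange(t_start, t_end - window_s + 1e-9, step_s)
    if starts.size == 0:
        starts = np.array([t_start])

    good = ibi.good()
    centers, hrs, fracs = [], [], []
    for w0 in starts:
        w1 = w0 + window_s
        inside = (ibi.onsets_s >= w0 - 1e-9) & (
            ibi.onsets_s + ibi.intervals_s <= w1 + 1e-9
        )
        sel = inside & good
        eff = ibi.intervals_s[sel].sum() / window_s
        centers.append(w0 + window_s / 2)
        fracs.append(eff)
        if eff > min_effective:
            hrs.append(60.0 / ibi.intervals_s[sel].mean())
        else:
            hrs.append(np.nan)
    return HrSeries(np.asarray(centers), np.asarray(hrs), np.asarray(fracs))


def exclude_artifact_overlap(
    ibi: IbiSeries, artifact_intervals_s: list[tuple[float, float]]
) -> IbiSeries:
    """Flag intervals overlapping any artifact segment as excluded."""
    flags = ibi.flags.copy()
    for k in range(len(ibi)):
        a0 = ibi.onsets_s[k]
        a1 = a0 + ibi.intervals_s[k]
        for b0, b1 in artifact_intervals_s:
            if min(a1, b1) > max(a0, b0):
                flags[k] = EXCLUDED
                break
    return IbiSeries(ibi.onsets_s.copy(), ibi.intervals_s.copy(), flags)
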