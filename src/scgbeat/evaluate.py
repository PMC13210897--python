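"""Detection scoring and HR agreement statistics.

Beat detection is scored by one-to-one matching of predicted against
reference beats within a 0.1 s tolerance; PPV, sensitivity and F1 follow
from the TP/FP/FN tallies.  HR agreement between two windowed series uses
MAE, RMSE, Pearson correlation and Bland–Altman bias with 1.96-SD limits
of agreement.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import BeatAnnotation, MatchResult
from .heart_rate import HrSeries

__all__ = [
    "AgreementStats",
    "DetectionMetrics",
    "match_beats",
    "detection_metrics",
    "hr_agreement",
    "exclude_beats_in_intervals",
    "bland_altman_plot",
]

log = logging.getLogger(__name__)


@dataclass
class DetectionMetrics:
    ppv: float | None
    sensitivity: float | None
    f1: float | None


@dataclass
class AgreementStats:
    mae_bpm: float
    rmse_bpm: float
    pearson_r: float | None
    bias_bpm: float
    loa_low_bpm: float
    loa_high_bpm: float
    see_bpm: float
    n: int


def _sorted_times(ann: BeatAnnotation, name: str) -> np.ndarray:
    t = ann.times_s
    if np.any(np.diff(t) < 0):
        log.warning("%s beats unsorted; sorting internally", name)
        t = np.sort(t)
    return t


def match_beats(
    pred: BeatAnnotation, ref: BeatAnnotation, tolerance_s: float = 0.1
) -> MatchResult:
    """Chronological greedy one-to-one matching within a tolerance.

    Predictions are scanned in time order; each is paired with the nearest
    unmatched reference within ``tolerance_s`` (tie -> earlier reference).
    Unmatched references count as FN, unmatched predictions as FP.
    """
    p = _sorted_times(pred, "predicted")
    r = _sorted_times(ref, "reference")
    used = np.zeros(r.size, dtype=bool)
    pairs: list[tuple[float, float]] = []
    # tiny slack keeps the boundary |pred - ref| == tolerance inclusive
    # despite float subtraction noise
    eps = 1e-12
    for tp_time in p:
        lo = np.searchsorted(r, tp_time - tolerance_s - eps, side="left")
        hi = np.searchsorted(r, tp_time + tolerance_s + eps, side="right")
        best, best_d = -1, np.inf
        for j in range(lo, hi):
            if used[j]:
                continue
            d = abs(r[j] - tp_time)
            if d < best_d - 1e-15:  # strict improvement; ties keep earlier
                best, best_d = j, d
        if best >= 0 and best_d <= tolerance_s + eps:
            used[best] = True
            pairs.append((float(tp_time), float(r[best])))
    tp = len(pairs)
    return MatchResult(
        pairs=pairs,
        tp=tp,
        fp=int(p.size - tp),
        fn=int(r.size - tp),
        tolerance_s=tolerance_s,
    )


def detection_metrics(m: MatchResult) -> DetectionMetrics:
    """PPV, sensitivity and F1; undefined denominators give None."""
    ppv = m.tp / (m.tp + m.fp) if (m.tp + m.fp) else None
    sens = m.tp / (m.tp + m.fn) if (m.tp + m.fn) else None
    if ppv is None or sens is None or (ppv + sens) == 0:
        f1 = None
    else:
        f1 = 2 * ppv * sens / (ppv + sens)
    return DetectionMetrics(ppv, sens, f1)


def hr_agreement(est: HrSeries, ref: HrSeries) -> AgreementStats | None:
    """Agreement over the common defined windows of two HR series.

    Windows are aligned on their centre times; fewer than two common
    defined windows means agreement is undefined (returns None).  Pearson
    r is None when either series has zero variance over the common
    windows.
    """
    # Align by window-centre time (rounded to a ms to absorb float noise).
    key_e = np.round(est.window_centers_s, 3)
    key_r = np.round(ref.window_centers_s, 3)
    common, ie, ir = np.intersect1d(key_e, key_r, return_indices=True)
    ok = est.defined()[ie] & ref.defined()[ir]
    e = est.hr_bpm[ie][ok]
    r = ref.hr_bpm[ir][ok]
    if e.size < 2:
        return None
    d = e - r
    mae = float(np.mean(np.abs(d)))
    rmse = float(np.sqrt(np.mean(d**2)))
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if np.std(e) == 0 or np.std(r) == 0:
        pr = None
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pr = float(stats.pearsonr(e, r)[0])
    return AgreementStats(
        mae_bpm=mae,
        rmse_bpm=rmse,
        pearson_r=pr,
        bias_bpm=bias,
        loa_low_bpm=bias - 1.96 * sd,
        loa_high_bpm=bias + 1.96 * sd,
        see_bpm=sd,
        n=int(e.size),
    )


def exclude_beats_in_intervals(
    beats: BeatAnnotation, intervals: list[tuple[float, float]]
) -> BeatAnnotation:
    """Drop beats falling inside any of the given intervals (artifact
    segments), mirroring evaluation on movement-free signal only."""
    if not intervals:
        return beats
    keep = np.ones(len(beats), dtype=bool)
    for i, t in enumerate(beats.times_s):
        for a, b in intervals:
            if a <= t < b:
                keep[i] = False
                break
    return BeatAnnotation(beats.times_s[keep])


def bland_altman_plot(est: HrSeries, ref: HrSeries, path: str) -> None:
    """Write a Bland–Altman plot of the common defined windows to disk."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stats_ba = hr_agreement(est, ref)
    if stats_ba is None:
        raise ValueError("too few common windows for a Bland-Altman plot")
    ok = est.defined() & ref.defined()
    e, r = est.hr_bpm[ok], ref.hr_bpm[ok]
    mean, diff = (e + r) / 2, e - r
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, diff, s=10, alpha=0.6)
    for y, style in (
        (stats_ba.bias_bpm, "--"),
        (stats_ba.loa_low_bpm, ":"),
        (stats_ba.loa_high_bpm, ":"),
    ):
        ax.axhline(y, linestyle=style, color="k")
    ax.set_xlabel("mean HR (bpm)")
    ax.set_ylabel("estimated - reference HR (bpm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
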