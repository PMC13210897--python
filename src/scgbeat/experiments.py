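"""Reproducible desk-scale studies: segment generation, end-to-end beat
detection and HR recovery, and artifact-detector recovery.

These functions define the package's study conditions on synthetic data.
The network trained here is a reduced instance of the segmentation
architecture (depth 3, 8 initial filters, kernel 9, 1024-sample windows at
200 Hz) sized for single-CPU training; the full-size configuration remains
the :class:`~scgbeat.model.UNetConfig` default.
"""
from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .artifacts import flag_artifacts, segment_spectral_energy
from .datatypes import BeatAnnotation, ScgRecording
from .detect import DetectionParams, localize_beats
from .evaluate import match_beats
from .heart_rate import beats_to_ibi, correct_ibi, estimate_hr
from .labels import beats_to_mask
from .model import (
    SegmentBatch,
    TrainConfig,
    UNet1D,
    UNetConfig,
    build_network,
    predict_proba,
    train,
)
from .preprocess import PreprocessParams, highpass, median_scale
from .sim import ArtifactConfig, SimConfig, inject_motion, simulate_recording
from .sim import intervals_to_segment_truth

__all__ = [
    "scaled_unet_config",
    "scaled_train_config",
    "make_segment_batch",
    "run_end_to_end",
    "run_artifact_study",
]

log = logging.getLogger(__name__)

# Per-segment mean-HR range drawn for training diversity (resting adults).
HR_RANGE_BPM = (50.0, 100.0)
EDGE_MARGIN_S = 0.25  # beats this close to a segment edge are not scored


def scaled_unet_config() -> UNetConfig:
    """CPU-scale instance of the segmentation architecture."""
    return UNetConfig(depth=3, init_filters=8, kernel_size=9, input_len=1024)


def scaled_train_config(seed: int = 0, max_epochs: int = 12) -> TrainConfig:
    return TrainConfig(batch_size=32, max_epochs=max_epochs, seed=seed)


def _prep(rec: ScgRecording) -> ScgRecording:
    params = PreprocessParams()
    return median_scale(highpass(rec, params), params)


def _segment_sim_config(base: SimConfig, rng: np.random.Generator,
                        duration_s: float) -> SimConfig:
    hr = rng.uniform(*HR_RANGE_BPM)
    return replace(
        base,
        duration_s=duration_s,
        mean_hr_bpm=hr,
        seed=int(rng.integers(2**31 - 1)),
    )


def make_segment_batch(
    n_segments: int,
    seed: int,
    unet_cfg: UNetConfig | None = None,
    base: SimConfig | None = None,
) -> SegmentBatch:
    """Simulate, preprocess and label ``n_segments`` training windows.

    Each segment is an independent recording of exactly ``input_len``
    samples with its own mean HR drawn from the resting range; targets are
    the 0.1 s half-width heartbeat masks of the known beat times.
    """
    unet_cfg = unet_cfg or scaled_unet_config()
    base = base or SimConfig()
    rng = np.random.default_rng(seed)
    duration = unet_cfg.input_len / base.fs

    xs, ys = [], []
    for _ in range(n_segments):
        cfg = _segment_sim_config(base, rng, duration)
        rec, beats = simulate_recording(cfg)
        rec = _prep(rec)
        mask = beats_to_mask(beats, fs=cfg.fs, length=unet_cfg.input_len)
        xs.append(rec.data[:, : unet_cfg.input_len])
        ys.append(mask.values[: unet_cfg.input_len])
    return SegmentBatch(
        np.stack(xs).astype(np.float32), np.stack(ys).astype(np.int64)
    )


def _score_recording(
    net: UNet1D,
    rec: ScgRecording,
    beats: BeatAnnotation,
    det: DetectionParams,
) -> tuple:
    """Detect beats on one preprocessed recording and score interior beats."""
    prob = predict_proba(net, rec)
    pred = localize_beats(prob, det)
    lo = rec.t0 + EDGE_MARGIN_S
    hi = rec.t0 + rec.duration_s - EDGE_MARGIN_S
    pred_i = BeatAnnotation(
        pred.times_s[(pred.times_s >= lo) & (pred.times_s <= hi)]
    )
    ref_i = BeatAnnotation(
        beats.times_s[(beats.times_s >= lo) & (beats.times_s <= hi)]
    )
    return match_beats(pred_i, ref_i, tolerance_s=0.1), pred


def run_end_to_end(
    seed: int = 1,
    n_train: int = 300,
    n_val: int = 48,
    n_test: int = 50,
    test_duration_s: float = 30.0,
    max_epochs: int = 12,
    hr_window_s: float = 20.0,
    hr_step_s: float = 5.0,
) -> dict:
    """Train the segmentation network on clean synthetic segments and
    score beat detection and windowed HR on held-out test recordings.

    Returns a dict with pooled detection counts/metrics, pooled HR errors,
    and the training history.
    """
    unet_cfg = scaled_unet_config()
    base = SimConfig()
    train_batch = make_segment_batch(n_train, seed=seed * 1000 + 1,
                                     unet_cfg=unet_cfg, base=base)
    val_batch = make_segment_batch(n_val, seed=seed * 1000 + 2,
                                   unet_cfg=unet_cfg, base=base)

    net = build_network(unet_cfg, seed=seed)
    history = train(
        net, train_batch, val_batch, scaled_train_config(seed, max_epochs)
    )

    det = DetectionParams()
    rng = np.random.default_rng(seed * 1000 + 3)
    tp = fp = fn = 0
    hr_diffs: list[float] = []
    n_hr_windows = 0
    for _ in range(n_test):
        cfg = _segment_sim_config(base, rng, test_duration_s)
        rec, beats = simulate_recording(cfg)
        rec = _prep(rec)
        match, pred = _score_recording(net, rec, beats, det)
        tp += match.tp
        fp += match.fp
        fn += match.fn

        # windowed HR from detected beats (after correction) vs truth
        est_hr = estimate_hr(
            correct_ibi(beats_to_ibi(pred)), window_s=hr_window_s,
            step_s=hr_step_s,
        )
        ref_hr = estimate_hr(
            beats_to_ibi(beats), window_s=hr_window_s, step_s=hr_step_s
        )
        key_e = np.round(est_hr.window_centers_s, 1)
        key_r = np.round(ref_hr.window_centers_s, 1)
        _, ie, ir = np.intersect1d(key_e, key_r, return_indices=True)
        ok = est_hr.defined()[ie] & ref_hr.defined()[ir]
        d = est_hr.hr_bpm[ie][ok] - ref_hr.hr_bpm[ir][ok]
        hr_diffs.extend(d.tolist())
        n_hr_windows += int(ok.sum())

    ppv = tp / (tp + fp) if (tp + fp) else None
    sens = tp / (tp + fn) if (tp + fn) else None
    f1 = (
        2 * ppv * sens / (ppv + sens)
        if ppv is not None and sens is not None and (ppv + sens)
        else None
    )
    diffs = np.asarray(hr_diffs)
    out = {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "ppv": ppv,
        "sensitivity": sens,
        "f1": f1,
        "n_beats_ref": tp + fn,
        "hr_mae_bpm": float(np.mean(np.abs(diffs))) if diffs.size else None,
        "hr_rmse_bpm": float(np.sqrt(np.mean(diffs**2))) if diffs.size else None,
        "hr_bias_bpm": float(np.mean(diffs)) if diffs.size else None,
        "n_hr_windows": n_hr_windows,
        "history": history,
    }
    log.info(
        "end-to-end: F1=%.4f PPV=%.4f sens=%.4f, HR MAE=%.3f bpm (%d windows)",
        out["f1"], out["ppv"], out["sensitivity"], out["hr_mae_bpm"] or -1,
        n_hr_windows,
    )
    return out


def run_artifact_study(
    seed: int = 1,
    n_runs: int = 50,
    duration_s: float = 300.0,
    energy_multiplier: float = 20.0,
    burst_rate_per_min: float = 1.0,
) -> dict:
    """Recovery of injected motion bursts by the spectral-energy detector.

    Per run: simulate a clean recording, inject bursts of
    ``energy_multiplier`` times the clean segment energy, flag artifacts,
    and compare against the known burst segments.  Returns pooled
    sensitivity and false-flag rate.
    """
    rng = np.random.default_rng(seed)
    tp = fn = fp = tn = 0
    for run in range(n_runs):
        cfg = SimConfig(
            duration_s=duration_s,
            mean_hr_bpm=float(rng.uniform(*HR_RANGE_BPM)),
            seed=int(rng.integers(2**31 - 1)),
        )
        rec, _ = simulate_recording(cfg)
        art = ArtifactConfig(
            burst_rate_per_min=burst_rate_per_min,
            energy_multiplier=energy_multiplier,
            seed=int(rng.integers(2**31 - 1)),
        )
        noisy, intervals = inject_motion(rec, art)
        energies = segment_spectral_energy(noisy)
        flags = flag_artifacts(energies).flags
        truth = intervals_to_segment_truth(intervals, energies.size)
        tp += int(np.sum(flags & truth))
        fn += int(np.sum(~flags & truth))
        fp += int(np.sum(flags & ~truth))
        tn += int(np.sum(~flags & ~truth))
    return {
        "sensitivity": tp / (tp + fn) if (tp + fn) else None,
        "false_flag_rate": fp / (fp + tn) if (fp + tn) else None,
        "tp": tp,
        "fn": fn,
        "fp": fp,
        "tn": tn,
        "n_runs": n_runs,
    }
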