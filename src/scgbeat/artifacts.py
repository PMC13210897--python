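"""Movement-artifact flagging by segment-wise STFT spectral energy.

The recording is tiled into 10-s segments; per segment, the spectral
energy is the sum over the three channels of squared STFT magnitudes in
the 2–25 Hz band (1 s Hann windows, 50% overlap).  A segment is flagged as
motion-corrupted when its energy strictly exceeds five times the minimum
segment energy of the same recording — motion shows up as broadband energy
far above the quiet-segment floor.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window
from scipy.signal import ShortTimeFFT

from .datatypes import ScgRecording

__all__ = ["StftConfig", "ArtifactFlags", "segment_spectral_energy", "flag_artifacts"]

log = logging.getLogger(__name__)


@dataclass
class StftConfig:
    window_s: float = 1.0
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ValueError(f"overlap must lie in [0, 1); got {self.overlap}")
        if self.window_s <= 0:
            raise ValueError(f"window_s must be > 0; got {self.window_s}")


@dataclass
class ArtifactFlags:
    """Per-segment energies and boolean artifact flags."""

    segment_bounds_s: list[tuple[float, float]]
    energies: np.ndarray
    flags: np.ndarray
    ratio_threshold: float = 5.0

    def flagged_intervals(self) -> list[tuple[float, float]]:
        return [b for b, f in zip(self.segment_bounds_s, self.flags) if f]


def _stft_band_energy(
    x: np.ndarray, fs: float, band_hz: tuple[float, float], cfg: StftConfig
) -> float:
    """Summed squared STFT magnitudes of one channel within the band."""
    nperseg = max(int(round(cfg.window_s * fs)), 8)
    hop = max(int(round(nperseg * (1 - cfg.overlap))), 1)
    win = get_window("hann", nperseg)
    sft = ShortTimeFFT(win, hop=hop, fs=fs)
    z = sft.stft(x)
    freqs = sft.f
    sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    return float(np.sum(np.abs(z[sel]) ** 2))


def segment_spectral_energy(
    rec: ScgRecording,
    seg_len_s: float = 10.0,
    band_hz: tuple[float, float] = (2.0, 25.0),
    stft_cfg: StftConfig | None = None,
) -> np.ndarray:
    """Spectral energy of each full ``seg_len_s`` segment (channels summed).

    The final partial segment is dropped; a recording shorter than one
    segment yields a single whole-recording value with a warning.
    """
    stft_cfg = stft_cfg or StftConfig()
    seg_len = int(round(seg_len_s * rec.fs))
    n_segments = rec.n_samples // seg_len
    if n_segments == 0:
        log.warning(
            "recording shorter than one %g s segment; using whole recording",
            seg_len_s,
        )
        segments = [rec.data]
    else:
        segments = [
            rec.data[:, i * seg_len : (i + 1) * seg_len] for i in range(n_segments)
        ]
    energies = np.array(
        [
            sum(_stft_band_energy(seg[c], rec.fs, band_hz, stft_cfg) for c in range(3))
            for seg in segments
        ]
    )
    return energies


def flag_artifacts(
    energies: np.ndarray,
    ratio_threshold: float = 5.0,
    seg_len_s: float = 10.0,
) -> ArtifactFlags:
    """Flag segments whose energy strictly exceeds threshold x minimum."""
    energies = np.asarray(energies, dtype=np.float64)
    if energies.size == 0:
        return ArtifactFlags([], energies, np.zeros(0, dtype=bool), ratio_threshold)
    if energies.size < 2:
        log.warning(
            "fewer than 2 segments: recording cannot self-normalise; no flags"
        )
        flags = np.zeros(energies.size, dtype=bool)
    else:
        flags = energies > ratio_threshold * energies.min()
    bounds = [(i * seg_len_s, (i + 1) * seg_len_s) for i in range(energies.size)]
    return ArtifactFlags(bounds, energies, flags, ratio_threshold)
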