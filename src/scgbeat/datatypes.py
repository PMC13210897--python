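"""Core containers shared across the pipeline.

All containers are thin, validated wrappers around NumPy arrays.  Times are
seconds on a common recording timeline; sampling rates are Hz; accelerations
are in arbitrary sensor units (the pipeline is scale-free after
normalisation).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ScgRecording",
    "BeatAnnotation",
    "SampleMask",
    "IbiSeries",
    "MatchResult",
    "GOOD",
    "CORRECTED",
    "EXCLUDED",
]

# Inter-beat-interval quality flags.
GOOD = 0
CORRECTED = 1
EXCLUDED = 2


@dataclass
class ScgRecording:
    """Uniformly sampled tri-axial acceleration signal.

    Parameters
    ----------
    data
        Array of shape ``(3, n_samples)`` holding the x, y, z channels.
    fs
        Sampling rate in Hz.
    t0
        Time of the first sample on the recording timeline, seconds.
    channel_names
        Channel identifiers, by convention ``("x", "y", "z")``.
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0
    channel_names: tuple[str, ...] = ("x", "y", "z")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != 3:
            raise ValueError(
                f"data must have shape (3, n_samples); got {self.data.shape}"
            )
        if self.data.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive; got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Per-sample times in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class BeatAnnotation:
    """Ordered heartbeat event times in seconds."""

    times_s: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=np.float64).ravel()
        if self.times_s.size:
            if np.any(self.times_s < 0):
                raise ValueError("beat times must be non-negative")
            if np.any(np.diff(self.times_s) <= 0):
                raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return self.times_s.size


@dataclass
class SampleMask:
    """Per-sample heartbeat label (binary) or probability sequence."""

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size < 1:
            raise ValueError("mask must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive; got {self.fs}")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("mask values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


@dataclass
class IbiSeries:
    """Inter-beat intervals with per-interval quality flags.

    ``onsets_s[k]`` is the time of the beat opening interval ``k``;
    ``intervals_s[k]`` is its duration.  Flags take the values
    :data:`GOOD`, :data:`CORRECTED` or :data:`EXCLUDED`.
    """

    onsets_s: np.ndarray
    intervals_s: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=np.float64).ravel()
        self.intervals_s = np.asarray(self.intervals_s, dtype=np.float64).ravel()
        if self.flags is None:
            self.flags = np.full(self.intervals_s.size, GOOD, dtype=np.int8)
        else:
            self.flags = np.asarray(self.flags, dtype=np.int8).ravel()
        if not (
            self.onsets_s.size == self.intervals_s.size == self.flags.size
        ):
            raise ValueError("onsets, intervals and flags must be equal length")
        if self.intervals_s.size:
            if np.any(self.intervals_s <= 0):
                raise ValueError("intervals must be positive")
            if np.any(np.diff(self.onsets_s) <= 0):
                raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return self.intervals_s.size

    @property
    def span_s(self) -> float:
        """Total time covered by the series (sum of intervals)."""
        return float(self.intervals_s.sum())

    def good(self) -> np.ndarray:
        """Boolean mask of intervals that are neither corrected nor excluded."""
        return self.flags == GOOD


@dataclass
class MatchResult:
    """One-to-one pairing of predicted vs reference beats."""

    pairs: list[tuple[float, float]]
    tp: int
    fp: int
    fn: int
    tolerance_s: float = 0.1

    def __post_init__(self) -> None:
        if self.tp != len(self.pairs):
            raise ValueError("tp must equal the number of pairs")
        for p, r in self.pairs:
            if abs(p - r) > self.tolerance_s + 1e-12:
                raise ValueError("pair outside tolerance")


def as_beats(times: Sequence[float] | BeatAnnotation) -> BeatAnnotation:
    """Coerce a sequence of times into a :class:`BeatAnnotation`."""
    if isinstance(times, BeatAnnotation):
        return times
    return BeatAnnotation(np.asarray(times, dtype=np.float64))
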