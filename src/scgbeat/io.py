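"""Plain-text readers and writers for recordings, beats, RR series, masks,
HR series and artifact flags.

Formats are deliberately simple columnar text so fixtures stay
human-readable and round-trip exactly:

* recording: ``time_s x y z`` rows (tab-separated, ``#`` header);
* beats: one beat time (seconds) per line;
* RR: one interval (ms) per line, optional ``# anchor_s: <v>`` header;
* HR: CSV ``window_center_s,hr_bpm,effective_fraction``;
* artifact flags: BED-like ``start_s<TAB>end_s<TAB>flag`` rows.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import BeatAnnotation, SampleMask, ScgRecording
from .heart_rate import HrSeries
from .labels import RrSeries

__all__ = [
    "write_recording",
    "read_recording",
    "write_beats",
    "read_beats",
    "write_rr",
    "read_rr",
    "write_mask",
    "read_mask",
    "write_hr",
    "read_hr",
    "write_artifact_flags",
    "read_artifact_flags",
]


def write_recording(rec: ScgRecording, path: str | Path) -> None:
    t = rec.times()
    arr = np.column_stack([t, rec.data.T])
    np.savetxt(
        path,
        arr,
        fmt="%.6f",
        delimiter="\t",
        header="time_s\t" + "\t".join(rec.channel_names),
    )


def read_recording(path: str | Path) -> ScgRecording:
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError(f"{path}: expected 4 columns (time_s, x, y, z)")
    t = arr[:, 0]
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise ValueError(f"{path}: timestamps must be strictly increasing")
    med_dt = float(np.median(dt))
    if np.any(np.abs(dt - med_dt) > 0.01 * med_dt):
        raise ValueError(f"{path}: non-uniform sampling; resample first")
    return ScgRecording(arr[:, 1:].T, fs=1.0 / med_dt, t0=float(t[0]))


def write_beats(beats: BeatAnnotation, path: str | Path) -> None:
    np.savetxt(path, beats.times_s, fmt="%.6f")


def read_beats(path: str | Path) -> BeatAnnotation:
    arr = np.loadtxt(path, ndmin=1)
    return BeatAnnotation(arr)


def write_rr(rr: RrSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# anchor_s: {rr.anchor_s:.6f}\n")
        for v in rr.intervals_ms:
            fh.write(f"{v:.3f}\n")


def read_rr(path: str | Path) -> RrSeries:
    anchor = 0.0
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "anchor_s" in line:
                    anchor = float(line.split(":", 1)[1])
                continue
            intervals.append(float(line))
    return RrSeries(np.asarray(intervals), anchor_s=anchor)


def write_mask(mask: SampleMask, path: str | Path) -> None:
    """Binary masks are stored run-length encoded; probability masks as
    one value per line.  The header records fs, t0 and the encoding."""
    binary = np.all(np.isin(mask.values, (0.0, 1.0)))
    with open(path, "w") as fh:
        fh.write(f"# fs: {mask.fs}\n# t0: {mask.t0}\n")
        fh.write(f"# n: {mask.n_samples}\n")
        if binary:
            fh.write("# encoding: runs\n")
            padded = np.concatenate([[0.0], mask.values, [0.0]])
            d = np.diff(padded)
            starts = np.flatnonzero(d == 1)
            ends = np.flatnonzero(d == -1)
            for s, e in zip(starts, ends):
                fh.write(f"{s}\t{e}\n")
        else:
            fh.write("# encoding: dense\n")
            for v in mask.values:
                fh.write(f"{v:.6f}\n")


def read_mask(path: str | Path) -> SampleMask:
    meta: dict[str, str] = {}
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                k, v = line[1:].split(":", 1)
                meta[k.strip()] = v.strip()
            else:
                rows.append(line)
    fs, t0, n = float(meta["fs"]), float(meta["t0"]), int(meta["n"])
    if meta["encoding"] == "runs":
        values = np.zeros(n)
        for row in rows:
            s, e = (int(v) for v in row.split())
            values[s:e] = 1.0
    else:
        values = np.asarray([float(r) for r in rows])
    return SampleMask(values, fs=fs, t0=t0)


def write_hr(hr: HrSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "window_center_s": hr.window_centers_s,
            "hr_bpm": hr.hr_bpm,
            "effective_fraction": hr.effective_fraction,
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_hr(path: str | Path) -> HrSeries:
    df = pd.read_csv(path)
    return HrSeries(
        df["window_center_s"].to_numpy(),
        df["hr_bpm"].to_numpy(),
        df["effective_fraction"].to_numpy(),
    )


def write_artifact_flags(flags, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ratio_threshold: {flags.ratio_threshold}\n")
        for (s, e), en, fl in zip(
            flags.segment_bounds_s, flags.energies, flags.flags
        ):
            fh.write(f"{s:.3f}\t{e:.3f}\t{int(fl)}\t{en:.6e}\n")


def read_artifact_flags(path: str | Path):
    from .artifacts import ArtifactFlags

    bounds, energies, flag_vals = [], [], []
    thr = 5.0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                thr = float(line.split(":", 1)[1])
                continue
            s, e, fl, en = line.split("\t")
            bounds.append((float(s), float(e)))
            flag_vals.append(bool(int(fl)))
            energies.append(float(en))
    return ArtifactFlags(
        bounds, np.asarray(energies), np.asarray(flag_vals), thr
    )
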