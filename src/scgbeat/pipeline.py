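"""Configuration schema and stage runner binding the pipeline together.

``PipelineConfig`` aggregates every stage's parameters with defaults equal
to the reference protocol's values; ``run_pipeline`` executes the stages
(simulate -> preprocess -> train -> detect -> hr -> artifacts -> evaluate)
independently or end to end, writing each stage's outputs plus a manifest
(config hash, seed, versions) for reproducibility.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as scgio
from .artifacts import flag_artifacts, segment_spectral_energy
from .detect import DetectionParams, localize_beats
from .evaluate import detection_metrics, hr_agreement, match_beats
from .experiments import make_segment_batch
from .heart_rate import beats_to_ibi, correct_ibi, estimate_hr
from .model import (
    TrainConfig,
    UNetConfig,
    build_network,
    load_model,
    predict_proba,
    save_model,
    train,
)
from .preprocess import PreprocessParams, preprocess_recording
from .sim import ArtifactConfig, SimConfig, inject_motion, simulate_recording

__all__ = ["PipelineConfig", "HrParams", "ArtifactParams", "run_pipeline"]

log = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "preprocess",
    "train",
    "detect",
    "hr",
    "artifacts",
    "evaluate",
)


@dataclass
class HrParams:
    window_s: float = 20.0
    step_s: float | None = None
    min_effective: float = 0.5


@dataclass
class ArtifactParams:
    seg_len_s: float = 10.0
    ratio_threshold: float = 5.0
    band_low_hz: float = 2.0
    band_high_hz: float = 25.0


@dataclass
class TrainStageParams:
    """Sizes of the synthetic training study run by the train stage."""

    n_train_segments: int = 300
    n_val_segments: int = 48
    max_epochs: int = 12


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    unet: UNetConfig = field(default_factory=UNetConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    hr: HrParams = field(default_factory=HrParams)
    artifacts: ArtifactParams = field(default_factory=ArtifactParams)
    train_stage: TrainStageParams = field(default_factory=TrainStageParams)
    motion: ArtifactConfig | None = None
    eval_tolerance_s: float = 0.1
    seed: int = 0
    out_dir: str = "scgbeat_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        section_types = {
            "sim": SimConfig,
            "preprocess": PreprocessParams,
            "unet": UNetConfig,
            "training": TrainConfig,
            "detection": DetectionParams,
            "hr": HrParams,
            "artifacts": ArtifactParams,
            "train_stage": TrainStageParams,
            "motion": ArtifactConfig,
        }
        kwargs = {}
        valid_top = {f.name for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if key not in valid_top:
                raise ValueError(f"unknown config section or field: {key!r}")
            if key in section_types and isinstance(value, dict):
                typ = section_types[key]
                valid = {f.name for f in dataclasses.fields(typ)}
                for sub in value:
                    if sub not in valid:
                        raise ValueError(
                            f"unknown field {sub!r} in section {key!r}"
                        )
                # YAML lists -> tuples for tuple-typed fields
                value = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in value.items()
                }
                kwargs[key] = typ(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir", None)  # hash the science, not the destination
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(cfg: PipelineConfig, out: Path, stage: str,
                    elapsed_s: float) -> None:
    import scgbeat

    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {
            "scgbeat": scgbeat.__version__,
            "numpy": np.__version__,
        },
        "elapsed_s": round(elapsed_s, 3),
    }
    with open(out / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_pipeline(cfg: PipelineConfig, stage: str = "all") -> Path:
    """Run one stage or all stages; returns the output directory.

    Stage inputs are read from the output directory, so stages can be run
    independently once their upstream artifacts exist.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = STAGES if stage == "all" else (stage,)
    for st in stages:
        if st not in STAGES:
            raise ValueError(f"unknown stage {st!r}; choose from {STAGES}")
        t0 = time.perf_counter()
        _run_stage(cfg, st, out)
        _write_manifest(cfg, out, st, time.perf_counter() - t0)
        log.info("stage %s done in %.2f s", st, time.perf_counter() - t0)
    return out


def _require(path: Path, hint: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path.name}: run the {hint} stage first"
        )
    return path


def _run_stage(cfg: PipelineConfig, stage: str, out: Path) -> None:
    if stage == "simulate":
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
        rec, beats = simulate_recording(sim_cfg)
        intervals: list[tuple[float, float]] = []
        if cfg.motion is not None:
            rec, intervals = inject_motion(rec, cfg.motion)
        scgio.write_recording(rec, out / "recording.tsv")
        scgio.write_beats(beats, out / "reference.beats")
        with open(out / "motion_intervals.json", "w") as fh:
            json.dump(intervals, fh)

    elif stage == "preprocess":
        rec = scgio.read_recording(_require(out / "recording.tsv", "simulate"))
        rec = preprocess_recording(rec, cfg.preprocess)
        scgio.write_recording(rec, out / "preprocessed.tsv")

    elif stage == "train":
        ts = cfg.train_stage
        train_batch = make_segment_batch(
            ts.n_train_segments, seed=cfg.seed * 1000 + 1, unet_cfg=cfg.unet,
            base=cfg.sim,
        )
        val_batch = make_segment_batch(
            ts.n_val_segments, seed=cfg.seed * 1000 + 2, unet_cfg=cfg.unet,
            base=cfg.sim,
        )
        net = build_network(cfg.unet, seed=cfg.seed)
        tc = dataclasses.replace(
            cfg.training, seed=cfg.seed, max_epochs=ts.max_epochs
        )
        history = train(net, train_batch, val_batch, tc)
        save_model(net, str(out / "model.npz"))
        import pandas as pd

        pd.DataFrame(history).to_csv(out / "training_history.csv", index=False)

    elif stage == "detect":
        net = load_model(str(_require(out / "model.npz", "train")))
        rec = scgio.read_recording(
            _require(out / "preprocessed.tsv", "preprocess")
        )
        prob = predict_proba(net, rec)
        scgio.write_mask(prob, out / "probability.mask")
        beats = localize_beats(prob, cfg.detection)
        scgio.write_beats(beats, out / "detected.beats")

    elif stage == "hr":
        beats = scgio.read_beats(_require(out / "detected.beats", "detect"))
        ibi = correct_ibi(beats_to_ibi(beats))
        hr = estimate_hr(
            ibi, window_s=cfg.hr.window_s, step_s=cfg.hr.step_s,
            min_effective=cfg.hr.min_effective,
        )
        scgio.write_hr(hr, out / "hr.csv")

    elif stage == "artifacts":
        rec = scgio.read_recording(_require(out / "recording.tsv", "simulate"))
        energies = segment_spectral_energy(
            rec,
            seg_len_s=cfg.artifacts.seg_len_s,
            band_hz=(cfg.artifacts.band_low_hz, cfg.artifacts.band_high_hz),
        )
        flags = flag_artifacts(
            energies, cfg.artifacts.ratio_threshold, cfg.artifacts.seg_len_s
        )
        scgio.write_artifact_flags(flags, out / "artifacts.bed")

    elif stage == "evaluate":
        pred = scgio.read_beats(_require(out / "detected.beats", "detect"))
        ref = scgio.read_beats(_require(out / "reference.beats", "simulate"))
        m = match_beats(pred, ref, tolerance_s=cfg.eval_tolerance_s)
        dm = detection_metrics(m)

        est_hr = estimate_hr(
            correct_ibi(beats_to_ibi(pred)), window_s=cfg.hr.window_s,
            step_s=cfg.hr.step_s, min_effective=cfg.hr.min_effective,
        )
        ref_hr = estimate_hr(
            beats_to_ibi(ref), window_s=cfg.hr.window_s, step_s=cfg.hr.step_s,
            min_effective=cfg.hr.min_effective,
        )
        agreement = hr_agreement(est_hr, ref_hr)
        report = {
            "counts": {"tp": m.tp, "fp": m.fp, "fn": m.fn},
            "ppv": dm.ppv,
            "sensitivity": dm.sensitivity,
            "f1": dm.f1,
            "tolerance_s": cfg.eval_tolerance_s,
            "hr_agreement": asdict(agreement) if agreement else None,
        }
        with open(out / "metrics.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
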