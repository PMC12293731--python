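"""End-to-end pipeline runs: simulate -> screen -> detect -> volume -> evaluate.

A run is described by a :class:`RunConfig` (parsed from a plain ``key: value``
text file) and executes its stages in dependency order into a run
directory.  Every output JSON carries the config hash and the seed that
produced it; rerunning the same config into a fresh directory reproduces
byte-identical files.  The global seed is fanned out to per-stage sub-seeds
by stage-name hashing, so adding a stage never shifts another stage's
randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import metrics as M
from . import volumetrics as V
from .expert import ExpertRule, detect_expert
from .lstm import LstmConfig, load_model, predict_lstm, save_model, train_lstm
from .screening import ScreeningRule, evaluate_screening, screen_signal
from .signal_extraction import read_signal_table
from .synthetic import CohortSpec, read_manifest, simulate_cohort, write_cohort
from .types import BoundaryInterval

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "stage_seed"]

_KNOWN_STAGES = ("simulate", "screen", "detect-expert", "train-lstm",
                 "detect-lstm", "volume", "evaluate")


class PipelineError(RuntimeError):
    """A stage could not run; the message names the missing artifact."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived by stage-name hashing."""
    h = zlib.crc32(stage.encode())
    return int(np.random.SeedSequence((int(global_seed), h)).generate_state(1)[0])


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "aaaquant_run"
    stages: tuple[str, ...] = ("simulate", "screen", "detect-expert",
                               "volume", "evaluate")
    detector: str = "expert"  # which predictions feed volume/evaluate
    cohort: dict = field(default_factory=dict)
    screening: dict = field(default_factory=dict)
    expert: dict = field(default_factory=dict)
    lstm: dict = field(default_factory=dict)
    signals_dir: Optional[str] = None  # input signals when not simulating
    lstm_weights: Optional[str] = None

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(_KNOWN_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if self.detector not in ("expert", "lstm"):
            raise ValueError("detector must be 'expert' or 'lstm'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_json(path: Path, payload: dict, meta: dict) -> None:
    with open(path, "w") as fh:
        json.dump({**meta, **payload}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _load_signals(directory: Path, manifest: pd.DataFrame):
    signals = {}
    for pid in manifest.patient_id:
        csv = directory / f"{pid}.csv"
        if not csv.exists():
            raise PipelineError(f"missing signal file {csv}")
        signals[pid] = read_signal_table(csv, patient_id=pid)
    return signals


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.config_hash(), "seed": config.seed}

    signals_dir = out / "signals"
    if "simulate" in config.stages:
        spec = CohortSpec(**config.cohort, seed=stage_seed(config.seed, "simulate"))
        cohort = simulate_cohort(spec)
        write_cohort(cohort, signals_dir)
    elif config.signals_dir is not None:
        signals_dir = Path(config.signals_dir)

    manifest_path = signals_dir / "manifest.csv"
    if not manifest_path.exists():
        raise PipelineError(f"missing cohort manifest {manifest_path}")
    manifest = read_manifest(manifest_path)
    signals = _load_signals(signals_dir, manifest)
    truths = {
        r.patient_id: None if r.start < 0 else BoundaryInterval(int(r.start), int(r.end))
        for r in manifest.itertuples()
    }

    if "screen" in config.stages:
        rule = ScreeningRule(**config.screening)
        results = {pid: screen_signal(sig, rule) for pid, sig in signals.items()}
        payload = {
            "results": {
                pid: {
                    "is_aneurysm": res.is_aneurysm,
                    "start": res.anomaly.start if res.anomaly else None,
                    "end": res.anomaly.end if res.anomaly else None,
                }
                for pid, res in results.items()
            }
        }
        cm = evaluate_screening(
            [(results[pid], bool(truths[pid] is not None)) for pid in results]
        )
        payload["confusion"] = {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
        payload["metrics"] = M.classification_metrics(cm)
        _write_json(out / "screening.json", payload, meta)

    predictions: dict[str, Optional[BoundaryInterval]] = {}
    if "detect-expert" in config.stages:
        rule = ExpertRule(**config.expert)
        predictions = {pid: detect_expert(sig, rule) for pid, sig in signals.items()}
        _write_json(out / "predictions_expert.json", {
            "detector": "expert",
            "predictions": {
                pid: None if p is None else {"start": p.start, "end": p.end}
                for pid, p in predictions.items()
            },
        }, meta)

    trained = None
    if "train-lstm" in config.stages:
        cfg = LstmConfig(**config.lstm, seed=stage_seed(config.seed, "train-lstm"))
        annotated = [(signals[pid], truths[pid]) for pid in signals]
        trained = train_lstm(annotated, cfg)
        save_model(trained, out / "lstm_weights.npz")
        trained.log.to_csv(out / "lstm_training_log.csv", index=False)
    if "detect-lstm" in config.stages:
        if trained is None:
            if config.lstm_weights is None:
                raise PipelineError(
                    "detect-lstm needs trained weights: add a train-lstm stage "
                    "or set lstm_weights"
                )
            weights = Path(config.lstm_weights)
            if not weights.exists():
                raise PipelineError(f"missing LSTM weights file {weights}")
            trained = load_model(weights)
        lstm_preds = {pid: predict_lstm(trained, sig)[1] for pid, sig in signals.items()}
        _write_json(out / "predictions_lstm.json", {
            "detector": "lstm",
            "predictions": {
                pid: None if p is None else {"start": p.start, "end": p.end}
                for pid, p in lstm_preds.items()
            },
        }, meta)
        if config.detector == "lstm":
            predictions = lstm_preds

    if "volume" in config.stages:
        if not predictions:
            raise PipelineError(
                f"volume stage needs predictions from detect-{config.detector}"
            )
        reports = {
            pid: V.volume_report(signals[pid], interval)
            for pid, interval in predictions.items()
            if interval is not None
        }
        payload = {
            "reports": {
                pid: {
                    "observed_volume": r.observed_volume,
                    "baseline_volume": r.baseline_volume,
                    "enlargement_pct": r.enlargement_pct,
                    "start": r.interval.start,
                    "end": r.interval.end,
                }
                for pid, r in reports.items()
            }
        }
        if reports:
            payload["cohort"] = V.cohort_enlargement_stats(list(reports.values()))
        _write_json(out / "volumes.json", payload, meta)

    if "evaluate" in config.stages:
        if not predictions:
            raise PipelineError(
                f"evaluate stage needs predictions from detect-{config.detector}"
            )
        pids = [pid for pid in predictions if truths[pid] is not None]
        if not pids:
            raise PipelineError("no annotated patients to evaluate against")
        preds = [predictions[pid] for pid in pids]
        gts = [truths[pid] for pid in pids]
        vols_true = [V.surrogate_volume(signals[pid], truths[pid]) for pid in pids]
        vols_pred = [
            V.surrogate_volume(signals[pid], predictions[pid])
            if predictions[pid] is not None else float("nan")
            for pid in pids
        ]
        table = M.boundary_report(preds, gts, vols_pred, vols_true,
                                  detector=config.detector)
        table.to_csv(out / "report.csv", index=False)
        _write_json(out / "metrics.json",
                    {"report": table.iloc[0].to_dict()}, meta)

    return out
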