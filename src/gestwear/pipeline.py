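"""End-to-end orchestration: simulate -> HAR -> gestures -> features -> correlate.

The pipeline is a pure function of (config, seed): rerunning with the same
configuration produces byte-identical feature and correlation tables.  A
run manifest records package and dependency versions, the seed, a config
hash and output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import score_effort_choice
from .errors import ConfigError, PipelineError
from .features import build_feature_vector
from .gesture import GestureConfig, detect_gesture_events, events_to_frame, magnitude
from .har import ClassifierSpec, SplitProtocol, evaluate_model, train_classifier, window_signal
from .stats import correlation_table
from .synthetic import CohortConfig, generate_cohort, generate_har_training_set

log = logging.getLogger("gestwear")

_REQUIRED = {
    "seed": (),
    "simulate": ("n_patients", "days_per_patient"),
    "har": ("duration_s", "stride_s", "classifier"),
    "gesture": ("sd_threshold_g", "window_s", "max_gap_s"),
    "features": ("min_wear_h",),
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``examples`` in the README).

    Every scientific threshold (SD threshold, window, gap rule, valid-day
    wear minimum) must be stated explicitly in the config file; validation
    happens before any computation.
    """

    raw: dict

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        for section, keys in _REQUIRED.items():
            if section not in raw:
                raise ConfigError(f"config missing section {section!r}")
            for key in keys:
                if not isinstance(raw[section], dict) or key not in raw[section]:
                    raise ConfigError(f"config missing {section}.{key}")
        return cls(raw=raw)

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=True)

    def sha256(self) -> str:
        return hashlib.sha256(self.canonical_yaml().encode()).hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*a, **k):
            log.info("stage %s: start", name)
            try:
                return fn(*a, **k)
            except Exception as exc:  # halt with a stage-named diagnostic
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Execute all stages and write ``features.csv``, ``table.csv`` and
    ``manifest.json`` under ``out_dir``.  Returns the output paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    s_cohort, s_har, s_split = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))

    sim = cfg.raw["simulate"]
    cohort = _stage("simulate")(generate_cohort)(
        CohortConfig(
            n_patients=int(sim["n_patients"]),
            days_per_patient=int(sim["days_per_patient"]),
            min_wear_h=float(cfg.raw["features"]["min_wear_h"]),
            seed=s_cohort,
        ),
        with_recordings=True,
    )

    model, labels_by_patient = _stage("har")(_train_and_predict)(cfg, cohort, s_har, s_split)

    gcfg = GestureConfig(
        sd_threshold_g=float(cfg.raw["gesture"]["sd_threshold_g"]),
        window_s=float(cfg.raw["gesture"]["window_s"]),
        max_gap_s=float(cfg.raw["gesture"]["max_gap_s"]),
    )
    min_wear_h = float(cfg.raw["features"]["min_wear_h"])

    rows = []
    for pid in sorted(cohort.recordings):
        rec = cohort.recordings[pid]
        labels = labels_by_patient[pid]
        events = _stage("gestures")(detect_gesture_events)(
            magnitude(rec), rec.time_s, labels.sample_code, rec.sample_rate_hz, gcfg
        )
        fv = _stage("features")(build_feature_vector)(rec, labels, events, min_wear_h)
        rows.append(fv.to_dict())
    features_df = pd.DataFrame(rows)

    effort = (
        cohort.trials.groupby("patient_id", sort=True)
        .apply(score_effort_choice, include_groups=False)
        .rename("high_effort_pct")
        .reset_index()
    )
    table_input = features_df.merge(cohort.scores, on="patient_id").merge(effort, on="patient_id")
    bh = bool(cfg.raw.get("correlate", {}).get("bh_correction", False))
    table = _stage("correlate")(correlation_table)(table_input, bh_correction=bh)

    paths = {
        "features": out / "features.csv",
        "table": out / "table.csv",
        "manifest": out / "manifest.json",
        "scores": out / "scores.csv",
        "trials": out / "trials.csv",
    }
    features_df.to_csv(paths["features"], index=False)
    table.to_csv(paths["table"], index=False)
    cohort.scores.to_csv(paths["scores"], index=False)
    cohort.trials.to_csv(paths["trials"], index=False)

    manifest = {
        "gestwear": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config_sha256": cfg.sha256(),
        "n_patients": int(sim["n_patients"]),
        "outputs": {
            k: hashlib.sha256(paths[k].read_bytes()).hexdigest()
            for k in ("features", "table")
        },
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("pipeline complete: %s", out)
    return paths


def _train_and_predict(cfg: PipelineConfig, cohort, s_har: int, s_split: int):
    har_cfg = cfg.raw["har"]
    spec = ClassifierSpec(kind=str(har_cfg["classifier"]), seed=s_har)
    windowsets, sources = generate_har_training_set(
        n_per_source=int(har_cfg.get("subjects_per_source", 9)),
        minutes=float(har_cfg.get("train_minutes_per_subject", 20.0)),
        seed=s_har,
        duration_s=float(har_cfg["duration_s"]),
        stride_s=float(har_cfg["stride_s"]),
    )
    split = SplitProtocol.leave_one_out_per_source(sources, seed=s_split)
    model, val_report = train_classifier(windowsets, spec, split)
    test_sets = [ws for ws in windowsets if ws.patient_id in split.test]
    test_report = evaluate_model(model, test_sets)
    log.info(
        "HAR val binary acc %.3f, test binary acc %.3f",
        val_report.binary_accuracy if val_report else float("nan"),
        test_report.binary_accuracy,
    )
    labels = {}
    for pid in sorted(cohort.recordings):
        ws = window_signal(
            cohort.recordings[pid],
            duration_s=float(har_cfg["duration_s"]),
            stride_s=float(har_cfg["stride_s"]),
        )
        labels[pid] = model.predict_windows(ws)
    return model, labels
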