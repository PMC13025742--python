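"""One-command reproducible runs: simulate -> preprocess -> split -> train
-> evaluate, with per-stage seeds derived from a single master seed and
every intermediate artifact persisted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import classify as _classify
from . import dataset as _dataset
from . import evaluate as _evaluate
from .exceptions import ActScreenError, ConfigError, PipelineStageError
from .io import write_recording
from .preprocess import PreprocessConfig
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["CohortConfig", "RunConfig", "derive_seed", "run_all"]

logger = logging.getLogger(__name__)

_STAGE_INDEX = {"simulate": 0, "preprocess": 1, "split": 2, "train": 3,
                "evaluate": 4}


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31) from the master seed."""
    if stage not in _STAGE_INDEX:
        raise ConfigError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(master, spawn_key=(_STAGE_INDEX[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and per-recording physics for a simulated run."""

    n_normal: int = 25
    n_exo: int = 18
    n_eso: int = 7
    n_hyper: int = 0
    samples_per_participant_range: tuple = (3, 7)
    amplitude_range: tuple = (0.05, 0.15)
    duration_s: float = 10.0
    sample_rate_hz: float = 60.0
    cover_dwell_range_s: tuple = (3.0, 6.0)
    noise_sd: float = 0.01
    invalid_frame_prob: float = 0.02

    def base_simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            duration_s=self.duration_s,
            sample_rate_hz=self.sample_rate_hz,
            cover_dwell_range_s=tuple(self.cover_dwell_range_s),
            noise_sd=self.noise_sd,
            invalid_frame_prob=self.invalid_frame_prob,
        )


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of an end-to-end run; round-trips through YAML."""

    seed: int = 0
    out_dir: str = "actscreen_run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    test_fraction: float = 0.12
    min_confidence: float = 0.25
    min_class_count: int = 5
    models: tuple = _classify.MODEL_NAMES
    feature_sets: tuple = ("raw", "preprocessed")
    acquisitions: tuple = ("multi",)
    folds: int = 5
    write_recordings: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("models", "feature_sets", "acquisitions"):
            d[key] = list(d[key])
        d["cohort"]["samples_per_participant_range"] = list(
            d["cohort"]["samples_per_participant_range"])
        d["cohort"]["amplitude_range"] = list(d["cohort"]["amplitude_range"])
        d["cohort"]["cover_dwell_range_s"] = list(
            d["cohort"]["cover_dwell_range_s"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        for key in ("samples_per_participant_range", "amplitude_range",
                    "cover_dwell_range_s"):
            if key in cohort:
                cohort[key] = tuple(cohort[key])
        pre = d.pop("preprocess", {})
        for key in ("models", "feature_sets", "acquisitions"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(cohort=CohortConfig(**cohort),
                   preprocess=PreprocessConfig(**pre), **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    """Decorator-free stage guard: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_all(config: RunConfig) -> tuple[_evaluate.DiagnosticReport, dict]:
    """Execute every stage in order, persisting all intermediate artifacts.

    Returns the diagnostic report and a dict of artifact paths.  Artifacts
    written before a failure are left on disk for inspection; the raised
    :class:`PipelineStageError` names the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    with _stage("simulate"):
        cc = config.cohort
        lo, hi = cc.amplitude_range
        cohort = simulate_cohort(
            cc.n_normal, cc.n_exo, cc.n_eso, cc.n_hyper,
            samples_per_participant_range=tuple(cc.samples_per_participant_range),
            amplitude_distribution=lambda rng: float(rng.uniform(lo, hi)),
            seed=derive_seed(config.seed, "simulate"),
            base_config=cc.base_simulation_config(),
        )
        artifacts["cohort_manifest"] = out / "cohort_manifest.csv"
        cohort.manifest.to_csv(artifacts["cohort_manifest"], index=False)
        if config.write_recordings:
            rec_dir = out / "recordings"
            rec_dir.mkdir(exist_ok=True)
            for rec in cohort.recordings:
                write_recording(rec, rec_dir / f"{rec.sample_id}.csv")
            artifacts["recordings"] = rec_dir

    with _stage("preprocess"):
        table = _dataset.build_sample_table(cohort, config.preprocess)
        for fs in config.feature_sets:
            p = out / f"features_{fs}.csv"
            _dataset.write_features(table, p, feature_set=fs)
            artifacts[f"features_{fs}"] = p

    with _stage("split"):
        retained = _dataset.quality_filter(table, config.min_confidence)
        retained = _dataset.exclude_rare_classes(retained, config.min_class_count)
        split = _dataset.participant_split(
            retained, config.test_fraction, derive_seed(config.seed, "split")
        )
        artifacts["split"] = out / "split.json"
        artifacts["split"].write_text(json.dumps(split.to_dict(), indent=2))

    with _stage("train"):
        specs = _classify.default_model_specs(tuple(config.models))
        bench = _classify.run_benchmark(
            retained, split, specs,
            feature_sets=tuple(config.feature_sets),
            acquisitions=tuple(config.acquisitions),
            folds=config.folds,
            seed=derive_seed(config.seed, "train"),
        )
        artifacts["benchmark"] = out / "benchmark.csv"
        bench.table.to_csv(artifacts["benchmark"], index=False)

    with _stage("evaluate"):
        rep = _evaluate.report(bench, retained, split)
        artifacts["report_json"] = out / "report.json"
        artifacts["report_json"].write_text(rep.to_json())
        artifacts["report_md"] = out / "report.md"
        artifacts["report_md"].write_text(rep.to_markdown())

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "actscreen_version": __version__,
        "stage_seeds": {s: derive_seed(config.seed, s) for s in _STAGE_INDEX},
        "artifacts": {k: str(v) for k, v in artifacts.items()},
    }
    path = out / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["run_manifest"] = path
    logger.info("run complete; artifacts in %s", out)
    return rep, artifacts
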